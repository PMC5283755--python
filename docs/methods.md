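# Methods

## Model and assumptions

The observation model at each time bin is the pairwise maximum-entropy
(Ising) distribution over binary population patterns x ∈ {0,1}^N,
p(x|θ) = exp[θ′F(x) − ψ(θ)] with feature vector
F(x) = (x_1,…,x_N, x_1x_2,…,x_{N−1}x_N) and natural parameters ordered as
fields first, then couplings in lexicographic i<j order. The latent state
θ_t follows a Gaussian random walk with isotropic noise covariance
Q = λ⁻¹I; the initial state has prior N(μ, Σ).

Two assumptions do real work and should be kept in mind when interpreting
fits:

* **Quasistatic equilibrium** — each bin's patterns are i.i.d. samples
  from the instantaneous model, identical across trials. Spike-history
  dependence (refractoriness, bursting) violates this and is not modeled.
* **Across-trial stationarity** — the same θ trajectory underlies every
  trial. `spikedata.stationarity_filter` screens units for gross
  violations before fitting: per-trial mean rates are z-scored per unit
  (own across-trial mean/SD) and a unit is dropped when more than
  `alpha` (default 5%) of its trials fall outside the two-sided 95%
  normal bound. The confidence-interval construction is normal-theory; an
  empirical-quantile variant would differ only for very non-Gaussian rate
  distributions. Units with zero across-trial variance are retained (and
  logged) since the screen is undefined for them.

## Inference

Filtering follows the standard approximate recursive scheme: the
Chapman-Kolmogorov prediction (mean unchanged, covariance + λ⁻¹I), a
Laplace approximation of the posterior at each bin, and fixed-interval
(RTS) smoothing with gain A_t = W_{t|t} W_{t+1|t}⁻¹ and lag-one
cross-covariance A_t W_{t+1|T}. The approximate marginal likelihood sums,
per bin, the data term θ′ΣF − Rψ, the Gaussian prediction penalty, and the
log-determinant ratio of filter to prediction covariance.

The MAP step offers two likelihoods:

* **exact** — gradient ΣF − Rη(θ) with η from the selected engine
  (enumeration for small N);
* **pseudo** — the penalized pseudo-log-posterior built from each neuron's
  conditional likelihood. Each coupling θ_ij receives gradient
  contributions from both conditionals n=i and n=j.

Both are concave; optimization is L-BFGS warm-started at the prediction
mean, followed when needed by a safeguarded Newton polish with the
analytic Hessian until the gradient max-norm is below `tol` (default
1e-6). The Hessian of the pseudolikelihood assembles from one N×N block
per conditional, so the polish is cheap. Prior precision is always applied
through Cholesky solves; covariance factorizations use adaptive jitter
(1e-10 growing tenfold to at most 1e-6) before failing.

### Moment engines

The filter covariance update W_{t|t}⁻¹ = R·G + W_{t|t−1}⁻¹ and the
marginal likelihood need η, ψ, and a Fisher matrix G at the MAP point:

* **exact** — full enumeration over 2^N states (configurable cap,
  default N ≤ 20); G is the exact d×d Fisher information.
* **bethe** — damped synchronous belief propagation (damping 0.5, message
  tolerance 1e-10, 500 sweeps) on the fully connected pairwise field.
  When BP fails to settle, a convergent double-loop minimizer of the
  Bethe free energy takes over: the outer loop updates the singleton
  marginals by quasi-Newton in logit space, the inner loop solves each
  pairwise belief in closed form given the marginals (the consistency
  constraints therefore hold at every iterate, and the envelope theorem
  makes the outer gradient exact). ψ is read off the belief assigned to
  the all-silent pattern, ψ = −log q(0), with the singleton-belief
  exponent N−2 of the pairwise-factorized joint.
* **tap** — second-order Plefka expansion around the independent model,
  written for {0,1} variables. The self-consistent equations
  logit(η_i) = θ_i + Σθ_ij η_j + Σθ_ij²(1/2−η_i)(η_j−η_j²) are solved by
  damped fixed-point iteration with a Newton (hybr) fallback; the
  Onsager coefficients are those of the true second-order expansion
  (verified against the exact ψ of a two-neuron model, whose error then
  scales as the third power of the coupling strength). Non-convergence
  raises an explicit error — expected behavior at strong couplings or
  large N — and callers fall back to the Bethe engine.

For the approximate engines, G is taken diagonal with entries
η_k(1−η_k), the Bernoulli variance of each of the d features. This is the
only reading of a "first- and second-order expectation" diagonal that
keeps W a valid covariance, and it is documented as interpretive. A
consequence worth knowing: with a diagonal G and a diagonal initial Σ the
whole filter stays diagonal, which is what makes the method linear in d
per bin.

### Empirical Bayes

EM alternates filtering+smoothing with closed-form hyperparameter
updates: λ* = (T−1)d / tr Σ_t⟨(θ_t−θ_{t−1})(θ_t−θ_{t−1})′⟩ (the
expectation expanded with smoother means, covariances, and lag-one
cross-covariances) and μ* = θ_{1|T}; Σ stays fixed at its initial value.
μ is re-optimized every iteration (its update is the exact maximizer of
the expected complete-data log-likelihood, so there is no reason to
freeze it after one pass). Initialization: λ = 100, Σ = 10I, μ from the
independent-model fit to time- and trial-averaged rates with all
couplings zero. Convergence is declared when the marginal-likelihood
change falls below 1e-4·|value| (relative, so the criterion is scale-free
in the data size); with the exact engine a repeatedly decreasing
objective raises an error (it indicates a bug, since each Laplace
E-step/M-step pair should not lose evidence), with approximate engines it
only warns.

The stationary alternative fixes λ⁻¹ = 0 (the prediction covariance is
never inflated, so θ is constant in distribution) and skips the λ update.
Model comparison uses AIC = −2·l + 2k with k = d+1 for the dynamic model
(λ plus the d entries of μ) and k = d for the stationary one; Σ is fixed
in both and not counted. The counting convention matters only by ±1, far
below the AIC differences the comparison is meant to resolve.

## Macroscopic measures

All measures are evaluated from (θ, η, ψ) supplied by a moment engine,
normally at the smoothed means: population rate (1/N)Ση_i; silence
probability exp(−ψ); entropy S = −θ′η + ψ (nats); heat capacity by the
central second difference of ψ(βθ) at β = 1 with step ε = 1e-3 (second-
order accurate; halving ε moves C by less than a part in 10⁴ on smooth
models); entropy fraction (S_ind − S_pair)/S_ind with S_ind the Bernoulli
entropy at the same rates. Under exact moments the fraction is
non-negative (the independent model is the maximum-entropy distribution
at fixed rates); approximate engines can produce slightly negative
values, which are clipped only when a floor is explicitly requested, and
counted in the log.

Credible bands resample θ per bin from the Gaussian smoother density —
by default using the diagonal of W_{t|T} (full d×d covariances for
hundreds of parameters are storage-heavy and the full-covariance mode is
a flag), 100 draws, 1%/99% quantiles. Engine failures on individual draws
are resampled and counted; more than 20% failures per bin aborts.
Significant edges are couplings whose central Gaussian interval
θ ± z·sd excludes zero at the configured level (default 98%).

Entropy, heat capacity, and ψ are extensive: for block-independent
subpopulations they add (silence probabilities multiply), which the tests
exploit to validate large-population values against small-block oracles.

## Synthetic data

The generator emulates the evoked-activity protocol the method assumes:
`n_sub` mutually independent subpopulations of `n_per_sub` neurons
(defaults 4 × 10), T = 500 bins, each θ component an independent
squared-exponential Gaussian process (length-scale 50 bins; marginal SD
0.2 for fields, 0.15 for couplings) around its mean profile. Field means
follow a fast-rise/slow-decay double-exponential bump (onset bin 100,
rise constant 5 bins, decay 50 bins, amplitude +1.0) over a baseline of
−2.2, calibrated so time-averaged spike probabilities land in the
0.10–0.21 band typical of cortical recordings at 10 ms bins; coupling
means are zero. Spike tensors are sampled exactly per bin and trial, so
the quasistatic assumption holds by construction.

What passing tests on these data do **not** show: robustness to
history-dependent spiking, to across-trial drift, to non-Gaussian or
abrupt parameter changes, or to model mismatch in general — the generator
realizes exactly the model class the fitter assumes.

## Problem sizes and scaled-down protocols

Validation runs use deliberately small instances so the whole suite
reruns quickly on one CPU: enumeration oracles at N ≤ 10; single-bin MAP
comparisons at N = 10, R = 500; the full-pipeline recovery study at one
subpopulation of 10 neurons, T = 200, R = 300 (and 600 for the
data-scaling contrast) over 3 seeds; model-selection and surrogate
contrasts at N = 4–8 with T = 80–100. These preserve the structure of the
full protocol (the evoked bump, GP smoothness, weak couplings) at reduced
bin and trial counts. Where a short window is used, the bump onset is
moved proportionally early so the elevated-rate phase is represented.

## Numerical choices and degenerate inputs

* Binning uses half-open intervals [t0+kΔ, t0+(k+1)Δ); multiple spikes
  per bin collapse to 1; spikes outside the window are dropped and
  counted in a log message; out-of-range unit/trial ids are errors.
* All log quantities are in nats; log-sum-exp and log1p(exp) guard every
  exponential.
* The Bethe pair-belief quadratic is solved in the numerically stable
  root form 2a·η_iη_j/(b+√(b²+4Aaη_iη_j)) and clipped to the Fréchet
  interval.
* Beliefs or rates at exactly 0/1 are handled by entropy limits or small
  clips (1e-12 to 1e-15 scale); ψ from beliefs raises if the all-silent
  cell has zero mass.
* Sampling beyond the enumeration cap uses a seeded systematic-sweep
  Gibbs sampler (burn-in 100·N sweeps, thinning N sweeps) — conservative
  defaults for a path the standard protocol never exercises.
* Every stochastic entry point takes an explicit integer seed; there is
  no hidden global RNG state.

## Known limitations

* The pseudolikelihood and exact-likelihood posteriors have genuinely
  different modes when per-bin data are weak (low rates, few trials):
  with ~500 trials at rates ~0.08 the single-bin coupling MAPs can differ
  by ~0.1 per coordinate even though both are ~0.3 from the truth. The
  discrepancy shrinks rapidly with rate and trial count and is negligible
  in the 0.10–0.21 operating band; interpret single-bin coupling
  estimates at very low rates with care.
* The diagonal-Fisher Laplace covariance ignores posterior correlations
  between parameters; credible intervals for strongly co-identified
  couplings can be mildly miscalibrated (coverage in the recovery study
  is nonetheless ≥ 0.95 at the 98% level).
* TAP may fail to solve at strong couplings or large N — by design it
  fails loudly; use the Bethe engine there.
* λ is a single smoothness constant for all d parameters and the whole
  recording; abrupt parameter changes are over-smoothed.
* The Bethe pairwise belief of an *uncoupled* pair factorizes, so
  Bethe η_ij omits correlations mediated by third neurons even on
  tree-structured models (where node marginals, coupled-edge marginals,
  and ψ are exact).
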