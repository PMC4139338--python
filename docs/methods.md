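# Methods

## Model

`gpordinal` implements Bayesian ordinal regression with a Gaussian-process
prior for staging disease progression over R ordered diagnostic classes
(default R = 4: CTL < MCI-s < MCI-c < AD).

**Prior.** The latent severity f has a zero-mean GP prior with linear
covariance k(x, x') = x·x' + θ_b.  The additive bias θ_b ≥ 0 plays the
role of an intercept's prior variance and controls the overall scale of
the latent function.  With this kernel the model is exactly a Bayesian
linear model f(x) = x·w + √θ_b·w₀ with standard-normal weights, which is
what licenses the weight-map output (below).  Only the linear kernel is
supported: nonlinear kernels would forfeit the weight-space view and are
out of scope.

**Likelihood.** Ordered-probit ("soft threshold") likelihood: the real
line is divided into R contiguous intervals by cut-points
b_0 = −∞ < b_1 < … < b_{R−1} < b_R = +∞ and the class probability is
P(y = k | f) = Φ((b_k − f)/σ) − Φ((b_{k−1} − f)/σ).  Cut-points are
parameterized as (b_1, log Δ_2, …, log Δ_{R−1}) with b_k = b_1 + ΣΔ, so
they remain strictly increasing by construction and are not constrained
to be equidistant.  The likelihood is log-concave in f (second derivative
≤ 0 everywhere, asserted in tests), so the posterior mode is unique.

**Inference.** Laplace approximation at the MAP latent solution, found by
Newton iteration in the standard stabilized parameterization
B = I + W^{1/2} K W^{1/2} (W = diagonal negative Hessian of the
log-likelihood; the formulation never inverts K and tolerates W entries
equal to zero).  The approximate log evidence is
log P(y|f̂) − ½ f̂ᵀK⁻¹f̂ − ½ log det B.

**Hyperparameter learning.** η = (log θ_b, log σ, b_1, log Δ_k) maximizes
the Laplace evidence with Powell's derivative-free method, restarted from
three fixed initializations: cut-points at probit-transformed empirical
label quantiles scaled by the prior latent spread s = √(mean diag K), with
σ ∈ {0.5 s, 1.0 s}, plus one equidistant-cut-point start; θ_b starts at 1.
The best evidence wins; the returned evidence is never worse than the
best initialization (enforced).  The MAP solution is warm-started across
nearby evidence evaluations.

**Prediction.** The latent predictive is Gaussian with mean
μ* = k*ᵀK⁻¹f̂ and variance k** − k*ᵀ(K + W⁻¹)⁻¹k*.  Class probabilities
integrate the noise model analytically:
P(y* = k) = Φ((b_k − μ*)/s) − Φ((b_{k−1} − μ*)/s), s = √(σ² + σ*²).
μ* itself is the continuous progression index (ORCHID when staging
dementia); larger = more AD-like.  Argmax class assignment breaks exact
ties toward the lower class index (conservative toward the less-affected
stage).  Training requires every class present; prediction does not.

**Recalibration and binarization.** To counter class imbalance, each
predicted class probability is divided by that class's training-set
proportion and the vector renormalized.  The four recalibrated
probabilities may then be aggregated to P(AD-like) = p₃ + p₄ with a 0.5
decision threshold (exact tie → CTL-like).  The order is fixed:
recalibrate the 4-class vector first, then aggregate (the reverse gives
different numbers; a flag prevents double recalibration).  ROC sweeps use
the aggregated recalibrated probability.

**Weight maps.** With A = [X, √θ_b·1], K = AAᵀ and the posterior-mean
weights are w = AᵀK⁻¹f̂ (bias component reported separately).  By
construction A·w reproduces f̂ exactly, which is tested to 1e-8.

## Feature preparation

Regional volumes are divided by the subject's intracranial volume
(normalize-then-average: each hemisphere volume is scaled by the shared
ICV before left/right averaging, which is algebraically identical to
averaging first but keeps every measure's treatment uniform); cortical
thicknesses are averaged in mm without normalization; configured regions
are excluded (defaults: white-matter hypointensities, optic chiasm, L/R
vessel, L/R choroid plexus — segmentations that are unreliable or mostly
zero).  The default ROI composition (34 Desikan-Killiany thickness pairs,
21 volume pairs, 2 midline volumes → 57 features) ships as an editable
configuration; the volume list beyond the standard subcortical structures
is a plausible composition, and downstream code relies on the counts, not
the names.

Features are z-scored (population SD, i.e. divide by N — recorded in the
stats and the model file) using *fitting-set* statistics before the GP.
A linear kernel over mixed units (mm vs volume ratios ~1e-3) would be
dominated by scale, so standardization is the default; a flag disables it
for data already on a common scale.  Missing values are a hard error;
there is no silent imputation.

## Synthetic cohorts

The generator draws exactly the structure the model assumes: features are
i.i.d. standard normal; a true weight vector w (unit direction ×
`latent_scale`, `informative_count` nonzero entries) gives the noise-free
latent X·w; adding N(0, noise_sd²) and thresholding yields the label.
Exact per-class counts are enforced by stratified rejection sampling so
experiments reproduce the study imbalance precisely; default thresholds
sit at the Gaussian quantiles of the requested class proportions so every
class is reachable.  A cognitive score (MMSE-like) is generated as
intercept − slope·rank + noise — linear in *rank*, not in the latent, so
ORCHID–cognition correlation tests exercise genuine rank correlation
rather than reading back the generator.  An optional per-feature
`site_shift` emulates a scanner offset in a test cohort (applied after
label generation, so labels are unchanged).

Presets: `adni-like` (191/164/62/147 subjects, 57 features, 10
informative, latent scale 1, noise 0.5 — signal-to-noise 2, which yields
staging accuracies in the range reported for real ROI data), `toy`
(10/10/10/10, 5 features, for fast tests), `high-separation`
(50×4, latent scale 3, noise 0.25: adjacent-class effect sizes ≥ 2),
`zero-signal` (30×4, no informative features: labels are pure noise).

What passing on these cohorts does *not* show: real cohorts have
correlated features, non-Gaussian atrophy distributions, site/protocol
effects beyond a mean shift, label noise in the diagnosis itself, and an
unknown true model class.  Synthetic results validate the inference
machinery and protocols, not clinical performance.

## Validation harness

Stratified k-fold CV (default k = 10, default seed 20140820) assigns each
class's shuffled members round-robin to folds (per-class fold counts
differ by ≤ 1).  Per fold: standardization statistics, hyperparameters
and class proportions are estimated from the training rows only; held-out
predictions are pooled across folds and every metric is computed once on
the pooled set (one confusion matrix per experiment, not a mean of
per-fold metrics).  Independent validation fits once on cohort A and
applies A's statistics and proportions to cohort B.  Three binary
contrasts are reported by subsetting the pooled predictions: CTL-like vs
AD-like (all subjects), CTL vs AD, and MCI-s vs MCI-c; the training
scheme is identical for all three.  `map_cohort` places held-out
subgroups on the fitted continuum via their ORCHID scores and compares
distributions with two-sample KS tests (singletons report scores but skip
KS).  The binary baseline trains the R = 2 pathway on the extreme classes
only (its training indices are logged and asserted), mirroring
conventional CTL-vs-AD transfer designs.

## Numerical choices

- Φ-differences are computed in the log domain via `log_ndtr` with the
  interval mirrored to whichever tail is representable; finite
  likelihoods, gradients and curvatures out to |z| ≈ 40.
- Newton: objective-change tolerance 1e-6, gradient-stationarity check,
  max 100 iterations, step-halving safeguard (rarely triggered; the
  objective is concave).  Diagonal jitter 1e-8·tr(K)/N with two
  escalations if a factorization fails.
- Evidence search: Powell with per-start `maxiter` 10 and relative
  tolerance 1e-4 by default; failed or overflowing evaluations return a
  large penalty rather than crashing the search.
- The linear kernel has rank ≤ M+1, so evidence evaluations inside the
  hyperparameter search run in the (M+1)-dimensional column space via the
  Woodbury identity when N > 2(M+1); the algebra is identical to the
  dense path (tested to 1e-6) and the final stored posterior is always
  computed densely.
- Predictive variances are clipped at zero with a warning if more
  negative than −1e-8.
- AUC uses the trapezoidal sweep over distinct thresholds, equal to the
  Mann–Whitney concordance probability with half credit for ties
  (cross-checked against exhaustive pair counting and scikit-learn).
- KS p-values are asymptotic (scipy `ks_2samp`, method="asymp"), matching
  common practice for the cohort sizes involved; not exact small-sample.
- Spearman uses scipy's tie-averaged ranks with the t-approximation
  p-value.

## Problem sizes

Default test and acceptance runs use: parameter recovery at N = 500,
M = 10; cross-validated staging at the full study imbalance N = 564,
M = 57, k = 10; independent validation with a 348-subject test cohort;
chance-level controls at N = 120 over multiple seeds; high-separation
control at N = 200, k = 10.  These sizes were chosen to match the study's
scale where it matters (the staging experiments) and to keep control
sweeps comfortably reproducible on a single CPU.

## Known limitations

- Laplace only; no expectation propagation or sampling-based inference.
- Linear kernel only (deliberate: the weight map is part of the method).
- Hyperparameter search is derivative-free and restarted from three fixed
  points; a pathological evidence surface could in principle retain a
  local optimum.
- Cut-points are optimized jointly with the other hyperparameters by
  evidence maximization — a single-criterion design; alternatives (e.g.
  fixing them at label quantiles, or a separate held-out criterion) are
  possible but not implemented.
- Recalibration is the proportional prior correction only; no Platt
  scaling or other post-hoc calibration.
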