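# Methods

## The count model

Tolerance assays observe colony counts `y` (c.f.u.·mL⁻¹, real-valued
because they are back-calculated from dilution plating; rounded to the
nearest integer for the likelihood) indexed by strain `s`, experiment
repetition `e`, and dose `d` (minutes, days, kGy, or mM — treated as an
abstract non-negative number with a unit label). The initial number of
cells in each suspension is unknown, which rules out direct survival-rate
or logistic modelling. The package therefore models the counts:

    y ~ NegBin(μ, θ),  Var(y) = μ + μ²/θ
    log μ = β₀ + α_s + γ_{e(s)} + f_s(√d)

* `α_s` — strain main effect (reference coding; the first strain in order
  of appearance is the reference).
* `γ_{e(s)}` — experiment effect, a fixed effect nested within strain:
  each strain's repetitions are distinct batches with their own inoculum.
  No random-effects formulation is used; with two repetitions per strain a
  fixed effect is the estimable choice.
* `f_s` — one penalized spline per strain on the square-root dose scale.
  The √ transform compresses the long dose tail and stabilises estimation;
  survival curves that decline exponentially in dose are smooth, gently
  curved functions of √d.
* `θ` — a single dispersion shared by all strains and experiments,
  estimated by profile maximum likelihood (bounded in [1e-3, 1e8]; the
  Poisson model is the θ → ∞ limit and is recovered numerically at θ =
  1e8 to about 1e-6 in the fitted means when counts are ≲ 10³).

Survival fractions are ratios of predicted means, `S_s(d) = μ_s(d)/μ_s(0)
= exp(f_s(√d) − f_s(0))`: the intercept, strain and experiment effects
cancel, which is precisely how the model sidesteps the unknown inoculum.
The baseline is the *model's* dose-0 prediction, not the observed dose-0
mean — the observed-fraction helper (`compute_survival_fractions`) uses the
group's minimum tested dose instead, which generalises designs without a
plated dose 0 (desiccation series starting at 20 days).

Exact consequence worth knowing: in the Poisson limit with the penalty
rescaled along with the counts, multiplying every count by k shifts β₀ by
exactly log k and changes no survival fraction. With estimated θ and
re-selected λ the equivariance is only approximate, and fitted curves can
differ visibly in the far tail where survival < 10⁻³ and every observed
count is zero (the curve is penalty-driven there); LD estimates move by
far less than bootstrap noise.

## Basis, penalty, and fitting

Each `f_s` is a cubic B-spline basis (default 8 functions) on equidistant
knots spanning the strain's observed √dose range, with degree-many padding
knots on each side, and a second-order difference penalty on adjacent
coefficients — heavy smoothing shrinks the curve toward a straight line in
√d. If a strain has fewer distinct √dose values than basis functions the
basis is reduced to that number with a warning. Each smooth is centred
(sum-to-zero over the strain's observed basis rows, implemented by a null
space reparametrisation) so the strain main effect absorbs level
differences.

Coefficients maximise the penalized NB log-likelihood by iteratively
reweighted least squares with step-halving, which makes the penalized
deviance provably non-increasing (a monitored test invariant). Convergence
is a relative penalized-deviance change below 1e-8 within 200 iterations.
Beyond the observed √dose range the linear predictor is extended linearly
from the boundary value and slope — polynomial B-spline extrapolation is
unstable — and LD values beyond the tested range are reported as censored
bounds, never extrapolated.

### Smoothing selection

λ_s is selected per strain by coordinate descent (two sweeps) over a
21-point log-spaced grid from 1e-4 to 1e6, minimising the negative
Laplace-approximate restricted marginal likelihood (LAML)

    dev(β̂; θ) + β̂ᵀP(λ)β̂ + log|XᵀWX + P(λ)| − log|P(λ)|₊

(λ-free constants dropped; |·|₊ is the product of positive eigenvalues).
This is the criterion family used by standard additive-model software for
NB smooths, and on simulated shoulder data it reproduces the effective
degrees of freedom such software selects. Corrected AIC
(`dev + 2·edf·n/(n−edf−1)`) is available via `ModelSpec(criterion="aicc")`
but oversmooths sharp shoulders at the default study size, biasing LD50
low; LAML is therefore the default. During the grid search θ is pinned at
a pilot profile estimate (fitted at λ = 1) for determinism and speed; the
final fit at the selected λ alternates IRLS with profile-ML θ updates
until the dispersion is stable to 0.1% on the log scale. Selection is
deterministic given the data.

All candidate fits along one coordinate-descent sweep are solved as one
batched penalized IRLS (a numba-compiled core with an in-loop Cholesky
solve); warm starts only speed the numerics — converged optima, and hence
the selected λ, depend on the data alone.

## Lethal doses and bootstrap inference

LDp is the smallest dose in [0, d_max] with S(d) ≤ p (d_max defaults to
the strain's maximum observed dose), found by a 512-point scan uniform in
√dose followed by interval refinement to |Δd| < d_max·1e-6; the result
agrees with a brute-force 10⁶-point scan to 1e-4·d_max (test invariant).
No crossing means a censored estimate at d_max.

Confidence intervals use a *full* parametric bootstrap: each replicate
draws counts from NB(μ̂, θ̂) at the original design points (gamma–Poisson
mixture, reproducible from a single seed) and repeats the entire fit —
smoothing re-selection and θ re-estimation included — so the intervals
carry smoothing uncertainty. Percentile 95% intervals are taken from the
replicate LD draws; censored draws sit at d_max in the order statistics
and a bound landing on them is flagged censored. Replicates that fail to
refit are counted and excluded (warning above 5%, hard error above 50%).
Strain contrasts use the per-replicate differences LDp(A) − LDp(B);
replicates censored for exactly one strain carry no usable difference and
are excluded with a count. Defaults: 1000 replicates for the CLI, 199 in
tests and simulation studies.

## The simulator

`simulate_dataset` emulates a two-strain tolerance assay: for each strain,
experiment, dose and plate replicate it draws
`count ~ NB(baseline · exp(experiment shift) · S(d), θ)`, with experiment
shifts drawn once per experiment from Normal(0, sd) on the log scale. The
ground-truth survival family is a softplus shoulder curve

    log S(d) = −k·softplus_s(d − D₀) + k·softplus_s(−D₀),  softplus_s(u) = s·log(1 + e^{u/s})

which is exactly 1 at dose 0, declines exponentially at rate k beyond the
shoulder D₀ with transition width s, nests pure exponential decay
(D₀ = 0), and has the closed-form limit LDp → D₀ + ln(1/p)/k as s → 0
(`true_ld` inverts the curve numerically for any s).

Defaults are the package's reference study conditions, chosen once:
baseline 10⁴ c.f.u.·mL⁻¹, θ = 5 (strong overdispersion typical of plate
counts), experiment shift sd 0.3 on the log scale (≈ ±35% batch-to-batch
inoculum variation), two experiments per strain, duplicate plates, dose
grid {0, 1, 5, 10, 20, 40, 60, 120} (a chemical-exposure design in
minutes; desiccation-style {0, 20, …, 100} days and radiation-style
{0, 2.5, …, 12.5} kGy grids are provided), and a shoulder curve with
D₀ = 2, k = 0.5, s = 0.1 for both strains. What the simulator does *not*
emulate: dilution-plating mechanics, fluence physics, dose-measurement
error, non-monotone survival (tailing subpopulations), or between-plate
correlation beyond the shared experiment shift — so passing tests show the
statistical machinery works under the model's own assumptions, not that
real assays satisfy those assumptions.

## Numerical choices

* Counts rounded to nearest integer for the NB likelihood; linear
  predictor clipped to ±40 inside IRLS.
* θ profile: Newton/secant on the profile score warm-started from the
  previous value, bounded scalar minimisation as fallback.
* Quantiles of bootstrap draws via linear interpolation (numpy default).
* Ties in the λ grid search resolve to the first (smallest) minimiser;
  the search is deterministic.
* Degenerate inputs: a strain with all-zero counts raises a degenerate-fit
  error (no curve is identifiable on the log scale); fewer than two
  distinct doses per strain is rejected at validation; a non-monotone MIC
  growth pattern is resolved conservatively (smallest concentration above
  which all calls are no-growth) with a warning.

## Known limitations

* **Sharp shoulders bias LD50 and its bootstrap coverage.** With the
  reference design's sparse dose grid, the LD50 (≈ 3.39) falls inside the
  observed gap between doses 1 and 5, and a cubic spline in √d rounds the
  sharp shoulder: even at effectively infinite information (huge counts,
  vanishing penalty) the inverted LD50 is ≈ 3.12 (−8%; the test suite
  computes this limit), and at the default sample size (64 rows) the
  median relative LD50 error is ≈ 19%. This is a property of spline
  dose–response estimation at this design — any smoother with the same
  basis and knots inherits it — not of the fitting algorithm.
  Because bootstrap replicates are generated from the
  *fitted* (already smoothed) curve, the replicate LD spread also
  underestimates the true sampling variation (~40%), and measured 95%
  CI coverage for LD50 is ≈ 80–85% rather than nominal; `scripts/
  acceptance.py` reports the honestly measured value. LD10, flanked by
  observed doses, is asymptotically unbiased (≈ +1%) with ≈ 6% median
  error. Practical advice: place doses near the anticipated LDp.
* One shared θ; no per-curve dispersion, no quasi-likelihood families.
* At most two strains per run in the pipeline/CLI (one test strain plus a
  control), matching the one-vs-positive-control assay design; the
  library functions themselves handle any number of strains.
* No multiple-testing correction across stressors; each stressor is
  analysed separately.
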