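# Methods

## Network construction

Epoch-level functional networks are Pearson correlation matrices of
broadband ROI signals, computed in a 2-s sliding window with 50% overlap
and averaged element-wise over windows. Choices that the procedure
leaves open, and how this package resolves them:

* **No variance-stabilizing transform.** Window matrices are averaged as
  raw correlation coefficients; no Fisher z-transform is applied before
  averaging, and negative correlations are kept as-is.
* **Window rounding.** Window length = `round(window_seconds * fs)`
  samples and step = `round(window_seconds * fs * (1 − overlap))`; the
  sampling rate must be supplied, never inferred. Trailing samples that
  do not fill a complete window are dropped so every correlation
  estimate uses the same sample count.
* **Degenerate input.** A region with zero variance inside a window
  (flat signal) is an error naming the region, not a silent NaN.
* **Inter-hemispheric masking.** Masked entries become NaN, not zero, so
  any downstream mean that accidentally included them would fail loudly.
  Masking is idempotent and leaves the within-hemisphere blocks (and the
  diagonal) untouched.
* **Epoch placement.** Up to `n_epochs` epochs (default three of 60 s)
  are placed uniformly at random subject to a minimum gap (default
  300 s) between consecutive epochs, by splitting the total slack with
  sorted uniform draws. This sampler is exact (every admissible ordered
  placement, including flush placement, has positive probability), always
  terminates, and is deterministic given its seed. If the recording
  cannot hold all requested epochs, as many as fit are returned — e.g. a
  420-s recording holds exactly two 60-s epochs with a 300-s gap, flush
  against both ends. The amplitude-correlation step operates directly on
  the broadband signals (no envelope extraction).

## Node strength and D_RS

Intra-hemispheric node strength is the *mean* correlation of a region
with the other regions of its hemisphere (not the row sum; for equal
hemisphere sizes the two are rank-equivalent and D_RS is identical — a
unit test asserts this). D_RS is the normalized Mann–Whitney U of the
spared strengths over all removed × spared pairs, computed by midranks
with 0.5 credit per tie (required for the identical-strengths case to
score 0.5), and validated against exhaustive pair enumeration.

The **spared set** defaults to every non-removed region in *both*
hemispheres (each node's strength still computed within its own
hemisphere), since contralateral high-strength nodes are informative
about how distinctive the resected tissue was; `spared_scope=
"ipsilateral"` restricts the comparison to the resected hemisphere. The
chosen scope is recorded in every output.

## Resection labeling

A region is removed iff ≥ 1 of its voxels lies under the binary
resection mask — the any-overlap rule, taken literally with no minimum
overlap threshold. Both volumes must already share a grid; registration
and mask drawing are upstream of this package. Label ids absent from the
atlas are an error (they signal a parcellation-scale mismatch). An empty
removed set only warns at labeling time but is an error when passed to
D_RS, which needs at least one region on each side.

## Group inference

* **AUC and CI.** The outcome AUC is the probability that a
  not-seizure-free subject outranks a seizure-free subject in D_RS
  (ties at half weight). Its confidence interval uses the Hanley–McNeil
  standard error `SE² = [A(1−A) + (n₁−1)(Q₁−A²) + (n₂−1)(Q₂−A²)]/(n₁n₂)`
  with `Q₁ = A/(2−A)`, `Q₂ = 2A²/(1+A)`, transformed to the logit scale
  (`SE_logit = SE/(A(1−A))`), expanded symmetrically, and mapped back —
  so the bounds always lie inside (0, 1). For A = 0.76 with n₁ = 12,
  n₂ = 19 this construction gives (0.54, 0.90) at the 95% level.
  A degenerate AUC of exactly 0 or 1 has no logit; `auc_logit_ci` raises
  and the pipeline reports a zero-width interval explicitly.
* **Rank-sum test.** One-tailed, alternative "seizure-free D_RS is
  stochastically smaller". Exact enumeration when n₁+n₂ ≤ 12 without
  ties; otherwise the normal approximation with tie and continuity
  corrections (so a 12-vs-19 comparison uses the approximation, as
  standard implementations do). The method used is recorded in the
  output. If every observation is identical the test is degenerate and
  p = 1.
* **Robust duration fit.** mean FC ~ 1 + log10(duration) by iteratively
  reweighted least squares with the Tukey bisquare norm, tuning constant
  4.685 (the standard 95%-efficiency value). Adjusted R² is computed
  from bisquare-weighted sums of squares:
  `adj R² = 1 − (1 − R²_w)(n−1)/(n−2)`. The likelihood-ratio p-value
  against the intercept-only robust fit uses Gaussian log-likelihoods
  evaluated at the robust estimates with maximum-likelihood scale, on
  one χ² degree of freedom. M-estimation has no canonical likelihood, so
  this is a quasi-likelihood ratio; the output flags it as
  `"likelihood": "gaussian_quasi"`. Simulation under the null (no
  duration effect, n = 31) shows the resulting test rejects at ≈ the
  nominal 5% rate (unit-tested at ≤ 10% over 200 replicates).
* **Mixed model.** mean FC ~ 1 + log10(duration) with a random intercept
  per recording segment, maximum-likelihood fit, LRT on one degree of
  freedom against the intercept-only mixed model. A single segment makes
  the random intercept unidentifiable and is rejected with a pointer to
  the robust per-segment fit.
* **Mean FC** is the mean of the strict upper triangle of the *unmasked*
  epoch matrix — inter-hemispheric connections included — deliberately
  different from the intra-hemispheric strength used for D_RS. Passing a
  masked matrix is an error.
* **No multiple-testing correction** is applied across segments;
  per-segment p-values are all emitted so users can correct downstream.

## Synthetic cohort generator

No patient recordings ship with the package, so validation uses a
generative model with the statistical structure the analysis assumes.
Each subject's ROI signals follow a Gaussian factor model

x_i(t) = λ_i·g_{H(i)}(t) + μ·c(t) + σ·ε_i(t),

with independent unit-variance white processes: one shared factor per
hemisphere (g_L, g_R), one global factor c coupling the hemispheres, and
per-region noise. Hubs load at `loading_hub` on their hemispheric
factor, other regions at `loading_base`. The factor form guarantees a
valid (positive semidefinite) covariance and closed-form pairwise
correlations — e.g. two same-hemisphere non-hubs correlate at
(λ²+μ²)/(λ²+μ²+σ²) — which the tests use as oracles
(`population_correlation`).

Planted effects:

* **Outcome.** Each hub of the epileptogenic hemisphere enters the
  resection independently with probability 0.9 (seizure-free) or 0.1
  (not seizure-free); remaining slots are uniform non-hubs of that
  hemisphere. The geometry must allow the draws: the resection size may
  not be smaller than the hub count (a full hit must fit) nor larger
  than the non-hub count (a zero-hit draw must fill). Setting both hit
  fractions equal is the null configuration with no outcome effect.
* **Duration.** All loadings are scaled by
  `1 + duration_slope·log10(duration_years)` (default slope 0.05 per
  decade), the simplest mechanism that makes mean FC increase
  monotonically with log duration. Durations are log-uniform on
  (2, 40) years so log10(duration) is uniform and strictly positive.
  Each subject's implied population mean FC is stored as ground truth.

Defaults: 31 subjects with 12 seizure-free (the reference cohort
split), 32 regions (16 per hemisphere — large enough for a stable rank
statistic, small enough to simulate cohorts by the hundred), 4 hubs and
a 6-region resection per hemisphere, 600 Hz sampling, one minute of
signal, loadings 0.9/0.4/0.2 and unit noise (pairwise correlations
≈ 0.17–0.47, hub strength ≈ 0.31 vs non-hub ≈ 0.20 at mid-range
duration). A master seed spawns independent per-subject substreams, so
cohorts are reproducible while subjects stay independent.

**What the generator does not emulate:** interictal spikes or other
transients (signals are stationary by design — the analysis targets the
stationary component of connectivity), field spread/source leakage,
1/f spectra or band-limited rhythms (white factors suffice because
Pearson correlation is spectrum-blind at fixed coupling), head movement,
or between-subject anatomical variability. Passing recovery tests
therefore demonstrates that the statistical machinery detects the
intended effects at realistic effect sizes and cohort sizes — not that
real MEG preprocessing artifacts are handled.

## Problem sizes in the test suite

Monte-Carlo recovery tests simulate 10 s of signal per subject (nine
2-s windows per epoch) — enough for the epoch-mean correlations to
stabilize near their population values — with 50 cohort replicates for
power checks and 200 for type-I-error checks; the mixed-model check uses
three 8-s segments drawn from 30-s recordings. These sizes were chosen
so the whole suite completes in a few minutes while the binomial bounds
asserted (≥ 80%, ≥ 90%, ≤ 10%) remain far from the simulated rates.

## Known limitations

* The rank-sum normal approximation is used at 12-vs-19; exact p-values
  at that size would differ in the third decimal.
* The quasi-likelihood LRT for the robust fit is a pragmatic construction,
  not a calibrated robust test (e.g. a robust Wald or τ-test); its type-I
  behaviour is verified by simulation only under Gaussian noise.
* The mixed model treats segment as the sole random effect (no random
  slope, no subject random effect), matching the reference analysis; with
  few segments the variance component is weakly identified and may fit to
  the boundary.
* The generator's hemisphere factor gives all same-hemisphere pairs a
  shared correlation floor; real networks have richer community
  structure.
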