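# Methods

This note documents the statistical models implemented in `ppx`, the
defaults and why they were chosen, what the synthetic cohorts emulate, and
the numerical conventions that affect results.

## Cohort structure, censoring, and interval views

The unit of observation is a plasma sample indexed by patient and
gestational age (GA, decimal weeks).  Patients carry outcome flags (early
preeclampsia; subgroup flags for placental maternal-vascular-malperfusion
lesions and for severe disease; optionally late preeclampsia) and a GA at
diagnosis.  All analyses use only samples drawn strictly before diagnosis:
samples taken at the diagnosis visit are excluded (strict inequality),
because an at-admission draw no longer *predicts* the disease.

Analyses are organized by GA interval — 8–16, 16.1–22, 22.1–28, 28.1–32 and
32.1–36 weeks.  Interval membership is half-open, `(lower_prev, upper]`,
with the first interval closed at 8; GA values in the typographic gaps of
the printed bounds (e.g. 16.05) join the upper interval, since the ".1"
bounds are display precision of a continuous variable.  When a patient has
several eligible samples in one interval, the one closest to the interval
midpoint is used, ties resolved to the earlier sample.  The midpoint rule is
a convention of this package: it is deterministic, symmetric, and favors
samples representative of the interval's center.  Contrast modes label each
patient case/control/excluded: all early-PE cases vs normal pregnancies,
MVM-only or severe-only cases vs normal pregnancies (other cases excluded),
or early PE vs the union of normal pregnancies and late-PE patients.

## MoM normalization

Protein abundances (relative fluorescence units, assumed plate-normalized
upstream) are prepared per protein as follows.

1. **Thresholding.** Values above twice the 98th percentile of all samples
   (cases and controls; linear-interpolation quantile estimator) are reset
   to that ceiling.  The ceiling is stored and reused when transforming new
   data.  All-zero proteins get ceiling 0, a warning, and propagate NaN.
2. **Reference curves.** On control samples only, log2 abundance is modeled
   as a cubic regression spline in GA with a per-subject random intercept:
   `y_ij = x(GA_ij)'β + b_i + ε_ij`, `b_i ~ N(0, τ²)`, `ε_ij ~ N(0, σ²)`.
   The spline has 3 interior knots at the 25/50/75% quantiles of control GA
   and clamped boundary knots at the observed control GA range; a subject
   random intercept is the minimal structure consistent with repeated
   measures.  The model is fitted by REML, profiling λ = τ²/σ² to a
   one-dimensional bounded search with closed-form GLS at each λ; the λ = 0
   boundary (no subject effect) is always evaluated as a candidate.  The
   fitter is validated in the test suite against `statsmodels` `MixedLM`
   (coefficients and both variance components) and degenerates exactly to
   ordinary least squares when every subject contributes one sample.
   Constant or singular proteins fall back to an intercept-only mean with a
   warning.
3. **MoM transform.** Every sample of every group becomes
   `MoM = 2^(log2 min(y, ceiling) − μ̂(GA))`.  Cases never influence μ̂.
   Prediction at GA outside the fitted control range clamps to the range
   boundary with a warning.  Curves, variances, knots and ceilings serialize
   to a versioned JSON document so transforms are bit-for-bit reproducible.

Downstream analyses use log2 MoM; the fold-change filter uses linear MoM.

## Panel selection

Within one interval view (one sample per patient, binary labels):

- **Filter.** Keep proteins with `|mean(MoM_cases)/mean(MoM_controls) − 1| ≥
  0.10` (arithmetic means of linear MoM, boundary inclusive).
- **Rank.** For each survivor, compute leave-one-patient-out
  cross-validated linear-discriminant scores and their partial AUC over
  FPR ∈ [0, 0.5].  The discriminant uses pooled within-class covariance
  with a relative ridge of `1e-8·trace(S)/p` (absolute 1e-8 when the trace
  vanishes), and the score of a held-out patient is
  `w'(x − (μ̂₀+μ̂₁)/2)` with `w = S⁻¹(μ̂₁−μ̂₀)`.  Ranking ties break by full
  AUC, then protein identifier, making selection fully deterministic.
- **Grow.** Candidate panels are the nested prefixes of the ranking
  (top-1 … top-5).  Size k+1 is accepted only when its LOOCV pAUC exceeds
  the last accepted pAUC by ≥ 0.01; selection stops at the first rejection.
  The 0.01 gain applies to the unnormalized pAUC (range 0–0.5) by default;
  a McClish-normalized alternative (`pauc_scale="normalized"`) is available
  and recorded in the panel metadata.
- **Fit.** The final discriminant is refitted on all patients of the view
  with the accepted set.  If nothing survives the filter the result is an
  explicit empty panel whose decision function is constantly zero (chance
  performance downstream), not an error.

ROC conventions: the empirical curve is built at every distinct threshold,
ties handled by trapezoidal interpolation (equivalent to the Mann–Whitney
statistic with ties counted half).  AUC and pAUC are trapezoidal areas;
pAUC interpolates the crossing segment at the FPR cap.  Sensitivity is the
TPR at the largest achievable empirical FPR not exceeding the 10% target —
a conservative step-function reading under which the achieved specificity
is always ≥ 90% (and in practice 0.90–0.93).

## Resampling evaluation

Because the panel is selected from the data, performance must be estimated
with the selection inside the resampling loop:

- **Stratified bootstrap (B = 200).** Each iteration resamples cases and
  controls separately with replacement to the original class sizes, reruns
  the entire pipeline on the resample, and computes AUC/pAUC/sensitivity/
  specificity on the out-of-bag patients.  Out-of-bag sets that lack a
  class (probability ≈ (1−1/n)ⁿ per class) are redrawn rather than skipped,
  keeping B fixed; redraws are counted in the report.
- **Repeated cross-validation.** 67 repeats of stratified 3-fold CV give
  exactly 201 train/test pairs; folds differ by at most one patient per
  class (round-robin remainder).

A single master seed spawns one `SeedSequence` substream per iteration, so
any iteration is reproducible in isolation and the full report is a pure
function of (view, scheme parameters, seed).  Aggregates are means with
empirical 2.5/97.5 percentile intervals across iterations; per-protein
inclusion frequency is the fraction of iterations whose accepted panel
contains the protein, reported at the 10%-or-more threshold (inclusive).

## Differential abundance

Per interval, log2 MoM is regressed on group plus (when a complete
covariate table is supplied) BMI, smoking status, maternal age, and
nulliparity, all entering linearly; incomplete covariates trigger a
documented fallback to the unadjusted model with a warning.  Per-protein
residual variances s²_g with d degrees of freedom are shrunk toward a
scaled inverse-chi-square prior (d₀, s₀²) estimated by moment matching on
e_g = log s²_g − ψ(d/2) + log(d/2): the excess of var(e) over the sampling
term ψ′(d/2) determines d₀ through the trigamma inverse (Newton iteration),
and mean(e) determines s₀².  When the observed spread does not exceed the
sampling component, d₀ = ∞ and all variances shrink fully to s₀².  The
moderated statistic `t = β/(s̃√v)` with `s̃² = (d₀s₀² + d s²)/(d₀ + d)` is
referred to a t distribution with d₀ + d degrees of freedom.  q-values are
Benjamini–Hochberg within each interval × contrast family (delegated to
statsmodels, verified in tests against the textbook step-up formula);
significance is q < 0.1.  Signed linear fold change is `2^β` for β ≥ 0 and
`−2^(−β)` otherwise, so negative values denote lower levels in cases.

## Enrichment

Over-representation uses the one-sided hypergeometric upper tail
P(X ≥ a) per term, with the full assay panel as the reference population;
term membership is intersected with the panel and terms without panel
members are untested.  The BH family is the set of tested terms.  Enriched
terms need ≥ 3 hits and q < 0.1.  The reported odds ratio is the plain
cross-product ad/bc of the 2×2 table, with infinity flagged (not truncated)
when b or c is zero.  Annotation comes from a GMT file; no ontology
download or ancestor propagation is performed — reproducibility over
freshness.

## Synthetic cohorts and what they can show

`SynthConfig` defaults encode the emulated study design: 33 early-PE cases,
90 controls (optionally late-PE patients for the combined contrast),
enrolment uniform on 8–12 weeks, prenatal visits every 4 ± 0.5 weeks until
28 weeks and every 2 weeks thereafter (the standard prenatal schedule),
delivery at 38.5–41 weeks for controls and shortly after diagnosis for
cases, diagnosis GA uniform on 24.6–33.4 weeks.  Of the scheduled visits,
2–6 per patient are retained (uniform count); the enrolment draw and, for
patients who develop disease, the last pre-diagnosis draw are always among
them (admission-adjacent banking).  About half of the cases also carry a
sample at the diagnosis visit, which exercises the censoring path.  24 of
33 cases are flagged MVM and 23 of 33 severe, with optional effect
multipliers.

Protein baselines on the log2 scale mix constant, linear and smooth
(sinusoidal) GA trends; the subject random-intercept and residual standard
deviations default to τ = 0.3 and σ = 0.4 log2 units — conventions, since
real per-protein variance magnitudes vary; they put a single 1.0-log2-MoM
marker at an oracle AUC of 0.92, a realistic strong-marker regime.  Planted
markers add interval-localized log2 MoM shifts for cases: by default one
dominant marker per analysis interval with magnitudes escalating toward
diagnosis (+1.0 at 8–16, +1.4 at 16.1–22, −1.4 at 22.1–28, +2.0 at
28.1–32 weeks), mirroring the interval-specific marker sets and
late-diverging trajectories seen in real early-onset disease; optional
onset ramps let effects grow gradually.  The closed-form oracle
`AUC = Φ(shift/√(2(τ²+σ²)))` (and its multi-marker extension with the
root-sum-of-squares shift) accompanies every generated cohort.

The generator deliberately omits several features of real aptamer data:
plate effects and batch structure, realistic fluorescence magnitudes,
inter-protein correlation (beyond what covariate confounding induces in
the confounded preset), missingness, and heavy-tailed noise.  Passing
tests therefore demonstrate that the *machinery* is correct and calibrated
under the assumed model — unbiased MoM construction, no selection optimism,
planted-effect recovery at the study's sample sizes — not that any
particular protein will validate in new clinical data.

## Numerical conventions and edge cases

- Quantiles use linear interpolation everywhere.
- The REML search runs over log λ ∈ [−12, 8] with a λ→0 boundary candidate;
  variance floors (1e-12) keep degenerate constants finite.
- LDA ridge: 1e-8 relative to mean within-class variance; absolute 1e-8
  for all-constant folds.
- The single-feature LOOCV fast path uses exact leave-one-out mean/variance
  updates and is tested to 1e-10 against a refit-per-fold oracle.
- Empty out-of-bag classes: redraw (logged), never skip.
- Bootstrap confidence intervals: empirical percentiles across iterations,
  matching the mean-with-interval presentation of the reference analyses.
- All randomness flows through `numpy.random.SeedSequence`; equal seeds
  give bit-identical cohorts, reports and panels.

## Problem sizes used in the shipped checks

The test suite and `scripts/acceptance.py` run on 200-protein cohorts at
the design's 33/90 sample sizes (the cohort-integrity check generates the
full 1,125-protein layout), with B = 200 bootstrap iterations, 5-cohort
replication for marker recovery, and 10 × 1,000-protein simulations for
null calibration of the moderated t — sizes at which the whole acceptance
run completes in about two minutes while keeping the binomial noise on
every reported rate well inside its acceptance band.

## Known limitations

- The random-effects structure is an intercept only; random GA slopes or
  penalized smoothing would change μ̂ slightly for proteins with strongly
  subject-specific trajectories.
- The +0.01 pAUC acceptance rule interacts with the winner's curse of
  pAUC-ranked selection at small interval views (~20 cases): second markers
  with true joint gains below ~0.02 are often rejected, so panels are
  deliberately parsimonious and correlated co-markers will be summarized by
  their strongest representative.
- Intervals are analyzed independently; no information is shared across a
  patient's repeated intervals in the differential analysis.
- ORA treats annotation as given (no ontology closure) and assumes the hit
  list is a subset of the assay panel.
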