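# Methods

`fibrosurv` implements an analysis chain for quantifying myocardial fibrosis
from stained endomyocardial-biopsy (EMB) images and evaluating its prognostic
value in dilated cardiomyopathy (DCM), together with the synthetic data
generators needed to validate every stage against known ground truth.

## Image model and quantification

### Synthetic slides

A biopsy fragment is a connected blob of tissue on a near-white background.
The fragment shape is the superlevel set of a radial ramp plus smoothed
Gaussian noise, thresholded at exactly the pixel count implied by the
requested physical area, so the planted tissue area is exact.  Interstitial
fibrosis is planted as the top-k pixels of an independent Gaussian-filtered
noise field inside the tissue (correlation length `blob_scale`, default
60 µm), giving spatially correlated collagen strands; k is chosen so the
planted collagen volume fraction (CVF) is exact up to a single-pixel
rounding.  Pixel colours are drawn from per-class trivariate Gaussians.

The default palettes (trichrome: muscle ≈ (180, 60, 70), fibrosis ≈
(70, 90, 170), background ≈ (245, 245, 245), σ = 12 per channel; AFOG
analogous) are package conventions.  Real Tri/AFOG colour statistics vary by
laboratory, stain batch and scanner, and no canonical reference values
exist; nothing downstream depends on the specific values, only on class
separability.

The default working resolution is 4 µm/px rather than the 0.46 µm/px of
clinical whole-slide scanners: a 1–2 mm² fragment is then ~10⁵ pixels and a
full simulation study runs in seconds.  Resolution is a parameter and all
areas are reported in mm², so results are resolution-independent; the pixel
classifier is pointwise and unaffected by scale.

Artifacts (dust, detached micro-fragments) are planted as small specks on
background with a one-pixel guard ring, so their connected-component count
is exact; they are deliberately labelled background in the ground truth
because the post-processing stage is supposed to remove them.

What the generator does *not* emulate: stain deconvolution-level colour
mixing, focus and illumination gradients, tissue folds, anatomically
realistic collagen architecture, or inter-slide stain variability.  Passing
recovery tests therefore shows the pipeline is correct under its own colour
model, not that it would hit ±2 percentage points on real slides.

### Quantification pipeline

1. **ROI detection.** The background colour is estimated as the mode of the
   image-border pixels; pixels farther than a Euclidean RGB distance
   threshold (default 30) are tissue.  The raw mask is returned; smoothing
   belongs to stage 3.
2. **Pixel classification.** "Linear Bayesian classifier in RGB space" is
   interpreted as Gaussian class-conditional densities with one pooled
   (shared) covariance — the canonical linear discriminant.  Training
   computes per-class sample means and the pooled within-class covariance
   (ridge ε = 10⁻³·tr(Σ)/3 added if near-singular).  Priors default to
   equal: training-region areas are annotator-dependent, so empirical priors
   would encode the annotator, not the tissue.  The decision rule assigns
   argmax of δ_k(x) = xᵀΣ⁻¹µ_k − ½µ_kᵀΣ⁻¹µ_k + log π_k with ties broken by
   the fixed order background < muscle < fibrosis (deterministic; ties have
   measure zero for continuous colours but occur in constructed fixtures).
3. **Morphological post-processing.** Per tissue class, binary opening then
   closing with a disk (default radius 1 px at 4 µm/px), then removal of
   connected tissue components below a minimum area (default 0.01 mm²,
   converted to pixels via the stored resolution).  The operator sizes are
   package defaults; the reference workflow names the operators but not
   their parameters.

CVF is `100 · fibrosis / (muscle + fibrosis)` on areas **pooled across all
retained fragments of a patient** — the ratio of totals, not the mean of
per-fragment ratios — weighting each fragment by its tissue area and
minimising sampling bias.  Background never enters the denominator.
Quality control excludes fragments with < 0.25 mm² tissue and flags patients
with < 2 mm² total retained tissue as unusable (the clinical
insufficient-quality rule applied at the patient level; the per-fragment
minimum is a separate configurable).

## Cohort model

The simulator reproduces the published marginal structure of a tertiary-
centre DCM biopsy cohort (n = 524): age N(54.0, 13.4²) years, BMI
N(27.1, 5.7²), LVEF N(31.3, 12.5²) truncated to (5, 70) %, NT-proBNP
log-normal with µ = ln 655 and σ = ln(2253/218)/(2·z₀.₇₅) ≈ 1.73 (median and
IQR-ratio matched exactly; a log-normal cannot also match both quartiles,
and the achieved quartiles are returned as a diagnostic), creatinine
log-normal with natural-scale mean 1.0 / SD 0.6 mg/dl, diabetes
Bernoulli(0.176), NYHA categorical (0.403, 0.256, 0.171, 0.171), CVF
N(32, 15²) truncated to [0, 100] (or supplied externally from the image
stage).

Event times follow a Weibull proportional-hazards model sampled by inverse
transform (exact, no root finding): S(t|x) = exp(−(t/λ)^k e^η z) with shape
k = 1.2 and linear predictor η = β_cvf·1[CVF > τ] + Σ β_j (x_j − c_j) on
centred covariates.  Defaults: τ = 32, β_cvf = ln 3, β on log NT-proBNP 0.32
and on LVEF/5 ln 0.87 (published univariable magnitudes).  Two endpoints
come from two latent times — an HF-event time (baseline scale 150 y) and a
death time (65 y) — sharing a log-normal frailty (σ = 0.3, mean-one) that
correlates them; the composite endpoint is their minimum, all-cause death is
the death time.  Censoring is exponential dropout (0.16/y) truncated at 8
years of administrative follow-up.  These baselines were calibrated once so
the default cohort reproduces the reference magnitudes — roughly 12%
composite events, 9–10% deaths, median follow-up ≈ 3.6 years — and were not
revisited.  The frailty exists only to correlate the endpoints; it is never
fitted.  The simulator is a test harness with known truth, not a claim about
any real cohort's data-generating process.

Missingness is injected completely at random (MCAR) per variable, never on
follow-up or event columns.  MCAR is the favourable case for predictive mean
matching; conclusions about MAR/MNAR robustness cannot be drawn from these
tests.

## Survival machinery

* **Kaplan–Meier / log-rank** are implemented directly (the 91-threshold
  scan makes log-rank the inner loop): product-limit over event-time risk
  sets; two-group Mantel–Haenszel statistic (ΣO₁ − ΣE₁)²/ΣV with
  hypergeometric variances, χ²₁ reference.  Both are cross-checked in the
  test suite against an independent brute-force risk-set enumeration (to
  1e-10) and against lifelines.
* **Cox regression** maximises the partial likelihood by damped Newton
  iterations on internally standardised covariates (gradient norm < 1e-8),
  with Efron's tie correction by default (Breslow available; Efron is the
  better-behaved default and the reference analysis does not state its
  choice).  Standard errors come from the inverse observed information,
  p-values are Wald, AIC = −2 logPL + 2k.  A monotone partial likelihood
  (perfect separation) is detected via unbounded standardised coefficients
  and flagged rather than silently reported.  The fitter agrees with
  lifelines to ~1e-4 in coefficients (their convergence tolerance) and
  ~1e-6 in log partial likelihood.
* **Model ladder**: each candidate predictor is fitted alone and with CVF
  added; on multiply-imputed data the coefficients are pooled by Rubin's
  rules and AIC is computed per imputation and averaged — AIC is undefined
  for a pooled fit, so the average is a reporting convention and is labelled
  as such.  Predictors collinear with the adjuster are flagged, not dropped.
* **Backward elimination**: univariable screening at α = 0.10, then repeated
  removal of the largest-Wald-p term until all terms satisfy α = 0.05.
  Multi-column (categorical) terms use multi-df Wald tests.  Ties remove the
  later term in declared order, making the path deterministic.  Wald is used
  for elimination decisions; the likelihood-ratio test is reserved for the
  spline nonlinearity comparison, which is explicitly a model-fit question.
* **Restricted cubic splines** use the standard truncated-power
  parameterisation with linear tails, knots at the conventional quantiles
  (0.05/0.35/0.65/0.95 for four knots).  Nonlinearity is tested by LR of the
  spline model against the nested linear model on k − 2 df.
* **Multiple imputation**: per imputation, a nonparametric bootstrap sample
  is drawn, a linear predictor for each incomplete variable is fitted on the
  bootstrap complete cases from the other imputation variables, and each
  missing value is filled with the observed value of a random donor among
  the 5 nearest predicted means (PMM).  The bootstrap propagates parameter
  uncertainty; PMM keeps imputations inside the observed support, so binary
  and ordinal variables need no special model (they are matched on the
  linear score).  Variables are chained in order of increasing missingness
  for one pass (configurable).  Pooling follows Rubin's rules with
  Barnard–Rubin degrees of freedom.  The library default is m = 50; the
  heavier simulation tests use m = 10, which changes only Monte-Carlo noise,
  not validity.
* **Descriptive comparisons** dispatch strictly by declared variable type
  (t-test / Mann–Whitney U / χ²) — never inferred from the data.  The
  logit-scale correlation uses Pearson's r on logit(x/100) with a Fisher-z
  interval; boundary percentages require an explicit clamp ε.
* **Printed percentages** are rounded half-up at the reported decimals
  (`proportion_percent`), matching clinical-table conventions; banker's
  rounding would print 2.10% as 2.1 but 0.755 as 0.76 inconsistently.

## Cutpoint scan

Integer thresholds t = 5 … 95 (91 candidates) dichotomise CVF as
"< t vs ≥ t"; each is log-ranked and the smallest p wins, ties going to the
smallest threshold.  (The reference analysis labels its final groups
"≤ 32 / > 32"; with continuous CVF the two conventions coincide almost
surely at integer thresholds.)  A threshold is degenerate — excluded from
the argmin — when either group is empty or has zero observed events.

Minimum-p selection is optimistic: `minp_null_calibration` simulates
cohorts with CVF independent of outcome and reports how often the minimum p
dips below 0.05 (≈ 0.5–0.6 at n = 500 with 91 thresholds), against a
fixed-threshold control arm that stays at the nominal 5%.  No corrected
p-value is offered; the number is the caveat.

### Operating characteristics and harness choices

Recovery and coverage simulations use a *minimal characterisation harness*:
only the change-point effect active, no frailty, administrative censoring
only.  Two deliberate reasons: the Cox-coverage experiment specifies a
proportional-hazards truth, which the frailty (by design) violates
marginally; and the cutpoint-recovery experiment characterises the scan
itself, so nuisance dispersion is switched off, as is standard in the
minimum-p cutpoint literature.  Under this harness (n = 500, HR 3 at 32%,
~100 events) the scan recovers the true change point within ±3 points in
roughly 80–88% of replicates.  Two honest caveats measured along the way:
under the default, dropout-calibrated censoring (~60 events) recovery drops
to ~66%, and rare extreme-threshold singletons (one subject above t with an
early event) can win the scan with absurdly small p — confirmed identical
in lifelines, i.e. a property of the unrestricted min-p procedure, not of
this implementation.  Both effects argue for restricting scans to an inner
covariate range in applied use.

## Numerical and engineering choices

Every stochastic operation takes an explicit seed; there is no global
random state, and identical inputs give bit-identical slides and cohorts.
Slide IO round-trips losslessly (PNG raster + single-channel PNG mask +
JSON sidecar; a missing sidecar is an error, never a defaulted resolution).
The pipeline runner writes a manifest with SHA-256 hashes of every output;
reruns with the same config are numerically identical.  Simulation sizes in
the test suite (e.g. 20 seeds per planted CVF, 100 Cox replicates at
n = 2000, m = 10 imputations × 50 replicates) are chosen so the whole suite
characterises the statistics in a few minutes on a single core.

## Known limitations

* The colour model is Gaussian and stationary; no stain normalisation is
  attempted or needed for synthetic data.
* Only two-group log-rank is implemented (the scan needs nothing more);
  no stratified or trend tests.
* No competing-risks treatment: all-cause death censors nothing in the
  composite analysis beyond ordinary right censoring.
* PMM with linear predictors assumes roughly monotone relationships among
  the eight imputation variables; highly nonlinear dependence would degrade
  imputations.
* The min-p cutpoint is reported without a selection-adjusted p-value; the
  null-calibration module quantifies, but does not correct, the optimism.
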