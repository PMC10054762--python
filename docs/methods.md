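# Methods

## Scope and data flow

The package takes integrated peak-area tables (CSV; comma-separated,
UTF-8, period decimals, header required) and produces: a fitted
calibration line with per-level back-calculation statistics and LOD/LOQ;
QC precision/accuracy with a threshold-based validation verdict;
extraction recovery, matrix effect and IS-normalized matrix effect from
paired two-group designs; a quantitative carryover check; and a
substrate-depletion kinetic analysis (k, in vitro t½, CLint, clearance
class). Chromatogram acquisition, peak integration and any in silico
site-of-metabolism modelling are out of scope; inputs begin at
integrated areas.

Units are fixed globally: concentrations in ng/mL, time in minutes,
areas in arbitrary detector counts. Intrinsic clearance is reported in
both mL/min/kg (headline, whole-body scaling) and µL/min/mg (per-mg
incubation scale); these differ by the factor 45·26/1000 = 1.17 under
the default scaling constants, and the two published unit labels for
this quantity refer to these two different scales.

## Calibration

The response is the analyte/IS area ratio. The fit is ordinary
*unweighted* least squares of ratio on nominal concentration — by
design, since the validated method this package mirrors applied no
weighting. Replicates are averaged to one ratio per level before
fitting (default; per-replicate fitting is an option). r² is regression
SS over total SS; a two-point fit is exact with r² = 1. All statistics
are carried at full floating precision; rounding to printed decimals
happens only at report rendering.

Back-calculation inverts the line and deliberately allows negative
results: values below LOD are reported and flagged by the caller, never
clipped, so that level summaries remain unbiased.

LOD/LOQ use the intercept-dispersion convention, with SD(intercept)
taken **across replicate calibration curves** (≥ 2 required; the
single-fit intercept standard error is available as a non-default
fallback) and the slope as the mean of curve slopes. LOQ/LOD = 10/3.3
identically.

Per-level and QC statistics use the sample SD (n−1). Accuracy is the
signed percent error; recovery = accuracy + 100 by algebraic identity
(both are reported because both conventions appear in validation
tables). Inter-batch statistics pool all replicates across batches
rather than averaging per-batch means.

## Validation thresholds

Guideline limits are configuration, not constants: defaults are |bias|
and RSD ≤ 15% (20% at the LLOQ), calibration r² ≥ 0.98, IS-normalized
matrix effect within 0.85–1.15, and blank carryover ≤ 20% of the LLOQ
response. Carryover is quantified (blank response after a high sample,
as a fraction of the LLOQ response) rather than assessed visually;
specificity review of chromatograms is out of scope. The acceptance
report lists every criterion as (value, limit, verdict) and the overall
verdict is their conjunction — failures are listed, never hidden, and
the evaluation is monotone: worsening any single statistic can only
flip pass→fail.

## Depletion kinetics

Replicate concentrations are averaged per stop time before
normalization (matching how reference tables report the mean of three
incubations); % remaining is 100·mean(t)/mean(0), so t = 0 is exactly
100%. The ln-linear fit is performed in %-remaining space (intercept
≈ ln 100 = 4.605); fitting ln-concentration gives the identical slope.
Both calibration and depletion share one OLS kernel
(`microstab._regression.ols_line`, backed by `scipy.stats.linregress`),
so the two stages cannot drift numerically.

Window selection is manual (default 0–30 min) or automatic. Automatic
mode takes the *longest prefix anchored at t = 0* whose ln-linear r²
clears a floor (default 0.98, ≥ 4 points); internal windows are
rejected to avoid cherry-picking a transiently linear stretch.

t½ = ln 2/|slope|. A reported-precision mode rounds the slope to 4
decimals before t½ and t½ to 2 decimals before clearance scaling,
reproducing the arithmetic chain of printed tables (23.82 vs the
full-precision 23.85 min, a ≈ 0.1% difference); full precision is the
default. The clearance scaling uses the literal constant 0.693 of the
conventional formula rather than ln 2 (0.02% difference, invisible at
reported precision). Default clearance bands put low < 15,
intermediate 15–45, high > 45 mL/min/kg; published scoring schemes
differ in their cut-points, so the bands are plain configuration.

Degenerate inputs are surfaced as typed errors: a non-negative slope
means no measurable depletion (t½ undefined, reported as such, never
as a huge number); a missing t = 0 or non-positive baseline blocks
normalization; identical times are a singular design.

## Synthetic data

No raw replicate-level peak areas are publicly deposited for this
assay, so the generators produce every input table with the statistical
structure the estimators assume; all are deterministic given a seed.

**Calibration/QC**: ratio = 1.7298·C + 3.62941 plus independent Normal
noise with SD = additive_sd + proportional_cv·slope·C. Negative draws
are resampled, not truncated, to avoid biasing low levels. The additive
default (0.03 ratio units) gives ~2% replicate RSD at the 1 ng/mL LLOQ,
matching the reported low-end precision. The proportional default is
0.001, pinned by the reported between-curve intercept dispersion: an
LOD of 0.26 ng/mL implies SD(intercept) ≈ 0.14 ratio units, and under
unweighted fitting over a 3000-fold range the intercept SD grows as
roughly 160·proportional_cv (established by simulation). This is a real
trade-off of the single-channel noise model: the reported *mid- and
high-level* RSDs (~1–1.4%) arise in practice largely from between-curve
slope variation, which an independent per-point noise model cannot
represent simultaneously with a stable intercept. The defaults
therefore anchor the low end (which drives LOD/LOQ and validation
verdicts); simulated mid/high-level RSDs run below the printed ones.

**Matrix-effect sets**: neat responses at nominal areas; matrix
responses scaled by the true ME with unit-mean lognormal noise, so the
mean-ratio estimator is unbiased.

**Depletion**: C(t) = c0·[(1 − p)·exp(−k·t) + p] with multiplicative
lognormal replicate noise (concentrations are positive and dispersion
roughly proportional to the mean). The plateau p is a fixed
non-depleting fraction — it reproduces the observed flattening of real
time courses near 30% remaining by 70 min without asserting a mechanism
(parallel non-CYP fate vs cofactor exhaustion are indistinguishable
here). Replicate CV defaults to 5%; reference tables publish only
means, so this dispersion is a chosen, realistic value, not a fitted
one. Note that with a plateau present, the 0–30 min ln-linear slope
*understates* the fast-phase rate constant (the same is true of the
real assay — the printed k of a real table is the fitted window slope,
not a pure fast-phase rate); parameter-recovery guarantees are
therefore stated for the monoexponential setting (p = 0), which
isolates estimator error from model mismatch.

What passing tests on synthetic data do **not** show: real instrument
drift, autocorrelated residuals within a run, heteroscedasticity beyond
the additive+proportional form, matrix lots with genuinely different
suppression, or incomplete NADPH initiation at t = 0.

## Problem sizes

Stochastic checks use 100–500 simulated studies of the real assay's
dimensions (11 levels × 6 replicates; 10 stop times × 3 replicates),
sizes at which the Monte-Carlo error of the checked medians and means
is far below the asserted tolerances.

## Known limitations

- Only the unweighted linear calibration model is implemented; 1/x,
  1/x² weighting and quadratic models are plausible extensions.
- No Michaelis–Menten kinetics: the depletion analysis presumes
  substrate ≪ Km so depletion is first order.
- CLint stops at the intrinsic scale: no well-stirred hepatic blood-flow
  model, no plasma-protein-binding correction, no in vivo PK simulation.
- No stock/freeze-thaw/bench-top stability assessments.
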