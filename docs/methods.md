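# Methods

`fltpet` implements the quantitative core of an early radiotherapy-response
analysis of [18F]fluorothymidine (FLT) PET in non-small cell lung cancer:
SUV quantification, test-retest repeatability, percent response with
biologically effective dose, a random-intercept offset ANCOVA on
log10-transformed lesion parameters, rank statistics, and exploratory
survival analysis. Because no per-lesion patient data are released for this
setting, every stage is exercised on a synthetic cohort generator that
reproduces the statistical structure the analysis assumes.

## SUV quantification

Activity-concentration images (kBq/ml) are converted voxelwise to
standardized uptake values

    SUV (g/ml) = A (kBq/ml) × weight (kg) / dose (MBq),

the conventional body-weight normalization in which 1 kBq/ml at a
dose-to-weight ratio of 1 MBq/kg gives SUV 1.0 (tissue density 1 g/ml is
implicit in the unit cancellation). If an image is not already
decay-corrected, activity is referred back to injection time — the universal
SUV convention — using the F-18 half-life of 109.77 min. Small negative
voxels (up to 1% of the image maximum, a reconstruction-noise allowance) are
clamped to zero; larger negatives are rejected.

Post-reconstruction smoothing is an isotropic Gaussian of given FWHM
(default 4 mm, the acquisition protocol's filter), with σ = FWHM/2.3548 per
axis converted to voxels. Smoothing and SUV normalization are both linear,
so their order is immaterial; the package smooths the SUV map.

VOI statistics are computed on voxel-aligned binary masks sharing the image
grid exactly: volume = voxel count × voxel volume, SUV_mean = arithmetic
mean, SUV_max = maximum. Fractional (partial-volume) masks and registration
are out of scope; mis-registration risk is addressed only by the
bone-overlap QC, which counts lesion voxels within a configurable
6-connectivity margin of a bone-marrow mask (default: zero overlapping
voxels allowed). Proliferating marrow is FLT-avid, so any overlap can
corrupt lesion uptake — especially SUV_max — and the delineation protocol
requires a margin.

## Test-retest repeatability

For duplicate baseline scans the percentage difference is
(S2 − S1)/(S1 + S2) × 200 — the difference relative to the pair mean,
antisymmetric under swap and bounded in (−200, 200). Reproducibility is the
sample SD (n − 1) of these differences and the mean absolute difference;
the repeatability coefficient RC = 1.96 × SD is the threshold a
longitudinal change must exceed to be distinguishable from measurement
noise. Differences are averaged at the lesion level by default (each lesion
one observation); patient-level averaging (patient means first) is a
documented option since summary conventions differ between publications.
Volume precision is size-dependent (checked by a Spearman correlation of
|difference| with the pair-mean size), so volume RCs are reported per
lesion type while SUV RCs are pooled.

Change classification compares a response to the closed interval
mean bias ± RC; a value exactly on the boundary is called "within"
(conservative calling of change).

## Response and biologically effective dose

Response (%) = (S3 − baseline)/baseline × 100, with the latest available
baseline (S2 if present, else S1). For small changes this agrees with the
test-retest difference metric to first order. Extreme responses are kept by
default (an exclusion flag exists but is off): a grossly enlarging node is
data, not an artifact. BED = n·D·(1 + D/(α/β)) converts the fractionation
actually delivered before the response scan (n fractions of D Gy) to a
linear-quadratic equivalent dose; α/β defaults to 10 Gy, the conventional
tumour value. Schedules are per patient; per-lesion dosimetry is not
modelled.

## The mixed-effects offset ANCOVA

The core inference engine is the log10-scale model

    log10(y1_ij) = log10(y0_ij) + (β0 + b_i) + β1·x1_ij + ε_ij,

where j indexes lesions within patient i, x1 is the node indicator,
b_i ~ N(0, σ_b²) is a patient random intercept and ε_ij ~ N(0, σ²) is
lesion-level error. The baseline enters as an offset (coefficient fixed at
1), so the model is a random-intercept regression of the log-ratio
z = log10(y1/y0). Applied to duplicate baselines it measures systematic
retest drift; applied to baseline→on-treatment pairs it measures the
treatment effect with the node-vs-primary contrast.

Estimation is maximum likelihood by profiling. For fixed λ = σ_b²/σ² the
marginal covariance is σ²(I + λZZ′) with a block-diagonal patient
structure, so GLS gives β̂(λ) and σ̂²(λ) in closed form via the per-block
Sherman-Morrison identity (I + λJ_m)⁻¹ = I − λ/(1 + λm)·J_m; the remaining
1-D profile likelihood in λ is maximized by a deterministic coarse log-grid
scan (λ ∈ {0} ∪ [1e−6, 1e4]) followed by bounded refinement, with the λ = 0
boundary always evaluated explicitly and flagged when optimal. The fit is
bit-stable across runs. ML (not REML) is the default so the AIC of the
four-parameter model (β0, β1, σ_b², σ²) is well defined; REML is available
for variance-component reporting. The implementation matches an independent
mixed-model reference (statsmodels MixedLM, ML) to ~1e−8 on fixed effects
in the cross-check tests, and its optimum dominates dense (λ, σ²) grid
searches to 1e−6 in log-likelihood.

Effect sizes are back-transformed to percent change, 10^β0 − 1 for
primaries and 10^(β0+β1) − 1 for nodes, with 95% Wald intervals computed on
the log10 scale (contrast SE from the fixed-effects covariance) and
back-transformed endpoint-wise; intervals are therefore asymmetric on the
natural scale. Wald-normal is the default; a Wald-t variant with
n_lesions − 2 degrees of freedom is offered because small-sample normal
intervals under-cover (observed coverage ~95% at the 12-patient scale in
the recovery suite, but this is configuration-dependent). The variance
partition σ_b²/(σ_b² + σ²) is the fraction of residual variation
attributable to patient heterogeneity. Boundary estimates (λ̂ = 0) are
reported with a flag and no boundary correction of p-values — a documented
limitation. A continuous covariate (BED) can be added as a fifth parameter;
model comparison is by ΔAIC, and a constant covariate is rejected as
collinear with the intercept.

Lesions with any missing required scan are dropped listwise per model.
Multiplying all y0 and y1 by a common constant leaves every estimate
unchanged (offset structure), which the tests assert.

## Rank statistics

Spearman correlation uses midranks for ties and a two-sided p from the
t-approximation with n − 2 df (standard at the cohort's n of ~18-48 pairs);
an exact full-permutation p is offered for n ≤ 10. The Wilcoxon rank-sum
test uses the exact null distribution of the rank sum (dynamic programming
over rank subsets) when n1 + n2 ≤ 20 without ties, otherwise a normal
approximation with tie-corrected variance and continuity correction. No
multiple-testing correction is applied anywhere, matching the exploratory
character of the analysis.

## Outcome analysis

The Kaplan-Meier estimator uses Greenwood's variance with log-log
confidence bands; the median is the earliest time with Ŝ ≤ 0.5 and its CI
is the set of times whose band contains 0.5. Univariate Cox regression
maximizes the partial likelihood by Newton-Raphson with step-halving; Efron
tie handling is the default (less biased than Breslow, which is also
available and identical when no ties exist). Hazard ratios are per one unit
of the continuous covariate; monotone likelihood (perfect separation) is
flagged as non-convergence. Both estimators match lifelines to ~1e−6 on
shared fixtures (tests only; lifelines is never used at runtime).

## Synthetic data

The cohort generator realizes the offset model exactly: per patient a node
count uniform on the configured range (default 0-3, one primary each) and a
random intercept per imaging parameter (a shared-intercept flag exists,
default off since each parameter is fitted separately); per lesion a true
baseline log10 value; per scan the baselines plus independent retest noise,
and the on-treatment value built from the observed latest baseline plus
fixed effects, random intercept and lesion residual. All draws come from
one seeded stream in documented order, so cohorts are bit-identical under a
fixed seed.

The reference preset encodes the published study conditions: 12 patients
(≈12 primaries and ≈18 nodes in expectation), baseline lognormal
distributions moment-matched to the published natural-scale baseline
means/SDs per lesion type, model coefficients and variance components per
parameter from the published response-model fits, and per-parameter retest
noise √((σ_b² + σ²)/2) from the published reproducibility-model components
so that duplicate-scan differences reproduce that model's total variance.
These defaults were fixed from the published tables once, not tuned.

What the generator does not emulate: partial-volume and respiratory-motion
interactions between size and uptake, delineation variability, non-Gaussian
heavy-tailed responses (the published cohort contained a +170% outlier
node), correlations between the three parameters beyond a shared random
intercept, and any dose-response structure (BED enters the synthetic data
only as a covariate candidate with zero true effect). Passing tests
therefore demonstrate that the estimators recover the model they assume at
the study's scale — not that real FLT PET data satisfy that model.

Phantoms voxelize ellipsoidal lesions (inclusion by voxel-center), a
bone-marrow box and uniform background at a configurable grid (default the
scanner's 2.67 × 2.67 × 2.00 mm voxels), then smooth and add Gaussian
noise; masks are returned pre-smoothing as ground truth, and overlapping
lesions are rejected as ambiguous. Survival data are exponential with
log-hazard linear in the patient's on-treatment primary SUV_max and
independent exponential censoring calibrated to an approximate censoring
fraction.

## Numerical choices and problem sizes

Profile-likelihood convergence tolerance 1e−12 on λ (bounded scalar
search); Cox Newton tolerance 1e−9 on score and step with up to 30
step-halvings; smoothing uses the truncated discrete Gaussian kernel
(truncation at 4σ). The validation suites run at deliberately modest sizes
chosen to give tight Monte-Carlo error while staying quick on one CPU: 200
simulated cohorts at the 12-patient study scale for parameter recovery and
coverage, 500 patients for closed-form effect checks, 10⁴ null datasets for
the exact rank-sum type-I error, and ≤10-record fixtures for the
grid-search oracles.

## Known limitations

Wald inference only (no likelihood-ratio or bootstrap intervals); no
boundary-corrected tests for σ_b² = 0; no REML-based AIC; no multivariate
Cox or cut-point survival analysis (deliberately excluded); NIfTI only, no
DICOM; masks must share the image grid (no resampling or registration).
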