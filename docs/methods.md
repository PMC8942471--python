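# Methods

This note documents the statistical procedures implemented in `lipidpipe`,
the assumptions behind them, the defaults and why they were chosen, what the
synthetic cohort generator does and does not emulate, and the numerical
conventions used throughout.

## Scope and data model

The package operates downstream of vendor peak integration: its input is a
samples × lipid-features table of non-negative concentrations (arbitrary
units relative to internal standards), a sample manifest (subject, role ∈
{biological, PQC, TQC, NIST}, batch, time point, matrix, exclusion flag), a
feature annotation (lipid class, species, quantification mode ∈ {standard,
NL, SIM}, retention flag) and a covariate table. Two kinds of "absent"
value are distinguished and never conflated: `0` is a measurement below the
instrument's detection threshold (handled by zero replacement), `NaN` is a
missing measurement (handled by kNN imputation).

All log-scale arithmetic is base 10: concentrations are log₁₀-transformed
for harmonization, imputation distances, outlier Z-scores, regression
outcomes and paired differences. The base matters only for coefficient
interpretation; percentage change uses the matching transform
(10^β − 1) × 100.

## Preprocessing chain

The stages run in a fixed order — zeros → batch alignment → imputation →
outlier detection → exclusions — because each stage's contract assumes the
previous one (log transforms need positive values; imputation distances need
aligned batches; the outlier screen needs a complete matrix).

### Zero replacement

Within each *sample type* (time point × matrix for biological samples; each
QC role its own group), every zero of feature *f* becomes min⁺(f)/10, one
tenth of the smallest positive observed value of that feature in the group.
Grouping by sample type keeps the imputed floor on the scale of the
biology at that age and matrix. A feature with no positive value in a group
has no anchor; its zeros are set to missing (and logged) rather than
guessed.

### Batch harmonization

Pooled plasma QC (PQC) samples are aliquots of one pool injected in every
batch, so any systematic between-batch difference in their measured values
is analytical. Per feature, on the log₁₀ scale:

1. **Location**: every sample in batch *b* is shifted by
   (median over all PQC samples − median over batch-*b* PQC samples).
2. **Scale**: within each batch, values are rescaled about the batch's
   *biological-sample* median so that the batch SD of biological samples
   equals the unweighted mean of those SDs across batches. The SD is
   estimated from biological samples only (QC replicates measure analytical,
   not biological, spread) but the correction is applied to all samples in
   the batch so QC samples stay on the same scale. A batch with zero
   biological SD for a feature is left unscaled for that feature.

Both corrections are monotone per batch, so within-batch rank order is
preserved, and the procedure is idempotent.

Two properties of this estimator are worth stating explicitly because the
recovery tests are built around them:

* It re-anchors location to the *global* PQC median and scale to the *mean*
  batch SD, so a planted distortion is exactly removable only when the
  planted shifts have median zero and the scale factors mean one — any
  other distortion is removed up to a global location/scale that no
  QC-anchored method could identify. The exact-recovery fixture
  (`synthdata.make_harmonization_fixture`) constructs identical biological
  blocks per batch, a pool profile equal to the biological median, and
  normalised shifts/scales accordingly.
* SD rescaling assumes batches are exchangeable in biological composition.
  The generator therefore randomises injection order before chunking samples
  into batches, as real studies do; if a biological contrast is confounded
  with batch, rescaling will shrink it. Relatedly, a multiplicative scale
  distortion multiplies every log-scale effect size, and harmonization
  restores effect sizes only up to the across-batch mean scale factor —
  the planted-effect recovery cohorts therefore carry batch location shifts
  (absorbed by the run-batch model term) but no scale distortion.

The "mean SD" target is the unweighted mean across batches; a
sample-size-weighted mean would differ only when batch sizes are very
unbalanced.

### kNN imputation

A missing value (sample *s*, feature *f*) is the arithmetic mean of log₁₀
values of *f* over the k nearest samples (default k = 5, uniform weights)
within the same sample-type group, back-transformed. Distance is plain
Euclidean over the log₁₀ features jointly observed in both samples —
deliberately not rescaled by the number of shared features, so the
documented metric is exactly what is computed. Neighbour search never
crosses sample types (serum and plasma matrices differ systematically, and
QC pools are not biology). Donors must observe the feature being imputed;
ties in distance break on sample id order. Groups smaller than k+1 samples
(small QC roles) fall back to all available donors with a logged warning.
Observed entries are never altered.

### Dual-criterion outlier screen

On biological samples only (QC replicates are monitored, never declared
cohort outliers): per-feature Z-scores of log₁₀ values (sample SD, ddof 1;
constant features contribute 0), then

* **Criterion A** — summed |Z| per sample, flag if strictly above the 95th
  percentile of the sums;
* **Criterion B** — PCA of the Z matrix (already unit-variance, no second
  scaling; full SVD solver for determinism), Euclidean distance to the
  origin over the first 7 component scores, flag if strictly above the 95th
  percentile of distances;
* **Declared** — A ∩ B.

Percentiles use linear interpolation between order statistics (the common
numerical default) and are computed globally over all scored samples; both
choices are configurable. Note what the rule controls: each criterion flags
a fixed ~5% of samples by construction, and for an exchangeable, noisy
cohort the two extremeness statistics are positively correlated, so the
intersection generally contains some ordinary samples. The screen is a
*triage* rule, not a false-positive-free detector; it cleanly isolates
planted gross outliers only against a homogeneous background, where the tied
percentile plus the strict ">" flags nothing ordinary.

### Retention bookkeeping and class totals

Exclusion reasons (missed injection, maternal contamination of cord serum,
declared outlier) are single-valued per sample; a pre-existing flag takes
precedence, and retained = total − |union of reasons|. Feature retention
marks irrecoverable measures; species-level analyses exclude SIM-mode
measures, which exist only to quantify triglyceride class totals. Class
totals are per-sample sums of species concentrations, with TG and TG(O)
summed from their SIM measures (abundant, less structurally resolved) and
every other class from non-SIM measures.

## QC metrics

Per-feature CV% = 100 × SD/mean (sample SD, ddof 1) over PQC replicates on
the concentration scale — the convention behind the usual 20% acceptability
threshold; a log-scale CV would not be comparable to it. Summaries are the
median CV and the fraction of features with CV < 20%. Computed by default
after harmonization (alignment removes between-batch offsets that would
otherwise inflate the pooled-QC spread); the before/after comparison is a
test invariant (harmonization never increases the median PQC CV).

## Association models

One OLS fit per lipid: log₁₀ concentration on the covariate set, listwise
deletion of rows with any missing covariate or outcome (effective n recorded
per fit). Inference is exact-t: 95% CIs at n − p degrees of freedom.
Implementation uses shared-design linear algebra (the (XᵀX)⁻¹ factor is
cached across features with identical row sets), cross-checked against
statsmodels OLS in the test suite.

Categorical covariates are treatment-coded; reference levels: unassisted
vaginal birth for mode of birth, female for sex, "n" for GDM and
breastfeeding, secondary for maternal education. Presets:

* `birth` — birth weight (kg), gestational age (days), mode of birth,
  duration of labour (h), sex, maternal pre-pregnancy BMI (kg/m²), GDM,
  maternal education, maternal age (y), birth order, run batch.
* `breastfeeding_6m` — breastfeeding status plus sex, child age at draw
  (days), gestational age, the maternal covariates, and run batch.
  Gestational age still influences lipids at 6 months, hence its inclusion.
* `breastfeeding_12m` — as above without gestational age.

Run batch enters every preset: even after harmonization a batch term is a
cheap guard against residual technical structure.

Percentage change (10^β − 1) × 100 is applied to the coefficient and both
CI bounds. BH step-up adjustment (statsmodels `fdr_bh`) is applied per
model term across features, i.e. FDR is controlled separately for each
tested covariate. Profile comparison regresses one term's per-feature betas
on another's (least squares; slope, intercept, r²) and reports the fraction
of opposing signs over features significant (adjusted p < 0.05) for at
least one of the two terms. The forest-table export orders species rows by
category (sphingolipids → phospholipids → other lipids) → class → species,
inserts one class row per class (filled from class-total associations when
supplied, structural otherwise), and tiers significance as non-significant /
significant / top-10 by raw p with id-order tie-breaking (ties at the
boundary are flagged).

## Paired comparisons and trajectory clustering

Paired tests operate on per-subject log₁₀ differences over complete pairs:
Wilcoxon signed-rank (exact null distribution for n ≤ 25, normal
approximation with continuity correction above; zero differences dropped;
an all-zero difference vector yields p = 1 with a degenerate flag) or
paired t. The fold difference is geometric, 10^(mean log₁₀ difference), and
log₂FC its base-2 counterpart — a mean of paired ratios on the log scale
rather than a ratio of group medians, because the pairing is the unit of
information. BH adjustment is across features.

Trajectories are per-feature medians of log₁₀ concentration per time point
(excluded samples omitted), z-normalised per feature so clustering groups by
*shape*; unnormalised trajectories would cluster by abundance. Dissimilarity
is classic dynamic time warping: absolute-difference local cost, symmetric
unit steps (match/insert/delete), no warping window — appropriate for
5-point trajectories where any constraint would forbid most alignments.
Clustering is PAM: greedy BUILD initialisation plus best-improvement SWAP,
run once from BUILD and from `restarts − 1` seeded random initialisations
(default 10), keeping the lowest total within-cluster dissimilarity with
sorted-medoid tie-breaking. k is fixed by the caller (default 10); no
automatic k selection is attempted. PAM matches the exhaustive medoid
optimum on all tested instances with n ≤ 10.

## Synthetic cohort generator

`generate_cohort` emulates, per feature *f*, sample *s* at time point *t*:

log₁₀ x = μ_f + τ_{f,t} + δ_{subject,f} + planted effects + ε,

with μ_f ~ U(−1, 3) (baselines spanning ~4 orders of magnitude, the spread
across lipid classes), τ time-point offsets (SD 0.10), δ between-subject
variation (SD 0.20), ε measurement noise (SD 0.05) — all log₁₀-scale SDs.
Batch distortions apply to all samples of a batch about the pool profile:
L′ = shift_b + μ_f + scale_b·(L − μ_f), shift ~ N(0, 0.15), scale lognormal
(σ = 0.10), or explicit per-batch values. PQC/TQC samples are noisy
replicates of the pool profile μ; the per-feature replicate noise SD has
median 0.044 with lognormal spread 0.5, chosen so the pooled-QC CV
distribution matches the analytical quality a well-run targeted assay
reports (median CV ≈ 10%, ≈ 92% of features < 20%). QC samples are
interleaved at one PQC and one TQC per 20 biological samples and one NIST
per 40 (floored at two PQC/TQC per batch so tiny test cohorts remain
harmonizable), and injection order is randomised before batch assignment.
Zeros are censoring: values below the per-feature `zero_rate` quantile are
recorded as 0. Missingness is independent thinning at `missing_rate`.
Covariates: gestational age (days) and birth weight (kg) jointly normal
with r = 0.45; four modes of birth at the cohort's observed proportions
(unassisted VB reference); labour duration zero for scheduled caesareans;
breastfeeding at 12 months persists from 6 months. Planted effects are
slopes on log₁₀ concentration per covariate unit (centred) or fold
differences between groups, optionally restricted to time points; default
antenatal profiles set β_birthweight = −10.5·β_gestational-age + noise so
most features associate with the two in opposite directions.

What the generator does **not** emulate: retention-time drift or hydrolysis
within a run, correlated missingness, matrix-specific lipid differences
(serum vs plasma enter only as grouping labels), lipid–lipid correlation
structure (features are independent given the subject), subject attrition,
and non-Gaussian heavy-tailed biology. Passing recovery tests therefore
demonstrate that the estimators invert the distortions they model, not that
real data meet those models.

## Problem sizes and determinism

Default verification sizes: CI coverage uses 200 replicate cohorts of 800
subjects × 50 features (10,000 CIs); type-I error uses 1,000 independent
features at n = 800; planted-fold recovery uses 700 subjects; the outlier
screen uses 500 samples × 120 features; trajectory recovery uses 10
archetypes × 20 features over 5 time points; DTW/PAM oracles enumerate
series of length ≤ 6 and medoid sets for n = 10. All randomness flows from
explicit integer seeds through `numpy.random.default_rng`; repeated runs are
bit-identical, and ties everywhere break on id order.

## Known limitations

* Harmonization identifies batch effects only relative to the pooled-QC
  anchor; drift *within* a batch is untouched (within-batch drift correction
  and visual curation are out of scope).
* The outlier screen's percentile thresholds flag a fixed share of samples;
  interpret declared outliers as candidates for exclusion under a
  homogeneity assumption, not as a calibrated test.
* Association models are cross-sectional per time point; no mixed-effects
  or joint longitudinal modelling.
* kNN imputation is not uncertainty-aware; imputed values shrink toward
  local means and slightly understate variance.
* PAM is exact only in the brute-force-verified regime; for large feature
  sets the restarts bound, but do not guarantee, global optimality.
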