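# lipidpipe

QC-anchored harmonization, per-lipid association testing and trajectory
clustering for multi-batch targeted LC-MS lipidomics, aimed at longitudinal
birth-cohort studies where hundreds of lipid species are quantified in
thousands of serum/plasma samples across many analytical batches and several
time points (antenatal, birth, infancy, early childhood).

Cohort lipidomics data of this kind are typically access-restricted, so the
package ships a first-class synthetic cohort generator that reproduces the
statistical structure every stage assumes — log-normal concentrations
spanning orders of magnitude, pooled-QC samples interleaved at fixed
intervals, batch location/scale distortions, below-detection zeros, missing
values, gross outlier samples, and planted covariate effects — making the
whole chain testable end to end without any data download.

## What the pipeline computes

**Preprocessing** (`lipidpipe.preprocess`), in order:

1. *Zero replacement*: below-detection zeros for lipid *f* become
   min⁺(f)/10 within the sample type (time point × matrix for biological
   samples; each QC role separately).
2. *Batch harmonization*: on the log₁₀ scale, per feature, every sample in
   batch *b* is shifted by (global PQC median − batch-*b* PQC median); each
   batch's biological-sample SD is then rescaled about the batch biological
   median to the across-batch mean SD.
3. *kNN imputation*: a missing value is the mean log₁₀ value of the feature
   over the k nearest samples (Euclidean distance on jointly observed log₁₀
   features, within sample type), back-transformed.
4. *Dual outlier screen*: per-sample summed |Z| of log₁₀ concentrations
   (criterion A) and Euclidean distance to the origin in the space of the
   first 7 principal components of the Z matrix (criterion B); samples above
   the 95th percentile of **both** statistics are declared outliers.
5. *Retention bookkeeping* for samples (missed injections, contaminated
   cord sera, outliers) and features, plus lipid class totals (TG and TG(O)
   totals from SIM-mode measures, all other classes from non-SIM measures).

**QC** (`lipidpipe.qc`): per-feature CV% = 100·SD/mean over pooled-QC
replicates, with the median CV and the fraction of features below 20%.

**Association** (`lipidpipe.associate`): one OLS fit per lipid of log₁₀
concentration on a covariate set (named presets for cord-serum models and
breastfeeding models), with t-based 95% CIs, the percentage-change
translation *(10^β − 1) × 100*, Benjamini–Hochberg adjustment per model term
across features, β-profile comparison between two terms (slope, r²,
opposing-sign fraction), and forest-table export.

**Longitudinal** (`lipidpipe.longitudinal`): paired Wilcoxon signed-rank /
t tests on log₁₀ differences with geometric-mean fold differences and log₂
fold changes; per-feature time trajectories (median log₁₀ per time point,
z-normalised) clustered by dynamic-time-warping dissimilarity with
partitioning around medoids (PAM, BUILD + SWAP, seeded restarts).

## Worked example

```python
import lipidpipe as lp
from lipidpipe import preprocess as pp

effect = lp.PlantedEffect(("F0016",), "breastfeeding_6m", "fold", 17.0,
                          group="y", timepoints=("6m",))
cfg = lp.CohortConfig(n_subjects=300, n_features=40, n_batches=3, seed=7,
                      effects=(effect,), zero_rate=0.002, missing_rate=0.002)
matrix, manifest, annotation, covariates = lp.generate_cohort(cfg)

matrix = pp.replace_zeros(matrix, manifest)
matrix = pp.harmonize_batches(matrix, manifest)
matrix = pp.impute_knn(matrix, manifest, k=5)
report = lp.detect_outliers(matrix, manifest)
manifest, summary = lp.apply_exclusions(manifest, report)

cv = lp.compute_cv(matrix, manifest, role="PQC")
print(f"median PQC CV = {cv.median_cv:.1f}%, "
      f"{100 * cv.fraction_below_threshold:.1f}% of features < 20% CV")

cov6 = covariates[covariates["timepoint"] == "6m"]
sub = lp.ConcentrationMatrix(matrix.data.loc[
    [s for s in matrix.sample_ids if s in set(cov6["sample_id"])]])
res = lp.fit_lipid_regressions(sub, cov6, preset="breastfeeding_6m",
                               report_terms=["breastfeeding_6m"])
row = res[res["feature_id"] == "F0016"].iloc[0]
print(f"TG(O) species F0016: fold = {10 ** row['beta']:.1f}, "
      f"pct change = {row['pct_change']:.0f}% "
      f"[{row['pct_ci_low']:.0f}%, {row['pct_ci_high']:.0f}%], "
      f"adj p = {row['p_adj']:.2e}, n = {row['n']}")
```

prints

```
median PQC CV = 10.2%, 90.9% of features < 20% CV
TG(O) species F0016: fold = 16.0, pct change = 1504% [1332%, 1696%], adj p = 3.07e-138, n = 300
```

The pooled-QC replicates give a median analytical CV near 10%. The planted
17-fold elevation of the alkyldiacylglycerol species in breastfed infants is
estimated as a 16.0-fold difference (the covariate-adjusted regression
coefficient back-transformed from log₁₀), i.e. a +1504% concentration
difference with a tight confidence interval — recovered through the full
zero-replacement → harmonization → imputation → exclusion chain.

The same stages are available from the shell:

```bash
lipidpipe simulate --out cohort/ --seed 7
lipidpipe preprocess --matrix cohort/matrix.csv --manifest cohort/manifest.csv --out run/
lipidpipe qc --matrix run/processed_matrix.csv --manifest cohort/manifest.csv
lipidpipe run-all --out run_all/ --seed 7
```

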