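"""Data-processing chain for multi-batch LC-MS lipidomics.

Stages, in the order they are applied to a quantified cohort:

1. ``replace_zeros`` — below-detection zeros become one tenth of the minimum
   positive value of the same lipid within the same sample type.
2. ``harmonize_batches`` — batches are aligned by centring the pooled-QC
   medians on the log10 scale, then each batch's biological-sample standard
   deviation is rescaled to the across-batch mean SD.
3. ``impute_knn`` — missing values filled by k-nearest-neighbour means in
   sample space (Euclidean distance over jointly observed log10 features).
4. ``detect_outliers`` — dual criterion: summed absolute Z-scores and
   distance to the origin in the space of the first principal components;
   only samples flagged by *both* screens are declared outliers.
5. ``apply_exclusions`` / ``retain_features`` — retention bookkeeping.
6. ``compute_class_totals`` — lipid class totals, with SIM-only summation
   for triglyceride classes.

All log-scale arithmetic is base 10.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .containers import (
    ConcentrationMatrix,
    OutlierReport,
    SIM_TOTAL_CLASSES,
    ValidationError,
    sample_type_groups,
    validate_annotation,
    validate_manifest,
)

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# zero replacement
# ---------------------------------------------------------------------------

def replace_zeros(
    matrix: ConcentrationMatrix, manifest: pd.DataFrame
) -> ConcentrationMatrix:
    """Replace below-detection zeros by min-positive/10 within sample types.

    A sample type is ``timepoint x matrix`` for biological samples and the
    role itself for QC samples.  If a feature has no positive value within a
    group its zeros cannot be anchored and are set to missing (logged).
    """
    manifest = validate_manifest(manifest)
    groups = sample_type_groups(manifest)
    out = matrix.copy()
    df = out.data
    group_of = groups.reindex(df.index)
    if group_of.isna().any():
        missing = df.index[group_of.isna()][:5].tolist()
        raise ValidationError(f"samples absent from manifest: {missing}")

    for gname, idx in df.groupby(group_of, sort=True).groups.items():
        block = df.loc[idx]
        vals = block.to_numpy()
        pos = np.where(vals > 0, vals, np.nan)
        import warnings as _warnings
        with np.errstate(all="ignore"), _warnings.catch_warnings():
            _warnings.simplefilter("ignore", RuntimeWarning)
            min_pos = np.nanmin(pos, axis=0)
        zero_mask = vals == 0
        dead = np.isnan(min_pos) & zero_mask.any(axis=0)
        if dead.any():
            feats = list(block.columns[dead])
            logger.warning(
                "group %s: features %s are all-zero; zeros set to missing",
                gname, feats,
            )
        fill = np.where(np.isnan(min_pos), np.nan, min_pos / 10.0)
        vals = np.where(zero_mask, fill[None, :], vals)
        df.loc[idx] = vals
    return out


# ---------------------------------------------------------------------------
# batch harmonization
# ---------------------------------------------------------------------------

def harmonize_batches(
    matrix: ConcentrationMatrix, manifest: pd.DataFrame
) -> ConcentrationMatrix:
    """Align batches via PQC median centring and biological-SD rescaling.

    On the log10 scale, per feature: every sample in batch *b* is shifted by
    (global PQC median − batch-*b* PQC median); then each batch's values are
    rescaled about the batch's biological-sample median so the batch SD of
    biological samples equals the unweighted mean of those SDs across
    batches.  Batches whose biological SD is zero for a feature are left
    unscaled for that feature.
    """
    manifest = validate_manifest(manifest)
    man = manifest.set_index("sample_id")
    L = matrix.log10()
    man = man.loc[L.index]
    batches = sorted(man["batch"].unique())

    pqc_idx = man.index[man["role"] == "PQC"]
    if len(pqc_idx) == 0:
        raise ValidationError("no PQC samples present; cannot harmonize")
    for b in batches:
        if ((man["role"] == "PQC") & (man["batch"] == b)).sum() == 0:
            raise ValidationError(f"batch {b!r} lacks PQC samples")

    batch_of = man["batch"]
    # step 1: PQC median centring
    pqc_med = L.loc[pqc_idx].groupby(batch_of.loc[pqc_idx]).median()
    global_med = L.loc[pqc_idx].median(axis=0)
    shift = (-pqc_med).add(global_med, axis=1)  # batches x features
    L = L + shift.reindex(batch_of).to_numpy()

    # step 2: biological SD rescaling about the batch biological median
    bio_idx = man.index[man["role"] == "biological"]
    bio_batches = batch_of.loc[bio_idx]
    bio_med = L.loc[bio_idx].groupby(bio_batches).median()
    bio_sd = L.loc[bio_idx].groupby(bio_batches).std(ddof=1)
    target = bio_sd.mean(axis=0)  # unweighted mean across batches
    with np.errstate(divide="ignore", invalid="ignore"):
        factor = target.to_numpy()[None, :] / bio_sd.to_numpy()
    factor = pd.DataFrame(factor, index=bio_sd.index, columns=bio_sd.columns)
    factor = factor.where(np.isfinite(factor), 1.0)

    med_full = bio_med.reindex(batch_of).to_numpy()
    fac_full = factor.reindex(batch_of).to_numpy()
    L = pd.DataFrame(
        med_full + (L.to_numpy() - med_full) * fac_full,
        index=L.index,
        columns=L.columns,
    )
    out = np.power(10.0, L)
    out[matrix.missing_mask] = np.nan
    return ConcentrationMatrix(out)


# ---------------------------------------------------------------------------
# kNN imputation
# ---------------------------------------------------------------------------

def _masked_sq_euclidean(X: np.ndarray) -> np.ndarray:
    """Pairwise squared Euclidean distance over jointly observed entries."""
    M = (~np.isnan(X)).astype(float)
    A = np.where(np.isnan(X), 0.0, X)
    A2 = A * A
    # sum over features observed in both samples
    d2 = A2 @ M.T + M @ A2.T - 2.0 * (A @ A.T)
    np.fill_diagonal(d2, 0.0)
    return np.maximum(d2, 0.0)


def impute_knn(
    matrix: ConcentrationMatrix, manifest: pd.DataFrame, k: int = 5
) -> ConcentrationMatrix:
    """Impute missing values by the mean of the k nearest samples.

    Distances are Euclidean over jointly observed log10 features, computed
    within the sample-type group; the imputed value is the plain mean of the
    feature over the k nearest neighbours that observe it (log10 scale,
    back-transformed).  Ties in distance break on sample id order.  Groups
    smaller than k+1 samples fall back to all available donors (logged).
    """
    if k < 1:
        raise ValidationError("k must be >= 1")
    manifest = validate_manifest(manifest)
    groups = sample_type_groups(manifest)
    out = matrix.copy()
    if not out.missing_mask.to_numpy().any():
        return out
    L = out.log10()

    group_of = groups.reindex(L.index)
    for gname, idx in L.groupby(group_of, sort=True).groups.items():
        idx = pd.Index(sorted(idx))
        block = L.loc[idx]
        X = block.to_numpy()
        nan_mask = np.isnan(X)
        if not nan_mask.any():
            continue
        all_missing = nan_mask.all(axis=0)
        if all_missing.any():
            feats = list(block.columns[all_missing])
            raise ValidationError(
                f"group {gname}: features missing in all samples: {feats}"
            )
        k_eff = k
        if len(idx) < k + 1:
            if len(idx) < 2:
                raise ValidationError(
                    f"group {gname}: needs at least 2 samples to impute"
                )
            k_eff = len(idx) - 1
            logger.warning(
                "group %s: only %d samples; using k=%d", gname, len(idx), k_eff
            )
        d2 = _masked_sq_euclidean(X)
        order = np.argsort(d2, axis=1, kind="stable")  # id-sorted rows => stable ties
        filled = X.copy()
        for i in np.flatnonzero(nan_mask.any(axis=1)):
            for j in np.flatnonzero(nan_mask[i]):
                donors = [
                    c for c in order[i] if c != i and not nan_mask[c, j]
                ][:k_eff]
                if not donors:
                    raise ValidationError(
                        f"group {gname}: no donor for sample {idx[i]!r}, "
                        f"feature {block.columns[j]!r}"
                    )
                filled[i, j] = np.mean(X[donors, j])
        L.loc[idx] = filled

    vals = np.power(10.0, L)
    observed = ~matrix.missing_mask
    vals = vals.where(~observed, out.data)  # never alter observed entries
    return ConcentrationMatrix(vals)


# ---------------------------------------------------------------------------
# outlier detection
# ---------------------------------------------------------------------------

def detect_outliers(
    matrix: ConcentrationMatrix,
    manifest: pd.DataFrame,
    n_components: int = 7,
    percentile: float = 0.95,
) -> OutlierReport:
    """Dual-criterion multivariate outlier screen on biological samples.

    Criterion A: per-feature Z-scores of log10 concentrations are computed,
    absolute Z-scores summed per sample, and samples above the chosen
    percentile of the sums flagged.  Criterion B: the Z-score matrix enters a
    PCA; samples whose Euclidean distance to the origin in the space of the
    first ``n_components`` scores exceeds the same percentile are flagged.
    Declared outliers are the intersection of the two flag sets.
    """
    if not 0 < percentile < 1:
        raise ValidationError("percentile must lie in (0, 1)")
    manifest = validate_manifest(manifest)
    man = manifest.set_index("sample_id")
    bio_ids = [s for s in matrix.sample_ids if man.loc[s, "role"] == "biological"]
    L = matrix.log10().loc[bio_ids]
    if L.isna().to_numpy().any():
        raise ValidationError("missing values present; run impute_knn first")
    n = len(bio_ids)
    if n < n_components + 1:
        raise ValidationError(
            f"need more than {n_components} samples, got {n}"
        )

    X = L.to_numpy()
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        Z = (X - mu) / sd
    Z[:, sd == 0] = 0.0  # constant features carry no outlier signal

    zsum = pd.Series(np.abs(Z).sum(axis=1), index=L.index, name="zscore_sum")
    zsum_thr = float(np.percentile(zsum.to_numpy(), 100 * percentile))
    flagged_a = sorted(zsum.index[zsum.to_numpy() > zsum_thr])

    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(Z)
    dist = pd.Series(
        np.linalg.norm(scores, axis=1), index=L.index, name="pc_distance"
    )
    dist_thr = float(np.percentile(dist.to_numpy(), 100 * percentile))
    flagged_b = sorted(dist.index[dist.to_numpy() > dist_thr])

    declared = sorted(set(flagged_a) & set(flagged_b))
    return OutlierReport(
        zscore_sum=zsum,
        pc_distance=dist,
        zsum_threshold=zsum_thr,
        distance_threshold=dist_thr,
        flagged_zsum=flagged_a,
        flagged_pca=flagged_b,
        outliers=declared,
        n_components=n_components,
        percentile=percentile,
    )


# ---------------------------------------------------------------------------
# retention bookkeeping
# ---------------------------------------------------------------------------

def apply_exclusions(
    manifest: pd.DataFrame, report: OutlierReport | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Flag declared outliers and tabulate sample retention.

    Pre-existing exclusion flags (missed injections, maternal contamination)
    take precedence; a sample carries a single flag.  Returns the updated
    manifest and a summary table with one row per exclusion reason plus the
    retained total (samples in the union of reasons count once).
    """
    manifest = validate_manifest(manifest).copy()
    outliers = list(report.outliers) if report is not None else []
    known = set(manifest["sample_id"])
    unknown = [s for s in outliers if s not in known]
    if unknown:
        raise ValidationError(f"outlier report names unknown samples: {unknown}")

    is_out = manifest["sample_id"].isin(outliers)
    untouched = manifest["exclusion"] == "none"
    manifest.loc[is_out & untouched, "exclusion"] = "outlier"

    total = len(manifest)
    counts = {
        "missed_injection": int((manifest["exclusion"] == "missed_injection").sum()),
        "maternal_contamination": int(
            (manifest["exclusion"] == "maternal_contamination").sum()
        ),
        "outlier": int((manifest["exclusion"] == "outlier").sum()),
    }
    excluded_union = int((manifest["exclusion"] != "none").sum())
    retained = total - excluded_union
    summary = pd.DataFrame(
        [
            {"reason": "total", "n": total},
            *({"reason": r, "n": c} for r, c in counts.items()),
            {"reason": "excluded", "n": excluded_union},
            {"reason": "retained", "n": retained},
        ]
    )
    return manifest, summary


def retain_features(
    annotation: pd.DataFrame, drop_ids: Sequence[str]
) -> tuple[pd.DataFrame, dict]:
    """Drop irrecoverable features and report retention counts.

    The species-level view excludes SIM-mode measures (used only for class
    totals).  Returns the updated annotation and counts of retained measures
    and species-level measures.
    """
    annotation = validate_annotation(annotation).copy()
    known = set(annotation["feature_id"])
    unknown = [f for f in drop_ids if f not in known]
    if unknown:
        raise ValidationError(f"unknown feature ids in drop list: {unknown}")
    annotation.loc[annotation["feature_id"].isin(drop_ids), "retained"] = False
    retained = annotation[annotation["retained"]]
    counts = {
        "retained_measures": int(len(retained)),
        "species_level_measures": int((retained["mode"] != "SIM").sum()),
    }
    return annotation, counts


def species_view(annotation: pd.DataFrame) -> pd.DataFrame:
    """Retained, non-SIM features — the set used in species-level analyses."""
    ann = validate_annotation(annotation)
    return ann[ann["retained"] & (ann["mode"] != "SIM")].reset_index(drop=True)


# ---------------------------------------------------------------------------
# class totals
# ---------------------------------------------------------------------------

def compute_class_totals(
    matrix: ConcentrationMatrix, annotation: pd.DataFrame
) -> ConcentrationMatrix:
    """Sum species concentrations into lipid class totals per sample.

    Triglyceride classes (TG, TG(O)) are summed from their SIM-mode measures
    only — the SIM peaks are the abundant, less structurally resolved
    quantification used for totals; every other class sums its non-SIM
    measures.  Only retained features contribute.
    """
    annotation = validate_annotation(annotation)
    ann = annotation[annotation["retained"]]
    totals = {}
    for cls, grp in ann.groupby("lipid_class", sort=True):
        if cls in SIM_TOTAL_CLASSES:
            contrib = grp.loc[grp["mode"] == "SIM", "feature_id"]
        else:
            contrib = grp.loc[grp["mode"] != "SIM", "feature_id"]
        contrib = [f for f in contrib if f in matrix.feature_ids]
        if not contrib:
            raise ValidationError(f"class {cls!r} has no contributing features")
        totals[cls] = matrix.data[contrib].sum(axis=1, skipna=False)
    out = pd.DataFrame(totals, index=matrix.sample_ids)
    return ConcentrationMatrix(out)
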