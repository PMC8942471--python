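"""Paired comparisons across time points and DTW/PAM trajectory clustering.

Two kinds of longitudinal summaries are produced:

* **Paired comparisons** between two sides of a subject-level pairing
  (mother vs newborn, or the same children at consecutive time points):
  Wilcoxon signed-rank or paired t-tests on log10 differences, summarised as
  geometric-mean fold differences and log2 fold changes, BH-corrected across
  features.

* **Trajectory clustering**: each lipid's trajectory is its median log10
  concentration per time point, z-normalised per feature so clusters group
  by shape rather than abundance; pairwise dissimilarity is classic dynamic
  time warping (absolute-difference local cost, symmetric unit steps, no
  window), and features are partitioned around medoids (PAM, BUILD + SWAP,
  best of several seeded restarts).
"""

from __future__ import annotations


import math
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.stats as st

from .associate import bh_adjust
from .containers import (
    ConcentrationMatrix,
    TrajectoryClustering,
    ValidationError,
    validate_manifest,
)

LOG2_10 = math.log2(10.0)


# ---------------------------------------------------------------------------
# paired tests
# ---------------------------------------------------------------------------

def paired_compare(
    matrix: ConcentrationMatrix,
    pairs: pd.DataFrame,
    test: str = "wilcoxon",
) -> pd.DataFrame:
    """Per-feature paired comparison between two sample sets.

    ``pairs`` has columns ``sample_1`` and ``sample_2`` (one row per
    subject).  Per feature, only pairs with both values observed and
    positive enter; the fold difference is ``10^(mean paired log10
    difference)`` (side 1 relative to side 2) and the log2 fold change its
    base-2 translation.  Wilcoxon signed-rank tests are exact for n <= 25
    and use the normal approximation with continuity correction otherwise;
    all-zero difference vectors yield p = 1 with a degenerate flag.
    P-values are BH-adjusted across features.
    """
    if test not in ("wilcoxon", "ttest"):
        raise ValidationError(f"unknown test {test!r}")
    for col in ("sample_1", "sample_2"):
        if col not in pairs.columns:
            raise ValidationError(f"pairs table needs column {col!r}")
    s1 = pairs["sample_1"].to_numpy()
    s2 = pairs["sample_2"].to_numpy()
    known = set(matrix.sample_ids)
    keep = np.array([a in known and b in known for a, b in zip(s1, s2)])
    s1, s2 = s1[keep], s2[keep]
    if len(s1) == 0:
        raise ValidationError("no complete pairs present in matrix")

    with np.errstate(divide="ignore", invalid="ignore"):
        l1 = np.log10(matrix.data.loc[s1].to_numpy())
        l2 = np.log10(matrix.data.loc[s2].to_numpy())
    l1[~np.isfinite(l1)] = np.nan
    l2[~np.isfinite(l2)] = np.nan
    diffs = l1 - l2

    rows = []
    for j, feat in enumerate(matrix.feature_ids):
        d = diffs[:, j]
        d = d[~np.isnan(d)]
        if d.size == 0:
            raise ValidationError(f"feature {feat!r}: zero complete pairs")
        mean_d = float(d.mean())
        degenerate = bool(np.all(d == 0))
        if test == "ttest":
            if degenerate or d.size < 2:
                p = 1.0 if degenerate else float("nan")
            else:
                p = float(st.ttest_1samp(d, 0.0).pvalue)
        else:
            if degenerate:
                p = 1.0
            else:
                method = "exact" if d.size <= 25 else "approx"
                p = float(
                    st.wilcoxon(
                        d, zero_method="wilcox", correction=(method == "approx"),
                        method=method,
                    ).pvalue
                )
        rows.append(
            {
                "feature_id": feat,
                "n_pairs": int(d.size),
                "fold": float(10.0 ** mean_d),
                "log2fc": float(mean_d * LOG2_10),
                "p": p,
                "test": test,
                "degenerate": degenerate,
            }
        )
    res = pd.DataFrame(rows)
    res["p_adj"] = bh_adjust(res["p"].to_numpy())
    return res


# ---------------------------------------------------------------------------
# dynamic time warping
# ---------------------------------------------------------------------------

def dtw_distance(a: Sequence[float], b: Sequence[float]) -> float:
    """Classic DTW distance with absolute-difference cost and unit steps.

    The optimal cumulative cost over monotone warping paths allowing match,
    insertion and deletion steps, with no window constraint.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValidationError("trajectories must be non-empty")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValidationError("trajectories must be finite")
    n, m = a.size, b.size
    cost = np.abs(a[:, None] - b[None, :])
    acc = np.full((n + 1, m + 1), np.inf)
    acc[0, 0] = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            acc[i, j] = cost[i - 1, j - 1] + min(
                acc[i - 1, j], acc[i, j - 1], acc[i - 1, j - 1]
            )
    return float(acc[n, m])


def dtw_matrix(trajectories: pd.DataFrame) -> pd.DataFrame:
    """Symmetric pairwise DTW dissimilarity matrix (features in rows)."""
    X = trajectories.to_numpy(dtype=float)
    n = X.shape[0]
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = dtw_distance(X[i], X[j])
    return pd.DataFrame(D, index=trajectories.index, columns=trajectories.index)


# ---------------------------------------------------------------------------
# partitioning around medoids
# ---------------------------------------------------------------------------

def _pam_cost(D: np.ndarray, medoids: np.ndarray) -> float:
    return float(D[:, medoids].min(axis=1).sum())


def _pam_build(D: np.ndarray, k: int) -> list[int]:
    """Greedy BUILD initialisation (lowest-index tie-break)."""
    n = D.shape[0]
    medoids = [int(np.argmin(D.sum(axis=1)))]
    while len(medoids) < k:
        best_gain, best = -np.inf, None
        dist = D[:, medoids].min(axis=1)
        for c in range(n):
            if c in medoids:
                continue
            gain = np.maximum(dist - D[:, c], 0.0).sum()
            if gain > best_gain:
                best_gain, best = gain, c
        medoids.append(int(best))
    return medoids


def _pam_swap(D: np.ndarray, medoids: list[int]) -> tuple[list[int], float]:
    """Best-improvement SWAP until no swap lowers the total cost."""
    medoids = list(medoids)
    n = D.shape[0]
    cost = _pam_cost(D, np.asarray(medoids))
    improved = True
    while improved:
        improved = False
        best = (0.0, None, None)
        for mi, m in enumerate(medoids):
            others = medoids[:mi] + medoids[mi + 1:]
            for c in range(n):
                if c in medoids:
                    continue
                new_cost = _pam_cost(D, np.asarray(others + [c]))
                delta = new_cost - cost
                if delta < best[0] - 1e-12:
                    best = (delta, mi, c)
        if best[1] is not None:
            medoids[best[1]] = best[2]
            cost += best[0]
            cost = _pam_cost(D, np.asarray(medoids))  # re-anchor against drift
            improved = True
    return medoids, cost


def pam_cluster(
    dmatrix: pd.DataFrame | np.ndarray,
    k: int,
    seed: int = 0,
    restarts: int = 10,
) -> tuple[list, pd.Series, float]:
    """PAM k-medoids on a precomputed dissimilarity matrix.

    One deterministic BUILD start plus ``restarts - 1`` seeded random
    starts, each refined by best-improvement SWAP; the solution with the
    lowest total within-cluster dissimilarity wins (ties broken by sorted
    medoid ids).  Returns (medoid labels, assignments, total cost).
    """
    if isinstance(dmatrix, pd.DataFrame):
        labels = list(dmatrix.index)
        D = dmatrix.to_numpy(dtype=float)
    else:
        D = np.asarray(dmatrix, dtype=float)
        labels = list(range(D.shape[0]))
    n = D.shape[0]
    if D.shape[0] != D.shape[1]:
        raise ValidationError("dissimilarity matrix must be square")
    if not np.allclose(D, D.T, atol=1e-8) or np.any(np.diag(D) > 1e-12) or np.any(D < 0):
        raise ValidationError("invalid dissimilarity matrix")
    if not 1 <= k <= n:
        raise ValidationError(f"k must lie in [1, {n}]")
    if k == n:
        medoids = list(range(n))
        assign = pd.Series(range(n), index=labels, name="cluster")
        return [labels[m] for m in medoids], assign, 0.0

    rng = np.random.default_rng(seed)
    best_medoids, best_cost = None, np.inf
    for r in range(max(1, restarts)):
        init = (
            _pam_build(D, k)
            if r == 0
            else sorted(rng.choice(n, size=k, replace=False).tolist())
        )
        medoids, cost = _pam_swap(D, init)
        key = sorted(medoids)
        if cost < best_cost - 1e-12 or (
            abs(cost - best_cost) <= 1e-12
            and best_medoids is not None
            and key < sorted(best_medoids)
        ):
            best_medoids, best_cost = key, cost
    medoids = sorted(best_medoids)
    assign_idx = np.argmin(D[:, medoids], axis=1)
    assign = pd.Series(assign_idx, index=labels, name="cluster")
    return [labels[m] for m in medoids], assign, float(best_cost)


# ---------------------------------------------------------------------------
# trajectory clustering
# ---------------------------------------------------------------------------

def feature_trajectories(
    matrix: ConcentrationMatrix,
    manifest: pd.DataFrame,
    timepoint_order: Sequence[str] | None = None,
    normalize: str = "zscore",
) -> pd.DataFrame:
    """Per-feature median log10 concentration per time point.

    ``normalize="zscore"`` standardises each feature's trajectory to mean 0,
    SD 1 so that clustering groups by shape, not abundance; constant
    trajectories become all-zero.
    """
    manifest = validate_manifest(manifest)
    man = manifest.set_index("sample_id")
    bio = [
        s for s in matrix.sample_ids
        if man.loc[s, "role"] == "biological" and man.loc[s, "exclusion"] == "none"
    ]
    L = matrix.log10().loc[bio]
    tps = man.loc[bio, "timepoint"]
    if timepoint_order is None:
        seen = []
        for t in manifest.loc[manifest["role"] == "biological", "timepoint"]:
            if t not in seen:
                seen.append(t)
        timepoint_order = seen
    present = [t for t in timepoint_order if (tps == t).any()]
    if len(present) < 2:
        raise ValidationError("need biological samples at >= 2 time points")
    traj = pd.DataFrame(
        {t: L.loc[tps.index[tps == t]].median(axis=0) for t in present}
    )
    if normalize == "zscore":
        mu = traj.mean(axis=1)
        sd = traj.std(axis=1, ddof=0)
        traj = traj.sub(mu, axis=0).div(sd.replace(0.0, np.nan), axis=0).fillna(0.0)
    elif normalize == "mean":
        traj = traj.sub(traj.mean(axis=1), axis=0)
    elif normalize != "none":
        raise ValidationError(f"unknown normalization {normalize!r}")
    traj.index.name = "feature_id"
    return traj


def cluster_trajectories(
    matrix: ConcentrationMatrix,
    manifest: pd.DataFrame,
    k: int = 10,
    seed: int = 0,
    restarts: int = 10,
    timepoint_order: Sequence[str] | None = None,
    normalize: str = "zscore",
) -> TrajectoryClustering:
    """DTW + PAM clustering of per-feature time trajectories."""
    traj = feature_trajectories(matrix, manifest, timepoint_order, normalize)
    if len(traj) < k:
        raise ValidationError(f"only {len(traj)} features for k = {k}")
    D = dtw_matrix(traj)
    medoids, assign, cost = pam_cluster(D, k=k, seed=seed, restarts=restarts)
    return TrajectoryClustering(
        trajectories=traj,
        dissimilarity=D,
        k=k,
        medoids=medoids,
        assignments=assign,
        total_cost=cost,
    )
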