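"""Shared fixtures and independent brute-force oracles.

The oracles deliberately use naive enumeration / per-element loops so they
share no code path with the implementations they check.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
import pytest
import scipy.stats as st

from lipidpipe.containers import validate_manifest


# ---------------------------------------------------------------------------
# fixture builders
# ---------------------------------------------------------------------------

def make_manifest(sample_ids, role="biological", batch="B00", timepoint="birth",
                  matrix="serum", exclusion="none"):
    """Build a valid manifest, broadcasting scalar fields."""
    n = len(sample_ids)

    def bc(v):
        return [v] * n if np.isscalar(v) or isinstance(v, str) else list(v)

    return validate_manifest(
        pd.DataFrame(
            {
                "sample_id": list(sample_ids),
                "subject_id": [f"sub{i}" for i in range(n)],
                "role": bc(role),
                "batch": bc(batch),
                "timepoint": bc(timepoint),
                "matrix": bc(matrix),
                "exclusion": bc(exclusion),
            }
        )
    )


# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------

def bh_stepup_oracle(p):
    """Textbook BH step-up: q_(i) = min_{j>=i} p_(j) * m / j, capped at 1."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        q[i] = running
    return q


def dtw_bruteforce(a, b):
    """Minimal path cost over all monotone warping paths (tiny inputs)."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    n, m = len(a), len(b)
    best = [np.inf]

    def walk(i, j, cost):
        cost += abs(a[i] - b[j])
        if cost >= best[0]:
            return
        if i == n - 1 and j == m - 1:
            best[0] = cost
            return
        for di, dj in ((1, 0), (0, 1), (1, 1)):
            if i + di < n and j + dj < m:
                walk(i + di, j + dj, cost)

    walk(0, 0, 0.0)
    return best[0]


def pam_bruteforce(D, k):
    """Exhaustive optimal k-medoid cost over all medoid subsets."""
    D = np.asarray(D, float)
    n = D.shape[0]
    best_cost, best_set = np.inf, None
    for combo in itertools.combinations(range(n), k):
        cost = D[:, combo].min(axis=1).sum()
        if cost < best_cost - 1e-12:
            best_cost, best_set = cost, combo
    return best_cost, best_set


def wilcoxon_signflip_oracle(d):
    """Two-sided exact signed-rank p by enumerating all 2^n sign vectors."""
    d = np.asarray(d, dtype=float)
    d = d[d != 0]
    n = d.size
    ranks = st.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    ws = np.array(
        [sum(r for s, r in zip(signs, ranks) if s)
         for signs in itertools.product([0, 1], repeat=n)]
    )
    cdf = np.mean(ws <= w_obs)
    sf = np.mean(ws >= w_obs)
    return min(1.0, 2 * min(cdf, sf))


def ols_normal_equations_oracle(X, y):
    """Closed-form OLS: beta, se, t-based two-sided p (naive formulas)."""
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    XtX = X.T @ X
    beta = np.linalg.solve(XtX, X.T @ y)
    resid = y - X @ beta
    dof = X.shape[0] - X.shape[1]
    sigma2 = resid @ resid / dof
    se = np.sqrt(np.diag(np.linalg.inv(XtX)) * sigma2)
    t = beta / se
    p = 2 * st.t.sf(np.abs(t), dof)
    return beta, se, p


def harmonize_oracle(matrix, manifest):
    """Step-by-step per-feature loop re-implementation of batch alignment."""
    df = np.log10(matrix.data.copy())
    man = manifest.set_index("sample_id").loc[df.index]
    batches = sorted(man["batch"].unique())
    out = df.copy()
    for f in df.columns:
        col = df[f].copy()
        gmed = col[man["role"] == "PQC"].median()
        for b in batches:
            bmed = col[(man["role"] == "PQC") & (man["batch"] == b)].median()
            col[man["batch"] == b] += gmed - bmed
        sds, meds = {}, {}
        for b in batches:
            bio = col[(man["role"] == "biological") & (man["batch"] == b)]
            sds[b] = bio.std(ddof=1)
            meds[b] = bio.median()
        target = float(np.mean(list(sds.values())))
        for b in batches:
            fac = target / sds[b] if sds[b] > 0 else 1.0
            mask = man["batch"] == b
            col[mask] = meds[b] + (col[mask] - meds[b]) * fac
        out[f] = col
    return 10.0 ** out


def outlier_oracle(L_bio, n_components=7, percentile=0.95):
    """Brute-force dual-criterion screen on a log10 biological matrix."""
    X = L_bio.to_numpy(float)
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    Z = np.zeros_like(X)
    nz = sd > 0
    Z[:, nz] = (X[:, nz] - mu[nz]) / sd[nz]
    zsum = np.abs(Z).sum(axis=1)
    thr_a = np.percentile(zsum, 100 * percentile)
    A = set(L_bio.index[zsum > thr_a])
    Zc = Z - Z.mean(axis=0)
    _, _, Vt = np.linalg.svd(Zc, full_matrices=False)
    scores = Zc @ Vt[:n_components].T
    dist = np.linalg.norm(scores, axis=1)
    thr_b = np.percentile(dist, 100 * percentile)
    B = set(L_bio.index[dist > thr_b])
    return zsum, dist, thr_a, thr_b, A, B, A & B


@pytest.fixture(scope="session")
def small_cohort():
    """A modest synthetic cohort shared by read-only tests."""
    import lipidpipe as lp

    cfg = lp.CohortConfig(
        n_subjects=60, n_features=24, n_batches=2, seed=11,
        zero_rate=0.005, missing_rate=0.005,
    )
    return lp.generate_cohort(cfg)
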