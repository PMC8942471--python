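"""Per-lipid covariate-adjusted association engine.

Each retained lipid feature's log10 concentration is regressed on a set of
perinatal / maternal covariates by ordinary least squares, one model per
feature.  Coefficients on the log10 scale are reported together with their
percentage-change translation, ``(10^beta - 1) x 100`` — the percent
difference in concentration per unit of the covariate.  P-values are
corrected for multiple comparisons per model term with the
Benjamini-Hochberg step-up procedure, across features.

Model presets
-------------
``birth``
    cord-lipid models: birth weight, gestational age, mode of birth,
    duration of labour, sex, maternal pre-pregnancy BMI, GDM, maternal
    education, maternal age, birth order, and run batch.
``breastfeeding_6m`` / ``breastfeeding_12m``
    breastfeeding status plus sex and child age at draw, maternal
    covariates, and run batch; gestational age additionally enters the
    6-month model only (it no longer influences lipids at 12 months).

Categorical covariates use treatment coding; reference levels are ``VB``
for mode of birth and ``female`` for sex (recorded in the output).
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
import scipy.stats as st
from statsmodels.stats.multitest import multipletests

from .containers import ConcentrationMatrix, ValidationError, validate_annotation

#: treatment-coding reference level per categorical covariate
REFERENCE_LEVELS = {
    "mode_of_birth": "VB",
    "sex": "female",
    "gdm": "n",
    "breastfeeding_6m": "n",
    "breastfeeding_12m": "n",
    "maternal_education": "secondary",
}

_MATERNAL = ["maternal_bmi", "gdm", "maternal_education", "maternal_age", "birth_order"]

PRESETS = {
    "birth": [
        "birth_weight", "gestational_age", "mode_of_birth", "labour_duration",
        "sex", *_MATERNAL, "batch",
    ],
    "breastfeeding_6m": [
        "breastfeeding_6m", "sex", "child_age_days", "gestational_age",
        *_MATERNAL, "batch",
    ],
    "breastfeeding_12m": [
        "breastfeeding_12m", "sex", "child_age_days", *_MATERNAL, "batch",
    ],
}

_CATEGORICAL_FALLBACK = ("batch",)


def beta_to_percent_change(beta):
    """Translate a log10-scale coefficient into percentage change.

    percentage change = (10^beta - 1) x 100.  Applies elementwise; raises on
    non-finite input.
    """
    arr = np.asarray(beta, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValidationError("beta must be finite")
    out = (np.power(10.0, arr) - 1.0) * 100.0
    return float(out) if np.isscalar(beta) or arr.ndim == 0 else out


def bh_adjust(pvalues, grouping=None) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, optionally per group.

    ``grouping`` assigns each p-value to a model term; adjustment is applied
    within each term across features, matching per-term FDR control.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size and (np.nanmin(p) < 0 or np.nanmax(p) > 1):
        raise ValidationError("p-values must lie in [0, 1]")
    out = np.empty_like(p)
    if grouping is None:
        out[:] = multipletests(p, method="fdr_bh")[1] if p.size else p
        return out
    grouping = np.asarray(grouping)
    for g in pd.unique(grouping):
        m = grouping == g
        out[m] = multipletests(p[m], method="fdr_bh")[1]
    return out


def _encode(covariates: pd.DataFrame, terms: Sequence[str]) -> tuple[pd.DataFrame, dict]:
    """Treatment-coded design matrix (without intercept) and term map."""
    cols = {}
    term_map: dict[str, list[str]] = {}
    for term in terms:
        if term not in covariates.columns:
            raise ValidationError(f"covariate {term!r} not in table")
        col = covariates[term]
        categorical = (
            col.dtype == object
            or isinstance(col.dtype, pd.CategoricalDtype)
            or term in _CATEGORICAL_FALLBACK
        )
        if categorical:
            levels = sorted(col.dropna().astype(str).unique())
            ref = REFERENCE_LEVELS.get(term, levels[0] if levels else None)
            if ref in levels:
                levels.remove(ref)
            names = []
            for lev in levels:
                name = f"{term}[{lev}]"
                cols[name] = (col.astype(str) == lev).astype(float).where(col.notna())
                names.append(name)
            term_map[term] = names
        else:
            cols[term] = col.astype(float)
            term_map[term] = [term]
    design = pd.DataFrame(cols, index=covariates.index)
    return design, term_map


def _check_rank(X: np.ndarray, names: Sequence[str]) -> None:
    if X.shape[0] <= X.shape[1]:
        raise ValidationError(
            f"n = {X.shape[0]} observations <= {X.shape[1]} parameters"
        )
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        import scipy.linalg as sla

        _, R, piv = sla.qr(X, mode="economic", pivoting=True)
        diag = np.abs(np.diag(R))
        tol = diag.max() * max(X.shape) * np.finfo(float).eps
        bad = [names[piv[i]] for i in range(len(diag)) if diag[i] < tol]
        raise ValidationError(f"rank-deficient design; collinear terms: {bad}")


def fit_lipid_regressions(
    matrix: ConcentrationMatrix,
    covariates: pd.DataFrame,
    terms: Sequence[str] | None = None,
    preset: str | None = None,
    report_terms: Sequence[str] | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """OLS of log10 concentration on covariates, one fit per feature.

    Rows with a missing outcome or any missing covariate are dropped per
    fit (listwise deletion) and the effective n recorded.  Returns a long
    table with one row per (feature, reported term level): ``beta`` and its
    t-based 95% CI on the log10 scale, the percentage-change translation,
    raw and per-term BH-adjusted p, and n.
    """
    if preset is not None:
        if preset not in PRESETS:
            raise ValidationError(f"unknown preset {preset!r}")
        terms = PRESETS[preset]
    if not terms:
        raise ValidationError("no model terms supplied")
    cov = covariates.set_index("sample_id") if "sample_id" in covariates.columns else covariates
    ids = [s for s in matrix.sample_ids if s in cov.index]
    if not ids:
        raise ValidationError("no overlap between matrix samples and covariate table")
    Y = matrix.log10().loc[ids]
    design, term_map = _encode(cov.loc[ids], terms)
    report = list(report_terms) if report_terms is not None else list(terms)
    for t in report:
        if t not in term_map:
            raise ValidationError(f"reported term {t!r} is not in the model")

    col_names = ["Intercept"] + list(design.columns)
    D = design.to_numpy(dtype=float)
    y_all = Y.to_numpy(dtype=float)
    cov_ok = ~np.isnan(D).any(axis=1)

    cache: dict[bytes, tuple] = {}
    rows = []
    crit_cache: dict[int, float] = {}
    for j, feat in enumerate(Y.columns):
        use = cov_ok & ~np.isnan(y_all[:, j])
        key = use.tobytes()
        if key not in cache:
            X = np.column_stack([np.ones(use.sum()), D[use]])
            _check_rank(X, col_names)
            XtX_inv = np.linalg.inv(X.T @ X)
            cache[key] = (X, XtX_inv)
        X, XtX_inv = cache[key]
        y = y_all[use, j]
        n, p = X.shape
        beta = XtX_inv @ (X.T @ y)
        resid = y - X @ beta
        dof = n - p
        sigma2 = float(resid @ resid) / dof
        se = np.sqrt(np.diag(XtX_inv) * sigma2)
        if dof not in crit_cache:
            crit_cache[dof] = float(st.t.ppf(1 - alpha / 2, dof))
        crit = crit_cache[dof]
        tstat = np.divide(beta, se, out=np.zeros_like(beta), where=se > 0)
        pval = 2 * st.t.sf(np.abs(tstat), dof)
        for term in report:
            for name in term_map[term]:
                i = col_names.index(name)
                b, s = beta[i], se[i]
                lo, hi = b - crit * s, b + crit * s
                rows.append(
                    {
                        "feature_id": feat,
                        "term": name,
                        "beta": b,
                        "se": s,
                        "ci_low": lo,
                        "ci_high": hi,
                        "pct_change": beta_to_percent_change(b),
                        "pct_ci_low": beta_to_percent_change(lo),
                        "pct_ci_high": beta_to_percent_change(hi),
                        "p": float(pval[i]),
                        "n": n,
                    }
                )
    res = pd.DataFrame(rows)
    res["p_adj"] = bh_adjust(res["p"].to_numpy(), res["term"].to_numpy())
    return res


def compare_effect_profiles(
    results_x: pd.DataFrame,
    results_y: pd.DataFrame,
    alpha: float = 0.05,
    restrict_to_significant: bool = True,
) -> dict:
    """Regress one term's per-feature betas on another's.

    Returns the least-squares slope/intercept and r² of the (βx, βy) cloud
    and the fraction of features whose two betas have opposing signs,
    computed over features significant (BH-adjusted p < alpha) for at least
    one of the two terms when available.
    """
    merged = results_x.merge(
        results_y, on="feature_id", suffixes=("_x", "_y"), how="inner"
    )
    if len(merged) < 3:
        raise ValidationError("need at least 3 shared features")
    bx = merged["beta_x"].to_numpy()
    by = merged["beta_y"].to_numpy()
    fit = st.linregress(bx, by)
    sig = np.ones(len(merged), dtype=bool)
    if restrict_to_significant and {"p_adj_x", "p_adj_y"} <= set(merged.columns):
        cand = (merged["p_adj_x"] < alpha) | (merged["p_adj_y"] < alpha)
        if cand.any():
            sig = cand.to_numpy()
    opposing = float(np.mean(np.sign(bx[sig]) * np.sign(by[sig]) < 0))
    return {
        "slope": float(fit.slope),
        "intercept": float(fit.intercept),
        "r_squared": float(fit.rvalue**2),
        "opposing_fraction": opposing,
        "n_features": int(len(merged)),
        "n_in_opposing": int(sig.sum()),
    }


_SPHINGO_PREFIXES = (
    "SM", "Cer", "dhCer", "HexCer", "Hex2Cer", "Hex3Cer", "GM", "Sph",
    "S1P", "C1P", "deoxyCer",
)
_PHOSPHO_PREFIXES = (
    "PC", "PE", "PS", "PI", "PG", "LPC", "LPE", "LPI", "LPS", "PC(O)",
    "PC(P)", "PE(O)", "PE(P)",
)

CATEGORY_ORDER = ("sphingolipids", "phospholipids", "other lipids")


def lipid_category(lipid_class: str) -> str:
    """Map a lipid class to its forest-plot category."""
    for p in _SPHINGO_PREFIXES:
        if lipid_class == p or lipid_class.startswith(p + "("):
            return "sphingolipids"
    for p in _PHOSPHO_PREFIXES:
        if lipid_class == p or lipid_class.startswith(p + "("):
            return "phospholipids"
    return "other lipids"


def export_forest_table(
    results: pd.DataFrame,
    annotation: pd.DataFrame,
    class_results: pd.DataFrame | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Order single-term association results for forest-plot rendering.

    Species rows are grouped into lipid class and ordered by category
    (sphingolipids, phospholipids, other lipids) then class then species.
    Each class contributes one class-level row — filled from
    ``class_results`` (associations of class totals, keyed by class name in
    ``feature_id``) when given, structural otherwise.  Significance tiers:
    ``non-significant`` (adjusted p >= alpha), ``significant``, and
    ``top-10`` for the ten smallest raw p (ties broken on feature id and
    flagged).
    """
    if results["term"].nunique() != 1:
        raise ValidationError("forest table expects results for a single term")
    ann = validate_annotation(annotation).set_index("feature_id")
    missing = [f for f in results["feature_id"] if f not in ann.index]
    if missing:
        raise ValidationError(f"unannotated features: {missing[:5]}")

    df = results.copy()
    df["lipid_class"] = ann.loc[df["feature_id"], "lipid_class"].to_numpy()
    df["species"] = ann.loc[df["feature_id"], "species"].to_numpy()
    df["category"] = [lipid_category(c) for c in df["lipid_class"]]
    df["row_type"] = "species"

    ranked = df.sort_values(["p", "feature_id"], kind="stable")
    top_ids = set(ranked["feature_id"].head(10))
    tie_flag = False
    if len(ranked) > 10:
        p10 = ranked["p"].iloc[9]
        tie_flag = bool((ranked["p"].iloc[10:] == p10).any())
    df["tier"] = np.where(
        df["p_adj"] < alpha, "significant", "non-significant"
    )
    df.loc[df["feature_id"].isin(top_ids), "tier"] = "top-10"
    df["top10_tiebreak"] = tie_flag and df["feature_id"].isin(top_ids)

    class_rows = []
    for cls in df["lipid_class"].unique():
        row = {
            "feature_id": cls,
            "term": df["term"].iloc[0],
            "lipid_class": cls,
            "species": cls,
            "category": lipid_category(cls),
            "row_type": "class",
            "tier": "",
            "top10_tiebreak": False,
        }
        if class_results is not None:
            hit = class_results[class_results["feature_id"] == cls]
            if len(hit):
                for c in ("beta", "ci_low", "ci_high", "pct_change",
                          "pct_ci_low", "pct_ci_high", "p", "p_adj", "n"):
                    if c in hit.columns:
                        row[c] = hit[c].iloc[0]
                row["tier"] = (
                    "significant" if row.get("p_adj", 1.0) < alpha else "non-significant"
                )
        class_rows.append(row)
    out = pd.concat([df, pd.DataFrame(class_rows)], ignore_index=True)

    cat_rank = {c: i for i, c in enumerate(CATEGORY_ORDER)}
    out["_cat"] = out["category"].map(cat_rank)
    out["_cls_first"] = (out["row_type"] != "class").astype(int)
    out = (
        out.sort_values(
            ["_cat", "lipid_class", "_cls_first", "species"], kind="stable"
        )
        .drop(columns=["_cat", "_cls_first"])
        .reset_index(drop=True)
    )
    return out
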