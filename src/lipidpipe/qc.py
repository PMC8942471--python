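"""Analytical quality metrics from pooled QC samples.

The pooled plasma QC (PQC) is extracted and injected alongside the study
samples, so the spread of its repeated measurements estimates the total
analytical variability of each lipid measure.  The headline metrics are the
median per-feature coefficient of variation and the fraction of features
with CV below 20%.
"""

from __future__ import annotations

import pandas as pd

from .containers import (
    CVReport,
    ConcentrationMatrix,
    ValidationError,
    validate_annotation,
    validate_manifest,
)


def compute_cv(
    matrix: ConcentrationMatrix,
    manifest: pd.DataFrame,
    role: str = "PQC",
    annotation: pd.DataFrame | None = None,
) -> CVReport:
    """Per-feature CV% over the given QC role's samples.

    CV = 100 x sample SD / mean on the concentration scale (the convention
    behind the usual 20%-CV acceptability threshold).  If an annotation is
    supplied, only retained features are summarised.
    """
    manifest = validate_manifest(manifest)
    ids = manifest.loc[manifest["role"] == role, "sample_id"]
    ids = [s for s in ids if s in matrix.sample_ids]
    if len(ids) < 2:
        raise ValidationError(
            f"need at least 2 samples of role {role!r}, found {len(ids)}"
        )
    block = matrix.data.loc[ids]
    if annotation is not None:
        ann = validate_annotation(annotation)
        keep = [f for f in ann.loc[ann["retained"], "feature_id"]
                if f in block.columns]
        block = block[keep]
    cv = 100.0 * block.std(axis=0, ddof=1) / block.mean(axis=0)
    cv.name = "cv_pct"
    return CVReport(cv=cv, role=role, n_samples=len(ids))
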