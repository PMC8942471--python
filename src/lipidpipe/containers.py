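"""Core data containers for the lipidomics pipeline.

The pipeline moves a single quantitative object — a samples x lipid-features
concentration matrix — through a chain of transformations, accompanied by
three metadata tables:

* a **sample manifest** (one row per injected sample: subject, role, batch,
  time point, matrix, exclusion flag),
* a **feature annotation** (lipid class, species name, quantification mode,
  retention flag),
* a **covariate table** (one row per biological sample: perinatal and
  maternal covariates used in the association models).

Conventions
-----------
Concentrations are non-negative, relative to internal standards (arbitrary
units).  In :class:`ConcentrationMatrix`, ``NaN`` marks a *missing* value
(not acquired / curated away) while ``0.0`` marks a value *below the
instrument's detection threshold* — the two are handled by different
pipeline stages (kNN imputation vs. zero replacement) and must not be
conflated.  Metadata tables are plain :class:`pandas.DataFrame` objects
validated by the ``validate_*`` helpers.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

ROLES = ("biological", "PQC", "TQC", "NIST")
MATRICES = ("serum", "plasma")
EXCLUSIONS = ("none", "missed_injection", "maternal_contamination", "outlier")
MODES = ("standard", "NL", "SIM")

#: lipid classes whose class totals are computed from SIM-mode measures only
SIM_TOTAL_CLASSES = ("TG", "TG(O)")

MANIFEST_COLUMNS = (
    "sample_id",
    "subject_id",
    "role",
    "batch",
    "timepoint",
    "matrix",
    "exclusion",
)
ANNOTATION_COLUMNS = ("feature_id", "lipid_class", "species", "mode", "retained")


class ValidationError(ValueError):
    """Raised when a container violates its documented invariants."""


@dataclass
class ConcentrationMatrix:
    """Samples x features concentration matrix with an explicit missing mask.

    Parameters
    ----------
    data:
        DataFrame indexed by sample id with feature ids as columns.
        Values are non-negative floats; ``NaN`` encodes missing.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        if not isinstance(self.data, pd.DataFrame):
            raise ValidationError("data must be a pandas DataFrame")
        if self.data.index.has_duplicates:
            raise ValidationError("duplicate sample ids in matrix")
        if self.data.columns.has_duplicates:
            raise ValidationError("duplicate feature ids in matrix")
        vals = self.data.to_numpy(dtype=float, copy=False)
        if np.nanmin(vals, initial=0.0) < 0:
            raise ValidationError("negative concentrations are not allowed")
        self.data = self.data.astype(float)
        self.data.index.name = "sample_id"
        self.data.columns.name = "feature_id"

    # -- basic introspection -------------------------------------------------
    @property
    def sample_ids(self) -> pd.Index:
        return self.data.index

    @property
    def feature_ids(self) -> pd.Index:
        return self.data.columns

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_features(self) -> int:
        return self.data.shape[1]

    @property
    def missing_mask(self) -> pd.DataFrame:
        return self.data.isna()

    def copy(self) -> "ConcentrationMatrix":
        return ConcentrationMatrix(self.data.copy())

    def log10(self) -> pd.DataFrame:
        """log10-transformed values; raises if non-positive values remain.

        Zero replacement must run before any log-scale stage.
        """
        vals = self.data.to_numpy(dtype=float)
        if np.any(vals[~np.isnan(vals)] <= 0):
            raise ValidationError(
                "matrix contains non-positive values; run replace_zeros first"
            )
        return pd.DataFrame(
            np.log10(vals), index=self.data.index, columns=self.data.columns
        )

    # -- I/O -----------------------------------------------------------------
    def to_csv(self, path: str | Path, sep: str = ",") -> None:
        self.data.to_csv(path, sep=sep)

    @classmethod
    def from_csv(cls, path: str | Path, sep: str = ",") -> "ConcentrationMatrix":
        """Read a matrix from CSV/TSV.

        Accepts wide format (samples x features, first column ``sample_id``)
        or long format with columns ``sample_id, feature_id, value``
        (auto-detected from the header).
        """
        head = pd.read_csv(path, sep=sep, nrows=0)
        if set(head.columns[:3].str.lower()) >= {"sample_id", "feature_id", "value"} or (
            list(head.columns[:1]) and head.columns[0].lower() == "sample_id"
            and "feature_id" in {c.lower() for c in head.columns}
        ):
            long = pd.read_csv(path, sep=sep)
            long.columns = [c.lower() for c in long.columns]
            wide = long.pivot(index="sample_id", columns="feature_id", values="value")
            return cls(wide)
        df = pd.read_csv(path, sep=sep, index_col=0)
        return cls(df)


def validate_manifest(manifest: pd.DataFrame) -> pd.DataFrame:
    """Validate a sample manifest and normalise column order."""
    missing = set(MANIFEST_COLUMNS) - set(manifest.columns)
    if missing:
        raise ValidationError(f"manifest missing columns: {sorted(missing)}")
    if manifest["sample_id"].duplicated().any():
        dup = manifest.loc[manifest["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise ValidationError(f"duplicate sample id in manifest: {dup!r}")
    bad_role = set(manifest["role"]) - set(ROLES)
    if bad_role:
        raise ValidationError(f"unknown sample roles: {sorted(bad_role)}")
    bad_excl = set(manifest["exclusion"]) - set(EXCLUSIONS)
    if bad_excl:
        raise ValidationError(f"unknown exclusion flags: {sorted(bad_excl)}")
    if manifest["batch"].isna().any():
        raise ValidationError("every sample must carry a batch id")
    return manifest.loc[:, list(MANIFEST_COLUMNS)].reset_index(drop=True)


def validate_annotation(annotation: pd.DataFrame) -> pd.DataFrame:
    """Validate a feature annotation table."""
    missing = set(ANNOTATION_COLUMNS) - set(annotation.columns)
    if missing:
        raise ValidationError(f"annotation missing columns: {sorted(missing)}")
    if annotation["feature_id"].duplicated().any():
        raise ValidationError("duplicate feature ids in annotation")
    bad_mode = set(annotation["mode"]) - set(MODES)
    if bad_mode:
        raise ValidationError(f"unknown quantification modes: {sorted(bad_mode)}")
    key = annotation[["lipid_class", "species", "mode"]]
    if key.duplicated().any():
        raise ValidationError("(class, species, mode) combinations must be unique")
    return annotation.loc[:, list(ANNOTATION_COLUMNS)].reset_index(drop=True)


def sample_type_groups(manifest: pd.DataFrame) -> pd.Series:
    """Sample-type group key used by zero replacement and kNN imputation.

    Biological samples group by ``timepoint x matrix``; each QC role forms
    its own group (pooled QC material is its own sample type).
    """
    m = manifest.set_index("sample_id")
    bio = m["role"] == "biological"
    key = pd.Series(index=m.index, dtype=object)
    key[bio] = (
        "bio:" + m.loc[bio, "timepoint"].astype(str) + ":" + m.loc[bio, "matrix"].astype(str)
    )
    key[~bio] = "qc:" + m.loc[~bio, "role"].astype(str)
    return key


@dataclass
class OutlierReport:
    """Intermediates and decisions of the dual-criterion outlier screen."""

    zscore_sum: pd.Series
    pc_distance: pd.Series
    zsum_threshold: float
    distance_threshold: float
    flagged_zsum: list
    flagged_pca: list
    outliers: list
    n_components: int
    percentile: float

    def to_json_dict(self) -> dict:
        return {
            "n_components": self.n_components,
            "percentile": self.percentile,
            "zsum_threshold": self.zsum_threshold,
            "distance_threshold": self.distance_threshold,
            "flagged_zsum": list(self.flagged_zsum),
            "flagged_pca": list(self.flagged_pca),
            "outliers": list(self.outliers),
        }


@dataclass
class CVReport:
    """Per-feature coefficient of variation on QC replicates."""

    cv: pd.Series  # percent, per feature
    role: str
    n_samples: int
    cv_threshold: float = 20.0

    @property
    def median_cv(self) -> float:
        return float(self.cv.median())

    @property
    def fraction_below_threshold(self) -> float:
        return float((self.cv < self.cv_threshold).mean())

    def summary(self) -> dict:
        return {
            "role": self.role,
            "n_qc_samples": self.n_samples,
            "n_features": int(self.cv.size),
            "median_cv_pct": self.median_cv,
            "fraction_cv_below_20pct": self.fraction_below_threshold,
        }


@dataclass
class TrajectoryClustering:
    """DTW/PAM clustering of per-feature time trajectories."""

    trajectories: pd.DataFrame  # features x timepoints (normalised)
    dissimilarity: pd.DataFrame  # features x features, symmetric DTW
    k: int
    medoids: list
    assignments: pd.Series  # feature -> medoid index position (0..k-1)
    total_cost: float

    @property
    def sizes(self) -> pd.Series:
        return self.assignments.value_counts().sort_index()

    def summary_table(self) -> pd.DataFrame:
        rows = []
        for ci, medoid in enumerate(self.medoids):
            members = self.assignments.index[self.assignments == ci]
            rows.append(
                {
                    "cluster": ci,
                    "medoid": medoid,
                    "size": len(members),
                }
            )
        return pd.DataFrame(rows)
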