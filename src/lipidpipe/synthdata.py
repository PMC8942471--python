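"""Seeded synthetic birth-cohort lipidomics generator.

Real multi-batch infant-cohort lipidomics data are access-restricted, so the
pipeline is exercised end to end on synthetic cohorts that reproduce the
statistical structure the downstream stages assume:

* per-feature log10-normal baseline concentrations spanning ~4 orders of
  magnitude (the spread across lipid classes),
* repeated sampling of each subject at ordered time points, with
  feature-specific time-point offsets (trajectories),
* analytical batches carrying additive location shifts and multiplicative
  scale distortions on the log10 scale — exactly the structure the
  harmonization stage removes,
* pooled-plasma QC samples (PQC), technical QC splits (TQC) and a reference
  plasma (NIST) interleaved into the injection order at fixed intervals,
* below-detection censoring (zeros), missing values, gross outlier samples,
* planted covariate effects: slopes on log10 concentration (e.g. per day of
  gestational age) and fold differences between groups (e.g. breastfed vs
  not), restricted to chosen time points.

Every generator is a pure function of its seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .containers import (
    ConcentrationMatrix,
    ValidationError,
    validate_annotation,
    validate_manifest,
)

DEFAULT_TIMEPOINTS = ("M28", "birth", "6m", "12m", "4y")
#: time points measured in serum; the rest are plasma
SERUM_TIMEPOINTS = ("M28", "birth")

#: default lipid-class vocabulary; TG and TG(O) carry paired NL/SIM measures
DEFAULT_CLASSES = (
    "SM", "Cer", "HexCer", "PC", "PE", "PC(O)", "PE(P)", "LPC", "LPE",
    "CE", "DG", "FFA", "AC", "PS", "PI", "TG", "TG(O)",
)

MODE_OF_BIRTH_LEVELS = ("VB", "assisted VB", "scheduled CS", "unscheduled CS")
#: group sizes of the four modes of birth used as default sampling proportions
MODE_OF_BIRTH_COUNTS = (525, 214, 178, 155)


@dataclass(frozen=True)
class PlantedEffect:
    """A covariate effect injected into the generated concentrations.

    ``kind="slope"``: ``magnitude`` is added to log10 concentration per unit
    of the covariate (centred at the cohort mean).  ``kind="fold"``:
    concentrations of samples in ``group`` are multiplied by ``magnitude``
    (a fold difference > 0).  ``timepoints=None`` affects every time point.
    """

    feature_ids: tuple
    covariate: str
    kind: str  # "slope" | "fold"
    magnitude: float
    group: object | None = None  # covariate level receiving the fold effect
    timepoints: tuple | None = None

    def __post_init__(self):
        if self.kind not in ("slope", "fold"):
            raise ValidationError(f"unknown effect kind: {self.kind!r}")
        if not np.isfinite(self.magnitude):
            raise ValidationError("effect magnitude must be finite")
        if self.kind == "fold" and self.magnitude <= 0:
            raise ValidationError("fold difference must be > 0")
        object.__setattr__(self, "feature_ids", tuple(self.feature_ids))
        if self.timepoints is not None:
            object.__setattr__(self, "timepoints", tuple(self.timepoints))


@dataclass
class CohortConfig:
    """Parameters of a synthetic cohort.

    Noise parameters are log10-scale standard deviations.  ``qc_noise_sd``
    is the *median* per-feature PQC replicate noise; per-feature values are
    spread lognormally (``qc_cv_spread``) so the CV distribution has a
    realistic tail (median CV near 10%, ~92% of features below 20%).
    """

    n_subjects: int = 100
    timepoints: tuple = DEFAULT_TIMEPOINTS
    n_batches: int = 3
    pqc_interval: int = 20
    tqc_interval: int = 20
    nist_interval: int = 40
    n_features: int = 40
    class_map: dict | None = None
    effects: tuple = ()
    zero_rate: float = 0.0
    missing_rate: float = 0.0
    n_outliers: int = 0
    outlier_scale: float = 100.0
    batch_shift_sd: float = 0.15
    batch_scale_sd: float = 0.10
    batch_shifts: tuple | None = None  # explicit per-batch log10 shifts
    batch_scales: tuple | None = None  # explicit per-batch log10 scale factors
    biological_sd: float = 0.20
    trajectory_sd: float = 0.10
    noise_sd: float = 0.05
    qc_noise_sd: float = 0.044
    qc_cv_spread: float = 0.5
    seed: int = 0

    def __post_init__(self):
        for name in ("n_subjects", "n_batches", "pqc_interval", "tqc_interval",
                     "nist_interval", "n_features"):
            if int(getattr(self, name)) <= 0:
                raise ValidationError(f"{name} must be a positive count")
        for name in ("zero_rate", "missing_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must lie in [0, 1]")
        for name in ("batch_shift_sd", "batch_scale_sd", "biological_sd",
                     "trajectory_sd", "noise_sd", "qc_noise_sd", "qc_cv_spread"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be non-negative")
        if self.outlier_scale <= 0:
            raise ValidationError("outlier_scale must be > 0")
        if self.n_outliers < 0:
            raise ValidationError("n_outliers must be non-negative")
        self.timepoints = tuple(self.timepoints)
        if len(set(self.timepoints)) != len(self.timepoints):
            raise ValidationError("timepoints must be unique")
        for tup_name in ("batch_shifts", "batch_scales"):
            tup = getattr(self, tup_name)
            if tup is not None:
                tup = tuple(float(x) for x in tup)
                if len(tup) != self.n_batches:
                    raise ValidationError(f"{tup_name} must have n_batches entries")
                setattr(self, tup_name, tup)
        self.effects = tuple(self.effects)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["effects"] = [dataclasses.asdict(e) for e in self.effects]
        return d


# ---------------------------------------------------------------------------
# covariates
# ---------------------------------------------------------------------------

def _draw_subject_covariates(n: int, rng: np.random.Generator) -> pd.DataFrame:
    """Subject-level perinatal and maternal covariates.

    Gestational age (days) and birth weight (kg) are drawn jointly with
    correlation 0.45; mode of birth uses the cohort's observed group sizes
    as proportions; duration of labour is zero for scheduled caesareans.
    """
    r = 0.45
    z1 = rng.standard_normal(n)
    z2 = r * z1 + np.sqrt(1 - r**2) * rng.standard_normal(n)
    ga_days = np.clip(279.0 + 9.0 * z1, 224, 300)
    birth_weight = np.clip(3.45 + 0.55 * z2, 1.2, 5.8)

    probs = np.asarray(MODE_OF_BIRTH_COUNTS, dtype=float)
    probs /= probs.sum()
    mob = rng.choice(MODE_OF_BIRTH_LEVELS, size=n, p=probs)
    labour = np.where(
        mob == "scheduled CS", 0.0, np.clip(rng.gamma(3.0, 2.5, size=n), 0, 40)
    )
    sex = rng.choice(["female", "male"], size=n, p=[0.49, 0.51])
    bmi = np.clip(rng.normal(25.5, 5.0, size=n), 15, 55)
    gdm = rng.choice(["n", "y"], size=n, p=[0.95, 0.05])
    education = rng.choice(
        ["secondary", "tertiary", "postgraduate"], size=n, p=[0.35, 0.45, 0.20]
    )
    maternal_age = np.clip(rng.normal(31.5, 4.5, size=n), 18, 46)
    birth_order = rng.choice([1, 2, 3], size=n, p=[0.45, 0.35, 0.20])
    bf6 = rng.choice(["n", "y"], size=n, p=[0.3, 0.7])
    # persistence: most who breastfeed at 6 months still do at 12
    bf12 = np.where(
        bf6 == "y",
        rng.choice(["n", "y"], size=n, p=[0.4, 0.6]),
        rng.choice(["n", "y"], size=n, p=[0.95, 0.05]),
    )
    return pd.DataFrame(
        {
            "gestational_age": ga_days,
            "birth_weight": birth_weight,
            "mode_of_birth": mob,
            "labour_duration": labour,
            "sex": sex,
            "maternal_bmi": bmi,
            "gdm": gdm,
            "maternal_education": education,
            "maternal_age": maternal_age,
            "birth_order": birth_order,
            "breastfeeding_6m": bf6,
            "breastfeeding_12m": bf12,
        },
        index=pd.Index([f"S{i:04d}" for i in range(n)], name="subject_id"),
    )


_NOMINAL_AGE_DAYS = {"M28": 0.0, "birth": 0.0, "6m": 183.0, "12m": 365.0, "4y": 1461.0}


def default_annotation(
    n_features: int, class_map: dict | None = None
) -> pd.DataFrame:
    """Build a feature annotation table.

    Features cycle through the default lipid classes; TG and TG(O) species
    are emitted as NL-mode measures with one SIM-mode companion measure per
    species (mirroring dual NL/SIM quantification of triglycerides).
    """
    rows = []
    classes = DEFAULT_CLASSES
    for i in range(n_features):
        fid = f"F{i:04d}"
        if class_map is not None:
            cls = class_map[fid] if fid in class_map else class_map.get(i, "PC")
            mode = "standard"
        else:
            cls = classes[i % len(classes)]
            mode = "NL" if cls in ("TG", "TG(O)") else "standard"
        rows.append(
            {
                "feature_id": fid,
                "lipid_class": cls,
                "species": f"{cls}({40 + i}:{i % 7})",
                "mode": mode,
                "retained": True,
            }
        )
    ann = pd.DataFrame(rows)
    # SIM companions for NL-quantified triglyceride species
    nl = ann[ann["mode"] == "NL"]
    sims = nl.assign(
        feature_id=nl["feature_id"] + "_SIM",
        species=nl["species"] + " [SIM]",
        mode="SIM",
    )
    ann = pd.concat([ann, sims], ignore_index=True)
    return validate_annotation(ann)


# ---------------------------------------------------------------------------
# injection order / manifest
# ---------------------------------------------------------------------------

def _build_manifest(
    bio: pd.DataFrame, config: CohortConfig
) -> pd.DataFrame:
    """Interleave QC samples into per-batch injection sequences.

    Biological samples are split into ``n_batches`` contiguous chunks.
    Within a batch, one PQC is injected per ``pqc_interval`` biological
    samples (likewise TQC and NIST at their intervals), with a floor of two
    PQC/TQC per batch so QC-anchored harmonization stays defined for small
    cohorts.
    """
    n_bio = len(bio)
    chunks = np.array_split(np.arange(n_bio), config.n_batches)
    rows = []
    for b, idx in enumerate(chunks):
        batch = f"B{b:02d}"
        nb = len(idx)
        n_pqc = max(2, nb // config.pqc_interval)
        n_tqc = max(2, nb // config.tqc_interval)
        n_nist = nb // config.nist_interval
        for j, i in enumerate(idx):
            rows.append(
                {
                    "sample_id": bio.index[i],
                    "subject_id": bio["subject_id"].iloc[i],
                    "role": "biological",
                    "batch": batch,
                    "timepoint": bio["timepoint"].iloc[i],
                    "matrix": bio["matrix"].iloc[i],
                    "exclusion": "none",
                }
            )
        for role, count in (("PQC", n_pqc), ("TQC", n_tqc), ("NIST", n_nist)):
            for j in range(count):
                rows.append(
                    {
                        "sample_id": f"{role}_{batch}_{j:02d}",
                        "subject_id": role,
                        "role": role,
                        "batch": batch,
                        "timepoint": "QC",
                        "matrix": "plasma",
                        "exclusion": "none",
                    }
                )
    return validate_manifest(pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# main generator
# ---------------------------------------------------------------------------

def generate_cohort(
    config: CohortConfig,
) -> tuple[ConcentrationMatrix, pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Generate (matrix, manifest, annotation, covariates) for a cohort.

    Biological log10 concentrations are built as::

        mu_f + trajectory_{f,t} + subject_{s,f} + planted effects + noise

    then shifted/scaled per batch about the pool profile ``mu_f``:
    ``L' = shift_b + mu_f + scale_b * (L - mu_f)``.  QC samples are noisy
    replicates of the pool profile and receive the same batch distortion.
    Censoring below detection (zeros) and missingness are applied last.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)

    annotation = default_annotation(cfg.n_features, cfg.class_map)
    feature_ids = annotation["feature_id"].to_numpy()
    n_feat = len(feature_ids)

    covsub = _draw_subject_covariates(cfg.n_subjects, rng)

    # per-feature baselines spanning ~4 orders of magnitude on log10 scale
    mu = rng.uniform(-1.0, 3.0, size=n_feat)
    traj = rng.normal(0.0, cfg.trajectory_sd, size=(len(cfg.timepoints), n_feat))
    subj_dev = rng.normal(0.0, cfg.biological_sd, size=(cfg.n_subjects, n_feat))

    # biological samples: every subject at every time point
    recs = []
    for t_i, tp in enumerate(cfg.timepoints):
        matrix_kind = "serum" if tp in SERUM_TIMEPOINTS else "plasma"
        for s_i, sid in enumerate(covsub.index):
            recs.append((f"{sid}_{tp}", sid, tp, matrix_kind, s_i, t_i))
    bio = pd.DataFrame(
        recs, columns=["sample_id", "subject_id", "timepoint", "matrix", "s_i", "t_i"]
    ).set_index("sample_id")

    L = (
        mu[None, :]
        + traj[bio["t_i"].to_numpy(), :]
        + subj_dev[bio["s_i"].to_numpy(), :]
    )

    fid_pos = {f: i for i, f in enumerate(feature_ids)}
    for eff in cfg.effects:
        cols = [fid_pos[f] for f in eff.feature_ids]
        tp_mask = (
            np.ones(len(bio), dtype=bool)
            if eff.timepoints is None
            else bio["timepoint"].isin(eff.timepoints).to_numpy()
        )
        cov = covsub[eff.covariate].loc[bio["subject_id"]].to_numpy()
        if eff.kind == "slope":
            x = cov.astype(float)
            delta = eff.magnitude * (x - x.mean())
        else:
            delta = np.log10(eff.magnitude) * (cov == eff.group).astype(float)
        rows_affected = np.flatnonzero(tp_mask)
        L[np.ix_(rows_affected, cols)] += delta[rows_affected, None]

    if cfg.noise_sd > 0:
        L += rng.normal(0.0, cfg.noise_sd, size=L.shape)

    # randomised injection order: batches must be exchangeable in biological
    # composition for QC-anchored SD rescaling to be meaningful
    perm = rng.permutation(len(bio))
    manifest = _build_manifest(bio.iloc[perm], cfg)

    # QC profiles: pool == per-feature baseline mean, feature-specific noise
    sigma_qc = cfg.qc_noise_sd * np.exp(
        rng.normal(0.0, cfg.qc_cv_spread, size=n_feat)
    ) if cfg.qc_cv_spread > 0 else np.full(n_feat, cfg.qc_noise_sd)
    nist_offset = rng.normal(0.0, 0.1, size=n_feat)

    qc_rows = manifest[manifest["role"] != "biological"]
    qc_L = np.empty((len(qc_rows), n_feat))
    for i, role in enumerate(qc_rows["role"].to_numpy()):
        base = mu + (nist_offset if role == "NIST" else 0.0)
        scale = 0.5 if role == "TQC" else 1.0
        qc_L[i] = base + rng.normal(0.0, 1.0, size=n_feat) * sigma_qc * scale

    log_all = pd.DataFrame(
        np.vstack([L, qc_L]),
        index=list(bio.index) + list(qc_rows["sample_id"]),
        columns=feature_ids,
    )
    log_all = log_all.loc[manifest["sample_id"]]

    # batch distortions on log10 scale, applied about the pool profile
    if cfg.batch_shifts is not None:
        shifts = np.asarray(cfg.batch_shifts, dtype=float)
    else:
        shifts = rng.normal(0.0, cfg.batch_shift_sd, size=cfg.n_batches)
    if cfg.batch_scales is not None:
        scales = np.asarray(cfg.batch_scales, dtype=float)
    else:
        scales = np.exp(rng.normal(0.0, cfg.batch_scale_sd, size=cfg.n_batches))
    batch_codes = manifest.set_index("sample_id")["batch"].loc[log_all.index]
    batch_idx = batch_codes.str.slice(1).astype(int).to_numpy()
    vals = log_all.to_numpy()
    vals = shifts[batch_idx, None] + mu[None, :] + scales[batch_idx, None] * (
        vals - mu[None, :]
    )

    conc = np.power(10.0, vals)

    # below-detection censoring: per-feature threshold at the zero_rate
    # quantile of generated concentrations
    if cfg.zero_rate > 0:
        thresh = np.quantile(conc, cfg.zero_rate, axis=0)
        conc = np.where(conc < thresh[None, :], 0.0, conc)
    if cfg.missing_rate > 0:
        miss = rng.random(conc.shape) < cfg.missing_rate
        conc = np.where(miss, np.nan, conc)

    matrix = ConcentrationMatrix(
        pd.DataFrame(conc, index=log_all.index, columns=feature_ids)
    )

    if cfg.n_outliers > 0:
        matrix, _ = inject_outliers(
            matrix, manifest, cfg.n_outliers, cfg.outlier_scale,
            seed=int(rng.integers(0, 2**31 - 1)),
        )

    covariates = covsub.loc[bio["subject_id"]].reset_index()
    covariates.insert(0, "sample_id", bio.index.to_numpy())
    covariates["timepoint"] = bio["timepoint"].to_numpy()
    # actual age at blood draw scatters around the nominal visit age
    nominal = np.array([_NOMINAL_AGE_DAYS.get(tp, 0.0) for tp in bio["timepoint"]])
    jitter = rng.normal(0.0, 10.0, size=len(nominal))
    covariates["child_age_days"] = np.where(nominal > 0, nominal + jitter, nominal)
    covariates["batch"] = (
        manifest.set_index("sample_id")["batch"].loc[covariates["sample_id"]].to_numpy()
    )
    return matrix, manifest, annotation, covariates


def inject_outliers(
    matrix: ConcentrationMatrix,
    manifest: pd.DataFrame,
    n: int,
    scale: float,
    seed: int,
) -> tuple[ConcentrationMatrix, list]:
    """Multiply all observed values of ``n`` random biological samples by ``scale``."""
    if scale <= 0:
        raise ValidationError("outlier scale must be > 0")
    manifest = validate_manifest(manifest)
    bio_ids = manifest.loc[manifest["role"] == "biological", "sample_id"]
    bio_ids = bio_ids[bio_ids.isin(matrix.sample_ids)].sort_values()
    if n >= len(bio_ids):
        raise ValidationError(
            f"cannot inject {n} outliers into {len(bio_ids)} biological samples"
        )
    rng = np.random.default_rng(seed)
    chosen = sorted(rng.choice(bio_ids.to_numpy(), size=n, replace=False).tolist())
    out = matrix.copy()
    out.data.loc[chosen] = out.data.loc[chosen] * scale
    return out, chosen


# ---------------------------------------------------------------------------
# exact-recovery harmonization fixture
# ---------------------------------------------------------------------------

def make_harmonization_fixture(
    n_bio_per_batch: int,
    n_features: int,
    shifts: Sequence[float],
    scales: Sequence[float],
    seed: int,
    n_pqc_per_batch: int = 3,
) -> tuple[ConcentrationMatrix, pd.DataFrame, ConcentrationMatrix]:
    """Noise-free multi-batch fixture whose batch distortion is exactly
    invertible by PQC-median centring + SD rescaling.

    Each batch holds an identical block of biological samples; the PQC pool
    profile equals the per-feature biological median; the supplied log10
    ``shifts`` are re-centred to median zero and ``scales`` renormalised to
    mean one (the harmonization re-anchors location to the global PQC median
    and scale to the mean batch SD, so only such distortions are exactly
    removable).  Returns (perturbed matrix, manifest, clean matrix).
    """
    shifts = np.asarray(shifts, dtype=float)
    scales = np.asarray(scales, dtype=float)
    if len(shifts) != len(scales):
        raise ValidationError("shifts and scales must have equal length")
    if np.any(scales <= 0):
        raise ValidationError("scale factors must be positive")
    shifts = shifts - np.median(shifts)
    scales = scales / scales.mean()
    n_batches = len(shifts)

    rng = np.random.default_rng(seed)
    base = rng.normal(0.0, 0.3, size=(n_bio_per_batch, n_features)) + rng.uniform(
        -1, 3, size=n_features
    )
    pool = np.median(base, axis=0)

    rows, clean_rows, ids = [], [], []
    man = []
    for b in range(n_batches):
        batch = f"B{b:02d}"
        med = np.median(base, axis=0)
        pert_bio = shifts[b] + med + scales[b] * (base - med)
        for i in range(n_bio_per_batch):
            sid = f"bio_{batch}_{i:03d}"
            ids.append(sid)
            rows.append(pert_bio[i])
            clean_rows.append(base[i])
            man.append((sid, f"S{i:03d}", "biological", batch, "birth", "serum"))
        pert_pqc = shifts[b] + med + scales[b] * (pool - med)
        for j in range(n_pqc_per_batch):
            sid = f"PQC_{batch}_{j:02d}"
            ids.append(sid)
            rows.append(pert_pqc)
            clean_rows.append(pool)
            man.append((sid, "PQC", "PQC", batch, "QC", "plasma"))

    cols = [f"F{i:04d}" for i in range(n_features)]
    perturbed = ConcentrationMatrix(
        pd.DataFrame(np.power(10.0, np.asarray(rows)), index=ids, columns=cols)
    )
    clean = ConcentrationMatrix(
        pd.DataFrame(np.power(10.0, np.asarray(clean_rows)), index=ids, columns=cols)
    )
    manifest = validate_manifest(
        pd.DataFrame(
            man,
            columns=["sample_id", "subject_id", "role", "batch", "timepoint", "matrix"],
        ).assign(exclusion="none")
    )
    return perturbed, manifest, clean


def default_antenatal_effects(
    feature_ids: Sequence[str],
    seed: int,
    ga_sd: float = 0.004,
    opposing_slope: float = -10.5,
    residual_sd: float = 0.0266,
) -> tuple[PlantedEffect, ...]:
    """Opposing gestational-age / birth-weight effect profiles.

    Per feature, a gestational-age slope (log10 per day) is drawn and the
    birth-weight slope (log10 per kg) set to ``opposing_slope`` times it plus
    noise, so that most features associate with the two covariates in
    opposite directions.
    """
    rng = np.random.default_rng(seed)
    effects = []
    for f in feature_ids:
        bga = rng.normal(0.0, ga_sd)
        bbw = opposing_slope * bga + rng.normal(0.0, residual_sd)
        effects.append(
            PlantedEffect((f,), "gestational_age", "slope", bga, timepoints=("birth",))
        )
        effects.append(
            PlantedEffect((f,), "birth_weight", "slope", bbw, timepoints=("birth",))
        )
    return tuple(effects)


def write_cohort(
    outdir,
    matrix: ConcentrationMatrix,
    manifest: pd.DataFrame,
    annotation: pd.DataFrame,
    covariates: pd.DataFrame,
) -> dict:
    """Write the four cohort tables as CSV; returns path map."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "matrix": outdir / "matrix.csv",
        "manifest": outdir / "manifest.csv",
        "annotation": outdir / "annotation.csv",
        "covariates": outdir / "covariates.csv",
    }
    matrix.to_csv(paths["matrix"])
    manifest.to_csv(paths["manifest"], index=False)
    annotation.to_csv(paths["annotation"], index=False)
    covariates.to_csv(paths["covariates"], index=False)
    return {k: str(v) for k, v in paths.items()}
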