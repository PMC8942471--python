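"""End-to-end pipeline orchestration.

``run_pipeline`` wires the stages together: simulate (or load) a cohort,
run the preprocessing chain, compute QC metrics, fit association models and
run the longitudinal analyses, writing every artifact as plain-text tables
plus a run manifest (config, seed, input hashes, per-stage counts) that is
sufficient to reproduce the run.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import associate, longitudinal, preprocess, qc, synthdata
from .containers import ConcentrationMatrix, ValidationError, validate_annotation, validate_manifest

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Configuration of a full pipeline run."""

    out_dir: str = "lipidpipe_out"
    # input tables; if None, a synthetic cohort is generated
    matrix_path: str | None = None
    manifest_path: str | None = None
    annotation_path: str | None = None
    covariates_path: str | None = None
    # synthetic cohort parameters (used when no inputs are given)
    simulate: dict = field(default_factory=dict)
    # preprocessing
    knn_k: int = 5
    n_components: int = 7
    percentile: float = 0.95
    # association
    presets: tuple = ("birth",)
    # clustering
    cluster_k: int = 10
    restarts: int = 10
    seed: int = 0

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        text = path.read_text()
        raw = yaml.safe_load(text) if path.suffix in (".yml", ".yaml") else json.loads(text)
        cfg = cls(**raw)
        for p in (cfg.matrix_path, cfg.manifest_path, cfg.annotation_path,
                  cfg.covariates_path):
            if p is not None and not Path(p).exists():
                raise ValidationError(f"input file not found: {p}")
        if not 1 <= cfg.n_components:
            raise ValidationError("n_components must be >= 1")
        if not 0 < cfg.percentile < 1:
            raise ValidationError("percentile must lie in (0, 1)")
        return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured stages; returns the run manifest dict."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, str] = {}
    counts: dict[str, object] = {}
    run_manifest = {
        "seed": config.seed,
        "config": dataclasses.asdict(config),
        "inputs": {},
        "artifacts": artifacts,
        "counts": counts,
        "status": "running",
    }

    def record(name: str, path: Path) -> None:
        artifacts[name] = str(path)

    try:
        # ---- stage: simulate or load -------------------------------------
        if config.matrix_path is None:
            sim_kwargs = dict(config.simulate)
            sim_kwargs.setdefault("seed", config.seed)
            cohort_cfg = synthdata.CohortConfig(**sim_kwargs)
            matrix, manifest, annotation, covariates = synthdata.generate_cohort(
                cohort_cfg
            )
            paths = synthdata.write_cohort(out / "cohort", matrix, manifest,
                                           annotation, covariates)
            artifacts.update({f"cohort_{k}": v for k, v in paths.items()})
        else:
            matrix = ConcentrationMatrix.from_csv(config.matrix_path)
            manifest = validate_manifest(pd.read_csv(config.manifest_path))
            annotation = validate_annotation(pd.read_csv(config.annotation_path))
            covariates = pd.read_csv(config.covariates_path)
            for key in ("matrix", "manifest", "annotation", "covariates"):
                p = Path(getattr(config, f"{key}_path"))
                run_manifest["inputs"][key] = {"path": str(p), "sha256": _sha256(p)}
        counts["samples_in"] = int(matrix.n_samples)
        counts["features_in"] = int(matrix.n_features)

        # ---- stage: preprocess -------------------------------------------
        matrix = preprocess.replace_zeros(matrix, manifest)
        matrix = preprocess.harmonize_batches(matrix, manifest)
        matrix = preprocess.impute_knn(matrix, manifest, k=config.knn_k)
        report = preprocess.detect_outliers(
            matrix, manifest, n_components=config.n_components,
            percentile=config.percentile,
        )
        manifest, summary = preprocess.apply_exclusions(manifest, report)
        retained_ids = manifest.loc[manifest["exclusion"] == "none", "sample_id"]
        matrix = ConcentrationMatrix(matrix.data.loc[
            [s for s in matrix.sample_ids if s in set(retained_ids)]
        ])
        counts["samples_excluded"] = int(summary.loc[
            summary["reason"] == "excluded", "n"].iloc[0])
        counts["samples_retained"] = int(summary.loc[
            summary["reason"] == "retained", "n"].iloc[0])
        p = out / "processed_matrix.csv"; matrix.to_csv(p); record("processed_matrix", p)
        p = out / "exclusion_summary.tsv"; summary.to_csv(p, sep="\t", index=False)
        record("exclusion_summary", p)
        p = out / "outlier_report.json"
        p.write_text(json.dumps(report.to_json_dict(), indent=2))
        record("outlier_report", p)

        class_totals = preprocess.compute_class_totals(matrix, annotation)
        p = out / "class_totals.csv"; class_totals.to_csv(p); record("class_totals", p)

        # ---- stage: qc ----------------------------------------------------
        cv = qc.compute_cv(matrix, manifest, role="PQC", annotation=annotation)
        p = out / "cv_report.tsv"; cv.cv.to_csv(p, sep="\t"); record("cv_report", p)
        p = out / "cv_summary.json"; p.write_text(json.dumps(cv.summary(), indent=2))
        record("cv_summary", p)
        counts["median_pqc_cv_pct"] = cv.median_cv

        # ---- stage: associate ----------------------------------------------
        cov = covariates.set_index("sample_id")
        species = set(preprocess.species_view(annotation)["feature_id"])
        for preset in config.presets:
            tp = {"birth": "birth", "breastfeeding_6m": "6m",
                  "breastfeeding_12m": "12m"}.get(preset)
            sel = cov[cov["timepoint"] == tp] if tp else cov
            ids = [s for s in matrix.sample_ids
                   if s in sel.index]
            sub = ConcentrationMatrix(
                matrix.data.loc[ids, [f for f in matrix.feature_ids if f in species]]
            )
            res = associate.fit_lipid_regressions(
                sub, sel.loc[ids].reset_index(), preset=preset
            )
            p = out / f"associations_{preset}.tsv"
            res.to_csv(p, sep="\t", index=False)
            record(f"associations_{preset}", p)
            counts[f"associations_{preset}_n_fits"] = int(res["feature_id"].nunique())

        # ---- stage: longitudinal -------------------------------------------
        clustering = longitudinal.cluster_trajectories(
            matrix, manifest, k=config.cluster_k, seed=config.seed,
            restarts=config.restarts,
        )
        p = out / "dtw_dissimilarity.tsv"
        clustering.dissimilarity.to_csv(p, sep="\t"); record("dtw_dissimilarity", p)
        assign = clustering.assignments.rename("cluster").to_frame()
        assign["medoid"] = [
            f in clustering.medoids for f in assign.index
        ]
        p = out / "cluster_assignments.tsv"
        assign.to_csv(p, sep="\t"); record("cluster_assignments", p)
        p = out / "cluster_summary.tsv"
        clustering.summary_table().to_csv(p, sep="\t", index=False)
        record("cluster_summary", p)
        counts["n_clusters"] = int(clustering.k)

        run_manifest["status"] = "ok"
    except Exception as exc:  # partial outputs stay, marked failed
        run_manifest["status"] = "failed"
        run_manifest["error"] = f"{type(exc).__name__}: {exc}"
        (out / "run_manifest.json").write_text(json.dumps(run_manifest, indent=2))
        raise
    (out / "run_manifest.json").write_text(json.dumps(run_manifest, indent=2))
    return run_manifest
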