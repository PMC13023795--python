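"""Validated pipeline configuration and the end-to-end driver.

``run_pipeline`` executes simulate -> preprocess -> decompose/features ->
(optional) select -> classify, writing every artifact as CSV/JSON under a
working directory together with a manifest (config, seed, counts) so any
output is traceable to the configuration hash that produced it.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, field_validator

from . import features as feat
from .classify import CLASSIFIER_IDS, accuracy_table, run_experiment
from .decomposition import EmdParams
from .preprocessing import DenoiseParams, preprocess_records
from .pso import SwarmParams, run_pso
from .synthetic import generate_dataset
from .types import COMPONENT_NAMES, DWT_COMPONENTS, IMF_COMPONENTS

__all__ = ["PipelineConfig", "run_pipeline", "standard_subsets"]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid", frozen=True)


class SimulateConfig(_Strict):
    n_mi: int = Field(default=25, ge=0)
    n_healthy: int = Field(default=25, ge=0)
    record_duration: float = Field(default=20.0, gt=0)


class DenoiseConfig(_Strict):
    wavelet_name: str = "db6"
    levels: int = Field(default=6, ge=1)
    threshold_mode: str = "soft"


class SegmentConfig(_Strict):
    segment_length: int = Field(default=10_000, ge=1)
    norm_scope: str = "record"

    @field_validator("norm_scope")
    @classmethod
    def _scope(cls, v: str) -> str:
        if v not in ("record", "segment"):
            raise ValueError("norm_scope must be 'record' or 'segment'")
        return v


class EmdConfig(_Strict):
    max_imfs: int = Field(default=5, ge=1)
    sift_stop_sd: float = Field(default=0.2, gt=0)
    max_sift_iters: int = Field(default=100, ge=1)


class PsoConfig(_Strict):
    enabled: bool = False
    n_particles: int = Field(default=30, ge=2)
    n_iterations: int = Field(default=100, ge=1)


class ClassifyConfig(_Strict):
    classifiers: tuple[str, ...] = CLASSIFIER_IDS
    folds: int = Field(default=10, ge=2)

    @field_validator("classifiers")
    @classmethod
    def _ids(cls, v):
        bad = set(v) - set(CLASSIFIER_IDS)
        if bad:
            raise ValueError(f"unknown classifier ids {sorted(bad)}")
        return tuple(v)


class PipelineConfig(_Strict):
    """Every tunable of the pipeline in one schema-validated document."""

    seed: int = 0
    simulate: SimulateConfig = SimulateConfig()
    denoise: DenoiseConfig = DenoiseConfig()
    segmentation: SegmentConfig = SegmentConfig()
    emd: EmdConfig = EmdConfig()
    pso: PsoConfig = PsoConfig()
    classify: ClassifyConfig = ClassifyConfig()

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.model_dump(), sort_keys=True).encode()
        ).hexdigest()[:16]


def standard_subsets(columns: list[str]) -> dict[str, list[str]]:
    """The three report-style feature groupings: per-component, DWT-only,
    IMF-only and the full 390-column set."""
    def cols(prefixes):
        return [c for c in columns if c.split("_", 1)[0] in prefixes]

    subsets = {comp: cols((comp,)) for comp in COMPONENT_NAMES}
    subsets["all_a_d"] = cols(DWT_COMPONENTS)
    subsets["all_imfs"] = cols(IMF_COMPONENTS)
    subsets["all"] = cols(COMPONENT_NAMES)
    return {k: v for k, v in subsets.items() if v}


def run_pipeline(config: PipelineConfig, workdir: str | Path) -> Path:
    """Execute the configured pipeline; returns the report directory."""
    workdir = Path(workdir)
    workdir.mkdir(parents=True, exist_ok=True)
    manifest = {"config": config.model_dump(), "config_hash": config.config_hash(),
                "seed": config.seed, "stages": {}}

    records = generate_dataset(config.simulate.n_mi, config.simulate.n_healthy,
                               config.simulate.record_duration, config.seed)
    manifest["stages"]["simulate"] = {"n_records": len(records)}

    segments = preprocess_records(
        records,
        DenoiseParams(wavelet_name=config.denoise.wavelet_name,
                      levels=config.denoise.levels,
                      threshold_mode=config.denoise.threshold_mode),
        segment_length=config.segmentation.segment_length,
        norm_scope=config.segmentation.norm_scope,
    )
    manifest["stages"]["preprocess"] = {"n_segments": len(segments)}
    if not segments:
        raise ValueError("preprocessing produced no segments; records too short?")

    emd_params = EmdParams(max_imfs=config.emd.max_imfs,
                           sift_stop_sd=config.emd.sift_stop_sd,
                           max_sift_iters=config.emd.max_sift_iters)
    matrix = feat.extract_feature_matrix(segments, emd_params=emd_params)
    matrix_path = workdir / "features.csv"
    matrix.to_csv(matrix_path, index=False, float_format="%.17g")
    manifest["stages"]["features"] = {"n_rows": len(matrix),
                                      "n_feature_columns": matrix.shape[1] - 3}

    feature_cols = [c for c in matrix.columns
                    if c not in ("record_id", "segment_index", "label")]
    subsets = standard_subsets(feature_cols)

    if config.pso.enabled:
        keep = ~matrix[feature_cols].isna().any(axis=1).to_numpy()
        x = matrix.loc[keep, feature_cols].to_numpy(dtype=float)
        y = matrix.loc[keep, "label"].to_numpy()
        mask, state = run_pso(x, y, SwarmParams(
            n_particles=config.pso.n_particles,
            n_iterations=config.pso.n_iterations, seed=config.seed))
        selected = [c for c, b in zip(feature_cols, mask) if b]
        subsets["pso_selected"] = selected
        (workdir / "mask.json").write_text(json.dumps({
            "selected_features": selected,
            "gbest_fitness": state.gbest_fitness,
            "fitness_history": state.fitness_history,
        }, indent=1))
        manifest["stages"]["select"] = {"n_selected": len(selected)}

    reports = run_experiment(matrix, config.classify.classifiers, subsets,
                             k=config.classify.folds, seed=config.seed)
    report_dir = workdir / "report"
    report_dir.mkdir(exist_ok=True)
    pd.DataFrame([r.as_dict() for r in reports]).to_csv(
        report_dir / "metrics.csv", index=False)
    accuracy_table(reports).to_csv(report_dir / "accuracy_grid.csv", index=False)
    with open(report_dir / "metrics.json", "w") as fh:
        json.dump([
            {**r.as_dict(),
             "fold_counts": [[c.tp, c.fp, c.tn, c.fn] for c in r.fold_counts]}
            for r in reports
        ], fh, indent=1)
    manifest["stages"]["classify"] = {"n_reports": len(reports)}

    with open(workdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)
    return report_dir
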