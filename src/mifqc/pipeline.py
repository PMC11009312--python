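"""End-to-end orchestration: simulate (or load) -> gate -> reports.

`run_validation_pipeline` composes the library stages into one audited run:
it resolves a study (simulated from a design, or loaded from disk), gates
it under the requested threshold policy, computes the concordance,
precision, MLE and spatial-distance reports, and writes everything to a run
directory together with a JSON verdict and the resolved configuration —
including every (run, marker) threshold actually used, since threshold
auditability is the central QC concern.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import cells_io, gating, mle as mle_mod, panel_stats, spatial_distance
from .errors import MifqcError, ValidationError
from .synthetic_tissue import (
    SimulationConfig,
    midpoint_global_thresholds,
    simulate_concordance_study,
    simulate_precision_study,
)


@dataclass
class PipelineConfig:
    """Resolved configuration of one validation run."""

    out_dir: str | Path
    design: str = "precision"  # "precision" | "concordance" | "load"
    study_dir: str | Path | None = None  # required when design == "load"
    sim: SimulationConfig = field(default_factory=SimulationConfig)
    seed: int | None = None  # overrides sim.seed when given
    mode: str = "local"  # gating: "global" | "local"
    global_thresholds: dict[str, float] | None = None
    ref_phenotype: str = "T_cyt"
    target_phenotype: str = "T_reg"
    cv_cutoff: float = panel_stats.DEFAULT_CV_CUTOFF
    rel_diff_band: float = panel_stats.DEFAULT_REL_DIFF_BAND
    mle_band: float = mle_mod.DEFAULT_MLE_BAND

    def __post_init__(self) -> None:
        if self.design not in ("precision", "concordance", "load"):
            raise ValidationError(f"unknown design {self.design!r}")
        if self.design == "load" and self.study_dir is None:
            raise ValidationError("design='load' requires study_dir")
        if self.mode not in ("global", "local"):
            raise ValidationError(f"unknown gating mode {self.mode!r}")
        if self.cv_cutoff <= 0 or self.rel_diff_band <= 0 or self.mle_band <= 0:
            raise ValidationError("report bands must be positive")


def _stage(name: str):
    """Prefix stage context onto any error raised inside the stage."""

    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and isinstance(exc, Exception):
                raise MifqcError(f"pipeline stage {name!r} failed: {exc}") from exc
            return False

    return _Ctx()


def resolve_study(config: PipelineConfig) -> cells_io.Study:
    sim = config.sim
    if config.seed is not None:
        sim = dataclasses.replace(sim, seed=config.seed)
    if config.design == "precision":
        return simulate_precision_study(sim)
    if config.design == "concordance":
        return simulate_concordance_study(sim)
    return cells_io.load_study(
        Path(config.study_dir) / "manifest.yaml", config.study_dir
    )


def resolve_policy(
    config: PipelineConfig, study: cells_io.Study
) -> gating.ThresholdPolicy:
    if config.mode == "local":
        return gating.fit_local_thresholds(study)
    thresholds = config.global_thresholds
    if thresholds is None:
        if config.design == "load":
            raise ValidationError(
                "global gating of a loaded study requires explicit thresholds"
            )
        thresholds = midpoint_global_thresholds(config.sim.intensity)
    return gating.ThresholdPolicy.global_policy(thresholds)


def run_validation_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and write the report bundle; returns the in-memory
    reports keyed by name, plus the verdict dict written to summary.json."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    # configured phenotype names must exist before any compute
    with _stage("validate"):
        pheno_names = {p.name for p in gating.DEFAULT_PHENOTYPES}
        if config.design == "load":
            study_probe = resolve_study(config)
            pheno_names = {p.name for p in study_probe.manifest.phenotypes} or pheno_names
        for name in (config.ref_phenotype, config.target_phenotype):
            if name not in pheno_names:
                raise ValidationError(f"unknown phenotype {name!r}")

    with _stage("simulate/load"):
        study = resolve_study(config)
        cells_io.save_study(study, out_dir / "study")
    with _stage("gate"):
        policy = resolve_policy(config, study)
        gated = gating.gate_study(study, policy)
    with _stage("summaries"):
        summaries = panel_stats.section_summaries(gated)
        summaries.to_csv(out_dir / "section_summaries.csv", index=False)

    results: dict = {"study": study, "gated": gated, "summaries": summaries}
    verdict: dict = {
        "design": config.design,
        "gating_mode": config.mode,
        "thresholds": {
            f"{scope}/{marker}": value
            for (scope, marker), value in sorted(policy.thresholds.items())
        },
    }

    has_singleplex = any(not s.is_multiplex for s in study.manifest.sections)
    if has_singleplex:
        with _stage("concordance"):
            conc = panel_stats.concordance_report(gated, band=config.rel_diff_band)
            conc.to_csv(out_dir / "concordance.csv", index=False)
            results["concordance"] = conc
            verdict["concordance_out_of_band"] = int(conc["flag_out_of_band"].sum())

    multi_runs = {s.run_id for s in study.manifest.sections if s.is_multiplex}
    if len(multi_runs) > 1:
        with _stage("precision"):
            prec = panel_stats.precision_report(gated, cv_cutoff=config.cv_cutoff)
            prec.intra.to_csv(out_dir / "precision_intra.csv", index=False)
            prec.summary.to_csv(out_dir / "precision_summary.csv", index=False)
            results["precision"] = prec
            verdict["precision_inter_above_cutoff"] = int(
                prec.summary["flag_inter_above_cutoff"].sum()
            )
        with _stage("mle"):
            mle_cfg = mle_mod.MLEConfig(band=config.mle_band)
            mle_rep = mle_mod.mle_report(gated, mle_cfg)
            mle_rep.per_section.to_csv(out_dir / "mle_per_section.csv", index=False)
            mle_rep.per_marker.to_csv(out_dir / "mle_per_marker.csv", index=False)
            mle_rep.flags.to_csv(out_dir / "mle_flags.csv", index=False)
            results["mle"] = mle_rep
            verdict["mle_flagged_sections"] = int(len(mle_rep.flags))
        with _stage("spatial"):
            dist = spatial_distance.distance_report(
                gated, config.ref_phenotype, config.target_phenotype
            )
            dist.per_section.to_csv(out_dir / "spatial_per_section.csv", index=False)
            dist.cv_by_specimen.to_csv(out_dir / "spatial_cv.csv", index=False)
            comp = spatial_distance.compare_directions(
                gated, config.ref_phenotype, config.target_phenotype
            )
            comp.to_csv(out_dir / "spatial_directions.csv", index=False)
            results["spatial"] = dist
            results["directions"] = comp
            finite = dist.cv_by_specimen["cv_mean_nn"].dropna()
            verdict["spatial_max_cv"] = float(finite.max()) if len(finite) else None

    cells_io.write_json_summary(_jsonable(verdict), out_dir / "summary.json")
    results["verdict"] = verdict
    return results


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj
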