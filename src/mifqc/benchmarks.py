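"""Reference benchmark computations for panel-validation claims.

Two kinds of quantities live here:

* definitional worked examples of the multiplex labeling efficiency on
  constructed cell tables (exact results by construction); and
* simulation benchmarks that measure the pipeline's headline behavior
  under the standard study designs — intra-/inter-run CV of % positive
  cells under fixed global gating with run-to-run channel gains, the
  cross-section CV of directional nearest-neighbor distances, and 1-plex
  vs 4-plex concordance.

A single simulated study's median CV is a noisy statistic (five gain draws
per run); each simulation benchmark therefore simulates ``n_replicates``
independent studies under identical conditions (sub-seeded from ``seed``)
and reports the median of the per-study statistic.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd

from .cells_io import SectionMeta, Study, StudyManifest
from .gating import DEFAULT_PHENOTYPES, ThresholdPolicy, gate_study
from .mle import mle_for_marker
from .panel_stats import concordance_report, precision_report
from .spatial_distance import compare_directions, distance_report
from .synthetic_tissue import (
    BatchModel,
    CompositionModel,
    SimulationConfig,
    midpoint_global_thresholds,
    simulate_concordance_study,
    simulate_precision_study,
    single_specimen_config,
    unit_gains,
)

T_CELL_PHENOTYPES = ("T_cyt", "T_helper", "T_reg")


def _child_seed(seed: int, tag: int, k: int) -> int:
    return int(np.random.SeedSequence((seed, tag, k)).generate_state(1)[0] % 2**31)


# ---------------------------------------------------------------------------
# constructed MLE examples


def _constructed_section(class_counts: dict[str, int]) -> tuple[Study, ThresholdPolicy]:
    """A single multiplex section with exact per-class cell counts.

    Cells of a class get intensity 100 on the class's markers and 1
    elsewhere; a fixed global threshold of 50 separates them perfectly.
    """
    from .synthetic_tissue import CLASS_MARKERS, DEFAULT_MARKERS

    rows = []
    i = 0
    for cls, count in class_counts.items():
        for _ in range(count):
            row = {
                "cell_id": f"demo-{i}",
                "section_id": "demo",
                "x_um": float(i % 100),
                "y_um": float(i // 100),
            }
            for m in DEFAULT_MARKERS:
                row[m] = 100.0 if m in CLASS_MARKERS[cls] else 1.0
            rows.append(row)
            i += 1
    meta = SectionMeta(
        section_id="demo",
        specimen="control",
        serial_index=1,
        run_id="1",
        replicate_index=1,
        assay="multiplex",
    )
    manifest = StudyManifest(
        sections=[meta], markers=list(DEFAULT_MARKERS), phenotypes=list(DEFAULT_PHENOTYPES)
    )
    study = Study(manifest=manifest, tables={"demo": pd.DataFrame(rows)})
    policy = ThresholdPolicy.global_policy({m: 50.0 for m in DEFAULT_MARKERS})
    return study, policy


def mle_perfect_colocalization() -> float:
    """MLE of CD8a when every CD8a+ cell is also CD3e+ (all T_cyt): 100%.

    50 CD3e+CD8a+ cells plus 200 all-negative cells.
    """
    study, policy = _constructed_section({"T_cyt": 50, "other": 200})
    gated = gate_study(study, policy)
    value, _, _ = mle_for_marker(gated.sections["demo"], "CD8a")
    return value


def mle_with_unphenotyped_fraction() -> float:
    """MLE of CD3e when 10 of 100 CD3e+ cells fall in no T-cell phenotype: 90%.

    40 T_cyt + 30 T_helper + 20 T_reg + 10 CD3e-single cells.
    """
    study, policy = _constructed_section(
        {"T_cyt": 40, "T_helper": 30, "T_reg": 20, "CD3e_only": 10, "other": 100}
    )
    gated = gate_study(study, policy)
    value, _, _ = mle_for_marker(gated.sections["demo"], "CD3e")
    return value


# ---------------------------------------------------------------------------
# simulation benchmarks


def precision_benchmark(seed: int, n_replicates: int = 5) -> dict[str, float]:
    """Precision of % positive cells under **global** midpoint gating in the
    5-run x 3-replicate design with log-uniform [0.5, 2] run gains
    (one high-T-cell-density specimen, 2000 cells/mm^2 over 4 mm^2).

    Returns the median (over replicate studies) of:

    * ``median_intra_run_cv`` — median intra-run CV across all seven
      entities (four single markers + three T-cell phenotypes);
    * ``median_inter_run_cv_tcell`` — median inter-run CV (over all 15
      sections) across the three multi-marker T-cell phenotypes;
    * ``median_inter_run_cv_all`` — the same median across all entities.
    """
    intra, inter_t, inter_all, n_cells = [], [], [], []
    for k in range(n_replicates):
        cfg = single_specimen_config("CT26", seed=_child_seed(seed, 3, k))
        study = simulate_precision_study(cfg)
        policy = ThresholdPolicy.global_policy(midpoint_global_thresholds(cfg.intensity))
        rep = precision_report(gate_study(study, policy))
        intra.append(float(np.nanmedian(rep.intra["intra_run_cv"])))
        by_entity = rep.summary.set_index("entity")["inter_run_cv"]
        inter_t.append(float(np.median([by_entity[p] for p in T_CELL_PHENOTYPES])))
        inter_all.append(float(np.nanmedian(by_entity)))
        n_cells.append(study.n_cells())
    return {
        "median_intra_run_cv": float(np.median(intra)),
        "median_inter_run_cv_tcell": float(np.median(inter_t)),
        "median_inter_run_cv_all": float(np.median(inter_all)),
        "n_cells_per_study": float(np.median(n_cells)),
    }


def spatial_benchmark(seed: int, n_replicates: int = 5) -> dict[str, float]:
    """Reproducibility of the mean T_cyt->T_reg nearest-neighbor distance
    across 15 sections drawn from one homogeneous Poisson process
    (T_cyt 80/mm^2, T_reg 30/mm^2 over 4 mm^2; unit gains, one gating).

    Returns the median over replicate studies of the cross-section CV of
    the per-section mean distance, plus the pooled direction medians.
    """
    cvs, med_ab, med_ba, n_pairs = [], [], [], []
    for k in range(n_replicates):
        cfg = single_specimen_config("CT26", seed=_child_seed(seed, 5, k))
        cfg = dataclasses.replace(
            cfg,
            batch=BatchModel(
                fixed_gains={
                    str(r): unit_gains(cfg.markers) for r in range(1, cfg.n_runs + 1)
                }
            ),
        )
        study = simulate_precision_study(cfg)
        policy = ThresholdPolicy.global_policy(midpoint_global_thresholds(cfg.intensity))
        gated = gate_study(study, policy)
        rep = distance_report(gated, "T_cyt", "T_reg")
        row = rep.cv_by_specimen[rep.cv_by_specimen["ref_phenotype"] == "T_cyt"]
        cvs.append(float(row["cv_mean_nn"].iloc[0]))
        comp = compare_directions(gated, "T_cyt", "T_reg").iloc[0]
        med_ab.append(float(comp["median_a_to_b_um"]))
        med_ba.append(float(comp["median_b_to_a_um"]))
        n_pairs.append(int(comp["n_a_to_b"]))
    return {
        "cv_mean_nn_tcyt_to_treg": float(np.median(cvs)),
        "median_tcyt_to_treg_um": float(np.median(med_ab)),
        "median_treg_to_tcyt_um": float(np.median(med_ba)),
        "n_distances": float(np.median(n_pairs)),
    }


def concordance_benchmark(seed: int, n_replicates: int = 5) -> dict[str, float]:
    """1-plex vs 4-plex concordance for an abundant marker (CD3e, 8% of
    cells) in the five-serial-section design: section 3 multiplex, the
    other four sections 1-plex for CD3e, one shared staining batch (unit
    gains), identical global gating on every section.

    Returns the median over replicate studies of the maximum
    |relative difference| in % positive cells across the four 1-plex
    comparisons.
    """
    composition = CompositionModel(
        density_per_mm2=2200.0,
        class_fractions={
            "T_cyt": 0.035,
            "T_helper": 0.025,
            "T_reg": 0.01,
            "CD3e_only": 0.01,
            "CD4_only": 0.02,
            "CD8a_only": 0.01,
            "FoxP3_only": 0.01,
        },
    )
    max_abs = []
    for k in range(n_replicates):
        cfg = SimulationConfig(
            composition={"CT26": composition},
            batch=BatchModel(fixed_gains={"1": unit_gains()}),
            seed=_child_seed(seed, 6, k),
        )
        study = simulate_concordance_study(cfg, singleplex_markers=["CD3e"] * 4)
        policy = ThresholdPolicy.global_policy(midpoint_global_thresholds(cfg.intensity))
        with warnings.catch_warnings():
            # only CD3e has 1-plex sections in this focused design
            warnings.simplefilter("ignore", UserWarning)
            rep = concordance_report(gate_study(study, policy))
        cd3e = rep[rep["marker"] == "CD3e"]
        max_abs.append(float(cd3e["rel_diff_pct"].abs().max()))
    return {"max_abs_rel_diff_pct_cd3e": float(np.median(max_abs))}
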