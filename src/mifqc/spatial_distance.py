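"""Directional nearest-neighbor cell-cell distances between phenotypes.

For reference phenotype A and target phenotype B, the A-to-B distance of a
reference cell is the Euclidean centroid distance to its closest B cell.
The two directions are generally asymmetric: when B cells are much rarer
than A cells, the average A-to-B distance exceeds the average B-to-A
distance (every B cell tends to have an A cell nearby, but not conversely).

Summaries report the per-section mean and median in both directions, the
cross-section CV of the per-section means (reproducibility across serial
sections and staining runs), and a two-sided Mann-Whitney rank comparison
of the pooled per-cell distances between the two directions.

Distances are centroid-to-centroid with no correction for cells near the
field border.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.stats import mannwhitneyu

from .errors import ValidationError
from .gating import GatedStudy
from .panel_stats import cv


def nn_distances(ref_cells: pd.DataFrame, target_cells: pd.DataFrame) -> np.ndarray:
    """One nearest-neighbor distance (µm) per reference cell.

    Both frames need ``x_um``/``y_um`` columns (and ``cell_id`` for
    self-exclusion).  A cell present in both sets — possible when the two
    phenotype gates overlap — is excluded from the target set while it is
    the reference, so no zero self-distances are produced.
    """
    if len(ref_cells) == 0 or len(target_cells) == 0:
        raise ValidationError("nn_distances needs non-empty reference and target sets")
    ref_xy = ref_cells[["x_um", "y_um"]].to_numpy(dtype=float)
    tgt_xy = target_cells[["x_um", "y_um"]].to_numpy(dtype=float)
    tree = cKDTree(tgt_xy)

    shared = np.zeros(len(ref_cells), dtype=bool)
    tgt_index: dict[str, int] = {}
    if "cell_id" in ref_cells.columns and "cell_id" in target_cells.columns:
        tgt_index = {cid: i for i, cid in enumerate(target_cells["cell_id"])}
        shared = np.array(
            [cid in tgt_index for cid in ref_cells["cell_id"]], dtype=bool
        )
    if shared.all() and len(target_cells) == 1:
        raise ValidationError(
            "target set contains only the reference cell itself"
        )

    k = 2 if shared.any() else 1
    dist, idx = tree.query(ref_xy, k=k)
    if k == 1:
        return np.asarray(dist, dtype=float)
    out = dist[:, 0].copy()
    ref_ids = ref_cells["cell_id"].to_numpy()
    for i in np.flatnonzero(shared):
        if idx[i, 0] == tgt_index[ref_ids[i]]:
            out[i] = dist[i, 1]
    return out


@dataclass
class DistanceSummary:
    """Per-section NN distances for one (reference, target) direction."""

    section_id: str
    specimen: str
    run_id: str
    ref_phenotype: str
    target_phenotype: str
    n_ref: int
    n_target: int
    mean_nn: float
    median_nn: float
    distances: np.ndarray = field(repr=False)


@dataclass
class DistanceReport:
    summaries: list[DistanceSummary]
    per_section: pd.DataFrame  # long: one row per section x direction
    cv_by_specimen: pd.DataFrame  # CV of per-section means, all sections pooled
    cv_by_run: pd.DataFrame  # supplementary per-run CVs
    skipped_sections: list[str]


def _phenotype_cells(gs, name: str) -> pd.DataFrame:
    mask = (gs.phenotype == name).to_numpy()
    return gs.cells.loc[mask, ["cell_id", "x_um", "y_um"]]


def distance_report(
    gated: GatedStudy, ref_phenotype: str, target_phenotype: str
) -> DistanceReport:
    """Per-section NN distance summaries in both directions, with
    cross-section CV of the per-section mean distance.

    The headline CV pools all sections of a specimen across runs; per-run
    CVs are reported as a supplementary table.  Sections lacking either
    phenotype are skipped and listed in ``skipped_sections``.
    """
    summaries: list[DistanceSummary] = []
    skipped: list[str] = []
    for gs in gated.multiplex_sections():
        a = _phenotype_cells(gs, ref_phenotype)
        b = _phenotype_cells(gs, target_phenotype)
        if len(a) == 0 or len(b) == 0:
            warnings.warn(
                f"section {gs.meta.section_id!r} lacks "
                f"{ref_phenotype if len(a) == 0 else target_phenotype}; skipped",
                stacklevel=2,
            )
            skipped.append(gs.meta.section_id)
            continue
        for ref_name, tgt_name, ref, tgt in (
            (ref_phenotype, target_phenotype, a, b),
            (target_phenotype, ref_phenotype, b, a),
        ):
            d = nn_distances(ref, tgt)
            summaries.append(
                DistanceSummary(
                    section_id=gs.meta.section_id,
                    specimen=gs.meta.specimen,
                    run_id=gs.meta.run_id,
                    ref_phenotype=ref_name,
                    target_phenotype=tgt_name,
                    n_ref=len(ref),
                    n_target=len(tgt),
                    mean_nn=float(d.mean()),
                    median_nn=float(np.median(d)),
                    distances=d,
                )
            )
    per_section = pd.DataFrame(
        [
            {
                "section_id": s.section_id,
                "specimen": s.specimen,
                "run_id": s.run_id,
                "ref_phenotype": s.ref_phenotype,
                "target_phenotype": s.target_phenotype,
                "n_ref": s.n_ref,
                "n_target": s.n_target,
                "mean_nn_um": s.mean_nn,
                "median_nn_um": s.median_nn,
            }
            for s in summaries
        ]
    )
    cv_spec_rows, cv_run_rows = [], []
    if not per_section.empty:
        grouped = per_section.groupby(
            ["specimen", "ref_phenotype", "target_phenotype"], sort=False
        )
        for (specimen, ref, tgt), grp in grouped:
            cv_spec_rows.append(
                {
                    "specimen": specimen,
                    "ref_phenotype": ref,
                    "target_phenotype": tgt,
                    "n_sections": len(grp),
                    "cv_mean_nn": cv(grp["mean_nn_um"], warn=False),
                }
            )
            for run_id, run_grp in grp.groupby("run_id", sort=False):
                cv_run_rows.append(
                    {
                        "specimen": specimen,
                        "run_id": run_id,
                        "ref_phenotype": ref,
                        "target_phenotype": tgt,
                        "n_sections": len(run_grp),
                        "cv_mean_nn": cv(run_grp["mean_nn_um"], warn=False)
                        if len(run_grp) >= 2
                        else np.nan,
                    }
                )
    return DistanceReport(
        summaries=summaries,
        per_section=per_section,
        cv_by_specimen=pd.DataFrame(cv_spec_rows),
        cv_by_run=pd.DataFrame(cv_run_rows),
        skipped_sections=skipped,
    )


def compare_directions(
    gated: GatedStudy, pheno_a: str, pheno_b: str
) -> pd.DataFrame:
    """Compare pooled A-to-B vs B-to-A distances per specimen.

    Pools the per-cell NN distances over all sections of a specimen in each
    direction and applies a two-sided Mann-Whitney rank test.  Returns one
    row per specimen with both medians, the U statistic and the p-value
    (``nan`` when either direction has fewer than two distances).
    """
    report = distance_report(gated, pheno_a, pheno_b)
    rows = []
    specimens = {s.specimen: None for s in report.summaries}
    for specimen in specimens:
        ab = np.concatenate(
            [
                s.distances
                for s in report.summaries
                if s.specimen == specimen and s.ref_phenotype == pheno_a
            ]
            or [np.empty(0)]
        )
        ba = np.concatenate(
            [
                s.distances
                for s in report.summaries
                if s.specimen == specimen and s.ref_phenotype == pheno_b
            ]
            or [np.empty(0)]
        )
        if len(ab) < 2 or len(ba) < 2:
            warnings.warn(
                f"specimen {specimen!r}: too few distances for a rank test; skipped",
                stacklevel=2,
            )
            stat, p = np.nan, np.nan
        else:
            stat, p = mannwhitneyu(ab, ba, alternative="two-sided")
        rows.append(
            {
                "specimen": specimen,
                "n_a_to_b": len(ab),
                "n_b_to_a": len(ba),
                "median_a_to_b_um": float(np.median(ab)) if len(ab) else np.nan,
                "median_b_to_a_um": float(np.median(ba)) if len(ba) else np.nan,
                "statistic": float(stat),
                "p_value": float(p),
            }
        )
    return pd.DataFrame(rows)
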