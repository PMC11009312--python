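"""Multiplex labeling efficiency (MLE).

MLE benchmarks the fidelity of a multiplex run for each marker: it is the
percentage of that marker's positive cells that fall into *valid*
multi-marker phenotypes containing the marker.  For the murine T-cell
panel::

    MLE(CD3e)  = 100 * (#T_cyt + #T_helper + #T_reg) / #CD3e+ cells
    MLE(CD4)   = 100 * (#T_helper + #T_reg)          / #CD4+  cells
    MLE(CD8a)  = 100 * #T_cyt                        / #CD8a+ cells
    MLE(FoxP3) = 100 * #T_reg                        / #FoxP3+ cells

An MLE of 100% for CD8a means CD3e co-localized in every CD8a+ cell; an MLE
of 90% for CD3e means 10% of CD3e+ cells fell in no analysed T-cell
phenotype.  Tracked across staining runs (ideally on a positive-control
specimen), a drop in MLE flags a run whose channel intensities drifted.

The qualifying phenotypes are counted from the mutually exclusive
priority-ordered labels (T_helper excludes FoxP3+ cells there), so each
cell contributes to a numerator at most once and MLE is bounded by 100%.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .gating import GatedSection, GatedStudy, PhenotypeDef
from .panel_stats import cv

#: the murine panel's qualifying phenotypes per marker
DEFAULT_QUALIFYING: dict[str, tuple[str, ...]] = {
    "CD3e": ("T_cyt", "T_helper", "T_reg"),
    "CD4": ("T_helper", "T_reg"),
    "CD8a": ("T_cyt",),
    "FoxP3": ("T_reg",),
}

DEFAULT_MLE_BAND = 10.0  # percentage points


@dataclass
class MLEConfig:
    """Qualifying phenotypes per marker and the run-flagging band.

    ``count_mode`` selects how qualifying cells are counted:
    ``"labels"`` (default) counts the exclusive assigned phenotype labels;
    ``"combinations"`` counts cells matching each definition's boolean
    marker combination directly, which may double-count a cell across
    overlapping definitions (a sensitivity-analysis mode; an inflated
    numerator is then rejected by the <= 100% check).
    """

    qualifying: dict[str, tuple[str, ...]] = field(
        default_factory=lambda: dict(DEFAULT_QUALIFYING)
    )
    band: float = DEFAULT_MLE_BAND
    count_mode: str = "labels"

    def __post_init__(self) -> None:
        if self.band <= 0:
            raise ValidationError("flagging band must be positive")
        if self.count_mode not in ("labels", "combinations"):
            raise ValidationError(f"unknown count_mode {self.count_mode!r}")

    def validate_against(self, defs: Sequence[PhenotypeDef]) -> None:
        """Check that every qualifying phenotype exists and requires its marker."""
        by_name = {d.name: d for d in defs}
        for marker, names in self.qualifying.items():
            for name in names:
                if name not in by_name:
                    raise ValidationError(
                        f"MLE for {marker!r} references unknown phenotype {name!r}"
                    )
                if marker not in by_name[name].require_pos:
                    raise ValidationError(
                        f"phenotype {name!r} does not require {marker!r} positive, "
                        "so it cannot qualify for its MLE"
                    )


def mle_for_marker(
    gated_section: GatedSection,
    marker: str,
    config: MLEConfig | None = None,
    defs: Sequence[PhenotypeDef] | None = None,
) -> tuple[float, int, int]:
    """MLE of one marker in one gated section.

    Returns ``(mle_percent, numerator, denominator)``.  The denominator is
    the total number of marker-positive cells; when it is zero the MLE is
    undefined and returned as ``nan`` with a warning (not as 0).
    """
    config = config or MLEConfig()
    if marker not in config.qualifying:
        raise ValidationError(f"no qualifying phenotypes configured for {marker!r}")
    if marker not in gated_section.positivity.columns:
        raise ValidationError(f"marker {marker!r} not gated in this section")
    if gated_section.phenotype is None:
        raise ValidationError("section has no phenotype labels; gate a multiplex section")

    denominator = int(gated_section.positivity[marker].sum())
    if denominator == 0:
        warnings.warn(
            f"section {gated_section.meta.section_id!r}: no {marker}+ cells; "
            "MLE undefined",
            stacklevel=2,
        )
        return float("nan"), 0, 0

    names = config.qualifying[marker]
    if config.count_mode == "labels":
        counts = gated_section.phenotype.value_counts()
        numerator = int(sum(counts.get(n, 0) for n in names))
    else:
        if defs is None:
            raise ValidationError("count_mode='combinations' needs phenotype defs")
        by_name = {d.name: d for d in defs}
        numerator = 0
        for n in names:
            d = by_name[n]
            mask = np.ones(gated_section.n_cells, dtype=bool)
            for m in d.require_pos:
                mask &= gated_section.positivity[m].to_numpy()
            for m in d.require_neg:
                mask &= ~gated_section.positivity[m].to_numpy()
            numerator += int(mask.sum())
    if numerator > denominator:
        raise ValidationError(
            f"MLE numerator {numerator} exceeds denominator {denominator} for "
            f"{marker!r}: qualifying phenotypes overlap (double counting)"
        )
    return 100.0 * numerator / denominator, numerator, denominator


@dataclass
class MLEReport:
    per_section: pd.DataFrame  # section_id, specimen, run_id, marker, mle, counts
    per_run: pd.DataFrame  # specimen, run_id, marker, mean_mle
    per_marker: pd.DataFrame  # specimen, marker, median_mle, cv_mle
    flags: pd.DataFrame  # out-of-band (section, marker) rows


def mle_report(
    gated: GatedStudy,
    config: MLEConfig | None = None,
    control_specimen: str | None = None,
) -> MLEReport:
    """MLE per section and marker across a gated study, with run tracking.

    Sections whose MLE deviates from the specimen's median by more than
    ``config.band`` percentage points are flagged (with a single section no
    flag is possible — the section is its own median).  ``control_specimen``
    restricts the report to one specimen, matching the recommended practice
    of computing MLE from a positive/run control sample.
    """
    config = config or MLEConfig()
    defs = gated.study.manifest.phenotypes
    if defs:
        config.validate_against(defs)
    rows = []
    for gs in gated.multiplex_sections():
        if control_specimen is not None and gs.meta.specimen != control_specimen:
            continue
        for marker in config.qualifying:
            if marker not in gs.positivity.columns:
                continue
            value, num, den = mle_for_marker(gs, marker, config, defs)
            rows.append(
                {
                    "section_id": gs.meta.section_id,
                    "specimen": gs.meta.specimen,
                    "run_id": gs.meta.run_id,
                    "marker": marker,
                    "mle": value,
                    "numerator": num,
                    "denominator": den,
                }
            )
    per_section = pd.DataFrame(rows)
    if per_section.empty:
        empty = per_section
        return MLEReport(per_section=empty, per_run=empty, per_marker=empty, flags=empty)

    per_run = (
        per_section.groupby(["specimen", "run_id", "marker"], sort=False)["mle"]
        .mean()
        .reset_index()
        .rename(columns={"mle": "mean_mle"})
    )
    per_marker_rows = []
    flag_rows = []
    for (specimen, marker), grp in per_section.groupby(["specimen", "marker"], sort=False):
        vals = grp["mle"].to_numpy()
        median = float(np.nanmedian(vals)) if np.isfinite(vals).any() else float("nan")
        per_marker_rows.append(
            {
                "specimen": specimen,
                "marker": marker,
                "median_mle": median,
                "cv_mle": cv(vals, warn=False),
            }
        )
        if len(grp) > 1:
            out = grp[np.abs(grp["mle"] - median) > config.band]
            for _, r in out.iterrows():
                flag_rows.append(
                    {
                        "section_id": r["section_id"],
                        "specimen": specimen,
                        "run_id": r["run_id"],
                        "marker": marker,
                        "mle": r["mle"],
                        "median_mle": median,
                        "deviation": float(r["mle"] - median),
                    }
                )
    return MLEReport(
        per_section=per_section,
        per_run=per_run,
        per_marker=pd.DataFrame(per_marker_rows),
        flags=pd.DataFrame(
            flag_rows,
            columns=[
                "section_id", "specimen", "run_id", "marker",
                "mle", "median_mle", "deviation",
            ],
        ),
    )
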