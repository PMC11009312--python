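"""Marker positivity gating and phenotype assignment.

A cell is *positive* for a marker when its mean intensity exceeds a
threshold.  Two thresholding policies are supported, mirroring the two
strategies compared in panel validation work:

* **global** — one fixed threshold per marker applied to every section of
  every staining run; and
* **local** — a per-run threshold per marker, recomputed by Otsu's method
  from the pooled cell intensities of that run, which absorbs run-to-run
  multiplicative drifts in staining intensity.

Phenotypes (e.g. cytotoxic T cells = CD3e+CD8a+) are assigned from boolean
marker combinations by priority-ordered first match, so that a more
specific definition (T_reg: CD3e+CD4+FoxP3+) can shadow a broader one
(T_helper: CD3e+CD4+FoxP3-), keeping the labels mutually exclusive.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .cells_io import SectionMeta, Study
from .errors import DegenerateInputError, ValidationError

GLOBAL_SCOPE = "*"


@dataclass(frozen=True)
class PhenotypeDef:
    """A phenotype as a boolean marker combination.

    ``require_pos`` markers must all gate positive and ``require_neg``
    markers must all gate negative for a cell to match.
    """

    name: str
    require_pos: frozenset[str]
    require_neg: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if not self.require_pos:
            raise ValidationError(f"phenotype {self.name!r}: require_pos is empty")
        overlap = self.require_pos & self.require_neg
        if overlap:
            raise ValidationError(
                f"phenotype {self.name!r}: markers {sorted(overlap)} are both "
                "required positive and required negative"
            )

    @property
    def markers(self) -> frozenset[str]:
        return self.require_pos | self.require_neg


#: the murine T-cell panel phenotypes, most specific first
DEFAULT_PHENOTYPES: tuple[PhenotypeDef, ...] = (
    PhenotypeDef("T_reg", frozenset({"CD3e", "CD4", "FoxP3"})),
    PhenotypeDef("T_helper", frozenset({"CD3e", "CD4"}), frozenset({"FoxP3"})),
    PhenotypeDef("T_cyt", frozenset({"CD3e", "CD8a"})),
)

OTHER_LABEL = "other"


@dataclass
class ThresholdPolicy:
    """Marker thresholds, either one global map or one map per run.

    ``thresholds`` is keyed by ``(scope, marker)`` where scope is ``"*"``
    for global mode or a ``run_id`` for local mode.
    """

    mode: str  # "global" | "local"
    thresholds: dict[tuple[str, str], float]

    def __post_init__(self) -> None:
        if self.mode not in ("global", "local"):
            raise ValidationError(f"mode must be 'global' or 'local', got {self.mode!r}")
        for (scope, marker), value in self.thresholds.items():
            if value < 0:
                raise ValidationError(
                    f"threshold for ({scope!r}, {marker!r}) is negative: {value}"
                )

    @classmethod
    def global_policy(cls, thresholds: dict[str, float]) -> "ThresholdPolicy":
        return cls(
            mode="global",
            thresholds={(GLOBAL_SCOPE, m): t for m, t in thresholds.items()},
        )

    def scope_for(self, meta: SectionMeta) -> str:
        return GLOBAL_SCOPE if self.mode == "global" else meta.run_id

    def threshold(self, scope: str, marker: str) -> float:
        try:
            return self.thresholds[(scope, marker)]
        except KeyError:
            raise ValidationError(
                f"no threshold for scope {scope!r}, marker {marker!r}"
            ) from None


def otsu_threshold(values: Iterable[float], n_bins: int = 256) -> float:
    """Otsu's threshold on a 1-D intensity sample.

    The sample is histogrammed into ``n_bins`` equal-width bins over
    ``[min, max]`` and the returned threshold is the interior bin edge that
    maximizes the between-class variance ``w0*w1*(mu0-mu1)**2``, where class
    0 holds the values below the edge.  Class means are exact (computed from
    the values, not bin centers).  Ties are broken toward the lowest edge.

    Raises :class:`DegenerateInputError` when the sample has fewer than two
    distinct values, in which case the caller should fall back to a fixed
    threshold.
    """
    vals = np.asarray(list(values) if not isinstance(values, np.ndarray) else values,
                      dtype=float)
    if vals.size < 2 or np.all(vals == vals[0]):
        raise DegenerateInputError(
            "Otsu thresholding needs at least two distinct values"
        )
    vmin, vmax = float(vals.min()), float(vals.max())
    edges = np.linspace(vmin, vmax, n_bins + 1)
    counts, _ = np.histogram(vals, bins=edges)
    sums, _ = np.histogram(vals, bins=edges, weights=vals)

    # cumulative count/sum below each interior edge
    c0 = np.cumsum(counts)[:-1].astype(float)
    s0 = np.cumsum(sums)[:-1]
    n = float(vals.size)
    c1 = n - c0
    s1 = float(vals.sum()) - s0
    valid = (c0 > 0) & (c1 > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        bcv = (c0 / n) * (c1 / n) * (s0 / c0 - s1 / c1) ** 2
    bcv[~valid] = -np.inf
    k = int(np.argmax(bcv))  # argmax returns the first (lowest-edge) maximizer
    return float(edges[1:-1][k])


def _meaningful_markers(meta: SectionMeta, markers: Sequence[str]) -> list[str]:
    if meta.is_multiplex:
        return list(markers)
    return [meta.singleplex_marker] if meta.singleplex_marker in markers else []


def fit_local_thresholds(
    study: Study,
    n_bins: int = 256,
    fallback: dict[str, float] | None = None,
) -> ThresholdPolicy:
    """Fit one Otsu threshold per (run, marker) on the pooled run intensities.

    All cells of all sections of a run contribute to the pool (singleplex
    sections contribute only their own channel).  A degenerate channel —
    constant intensity within a run — falls back to ``fallback[marker]``
    with a warning when a fallback map is supplied, and is otherwise left
    missing so that downstream statistics for that (run, marker) are
    reported as missing.
    """
    thresholds: dict[tuple[str, str], float] = {}
    for run_id in study.manifest.run_ids:
        sections = study.sections_of_run(run_id)
        for marker in study.manifest.markers:
            pools = [
                study.tables[meta.section_id][marker].to_numpy()
                for meta in sections
                if marker in _meaningful_markers(meta, study.manifest.markers)
            ]
            if not pools:
                continue
            pooled = np.concatenate(pools)
            try:
                thresholds[(run_id, marker)] = otsu_threshold(pooled, n_bins=n_bins)
            except DegenerateInputError:
                if fallback is not None and marker in fallback:
                    warnings.warn(
                        f"run {run_id!r}, marker {marker!r}: degenerate channel; "
                        f"using fallback threshold {fallback[marker]}",
                        stacklevel=2,
                    )
                    thresholds[(run_id, marker)] = fallback[marker]
                else:
                    warnings.warn(
                        f"run {run_id!r}, marker {marker!r}: degenerate channel; "
                        "threshold marked missing",
                        stacklevel=2,
                    )
    return ThresholdPolicy(mode="local", thresholds=thresholds)


@dataclass
class GatedSection:
    """One section after gating: cells, boolean positivity, phenotype labels."""

    meta: SectionMeta
    cells: pd.DataFrame
    positivity: pd.DataFrame  # boolean, one column per gated marker
    phenotype: pd.Series | None = None  # labels, multiplex sections only
    combo_counts: dict[str, int] = field(default_factory=dict)

    @property
    def n_cells(self) -> int:
        return len(self.cells)


@dataclass
class GatedStudy:
    study: Study
    policy: ThresholdPolicy
    sections: dict[str, GatedSection]

    def iter_sections(self):
        for meta in self.study.manifest.sections:
            yield self.sections[meta.section_id]

    def multiplex_sections(self) -> list[GatedSection]:
        return [g for g in self.iter_sections() if g.meta.is_multiplex]


def apply_thresholds(study: Study, policy: ThresholdPolicy) -> GatedStudy:
    """Gate every section of a study: positive means intensity **strictly above**
    the threshold (a cell exactly at the threshold is negative).

    Singleplex sections are gated only on their own marker.  A missing
    (scope, marker) threshold raises :class:`ValidationError`.
    """
    gated: dict[str, GatedSection] = {}
    for meta, frame in study.iter_sections():
        scope = policy.scope_for(meta)
        markers = _meaningful_markers(meta, study.manifest.markers)
        pos = pd.DataFrame(index=frame.index)
        for marker in markers:
            thr = policy.threshold(scope, marker)
            pos[marker] = frame[marker].to_numpy() > thr
        gated[meta.section_id] = GatedSection(meta=meta, cells=frame, positivity=pos)
    return GatedStudy(study=study, policy=policy, sections=gated)


def _combo_label(row_pos: np.ndarray, markers: Sequence[str]) -> str:
    positives = [m for m, p in zip(markers, row_pos) if p]
    return "+".join(positives) + "+" if positives else "(none)"


def assign_phenotypes(
    positivity: pd.DataFrame, defs: Sequence[PhenotypeDef]
) -> tuple[pd.Series, dict[str, int]]:
    """Label each cell with the first matching phenotype definition.

    Definitions are tried in order; a cell matching none is labeled
    ``"other"``.  Also returns counts of every observed raw positive-marker
    combination, which surfaces unusual co-positivities (touching-cell
    artefacts) that no definition anticipates.
    """
    markers = list(positivity.columns)
    for d in defs:
        missing = [m for m in d.markers if m not in markers]
        if missing:
            raise ValidationError(
                f"phenotype {d.name!r} references ungated marker(s) {missing}"
            )
    labels = pd.Series(OTHER_LABEL, index=positivity.index, dtype=object)
    unassigned = np.ones(len(positivity), dtype=bool)
    for d in defs:
        mask = np.ones(len(positivity), dtype=bool)
        for m in d.require_pos:
            mask &= positivity[m].to_numpy()
        for m in d.require_neg:
            mask &= ~positivity[m].to_numpy()
        take = mask & unassigned
        labels.iloc[np.flatnonzero(take)] = d.name
        unassigned &= ~take

    pos_arr = positivity.to_numpy(dtype=bool)
    combos: dict[str, int] = {}
    if len(positivity):
        uniq, counts = np.unique(pos_arr, axis=0, return_counts=True)
        for row, count in zip(uniq, counts):
            combos[_combo_label(row, markers)] = int(count)
    return labels, combos


def gate_study(
    study: Study,
    policy: ThresholdPolicy,
    phenotypes: Sequence[PhenotypeDef] | None = None,
) -> GatedStudy:
    """Apply thresholds and assign phenotypes (multiplex sections only)."""
    if phenotypes is None:
        phenotypes = study.manifest.phenotypes or list(DEFAULT_PHENOTYPES)
    gated = apply_thresholds(study, policy)
    for gs in gated.iter_sections():
        if gs.meta.is_multiplex:
            gs.phenotype, gs.combo_counts = assign_phenotypes(gs.positivity, phenotypes)
    return gated
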