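"""Synthetic per-cell tables with the statistical structure of a panel
validation study.

The generator emulates what the analysis modules assume about real
segmentation exports, without modelling images themselves:

* cells as a homogeneous Poisson point pattern over a rectangular field
  (an optional parent–offspring cluster mode is available for illustrating
  asymmetric nearest-neighbor distances);
* a mutually exclusive ground-truth phenotype class per cell (multi-marker
  T-cell classes, single-marker classes, and "other"), with per-section
  multiplicative jitter on the class fractions emulating serial-section
  composition drift;
* per-marker lognormal intensity populations — a background population for
  class-negative cells and a brighter positive population — multiplied by a
  per-run, per-marker gain factor emulating staining batch effects.

Two study designs are provided: a precision design (n_runs x n_replicates
multiplex sections per specimen, serial positions shuffled so no run gets
adjacent sections) and a concordance design (five serial sections, the
third multiplex and the rest 1-plex, all sharing one staining batch).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cells_io import SectionMeta, Study, StudyManifest
from .errors import ValidationError
from .gating import DEFAULT_PHENOTYPES

DEFAULT_MARKERS: tuple[str, ...] = ("CD3e", "CD4", "CD8a", "FoxP3")

#: ground-truth classes and the markers each expresses
CLASS_MARKERS: dict[str, frozenset[str]] = {
    "T_cyt": frozenset({"CD3e", "CD8a"}),
    "T_helper": frozenset({"CD3e", "CD4"}),
    "T_reg": frozenset({"CD3e", "CD4", "FoxP3"}),
    "CD3e_only": frozenset({"CD3e"}),
    "CD4_only": frozenset({"CD4"}),
    "CD8a_only": frozenset({"CD8a"}),
    "FoxP3_only": frozenset({"FoxP3"}),
    "other": frozenset(),
}

_GAINS_STREAM = 7919  # sub-seed tag separating the gain stream from sections


@dataclass(frozen=True)
class MarkerIntensityModel:
    """Lognormal intensity populations for one marker channel.

    ``mu``/``sigma`` are the log-scale location and scale; the positive
    population must sit above background (``exp(mu_pos) > exp(mu_neg)``).
    """

    mu_pos: float
    sigma_pos: float
    mu_neg: float
    sigma_neg: float

    def __post_init__(self) -> None:
        if self.mu_pos <= self.mu_neg:
            raise ValidationError(
                "positive population must sit above background "
                f"(mu_pos={self.mu_pos} <= mu_neg={self.mu_neg})"
            )

    @property
    def median_pos(self) -> float:
        return float(np.exp(self.mu_pos))

    @property
    def median_neg(self) -> float:
        return float(np.exp(self.mu_neg))


def default_intensity_model(
    markers: Sequence[str] = DEFAULT_MARKERS,
) -> dict[str, MarkerIntensityModel]:
    """Background median 20 AU (log-scale sigma 0.12), signal median 100 AU
    (sigma 0.2).

    The two populations are well separated (as in signal/background
    histograms of validated panels) so that a within-run Otsu threshold
    lands in the gap between them, while a *fixed* midpoint threshold
    straddles the positive population once run gains drift below ~1 —
    reproducing the strong run-to-run sensitivity of global gating.
    """
    return {
        m: MarkerIntensityModel(
            mu_pos=float(np.log(100.0)),
            sigma_pos=0.2,
            mu_neg=float(np.log(20.0)),
            sigma_neg=0.12,
        )
        for m in markers
    }


@dataclass
class CompositionModel:
    """Expected cell density and ground-truth class mix for one specimen."""

    density_per_mm2: float
    class_fractions: dict[str, float]  # named classes; "other" absorbs the rest
    section_jitter_cv: float = 0.07
    spatial_mode: str = "uniform"  # "uniform" | "clustered"
    cluster_parent_per_mm2: float = 20.0
    cluster_sd_um: float = 40.0

    def __post_init__(self) -> None:
        unknown = [c for c in self.class_fractions if c not in CLASS_MARKERS]
        if unknown:
            raise ValidationError(f"unknown ground-truth class(es): {unknown}")
        if any(f < 0 for f in self.class_fractions.values()):
            raise ValidationError("class fractions must be >= 0")
        if sum(self.class_fractions.values()) > 1.0:
            raise ValidationError("class fractions sum to more than 1")
        if self.density_per_mm2 <= 0:
            raise ValidationError("density must be positive")
        if self.spatial_mode not in ("uniform", "clustered"):
            raise ValidationError(f"unknown spatial_mode {self.spatial_mode!r}")


def default_compositions() -> dict[str, CompositionModel]:
    """Three tumor models with high, medium and low T-cell density.

    The high-density model carries ~9.5% CD3e+ cells (T_cyt 4%, T_helper 3%,
    T_reg 1.5%, plus 1% CD3e-single); the medium model halves the T-cell
    classes and the low model is ten-fold sparser.
    """
    high = {
        "T_cyt": 0.04,
        "T_helper": 0.03,
        "T_reg": 0.015,
        "CD3e_only": 0.01,
        "CD4_only": 0.02,
        "CD8a_only": 0.01,
        "FoxP3_only": 0.01,
    }
    medium = {
        "T_cyt": 0.02,
        "T_helper": 0.015,
        "T_reg": 0.0075,
        "CD3e_only": 0.005,
        "CD4_only": 0.01,
        "CD8a_only": 0.005,
        "FoxP3_only": 0.015,
    }
    low = {
        "T_cyt": 0.004,
        "T_helper": 0.003,
        "T_reg": 0.0015,
        "CD3e_only": 0.001,
        "CD4_only": 0.002,
        "CD8a_only": 0.001,
        "FoxP3_only": 0.005,
    }
    return {
        "CT26": CompositionModel(density_per_mm2=2000.0, class_fractions=high),
        "4T1": CompositionModel(density_per_mm2=2000.0, class_fractions=medium),
        "B16F10": CompositionModel(density_per_mm2=2000.0, class_fractions=low),
    }


@dataclass
class BatchModel:
    """Per-run multiplicative channel gains.

    By default each run draws one gain per marker log-uniformly from
    ``[gain_low, gain_high]``; ``fixed_gains`` (run_id -> marker -> gain)
    overrides the draw, e.g. to build a gain-free reference study.
    """

    gain_low: float = 0.5
    gain_high: float = 2.0
    fixed_gains: dict[str, dict[str, float]] | None = None

    def __post_init__(self) -> None:
        if self.gain_low <= 0 or self.gain_high < self.gain_low:
            raise ValidationError("need 0 < gain_low <= gain_high")

    def gains_for_run(
        self, run_id: str, run_index: int, markers: Sequence[str], seed: int
    ) -> dict[str, float]:
        if self.fixed_gains is not None:
            g = self.fixed_gains[run_id]
            if any(v <= 0 for v in g.values()):
                raise ValidationError("gains must be positive")
            return dict(g)
        rng = np.random.default_rng(
            np.random.SeedSequence((seed, _GAINS_STREAM, run_index))
        )
        lo, hi = np.log(self.gain_low), np.log(self.gain_high)
        return {m: float(np.exp(rng.uniform(lo, hi))) for m in markers}


def unit_gains(markers: Sequence[str] = DEFAULT_MARKERS) -> dict[str, float]:
    return {m: 1.0 for m in markers}


@dataclass
class SimulationConfig:
    """Field geometry, intensity/composition/batch models and study shape."""

    field_width_um: float = 2000.0
    field_height_um: float = 2000.0
    intensity: dict[str, MarkerIntensityModel] = field(
        default_factory=default_intensity_model
    )
    composition: dict[str, CompositionModel] = field(default_factory=default_compositions)
    batch: BatchModel = field(default_factory=BatchModel)
    markers: tuple[str, ...] = DEFAULT_MARKERS
    n_runs: int = 5
    n_replicates: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_runs < 1 or self.n_replicates < 1:
            raise ValidationError("n_runs and n_replicates must be >= 1")
        if self.field_width_um <= 0 or self.field_height_um <= 0:
            raise ValidationError("field area must be positive")
        missing = [m for m in self.markers if m not in self.intensity]
        if missing:
            raise ValidationError(f"no intensity model for marker(s) {missing}")

    @property
    def area_mm2(self) -> float:
        return (self.field_width_um / 1000.0) * (self.field_height_um / 1000.0)


def midpoint_global_thresholds(
    intensity: Mapping[str, MarkerIntensityModel],
) -> dict[str, float]:
    """Fixed per-marker thresholds midway between the background and signal
    medians of the (gain-free) intensity model — the global-gating analogue
    of an operator picking one stringent cutoff from representative images."""
    return {m: (im.median_neg + im.median_pos) / 2.0 for m, im in intensity.items()}


def _jittered_fractions(
    comp: CompositionModel, rng: np.random.Generator
) -> tuple[list[str], np.ndarray]:
    names = list(comp.class_fractions)
    fracs = np.array([comp.class_fractions[c] for c in names], dtype=float)
    if comp.section_jitter_cv > 0:
        sigma = float(np.sqrt(np.log1p(comp.section_jitter_cv**2)))
        fracs = fracs * rng.lognormal(mean=0.0, sigma=sigma, size=fracs.size)
    total = fracs.sum()
    if total > 1.0:
        warnings.warn(
            "jittered class fractions sum to more than 1; renormalizing",
            stacklevel=2,
        )
        fracs = fracs / total
        total = 1.0
    names.append("other")
    return names, np.append(fracs, 1.0 - total)


def _positions(
    n: int, config: SimulationConfig, comp: CompositionModel, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    w, h = config.field_width_um, config.field_height_um
    if comp.spatial_mode == "uniform":
        return rng.uniform(0, w, n), rng.uniform(0, h, n)
    # Thomas-like clustering: Poisson parents, Gaussian offspring dispersal
    n_parents = max(1, rng.poisson(comp.cluster_parent_per_mm2 * config.area_mm2))
    px, py = rng.uniform(0, w, n_parents), rng.uniform(0, h, n_parents)
    owner = rng.integers(0, n_parents, n)
    x = np.clip(px[owner] + rng.normal(0, comp.cluster_sd_um, n), 0, w)
    y = np.clip(py[owner] + rng.normal(0, comp.cluster_sd_um, n), 0, h)
    return x, y


def simulate_section(
    config: SimulationConfig,
    meta: SectionMeta,
    gains: Mapping[str, float],
    seed_seq: np.random.SeedSequence | int,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate one section's cell table.

    Returns ``(cells, truth)`` where ``cells`` is a canonical cell frame and
    ``truth`` records the ground-truth class per cell.  Gains multiply
    intensities only, after all stochastic draws, so two sections simulated
    from the same seed with different gains carry identical positions and
    ground-truth classes and exactly proportional intensities.
    """
    missing = [m for m in config.markers if m not in gains]
    if missing:
        raise ValidationError(f"no gain supplied for marker(s) {missing}")
    comp = config.composition[meta.specimen]
    rng = np.random.default_rng(seed_seq)

    names, probs = _jittered_fractions(comp, rng)
    n = int(rng.poisson(comp.density_per_mm2 * config.area_mm2))
    x, y = _positions(n, config, comp, rng)
    classes = rng.choice(np.array(names, dtype=object), size=n, p=probs)

    own = meta.singleplex_marker
    data: dict[str, object] = {
        "cell_id": [f"{meta.section_id}-{i}" for i in range(n)],
        "section_id": [meta.section_id] * n,
        "x_um": x,
        "y_um": y,
    }
    for marker in config.markers:
        im = config.intensity[marker]
        neg = rng.lognormal(im.mu_neg, im.sigma_neg, n)
        pos = rng.lognormal(im.mu_pos, im.sigma_pos, n)
        if meta.is_multiplex or marker == own:
            expressed = np.array([marker in CLASS_MARKERS[c] for c in classes])
        else:
            expressed = np.zeros(n, dtype=bool)  # 1-plex: channel is background only
        data[marker] = np.where(expressed, pos, neg) * float(gains[marker])
    cells = pd.DataFrame(data)
    truth = pd.DataFrame(
        {
            "section_id": cells["section_id"],
            "cell_id": cells["cell_id"],
            "true_class": classes,
        }
    )
    return cells, truth


def _default_manifest(sections: list[SectionMeta], config: SimulationConfig) -> StudyManifest:
    return StudyManifest(
        sections=sections,
        markers=list(config.markers),
        phenotypes=list(DEFAULT_PHENOTYPES),
    )


def _build_study(
    config: SimulationConfig, plan: list[tuple[SectionMeta, dict[str, float]]]
) -> Study:
    specimen_index = {s: i for i, s in enumerate(config.composition)}
    tables: dict[str, pd.DataFrame] = {}
    truths = []
    for meta, gains in plan:
        seed_seq = np.random.SeedSequence(
            (config.seed, specimen_index[meta.specimen], meta.serial_index)
        )
        cells, truth = simulate_section(config, meta, gains, seed_seq)
        tables[meta.section_id] = cells
        truths.append(truth)
    manifest = _default_manifest([m for m, _ in plan], config)
    truth = (
        pd.concat(truths, ignore_index=True)
        if truths
        else pd.DataFrame(columns=["section_id", "cell_id", "true_class"])
    )
    return Study(manifest=manifest, tables=tables, truth=truth)


def simulate_precision_study(config: SimulationConfig) -> Study:
    """Simulate the precision design: ``n_runs`` staining runs with
    ``n_replicates`` serial sections each, per specimen.

    Serial positions are shuffled across runs so no run receives adjacent
    sections: run ``r`` (1-based) gets serial positions ``r, r + n_runs,
    r + 2*n_runs, ...``.  Every section of a run shares that run's gain
    vector; each section draws its own composition jitter.
    """
    plan: list[tuple[SectionMeta, dict[str, float]]] = []
    for r in range(1, config.n_runs + 1):
        run_id = str(r)
        gains = config.batch.gains_for_run(run_id, r, config.markers, config.seed)
        for k in range(config.n_replicates):
            serial = r + k * config.n_runs
            for specimen in config.composition:
                meta = SectionMeta(
                    section_id=f"{specimen}_s{serial:02d}",
                    specimen=specimen,
                    serial_index=serial,
                    run_id=run_id,
                    replicate_index=k + 1,
                    assay="multiplex",
                )
                plan.append((meta, gains))
    return _build_study(config, plan)


def simulate_concordance_study(
    config: SimulationConfig,
    singleplex_markers: Sequence[str] | None = None,
) -> Study:
    """Simulate the concordance design: five serial sections per specimen,
    the third labeled with the full multiplex panel and the remaining four
    with 1-plex assays, all sections sharing a single staining batch (one
    gain vector).

    ``singleplex_markers`` assigns the 1-plex markers of serial sections
    1, 2, 4, 5 in order; the default is one section per panel marker in
    manifest order.  Repeating one marker (e.g. four CD3e 1-plex sections)
    yields several serial-section comparisons for that marker.
    """
    if singleplex_markers is None:
        singleplex_markers = list(config.markers)
    if len(singleplex_markers) != 4:
        raise ValidationError(
            "the concordance design has four 1-plex sections; "
            f"got {len(singleplex_markers)} singleplex markers"
        )
    unknown = [m for m in singleplex_markers if m not in config.markers]
    if unknown:
        raise ValidationError(f"singleplex marker(s) not in panel: {unknown}")
    gains = config.batch.gains_for_run("1", 1, config.markers, config.seed)
    singleplex_serials = [1, 2, 4, 5]
    plan: list[tuple[SectionMeta, dict[str, float]]] = []
    for specimen in config.composition:
        for serial in range(1, 6):
            if serial == 3:
                assay = "multiplex"
            else:
                marker = singleplex_markers[singleplex_serials.index(serial)]
                assay = f"singleplex:{marker}"
            meta = SectionMeta(
                section_id=f"{specimen}_s{serial:02d}",
                specimen=specimen,
                serial_index=serial,
                run_id="1",
                replicate_index=serial,
                assay=assay,
            )
            plan.append((meta, gains))
    return _build_study(config, plan)


def single_specimen_config(
    specimen: str = "CT26", **overrides
) -> SimulationConfig:
    """A config restricted to one specimen (convenience for focused studies)."""
    comps = default_compositions()
    if specimen not in comps:
        raise ValidationError(f"unknown specimen {specimen!r}")
    cfg = SimulationConfig(composition={specimen: comps[specimen]}, **overrides)
    return cfg


def with_unit_gains(config: SimulationConfig) -> SimulationConfig:
    """The same study conditions with every run's gains pinned to 1 —
    the gain-free reference used in invariance tests."""
    fixed = {str(r): unit_gains(config.markers) for r in range(1, config.n_runs + 1)}
    return replace(config, batch=BatchModel(fixed_gains=fixed))
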