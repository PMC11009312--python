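import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from mifqc.errors import DegenerateInputError, ValidationError
from mifqc.gating import (
    PhenotypeDef,
    ThresholdPolicy,
    apply_thresholds,
    assign_phenotypes,
    fit_local_thresholds,
    gate_study,
    otsu_threshold,
)
from mifqc.synthetic_tissue import (
    DEFAULT_MARKERS,
    simulate_precision_study,
    simulate_section,
    single_specimen_config,
    unit_gains,
    with_unit_gains,
)
from helpers import make_cells, make_section_study


def brute_force_otsu(values: np.ndarray, n_bins: int = 256) -> float:
    """Independent oracle: try every interior bin edge, split the raw values
    there, and compute the between-class variance directly."""
    vmin, vmax = values.min(), values.max()
    edges = np.linspace(vmin, vmax, n_bins + 1)[1:-1]
    best_edge, best_bcv = None, -np.inf
    n = len(values)
    for e in edges:
        lo = values[values < e]
        hi = values[values >= e]
        if len(lo) == 0 or len(hi) == 0:
            continue
        bcv = (len(lo) / n) * (len(hi) / n) * (lo.mean() - hi.mean()) ** 2
        if bcv > best_bcv:  # strict: ties keep the lowest edge
            best_bcv, best_edge = bcv, e
    return best_edge


def test_otsu_separates_perfect_bimodal_sample():
    values = np.array([1.0] * 50 + [10.0] * 50)
    t = otsu_threshold(values)
    assert 1.0 < t <= 10.0
    assert (values > t).sum() == 50  # exactly the high group exceeds it


@pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
def test_otsu_equals_brute_force_search(seed):
    rng = np.random.default_rng(seed)
    values = np.concatenate(
        [rng.lognormal(3.0, 0.12, 4500), rng.lognormal(4.6, 0.2, 500)]
    )
    assert otsu_threshold(values) == pytest.approx(brute_force_otsu(values), rel=1e-12)


def test_otsu_close_to_skimage_reference():
    """Cross-check against an independent implementation: agreement within
    one bin width (conventions differ at the returned edge)."""
    from skimage.filters import threshold_otsu

    rng = np.random.default_rng(7)
    values = np.concatenate(
        [rng.lognormal(3.0, 0.12, 9000), rng.lognormal(4.6, 0.2, 1000)]
    )
    bin_width = (values.max() - values.min()) / 256
    assert abs(otsu_threshold(values) - threshold_otsu(values, nbins=256)) <= bin_width


def test_otsu_scale_equivariance():
    rng = np.random.default_rng(1)
    values = np.concatenate([rng.lognormal(3.0, 0.12, 2000), rng.lognormal(4.6, 0.2, 200)])
    t = otsu_threshold(values)
    t2 = otsu_threshold(values * 2.0)
    assert t2 == pytest.approx(2.0 * t, rel=1e-12)
    assert np.array_equal(values > t, values * 2.0 > t2)


def test_otsu_degenerate_input_raises():
    with pytest.raises(DegenerateInputError):
        otsu_threshold(np.full(100, 3.0))
    with pytest.raises(DegenerateInputError):
        otsu_threshold([1.0])


def test_local_thresholds_track_run_gains():
    """Two runs holding the same cells at gains 1 vs 2 get thresholds in
    exactly that ratio, and identical positivity labels."""
    cfg = single_specimen_config("CT26", seed=5, field_width_um=1000.0,
                                 field_height_um=1000.0)
    from mifqc.cells_io import SectionMeta, Study, StudyManifest
    from mifqc.gating import DEFAULT_PHENOTYPES

    metas, tables = [], {}
    for run_id, gain in (("1", 1.0), ("2", 2.0)):
        meta = SectionMeta(
            section_id=f"r{run_id}", specimen="CT26", serial_index=int(run_id),
            run_id=run_id, replicate_index=1, assay="multiplex",
        )
        cells, _ = simulate_section(cfg, meta, {m: gain for m in DEFAULT_MARKERS}, 42)
        metas.append(meta)
        tables[meta.section_id] = cells
    study = Study(
        manifest=StudyManifest(sections=metas, markers=list(DEFAULT_MARKERS),
                               phenotypes=list(DEFAULT_PHENOTYPES)),
        tables=tables,
    )
    policy = fit_local_thresholds(study)
    for m in DEFAULT_MARKERS:
        assert policy.threshold("2", m) == pytest.approx(
            2.0 * policy.threshold("1", m), rel=1e-12
        )
    gated = apply_thresholds(study, policy)
    assert np.array_equal(
        gated.sections["r1"].positivity.to_numpy(),
        gated.sections["r2"].positivity.to_numpy(),
    )


def test_local_gating_labels_invariant_under_run_gains(
    precision_study, precision_study_unit_gains
):
    """Per-run Otsu gating of the gain-perturbed study reproduces the
    gain-free study's positivity labels bit for bit."""
    ga = gate_study(precision_study, fit_local_thresholds(precision_study))
    gb = gate_study(
        precision_study_unit_gains, fit_local_thresholds(precision_study_unit_gains)
    )
    for sid in ga.sections:
        assert np.array_equal(
            ga.sections[sid].positivity.to_numpy(),
            gb.sections[sid].positivity.to_numpy(),
        )


def test_cell_at_threshold_is_negative():
    frame = make_cells(DEFAULT_MARKERS, [dict.fromkeys(DEFAULT_MARKERS, 50.0)])
    study = make_section_study(frame)
    gated = apply_thresholds(
        study, ThresholdPolicy.global_policy(dict.fromkeys(DEFAULT_MARKERS, 50.0))
    )
    assert not gated.sections["s1"].positivity.to_numpy().any()


def test_zero_thresholds_make_every_cell_positive(precision_study):
    policy = ThresholdPolicy.global_policy(dict.fromkeys(DEFAULT_MARKERS, 0.0))
    gated = apply_thresholds(precision_study, policy)
    for gs in gated.iter_sections():
        assert gs.positivity.to_numpy().all()


def test_raising_threshold_never_increases_positive_count(precision_study):
    low = ThresholdPolicy.global_policy(dict.fromkeys(DEFAULT_MARKERS, 40.0))
    high = ThresholdPolicy.global_policy(dict.fromkeys(DEFAULT_MARKERS, 60.0))
    ga, gb = apply_thresholds(precision_study, low), apply_thresholds(precision_study, high)
    for sid in ga.sections:
        assert (
            gb.sections[sid].positivity.sum().to_numpy()
            <= ga.sections[sid].positivity.sum().to_numpy()
        ).all()


def test_missing_threshold_names_scope_and_marker(precision_study):
    policy = ThresholdPolicy(mode="local", thresholds={("1", "CD3e"): 10.0})
    with pytest.raises(ValidationError, match=r"('1'|scope).*CD4|CD4.*'1'"):
        apply_thresholds(precision_study, policy)


@pytest.mark.parametrize(
    "positive,expected",
    [
        ({"CD3e", "CD4", "FoxP3"}, "T_reg"),
        ({"CD3e", "CD4"}, "T_helper"),
        ({"CD3e", "CD8a"}, "T_cyt"),
        ({"CD3e"}, "other"),
        (set(), "other"),
    ],
)
def test_phenotype_priority_assignment(positive, expected):
    pos = pd.DataFrame({m: [m in positive] for m in DEFAULT_MARKERS})
    from mifqc.gating import DEFAULT_PHENOTYPES

    labels, combos = assign_phenotypes(pos, DEFAULT_PHENOTYPES)
    assert labels.iloc[0] == expected
    assert sum(combos.values()) == 1


def test_phenotype_labels_partition_cells(gated_global):
    for gs in gated_global.multiplex_sections():
        assert gs.phenotype.notna().all()
        assert gs.phenotype.value_counts().sum() == gs.n_cells
        assert sum(gs.combo_counts.values()) == gs.n_cells


def test_unusual_combination_surfaces_in_combo_counts():
    rows = [
        {"CD3e": 100.0, "CD4": 1.0, "CD8a": 1.0, "FoxP3": 100.0},  # odd: CD3e+FoxP3+
        {"CD3e": 1.0, "CD4": 1.0, "CD8a": 1.0, "FoxP3": 1.0},
    ]
    study = make_section_study(make_cells(DEFAULT_MARKERS, rows))
    gated = gate_study(
        study, ThresholdPolicy.global_policy(dict.fromkeys(DEFAULT_MARKERS, 50.0))
    )
    gs = gated.sections["s1"]
    assert gs.phenotype.iloc[0] == "other"
    assert gs.combo_counts.get("CD3e+FoxP3+") == 1
    assert gs.combo_counts.get("(none)") == 1


def test_phenotype_def_validation():
    with pytest.raises(ValidationError):
        PhenotypeDef("bad", frozenset(), frozenset())
    with pytest.raises(ValidationError):
        PhenotypeDef("bad", frozenset({"CD4"}), frozenset({"CD4"}))


@given(st.floats(min_value=0.01, max_value=100.0))
def test_policy_scale_with_positive_thresholds_valid(value):
    ThresholdPolicy.global_policy({"CD3e": value})


def test_negative_threshold_rejected():
    with pytest.raises(ValidationError):
        ThresholdPolicy.global_policy({"CD3e": -1.0})
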