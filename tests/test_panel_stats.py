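import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from helpers import make_cells, make_multi_section_study, make_section_study
from mifqc.cells_io import SectionMeta
from mifqc.errors import ValidationError
from mifqc.gating import ThresholdPolicy, fit_local_thresholds, gate_study
from mifqc.panel_stats import (
    concordance_report,
    cv,
    intensity_histograms,
    precision_report,
    relative_difference,
    section_summaries,
)
from mifqc.synthetic_tissue import (
    DEFAULT_MARKERS,
    midpoint_global_thresholds,
    simulate_precision_study,
    single_specimen_config,
)


# ---------------------------------------------------------------------------
# cv


def test_cv_zero_for_constant_values():
    assert cv([5, 5, 5]) == 0.0


def test_cv_matches_hand_formula():
    # sd([2,4]) = sqrt(2), mean 3 -> 47.1405%
    assert cv([2, 4]) == pytest.approx(100 * np.sqrt(2) / 3, abs=1e-9)


@given(
    st.lists(st.floats(min_value=0.1, max_value=1e3), min_size=2, max_size=20),
    st.floats(min_value=0.01, max_value=100.0),
)
def test_cv_scale_invariance(values, c):
    assert cv(np.array(values) * c, warn=False) == pytest.approx(
        cv(values, warn=False), rel=1e-6
    )


def test_cv_undefined_cases_warn_and_return_nan():
    with pytest.warns(UserWarning):
        assert np.isnan(cv([3.0]))
    with pytest.warns(UserWarning):
        assert np.isnan(cv([-1.0, 1.0]))


# ---------------------------------------------------------------------------
# relative difference


def test_relative_difference_examples():
    assert relative_difference(10.0, 10.0) == 0.0
    assert relative_difference(12.0, 10.0) == pytest.approx(200.0 / 11.0)  # 18.1818%
    assert relative_difference(0.0, 0.0) == 0.0


@given(
    st.floats(min_value=0.0, max_value=1e3), st.floats(min_value=0.001, max_value=1e3)
)
def test_relative_difference_antisymmetry(a, b):
    assert relative_difference(a, b) == pytest.approx(-relative_difference(b, a))


def test_relative_difference_rejects_negative():
    with pytest.raises(ValidationError):
        relative_difference(-1.0, 2.0)


# ---------------------------------------------------------------------------
# section summaries


def test_section_summary_percentage_arithmetic():
    rows = [dict.fromkeys(DEFAULT_MARKERS, 100.0)] * 94 + [
        dict.fromkeys(DEFAULT_MARKERS, 1.0)
    ] * 906
    study = make_section_study(make_cells(DEFAULT_MARKERS, rows))
    gated = gate_study(
        study, ThresholdPolicy.global_policy(dict.fromkeys(DEFAULT_MARKERS, 50.0))
    )
    summ = section_summaries(gated)
    cd3 = summ[(summ.entity == "CD3e") & (summ.kind == "marker")].iloc[0]
    assert cd3["pct_positive"] == pytest.approx(9.4)
    assert cd3["n_total"] == 1000
    assert cd3["mean_intensity_positive"] == pytest.approx(100.0)
    assert cd3["mean_intensity_negative"] == pytest.approx(1.0)


def test_section_summary_zero_positive_has_missing_intensity():
    rows = [dict.fromkeys(DEFAULT_MARKERS, 1.0)] * 10
    study = make_section_study(make_cells(DEFAULT_MARKERS, rows))
    gated = gate_study(
        study, ThresholdPolicy.global_policy(dict.fromkeys(DEFAULT_MARKERS, 50.0))
    )
    row = section_summaries(gated).iloc[0]
    assert row["pct_positive"] == 0.0
    assert np.isnan(row["mean_intensity_positive"])


def test_local_gating_recovers_ground_truth_fraction():
    """% positive after per-run Otsu gating matches the section's realized
    ground-truth marker fraction within 3 binomial SE."""
    cfg = single_specimen_config("CT26", seed=11)
    cfg.composition["CT26"].section_jitter_cv = 0.0
    study = simulate_precision_study(cfg)
    gated = gate_study(study, fit_local_thresholds(study))
    summ = section_summaries(gated)
    truth = study.truth
    cd3_classes = {"T_cyt", "T_helper", "T_reg", "CD3e_only"}
    for _, row in summ[(summ.kind == "marker") & (summ.entity == "CD3e")].iterrows():
        t = truth[truth.section_id == row.section_id]
        f = t["true_class"].isin(cd3_classes).mean()
        se = np.sqrt(f * (1 - f) / row.n_total)
        assert abs(row.pct_positive / 100 - f) < 3 * se


# ---------------------------------------------------------------------------
# concordance


def _paired_assay_study(extra_marker_value=None):
    """One multiplex section and a CD3e 1-plex section with identical cells."""
    rng = np.random.default_rng(3)
    rows = [dict.fromkeys(DEFAULT_MARKERS, 100.0)] * 80 + [
        dict.fromkeys(DEFAULT_MARKERS, 1.0)
    ] * 920
    f4 = make_cells(DEFAULT_MARKERS, rows, section_id="m", rng=rng)
    f1 = f4.copy()
    f1["section_id"] = "s"
    f1["cell_id"] = [c.replace("m-", "s-") for c in f4["cell_id"]]
    metas = [
        SectionMeta("m", "spec", 3, "1", 1, "multiplex"),
        SectionMeta("s", "spec", 1, "1", 2, "singleplex:CD3e"),
    ]
    return make_multi_section_study({"m": f4, "s": f1}, metas)


def test_concordance_identical_sections_have_zero_rel_diff():
    study = _paired_assay_study()
    gated = gate_study(
        study, ThresholdPolicy.global_policy(dict.fromkeys(DEFAULT_MARKERS, 50.0))
    )
    with pytest.warns(UserWarning):  # other markers have no 1-plex section
        rep = concordance_report(gated)
    assert len(rep) == 1
    assert rep.iloc[0]["rel_diff_pct"] == 0.0
    assert rep.iloc[0]["rel_diff_int"] == 0.0
    assert not rep.iloc[0]["flag_out_of_band"]


def test_concordance_low_abundance_flagging():
    rng = np.random.default_rng(4)
    rows = [dict.fromkeys(DEFAULT_MARKERS, 100.0)] * 3 + [
        dict.fromkeys(DEFAULT_MARKERS, 1.0)
    ] * 997
    f4 = make_cells(DEFAULT_MARKERS, rows, section_id="m", rng=rng)
    f1 = f4.copy()
    f1["section_id"] = "s"
    f1["cell_id"] = [c.replace("m-", "s-") for c in f4["cell_id"]]
    metas = [
        SectionMeta("m", "spec", 3, "1", 1, "multiplex"),
        SectionMeta("s", "spec", 1, "1", 2, "singleplex:CD3e"),
    ]
    study = make_multi_section_study({"m": f4, "s": f1}, metas)
    gated = gate_study(
        study, ThresholdPolicy.global_policy(dict.fromkeys(DEFAULT_MARKERS, 50.0))
    )
    with pytest.warns(UserWarning):
        rep = concordance_report(gated)
    assert rep.iloc[0]["flag_low_abundance"]


# ---------------------------------------------------------------------------
# precision


def _replicated_study(values_by_run):
    """Sections whose CD3e-positive count is set exactly per (run, replicate)."""
    metas, frames = [], {}
    serial = 1
    for run_id, counts in values_by_run.items():
        for rep_i, n_pos in enumerate(counts, start=1):
            sid = f"r{run_id}x{rep_i}"
            rows = [dict.fromkeys(DEFAULT_MARKERS, 100.0)] * n_pos + [
                dict.fromkeys(DEFAULT_MARKERS, 1.0)
            ] * (1000 - n_pos)
            frames[sid] = make_cells(DEFAULT_MARKERS, rows, section_id=sid)
            metas.append(SectionMeta(sid, "spec", serial, run_id, rep_i, "multiplex"))
            serial += 1
    return make_multi_section_study(frames, metas)


def test_intra_run_cv_zero_for_identical_replicates():
    study = _replicated_study({"1": [50, 50, 50], "2": [80, 80, 80]})
    gated = gate_study(
        study, ThresholdPolicy.global_policy(dict.fromkeys(DEFAULT_MARKERS, 50.0))
    )
    rep = precision_report(gated)
    cd3 = rep.intra[rep.intra.entity == "CD3e"]
    assert (cd3["intra_run_cv"] == 0.0).all()


def test_inter_run_cv_equals_cv_of_pooled_sections():
    study = _replicated_study({"1": [40, 50, 60], "2": [80, 90, 100]})
    gated = gate_study(
        study, ThresholdPolicy.global_policy(dict.fromkeys(DEFAULT_MARKERS, 50.0))
    )
    rep = precision_report(gated)
    summ = section_summaries(gated)
    pooled = summ[(summ.kind == "marker") & (summ.entity == "CD3e")]["pct_positive"]
    expected = cv(pooled, warn=False)
    got = rep.summary[rep.summary.entity == "CD3e"]["inter_run_cv"].iloc[0]
    assert got == pytest.approx(expected, rel=1e-12)


def test_single_replicate_runs_have_missing_intra_cv():
    study = _replicated_study({"1": [50], "2": [80]})
    gated = gate_study(
        study, ThresholdPolicy.global_policy(dict.fromkeys(DEFAULT_MARKERS, 50.0))
    )
    rep = precision_report(gated)
    assert rep.intra["intra_run_cv"].isna().all()
    cd3e = rep.summary[rep.summary.entity == "CD3e"]["inter_run_cv"]
    assert np.isfinite(cd3e).all()


def test_local_gating_reduces_inter_run_cv_without_hurting_intra(
    precision_study, gated_global
):
    """On gain-perturbed runs, per-run Otsu regating drives the inter-run CV
    below the global-gating value for every T-cell phenotype, while intra-run
    CVs stay comparable."""
    gated_local = gate_study(precision_study, fit_local_thresholds(precision_study))
    rep_g = precision_report(gated_global).summary.set_index("entity")
    rep_l = precision_report(gated_local).summary.set_index("entity")
    for pheno in ("T_cyt", "T_helper", "T_reg"):
        assert rep_l.loc[pheno, "inter_run_cv"] < rep_g.loc[pheno, "inter_run_cv"]
    med_intra_g = np.nanmedian(rep_g["intra_run_cv_mean"])
    med_intra_l = np.nanmedian(rep_l["intra_run_cv_mean"])
    assert med_intra_l < 2 * med_intra_g + 5


# ---------------------------------------------------------------------------
# histograms


def test_intensity_histograms_normalized_and_separated(gated_global):
    gs = next(iter(gated_global.multiplex_sections()))
    h = intensity_histograms(gs, "CD3e")
    assert h["positive"].sum() == pytest.approx(1.0)
    assert h["negative"].sum() == pytest.approx(1.0)
    assert h["overlap"] < 0.05  # well-separated signal and background


def test_intensity_histograms_all_positive_leaves_negative_empty():
    rows = [dict.fromkeys(DEFAULT_MARKERS, 100.0)] * 20
    study = make_section_study(make_cells(DEFAULT_MARKERS, rows))
    gated = gate_study(
        study, ThresholdPolicy.global_policy(dict.fromkeys(DEFAULT_MARKERS, 50.0))
    )
    h = intensity_histograms(gated.sections["s1"], "CD3e")
    assert h["n_neg"] == 0
    assert h["negative"].sum() == 0.0
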