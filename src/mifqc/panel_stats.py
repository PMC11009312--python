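"""Concordance and precision statistics on gated studies.

Concordance (accuracy) compares the % positive cells and the mean
intensity/cell of each marker between a multiplex section and the 1-plex
serial section labeled for that marker alone, summarised as symmetric
Bland-Altman relative differences.  Precision summarises reproducibility of
% positive cells as coefficients of variation: intra-run CV over the
replicate sections of one staining run, and inter-run CV over all sections
of all runs pooled.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError
from .gating import GatedSection, GatedStudy

#: working CV cutoff used to annotate reproducibility reports (%)
DEFAULT_CV_CUTOFF = 25.0
#: annotation band for concordance relative differences (%)
DEFAULT_REL_DIFF_BAND = 20.0
#: below this many positive cells per section an estimate is flagged
#: as low-abundance (high sampling variance expected)
DEFAULT_LOW_ABUNDANCE_FLOOR = 50


def cv(values, warn: bool = True) -> float:
    """Coefficient of variation in percent: ``100 * sd / mean`` with the
    sample (n-1) standard deviation.

    Returns ``nan`` (undefined) when fewer than two finite values are given
    or the mean is zero.
    """
    arr = np.asarray(values, dtype=float)
    arr = arr[np.isfinite(arr)]
    if arr.size < 2:
        if warn:
            warnings.warn("cv undefined for fewer than two values", stacklevel=2)
        return float("nan")
    mean = arr.mean()
    if mean == 0:
        if warn:
            warnings.warn("cv undefined for zero mean", stacklevel=2)
        return float("nan")
    return float(100.0 * arr.std(ddof=1) / mean)


def relative_difference(a: float, b: float, denominator: str = "mean") -> float:
    """Bland-Altman relative difference in percent between two paired
    measurements ``a`` (multiplex) and ``b`` (1-plex).

    With the default symmetric convention the denominator is the mean of
    the pair: ``100 * (a - b) / ((a + b) / 2)``; ``denominator="b"``
    divides by the 1-plex value instead.  Both inputs must be nonnegative;
    ``a == b == 0`` returns 0 by convention.
    """
    if a < 0 or b < 0:
        raise ValidationError(f"relative_difference needs nonnegative inputs, got {a}, {b}")
    if a == 0 and b == 0:
        return 0.0
    if denominator == "mean":
        return float(100.0 * (a - b) / ((a + b) / 2.0))
    if denominator == "b":
        if b == 0:
            return float("nan")
        return float(100.0 * (a - b) / b)
    raise ValueError(f"unknown denominator convention {denominator!r}")


def section_summaries(gated: GatedStudy) -> pd.DataFrame:
    """Per-section counts and percentages for every marker and phenotype.

    Returns a long-format frame with one row per (section, entity), where
    an entity is a gated marker or an assigned phenotype.  ``pct_positive``
    is ``100 * n_positive / n_total`` (``nan`` for an empty section);
    intensity means are computed separately over positive and negative
    cells and are reported for markers only.
    """
    rows = []
    for gs in gated.iter_sections():
        meta = gs.meta
        n_total = gs.n_cells
        base = {
            "section_id": meta.section_id,
            "specimen": meta.specimen,
            "run_id": meta.run_id,
            "replicate_index": meta.replicate_index,
            "serial_index": meta.serial_index,
            "assay": meta.assay,
            "n_total": n_total,
        }
        for marker in gs.positivity.columns:
            pos = gs.positivity[marker].to_numpy()
            n_pos = int(pos.sum())
            intens = gs.cells[marker].to_numpy()
            rows.append(
                base
                | {
                    "entity": marker,
                    "kind": "marker",
                    "n_positive": n_pos,
                    "pct_positive": 100.0 * n_pos / n_total if n_total else np.nan,
                    "mean_intensity_positive": float(intens[pos].mean())
                    if n_pos
                    else np.nan,
                    "mean_intensity_negative": float(intens[~pos].mean())
                    if n_pos < n_total
                    else np.nan,
                }
            )
        if gs.phenotype is not None:
            counts = gs.phenotype.value_counts()
            names = [
                p.name
                for p in (gated.study.manifest.phenotypes or [])
            ] or [str(k) for k in counts.index]
            for name in names:
                n_pos = int(counts.get(name, 0))
                rows.append(
                    base
                    | {
                        "entity": name,
                        "kind": "phenotype",
                        "n_positive": n_pos,
                        "pct_positive": 100.0 * n_pos / n_total if n_total else np.nan,
                        "mean_intensity_positive": np.nan,
                        "mean_intensity_negative": np.nan,
                    }
                )
    return pd.DataFrame(rows)


def intensity_histograms(
    gated_section: GatedSection, marker: str, n_bins: int = 64
) -> dict:
    """Paired normalized intensity histograms of positive and negative cells
    for one marker over a shared bin grid.

    Each histogram sums to 1 when its class is non-empty.  Returns a dict
    with ``edges``, ``positive``, ``negative``, counts, and an ``overlap``
    coefficient (sum of bin-wise minima; near 0 for well-separated
    signal/background populations).
    """
    if marker not in gated_section.positivity.columns:
        raise ValidationError(f"marker {marker!r} not gated in this section")
    pos_mask = gated_section.positivity[marker].to_numpy()
    intens = gated_section.cells[marker].to_numpy(dtype=float)
    edges = np.histogram_bin_edges(intens, bins=n_bins)
    out = {"edges": edges, "n_pos": int(pos_mask.sum()), "n_neg": int((~pos_mask).sum())}
    for key, mask in (("positive", pos_mask), ("negative", ~pos_mask)):
        h, _ = np.histogram(intens[mask], bins=edges)
        total = h.sum()
        out[key] = h / total if total else h.astype(float)
    out["overlap"] = float(np.minimum(out["positive"], out["negative"]).sum())
    if out["n_pos"] == 0:
        warnings.warn(f"no positive cells for {marker!r}; positive histogram empty",
                      stacklevel=2)
    return out


def concordance_report(
    gated: GatedStudy,
    band: float = DEFAULT_REL_DIFF_BAND,
    low_abundance_floor: int = DEFAULT_LOW_ABUNDANCE_FLOOR,
    denominator: str = "mean",
) -> pd.DataFrame:
    """Pair each marker's 1-plex summary with the multiplex summary.

    One row per (specimen, marker, 1-plex section): % positive cells and
    mean positive-cell intensity in both assays with their relative
    differences, an out-of-band flag (|rel diff| above ``band``), and a
    low-abundance flag when either assay counted fewer positives than
    ``low_abundance_floor`` (such markers are expected to show high
    serial-section variance).  In the standard design each marker has one
    1-plex section and hence one row.
    """
    summaries = section_summaries(gated)
    markers = summaries[summaries["kind"] == "marker"]
    rows = []
    for specimen, spec_rows in markers.groupby("specimen", sort=False):
        multi = spec_rows[spec_rows["assay"] == "multiplex"]
        if multi.empty:
            raise ValidationError(f"specimen {specimen!r} has no multiplex section")
        for marker in gated.study.manifest.markers:
            m4 = multi[multi["entity"] == marker]
            m1_all = spec_rows[
                (spec_rows["assay"] == f"singleplex:{marker}")
                & (spec_rows["entity"] == marker)
            ]
            if m1_all.empty:
                warnings.warn(
                    f"specimen {specimen!r}: no 1-plex section for {marker!r}; skipped",
                    stacklevel=2,
                )
                continue
            for _, m1 in m1_all.iterrows():
                p4 = float(m4["pct_positive"].iloc[0])
                p1 = float(m1["pct_positive"])
                i4 = float(m4["mean_intensity_positive"].iloc[0])
                i1 = float(m1["mean_intensity_positive"])
                rel_pct = relative_difference(p4, p1, denominator=denominator)
                rel_int = (
                    relative_difference(i4, i1, denominator=denominator)
                    if np.isfinite(i4) and np.isfinite(i1)
                    else np.nan
                )
                n_pos_min = int(min(m4["n_positive"].iloc[0], m1["n_positive"]))
                rows.append(
                    {
                        "specimen": specimen,
                        "marker": marker,
                        "section_id_1plex": str(m1["section_id"]),
                        "pct_positive_1plex": p1,
                        "pct_positive_4plex": p4,
                        "rel_diff_pct": rel_pct,
                        "mean_int_1plex": i1,
                        "mean_int_4plex": i4,
                        "rel_diff_int": rel_int,
                        "n_positive_min": n_pos_min,
                        "flag_out_of_band": bool(abs(rel_pct) > band),
                        "flag_low_abundance": bool(n_pos_min < low_abundance_floor),
                    }
                )
    return pd.DataFrame(rows)


@dataclass
class PrecisionReport:
    """Intra-run CVs (one row per specimen/entity/run) and the per-entity
    summary (pooled intra-run CV and inter-run CV over all sections)."""

    intra: pd.DataFrame
    summary: pd.DataFrame


def precision_report(
    gated: GatedStudy,
    cv_cutoff: float = DEFAULT_CV_CUTOFF,
    low_abundance_floor: int = DEFAULT_LOW_ABUNDANCE_FLOOR,
) -> PrecisionReport:
    """Reproducibility of % positive cells per specimen and entity.

    Intra-run CV is computed over the replicate sections within each run
    (missing for single-replicate runs); the pooled intra-run CV is the mean
    of the per-run values.  Inter-run CV is the CV over **all** sections of
    all runs, so it captures both within- and between-run dispersion.
    """
    summaries = section_summaries(gated)
    summaries = summaries[summaries["assay"] == "multiplex"]
    intra_rows, summary_rows = [], []
    for (specimen, entity), grp in summaries.groupby(["specimen", "entity"], sort=False):
        kind = grp["kind"].iloc[0]
        run_cvs = []
        for run_id, run_grp in grp.groupby("run_id", sort=False):
            vals = run_grp["pct_positive"].to_numpy()
            run_cv = cv(vals, warn=False) if len(vals) >= 2 else np.nan
            run_cvs.append(run_cv)
            intra_rows.append(
                {
                    "specimen": specimen,
                    "entity": entity,
                    "kind": kind,
                    "run_id": run_id,
                    "n_sections": len(vals),
                    "intra_run_cv": run_cv,
                }
            )
        all_vals = grp["pct_positive"].to_numpy()
        inter = cv(all_vals, warn=False)
        finite = [c for c in run_cvs if np.isfinite(c)]
        min_pos = int(grp["n_positive"].min())
        summary_rows.append(
            {
                "specimen": specimen,
                "entity": entity,
                "kind": kind,
                "n_sections": len(all_vals),
                "intra_run_cv_mean": float(np.mean(finite)) if finite else np.nan,
                "inter_run_cv": inter,
                "flag_low_abundance": bool(min_pos < low_abundance_floor),
                "flag_inter_above_cutoff": bool(
                    np.isfinite(inter) and inter > cv_cutoff
                ),
            }
        )
    return PrecisionReport(
        intra=pd.DataFrame(intra_rows), summary=pd.DataFrame(summary_rows)
    )
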