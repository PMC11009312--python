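"""Hand-built study construction helpers shared across test modules."""

import numpy as np
import pandas as pd

from mifqc.cells_io import SectionMeta, Study, StudyManifest
from mifqc.gating import DEFAULT_PHENOTYPES
from mifqc.synthetic_tissue import DEFAULT_MARKERS


def make_section_study(frame: pd.DataFrame, markers=DEFAULT_MARKERS, assay="multiplex"):
    """Wrap a single hand-built cell frame into a one-section Study."""
    sid = str(frame["section_id"].iloc[0]) if len(frame) else "s1"
    meta = SectionMeta(
        section_id=sid,
        specimen="spec",
        serial_index=1,
        run_id="1",
        replicate_index=1,
        assay=assay,
    )
    manifest = StudyManifest(
        sections=[meta], markers=list(markers), phenotypes=list(DEFAULT_PHENOTYPES)
    )
    return Study(manifest=manifest, tables={sid: frame})


def make_cells(markers, intensity_rows, section_id="s1", rng=None):
    """Build a canonical cell frame from a list of per-marker intensity dicts."""
    rng = rng or np.random.default_rng(0)
    n = len(intensity_rows)
    data = {
        "cell_id": [f"{section_id}-{i}" for i in range(n)],
        "section_id": [section_id] * n,
        "x_um": rng.uniform(0, 1000, n),
        "y_um": rng.uniform(0, 1000, n),
    }
    for m in markers:
        data[m] = [float(row[m]) for row in intensity_rows]
    return pd.DataFrame(data)


def make_multi_section_study(frames: dict, metas: list[SectionMeta]):
    manifest = StudyManifest(
        sections=metas, markers=list(DEFAULT_MARKERS), phenotypes=list(DEFAULT_PHENOTYPES)
    )
    return Study(manifest=manifest, tables=frames)
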