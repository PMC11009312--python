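"""Data model and readers/writers for per-cell tables and study manifests.

The package operates on tables exported by whole-slide image analysis
(one row per segmented cell, with centroid coordinates in microns and the
mean fluorescence intensity of every marker channel), plus a manifest that
maps each tissue section to its specimen, staining run, replicate index and
assay type (4-plex multiplex, or 1-plex for a single marker).

Two table dialects are supported:

* ``generic``: columns ``cell_id, section_id, x_um, y_um`` followed by one
  column per marker.
* ``qupath-like``: ``Object ID``, ``Image``, ``Centroid X µm``,
  ``Centroid Y µm`` and ``<marker>: Cell: Mean`` columns, as produced by
  cell-detection exports from QuPath-style software.

Internally all tables are canonical :class:`pandas.DataFrame` objects with
the generic column layout; :class:`CellRecord` is the per-cell view.
"""

from __future__ import annotations

import json
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import pandas as pd
import yaml

from .errors import FormatError, ValidationError

#: canonical non-marker columns of a cell table, in order
BASE_COLUMNS = ("cell_id", "section_id", "x_um", "y_um")

#: alternate marker spellings seen in exports, mapped to canonical names
DEFAULT_MARKER_ALIASES: dict[str, str] = {
    "CD3ε": "CD3e",
    "CD3E": "CD3e",
    "CD8α": "CD8a",
    "CD8A": "CD8a",
    "FOXP3": "FoxP3",
}

_QUPATH_BASE = {
    "Object ID": "cell_id",
    "Image": "section_id",
    "Centroid X µm": "x_um",
    "Centroid Y µm": "y_um",
}
_QUPATH_MARKER_RE = re.compile(r"^(?P<marker>.+): Cell: Mean$")


@dataclass(frozen=True)
class CellRecord:
    """One segmented cell: identity, centroid (µm) and per-marker mean intensity."""

    cell_id: str
    section_id: str
    x_um: float
    y_um: float
    intensities: Mapping[str, float]

    def __post_init__(self) -> None:
        for marker, value in self.intensities.items():
            if value < 0:
                raise ValidationError(
                    f"negative intensity {value} for marker {marker!r} "
                    f"in cell {self.cell_id!r}"
                )


@dataclass(frozen=True)
class SectionMeta:
    """Metadata for one tissue section.

    ``assay`` is either ``"multiplex"`` or ``"singleplex:<marker>"``;
    for a 1-plex section only its own marker channel is meaningful for
    gating (the other channels carry background signal only).
    """

    section_id: str
    specimen: str
    serial_index: int
    run_id: str
    replicate_index: int
    assay: str

    def __post_init__(self) -> None:
        if self.serial_index < 1:
            raise ValidationError(f"serial_index must be >= 1, got {self.serial_index}")
        if self.replicate_index < 1:
            raise ValidationError(
                f"replicate_index must be >= 1, got {self.replicate_index}"
            )
        if self.assay != "multiplex" and not self.assay.startswith("singleplex:"):
            raise ValidationError(
                f"assay must be 'multiplex' or 'singleplex:<marker>', got {self.assay!r}"
            )

    @property
    def is_multiplex(self) -> bool:
        return self.assay == "multiplex"

    @property
    def singleplex_marker(self) -> str | None:
        if self.assay.startswith("singleplex:"):
            return self.assay.split(":", 1)[1]
        return None


@dataclass
class StudyManifest:
    """Sections, ordered marker list and phenotype definitions of one study."""

    sections: list[SectionMeta]
    markers: list[str]
    phenotypes: list = field(default_factory=list)  # list[PhenotypeDef]

    def __post_init__(self) -> None:
        ids = [s.section_id for s in self.sections]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate section_id(s) in manifest: {dupes}")
        for specimen in {s.specimen for s in self.sections}:
            serials = [s.serial_index for s in self.sections if s.specimen == specimen]
            if len(serials) != len(set(serials)):
                raise ValidationError(
                    f"serial_index values not unique within specimen {specimen!r}"
                )

    def section(self, section_id: str) -> SectionMeta:
        for s in self.sections:
            if s.section_id == section_id:
                return s
        raise KeyError(section_id)

    @property
    def specimens(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.sections:
            seen.setdefault(s.specimen)
        return list(seen)

    @property
    def run_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.sections:
            seen.setdefault(s.run_id)
        return list(seen)


@dataclass
class Study:
    """A manifest plus the loaded cell table of every section.

    ``truth`` optionally holds simulated ground-truth phenotype classes
    (columns ``section_id, cell_id, true_class``) for use in tests.
    """

    manifest: StudyManifest
    tables: dict[str, pd.DataFrame]
    truth: pd.DataFrame | None = None

    def iter_sections(self) -> Iterator[tuple[SectionMeta, pd.DataFrame]]:
        for meta in self.manifest.sections:
            yield meta, self.tables[meta.section_id]

    def sections_of_run(self, run_id: str) -> list[SectionMeta]:
        return [s for s in self.manifest.sections if s.run_id == run_id]

    def n_cells(self) -> int:
        return sum(len(t) for t in self.tables.values())


# ---------------------------------------------------------------------------
# cell tables


def _canonicalize_markers(names: Iterable[str], alias_map: Mapping[str, str]) -> list[str]:
    return [alias_map.get(n, n) for n in names]


def frame_to_records(frame: pd.DataFrame) -> list[CellRecord]:
    """Convert a canonical cell frame into a list of :class:`CellRecord`."""
    markers = [c for c in frame.columns if c not in BASE_COLUMNS]
    records = []
    for row in frame.itertuples(index=False):
        d = row._asdict()
        records.append(
            CellRecord(
                cell_id=str(d["cell_id"]),
                section_id=str(d["section_id"]),
                x_um=float(d["x_um"]),
                y_um=float(d["y_um"]),
                intensities={m: float(d[m]) for m in markers},
            )
        )
    return records


def records_to_frame(
    cells: Sequence[CellRecord], markers: Sequence[str] | None = None
) -> pd.DataFrame:
    """Convert records to a canonical frame; marker sets must agree cell-to-cell."""
    if not cells:
        cols = list(BASE_COLUMNS) + (list(markers) if markers else [])
        return pd.DataFrame(columns=cols)
    marker_set = set(cells[0].intensities)
    for c in cells:
        if set(c.intensities) != marker_set:
            raise ValidationError(
                f"inconsistent marker sets: cell {c.cell_id!r} has "
                f"{sorted(c.intensities)} but expected {sorted(marker_set)}"
            )
    if markers is None:
        markers = list(cells[0].intensities)
    elif set(markers) != marker_set:
        raise ValidationError(
            f"marker order {list(markers)} does not match cell markers "
            f"{sorted(marker_set)}"
        )
    data = {
        "cell_id": [c.cell_id for c in cells],
        "section_id": [c.section_id for c in cells],
        "x_um": [c.x_um for c in cells],
        "y_um": [c.y_um for c in cells],
    }
    for m in markers:
        data[m] = [c.intensities[m] for c in cells]
    return pd.DataFrame(data)


def read_cell_frame(
    path: str | Path,
    dialect: str = "generic",
    alias_map: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Read a cell table into the canonical frame layout.

    Rows with a missing coordinate or intensity value are rejected (per-cell
    means are never legitimately missing in a segmentation export); their
    1-based data-row numbers are reported in a warning.  A negative intensity
    raises :class:`ValidationError`.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"cell table not found: {path}")
    aliases = dict(DEFAULT_MARKER_ALIASES)
    if alias_map:
        aliases.update(alias_map)

    frame = pd.read_csv(path, sep=None, engine="python")
    if dialect == "qupath-like":
        missing = [c for c in _QUPATH_BASE if c not in frame.columns]
        if missing:
            raise FormatError(
                f"{path}: missing required column(s) {missing} for qupath-like dialect"
            )
        rename = dict(_QUPATH_BASE)
        markers = []
        for col in frame.columns:
            m = _QUPATH_MARKER_RE.match(col)
            if m:
                marker = aliases.get(m.group("marker"), m.group("marker"))
                rename[col] = marker
                markers.append(marker)
        frame = frame.rename(columns=rename)
        frame = frame[list(BASE_COLUMNS) + markers]
    elif dialect == "generic":
        missing = [c for c in BASE_COLUMNS if c not in frame.columns]
        if missing:
            raise FormatError(f"{path}: missing required column(s) {missing}")
        markers = [c for c in frame.columns if c not in BASE_COLUMNS]
        frame = frame.rename(columns={m: aliases.get(m, m) for m in markers})
        markers = [c for c in frame.columns if c not in BASE_COLUMNS]
    else:
        raise ValueError(f"unknown dialect {dialect!r}")

    if len(frame) == 0:
        return frame.astype({"x_um": float, "y_um": float})

    value_cols = ["x_um", "y_um"] + markers
    bad = frame[value_cols].isna().any(axis=1)
    if bad.any():
        rows = [int(i) + 1 for i in frame.index[bad]]
        warnings.warn(
            f"{path}: rejected {bad.sum()} malformed row(s) with missing values "
            f"(data rows {rows})",
            stacklevel=2,
        )
        frame = frame[~bad].reset_index(drop=True)
    for m in markers:
        if (frame[m] < 0).any():
            row = int(frame.index[frame[m] < 0][0]) + 1
            raise ValidationError(
                f"{path}: negative intensity in column {m!r} (data row {row})"
            )
    frame["cell_id"] = frame["cell_id"].astype(str)
    frame["section_id"] = frame["section_id"].astype(str)
    return frame


def read_cell_table(
    path: str | Path,
    dialect: str = "generic",
    alias_map: Mapping[str, str] | None = None,
) -> list[CellRecord]:
    """Read a cell table as a list of :class:`CellRecord` (see :func:`read_cell_frame`)."""
    return frame_to_records(read_cell_frame(path, dialect=dialect, alias_map=alias_map))


def write_cell_table(
    cells: Sequence[CellRecord] | pd.DataFrame,
    path: str | Path,
    markers: Sequence[str] | None = None,
    dialect: str = "generic",
) -> None:
    """Write cells to a delimited-text table.

    Floats are written at full round-trip precision so that
    ``read(write(x)) == x`` exactly.
    """
    if isinstance(cells, pd.DataFrame):
        frame = cells
        table_markers = [c for c in frame.columns if c not in BASE_COLUMNS]
        if markers is not None:
            if set(markers) != set(table_markers):
                raise ValidationError(
                    f"marker list {list(markers)} does not match table columns "
                    f"{table_markers}"
                )
            frame = frame[list(BASE_COLUMNS) + list(markers)]
    else:
        frame = records_to_frame(cells, markers=markers)
        table_markers = [c for c in frame.columns if c not in BASE_COLUMNS]

    if dialect == "qupath-like":
        rename = {v: k for k, v in _QUPATH_BASE.items()}
        rename.update({m: f"{m}: Cell: Mean" for m in table_markers})
        frame = frame.rename(columns=rename)
    elif dialect != "generic":
        raise ValueError(f"unknown dialect {dialect!r}")
    frame.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# manifests and studies


def _phenotypes_from_config(entries: list[dict]) -> list:
    from .gating import PhenotypeDef  # local import to avoid a module cycle

    return [
        PhenotypeDef(
            name=e["name"],
            require_pos=frozenset(e["require_pos"]),
            require_neg=frozenset(e.get("require_neg", ())),
        )
        for e in entries
    ]


def load_manifest(path: str | Path) -> StudyManifest:
    """Load a YAML study manifest (``markers``, ``phenotypes``, ``sections`` blocks)."""
    path = Path(path)
    with open(path, "r", encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict) or "sections" not in cfg or "markers" not in cfg:
        raise FormatError(f"{path}: manifest must define 'markers' and 'sections'")
    sections = [
        SectionMeta(
            section_id=str(s["section_id"]),
            specimen=str(s["specimen"]),
            serial_index=int(s["serial_index"]),
            run_id=str(s["run_id"]),
            replicate_index=int(s["replicate_index"]),
            assay=str(s["assay"]),
        )
        for s in cfg["sections"]
    ]
    phenotypes = _phenotypes_from_config(cfg.get("phenotypes", []))
    return StudyManifest(
        sections=sections, markers=[str(m) for m in cfg["markers"]], phenotypes=phenotypes
    )


def save_manifest(manifest: StudyManifest, path: str | Path) -> None:
    cfg = {
        "markers": list(manifest.markers),
        "phenotypes": [
            {
                "name": p.name,
                "require_pos": sorted(p.require_pos),
                "require_neg": sorted(p.require_neg),
            }
            for p in manifest.phenotypes
        ],
        "sections": [
            {
                "section_id": s.section_id,
                "specimen": s.specimen,
                "serial_index": s.serial_index,
                "run_id": s.run_id,
                "replicate_index": s.replicate_index,
                "assay": s.assay,
            }
            for s in manifest.sections
        ],
    }
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)


def load_study(
    manifest_path: str | Path,
    table_dir: str | Path,
    dialect: str = "generic",
    strict: bool = True,
) -> Study:
    """Load a manifest and all of its cell tables, cross-checking marker sets.

    Each section's table is expected at ``<table_dir>/<section_id>.csv``.
    With ``strict=True`` (the default) a table column not listed in the
    manifest's marker block is an error — a silent channel mismatch is the
    most dangerous failure mode in panel QC.  With ``strict=False`` the
    extra column is dropped with a warning.
    """
    manifest = load_manifest(manifest_path)
    table_dir = Path(table_dir)
    tables: dict[str, pd.DataFrame] = {}
    missing = [
        s.section_id
        for s in manifest.sections
        if not (table_dir / f"{s.section_id}.csv").exists()
    ]
    if missing:
        raise FormatError(
            f"manifest references section(s) with no cell table in {table_dir}: {missing}"
        )
    for meta in manifest.sections:
        frame = read_cell_frame(table_dir / f"{meta.section_id}.csv", dialect=dialect)
        table_markers = [c for c in frame.columns if c not in BASE_COLUMNS]
        unknown = [m for m in table_markers if m not in manifest.markers]
        if unknown:
            if strict:
                raise ValidationError(
                    f"section {meta.section_id!r}: marker(s) {unknown} not in manifest"
                )
            warnings.warn(
                f"section {meta.section_id!r}: ignoring unknown marker(s) {unknown}",
                stacklevel=2,
            )
            frame = frame.drop(columns=unknown)
            table_markers = [m for m in table_markers if m not in unknown]
        absent = [m for m in manifest.markers if m not in table_markers]
        if absent:
            raise ValidationError(
                f"section {meta.section_id!r}: manifest marker(s) {absent} missing "
                "from its table"
            )
        tables[meta.section_id] = frame[list(BASE_COLUMNS) + list(manifest.markers)]

    truth_path = table_dir / "ground_truth.csv"
    truth = None
    if truth_path.exists():
        truth = pd.read_csv(truth_path, dtype={"section_id": str, "cell_id": str})
    return Study(manifest=manifest, tables=tables, truth=truth)


def save_study(study: Study, out_dir: str | Path) -> None:
    """Write manifest, one table per section and (if present) the ground truth."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    save_manifest(study.manifest, out_dir / "manifest.yaml")
    for meta, frame in study.iter_sections():
        write_cell_table(frame, out_dir / f"{meta.section_id}.csv")
    if study.truth is not None:
        study.truth.to_csv(out_dir / "ground_truth.csv", index=False)


def write_json_summary(summary: dict, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
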