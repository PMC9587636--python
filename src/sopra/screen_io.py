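"""Reading/writing of screen description files and single-object feature data.

A screen is described by three tab-delimited text files plus one single-cell
feature file per physical plate pass (plate x replicate):

``PlateList.txt``
    Columns ``Plate``, ``Replicate``, ``Filename``. One row per plate pass;
    ``Filename`` points to the single-cell feature file.
``PlateConf_LookUp.txt``
    Columns ``Plate``, ``Well``, ``Content``, ``RNA.ID``, ``GeneSymbol``.
    One row per well, describing what the well contains.
``ScreenLog.txt``
    Columns ``Plate``, ``Well``, ``Reason``. Wells flagged here are excluded
    from all analysis.
``Single Cell Feature Files``
    Column ``Well`` (1-based integer well index, row-major across the plate)
    plus one numeric column per measured feature (e.g. ``Area``,
    ``Mean Intensity DAPI``, ``Total Intensity DAPI``); one row per
    segmented object.

All files are UTF-8, tab-delimited, with a header line. Decimal separator is
'.' by default; a ``decimal=','`` switch supports European exports.

The assembled in-memory container is the *cell table*: a pandas DataFrame
with one row per retained object, carrying plate/replicate/well keys, the
well annotation and the raw feature values.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger("sopra")

__all__ = [
    "ContentType",
    "PlateListEntry",
    "WellAnnotation",
    "FlagRecord",
    "ParseReport",
    "ScreenFormatError",
    "DEFAULT_CONTENT_MAP",
    "well_name_to_index",
    "read_plate_list",
    "read_plate_conf",
    "read_screen_log",
    "read_single_cell_file",
    "assemble_cell_table",
    "load_screen",
    "write_all_data_table",
    "read_all_data_table",
]


class ScreenFormatError(ValueError):
    """A descriptive or data file violates the documented layout."""


class ContentType(str, Enum):
    SAMPLE = "sample"
    NEUTRAL_CONTROL = "neutral_control"
    POSITIVE_CONTROL = "positive_control"
    MOCK = "mock"
    EMPTY = "empty"


#: Default mapping from well-content labels to content types. Neutral controls
#: are non-targeting siRNAs (AllStars, Luciferase); Mock is untreated;
#: aphidicolin (A1-A4, G1/S arrest) and nocodazole (N1-N4, G2/M arrest) are
#: chemical positive controls. Matching is case-insensitive.
DEFAULT_CONTENT_MAP: dict[str, ContentType] = {
    "allstars": ContentType.NEUTRAL_CONTROL,
    "luciferase": ContentType.NEUTRAL_CONTROL,
    "neutral_control": ContentType.NEUTRAL_CONTROL,
    "mock": ContentType.MOCK,
    "sample": ContentType.SAMPLE,
    "empty": ContentType.EMPTY,
    "aphidicolin": ContentType.POSITIVE_CONTROL,
    "nocodazole": ContentType.POSITIVE_CONTROL,
    "positive_control": ContentType.POSITIVE_CONTROL,
    **{f"a{i}": ContentType.POSITIVE_CONTROL for i in range(1, 5)},
    **{f"n{i}": ContentType.POSITIVE_CONTROL for i in range(1, 5)},
}


@dataclass(frozen=True)
class PlateListEntry:
    plate_id: str
    replicate: int
    file_path: str


@dataclass(frozen=True)
class WellAnnotation:
    plate_id: str
    well_index: int
    content_type: ContentType
    rna_id: str | None = None
    gene_symbol: str | None = None
    treatment_label: str | None = None


@dataclass(frozen=True)
class FlagRecord:
    plate_id: str
    well_index: int
    reason: str = ""


@dataclass
class ParseReport:
    """Accounting of rows read vs dropped while parsing a single-cell file."""

    path: str
    n_rows: int
    n_dropped: int

    @property
    def n_kept(self) -> int:
        return self.n_rows - self.n_dropped


def well_name_to_index(name: str, n_cols: int = 24) -> int:
    """Convert an 'A01'-style well name to the 1-based row-major index.

    ``n_cols`` is the plate width (24 for 384-well, 12 for 96-well plates).
    """
    name = name.strip().upper()
    if len(name) < 2 or not name[0].isalpha():
        raise ScreenFormatError(f"not a well name: {name!r}")
    row = ord(name[0]) - ord("A")
    try:
        col = int(name[1:])
    except ValueError as exc:
        raise ScreenFormatError(f"not a well name: {name!r}") from exc
    if not 1 <= col <= n_cols:
        raise ScreenFormatError(f"column {col} outside 1..{n_cols}: {name!r}")
    return row * n_cols + col


def _read_table(path: str | Path, required: Sequence[str], decimal: str = ".") -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str, encoding="utf-8", decimal=decimal)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ScreenFormatError(f"{path}: missing column(s) {missing}; found {list(df.columns)}")
    return df


def read_plate_list(path: str | Path) -> list[PlateListEntry]:
    """Read ``PlateList.txt``: one entry per plate pass, in file order."""
    df = _read_table(path, ["Plate", "Replicate", "Filename"])
    entries = []
    seen: set[tuple[str, int]] = set()
    for _, row in df.iterrows():
        try:
            rep = int(row["Replicate"])
        except (TypeError, ValueError) as exc:
            raise ScreenFormatError(f"{path}: replicate {row['Replicate']!r} is not an integer") from exc
        if rep < 1:
            raise ScreenFormatError(f"{path}: replicate must be positive, got {rep}")
        key = (str(row["Plate"]), rep)
        if key in seen:
            raise ScreenFormatError(f"{path}: duplicate plate/replicate entry {key}")
        seen.add(key)
        fname = str(row["Filename"]) if pd.notna(row["Filename"]) else ""
        if not fname:
            raise ScreenFormatError(f"{path}: empty Filename for {key}")
        entries.append(PlateListEntry(plate_id=key[0], replicate=rep, file_path=fname))
    return entries


def read_plate_conf(
    path: str | Path,
    plate_ids: Iterable[str],
    content_map: Mapping[str, ContentType] | None = None,
) -> list[WellAnnotation]:
    """Read ``PlateConf_LookUp.txt`` and annotate every well of every plate.

    Content labels are resolved through ``content_map`` (case-insensitive;
    defaults to :data:`DEFAULT_CONTENT_MAP`); unmapped labels raise. Every
    plate in ``plate_ids`` must appear in the file and carry at least one
    neutral-control well.
    """
    cmap = {k.lower(): v for k, v in (content_map or DEFAULT_CONTENT_MAP).items()}
    df = _read_table(path, ["Plate", "Well", "Content"])
    annotations: list[WellAnnotation] = []
    for _, row in df.iterrows():
        label = str(row["Content"]).strip()
        ctype = cmap.get(label.lower())
        if ctype is None:
            raise ScreenFormatError(f"{path}: unknown well content label {label!r}")

        def _opt(col: str) -> str | None:
            val = row.get(col)
            return None if val is None or pd.isna(val) or str(val) in ("", "NA") else str(val)

        annotations.append(
            WellAnnotation(
                plate_id=str(row["Plate"]),
                well_index=int(row["Well"]),
                content_type=ctype,
                rna_id=_opt("RNA.ID"),
                gene_symbol=_opt("GeneSymbol"),
                treatment_label=label,
            )
        )
    by_plate: dict[str, list[WellAnnotation]] = {}
    for ann in annotations:
        by_plate.setdefault(ann.plate_id, []).append(ann)
    for pid in plate_ids:
        anns = by_plate.get(str(pid))
        if not anns:
            raise ScreenFormatError(f"{path}: plate {pid!r} listed in PlateList has no well annotations")
        if not any(a.content_type is ContentType.NEUTRAL_CONTROL for a in anns):
            raise ScreenFormatError(f"{path}: plate {pid!r} has no neutral-control wells")
    return annotations


def read_screen_log(path: str | Path) -> list[FlagRecord]:
    """Read ``ScreenLog.txt`` listing flagged (excluded) wells."""
    df = _read_table(path, ["Plate", "Well"])
    records = []
    for _, row in df.iterrows():
        reason = str(row["Reason"]) if "Reason" in df.columns and pd.notna(row.get("Reason")) else ""
        records.append(FlagRecord(plate_id=str(row["Plate"]), well_index=int(row["Well"]), reason=reason))
    return records


def read_single_cell_file(
    path: str | Path,
    feature_names: Sequence[str],
    decimal: str = ".",
    well_column: str = "Well",
) -> tuple[pd.DataFrame, ParseReport]:
    """Read one single-cell feature file.

    Returns a DataFrame with columns ``well`` plus the requested features,
    one row per object, and a :class:`ParseReport`. Rows with missing or
    non-numeric feature values (or well index) are dropped, not imputed:
    histogramming cannot use them.
    """
    df = pd.read_csv(path, sep="\t", encoding="utf-8", decimal=decimal, dtype=str)
    required = [well_column, *feature_names]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ScreenFormatError(f"{path}: missing column(s) {missing}")
    n_rows = len(df)

    def _numeric(col: pd.Series) -> pd.Series:
        if decimal != ".":
            col = col.str.replace(decimal, ".", regex=False)
        return pd.to_numeric(col, errors="coerce")

    out = pd.DataFrame({"well": _numeric(df[well_column])})
    for feat in feature_names:
        out[feat] = _numeric(df[feat])
    kept = out.dropna()
    report = ParseReport(path=str(path), n_rows=n_rows, n_dropped=n_rows - len(kept))
    if report.n_dropped:
        logger.info("%s: dropped %d/%d rows with unparseable values", path, report.n_dropped, n_rows)
    kept = kept.astype({"well": int}).reset_index(drop=True)
    return kept, report


def assemble_cell_table(
    entries: Sequence[PlateListEntry],
    annotations: Sequence[WellAnnotation],
    flags: Sequence[FlagRecord],
    raw_rows: Mapping[tuple[str, int], pd.DataFrame],
) -> pd.DataFrame:
    """Join raw object rows with well annotations and drop flagged wells.

    ``raw_rows`` maps (plate_id, replicate) to the frame returned by
    :func:`read_single_cell_file`. Every (plate, well) seen in the data must
    be annotated. The result has one row per retained object with columns
    ``plate, replicate, well, object, content, rna_id, gene`` plus the
    feature columns.
    """
    ann_by_key = {(a.plate_id, a.well_index): a for a in annotations}
    flagged = {(f.plate_id, f.well_index) for f in flags}
    parts: list[pd.DataFrame] = []
    for entry in entries:
        raw = raw_rows.get((entry.plate_id, entry.replicate))
        if raw is None or raw.empty:
            continue
        unknown = {
            (entry.plate_id, int(w)) for w in raw["well"].unique()
        } - set(ann_by_key)
        if unknown:
            raise ScreenFormatError(
                f"plate {entry.plate_id}: wells without annotation: "
                f"{sorted(w for _, w in unknown)[:10]}"
            )
        part = raw.copy()
        part.insert(0, "plate", entry.plate_id)
        part.insert(1, "replicate", entry.replicate)
        part = part[~part["well"].map(lambda w: (entry.plate_id, int(w)) in flagged)]
        if part.empty:
            continue
        keys = list(zip(part["plate"], part["well"]))
        part["content"] = [ann_by_key[k].content_type.value for k in keys]
        part["rna_id"] = [ann_by_key[k].rna_id for k in keys]
        part["gene"] = [ann_by_key[k].gene_symbol for k in keys]
        part["treatment"] = [ann_by_key[k].treatment_label for k in keys]
        part["object"] = range(len(part))
        parts.append(part)
    if not parts:
        warnings.warn("assembled cell table is empty (all wells flagged or no data)", stacklevel=2)
        cols = ["plate", "replicate", "well", "object", "content", "rna_id", "gene", "treatment"]
        return pd.DataFrame(columns=cols)
    table = pd.concat(parts, ignore_index=True)
    counts = table.groupby(["plate", "replicate", "well"]).size()
    logger.info(
        "cell table: %d objects, %d wells, %d plate passes",
        len(table), len(counts), len(parts),
    )
    return table


def load_screen(
    folder: str | Path,
    feature_names: Sequence[str],
    decimal: str = ".",
    content_map: Mapping[str, ContentType] | None = None,
) -> pd.DataFrame:
    """Load a complete screen from a folder holding the canonical files."""
    folder = Path(folder)
    entries = read_plate_list(folder / "PlateList.txt")
    annotations = read_plate_conf(
        folder / "PlateConf_LookUp.txt", [e.plate_id for e in entries], content_map
    )
    log_path = folder / "ScreenLog.txt"
    flags = read_screen_log(log_path) if log_path.exists() else []
    raw: dict[tuple[str, int], pd.DataFrame] = {}
    for entry in entries:
        fpath = Path(entry.file_path)
        if not fpath.is_absolute():
            fpath = folder / fpath
        raw[(entry.plate_id, entry.replicate)], _ = read_single_cell_file(
            fpath, feature_names, decimal=decimal
        )
    return assemble_cell_table(entries, annotations, flags, raw)


# Column order of AllDataTable.txt: one row per (plate, replicate, well,
# feature, bin) with annotation, raw (pseudocounted) bin count, relative
# frequency and the control-normalized value.
_ALL_DATA_COLUMNS = [
    "plate", "replicate", "well", "content", "rna_id", "gene",
    "feature", "bin", "count", "rel_freq", "value", "scale",
]


def write_all_data_table(profiles: pd.DataFrame, path: str | Path) -> None:
    """Write normalized, annotated profiles to ``AllDataTable.txt``.

    Floats are serialized with full round-trip precision so that
    :func:`read_all_data_table` restores values exactly.
    """
    out = profiles.reindex(columns=_ALL_DATA_COLUMNS)
    out.to_csv(path, sep="\t", index=False, encoding="utf-8", float_format="%.17g")


def read_all_data_table(path: str | Path) -> pd.DataFrame:
    """Read an ``AllDataTable.txt`` written by :func:`write_all_data_table`."""
    df = pd.read_csv(
        path, sep="\t", encoding="utf-8", dtype={"plate": str}, float_precision="round_trip"
    )
    missing = [c for c in _ALL_DATA_COLUMNS if c not in df.columns]
    if missing:
        raise ScreenFormatError(f"{path}: missing column(s) {missing}")
    return df
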