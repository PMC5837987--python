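"""Readers and writers for the tab-separated tables the toolkit consumes.

All files are UTF-8, hard-TAB delimited, with ``#`` comment lines allowed
before the header.  Readers only parse: they never reorder, rescale,
filter or normalize.  Writers print floating-point values with ``repr``
(shortest round-trip formatting), so ``read(write(x)) == x`` bit for bit.

Identifiers are case-sensitive opaque strings; no database (Greengenes,
KEGG, ...) is consulted.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import InputFormatError

#: Reserved per-taxon companion columns in genomic content tables.
RRNA_COLUMN = "16S_copies"
NSTI_COLUMN = "NSTI"


def format_value(x: float) -> str:
    """Shortest round-trip decimal representation of a float."""
    return repr(float(x))


def _check_unique(ids: Sequence[str], what: str, where: str) -> None:
    seen: set[str] = set()
    for i in ids:
        if i in seen:
            raise InputFormatError(f"duplicate {what} id {i!r} in {where}")
        seen.add(i)


def _parse_cell(text: str, row_label: str, col_label: str, where: str) -> float:
    try:
        v = float(text)
    except ValueError:
        raise InputFormatError(
            f"non-numeric value {text!r} at row {row_label!r}, "
            f"column {col_label!r} in {where}"
        ) from None
    if not math.isfinite(v):
        raise InputFormatError(
            f"non-finite value {text!r} at row {row_label!r}, "
            f"column {col_label!r} in {where}"
        )
    if v < 0:
        raise InputFormatError(
            f"negative value {v!r} at row {row_label!r}, "
            f"column {col_label!r} in {where}"
        )
    return v


# ---------------------------------------------------------------------------
# Domain containers
# ---------------------------------------------------------------------------


@dataclass
class MatrixTable:
    """A features x samples abundance matrix.

    Rows are taxa or gene families (``axis_kind``), columns are samples.
    Values are nonnegative finite reals; row and column identifiers are
    unique and keep their input order.
    """

    row_ids: list[str]
    col_ids: list[str]
    values: np.ndarray
    axis_kind: str = "taxon"

    def __post_init__(self) -> None:
        self.row_ids = [str(r) for r in self.row_ids]
        self.col_ids = [str(c) for c in self.col_ids]
        self.values = np.asarray(self.values, dtype=float)
        if self.axis_kind not in ("taxon", "function"):
            raise InputFormatError(f"unknown axis_kind {self.axis_kind!r}")
        if len(self.row_ids) == 0 or len(self.col_ids) == 0:
            raise InputFormatError("MatrixTable must have at least 1 row and 1 column")
        if self.values.shape != (len(self.row_ids), len(self.col_ids)):
            raise InputFormatError(
                f"value shape {self.values.shape} does not match "
                f"{len(self.row_ids)} rows x {len(self.col_ids)} columns"
            )
        _check_unique(self.row_ids, "row", "MatrixTable")
        _check_unique(self.col_ids, "column", "MatrixTable")
        if not np.all(np.isfinite(self.values)):
            raise InputFormatError("MatrixTable contains non-finite values")
        if np.any(self.values < 0):
            raise InputFormatError("MatrixTable contains negative values")

    # -- convenience -------------------------------------------------------
    def row_index(self) -> dict[str, int]:
        return {r: i for i, r in enumerate(self.row_ids)}

    def col_index(self) -> dict[str, int]:
        return {c: j for j, c in enumerate(self.col_ids)}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.row_ids, columns=self.col_ids)

    def copy(self) -> "MatrixTable":
        return MatrixTable(
            list(self.row_ids), list(self.col_ids), self.values.copy(), self.axis_kind
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, MatrixTable):
            return NotImplemented
        return (
            self.row_ids == other.row_ids
            and self.col_ids == other.col_ids
            and self.axis_kind == other.axis_kind
            and np.array_equal(self.values, other.values)
        )


@dataclass
class GenomeAnnotationTable:
    """Per-taxon gene-family copy numbers, g(t, f).

    Optionally carries each taxon's 16S rRNA operon count c16S(t)
    (strictly positive, used for copy-number correction) and its NSTI
    value n(t) (nonnegative, used for prediction-confidence summaries).
    """

    taxon_ids: list[str]
    function_ids: list[str]
    copy_numbers: np.ndarray
    rrna_copies: np.ndarray | None = None
    nsti: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.taxon_ids = [str(t) for t in self.taxon_ids]
        self.function_ids = [str(f) for f in self.function_ids]
        self.copy_numbers = np.asarray(self.copy_numbers, dtype=float)
        _check_unique(self.taxon_ids, "taxon", "GenomeAnnotationTable")
        _check_unique(self.function_ids, "function", "GenomeAnnotationTable")
        if self.copy_numbers.shape != (len(self.taxon_ids), len(self.function_ids)):
            raise InputFormatError("copy_numbers shape does not match id lists")
        if not np.all(np.isfinite(self.copy_numbers)) or np.any(self.copy_numbers < 0):
            raise InputFormatError("copy numbers must be finite and >= 0")
        if self.rrna_copies is not None:
            self.rrna_copies = np.asarray(self.rrna_copies, dtype=float)
            if self.rrna_copies.shape != (len(self.taxon_ids),):
                raise InputFormatError("rrna_copies length does not match taxa")
            if not np.all(np.isfinite(self.rrna_copies)) or np.any(self.rrna_copies <= 0):
                raise InputFormatError("16S copy numbers must be finite and > 0")
        if self.nsti is not None:
            self.nsti = np.asarray(self.nsti, dtype=float)
            if self.nsti.shape != (len(self.taxon_ids),):
                raise InputFormatError("nsti length does not match taxa")
            if not np.all(np.isfinite(self.nsti)) or np.any(self.nsti < 0):
                raise InputFormatError("NSTI values must be finite and >= 0")

    def taxon_index(self) -> dict[str, int]:
        return {t: i for i, t in enumerate(self.taxon_ids)}

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenomeAnnotationTable):
            return NotImplemented

        def _opt_eq(a, b):
            if a is None or b is None:
                return a is None and b is None
            return np.array_equal(a, b)

        return (
            self.taxon_ids == other.taxon_ids
            and self.function_ids == other.function_ids
            and np.array_equal(self.copy_numbers, other.copy_numbers)
            and _opt_eq(self.rrna_copies, other.rrna_copies)
            and _opt_eq(self.nsti, other.nsti)
        )


@dataclass
class AttributionLongTable:
    """Sparse long-form attribution records (taxon, function, sample, abundance).

    Triples absent from the table mean abundance 0.  Duplicate triples
    and negative abundances are rejected.
    """

    taxa: list[str]
    functions: list[str]
    samples: list[str]
    abundances: np.ndarray

    def __post_init__(self) -> None:
        self.taxa = [str(t) for t in self.taxa]
        self.functions = [str(f) for f in self.functions]
        self.samples = [str(s) for s in self.samples]
        self.abundances = np.asarray(self.abundances, dtype=float)
        n = len(self.taxa)
        if not (len(self.functions) == len(self.samples) == len(self.abundances) == n):
            raise InputFormatError("attribution record columns have unequal lengths")
        if n and (not np.all(np.isfinite(self.abundances)) or np.any(self.abundances < 0)):
            raise InputFormatError("attribution abundances must be finite and >= 0")
        seen: set[tuple[str, str, str]] = set()
        for key in zip(self.taxa, self.functions, self.samples):
            if key in seen:
                raise InputFormatError(
                    f"duplicate (taxon, function, sample) triple {key!r}"
                )
            seen.add(key)

    def records(self) -> Iterable[tuple[str, str, str, float]]:
        yield from zip(self.taxa, self.functions, self.samples, self.abundances)

    def __len__(self) -> int:
        return len(self.taxa)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AttributionLongTable):
            return NotImplemented
        return sorted(self.records()) == sorted(other.records())


@dataclass
class HierarchyMap:
    """Leaf id -> ordered ancestor labels (root-most first).

    ``lineages[leaf]`` is a tuple of one or more lineages; file input
    always yields exactly one lineage per leaf, but multi-parent leaves
    (e.g. a gene family listed under several pathways) may be built
    programmatically.
    """

    lineages: dict[str, tuple[tuple[str, ...], ...]]
    level_names: tuple[str, ...]

    def __post_init__(self) -> None:
        self.level_names = tuple(str(n) for n in self.level_names)
        if not self.level_names:
            raise InputFormatError("hierarchy must declare at least one level")
        norm: dict[str, tuple[tuple[str, ...], ...]] = {}
        for leaf, lins in self.lineages.items():
            leaf = str(leaf)
            lins = tuple(tuple(str(x) for x in lin) for lin in lins)
            if not lins:
                raise InputFormatError(f"leaf {leaf!r} has no lineage")
            for lin in lins:
                if len(lin) != len(self.level_names):
                    raise InputFormatError(
                        f"leaf {leaf!r} lineage depth {len(lin)} != "
                        f"{len(self.level_names)} declared levels"
                    )
                if leaf in lin:
                    raise InputFormatError(f"leaf {leaf!r} appears in its own lineage")
            norm[leaf] = lins
        if not norm:
            raise InputFormatError("hierarchy map has no leaves")
        self.lineages = norm

    @property
    def depth(self) -> int:
        return len(self.level_names)

    def leaves(self) -> list[str]:
        return list(self.lineages)


@dataclass
class SampleGroupMap:
    """Sample id -> free-form group label."""

    groups: dict[str, str]

    def __post_init__(self) -> None:
        self.groups = {str(s): str(g) for s, g in self.groups.items()}
        if not self.groups:
            raise InputFormatError("sample group map is empty")

    def labels(self) -> list[str]:
        out: list[str] = []
        for g in self.groups.values():
            if g not in out:
                out.append(g)
        return out


# ---------------------------------------------------------------------------
# Line-level helpers
# ---------------------------------------------------------------------------


def _read_rows(path: str | Path) -> tuple[list[str], list[list[str]]]:
    """Return (header cells, body rows) of a TSV file.

    Comment lines (``#`` first char) before the header are skipped;
    blank lines are ignored everywhere.
    """
    path = Path(path)
    if not path.exists():
        raise InputFormatError(f"file not found: {path}")
    header: list[str] | None = None
    body: list[list[str]] = []
    with open(path, encoding="utf-8") as fh:
        for raw in fh:
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            if header is None:
                if line.startswith("#"):
                    continue
                header = line.split("\t")
            else:
                body.append(line.split("\t"))
    if header is None:
        raise InputFormatError(f"{path}: no header line found")
    if not body:
        raise InputFormatError(f"{path}: empty table body")
    return header, body


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------


def read_matrix_table(path: str | Path, axis_kind: str = "taxon") -> MatrixTable:
    """Read a features x samples abundance table.

    The header's first cell names the id column; the remaining cells are
    sample ids.  Rows of all zeros are retained — filtering is always a
    separate, explicit step.
    """
    header, body = _read_rows(path)
    where = str(path)
    if len(header) < 2:
        raise InputFormatError(f"{where}: need at least one sample column")
    col_ids = header[1:]
    _check_unique(col_ids, "sample", where)
    row_ids: list[str] = []
    rows: list[list[float]] = []
    for cells in body:
        if len(cells) != len(header):
            raise InputFormatError(
                f"{where}: row {cells[0]!r} has {len(cells)} cells, "
                f"expected {len(header)}"
            )
        rid = cells[0]
        row_ids.append(rid)
        rows.append(
            [_parse_cell(c, rid, col_ids[j], where) for j, c in enumerate(cells[1:])]
        )
    _check_unique(row_ids, "row", where)
    return MatrixTable(row_ids, col_ids, np.array(rows, dtype=float), axis_kind)


def read_genomic_content(path: str | Path, layout: str = "wide") -> GenomeAnnotationTable:
    """Read a per-taxon gene copy-number table.

    ``wide``: taxon rows x function columns, with optional reserved
    columns ``16S_copies`` and ``NSTI``.  ``long``: columns (taxon,
    function, copy_number) plus the same optional companions; absent
    (taxon, function) pairs mean a copy number of 0.  Both layouts
    produce identical in-memory tables for equivalent content.
    """
    where = str(path)
    if layout == "wide":
        header, body = _read_rows(path)
        func_cols = header[1:]
        _check_unique(func_cols, "column", where)
        rrna_j = func_cols.index(RRNA_COLUMN) if RRNA_COLUMN in func_cols else None
        nsti_j = func_cols.index(NSTI_COLUMN) if NSTI_COLUMN in func_cols else None
        function_ids = [
            f for j, f in enumerate(func_cols) if j not in (rrna_j, nsti_j)
        ]
        taxon_ids: list[str] = []
        g_rows: list[list[float]] = []
        rrna: list[float] = []
        nsti: list[float] = []
        for cells in body:
            if len(cells) != len(header):
                raise InputFormatError(
                    f"{where}: row {cells[0]!r} has {len(cells)} cells, "
                    f"expected {len(header)}"
                )
            tid = cells[0]
            taxon_ids.append(tid)
            vals = cells[1:]
            g_rows.append(
                [
                    _parse_cell(vals[j], tid, func_cols[j], where)
                    for j in range(len(func_cols))
                    if j not in (rrna_j, nsti_j)
                ]
            )
            if rrna_j is not None:
                c = _parse_cell(vals[rrna_j], tid, RRNA_COLUMN, where)
                if c <= 0:
                    raise InputFormatError(
                        f"{where}: 16S copy number for taxon {tid!r} must be > 0"
                    )
                rrna.append(c)
            if nsti_j is not None:
                nsti.append(_parse_cell(vals[nsti_j], tid, NSTI_COLUMN, where))
        _check_unique(taxon_ids, "taxon", where)
        return GenomeAnnotationTable(
            taxon_ids,
            function_ids,
            np.array(g_rows, dtype=float),
            np.array(rrna) if rrna_j is not None else None,
            np.array(nsti) if nsti_j is not None else None,
        )
    if layout == "long":
        header, body = _read_rows(path)
        if len(header) < 3:
            raise InputFormatError(
                f"{where}: long layout needs (taxon, function, copy_number) columns"
            )
        extra = header[3:]
        rrna_j = extra.index(RRNA_COLUMN) + 3 if RRNA_COLUMN in extra else None
        nsti_j = extra.index(NSTI_COLUMN) + 3 if NSTI_COLUMN in extra else None
        taxon_ids: list[str] = []
        function_ids: list[str] = []
        entries: dict[tuple[str, str], float] = {}
        rrna_map: dict[str, float] = {}
        nsti_map: dict[str, float] = {}
        for cells in body:
            if len(cells) != len(header):
                raise InputFormatError(
                    f"{where}: row {cells[:2]!r} has {len(cells)} cells, "
                    f"expected {len(header)}"
                )
            t, f = cells[0], cells[1]
            if (t, f) in entries:
                raise InputFormatError(
                    f"{where}: duplicate (taxon, function) pair ({t!r}, {f!r})"
                )
            entries[(t, f)] = _parse_cell(cells[2], t, f, where)
            if t not in taxon_ids:
                taxon_ids.append(t)
            if f not in function_ids:
                function_ids.append(f)
            for j, column, target in (
                (rrna_j, RRNA_COLUMN, rrna_map),
                (nsti_j, NSTI_COLUMN, nsti_map),
            ):
                if j is None:
                    continue
                v = _parse_cell(cells[j], t, column, where)
                if column == RRNA_COLUMN and v <= 0:
                    raise InputFormatError(
                        f"{where}: 16S copy number for taxon {t!r} must be > 0"
                    )
                if t in target and target[t] != v:
                    raise InputFormatError(
                        f"{where}: conflicting {column} values for taxon {t!r}"
                    )
                target[t] = v
        g = np.zeros((len(taxon_ids), len(function_ids)))
        f_idx = {f: j for j, f in enumerate(function_ids)}
        t_idx = {t: i for i, t in enumerate(taxon_ids)}
        for (t, f), v in entries.items():
            g[t_idx[t], f_idx[f]] = v
        return GenomeAnnotationTable(
            taxon_ids,
            function_ids,
            g,
            np.array([rrna_map[t] for t in taxon_ids]) if rrna_j is not None else None,
            np.array([nsti_map[t] for t in taxon_ids]) if nsti_j is not None else None,
        )
    raise InputFormatError(f"unknown genomic content layout {layout!r}")


def read_attribution_long(path: str | Path) -> AttributionLongTable:
    """Read a 4-column (taxon, function, sample, abundance) long table."""
    header, body = _read_rows(path)
    where = str(path)
    if len(header) != 4:
        raise InputFormatError(
            f"{where}: expected 4 columns (taxon, function, sample, abundance)"
        )
    taxa, funcs, samples, ab = [], [], [], []
    for cells in body:
        if len(cells) != 4:
            raise InputFormatError(
                f"{where}: row {cells[:3]!r} has {len(cells)} cells, expected 4"
            )
        taxa.append(cells[0])
        funcs.append(cells[1])
        samples.append(cells[2])
        ab.append(_parse_cell(cells[3], cells[0], cells[2], where))
    return AttributionLongTable(taxa, funcs, samples, np.array(ab))


def read_hierarchy_map(path: str | Path) -> HierarchyMap:
    """Read a hierarchy file: header of level names, then leaf + one label per level.

    Empty trailing cells are padded by repeating the last defined label,
    giving every leaf uniform depth.  A leaf listed twice is rejected.
    """
    header, body = _read_rows(path)
    where = str(path)
    if len(header) < 2:
        raise InputFormatError(f"{where}: hierarchy file needs at least one level column")
    level_names = tuple(header[1:])
    lineages: dict[str, tuple[tuple[str, ...], ...]] = {}
    for cells in body:
        if len(cells) != len(header):
            raise InputFormatError(
                f"{where}: leaf {cells[0]!r} has {len(cells) - 1} lineage cells, "
                f"expected {len(level_names)} (ragged hierarchies are rejected)"
            )
        leaf = cells[0]
        labels = cells[1:]
        if not labels[0].strip():
            raise InputFormatError(f"{where}: leaf {leaf!r} has an empty root-most label")
        padded: list[str] = []
        for lab in labels:
            padded.append(lab.strip() if lab.strip() else padded[-1])
        if leaf in lineages:
            if lineages[leaf] != (tuple(padded),):
                raise InputFormatError(
                    f"{where}: leaf {leaf!r} listed twice with different lineages"
                )
            raise InputFormatError(f"{where}: leaf {leaf!r} listed twice")
        lineages[leaf] = (tuple(padded),)
    return HierarchyMap(lineages, level_names)


def read_sample_groups(path: str | Path) -> SampleGroupMap:
    """Read a 2-column (sample, group) file; labels stay strings."""
    header, body = _read_rows(path)
    where = str(path)
    if len(header) != 2:
        raise InputFormatError(f"{where}: expected 2 columns (sample, group)")
    groups: dict[str, str] = {}
    for cells in body:
        if len(cells) != 2:
            raise InputFormatError(f"{where}: row {cells!r} does not have 2 cells")
        s, g = cells
        if s in groups:
            raise InputFormatError(f"{where}: sample {s!r} listed twice")
        groups[s] = g
    return SampleGroupMap(groups)


def read_biom_json(path: str | Path, axis_kind: str = "taxon") -> MatrixTable:
    """Convenience reader for BIOM 1.0 (JSON) observation tables.

    Converts to a :class:`MatrixTable`; TSV remains the contract format.
    Supports both ``dense`` and ``sparse`` matrix encodings.
    """
    path = Path(path)
    if not path.exists():
        raise InputFormatError(f"file not found: {path}")
    try:
        doc = json.loads(path.read_text(encoding="utf-8"))
    except json.JSONDecodeError as exc:
        raise InputFormatError(f"{path}: not valid BIOM JSON: {exc}") from None
    try:
        row_ids = [r["id"] for r in doc["rows"]]
        col_ids = [c["id"] for c in doc["columns"]]
        shape = tuple(doc["shape"])
        mtype = doc["matrix_type"]
        data = doc["data"]
    except (KeyError, TypeError) as exc:
        raise InputFormatError(f"{path}: missing BIOM field {exc}") from None
    if shape != (len(row_ids), len(col_ids)):
        raise InputFormatError(f"{path}: BIOM shape field disagrees with id lists")
    values = np.zeros(shape)
    if mtype == "dense":
        values[:] = np.asarray(data, dtype=float)
    elif mtype == "sparse":
        for i, j, v in data:
            values[int(i), int(j)] = float(v)
    else:
        raise InputFormatError(f"{path}: unknown BIOM matrix_type {mtype!r}")
    return MatrixTable(row_ids, col_ids, values, axis_kind)


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------


def _id_column_name(axis_kind: str) -> str:
    return {"taxon": "taxon_id", "function": "function_id"}[axis_kind]


def write_table(obj, path: str | Path) -> Path:
    """Write a MatrixTable, AttributionLongTable, or DataFrame as TSV.

    Matrix rows/columns keep their stored order; long tables are sorted
    taxon-major (taxon, function, sample) with zero cells omitted.
    """
    path = Path(path)
    try:
        fh = open(path, "w", encoding="utf-8", newline="\n")
    except OSError as exc:
        raise InputFormatError(f"cannot write {path}: {exc}") from None
    with fh:
        if isinstance(obj, MatrixTable):
            fh.write("\t".join([_id_column_name(obj.axis_kind), *obj.col_ids]) + "\n")
            for i, rid in enumerate(obj.row_ids):
                cells = [format_value(v) for v in obj.values[i]]
                fh.write("\t".join([rid, *cells]) + "\n")
        elif isinstance(obj, AttributionLongTable):
            fh.write("taxon\tfunction\tsample\tabundance\n")
            recs = sorted(obj.records(), key=lambda r: (r[0], r[1], r[2]))
            for t, f, s, v in recs:
                if v != 0:
                    fh.write(f"{t}\t{f}\t{s}\t{format_value(v)}\n")
        elif isinstance(obj, pd.DataFrame):
            fh.write("\t".join(str(c) for c in obj.columns) + "\n")
            for _, row in obj.iterrows():
                cells = [
                    format_value(v) if isinstance(v, float) else str(v) for v in row
                ]
                fh.write("\t".join(cells) + "\n")
        else:
            raise InputFormatError(f"cannot write object of type {type(obj).__name__}")
    return path


def write_hierarchy_map(hmap: HierarchyMap, path: str | Path) -> Path:
    """Write a single-lineage hierarchy map back to its file format."""
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\t".join(["leaf_id", *hmap.level_names]) + "\n")
        for leaf, lins in hmap.lineages.items():
            if len(lins) != 1:
                raise InputFormatError(
                    f"leaf {leaf!r} has multiple lineages; file format stores one"
                )
            fh.write("\t".join([leaf, *lins[0]]) + "\n")
    return path


def write_sample_groups(groups: SampleGroupMap, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("sample\tgroup\n")
        for s, g in groups.groups.items():
            fh.write(f"{s}\t{g}\n")
    return path


def write_genomic_content(annot: GenomeAnnotationTable, path: str | Path) -> Path:
    """Write a genomic content table in the wide layout."""
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        cols = list(annot.function_ids)
        if annot.rrna_copies is not None:
            cols.append(RRNA_COLUMN)
        if annot.nsti is not None:
            cols.append(NSTI_COLUMN)
        fh.write("\t".join(["taxon_id", *cols]) + "\n")
        for i, t in enumerate(annot.taxon_ids):
            cells = [format_value(v) for v in annot.copy_numbers[i]]
            if annot.rrna_copies is not None:
                cells.append(format_value(annot.rrna_copies[i]))
            if annot.nsti is not None:
                cells.append(format_value(annot.nsti[i]))
            fh.write("\t".join([t, *cells]) + "\n")
    return path
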