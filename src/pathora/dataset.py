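"""Import of tabular omics data.

A dataset is a typed table whose rows are keyed by an :class:`~pathora.model.
Xref` — e.g. a differential-expression table with ``log2FC`` and ``pvalue``
columns keyed by Entrez Gene ids. Several rows may share one Xref (multiple
probes or experiments measuring the same gene); visualization shows them as
separate box rows and the statistics collapse them to gene level.

Column kinds are inferred, not declared: a column is numeric exactly when
every non-missing cell parses as a real number (decimal point, optional
scientific notation — locale separators are rejected for cross-machine
determinism). The empty cell is the only missing-value marker; tokens like
``n/a`` are ordinary text and force the column to text kind.
"""

from __future__ import annotations

import csv
import io
import re
from dataclasses import dataclass, field
from typing import List, Optional

from .errors import TableFormatError
from .idmap import IdMapper
from .model import Xref

__all__ = [
    "ColumnSpec",
    "DataRow",
    "Dataset",
    "import_data_table",
    "rows_for_xref",
]

_NUMBER_RE = re.compile(r"^[+-]?(?:\d+\.?\d*|\.\d+)(?:[eE][+-]?\d+)?$")


@dataclass(frozen=True)
class ColumnSpec:
    name: str
    kind: str  # "numeric" | "text"

    def __post_init__(self):
        if not self.name:
            raise ValueError("column name must be non-empty")
        if self.kind not in ("numeric", "text"):
            raise ValueError(f"unknown column kind {self.kind!r}")


@dataclass
class DataRow:
    """One measurement row: its Xref key and a column-name -> value map.

    Missing values are stored as ``None``.
    """

    xref: Xref
    values: dict = field(default_factory=dict)


@dataclass
class Dataset:
    columns: List[ColumnSpec]
    rows: List[DataRow] = field(default_factory=list)
    warnings: List[str] = field(default_factory=list)

    def column_names(self) -> List[str]:
        return [c.name for c in self.columns]

    def column(self, name: str) -> ColumnSpec:
        for c in self.columns:
            if c.name == name:
                return c
        raise KeyError(name)


def _parse_number(cell: str) -> Optional[float]:
    if _NUMBER_RE.match(cell):
        return float(cell)
    return None


def import_data_table(
    source,
    id_column: str,
    system: Optional[str] = None,
    system_column: Optional[str] = None,
    sep: str = "\t",
) -> Dataset:
    """Parse delimited text into a :class:`Dataset`.

    Exactly one of ``system`` (one identifier system for every row) or
    ``system_column`` (a column naming each row's system) must be given.
    Rows with a blank identifier (or blank system) are skipped with a
    counted warning; file order is preserved for the rest.
    """
    if (system is None) == (system_column is None):
        raise ValueError("provide exactly one of system= or system_column=")
    text = source.read() if hasattr(source, "read") else source
    reader = csv.reader(io.StringIO(text), delimiter=sep)
    try:
        header = next(reader)
    except StopIteration:
        raise TableFormatError("data table is empty (missing header)") from None
    header = [h.strip() for h in header]
    if id_column not in header:
        raise TableFormatError(
            f"id column {id_column!r} not found in header {header}"
        )
    if system_column is not None and system_column not in header:
        raise TableFormatError(
            f"system column {system_column!r} not found in header {header}"
        )
    id_idx = header.index(id_column)
    sys_idx = header.index(system_column) if system_column is not None else None
    meta = {id_idx} | ({sys_idx} if sys_idx is not None else set())
    value_cols = [(i, name) for i, name in enumerate(header) if i not in meta]
    if not value_cols:
        raise TableFormatError("data table has no measurement columns")

    raw_rows = []
    skipped = 0
    for fields in reader:
        if not any(f.strip() for f in fields):
            continue  # blank line
        fields += [""] * (len(header) - len(fields))
        ident = fields[id_idx].strip()
        row_system = system if sys_idx is None else fields[sys_idx].strip()
        if not ident or not row_system:
            skipped += 1
            continue
        raw_rows.append((Xref(row_system, ident), [fields[i] for i, _ in value_cols]))

    # kind inference: numeric iff every non-missing cell parses as a real
    kinds = []
    for j, (_, name) in enumerate(value_cols):
        numeric = True
        for _, cells in raw_rows:
            cell = cells[j].strip()
            if cell and _parse_number(cell) is None:
                numeric = False
                break
        kinds.append("numeric" if numeric else "text")

    columns = [ColumnSpec(name, kind) for (_, name), kind in zip(value_cols, kinds)]
    dataset = Dataset(columns=columns)
    for xref, cells in raw_rows:
        values = {}
        for spec, cell in zip(columns, cells):
            cell = cell.strip()
            if not cell:
                values[spec.name] = None
            elif spec.kind == "numeric":
                values[spec.name] = _parse_number(cell)
            else:
                values[spec.name] = cell
        dataset.rows.append(DataRow(xref=xref, values=values))
    if skipped:
        dataset.warnings.append(f"{skipped} rows skipped (blank identifier)")
    return dataset


def rows_for_xref(d: Dataset, m: IdMapper, node_xref: Xref) -> List[DataRow]:
    """All rows whose key matches ``node_xref`` under the mapping, in file
    order. This is how a pathway node finds its measurements even when the
    dataset uses a different identifier system."""
    key = m.equivalence_key(node_xref)
    return [row for row in d.rows if m.equivalence_key(row.xref) == key]
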