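"""Over-representation analysis (ORA) with the hypergeometric Z-score.

For each pathway in a collection the analysis counts

* ``total`` — distinct annotated entities of the selected node types,
* ``n``     — how many of those are measured in the dataset,
* ``r``     — how many of those meet the user's criterion,

against the collection-wide universe of

* ``N`` — measured genes present in at least one pathway (genes found in no
  pathway are ignored), and
* ``R`` — those of them meeting the criterion.

Under the hypergeometric null (drawing the pathway's n measured genes from
the N-gene universe containing R positives) the expected number of positives
is nR/N and the Z-score is

    Z = (r - nR/N) / sqrt( n (R/N) (1 - R/N) (1 - (n-1)/(N-1)) )

A positive Z means more criterion-positive genes than expected; pathways are
ranked by Z descending. When the variance term collapses (n = 0, n = N,
R = 0 or R = N) the score is undefined and reported as NA, sorted last —
coercing it to 0 would fake "exactly as expected".

Counting is gene-level: rows are bucketed into identifier-equivalence
classes under the mapping, so multiple probes for one gene never inflate a
count, and one true row suffices to make its gene positive.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, List, Optional, Tuple

from .criteria import Criterion, evaluate_criterion, parse_criterion
from .dataset import Dataset
from .idmap import IdMapper
from .model import GENE_LIKE_TYPES, Pathway, PathwayCollection, annotated_xrefs

__all__ = [
    "OraRow",
    "OraReport",
    "zscore",
    "pathway_counts",
    "global_counts",
    "run_ora",
    "write_ora_report",
]


@dataclass
class OraRow:
    pathway_name: str
    source_file: str
    total: int
    n: int
    r: int
    z: Optional[float]


@dataclass
class OraReport:
    criterion_text: str
    N: int
    R: int
    rows: List[OraRow] = field(default_factory=list)
    warnings: List[str] = field(default_factory=list)


def zscore(n: int, r: int, N: int, R: int) -> Optional[float]:
    """Hypergeometric Z-score; ``None`` when the variance is degenerate.

    Arguments follow the counting convention above: ``r`` of the pathway's
    ``n`` measured genes are positive, out of ``R`` positives among ``N``
    measured genes overall.
    """
    if not (0 <= r <= n <= N and 0 <= R <= N and N >= 1):
        raise ValueError(
            f"invalid counts: need 0 <= r <= n <= N and 0 <= R <= N, "
            f"got n={n}, r={r}, N={N}, R={R}"
        )
    if n == 0 or n == N or R == 0 or R == N:
        return None  # variance term is exactly zero
    p = R / N
    variance = n * p * (1.0 - p) * (1.0 - (n - 1) / (N - 1))
    return (r - n * R / N) / math.sqrt(variance)


class _OraContext:
    """Shared per-analysis state: rows bucketed by gene-equivalence class
    and memoized criterion outcomes."""

    def __init__(self, d: Dataset, m: IdMapper, c: Criterion):
        self.mapper = m
        self.criterion = c
        self.rows_by_key: dict = {}
        for row in d.rows:
            self.rows_by_key.setdefault(m.equivalence_key(row.xref), []).append(row)
        self._positive_cache: dict = {}

    def measured(self, key) -> bool:
        return key in self.rows_by_key

    def positive(self, key) -> bool:
        if key not in self._positive_cache:
            self._positive_cache[key] = any(
                evaluate_criterion(self.criterion, row) is True
                for row in self.rows_by_key.get(key, ())
            )
        return self._positive_cache[key]


def _pathway_counts(p: Pathway, ctx: _OraContext, types) -> Tuple[int, int, int]:
    xrefs = annotated_xrefs(p, types)
    total = len(xrefs)
    n = r = 0
    for x in xrefs:
        key = ctx.mapper.equivalence_key(x)
        if ctx.measured(key):
            n += 1
            if ctx.positive(key):
                r += 1
    return total, n, r


def pathway_counts(
    p: Pathway,
    d: Dataset,
    m: IdMapper,
    c: Criterion,
    types: Optional[Iterable] = None,
) -> Tuple[int, int, int]:
    """(total, n, r) for one pathway. ``types`` defaults to gene-like nodes."""
    c.check_columns(d.column_names())
    return _pathway_counts(p, _OraContext(d, m, c), types)


def _global_counts(
    coll: PathwayCollection, ctx: _OraContext, types
) -> Tuple[int, int]:
    keys = set()
    for _, p in coll:
        for x in annotated_xrefs(p, types):
            keys.add(ctx.mapper.equivalence_key(x))
    N = sum(1 for k in keys if ctx.measured(k))
    R = sum(1 for k in keys if ctx.measured(k) and ctx.positive(k))
    return N, R


def global_counts(
    coll: PathwayCollection,
    d: Dataset,
    m: IdMapper,
    c: Criterion,
    types: Optional[Iterable] = None,
) -> Tuple[int, int]:
    """(N, R) over the collection: measured genes found in >= 1 pathway and
    those meeting the criterion. Genes absent from every pathway are
    ignored; a gene shared by several pathways counts once."""
    c.check_columns(d.column_names())
    return _global_counts(coll, _OraContext(d, m, c), types)


def run_ora(
    coll: PathwayCollection,
    d: Dataset,
    m: IdMapper,
    criterion_text: str,
    types: Optional[Iterable] = None,
) -> OraReport:
    """Full over-representation analysis, ranked by Z-score.

    Rows sort by Z descending with undefined scores last; ties break by
    pathway name then source file, ascending.
    """
    criterion = parse_criterion(criterion_text)
    criterion.check_columns(d.column_names())
    types = GENE_LIKE_TYPES if types is None else frozenset(types)
    ctx = _OraContext(d, m, criterion)
    N, R = _global_counts(coll, ctx, types)

    report = OraReport(criterion_text=criterion_text, N=N, R=R)
    for filename, p in coll:
        total, n, r = _pathway_counts(p, ctx, types)
        z = zscore(n, r, N, R) if N >= 1 else None
        report.rows.append(
            OraRow(
                pathway_name=p.name,
                source_file=filename,
                total=total,
                n=n,
                r=r,
                z=z,
            )
        )
    report.rows.sort(
        key=lambda row: (
            row.z is None,                       # defined scores first
            -row.z if row.z is not None else 0.0,
            row.pathway_name,
            row.source_file,
        )
    )
    if R == 0:
        report.warnings.append(
            "no gene meets the criterion (R = 0); all Z-scores are undefined"
        )
    return report


def write_ora_report(report: OraReport, destination=None) -> str:
    """Serialize a report as TSV; also written to ``destination`` if given.

    The ``zscore`` column shows 2 decimals (NA when undefined); the final
    ``zscore_full`` column keeps full precision for downstream parsing.
    """
    lines = ["pathway\tfile\ttotal\tmeasured\tpositive\tzscore\tzscore_full"]
    for row in report.rows:
        if row.z is None:
            z2 = zfull = "NA"
        else:
            z2 = f"{row.z:.2f}"
            zfull = repr(row.z)
        lines.append(
            f"{row.pathway_name}\t{row.source_file}\t{row.total}\t{row.n}\t"
            f"{row.r}\t{z2}\t{zfull}"
        )
    text = "\n".join(lines) + "\n"
    if destination is not None:
        Path(destination).write_text(text, encoding="utf-8")
    return text
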