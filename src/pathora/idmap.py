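"""Table-driven identifier cross-reference mapping.

Omics datasets rarely use the identifier system a pathway author chose:
a pathway node annotated with an HGNC symbol must still pick up data rows
keyed by Entrez Gene ids. An :class:`IdMapper` holds symmetric Xref pairs
loaded from a plain TSV and answers reachability queries over the full
transitive closure of the resulting undirected graph, so chains like
symbol -> Entrez -> Ensembl resolve without designating a backbone system.

Identifiers and system names are compared exactly and case-sensitively,
matching how GPML stores them.
"""

from __future__ import annotations

import io
from typing import Optional, Set

import networkx as nx

from .errors import TableFormatError
from .model import Xref

__all__ = ["IdMapper", "load_mapping_table"]

_HEADER = ["source_system", "source_id", "target_system", "target_id"]


class IdMapper:
    """Symmetric Xref pairs with memoized transitive closure."""

    def __init__(self, pairs=()):
        self._graph = nx.Graph()
        self._component_of: Optional[dict] = None  # xref -> representative
        for a, b in pairs:
            self.add_pair(a, b)

    def add_pair(self, a: Xref, b: Xref) -> None:
        if a == b:
            raise ValueError(f"mapping pair links {a} to itself")
        self._graph.add_edge(a, b)
        self._component_of = None  # invalidate memo

    @property
    def pairs(self) -> Set[frozenset]:
        return {frozenset((a, b)) for a, b in self._graph.edges}

    @property
    def systems(self) -> Set[str]:
        return {x.datasource for x in self._graph.nodes}

    def __len__(self) -> int:
        return self._graph.number_of_edges()

    def _components(self) -> dict:
        if self._component_of is None:
            self._component_of = {}
            for comp in nx.connected_components(self._graph):
                rep = min(comp, key=lambda x: (x.datasource, x.identifier))
                for x in comp:
                    self._component_of[x] = rep
        return self._component_of

    def closure(self, x: Xref) -> Set[Xref]:
        """All Xrefs linked to ``x`` (including ``x``) by any chain of pairs.

        An Xref absent from the table maps to the singleton ``{x}``.
        """
        if x not in self._graph:
            return {x}
        rep = self._components()[x]
        return {y for y, r in self._components().items() if r == rep}

    def equivalence_key(self, x: Xref) -> Xref:
        """A canonical representative of ``x``'s closure.

        Two Xrefs match (:meth:`xrefs_match`) exactly when their keys are
        equal, which lets callers bucket data rows by gene.
        """
        if x not in self._graph:
            return x
        return self._components()[x]

    def map_xref(self, x: Xref, target_system: str) -> Set[Xref]:
        """Xrefs in ``target_system`` reachable from ``x``.

        If ``x`` itself is already in the target system it is part of the
        result, so mapping is always identity-preserving.
        """
        return {y for y in self.closure(x) if y.datasource == target_system}

    def xrefs_match(self, a: Xref, b: Xref) -> bool:
        """True when ``a`` and ``b`` name the same entity under this mapping."""
        return a == b or self.equivalence_key(a) == self.equivalence_key(b)


def load_mapping_table(source) -> IdMapper:
    """Build an :class:`IdMapper` from TSV text (or a file-like object).

    The required header is ``source_system  source_id  target_system
    target_id`` (tab-separated). Each row adds one symmetric pair; duplicate
    rows collapse. Blank identifiers are row-level errors reported with their
    line number.
    """
    if hasattr(source, "read"):
        text = source.read()
    else:
        text = source
    lines = io.StringIO(text).read().splitlines()
    if not lines:
        raise TableFormatError("mapping table is empty (missing header)")
    header = lines[0].rstrip("\n").split("\t")
    missing = [c for c in _HEADER if c not in header]
    if missing:
        raise TableFormatError(
            f"mapping table missing column(s): {', '.join(missing)}"
        )
    idx = {c: header.index(c) for c in _HEADER}

    mapper = IdMapper()
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        fields = line.split("\t")
        try:
            values = {c: fields[idx[c]].strip() for c in _HEADER}
        except IndexError:
            raise TableFormatError(
                f"line {lineno}: expected {len(header)} fields, got {len(fields)}"
            ) from None
        blank = [c for c in _HEADER if not values[c]]
        if blank:
            raise TableFormatError(
                f"line {lineno}: blank value in column(s) {', '.join(blank)}"
            )
        a = Xref(values["source_system"], values["source_id"])
        b = Xref(values["target_system"], values["target_id"])
        if a == b:
            raise TableFormatError(f"line {lineno}: pair links {a} to itself")
        mapper.add_pair(a, b)
    return mapper
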