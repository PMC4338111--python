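"""Pathway object model.

A :class:`Pathway` is an in-memory representation of a biological pathway
diagram: data nodes (genes, proteins, metabolites, ...), the interactions
between them, free-text labels, graphical shapes and groups, all placed on a
drawing board whose origin is the top-left corner with the y axis pointing
down (the convention shared by GPML and SVG).

Biological entities are annotated with external database cross-references
(:class:`Xref`), e.g. the *KNG1* gene annotated with Entrez Gene id 3827.
These annotations are what connect a diagram to experimental data tables and
drive over-representation statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional

__all__ = [
    "Xref",
    "Geometry",
    "DataNode",
    "Waypoint",
    "Anchor",
    "Interaction",
    "Label",
    "Shape",
    "Group",
    "Pathway",
    "PathwayCollection",
    "Issue",
    "validate",
    "annotated_xrefs",
    "DATA_NODE_TYPES",
    "SHAPE_TYPES",
    "GENE_LIKE_TYPES",
]

#: Recognized data-node types (GPML ``Type`` attribute).
DATA_NODE_TYPES = frozenset(
    {"GeneProduct", "Protein", "Rna", "Metabolite", "Pathway", "Unknown"}
)

#: Node types counted as "genes" by default in over-representation analysis.
GENE_LIKE_TYPES = frozenset({"GeneProduct", "Protein", "Rna"})

#: Recognized shape types.
SHAPE_TYPES = frozenset({"Rectangle", "Oval", "RoundedRectangle", "Compartment"})


@dataclass(frozen=True)
class Xref:
    """A database cross-reference: (identifier system, identifier).

    Both fields must be non-empty; an absent annotation is represented by
    ``None`` on the carrying element, never by empty strings. Equality is
    exact, case-sensitive string equality on both fields.
    """

    datasource: str
    identifier: str

    def __post_init__(self) -> None:
        if not self.datasource or not self.identifier:
            raise ValueError(
                "Xref requires non-empty datasource and identifier; "
                "represent a missing annotation as None, not empty strings"
            )


@dataclass
class Geometry:
    """Placement of a rectangular element in canvas units (y points down)."""

    center_x: float
    center_y: float
    width: float
    height: float


@dataclass
class Waypoint:
    """One point on an interaction's path, optionally attached to an element."""

    x: float
    y: float
    anchor_ref: Optional[str] = None
    extra_attrs: dict = field(default_factory=dict)


@dataclass
class Anchor:
    """A named attachment point along an interaction (referenceable by id)."""

    graph_id: str
    position: float = 0.5
    shape: str = "None"
    extra_attrs: dict = field(default_factory=dict)


@dataclass
class _Element:
    graph_id: str
    comments: list = field(default_factory=list)
    literature_refs: list = field(default_factory=list)
    extra_attrs: dict = field(default_factory=dict)
    graphics_extra: dict = field(default_factory=dict)
    opaque_children: list = field(default_factory=list)


@dataclass
class DataNode(_Element):
    """A box representing a biological entity, optionally Xref-annotated."""

    text_label: str = ""
    node_type: str = "Unknown"
    geometry: Geometry = field(default_factory=lambda: Geometry(0.0, 0.0, 90.0, 25.0))
    xref: Optional[Xref] = None


@dataclass
class Interaction(_Element):
    """A polyline connecting elements (conversion, stimulation, inhibition...).

    ``graphical_line`` marks purely graphical lines that carry no biological
    annotation; they behave like interactions everywhere else.
    """

    waypoints: list = field(default_factory=list)
    start_arrow: str = "Line"
    end_arrow: str = "Line"
    xref: Optional[Xref] = None
    anchors: list = field(default_factory=list)
    graphical_line: bool = False


@dataclass
class Label(_Element):
    text: str = ""
    geometry: Geometry = field(default_factory=lambda: Geometry(0.0, 0.0, 90.0, 25.0))


@dataclass
class Shape(_Element):
    shape_type: str = "Rectangle"
    geometry: Geometry = field(default_factory=lambda: Geometry(0.0, 0.0, 90.0, 25.0))


@dataclass
class Group(_Element):
    """A named grouping of other elements (by their graph ids)."""

    member_ids: list = field(default_factory=list)
    label: Optional[str] = None


@dataclass
class Pathway:
    """A pathway diagram: metadata, board geometry and element lists."""

    name: str = ""
    organism: Optional[str] = None
    version: Optional[str] = None
    board_width: float = 500.0
    board_height: float = 500.0
    data_nodes: list = field(default_factory=list)
    interactions: list = field(default_factory=list)
    labels: list = field(default_factory=list)
    shapes: list = field(default_factory=list)
    groups: list = field(default_factory=list)
    extra_attrs: dict = field(default_factory=dict)
    graphics_extra: dict = field(default_factory=dict)
    opaque_children: list = field(default_factory=list)

    def elements(self) -> Iterator:
        """All placed elements in canonical order."""
        yield from self.data_nodes
        yield from self.interactions
        yield from self.labels
        yield from self.shapes
        yield from self.groups

    def graph_ids(self) -> list:
        """Every graph id in the pathway, including interaction anchors."""
        ids = [el.graph_id for el in self.elements()]
        for inter in self.interactions:
            ids.extend(a.graph_id for a in inter.anchors)
        return ids

    def find(self, graph_id: str):
        for el in self.elements():
            if el.graph_id == graph_id:
                return el
        return None


@dataclass
class PathwayCollection:
    """An ordered set of pathways loaded from files, analyzed together."""

    entries: list = field(default_factory=list)  # (filename, Pathway) pairs
    warnings: list = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self) -> Iterator:
        return iter(self.entries)

    def pathways(self) -> list:
        return [p for _, p in self.entries]


@dataclass
class Issue:
    """A validation finding: severity is ``"error"`` or ``"warning"``."""

    severity: str
    graph_id: Optional[str]
    message: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        where = f" [{self.graph_id}]" if self.graph_id else ""
        return f"{self.severity}{where}: {self.message}"


def _bounding_box(p: Pathway):
    xs, ys = [], []
    for el in p.elements():
        geo = getattr(el, "geometry", None)
        if geo is not None:
            xs += [geo.center_x - geo.width / 2, geo.center_x + geo.width / 2]
            ys += [geo.center_y - geo.height / 2, geo.center_y + geo.height / 2]
    for inter in p.interactions:
        for wp in inter.waypoints:
            xs.append(wp.x)
            ys.append(wp.y)
    if not xs:
        return None
    return min(xs), min(ys), max(xs), max(ys)


def validate(p: Pathway) -> list:
    """Check every model invariant; returns issues instead of raising.

    An empty list means the pathway is valid. Errors cover duplicate graph
    ids, unknown node/shape types, non-positive element dimensions,
    interactions with fewer than two waypoints, dangling references and
    unresolvable group members; board geometry smaller than the drawn
    content is only a warning.
    """
    issues: list = []
    seen: dict = {}
    for gid in p.graph_ids():
        seen[gid] = seen.get(gid, 0) + 1
    for gid, count in seen.items():
        if count > 1:
            issues.append(
                Issue("error", gid, f"duplicate graph_id {gid!r} ({count} elements)")
            )
    known_ids = set(seen)

    for node in p.data_nodes:
        if node.node_type not in DATA_NODE_TYPES:
            issues.append(
                Issue("error", node.graph_id, f"unknown node_type {node.node_type!r}")
            )
    for shape in p.shapes:
        if shape.shape_type not in SHAPE_TYPES:
            issues.append(
                Issue("error", shape.graph_id, f"unknown shape_type {shape.shape_type!r}")
            )
    for el in p.elements():
        geo = getattr(el, "geometry", None)
        if geo is not None and (geo.width <= 0 or geo.height <= 0):
            issues.append(
                Issue(
                    "error",
                    el.graph_id,
                    f"non-positive dimensions {geo.width} x {geo.height}",
                )
            )

    for inter in p.interactions:
        if len(inter.waypoints) < 2:
            issues.append(
                Issue("error", inter.graph_id, "interaction has fewer than 2 waypoints")
            )
        for wp in inter.waypoints:
            if wp.anchor_ref is not None and wp.anchor_ref not in known_ids:
                issues.append(
                    Issue(
                        "error",
                        inter.graph_id,
                        f"dangling anchor_ref {wp.anchor_ref!r}",
                    )
                )

    membership: dict = {}
    for grp in p.groups:
        for mid in grp.member_ids:
            if mid not in known_ids:
                issues.append(
                    Issue("error", grp.graph_id, f"unresolved group member {mid!r}")
                )
            membership.setdefault(mid, []).append(grp.graph_id)
    for mid, gids in membership.items():
        if len(gids) > 1:
            issues.append(
                Issue(
                    "error",
                    mid,
                    f"element belongs to multiple groups: {', '.join(sorted(gids))}",
                )
            )

    bbox = _bounding_box(p)
    if bbox is not None:
        _, _, xmax, ymax = bbox
        if xmax > p.board_width or ymax > p.board_height:
            issues.append(
                Issue(
                    "warning",
                    None,
                    f"board {p.board_width} x {p.board_height} smaller than "
                    f"content extent {xmax} x {ymax}",
                )
            )
    return issues


def annotated_xrefs(p: Pathway, types: Optional[Iterable] = None) -> set:
    """Distinct Xrefs on data nodes of the given types.

    Unannotated nodes are excluded and duplicate annotations collapse, so the
    result size is the pathway's "total" in over-representation counting.
    ``types`` defaults to the gene-like node types.
    """
    wanted = GENE_LIKE_TYPES if types is None else frozenset(types)
    return {
        n.xref
        for n in p.data_nodes
        if n.xref is not None and n.node_type in wanted
    }
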