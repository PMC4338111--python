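"""Reading and writing GPML (Graphical Pathway Markup Language).

GPML is the XML interchange format used by WikiPathways for pathway
diagrams. This module targets the 2013a dialect
(``http://pathvisio.org/GPML/2013a``); documents in the older 2010a
namespace are read and normalized to the same model, and writing always
emits 2013a.

Fidelity rules:

* every recognized element is materialized into the :mod:`pathora.model`
  types;
* unknown attributes and unrecognized child elements (InfoBox, Legend,
  Biopax payloads, dynamic ``Attribute`` properties, ...) are preserved
  verbatim in an opaque side-store so that write → read round-trips them;
* output is deterministic: the same model always serializes to byte-identical
  text, with elements ordered data nodes, interactions, labels, shapes,
  groups.
"""

from __future__ import annotations

import copy
import xml.etree.ElementTree as ET
from pathlib import Path
from typing import Optional

from .errors import GpmlParseError, GpmlValidationError, UnsupportedDialectError
from .model import (
    Anchor,
    DataNode,
    Geometry,
    Group,
    Interaction,
    Label,
    Pathway,
    PathwayCollection,
    Shape,
    Waypoint,
    Xref,
    validate,
)

GPML_2013A = "http://pathvisio.org/GPML/2013a"
GPML_2010A = "http://genmapp.org/GPML/2010a"
_KNOWN_NAMESPACES = {GPML_2013A, GPML_2010A}

__all__ = [
    "read_gpml",
    "read_gpml_file",
    "write_gpml",
    "write_gpml_file",
    "load_collection",
    "write_datanode_list",
    "GPML_2013A",
    "GPML_2010A",
]


# ---------------------------------------------------------------------------
# helpers

def _fmt(x: float) -> str:
    # shortest decimal text that parses back to the same float
    return repr(float(x))


def _split_tag(tag: str):
    if tag.startswith("{"):
        ns, local = tag[1:].split("}", 1)
        return ns, local
    return None, tag


def _local(tag: str) -> str:
    return _split_tag(tag)[1]


def _canonical_fragment(elem: ET.Element) -> str:
    """Serialize an element as a namespace-normalized, whitespace-stripped
    string used for the opaque round-trip store."""
    node = copy.deepcopy(elem)

    def scrub(e: ET.Element) -> None:
        ns, local = _split_tag(e.tag)
        if ns in _KNOWN_NAMESPACES:
            e.tag = local
        if e.text is not None and not e.text.strip():
            e.text = None
        e.tail = None
        for child in e:
            scrub(child)

    scrub(node)
    return ET.tostring(node, encoding="unicode")


def _take_extras(attrib: dict, known) -> dict:
    return {k: v for k, v in attrib.items() if k not in known}


_HIDDEN_PREFIX = "__"  # extra_attrs keys carrying side-channel state


def _visible_extras(extras: dict) -> dict:
    return {k: v for k, v in extras.items() if not k.startswith(_HIDDEN_PREFIX)}


# ---------------------------------------------------------------------------
# reading

def read_gpml(document: str) -> Pathway:
    """Parse a GPML document into a :class:`Pathway`.

    Raises :class:`GpmlParseError` (naming the line) for malformed XML,
    :class:`UnsupportedDialectError` for foreign namespaces and
    :class:`GpmlValidationError` for duplicate graph ids.
    """
    try:
        root = ET.fromstring(document)
    except ET.ParseError as exc:
        line, col = exc.position
        raise GpmlParseError(
            f"malformed XML at line {line}, column {col}: {exc}"
        ) from exc

    ns, local = _split_tag(root.tag)
    if local != "Pathway" or ns not in _KNOWN_NAMESPACES:
        raise UnsupportedDialectError(
            f"root element {root.tag!r} is not a recognized GPML dialect "
            f"(expected Pathway in {GPML_2013A} or {GPML_2010A})"
        )

    p = Pathway(
        name=root.get("Name", ""),
        organism=root.get("Organism"),
        version=root.get("Version"),
    )
    p.extra_attrs = _take_extras(root.attrib, {"Name", "Organism", "Version"})

    group_refs: list = []  # (member graph_id, group id) in document order
    for child in root:
        tag = _local(child.tag)
        if tag == "Graphics":
            p.board_width = float(child.get("BoardWidth", "0"))
            p.board_height = float(child.get("BoardHeight", "0"))
            p.graphics_extra = _take_extras(
                child.attrib, {"BoardWidth", "BoardHeight"}
            )
        elif tag == "DataNode":
            p.data_nodes.append(_read_datanode(child, group_refs))
        elif tag in ("Interaction", "Line", "GraphicalLine"):
            p.interactions.append(
                _read_interaction(child, group_refs, graphical=tag == "GraphicalLine")
            )
        elif tag == "Label":
            p.labels.append(_read_label(child, group_refs))
        elif tag == "Shape":
            p.shapes.append(_read_shape(child, group_refs))
        elif tag == "Group":
            p.groups.append(_read_group(child))
        else:
            p.opaque_children.append(_canonical_fragment(child))

    groups_by_id = {g.graph_id: g for g in p.groups}
    for member_id, gid in group_refs:
        if gid in groups_by_id:
            groups_by_id[gid].member_ids.append(member_id)
        else:
            # dangling GroupRef: keep it verbatim on the element so writing
            # re-emits it unchanged
            el = p.find(member_id)
            if el is not None:
                el.extra_attrs["GroupRef"] = gid

    ids = p.graph_ids()
    dupes = sorted({g for g in ids if ids.count(g) > 1})
    if dupes:
        raise GpmlValidationError(f"duplicate graph_id(s): {', '.join(dupes)}")
    return p


def _read_common(elem: ET.Element, target) -> None:
    """Comments, literature refs and unrecognized children shared by all
    element kinds."""
    n_comments = 0
    for child in elem:
        tag = _local(child.tag)
        if tag == "Comment":
            target.comments.append(child.text or "")
            src = child.get("Source")
            if src is not None:
                target.extra_attrs[f"__comment{n_comments}.Source"] = src
            n_comments += 1
        elif tag == "BiopaxRef":
            target.literature_refs.append(child.text or "")
        elif tag in ("Graphics", "Xref"):
            pass  # handled by the per-kind readers
        else:
            target.opaque_children.append(_canonical_fragment(child))


def _read_xref(elem: ET.Element, target) -> Optional[Xref]:
    for child in elem:
        if _local(child.tag) == "Xref":
            db = child.get("Database", "")
            ident = child.get("ID", "")
            for k, v in child.attrib.items():
                if k not in ("Database", "ID"):
                    target.extra_attrs[f"__xref.{k}"] = v
            if db and ident:
                return Xref(db, ident)
            return None
    return None


def _read_geometry(elem: ET.Element, target, extra_known=()) -> Geometry:
    known = {"CenterX", "CenterY", "Width", "Height", *extra_known}
    for child in elem:
        if _local(child.tag) == "Graphics":
            target.graphics_extra = _take_extras(child.attrib, known)
            return Geometry(
                float(child.get("CenterX", "0")),
                float(child.get("CenterY", "0")),
                float(child.get("Width", "0")),
                float(child.get("Height", "0")),
            )
    return Geometry(0.0, 0.0, 0.0, 0.0)


def _grab_group_ref(elem: ET.Element, graph_id: str, group_refs: list) -> None:
    gid = elem.get("GroupRef")
    if gid is not None:
        group_refs.append((graph_id, gid))


def _read_datanode(elem: ET.Element, group_refs: list) -> DataNode:
    node = DataNode(
        graph_id=elem.get("GraphId", ""),
        text_label=elem.get("TextLabel", ""),
        node_type=elem.get("Type", "Unknown"),
    )
    node.extra_attrs.update(
        _take_extras(elem.attrib, {"GraphId", "TextLabel", "Type", "GroupRef"})
    )
    _grab_group_ref(elem, node.graph_id, group_refs)
    _read_common(elem, node)
    node.geometry = _read_geometry(elem, node)
    node.xref = _read_xref(elem, node)
    return node


def _read_interaction(
    elem: ET.Element, group_refs: list, graphical: bool
) -> Interaction:
    inter = Interaction(graph_id=elem.get("GraphId", ""), graphical_line=graphical)
    inter.extra_attrs.update(_take_extras(elem.attrib, {"GraphId", "GroupRef"}))
    _grab_group_ref(elem, inter.graph_id, group_refs)
    _read_common(elem, inter)
    for child in elem:
        if _local(child.tag) != "Graphics":
            continue
        inter.graphics_extra = dict(child.attrib)
        points = [gc for gc in child if _local(gc.tag) == "Point"]
        for i, pt in enumerate(points):
            wp = Waypoint(
                x=float(pt.get("X", "0")),
                y=float(pt.get("Y", "0")),
                anchor_ref=pt.get("GraphRef"),
            )
            arrow = pt.get("ArrowHead")
            if arrow is not None:
                if i == 0:
                    inter.start_arrow = arrow
                elif i == len(points) - 1:
                    inter.end_arrow = arrow
                else:  # non-terminal arrowheads are kept verbatim
                    wp.extra_attrs["ArrowHead"] = arrow
            wp.extra_attrs.update(
                _take_extras(pt.attrib, {"X", "Y", "GraphRef", "ArrowHead"})
            )
            inter.waypoints.append(wp)
        for gc in child:
            if _local(gc.tag) == "Anchor":
                inter.anchors.append(
                    Anchor(
                        graph_id=gc.get("GraphId", ""),
                        position=float(gc.get("Position", "0.5")),
                        shape=gc.get("Shape", "None"),
                        extra_attrs=_take_extras(
                            gc.attrib, {"GraphId", "Position", "Shape"}
                        ),
                    )
                )
    if not graphical:
        inter.xref = _read_xref(elem, inter)
    return inter


def _read_label(elem: ET.Element, group_refs: list) -> Label:
    lab = Label(graph_id=elem.get("GraphId", ""), text=elem.get("TextLabel", ""))
    lab.extra_attrs.update(
        _take_extras(elem.attrib, {"GraphId", "TextLabel", "GroupRef"})
    )
    _grab_group_ref(elem, lab.graph_id, group_refs)
    _read_common(elem, lab)
    lab.geometry = _read_geometry(elem, lab)
    return lab


def _read_shape(elem: ET.Element, group_refs: list) -> Shape:
    shp = Shape(graph_id=elem.get("GraphId", ""))
    shp.extra_attrs.update(_take_extras(elem.attrib, {"GraphId", "GroupRef"}))
    _grab_group_ref(elem, shp.graph_id, group_refs)
    _read_common(elem, shp)
    shp.geometry = _read_geometry(elem, shp, extra_known=("ShapeType",))
    for child in elem:
        if _local(child.tag) == "Graphics":
            shp.shape_type = child.get("ShapeType", "Rectangle")
    return shp


def _read_group(elem: ET.Element) -> Group:
    gid = elem.get("GroupId") or elem.get("GraphId", "")
    grp = Group(graph_id=gid, label=elem.get("TextLabel"))
    graph_attr = elem.get("GraphId")
    if graph_attr is not None and graph_attr != gid:
        grp.extra_attrs["__groupGraphId"] = graph_attr
    grp.extra_attrs.update(
        _take_extras(elem.attrib, {"GroupId", "GraphId", "TextLabel"})
    )
    _read_common(elem, grp)
    return grp


def read_gpml_file(path) -> Pathway:
    return read_gpml(Path(path).read_text(encoding="utf-8"))


# ---------------------------------------------------------------------------
# writing

def write_gpml(p: Pathway) -> str:
    """Serialize a pathway to GPML 2013a text.

    Model invariants are checked first; any validation *error* aborts the
    write. Output is byte-deterministic for a given model.
    """
    errors = [i for i in validate(p) if i.severity == "error"]
    if errors:
        raise GpmlValidationError(
            "cannot write invalid pathway: " + "; ".join(str(i) for i in errors)
        )

    member_to_group: dict = {}
    for grp in p.groups:
        for mid in grp.member_ids:
            member_to_group[mid] = grp.graph_id

    root = ET.Element("Pathway")
    root.set("xmlns", GPML_2013A)
    root.set("Name", p.name)
    if p.organism is not None:
        root.set("Organism", p.organism)
    if p.version is not None:
        root.set("Version", p.version)
    for k, v in _visible_extras(p.extra_attrs).items():
        root.set(k, v)

    graphics = ET.SubElement(root, "Graphics")
    graphics.set("BoardWidth", _fmt(p.board_width))
    graphics.set("BoardHeight", _fmt(p.board_height))
    for k, v in p.graphics_extra.items():
        graphics.set(k, v)

    for node in p.data_nodes:
        root.append(_write_datanode(node, member_to_group))
    for inter in p.interactions:
        root.append(_write_interaction(inter, member_to_group))
    for lab in p.labels:
        root.append(_write_label(lab, member_to_group))
    for shp in p.shapes:
        root.append(_write_shape(shp, member_to_group))
    for grp in p.groups:
        root.append(_write_group(grp))
    for fragment in p.opaque_children:
        root.append(ET.fromstring(fragment))

    ET.indent(root, space="  ")
    return (
        '<?xml version="1.0" encoding="UTF-8"?>\n'
        + ET.tostring(root, encoding="unicode")
        + "\n"
    )


def _write_common_children(elem: ET.Element, obj) -> None:
    for i, text in enumerate(obj.comments):
        c = ET.SubElement(elem, "Comment")
        src = obj.extra_attrs.get(f"__comment{i}.Source")
        if src is not None:
            c.set("Source", src)
        c.text = text
    for ref in obj.literature_refs:
        b = ET.SubElement(elem, "BiopaxRef")
        b.text = ref
    for fragment in obj.opaque_children:
        elem.append(ET.fromstring(fragment))


def _write_xref_child(elem: ET.Element, obj) -> None:
    x = ET.SubElement(elem, "Xref")
    x.set("Database", obj.xref.datasource if obj.xref else "")
    x.set("ID", obj.xref.identifier if obj.xref else "")
    for k, v in obj.extra_attrs.items():
        if k.startswith("__xref."):
            x.set(k[len("__xref.") :], v)


def _geometry_elem(parent: ET.Element, geo: Geometry, graphics_extra: dict):
    g = ET.SubElement(parent, "Graphics")
    g.set("CenterX", _fmt(geo.center_x))
    g.set("CenterY", _fmt(geo.center_y))
    g.set("Width", _fmt(geo.width))
    g.set("Height", _fmt(geo.height))
    for k, v in graphics_extra.items():
        g.set(k, v)
    return g


def _set_common_attrs(elem: ET.Element, obj, member_to_group: dict) -> None:
    if obj.graph_id in member_to_group:
        elem.set("GroupRef", member_to_group[obj.graph_id])
    for k, v in _visible_extras(obj.extra_attrs).items():
        elem.set(k, v)


def _write_datanode(node: DataNode, member_to_group: dict) -> ET.Element:
    el = ET.Element("DataNode")
    el.set("TextLabel", node.text_label)
    el.set("GraphId", node.graph_id)
    el.set("Type", node.node_type)
    _set_common_attrs(el, node, member_to_group)
    _write_common_children(el, node)
    _geometry_elem(el, node.geometry, node.graphics_extra)
    _write_xref_child(el, node)
    return el


def _write_interaction(inter: Interaction, member_to_group: dict) -> ET.Element:
    el = ET.Element("GraphicalLine" if inter.graphical_line else "Interaction")
    el.set("GraphId", inter.graph_id)
    _set_common_attrs(el, inter, member_to_group)
    _write_common_children(el, inter)
    g = ET.SubElement(el, "Graphics")
    for k, v in inter.graphics_extra.items():
        g.set(k, v)
    last = len(inter.waypoints) - 1
    for i, wp in enumerate(inter.waypoints):
        pt = ET.SubElement(g, "Point")
        pt.set("X", _fmt(wp.x))
        pt.set("Y", _fmt(wp.y))
        if wp.anchor_ref is not None:
            pt.set("GraphRef", wp.anchor_ref)
        if i == 0 and inter.start_arrow != "Line":
            pt.set("ArrowHead", inter.start_arrow)
        elif i == last and inter.end_arrow != "Line":
            pt.set("ArrowHead", inter.end_arrow)
        for k, v in wp.extra_attrs.items():
            pt.set(k, v)
    for anchor in inter.anchors:
        a = ET.SubElement(g, "Anchor")
        a.set("Position", _fmt(anchor.position))
        a.set("Shape", anchor.shape)
        a.set("GraphId", anchor.graph_id)
        for k, v in anchor.extra_attrs.items():
            a.set(k, v)
    if not inter.graphical_line:
        _write_xref_child(el, inter)
    return el


def _write_label(lab: Label, member_to_group: dict) -> ET.Element:
    el = ET.Element("Label")
    el.set("TextLabel", lab.text)
    el.set("GraphId", lab.graph_id)
    _set_common_attrs(el, lab, member_to_group)
    _write_common_children(el, lab)
    _geometry_elem(el, lab.geometry, lab.graphics_extra)
    return el


def _write_shape(shp: Shape, member_to_group: dict) -> ET.Element:
    el = ET.Element("Shape")
    el.set("GraphId", shp.graph_id)
    _set_common_attrs(el, shp, member_to_group)
    _write_common_children(el, shp)
    g = _geometry_elem(el, shp.geometry, {})
    g.set("ShapeType", shp.shape_type)
    for k, v in shp.graphics_extra.items():
        g.set(k, v)
    return el


def _write_group(grp: Group) -> ET.Element:
    el = ET.Element("Group")
    el.set("GroupId", grp.graph_id)
    el.set("GraphId", grp.extra_attrs.get("__groupGraphId", grp.graph_id))
    if grp.label is not None:
        el.set("TextLabel", grp.label)
    for k, v in _visible_extras(grp.extra_attrs).items():
        el.set(k, v)
    _write_common_children(el, grp)
    return el


def write_gpml_file(p: Pathway, path) -> None:
    Path(path).write_text(write_gpml(p), encoding="utf-8")


# ---------------------------------------------------------------------------
# collections and exports

def load_collection(directory) -> PathwayCollection:
    """Load every ``.gpml`` file in a directory, sorted by filename.

    Files that fail to parse become warnings on the returned collection
    rather than aborting the load.
    """
    directory = Path(directory)
    if not directory.is_dir():
        raise FileNotFoundError(f"not a directory: {directory}")
    coll = PathwayCollection()
    files = sorted(directory.glob("*.gpml"), key=lambda f: f.name)
    if not files:
        coll.warnings.append(f"no .gpml files found in {directory}")
        return coll
    for f in files:
        try:
            coll.entries.append((f.name, read_gpml_file(f)))
        except Exception as exc:  # per-file failures are non-fatal
            coll.warnings.append(f"{f.name}: {exc}")
    return coll


def write_datanode_list(p: Pathway) -> str:
    """TSV of all data nodes: text label, type and Xref annotation."""
    lines = ["text_label\tnode_type\tdatasource\tidentifier"]
    for node in p.data_nodes:
        ds = node.xref.datasource if node.xref else ""
        ident = node.xref.identifier if node.xref else ""
        lines.append(f"{node.text_label}\t{node.node_type}\t{ds}\t{ident}")
    return "\n".join(lines) + "\n"
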