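"""Multi-omics visualization on pathway diagrams, rendered as SVG.

Each data-node box is split into one column per configured visualization
(e.g. column 1: log2 fold change on a blue-white-red gradient; column 2:
p-value bands as discrete color rules) and one horizontal row per data row
matching the node, so two measurements of a gene appear as two stacked
rows. Unmeasured nodes are filled with the scheme's ``not_measured_color``.

Gradients interpolate channel-wise in integer-rounded linear RGB (round
half up, no gamma correction); color rules are first-match-wins in declared
order and an undefined criterion never matches.

SVG output is plain deterministic text: identical inputs give byte-identical
documents. PNG export rasterizes that SVG through cairosvg when available
and raises :class:`~pathora.errors.CapabilityError` otherwise.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

from .criteria import Criterion, evaluate_criterion, parse_criterion
from .dataset import Dataset, rows_for_xref
from .errors import CapabilityError, GpmlValidationError, PathoraError
from .idmap import IdMapper
from .model import Pathway, validate

__all__ = [
    "Color",
    "GradientSpec",
    "ColorRule",
    "ColumnViz",
    "VisualizationScheme",
    "gradient_color",
    "rule_color",
    "node_cells",
    "render_svg",
    "export_png",
    "load_scheme",
    "scheme_to_json",
]


@dataclass(frozen=True)
class Color:
    r: int
    g: int
    b: int

    def __post_init__(self):
        for channel in (self.r, self.g, self.b):
            if not (isinstance(channel, int) and 0 <= channel <= 255):
                raise ValueError(f"RGB channel out of range: {channel!r}")

    @classmethod
    def from_hex(cls, text: str) -> "Color":
        t = text.strip().lstrip("#")
        if len(t) != 6:
            raise ValueError(f"expected #RRGGBB, got {text!r}")
        return cls(int(t[0:2], 16), int(t[2:4], 16), int(t[4:6], 16))

    def to_hex(self) -> str:
        return f"#{self.r:02X}{self.g:02X}{self.b:02X}"


@dataclass(frozen=True)
class GradientSpec:
    """2 or 3 (value, color) anchors with strictly increasing values."""

    anchors: Tuple[Tuple[float, Color], ...]

    def __post_init__(self):
        if len(self.anchors) not in (2, 3):
            raise ValueError("gradient needs 2 or 3 anchors")
        vals = [v for v, _ in self.anchors]
        if any(b <= a for a, b in zip(vals, vals[1:])):
            raise ValueError(f"anchor values must be strictly increasing: {vals}")


@dataclass(frozen=True)
class ColorRule:
    criterion: Criterion
    color: Color


@dataclass(frozen=True)
class ColumnViz:
    """One visualization column: a gradient or an ordered rule list."""

    column_name: str
    gradient: Optional[GradientSpec] = None
    rules: Optional[Tuple[ColorRule, ...]] = None

    def __post_init__(self):
        if (self.gradient is None) == (self.rules is None):
            raise ValueError("give exactly one of gradient= or rules=")


@dataclass(frozen=True)
class VisualizationScheme:
    columns: Tuple[ColumnViz, ...]
    not_measured_color: Color = Color(192, 192, 192)
    no_match_color: Color = Color(255, 255, 255)

    def __post_init__(self):
        if not self.columns:
            raise ValueError("scheme needs at least one column")
        names = [c.column_name for c in self.columns]
        if len(set(names)) != len(names):
            raise ValueError(f"duplicate scheme columns: {names}")


def _round_half_up(x: float) -> int:
    return math.floor(x + 0.5)


def gradient_color(g: GradientSpec, v: float) -> Color:
    """Map a value through the gradient.

    Values at an anchor give that anchor's color exactly; between anchors
    channels interpolate linearly (rounded half up); outside the range the
    nearest end color is clamped."""
    anchors = g.anchors
    if v <= anchors[0][0]:
        return anchors[0][1]
    if v >= anchors[-1][0]:
        return anchors[-1][1]
    for (v0, c0), (v1, c1) in zip(anchors, anchors[1:]):
        if v0 <= v <= v1:
            if v == v0:
                return c0
            if v == v1:
                return c1
            t = (v - v0) / (v1 - v0)
            return Color(
                _round_half_up(c0.r + (c1.r - c0.r) * t),
                _round_half_up(c0.g + (c1.g - c0.g) * t),
                _round_half_up(c0.b + (c1.b - c0.b) * t),
            )
    raise AssertionError("unreachable: anchors are ordered")  # pragma: no cover


def rule_color(rules: Sequence[ColorRule], row, no_match: Color) -> Color:
    """First rule whose criterion is exactly true wins; undefined never
    matches; no rule true gives ``no_match``."""
    for rule in rules:
        if evaluate_criterion(rule.criterion, row) is True:
            return rule.color
    return no_match


def node_cells(scheme: VisualizationScheme, rows) -> List[List[Color]]:
    """The color grid painted onto one data-node box.

    One grid row per matching data row (order preserved), one grid column
    per scheme column. A node with no data gets a single row of
    ``not_measured_color``; a missing value in a gradient column blanks
    only that cell."""
    if not rows:
        return [[scheme.not_measured_color for _ in scheme.columns]]
    grid = []
    for row in rows:
        cells = []
        for col in scheme.columns:
            if col.gradient is not None:
                v = row.values.get(col.column_name)
                if v is None or isinstance(v, str):
                    cells.append(scheme.not_measured_color)
                else:
                    cells.append(gradient_color(col.gradient, v))
            else:
                cells.append(rule_color(col.rules, row, scheme.no_match_color))
        grid.append(cells)
    return grid


# ---------------------------------------------------------------------------
# scheme configuration (JSON)

def load_scheme(source) -> VisualizationScheme:
    """Parse a scheme config: JSON text, dict, or a path-like/file object.

    Layout::

        {"columns": [
            {"column": "log2FC", "method": "gradient",
             "anchors": [[-2, "#0000FF"], [0, "#FFFFFF"], [2, "#FF0000"]]},
            {"column": "pvalue", "method": "rules",
             "rules": [["[pvalue] < 0.01", "#AA0000"], ...]}],
         "not_measured_color": "#C0C0C0",
         "no_match_color": "#FFFFFF"}
    """
    if isinstance(source, dict):
        config = source
    else:
        if hasattr(source, "read"):
            text = source.read()
        else:
            text = str(source)
            if not text.lstrip().startswith("{"):
                text = Path(text).read_text(encoding="utf-8")
        try:
            config = json.loads(text)
        except json.JSONDecodeError as exc:
            raise PathoraError(f"invalid scheme JSON: {exc}") from exc

    columns = []
    for entry in config.get("columns", []):
        name = entry["column"]
        method = entry.get("method")
        if method == "gradient":
            anchors = tuple(
                (float(v), Color.from_hex(c)) for v, c in entry["anchors"]
            )
            columns.append(ColumnViz(name, gradient=GradientSpec(anchors)))
        elif method == "rules":
            rules = tuple(
                ColorRule(parse_criterion(expr), Color.from_hex(c))
                for expr, c in entry["rules"]
            )
            columns.append(ColumnViz(name, rules=rules))
        else:
            raise PathoraError(
                f"scheme column {name!r}: method must be 'gradient' or 'rules', "
                f"got {method!r}"
            )
    return VisualizationScheme(
        columns=tuple(columns),
        not_measured_color=Color.from_hex(config.get("not_measured_color", "#C0C0C0")),
        no_match_color=Color.from_hex(config.get("no_match_color", "#FFFFFF")),
    )


def scheme_to_json(scheme: VisualizationScheme) -> str:
    entries = []
    for col in scheme.columns:
        if col.gradient is not None:
            entries.append(
                {
                    "column": col.column_name,
                    "method": "gradient",
                    "anchors": [[v, c.to_hex()] for v, c in col.gradient.anchors],
                }
            )
        else:
            entries.append(
                {
                    "column": col.column_name,
                    "method": "rules",
                    "rules": [
                        [r.criterion.source_text, r.color.to_hex()] for r in col.rules
                    ],
                }
            )
    return json.dumps(
        {
            "columns": entries,
            "not_measured_color": scheme.not_measured_color.to_hex(),
            "no_match_color": scheme.no_match_color.to_hex(),
        },
        indent=2,
    ) + "\n"


# ---------------------------------------------------------------------------
# SVG rendering

def _esc(text: str) -> str:
    return (
        text.replace("&", "&amp;").replace("<", "&lt;").replace(">", "&gt;")
        .replace('"', "&quot;")
    )


def _num(x: float) -> str:
    # compact: drop a trailing .0 so coordinates read naturally
    r = repr(float(x))
    return r[:-2] if r.endswith(".0") else r


_MARKER_DEFS = """\
  <defs>
    <marker id="arrowhead" markerWidth="10" markerHeight="8" refX="9" refY="4" orient="auto" markerUnits="userSpaceOnUse">
      <path d="M 0 0 L 10 4 L 0 8 z" fill="black"/>
    </marker>
    <marker id="tbar" markerWidth="2" markerHeight="12" refX="1" refY="6" orient="auto" markerUnits="userSpaceOnUse">
      <rect x="0" y="0" width="2" height="12" fill="black"/>
    </marker>
  </defs>
"""

_MARKER_FOR = {"Arrow": "arrowhead", "TBar": "tbar"}


def render_svg(
    p: Pathway,
    scheme: Optional[VisualizationScheme] = None,
    dataset: Optional[Dataset] = None,
    mapper: Optional[IdMapper] = None,
) -> str:
    """Render a pathway (optionally with data painted on it) as SVG text.

    Every element becomes a ``<g>`` carrying its graph id; data nodes carry
    ``class="data-node"`` and, when a scheme plus dataset are supplied,
    their boxes are tiled with the :func:`node_cells` grid (columns split
    the width, rows split the height). Output is byte-deterministic.
    """
    errors = [i for i in validate(p) if i.severity == "error"]
    if errors:
        raise GpmlValidationError(
            "cannot render invalid pathway: " + "; ".join(str(i) for i in errors)
        )
    if scheme is not None and (dataset is None or mapper is None):
        raise ValueError("a scheme requires dataset and mapper")

    out = []
    out.append(
        f'<svg xmlns="http://www.w3.org/2000/svg" '
        f'width="{_num(p.board_width)}" height="{_num(p.board_height)}" '
        f'viewBox="0 0 {_num(p.board_width)} {_num(p.board_height)}">\n'
    )
    out.append(_MARKER_DEFS)
    out.append('  <rect width="100%" height="100%" fill="white"/>\n')

    for grp in p.groups:
        out.append(_render_group_box(p, grp))
    for shp in p.shapes:
        out.append(_render_shape(shp))
    for inter in p.interactions:
        out.append(_render_interaction(inter))
    for node in p.data_nodes:
        out.append(_render_datanode(node, scheme, dataset, mapper))
    for lab in p.labels:
        out.append(
            f'  <g id="{_esc(lab.graph_id)}" class="label">\n'
            f"    {_text(lab.geometry.center_x, lab.geometry.center_y, lab.text)}\n"
            "  </g>\n"
        )
    out.append("</svg>\n")
    return "".join(out)


def _text(cx: float, cy: float, text: str, clip: str = "") -> str:
    return (
        f'<text x="{_num(cx)}" y="{_num(cy)}" text-anchor="middle" '
        f'dominant-baseline="central" font-family="sans-serif" '
        f'font-size="10"{clip}>{_esc(text)}</text>'
    )


def _render_datanode(node, scheme, dataset, mapper) -> str:
    geo = node.geometry
    x = geo.center_x - geo.width / 2
    y = geo.center_y - geo.height / 2
    parts = [f'  <g id="{_esc(node.graph_id)}" class="data-node">\n']
    if scheme is not None:
        if node.xref is not None:
            rows = rows_for_xref(dataset, mapper, node.xref)
            grid = node_cells(scheme, rows)
        else:
            grid = [[scheme.not_measured_color for _ in scheme.columns]]
        n_rows, n_cols = len(grid), len(grid[0])
        cell_w, cell_h = geo.width / n_cols, geo.height / n_rows
        for i, grid_row in enumerate(grid):
            for j, color in enumerate(grid_row):
                parts.append(
                    f'    <rect class="cell" x="{_num(x + j * cell_w)}" '
                    f'y="{_num(y + i * cell_h)}" width="{_num(cell_w)}" '
                    f'height="{_num(cell_h)}" fill="{color.to_hex()}"/>\n'
                )
    parts.append(
        f'    <rect class="outline" x="{_num(x)}" y="{_num(y)}" '
        f'width="{_num(geo.width)}" height="{_num(geo.height)}" '
        f'fill="{"none" if scheme is not None else "white"}" stroke="black"/>\n'
    )
    clip_id = f"clip-{node.graph_id}"
    parts.append(
        f'    <clipPath id="{_esc(clip_id)}"><rect x="{_num(x)}" y="{_num(y)}" '
        f'width="{_num(geo.width)}" height="{_num(geo.height)}"/></clipPath>\n'
    )
    parts.append(
        "    "
        + _text(
            geo.center_x,
            geo.center_y,
            node.text_label,
            clip=f' clip-path="url(#{_esc(clip_id)})"',
        )
        + "\n"
    )
    parts.append("  </g>\n")
    return "".join(parts)


def _render_interaction(inter) -> str:
    pts = " ".join(f"{_num(wp.x)},{_num(wp.y)}" for wp in inter.waypoints)
    markers = ""
    if inter.start_arrow in _MARKER_FOR:
        markers += f' marker-start="url(#{_MARKER_FOR[inter.start_arrow]})"'
    if inter.end_arrow in _MARKER_FOR:
        markers += f' marker-end="url(#{_MARKER_FOR[inter.end_arrow]})"'
    return (
        f'  <g id="{_esc(inter.graph_id)}" class="interaction">\n'
        f'    <polyline points="{pts}" fill="none" stroke="black"{markers}/>\n'
        "  </g>\n"
    )


def _render_shape(shp) -> str:
    geo = shp.geometry
    x = geo.center_x - geo.width / 2
    y = geo.center_y - geo.height / 2
    if shp.shape_type == "Oval":
        body = (
            f'<ellipse cx="{_num(geo.center_x)}" cy="{_num(geo.center_y)}" '
            f'rx="{_num(geo.width / 2)}" ry="{_num(geo.height / 2)}" '
            f'fill="none" stroke="black"/>'
        )
    else:
        rx = {"RoundedRectangle": 8.0, "Compartment": 15.0}.get(shp.shape_type, 0.0)
        rx_attr = f' rx="{_num(rx)}"' if rx else ""
        body = (
            f'<rect x="{_num(x)}" y="{_num(y)}" width="{_num(geo.width)}" '
            f'height="{_num(geo.height)}"{rx_attr} fill="none" stroke="gray"/>'
        )
    return f'  <g id="{_esc(shp.graph_id)}" class="shape">\n    {body}\n  </g>\n'


def _render_group_box(p: Pathway, grp) -> str:
    xs, ys = [], []
    for mid in grp.member_ids:
        el = p.find(mid)
        geo = getattr(el, "geometry", None)
        if geo is not None:
            xs += [geo.center_x - geo.width / 2, geo.center_x + geo.width / 2]
            ys += [geo.center_y - geo.height / 2, geo.center_y + geo.height / 2]
    parts = [f'  <g id="{_esc(grp.graph_id)}" class="group">\n']
    if xs:
        pad = 6.0
        parts.append(
            f'    <rect x="{_num(min(xs) - pad)}" y="{_num(min(ys) - pad)}" '
            f'width="{_num(max(xs) - min(xs) + 2 * pad)}" '
            f'height="{_num(max(ys) - min(ys) + 2 * pad)}" '
            f'fill="none" stroke="gray" stroke-dasharray="4 2"/>\n'
        )
    parts.append("  </g>\n")
    return "".join(parts)


def export_png(svg_text: str, destination, scale: float = 1.0) -> None:
    """Rasterize SVG text to a PNG file at ``scale`` times board size.

    Requires the optional ``cairosvg`` dependency; without it a
    :class:`CapabilityError` is raised and the SVG path remains usable.
    """
    try:
        import cairosvg
    except ImportError as exc:
        raise CapabilityError(
            "PNG export requires the optional 'cairosvg' package "
            "(pip install pathora[png]); SVG output is always available"
        ) from exc
    try:
        cairosvg.svg2png(
            bytestring=svg_text.encode("utf-8"),
            write_to=str(destination),
            scale=scale,
        )
    except Exception as exc:
        raise PathoraError(f"PNG rasterization failed: {exc}") from exc
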