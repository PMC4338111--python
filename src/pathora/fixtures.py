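"""Synthetic pathway collections, datasets and mappings.

Everything needed to exercise the full analysis pipeline is generated from
a seed: a collection of pathways whose nodes are annotated in one synthetic
identifier system ("SysA", ids ``G000001``...), a 1:1 mapping table linking
each gene to a second system ("SysB", ids ``B000001``...), and a
differential-expression table keyed in SysB — so identifier mapping is
always on the critical path, as it is with real data.

Optionally one pathway is *planted*: its genes meet the default criterion
(|log2FC| > 1 and p < 0.05) with high probability while background genes
rarely do, giving a known-answer enrichment that over-representation
analysis must recover. Positive genes draw |log2FC| ~ U(1.5, 3) with random
sign and p ~ U(1e-4, 0.01); background genes draw log2FC ~ U(-0.5, 0.5) and
p ~ U(0.2, 0.9).

All randomness flows through one ``random.Random`` per artifact, derived
from the spec seed; no global state is touched, so every output is
byte-reproducible.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Tuple

from .gpml import write_gpml
from .model import (
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
)

__all__ = [
    "FixtureSpec",
    "generate_collection",
    "generate_dataset",
    "default_scheme_config",
    "default_criterion",
    "write_demo",
    "random_pathway",
]

#: The demo criterion, mirroring a standard differential-expression cutoff.
DEFAULT_CRITERION = "ABS([log2FC]) > 1 AND [pvalue] < 0.05"


def default_criterion() -> str:
    return DEFAULT_CRITERION


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of the synthetic world.

    Defaults give 20 pathways of 10 genes each drawn from a 200-gene
    universe, with pathway 0 planted at 90% positive genes against a 10%
    background — small enough to run in seconds, structured enough that a
    correct analysis recovers the planted pathway essentially always.
    """

    n_pathways: int = 20
    genes_per_pathway: int = 10
    gene_universe: int = 200
    planted_index: Optional[int] = 0
    positive_fraction_planted: float = 0.9
    positive_fraction_background: float = 0.1
    seed: int = 7

    def __post_init__(self):
        if self.n_pathways < 1 or self.genes_per_pathway < 1:
            raise ValueError("need at least one pathway and one gene per pathway")
        if self.genes_per_pathway > self.gene_universe:
            raise ValueError(
                f"genes_per_pathway ({self.genes_per_pathway}) exceeds "
                f"gene_universe ({self.gene_universe})"
            )
        for frac in (self.positive_fraction_planted, self.positive_fraction_background):
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"fraction out of [0, 1]: {frac}")
        if self.planted_index is not None and not (
            0 <= self.planted_index < self.n_pathways
        ):
            raise ValueError(
                f"planted_index {self.planted_index} out of range "
                f"[0, {self.n_pathways})"
            )


def _sys_a(i: int) -> Xref:
    return Xref("SysA", f"G{i + 1:06d}")


def _sys_b(i: int) -> Xref:
    return Xref("SysB", f"B{i + 1:06d}")


def generate_collection(spec: FixtureSpec) -> Tuple[PathwayCollection, str]:
    """Build the pathway collection and its SysA<->SysB mapping table.

    Each pathway samples its genes without replacement from the universe and
    lays its nodes out on a grid; the board is sized to the content.
    Deterministic for a given spec (same seed, byte-identical GPML).
    """
    rng = random.Random(spec.seed)
    coll = PathwayCollection()
    cols = 4
    node_w, node_h = 90.0, 25.0
    x_step, y_step = 130.0, 45.0
    for idx in range(spec.n_pathways):
        genes = sorted(rng.sample(range(spec.gene_universe), spec.genes_per_pathway))
        p = Pathway(
            name=f"Synthetic pathway {idx:03d}",
            organism="Synthetic organism",
            version="1",
        )
        for j, gene in enumerate(genes):
            col, row = j % cols, j // cols
            p.data_nodes.append(
                DataNode(
                    graph_id=f"n{j:03d}",
                    text_label=f"Gene{gene + 1}",
                    node_type="GeneProduct",
                    geometry=Geometry(
                        80.0 + col * x_step, 60.0 + row * y_step, node_w, node_h
                    ),
                    xref=_sys_a(gene),
                )
            )
        n_rows = (len(genes) + cols - 1) // cols
        p.board_width = 80.0 + (cols - 1) * x_step + node_w / 2 + 40.0
        p.board_height = 60.0 + (n_rows - 1) * y_step + node_h / 2 + 40.0
        coll.entries.append((f"pathway_{idx:03d}.gpml", p))

    lines = ["source_system\tsource_id\ttarget_system\ttarget_id"]
    for i in range(spec.gene_universe):
        a, b = _sys_a(i), _sys_b(i)
        lines.append(f"{a.datasource}\t{a.identifier}\t{b.datasource}\t{b.identifier}")
    return coll, "\n".join(lines) + "\n"


def generate_dataset(spec: FixtureSpec, collection: PathwayCollection) -> str:
    """Emit the expression table (TSV text) for a generated collection.

    One row per universe gene, keyed by the SysB identifier the pathways do
    NOT use, with ``log2FC`` and ``pvalue`` columns drawn as described in
    the module docstring.
    """
    rng = random.Random(spec.seed + 1_000_003)
    planted_genes = set()
    if spec.planted_index is not None:
        _, planted = collection.entries[spec.planted_index]
        for node in planted.data_nodes:
            if node.xref is not None and node.xref.datasource == "SysA":
                planted_genes.add(int(node.xref.identifier[1:]) - 1)

    lines = ["id\tlog2FC\tpvalue"]
    for i in range(spec.gene_universe):
        frac = (
            spec.positive_fraction_planted
            if i in planted_genes
            else spec.positive_fraction_background
        )
        if rng.random() < frac:
            magnitude = rng.uniform(1.5, 3.0)
            sign = rng.choice((-1.0, 1.0))
            log2fc = sign * magnitude
            pvalue = rng.uniform(0.0001, 0.01)
        else:
            log2fc = rng.uniform(-0.5, 0.5)
            pvalue = rng.uniform(0.2, 0.9)
        lines.append(f"{_sys_b(i).identifier}\t{log2fc!r}\t{pvalue!r}")
    return "\n".join(lines) + "\n"


def default_scheme_config() -> dict:
    """The demo visualization: log2FC gradient + p-value bands (as JSON-able
    config; feed to :func:`pathora.visualize.load_scheme`)."""
    return {
        "columns": [
            {
                "column": "log2FC",
                "method": "gradient",
                "anchors": [[-2.0, "#0000FF"], [0.0, "#FFFFFF"], [2.0, "#FF0000"]],
            },
            {
                "column": "pvalue",
                "method": "rules",
                "rules": [
                    ["[pvalue] < 0.01", "#B2182B"],
                    ["[pvalue] < 0.05", "#EF8A62"],
                    ["[pvalue] >= 0.05", "#FDDBC7"],
                ],
            },
        ],
        "not_measured_color": "#C0C0C0",
        "no_match_color": "#FFFFFF",
    }


def write_demo(spec: FixtureSpec, out_dir) -> dict:
    """Write a complete demo to disk: ``pathways/*.gpml``, ``idmap.tsv``,
    ``data.tsv`` and ``scheme.json``. Returns the paths."""
    import json

    out = Path(out_dir)
    pathway_dir = out / "pathways"
    pathway_dir.mkdir(parents=True, exist_ok=True)
    coll, idmap_text = generate_collection(spec)
    for filename, p in coll:
        (pathway_dir / filename).write_text(write_gpml(p), encoding="utf-8")
    (out / "idmap.tsv").write_text(idmap_text, encoding="utf-8")
    data_text = generate_dataset(spec, coll)
    (out / "data.tsv").write_text(data_text, encoding="utf-8")
    (out / "scheme.json").write_text(
        json.dumps(default_scheme_config(), indent=2) + "\n", encoding="utf-8"
    )
    return {
        "pathways": pathway_dir,
        "idmap": out / "idmap.tsv",
        "data": out / "data.tsv",
        "scheme": out / "scheme.json",
    }


# ---------------------------------------------------------------------------
# randomized pathways for property tests

_WORDS = ["kinase", "ligand", "receptor", "complex", "cycle", "flux", "decay"]
_ARROWS = ["Line", "Arrow", "TBar", "ReceptorRound", "LigandSquare"]


def random_pathway(rng: random.Random, max_nodes: int = 8) -> Pathway:
    """A structurally varied valid pathway for round-trip/property testing.

    Exercises every element kind, optional fields, comments, literature
    refs, extra attributes and groups.
    """
    p = Pathway(
        name=f"Random pathway {rng.randrange(10_000)}",
        organism=rng.choice([None, "Homo sapiens", "Mus musculus"]),
        version=rng.choice([None, "1", "20240101"]),
        board_width=800.0,
        board_height=600.0,
    )
    uid = iter(range(10_000))

    def gid(prefix: str) -> str:
        return f"{prefix}{next(uid):04x}"

    def geometry() -> Geometry:
        return Geometry(
            round(rng.uniform(50, 700), 1),
            round(rng.uniform(50, 500), 1),
            round(rng.uniform(30, 120), 1),
            round(rng.uniform(15, 60), 1),
        )

    for _ in range(rng.randint(1, max_nodes)):
        node = DataNode(
            graph_id=gid("dn"),
            text_label=rng.choice(_WORDS).capitalize(),
            node_type=rng.choice(
                ["GeneProduct", "Protein", "Rna", "Metabolite", "Unknown"]
            ),
            geometry=geometry(),
            xref=(
                Xref(
                    rng.choice(["Entrez Gene", "Ensembl", "HMDB", "SysA"]),
                    str(rng.randrange(1, 99_999)),
                )
                if rng.random() < 0.8
                else None
            ),
        )
        if rng.random() < 0.3:
            node.comments.append(f"comment {rng.randrange(100)}")
        if rng.random() < 0.2:
            node.literature_refs.append(f"ref{rng.randrange(10)}")
        if rng.random() < 0.3:
            node.graphics_extra["Color"] = f"{rng.randrange(16**6):06x}"
        p.data_nodes.append(node)

    node_ids = [n.graph_id for n in p.data_nodes]
    for _ in range(rng.randint(0, 3)):
        waypoints = [
            Waypoint(
                round(rng.uniform(0, 800), 1),
                round(rng.uniform(0, 600), 1),
                anchor_ref=(rng.choice(node_ids) if rng.random() < 0.5 else None),
            )
            for _ in range(rng.randint(2, 4))
        ]
        p.interactions.append(
            Interaction(
                graph_id=gid("in"),
                waypoints=waypoints,
                start_arrow=rng.choice(_ARROWS),
                end_arrow=rng.choice(_ARROWS),
                graphical_line=rng.random() < 0.2,
            )
        )
    for _ in range(rng.randint(0, 2)):
        p.labels.append(
            Label(graph_id=gid("lb"), text=rng.choice(_WORDS), geometry=geometry())
        )
    for _ in range(rng.randint(0, 2)):
        p.shapes.append(
            Shape(
                graph_id=gid("sh"),
                shape_type=rng.choice(
                    ["Rectangle", "Oval", "RoundedRectangle", "Compartment"]
                ),
                geometry=geometry(),
            )
        )
    if len(node_ids) >= 2 and rng.random() < 0.5:
        # member order follows document order (what GPML round-trips preserve)
        chosen = set(rng.sample(node_ids, 2))
        members = [nid for nid in node_ids if nid in chosen]
        p.groups.append(
            Group(
                graph_id=gid("gr"),
                member_ids=members,
                label=rng.choice([None, "module"]),
            )
        )
    # board always covers content; avoid bbox warnings in strict tests
    p.board_width = 1000.0
    p.board_height = 800.0
    return p
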