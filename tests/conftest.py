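import random

import pytest

from pathora import (
    DataNode,
    Geometry,
    Interaction,
    Pathway,
    Waypoint,
    Xref,
)
from pathora.fixtures import FixtureSpec, generate_collection, generate_dataset
from pathora.idmap import load_mapping_table
from pathora.dataset import import_data_table

# a hand-written 2013a document: the KNG1 gene annotated with Entrez Gene 3827
KNG1_GPML = """<?xml version="1.0" encoding="UTF-8"?>
<Pathway xmlns="http://pathvisio.org/GPML/2013a" Name="Kinin cascade" Organism="Homo sapiens">
  <Graphics BoardWidth="300.0" BoardHeight="200.0"/>
  <DataNode TextLabel="KNG1" GraphId="a1b" Type="GeneProduct">
    <Graphics CenterX="150.0" CenterY="100.0" Width="90.0" Height="25.0"/>
    <Xref Database="Entrez Gene" ID="3827"/>
  </DataNode>
  <InfoBox CenterX="0.0" CenterY="0.0"/>
</Pathway>
"""


@pytest.fixture
def kng1_document():
    return KNG1_GPML


def make_node(gid, label="X", xref=None, node_type="GeneProduct", cx=100.0, cy=100.0):
    return DataNode(
        graph_id=gid,
        text_label=label,
        node_type=node_type,
        geometry=Geometry(cx, cy, 90.0, 25.0),
        xref=xref,
    )


def make_interaction(gid, points=((10.0, 10.0), (90.0, 90.0)), **kw):
    return Interaction(
        graph_id=gid,
        waypoints=[Waypoint(x, y) for x, y in points],
        **kw,
    )


@pytest.fixture
def simple_pathway():
    p = Pathway(name="Simple", board_width=400.0, board_height=300.0)
    p.data_nodes.append(make_node("n1", "KNG1", Xref("Entrez Gene", "3827")))
    p.data_nodes.append(make_node("n2", "BDKRB2", Xref("Entrez Gene", "624"), cy=150.0))
    p.data_nodes.append(make_node("n3", "orphan", None, cy=200.0))
    p.interactions.append(make_interaction("e1", end_arrow="Arrow"))
    return p


@pytest.fixture(scope="session")
def demo_world():
    """A fully generated synthetic world shared by read-only tests."""
    spec = FixtureSpec(seed=7)
    coll, idmap_text = generate_collection(spec)
    mapper = load_mapping_table(idmap_text)
    dataset = import_data_table(
        generate_dataset(spec, coll), id_column="id", system="SysB"
    )
    return spec, coll, mapper, dataset


@pytest.fixture
def rng():
    return random.Random(20240917)
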