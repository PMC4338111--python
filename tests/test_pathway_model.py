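"""Pathway model, GPML I/O and validation."""

import random
import xml.etree.ElementTree as ET

import pytest

from pathora import (
    GpmlParseError,
    GpmlValidationError,
    Pathway,
    UnsupportedDialectError,
    Xref,
    annotated_xrefs,
    read_gpml,
    validate,
    write_datanode_list,
    write_gpml,
)
from pathora.gpml import GPML_2013A, load_collection
from pathora.fixtures import FixtureSpec, generate_collection, random_pathway

from conftest import make_interaction, make_node


def _local_tags(document, tag):
    root = ET.fromstring(document)
    return [el for el in root.iter() if el.tag == f"{{{GPML_2013A}}}{tag}"]


class TestXref:
    def test_empty_fields_rejected(self):
        with pytest.raises(ValueError):
            Xref("", "3827")
        with pytest.raises(ValueError):
            Xref("Entrez Gene", "")

    def test_equality_is_case_sensitive(self):
        assert Xref("HGNC", "KNG1") == Xref("HGNC", "KNG1")
        assert Xref("HGNC", "KNG1") != Xref("HGNC", "kng1")
        assert Xref("HGNC", "KNG1") != Xref("hgnc", "KNG1")


class TestReadGpml:
    def test_kng1_annotation(self, kng1_document):
        p = read_gpml(kng1_document)
        assert p.name == "Kinin cascade"
        assert len(p.data_nodes) == 1
        node = p.data_nodes[0]
        assert node.text_label == "KNG1"
        assert node.xref == Xref("Entrez Gene", "3827")
        assert node.geometry.center_x == 150.0
        # the InfoBox survives opaquely
        assert any("InfoBox" in frag for frag in p.opaque_children)

    def test_roundtrip_via_text(self, kng1_document):
        p1 = read_gpml(kng1_document)
        p2 = read_gpml(write_gpml(p1))
        assert p1 == p2

    def test_malformed_xml_names_line(self):
        bad = "<Pathway xmlns='http://pathvisio.org/GPML/2013a'>\n<broken\n"
        with pytest.raises(GpmlParseError, match=r"line \d+"):
            read_gpml(bad)

    def test_unrecognized_namespace(self):
        doc = '<Pathway xmlns="http://example.org/not-gpml" Name="x"/>'
        with pytest.raises(UnsupportedDialectError):
            read_gpml(doc)

    def test_duplicate_graph_id_rejected(self, kng1_document):
        doc = kng1_document.replace(
            "<InfoBox",
            '<DataNode TextLabel="dup" GraphId="a1b" Type="GeneProduct">'
            '<Graphics CenterX="10.0" CenterY="10.0" Width="9.0" Height="9.0"/>'
            '<Xref Database="" ID=""/></DataNode><InfoBox',
        )
        with pytest.raises(GpmlValidationError, match="a1b"):
            read_gpml(doc)

    def test_2010a_namespace_normalized(self, kng1_document):
        old = kng1_document.replace(
            "http://pathvisio.org/GPML/2013a", "http://genmapp.org/GPML/2010a"
        )
        p = read_gpml(old)
        assert p.data_nodes[0].xref == Xref("Entrez Gene", "3827")
        assert GPML_2013A in write_gpml(p)

    def test_unknown_attributes_preserved(self, kng1_document):
        doc = kng1_document.replace(
            'Organism="Homo sapiens"', 'Organism="Homo sapiens" License="CC0"'
        )
        out = write_gpml(read_gpml(doc))
        assert 'License="CC0"' in out


class TestWriteGpml:
    def test_empty_pathway_minimal_document(self):
        out = write_gpml(Pathway(name="Empty"))
        root = ET.fromstring(out)
        assert root.tag == f"{{{GPML_2013A}}}Pathway"
        assert root.get("Name") == "Empty"
        graphics = root.find(f"{{{GPML_2013A}}}Graphics")
        assert graphics is not None
        assert float(graphics.get("BoardWidth")) > 0

    def test_three_nodes_three_elements(self, simple_pathway):
        out = write_gpml(simple_pathway)
        assert len(_local_tags(out, "DataNode")) == 3

    def test_missing_xref_written_as_empty_element(self, simple_pathway):
        out = write_gpml(simple_pathway)
        nodes = _local_tags(out, "DataNode")
        orphan = [n for n in nodes if n.get("TextLabel") == "orphan"]
        (xref,) = orphan[0].findall(f"{{{GPML_2013A}}}Xref")
        assert xref.get("Database") == "" and xref.get("ID") == ""

    def test_invalid_pathway_refuses_to_write(self, simple_pathway):
        simple_pathway.data_nodes[0].geometry.width = 0.0
        with pytest.raises(GpmlValidationError):
            write_gpml(simple_pathway)

    def test_write_is_deterministic(self, simple_pathway):
        assert write_gpml(simple_pathway) == write_gpml(simple_pathway)


class TestRoundTripProperty:
    def test_random_pathways_roundtrip(self, rng):
        # 30 here; the 100-pathway sweep lives in the acceptance suite
        for _ in range(30):
            p = random_pathway(rng)
            text = write_gpml(p)
            assert read_gpml(text) == p
            assert write_gpml(read_gpml(text)) == text


class TestValidate:
    def test_valid_pathway_is_clean(self, simple_pathway):
        assert validate(simple_pathway) == []

    def test_dangling_anchor_ref(self, simple_pathway):
        simple_pathway.interactions[0].waypoints[0].anchor_ref = "ghost"
        issues = validate(simple_pathway)
        assert any("ghost" in i.message and i.severity == "error" for i in issues)

    def test_zero_width(self, simple_pathway):
        simple_pathway.data_nodes[0].geometry.width = 0.0
        issues = validate(simple_pathway)
        assert any(i.severity == "error" and i.graph_id == "n1" for i in issues)

    @pytest.mark.parametrize(
        "corrupt",
        [
            lambda p: p.data_nodes.append(make_node("n1")),  # duplicate id
            lambda p: setattr(p.data_nodes[0], "node_type", "Gene"),
            lambda p: setattr(p.data_nodes[0].geometry, "height", -1.0),
            lambda p: p.interactions.append(
                make_interaction("e2", points=((0.0, 0.0),))
            ),
            lambda p: p.groups.append(
                __import__("pathora").Group(graph_id="g1", member_ids=["nope"])
            ),
        ],
        ids=["dup-id", "bad-node-type", "neg-height", "one-waypoint", "bad-member"],
    )
    def test_single_corruption_detected(self, simple_pathway, corrupt):
        corrupt(simple_pathway)
        assert any(i.severity == "error" for i in validate(simple_pathway))


class TestCollection:
    def test_mixed_directory(self, tmp_path, simple_pathway):
        (tmp_path / "a.gpml").write_text(write_gpml(simple_pathway))
        (tmp_path / "b.gpml").write_text(write_gpml(Pathway(name="B")))
        (tmp_path / "c.gpml").write_text("<not xml")
        coll = load_collection(tmp_path)
        assert [name for name, _ in coll] == ["a.gpml", "b.gpml"]
        assert len(coll.warnings) == 1 and "c.gpml" in coll.warnings[0]

    def test_empty_directory(self, tmp_path):
        coll = load_collection(tmp_path)
        assert len(coll) == 0
        assert coll.warnings

    def test_generated_collection_loads_in_filename_order(self, tmp_path):
        from pathora.fixtures import write_demo

        write_demo(FixtureSpec(n_pathways=20, seed=3), tmp_path)
        coll = load_collection(tmp_path / "pathways")
        assert len(coll) == 20
        names = [name for name, _ in coll]
        assert names == sorted(names)
        assert not coll.warnings


class TestAnnotatedXrefs:
    def test_duplicate_annotations_collapse(self):
        p = Pathway(name="dup", board_width=400, board_height=400)
        x = Xref("Entrez Gene", "3827")
        p.data_nodes += [make_node("n1", xref=x), make_node("n2", xref=x, cy=150.0)]
        assert annotated_xrefs(p) == {x}

    def test_labels_and_shapes_do_not_count(self, simple_pathway):
        simple_pathway.data_nodes.clear()
        assert annotated_xrefs(simple_pathway) == set()

    def test_type_filter(self):
        p = Pathway(name="mix", board_width=400, board_height=400)
        p.data_nodes += [
            make_node("n1", xref=Xref("Entrez Gene", "1")),
            make_node("n2", xref=Xref("HMDB", "HMDB01"), node_type="Metabolite", cy=150.0),
        ]
        assert annotated_xrefs(p) == {Xref("Entrez Gene", "1")}
        assert annotated_xrefs(p, {"Metabolite"}) == {Xref("HMDB", "HMDB01")}

    def test_fixture_bookkeeping(self, demo_world):
        spec, coll, _, _ = demo_world
        for _, p in coll:
            assert len(annotated_xrefs(p)) == spec.genes_per_pathway


def test_datanode_list_export(simple_pathway):
    text = write_datanode_list(simple_pathway)
    lines = text.rstrip("\n").split("\n")
    assert lines[0] == "text_label\tnode_type\tdatasource\tidentifier"
    assert lines[1] == "KNG1\tGeneProduct\tEntrez Gene\t3827"
    assert lines[3] == "orphan\tGeneProduct\t\t"
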