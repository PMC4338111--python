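"""Over-representation analysis: counts, z-score, ranking, report."""

import math
import random

import pytest

from pathora import (
    Pathway,
    PathwayCollection,
    Xref,
    global_counts,
    import_data_table,
    pathway_counts,
    run_ora,
    write_ora_report,
    zscore,
)
from pathora.criteria import parse_criterion
from pathora.idmap import IdMapper, load_mapping_table

from conftest import make_node
from oracles import zscore_oracle

CRIT = "ABS([log2FC]) > 1 AND [pvalue] < 0.05"


def pathway_of(name, xrefs):
    p = Pathway(name=name, board_width=2000.0, board_height=2000.0)
    for i, x in enumerate(xrefs):
        p.data_nodes.append(make_node(f"n{i}", xref=x, cx=100.0 + (i % 8) * 110.0,
                                      cy=100.0 + (i // 8) * 50.0))
    return p


def table_for(rows):
    lines = ["id\tlog2FC\tpvalue"]
    lines += [f"{ident}\t{fc}\t{p}" for ident, fc, p in rows]
    return import_data_table("\n".join(lines) + "\n", id_column="id", system="S")


class TestZscore:
    def test_zero_when_observed_equals_expected(self):
        assert zscore(n=10, r=2, N=100, R=20) == 0.0

    def test_matches_rational_oracle(self):
        z = zscore(n=10, r=5, N=100, R=20)
        assert z == pytest.approx(zscore_oracle(10, 5, 100, 20), abs=1e-12)

    def test_degenerate_variance_is_undefined(self):
        assert zscore(n=5, r=0, N=50, R=0) is None
        assert zscore(n=0, r=0, N=50, R=10) is None
        assert zscore(n=50, r=10, N=50, R=10) is None
        assert zscore(n=5, r=5, N=50, R=50) is None

    def test_sign_tracks_enrichment_direction(self):
        assert zscore(n=10, r=5, N=100, R=20) > 0   # more than expected 2
        assert zscore(n=10, r=1, N=100, R=20) < 0   # fewer than expected

    def test_strictly_increasing_in_r(self):
        values = [zscore(n=10, r=r, N=100, R=20) for r in range(11)]
        assert all(b > a for a, b in zip(values, values[1:]))

    def test_invalid_counts_raise(self):
        with pytest.raises(ValueError):
            zscore(n=5, r=6, N=50, R=10)
        with pytest.raises(ValueError):
            zscore(n=60, r=1, N=50, R=10)

    def test_variance_factor_forms_agree(self):
        rng = random.Random(3)
        for _ in range(200):
            N = rng.randint(2, 1000)
            n = rng.randint(2, N)
            assert (1 - (n - 1) / (N - 1)) == pytest.approx(
                (N - n) / (N - 1), abs=1e-12
            )


class TestPathwayCounts:
    def test_direct_count(self):
        xrefs = [Xref("S", f"G{i}") for i in range(4)]
        p = pathway_of("P", xrefs)
        d = table_for([("G0", 2.0, 0.01), ("G1", 0.1, 0.5), ("G2", 0.0, 0.9)])
        c = parse_criterion(CRIT)
        assert pathway_counts(p, d, IdMapper(), c) == (4, 3, 1)

    def test_unannotated_nodes_count_nothing(self):
        p = pathway_of("P", [None, None])
        d = table_for([("G0", 2.0, 0.01)])
        assert pathway_counts(p, d, IdMapper(), parse_criterion(CRIT)) == (0, 0, 0)

    def test_duplicate_xref_collapses(self):
        x = Xref("S", "G0")
        p = pathway_of("P", [x, x])
        d = table_for([("G0", 2.0, 0.01)])
        assert pathway_counts(p, d, IdMapper(), parse_criterion(CRIT)) == (1, 1, 1)

    def test_multiple_rows_one_gene_any_row_true(self):
        p = pathway_of("P", [Xref("S", "G0")])
        d = table_for([("G0", 0.0, 0.9), ("G0", 2.0, 0.01)])
        assert pathway_counts(p, d, IdMapper(), parse_criterion(CRIT)) == (1, 1, 1)

    def test_counts_through_mapping(self):
        header = "source_system\tsource_id\ttarget_system\ttarget_id"
        m = load_mapping_table(f"{header}\nS\tG0\tT\tX0\n")
        p = pathway_of("P", [Xref("T", "X0")])
        d = table_for([("G0", 2.0, 0.01)])
        assert pathway_counts(p, d, m, parse_criterion(CRIT)) == (1, 1, 1)


class TestGlobalCounts:
    def test_genes_outside_pathways_ignored(self):
        coll = PathwayCollection(
            entries=[("a.gpml", pathway_of("A", [Xref("S", "G0"), Xref("S", "G1"),
                                                 Xref("S", "G2")]))]
        )
        d = table_for([(f"G{i}", 0.0, 0.5) for i in range(5)])  # 5 measured
        N, R = global_counts(coll, d, IdMapper(), parse_criterion(CRIT))
        assert (N, R) == (3, 0)

    def test_shared_gene_counted_once(self):
        shared = Xref("S", "G0")
        coll = PathwayCollection(
            entries=[
                ("a.gpml", pathway_of("A", [shared])),
                ("b.gpml", pathway_of("B", [shared])),
            ]
        )
        d = table_for([("G0", 2.0, 0.01)])
        assert global_counts(coll, d, IdMapper(), parse_criterion(CRIT)) == (1, 1)


class TestRunOra:
    def test_pathway_with_all_positives_ranks_first(self, demo_world):
        spec, coll, mapper, dataset = demo_world
        report = run_ora(coll, dataset, mapper, CRIT)
        assert report.rows[0].source_file == "pathway_000.gpml"
        assert report.rows[0].z == max(r.z for r in report.rows if r.z is not None)
        assert report.N >= report.R >= 0
        for row in report.rows:
            assert 0 <= row.r <= row.n <= row.total
            assert row.n <= report.N

    def test_no_positives_all_undefined(self):
        coll = PathwayCollection(entries=[("a.gpml", pathway_of("A", [Xref("S", "G0")]))])
        d = table_for([("G0", 0.0, 0.9)])
        report = run_ora(coll, d, IdMapper(), CRIT)
        assert report.R == 0
        assert all(row.z is None for row in report.rows)
        assert report.warnings

    def test_identical_pathways_tie_break_by_name(self):
        xrefs = [Xref("S", f"G{i}") for i in range(3)]
        coll = PathwayCollection(
            entries=[
                ("z.gpml", pathway_of("Zeta", xrefs)),
                ("a.gpml", pathway_of("Alpha", xrefs)),
            ]
        )
        d = table_for(
            [("G0", 2.0, 0.01), ("G1", 0.0, 0.9), ("G2", 0.0, 0.9),
             ("G9", 0.0, 0.9)]
        )
        # add a background pathway so variance is defined
        coll.entries.append(("bg.gpml", pathway_of("Background", [Xref("S", "G9")])))
        report = run_ora(coll, d, IdMapper(), CRIT)
        assert report.rows[0].pathway_name == "Alpha"
        assert report.rows[1].pathway_name == "Zeta"
        assert report.rows[0].z == report.rows[1].z

    def test_parse_error_propagates_before_counting(self):
        from pathora import CriterionSyntaxError

        with pytest.raises(CriterionSyntaxError):
            run_ora(PathwayCollection(), table_for([]), IdMapper(), "[a] >")


class TestReport:
    def test_layout_and_na(self):
        coll = PathwayCollection(
            entries=[
                ("a.gpml", pathway_of("A", [Xref("S", "G0"), Xref("S", "G1")])),
                ("b.gpml", pathway_of("B", [Xref("S", "G2")])),
                ("c.gpml", pathway_of("C", [])),
            ]
        )
        d = table_for([("G0", 2.0, 0.01), ("G1", 0.0, 0.9), ("G2", 0.0, 0.9)])
        report = run_ora(coll, d, IdMapper(), CRIT)
        text = write_ora_report(report)
        lines = text.strip().split("\n")
        assert len(lines) == 4  # header + 3 rows
        assert lines[0].startswith("pathway\tfile\ttotal\tmeasured\tpositive\tzscore")
        assert lines[-1].split("\t")[5] == "NA"  # n == 0 pathway sorts last

    def test_roundtrip_recovers_counts_exactly(self, demo_world, tmp_path):
        _, coll, mapper, dataset = demo_world
        report = run_ora(coll, dataset, mapper, CRIT)
        out = tmp_path / "report.tsv"
        write_ora_report(report, out)
        lines = out.read_text().strip().split("\n")[1:]
        assert len(lines) == len(report.rows)
        for line, row in zip(lines, report.rows):
            fields = line.split("\t")
            assert [int(fields[2]), int(fields[3]), int(fields[4])] == [
                row.total,
                row.n,
                row.r,
            ]
            if row.z is not None:
                assert float(fields[6]) == row.z
                assert float(fields[5]) == pytest.approx(row.z, abs=0.005)
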