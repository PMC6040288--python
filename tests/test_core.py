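"""Domain types, readers/writers, and their round-trip identities."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import phytonet as pn


class TestCompoundTable:
    def test_reference_table_shape_and_first_row(self, reference_table):
        assert len(reference_table) == 32
        first = next(iter(reference_table))
        assert first.compound_id == "M1"
        assert first.ob == pytest.approx(54.04)
        assert reference_table["M7"].dl == pytest.approx(0.39)

    def test_header_only_file_gives_empty_table(self, tmp_path):
        p = tmp_path / "empty.tsv"
        p.write_text("id\tname\tob\tbbb\tdl\n")
        assert len(pn.read_compound_table(p)) == 0

    def test_duplicate_id_rejected(self, tmp_path):
        p = tmp_path / "dup.tsv"
        p.write_text("id\tname\tob\tbbb\tdl\nM7\ta\t1\t1\t1\nM7\tb\t2\t2\t2\n")
        with pytest.raises(pn.DataError, match="M7"):
            pn.read_compound_table(p)

    def test_missing_column_names_the_column(self, tmp_path):
        p = tmp_path / "miss.tsv"
        p.write_text("id\tname\tob\tbbb\n")
        with pytest.raises(pn.ConfigurationError, match="dl"):
            pn.read_compound_table(p)

    def test_unparsable_cell_names_row_and_column(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text("id\tname\tob\tbbb\tdl\nM1\tx\tfifty\t1\t0.2\n")
        with pytest.raises(pn.DataError, match=r"row 2.*ob"):
            pn.read_compound_table(p)

    def test_dialect_maps_column_names(self, tmp_path):
        p = tmp_path / "alt.tsv"
        p.write_text("ID\tActive compounds\tOB\tBBB\tDL\nM1\tx\t54.04\t2.07\t0.1\n")
        t = pn.read_compound_table(
            p, dialect={"id": "ID", "name": "Active compounds",
                        "ob": "OB", "bbb": "BBB", "dl": "DL"}
        )
        assert t["M1"].bbb == pytest.approx(2.07)

    def test_roundtrip_write_read(self, reference_table, tmp_path):
        p = tmp_path / "rt.tsv"
        pn.write_compound_table(reference_table, p)
        back = pn.read_compound_table(p)
        assert back.ids == reference_table.ids
        assert back["M23"].bbb == reference_table["M23"].bbb

    def test_non_finite_property_rejected(self):
        with pytest.raises(pn.DataError, match="finite"):
            pn.CompoundRecord("M1", "x", ob=float("nan"), bbb=0.0, dl=0.1)


class TestInteractionTable:
    def test_case_normalization_collapses_duplicates(self, tmp_path):
        p = tmp_path / "i.tsv"
        p.write_text("M7\tCHRM1\nM7\tchrm1\n")
        t = pn.read_interaction_table(p)
        assert t.edges == [("M7", "CHRM1")]

    def test_distinct_pairs_kept(self, tmp_path):
        p = tmp_path / "i.tsv"
        p.write_text("compound_id\ttarget\nM7\tCHRM1\nM9\tACHE\n")
        assert len(pn.read_interaction_table(p)) == 2

    def test_empty_symbol_reports_row(self, tmp_path):
        p = tmp_path / "i.tsv"
        p.write_text("M7\tCHRM1\nM7\t\n")
        with pytest.raises(pn.DataError, match="row 2"):
            pn.read_interaction_table(p)


class TestGmt:
    def test_parse_sets(self, tmp_path):
        p = tmp_path / "a.gmt"
        p.write_text("S1\tdesc\tA\tB\nS2\tdesc\tb\tC\tD\n")
        coll = pn.read_gmt(p)
        assert coll.sets["S1"].genes == frozenset({"A", "B"})
        assert coll.sets["S2"].genes == frozenset({"B", "C", "D"})

    @pytest.mark.parametrize(
        "body, pattern",
        [
            ("S1\tdesc\tA\nS1\tdesc\tB\n", "duplicate"),
            ("S1\tdesc\n", ">= 3"),
            ("S1\tdesc\tA\t\tB\n", "empty gene"),
        ],
    )
    def test_malformed_lines_rejected(self, tmp_path, body, pattern):
        p = tmp_path / "a.gmt"
        p.write_text(body)
        with pytest.raises(pn.DataError, match=pattern):
            pn.read_gmt(p)

    def test_roundtrip(self, tmp_path):
        coll = pn.AnnotationCollection(
            sets={"S1": pn.GeneSet("S1", frozenset({"A", "B"}), "d")}
        )
        p = tmp_path / "rt.gmt"
        pn.write_gmt(coll, p)
        assert pn.read_gmt(p).sets["S1"].genes == coll.sets["S1"].genes


class TestNetworkIO:
    def test_sif_single_edge(self, tmp_path):
        net = pn.BipartiteNetwork({"M1"}, {"CHRM1"}, [("M1", "CHRM1")])
        p = tmp_path / "n.sif"
        pn.write_network(net, p, "sif")
        assert p.read_text() == "M1\ttargets\tCHRM1\n"

    def test_empty_network_sif(self, tmp_path):
        net = pn.BipartiteNetwork(set(), set(), [])
        p = tmp_path / "n.sif"
        pn.write_network(net, p, "sif")
        assert p.read_text() == ""

    def test_unknown_format_rejected(self, tmp_path, tiny_net):
        with pytest.raises(pn.ConfigurationError, match="xml"):
            pn.write_network(tiny_net, tmp_path / "n.xml", "xml")

    def test_graphml_roundtrip_on_synthetic_net(self, tmp_path):
        cfg = pn.GeneratorConfig(
            seed=5, n_compounds=5, n_targets=7, pass_fraction=1.0,
            targetless_fraction=0.0, mean_degree=3.0,
        )
        compounds, _ = pn.gen_compound_table(cfg)
        interactions, _ = pn.gen_interactions(cfg, compounds)
        net = pn.build_ct_network(compounds, interactions)
        p = tmp_path / "n.graphml"
        pn.write_network(net, p, "graphml")
        back = pn.read_network_graphml(p)
        assert back == net
        assert pn.summarize(back) == pn.summarize(net)


class TestExpressionMatrix:
    def test_missing_cells_rejected(self):
        df = pd.DataFrame({"t1": [1.0, np.nan], "t2": [2.0, 3.0]}, index=["A", "B"])
        with pytest.raises(pn.DataError, match="missing"):
            pn.ExpressionMatrix(df)

    def test_duplicate_tissue_rejected(self):
        df = pd.DataFrame([[1.0, 2.0]], index=["A"], columns=["t1", "t1"])
        with pytest.raises(pn.DataError, match="duplicate tissue"):
            pn.ExpressionMatrix(df)

    def test_negative_values_rejected(self):
        df = pd.DataFrame({"t1": [-1.0]}, index=["A"])
        with pytest.raises(pn.DataError, match="non-negative"):
            pn.ExpressionMatrix(df)

    def test_probes_collapse_by_mean(self):
        df = pd.DataFrame({"t1": [1.0, 3.0], "t2": [4.0, 6.0]}, index=["A", "A"])
        m = pn.ExpressionMatrix(df)
        assert m.row("A").tolist() == [2.0, 5.0]

    def test_roundtrip(self, tmp_path):
        df = pd.DataFrame({"t1": [1.0, 2.5], "t2": [0.0, 3.0]}, index=["A", "B"])
        m = pn.ExpressionMatrix(df)
        p = tmp_path / "e.tsv"
        pn.write_expression_matrix(m, p)
        back = pn.read_expression_matrix(p)
        pd.testing.assert_frame_equal(back.frame, m.frame)


class TestInvariants:
    @given(st.text(max_size=30))
    @settings(max_examples=100, deadline=None)
    def test_symbol_normalization_idempotent(self, s):
        once = pn.normalize_symbol(s)
        assert pn.normalize_symbol(once) == once

    def test_bipartite_invariants_enforced(self):
        with pytest.raises(pn.DataError, match="disjoint"):
            pn.BipartiteNetwork({"X"}, {"X"}, [("X", "X")])
        with pytest.raises(pn.DataError, match="isolated"):
            pn.BipartiteNetwork({"C1", "C2"}, {"T"}, [("C1", "T")])
        with pytest.raises(pn.DataError, match="unknown"):
            pn.BipartiteNetwork({"C1"}, {"T"}, [("C2", "T")])

    def test_degree_sums_equal_edge_count(self, tiny_net):
        comp = sum(tiny_net.degree(c) for c in tiny_net.compound_nodes)
        targ = sum(tiny_net.degree(t) for t in tiny_net.target_nodes)
        assert comp == targ == tiny_net.n_edges
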