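"""Synthetic generators: determinism, ground-truth consistency, feasibility."""

import json

import pytest

import phytonet as pn
from phytonet.synth import target_symbols


class TestConfig:
    def test_seed_is_mandatory_and_validated(self):
        with pytest.raises(TypeError):
            pn.GeneratorConfig()
        with pytest.raises(pn.ConfigurationError):
            pn.GeneratorConfig(seed=-1)

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"pass_fraction": 1.5},
            {"ob_range": (50.0, 10.0)},
            {"n_compounds": 0},
        ],
    )
    def test_invalid_fields_rejected(self, kwargs):
        with pytest.raises(pn.ConfigurationError):
            pn.GeneratorConfig(seed=1, **kwargs)


class TestCompoundGenerator:
    def test_screen_recovers_engineered_pass_set(self):
        cfg = pn.GeneratorConfig(seed=1)
        table, truth = pn.gen_compound_table(cfg)
        assert len(table) == 105
        assert len(truth.passing_compounds) == 30
        filtered, _ = pn.filter_compounds(table)
        assert filtered.ids == truth.passing_compounds

    def test_same_seed_identical_different_seed_not(self):
        a, _ = pn.gen_compound_table(pn.GeneratorConfig(seed=5))
        b, _ = pn.gen_compound_table(pn.GeneratorConfig(seed=5))
        c, _ = pn.gen_compound_table(pn.GeneratorConfig(seed=6))
        assert a == b
        assert a != c

    def test_pass_fraction_one_makes_filter_identity(self):
        table, _ = pn.gen_compound_table(
            pn.GeneratorConfig(seed=2, n_compounds=20, pass_fraction=1.0)
        )
        filtered, _ = pn.filter_compounds(table)
        assert filtered.ids == table.ids

    def test_ranges_unable_to_fail_rejected(self):
        with pytest.raises(pn.ConfigurationError):
            pn.gen_compound_table(
                pn.GeneratorConfig(
                    seed=1, pass_fraction=0.5,
                    ob_range=(20.0, 80.0), bbb_range=(0.0, 2.0), dl_range=(0.2, 0.8),
                )
            )


class TestInteractionGenerator:
    def test_edge_budget_and_target_coverage(self):
        cfg = pn.GeneratorConfig(seed=7)
        compounds, _ = pn.gen_compound_table(cfg)
        interactions, truth = pn.gen_interactions(cfg, compounds)
        active = 105 - len(truth.targetless_compounds)
        assert len(interactions) == round(cfg.mean_degree * active)
        assert interactions.targets == set(target_symbols(181))
        realized = len(interactions) / active
        assert abs(realized - cfg.mean_degree) / cfg.mean_degree <= 0.10

    def test_all_targetless_gives_empty_table(self):
        cfg = pn.GeneratorConfig(seed=7, targetless_fraction=1.0)
        compounds, _ = pn.gen_compound_table(cfg)
        interactions, truth = pn.gen_interactions(cfg, compounds)
        assert len(interactions) == 0
        assert len(truth.targetless_compounds) == 105

    def test_unattainable_coverage_rejected(self):
        cfg = pn.GeneratorConfig(
            seed=7, n_compounds=5, pass_fraction=1.0,
            targetless_fraction=0.0, mean_degree=2.0, n_targets=50,
        )
        compounds, _ = pn.gen_compound_table(cfg)
        with pytest.raises(pn.ConfigurationError, match="cover"):
            pn.gen_interactions(cfg, compounds)

    def test_determinism(self):
        cfg = pn.GeneratorConfig(seed=9)
        compounds, _ = pn.gen_compound_table(cfg)
        a, _ = pn.gen_interactions(cfg, compounds)
        b, _ = pn.gen_interactions(cfg, compounds)
        assert a == b


class TestAnnotationGenerator:
    BG = pn.GeneSet("bg", frozenset(f"G{i:04d}" for i in range(500)))

    def test_shapes_and_planting(self):
        cfg = pn.GeneratorConfig(seed=3)
        coll, query, truth = pn.gen_annotation_collection(cfg, self.BG)
        assert len(coll) == 20
        assert all(len(s) == 25 for s in coll.sets.values())
        assert len(query.genes) == 40
        planted = coll.sets[truth.planted_set_ids[0]]
        assert len(query.genes & planted.genes) >= 15

    def test_small_background_rejected(self):
        tiny = pn.GeneSet("bg", frozenset(f"G{i}" for i in range(10)))
        with pytest.raises(pn.ConfigurationError, match="50"):
            pn.gen_annotation_collection(pn.GeneratorConfig(seed=1), tiny)

    def test_overlap_exceeding_set_size_rejected(self):
        cfg = pn.GeneratorConfig(seed=1, set_size_range=(5, 5), planted_overlap=15)
        with pytest.raises(pn.ConfigurationError, match="exceeds"):
            pn.gen_annotation_collection(cfg, self.BG)

    def test_no_planting_yields_mostly_null_results(self):
        significant_runs = 0
        for seed in range(10):
            cfg = pn.GeneratorConfig(seed=seed, planted_sets=0)
            coll, query, _ = pn.gen_annotation_collection(cfg, self.BG)
            rows = pn.enrich(query, coll)
            if any(r.significant for r in rows):
                significant_runs += 1
        assert significant_runs <= 1  # >= 90% of runs have no significant set


class TestExpressionGenerator:
    def test_omission_and_planted_tissue_bookkeeping(self):
        cfg = pn.GeneratorConfig(seed=4)
        genes = target_symbols(181)
        expr, truth = pn.gen_expression_matrix(cfg, genes)
        assert len(truth.unprofiled_genes) == round(6 / 181 * 181)
        assert len(expr.genes) == 181 - len(truth.unprofiled_genes)
        assert set(truth.primary_tissue) == set(expr.genes)

    @pytest.mark.parametrize(
        "kwargs", [{"n_tissues": 1}, {"elevation_factor": 1.5}]
    )
    def test_degenerate_configs_rejected(self, kwargs):
        cfg = pn.GeneratorConfig(seed=4, **kwargs)
        with pytest.raises(pn.ConfigurationError):
            pn.gen_expression_matrix(cfg, ["A", "B", "C"])


class TestBundle:
    def test_truth_revalidates_against_emitted_files(self, bundle):
        cfg, truth, outdir = bundle
        table = pn.read_compound_table(outdir / "compounds.tsv")
        filtered, _ = pn.filter_compounds(table)
        assert filtered.ids == truth.passing_compounds

        interactions = pn.read_interaction_table(outdir / "interactions.tsv")
        assert len(interactions) == truth.n_edges
        assert interactions.compound_ids.isdisjoint(truth.targetless_compounds)

        disease = pn.read_gene_list(outdir / "disease.txt")
        assert disease.genes == frozenset(truth.disease_targets)

        expr = pn.read_expression_matrix(outdir / "expression.tsv")
        assert set(expr.genes) | set(truth.unprofiled_genes) == set(
            truth.target_symbols
        )

        saved = json.loads((outdir / "truth.json").read_text())
        assert saved["passing_compounds"] == truth.passing_compounds

    def test_bundle_files_are_seed_deterministic(self, bundle, tmp_path):
        cfg, _, outdir = bundle
        again = tmp_path / "again"
        pn.write_bundle(pn.GeneratorConfig(seed=cfg.seed), again)
        for name in ("compounds.tsv", "interactions.tsv", "disease.txt",
                     "annotation.gmt", "expression.tsv", "truth.json"):
            assert (again / name).read_bytes() == (outdir / name).read_bytes()
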