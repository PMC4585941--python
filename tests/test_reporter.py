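import math

import numpy as np
import pandas as pd
import pytest

from reporterpath import (
    ConfigurationError,
    InputError,
    aggregate_z,
    bh_adjust,
    build_background,
    build_pathway_index,
    correct_z,
    directional_analysis,
    map_genes_to_reactions,
    parse_network,
    pvalue_to_z,
    reporter_metabolites,
    reporter_pathways_metabolite_centric,
    reporter_pathways_reaction_centric,
    run_analysis,
    significant_pathways,
    stage_seed,
)

from conftest import make_gene_stats

# two chain pathways sharing metabolite B through the cross-linking reaction R4:
# P1 = A-B-C-D (R1..R3), P2 = B-E-F-G (R4..R6), R4 consumes B of P1
FIG_TSV = (
    "reaction\tmetabolites\tgenes\tpathways\n"
    "R1\tA // B\tg1\tP1\n"
    "R2\tB // C\tg2\tP1\n"
    "R3\tC // D\tg3\tP1\n"
    "R4\tB // E\tg4\tP2\n"
    "R5\tE // F\tg5\tP2\n"
    "R6\tF // G\tg6\tP2\n"
)


@pytest.fixture
def crosslink_network(tmp_path):
    path = tmp_path / "fig.tsv"
    path.write_text(FIG_TSV)
    return parse_network(path)


class TestAggregateZ:
    def test_zero_preservation(self):
        assert aggregate_z([0.0]) == 0.0

    def test_two_equal_deviates(self):
        assert aggregate_z([1.6449, 1.6449]) == pytest.approx(2.3262398887, abs=1e-6)

    def test_singleton_identity(self):
        for z in (-2.5, 0.3, 4.0):
            assert aggregate_z([z]) == pytest.approx(z, abs=1e-15)

    def test_empty_rejected(self):
        with pytest.raises(InputError):
            aggregate_z([])


class TestBackground:
    def test_standard_normal_pool_has_unit_moments(self):
        rng = np.random.default_rng(0)
        pool = rng.standard_normal(500)
        model = build_background(pool, k_set=[2, 5, 10], n_samples=4000, seed=1)
        for k in (2, 5, 10):
            assert abs(model.mu[k]) < 3 / math.sqrt(4000) + 3 * abs(pool.mean())
            assert model.sigma[k] == pytest.approx(1.0, abs=0.1)

    def test_same_seed_reproduces_exactly(self):
        pool = np.random.default_rng(3).standard_normal(100)
        a = build_background(pool, [3, 7], n_samples=500, seed=9)
        b = build_background(pool, [3, 7], n_samples=500, seed=9)
        assert a == b

    def test_constant_pool_is_degenerate(self):
        with pytest.raises(InputError, match="degenerate"):
            build_background(np.full(50, 1.3), [4], n_samples=200, seed=0)

    def test_oversized_k_names_the_size(self):
        with pytest.raises(InputError, match="12"):
            build_background(np.arange(10, dtype=float), [12], n_samples=200, seed=0)

    def test_small_sample_count_warns(self):
        with pytest.warns(UserWarning, match="n_samples"):
            build_background(np.arange(10, dtype=float), [2], n_samples=50, seed=0)


class TestCorrectZ:
    def test_centering_and_scaling(self):
        model = build_background(np.random.default_rng(1).normal(size=50), [2],
                                 n_samples=500, seed=0)
        mu, sigma = model.mu[2], model.sigma[2]
        assert correct_z(mu, 2, model) == pytest.approx(0.0, abs=1e-12)
        assert correct_z(mu + sigma, 2, model) == pytest.approx(1.0, abs=1e-12)

    def test_hand_arithmetic(self):
        from reporterpath import BackgroundModel

        model = BackgroundModel(mu={5: 0.1}, sigma={5: 1.2}, n_samples=100, seed=0,
                                universe="test")
        assert correct_z(2.5, 5, model) == pytest.approx(2.0, abs=1e-12)

    def test_missing_size_raises(self):
        from reporterpath import BackgroundModel

        model = BackgroundModel(mu={5: 0.0}, sigma={5: 1.0}, n_samples=100, seed=0,
                                universe="test")
        with pytest.raises(InputError):
            correct_z(1.0, 6, model)


class TestBHAdjust:
    def test_step_up_by_hand(self):
        assert np.allclose(bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_single_value_unchanged(self):
        assert bh_adjust([0.2]) == pytest.approx([0.2])

    def test_equal_values_stay_equal(self):
        assert np.allclose(bh_adjust([0.04] * 5), [0.04] * 5)

    def test_out_of_range_rejected(self):
        with pytest.raises(InputError):
            bh_adjust([0.1, 0.0])

    def test_order_preserved(self):
        p = [0.04, 0.001, 0.2]
        q = bh_adjust(p)
        assert q[1] == min(q)


class TestReporterMetabolites:
    def test_all_zero_deviates_is_degenerate_background(self, crosslink_network):
        # every gene at p = 0.5 makes the gene pool constant: no null spread
        gs = make_gene_stats({g: 0.5 for g in crosslink_network.genes})
        rstats = map_genes_to_reactions(crosslink_network, gs)
        with pytest.raises(InputError, match="degenerate"):
            reporter_metabolites(crosslink_network, rstats, gene_stats=gs,
                                 n_samples=300, seed=0)

    def test_isolated_signal_has_minimum_p(self, crosslink_network):
        p = {g: 0.5 - 0.01 * i for i, g in enumerate(sorted(crosslink_network.genes))}
        p["g6"] = 1e-6  # only G and F touch reactions selecting g6
        gs = make_gene_stats(p)
        rstats = map_genes_to_reactions(crosslink_network, gs)
        scores = reporter_metabolites(crosslink_network, rstats, gene_stats=gs,
                                      n_samples=1000, seed=0)
        best = scores.table["p_value"].idxmin()
        assert best in {"F", "G"}

    def test_unmeasured_metabolites_omitted(self, toy_network):
        gs = make_gene_stats({"g1": 0.2, "g2": 0.4, "g3": 0.6})
        rstats = map_genes_to_reactions(toy_network, gs)
        scores = reporter_metabolites(toy_network, rstats, gene_stats=gs,
                                      n_samples=300, seed=0)
        assert "D" not in scores.table.index  # only touched by unmeasured R3


class TestPathwayScoring:
    def _scores(self, network, gene_stats, **kwargs):
        rstats = map_genes_to_reactions(network, gene_stats)
        return reporter_metabolites(network, rstats, gene_stats=gene_stats,
                                    n_samples=500, seed=11), rstats

    def test_crosslink_gene_moves_rpam_not_rpar(self, crosslink_network):
        """A foreign reaction touching this pathway's metabolite shifts the
        metabolite-centric raw score but leaves the reaction-centric one as-is."""
        index = build_pathway_index(crosslink_network, min_reactions=3)
        base = {g: 0.3 + 0.05 * i for i, g in enumerate(sorted(crosslink_network.genes))}
        strong = dict(base, g4=1e-5)
        gs_base, gs_strong = make_gene_stats(base), make_gene_stats(strong)
        rs_base = map_genes_to_reactions(crosslink_network, gs_base)
        rs_strong = map_genes_to_reactions(crosslink_network, gs_strong)
        # shared metabolite background so only the scoring inputs differ
        pool = gs_base["z"].to_numpy() + np.linspace(0, 0.3, len(gs_base))
        bg = build_background(pool, [1, 2, 3], n_samples=500, seed=2)
        ms_base = reporter_metabolites(crosslink_network, rs_base, background=bg)
        ms_strong = reporter_metabolites(crosslink_network, rs_strong, background=bg)
        rpam_base = reporter_pathways_metabolite_centric(
            crosslink_network, index, ms_base, n_samples=400, seed=3, background="pool")
        rpam_strong = reporter_pathways_metabolite_centric(
            crosslink_network, index, ms_strong, n_samples=400, seed=3, background="pool")
        assert rpam_strong.loc["P1", "raw_z"] > rpam_base.loc["P1", "raw_z"]

        rpar_base = reporter_pathways_reaction_centric(
            crosslink_network, index, rs_base, n_samples=400, seed=4)
        rpar_strong = reporter_pathways_reaction_centric(
            crosslink_network, index, rs_strong, n_samples=400, seed=4)
        assert rpar_strong.loc["P1", "raw_z"] == pytest.approx(
            rpar_base.loc["P1", "raw_z"], abs=1e-12)
        # while P2, which owns R4, moves under both scores
        assert rpar_strong.loc["P2", "raw_z"] > rpar_base.loc["P2", "raw_z"]

    def test_signal_monotonicity_of_raw_rpam(self, crosslink_network):
        index = build_pathway_index(crosslink_network, min_reactions=3)
        pool_bg = build_background(np.linspace(-1.5, 1.5, 6), [1, 2, 3],
                                   n_samples=500, seed=5)
        raws = []
        for p4 in (0.5, 0.1, 0.001):
            gs = make_gene_stats({**{g: 0.4 for g in crosslink_network.genes}, "g4": p4})
            rs = map_genes_to_reactions(crosslink_network, gs)
            ms = reporter_metabolites(crosslink_network, rs, background=pool_bg)
            rpam = reporter_pathways_metabolite_centric(
                crosslink_network, index, ms, n_samples=400, seed=6, background="pool")
            raws.append(rpam.loc["P1", "raw_z"])
        assert raws[0] < raws[1] < raws[2]

    def test_branch_point_gene_counts_once_per_metabolite(self, crosslink_network):
        """An interior chain gene touches two pathway metabolites, so its deviate
        enters the pathway's raw evidence twice (sqrt(2)-fold, not 1-fold)."""
        index = build_pathway_index(crosslink_network, min_reactions=3)
        z2 = pvalue_to_z(0.01)
        gs = make_gene_stats({**{g: 0.5 for g in crosslink_network.genes}, "g2": 0.01})
        rs = map_genes_to_reactions(crosslink_network, gs)
        bg = build_background(np.linspace(-1.0, 3.0, 6), [1, 2, 3], n_samples=400, seed=7)
        ms = reporter_metabolites(crosslink_network, rs, background=bg)
        rpam = reporter_pathways_metabolite_centric(
            crosslink_network, index, ms, n_samples=400, seed=8,
            background="pool", statistic="raw")
        # P1 metabolites: A{g1}, B{g1,g2,g4}, C{g2,g3}, D{g3}; only g2 deviates
        expected = (z2 / math.sqrt(3) + z2 / math.sqrt(2)) / math.sqrt(4)
        assert rpam.loc["P1", "raw_z"] == pytest.approx(expected, abs=1e-9)
        # collapsing the duplicate contribution would give a different number
        assert abs(rpam.loc["P1", "raw_z"] - z2 / math.sqrt(3) / math.sqrt(4)) > 0.1

    def test_pathway_without_scored_metabolites_omitted(self, crosslink_network):
        index = build_pathway_index(crosslink_network, min_reactions=3)
        gs = make_gene_stats({"g1": 0.3, "g2": 0.1, "g3": 0.7})  # P2 unmeasured
        rs = map_genes_to_reactions(crosslink_network, gs)
        ms = reporter_metabolites(crosslink_network, rs, gene_stats=gs,
                                  n_samples=300, seed=9)
        rpar = reporter_pathways_reaction_centric(crosslink_network, index, rs,
                                                  n_samples=300, seed=10)
        assert "P2" not in rpar.index


class TestSignificantPathways:
    def _table(self, p_map):
        return pd.DataFrame(
            {"n_metabolites": 5, "p_value": list(p_map.values()),
             "q_value": list(p_map.values())},
            index=pd.Index(p_map.keys(), name="pathway"),
        )

    def test_alpha_one_keeps_all(self):
        table = self._table({"Pa": 0.4, "Pb": 0.9})
        assert len(significant_pathways(table, alpha=1.0)) == 2

    def test_alpha_zero_keeps_none(self):
        table = self._table({"Pa": 0.001})
        assert significant_pathways(table, alpha=0.0).empty

    def test_threshold_is_strict(self):
        table = self._table({"Pa": 0.005, "Pb": 0.02})
        assert list(significant_pathways(table, alpha=0.01).index) == ["Pa"]


class TestDirectional:
    def test_all_up_matches_manual_one_tailed_run(self, crosslink_network):
        index = build_pathway_index(crosslink_network, min_reactions=3)
        p = {g: 0.2 + 0.05 * i for i, g in enumerate(sorted(crosslink_network.genes))}
        gs = make_gene_stats(p)  # all signs +1 by default
        up = directional_analysis(crosslink_network, index, gs, "up",
                                  n_samples=400, seed=12)
        manual = gs.copy()
        manual["p_value"] = manual["p_value"] / 2
        manual["z"] = pvalue_to_z(manual["p_value"].to_numpy())
        rs = map_genes_to_reactions(crosslink_network, manual)
        ms = reporter_metabolites(crosslink_network, rs, gene_stats=manual,
                                  n_samples=400, seed=12)
        expected = reporter_pathways_metabolite_centric(
            crosslink_network, index, ms, n_samples=400, seed=12)
        pd.testing.assert_frame_equal(up.drop(columns="direction"), expected)

    def test_no_matching_genes_is_input_error(self, crosslink_network):
        index = build_pathway_index(crosslink_network, min_reactions=3)
        gs = make_gene_stats({g: 0.3 for g in crosslink_network.genes})  # all up
        with pytest.raises(InputError):
            directional_analysis(crosslink_network, index, gs, "down",
                                 n_samples=300, seed=0)

    def test_invalid_direction_rejected(self, crosslink_network):
        index = build_pathway_index(crosslink_network, min_reactions=3)
        gs = make_gene_stats({g: 0.3 for g in crosslink_network.genes})
        with pytest.raises(ConfigurationError):
            directional_analysis(crosslink_network, index, gs, "sideways")


class TestDeterminism:
    def test_pipeline_is_bit_identical_for_equal_seeds(self, crosslink_network):
        gs = make_gene_stats(
            {g: 0.1 + 0.1 * i for i, g in enumerate(sorted(crosslink_network.genes))}
        )
        a = run_analysis(crosslink_network, gs, n_samples=400, seed=21,
                         min_reactions=3, directions=("up",))
        b = run_analysis(crosslink_network, gs, n_samples=400, seed=21,
                         min_reactions=3, directions=("up",))
        pd.testing.assert_frame_equal(a.rpam, b.rpam)
        pd.testing.assert_frame_equal(a.rpar, b.rpar)
        pd.testing.assert_frame_equal(a.metabolite_scores.table, b.metabolite_scores.table)
        pd.testing.assert_frame_equal(a.directional["up"], b.directional["up"])

    def test_stage_seeds_are_distinct(self):
        seeds = {stage_seed(7, s) for s in ("metabolite", "rpam", "rpar", "up", "down")}
        assert len(seeds) == 5
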