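import numpy as np
import networkx as nx
import pandas as pd
import pytest
from scipy import stats as sps

from targetrank.simulate import (ScenarioConfig, SampleMatrix, TargetSet,
                                 aggregate_samples, generate_network,
                                 generate_sample_matrices, generate_scenario,
                                 generate_universe, write_scenario)


class TestUniverse:
    def test_unique_and_deterministic(self):
        u1 = generate_universe(100, seed=1)
        u2 = generate_universe(100, seed=1)
        assert u1 == u2
        assert len(set(u1)) == 100

    def test_symbols_are_index_based_across_seeds(self):
        # documented choice: symbol scheme ignores the seed
        assert generate_universe(100, seed=1) == generate_universe(100, seed=2)

    def test_too_small_rejected(self):
        with pytest.raises(ValueError, match=">= 50"):
            generate_universe(10, seed=1)


class TestNetwork:
    def test_edge_count_matches_mean_degree(self):
        cfg = ScenarioConfig(n_genes=100, n_targets=4, mean_degree=6.0, seed=3)
        g = generate_network(generate_universe(100), cfg)
        # expectation of the attachment model is n * k / 2 = 300
        assert 240 <= g.number_of_edges() <= 360

    def test_every_gene_is_a_node(self):
        cfg = ScenarioConfig(n_genes=120, n_targets=5, mean_degree=4.0, seed=0)
        uni = generate_universe(120)
        g = generate_network(uni, cfg)
        assert set(g.nodes()) == set(uni)
        assert not any(u == v for u, v in g.edges())

    def test_planted_communities_beat_random_partition(self):
        cfg = ScenarioConfig(n_genes=200, n_targets=8, mean_degree=8.0,
                             n_communities=2, community_mixing=0.05, seed=5)
        uni = generate_universe(200)
        g = generate_network(uni, cfg)
        from targetrank.simulate import _communities
        comm = _communities(cfg, np.empty(0, dtype=int))
        planted = [{uni[i] for i in np.flatnonzero(comm == c)} for c in (0, 1)]
        rng = np.random.default_rng(0)
        mixed = np.array(uni)[rng.permutation(200)]
        random_part = [set(mixed[:100]), set(mixed[100:])]
        q_planted = nx.community.modularity(g, planted)
        q_random = nx.community.modularity(g, random_part)
        assert q_planted > q_random

    def test_zero_mean_degree_gives_isolated_nodes(self):
        cfg = ScenarioConfig(n_genes=100, n_targets=4, mean_degree=0.0, seed=1)
        g = generate_network(generate_universe(100), cfg)
        assert g.number_of_edges() == 0
        assert g.number_of_nodes() == 100


@pytest.fixture(scope="module")
def scenario_parts():
    cfg = ScenarioConfig(n_genes=700, n_targets=30, n_samples_mutation=50,
                         mutation_effect=3.0, expression_effect=0.0,
                         essentiality_effect=0.0, seed=9)
    uni = generate_universe(700)
    rng = np.random.default_rng(9)
    targets = TargetSet("t", tuple(sorted(rng.choice(uni, 30, replace=False))))
    return cfg, uni, targets, generate_sample_matrices(uni, targets, cfg)


class TestSampleMatrices:
    def test_shapes_and_binary_mutation(self, scenario_parts):
        cfg, uni, targets, mats = scenario_parts
        for name, m in mats.items():
            assert m.values.shape[0] == cfg.n_genes
        assert set(np.unique(mats["mutation"].values)) <= {0, 1}

    def test_mutation_shift_detectable(self, scenario_parts):
        # +3 SD shift, 50 samples, 30 targets: aggregated rates separate
        cfg, uni, targets, mats = scenario_parts
        agg = aggregate_samples(mats["mutation"])
        is_t = agg.index.isin(targets.genes)
        res = sps.mannwhitneyu(agg[is_t], agg[~is_t], alternative="greater")
        assert res.pvalue < 0.01

    def test_null_essentiality_indistinguishable(self, scenario_parts):
        cfg, uni, targets, mats = scenario_parts
        agg = aggregate_samples(mats["essentiality"])
        is_t = agg.index.isin(targets.genes)
        res = sps.mannwhitneyu(agg[is_t], agg[~is_t], alternative="two-sided")
        assert res.pvalue > 0.01

    def test_extreme_effect_clips_with_warning(self):
        cfg = ScenarioConfig(n_genes=300, n_targets=10, mutation_effect=50.0,
                             seed=2)
        uni = generate_universe(300)
        targets = TargetSet("t", tuple(uni[:10]))
        with pytest.warns(UserWarning, match="clipped"):
            mats = generate_sample_matrices(uni, targets, cfg)
        assert aggregate_samples(mats["mutation"]).between(0, 1).all()


class TestAggregation:
    @pytest.mark.parametrize("data_type,row,expected", [
        ("mutation", [1, 0, 0, 1], 0.5),
        ("expression", [1.0, 9.0, 2.0], 2.0),
        ("essentiality", [-1.0, -1.0], -1.0),
    ])
    def test_aggregation_rule(self, data_type, row, expected):
        m = SampleMatrix(data_type, ["g"], np.array([row], dtype=float))
        assert aggregate_samples(m).iloc[0] == pytest.approx(expected)

    def test_empty_sample_dimension_rejected(self):
        with pytest.raises(ValueError):
            SampleMatrix("expression", ["g"], np.empty((1, 0)))


class TestScenario:
    def test_full_determinism(self, tmp_path):
        cfg = ScenarioConfig(n_genes=300, n_targets=12, seed=4)
        a, b = generate_scenario(cfg), generate_scenario(cfg)
        assert a.universe == b.universe
        assert a.targets.genes == b.targets.genes
        assert sorted(a.network.edges()) == sorted(b.network.edges())
        pd.testing.assert_frame_equal(a.primary_features, b.primary_features)
        pa = write_scenario(a, tmp_path / "a")
        pb = write_scenario(b, tmp_path / "b")
        for key in pa:
            assert open(pa[key], "rb").read() == open(pb[key], "rb").read()

    def test_effect_direction_recovered_across_seeds(self):
        # planted mutation shift shows the right sign essentially always
        hits = 0
        for seed in range(20):
            cfg = ScenarioConfig(n_genes=300, n_targets=12,
                                 n_samples_mutation=30, n_samples_expression=5,
                                 n_samples_essentiality=5,
                                 mutation_effect=3.0, seed=seed)
            sc = generate_scenario(cfg)
            agg = sc.primary_features["mutation"]
            is_t = agg.index.isin(sc.targets.genes)
            hits += agg[is_t].mean() > agg[~is_t].mean()
        assert hits >= 19

    def test_universe_must_fit_negative_design(self):
        with pytest.raises(ValueError, match="at least"):
            ScenarioConfig(n_genes=100, n_targets=10)

    def test_heldout_genes_are_planted_but_not_positive(self):
        cfg = ScenarioConfig(n_genes=300, n_targets=12, n_heldout=4, seed=0)
        sc = generate_scenario(cfg)
        assert len(sc.heldout) == 4
        assert set(sc.heldout) <= set(sc.targets.genes)
        assert not set(sc.heldout) & set(sc.positives)
        assert len(sc.positives) == 8
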