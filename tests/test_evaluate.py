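import numpy as np
import pandas as pd
import pytest

import oracles
from targetrank.evaluate import (auroc, citation_validation,
                                 heldout_rank_test, predict_genomewide)


class TestAuroc:
    def test_perfect_separation(self):
        assert auroc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0

    def test_half_right_pairs(self):
        # 2 of 4 (pos, neg) pairs ranked correctly
        assert auroc([0.9, 0.3, 0.6, 0.2], [1, 0, 0, 1]) == pytest.approx(0.5)

    def test_all_tied_scores(self):
        assert auroc([0.5] * 6, [1, 1, 1, 0, 0, 0]) == pytest.approx(0.5)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            auroc([0.1, 0.2], [1, 1])


class TestEvaluationAndRetraining:
    def test_report_covers_methods_by_negative_sets(self, small_run):
        table = small_run.evaluation.table
        assert table.shape == (5, 10)
        assert ((table >= 0) & (table <= 1)).all().all()
        best = small_run.best_method
        assert small_run.evaluation.means[best] == small_run.evaluation.means.max()

    def test_ensemble_retrained_on_full_balanced_data(self, small_run):
        assert len(small_run.ensemble) == 10
        n_pos = len(small_run.positives)
        for member, ds in zip(small_run.ensemble, small_run.datasets):
            assert member.method == small_run.best_method
            assert member.negative_set_index == ds.negative_set_index
            assert len(ds.frame) == 2 * n_pos


class TestGenomewidePrediction:
    def test_positives_absent_and_ranks_are_permutation(self, small_run):
        ranking = small_run.ranking
        assert not set(small_run.positives) & set(ranking.index)
        assert sorted(ranking["rank"]) == list(range(1, len(ranking) + 1))

    def test_negative_set_genes_use_nine_models(self, small_run):
        ranking = small_run.ranking
        neg_union = set().union(*small_run.negatives.sets)
        in_neg = ranking.index.isin(neg_union)
        assert (ranking.loc[in_neg, "n_models"] == 9).all()
        assert (ranking.loc[~in_neg, "n_models"] == 10).all()

    def test_zscores_standardised(self, small_run):
        z = small_run.ranking["zscore"]
        assert z.mean() == pytest.approx(0.0, abs=1e-9)
        assert z.std(ddof=0) == pytest.approx(1.0, abs=1e-9)

    def test_rank_ties_broken_by_gene_symbol(self):
        # two genes with identical probabilities: lexicographic order wins
        ranking = pd.DataFrame({"mean_probability": [0.7, 0.7, 0.2]},
                               index=pd.Index(["gB", "gA", "gC"], name="gene"))
        order = ranking.sort_values(["mean_probability", "gene"],
                                    ascending=[False, True]).index
        assert list(order) == ["gA", "gB", "gC"]

    def test_wrong_ensemble_size_rejected(self, small_run):
        with pytest.raises(ValueError, match="one ensemble member"):
            predict_genomewide(small_run.ensemble[:5], small_run.features,
                               small_run.positives, small_run.negatives)


class TestCitationValidation:
    @pytest.fixture
    def ranking(self):
        rng = np.random.default_rng(1)
        p = rng.random(50)
        return pd.DataFrame({"mean_probability": p},
                            index=pd.Index([f"g{i}" for i in range(50)],
                                           name="gene"))

    def test_counts_matching_ranks_give_perfect_rho(self, ranking):
        counts = ranking["mean_probability"].rank()
        rho, p = citation_validation(ranking, counts, n_sample=50, seed=0)
        assert rho == pytest.approx(1.0)

    def test_reversed_counts_give_minus_one(self, ranking):
        counts = (-ranking["mean_probability"]).rank()
        rho, _ = citation_validation(ranking, counts, n_sample=50, seed=0)
        assert rho == pytest.approx(-1.0)

    def test_matches_rank_correlation_oracle(self):
        x = np.array([0.1, 0.9, 0.4, 0.4, 0.7, 0.2])
        y = np.array([3.0, 50.0, 5.0, 9.0, 5.0, 1.0])
        ranking = pd.DataFrame({"mean_probability": x},
                               index=pd.Index([f"g{i}" for i in range(6)],
                                              name="gene"))
        rho, _ = citation_validation(ranking, pd.Series(y, index=ranking.index),
                                     n_sample=6, seed=0)
        assert rho == pytest.approx(oracles.spearman_rho(x, y), abs=1e-12)

    def test_missing_genes_count_as_zero(self, ranking):
        counts = ranking["mean_probability"].rank().iloc[:25]
        rho, _ = citation_validation(ranking, counts, n_sample=50, seed=0)
        assert np.isfinite(rho)


class TestHeldoutRankTest:
    def test_top_ranked_heldout_genes_detected(self):
        n = 200
        prob = np.linspace(1, 0, n)
        ranking = pd.DataFrame(
            {"mean_probability": prob, "rank": np.arange(1, n + 1)},
            index=pd.Index([f"g{i}" for i in range(n)], name="gene"))
        frac, p = heldout_rank_test(ranking, [f"g{i}" for i in range(10)])
        assert p < 0.001
        assert frac < 0.1

    def test_absent_heldout_genes_rejected(self):
        ranking = pd.DataFrame({"mean_probability": [0.5], "rank": [1]},
                               index=pd.Index(["gX"], name="gene"))
        with pytest.raises(ValueError):
            heldout_rank_test(ranking, ["gZ"])
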