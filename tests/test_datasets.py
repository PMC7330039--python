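import numpy as np
import pandas as pd
import pytest

from targetrank.datasets import (assemble_feature_table, build_datasets,
                                 build_positive_set, sample_negative_sets,
                                 stratified_split)
from targetrank.embedding import feature_names


def records(rows):
    return pd.DataFrame(rows, columns=["gene", "drug", "interaction_type"])


class TestPositiveSet:
    def test_union_of_evidenced_targets_and_drivers(self):
        recs = records([("A", "d1", "inhibitor"), ("B", "d1", None)])
        assert build_positive_set(recs, driver_genes={"C"}) == ["A", "C"]

    def test_overlapping_driver_counted_once(self):
        recs = records([("A", "d1", "inhibitor")])
        assert build_positive_set(recs, driver_genes={"A"}) == ["A"]

    def test_empty_result_is_an_error(self):
        recs = records([("A", "d1", None), ("B", "d2", "")])
        with pytest.raises(ValueError, match="empty"):
            build_positive_set(recs, driver_genes=())


class TestNegativeSets:
    def test_ten_disjoint_sets_cover_required_pool(self):
        universe = [f"g{i}" for i in range(200)]
        positives = universe[:10]
        coll = sample_negative_sets(universe, positives, k=10, seed=1)
        union = set().union(*coll.sets)
        assert all(len(s) == 10 for s in coll.sets)
        assert len(union) == 100                      # pairwise disjoint
        assert not union & set(positives)

    def test_pool_too_small_names_required_size(self):
        universe = [f"g{i}" for i in range(105)]
        with pytest.raises(ValueError, match="100"):
            sample_negative_sets(universe, universe[:10], k=10, seed=0)

    def test_deterministic_per_seed(self):
        universe = [f"g{i}" for i in range(300)]
        a = sample_negative_sets(universe, universe[:12], seed=5)
        b = sample_negative_sets(universe, universe[:12], seed=5)
        assert a.sets == b.sets

    def test_membership_lookup(self):
        universe = [f"g{i}" for i in range(200)]
        coll = sample_negative_sets(universe, universe[:8], seed=2)
        g = next(iter(coll.sets[3]))
        assert coll.membership(g) == 3
        assert coll.membership("g0") is None


class TestFeatureTable:
    @pytest.fixture
    def primary(self):
        return pd.DataFrame({
            "mutation": [0.1, 0.2, 0.3, 0.4, 0.5],
            "expression": [1.0, np.nan, 3.0, 4.0, 5.0],
            "essentiality": [-0.5, 0.0, 0.1, -1.0, 0.2]},
            index=pd.Index(list("ABCDE"), name="gene"))

    def test_incomplete_gene_dropped(self, primary):
        table = assemble_feature_table(primary)
        assert list(table.index) == ["A", "C", "D", "E"]

    def test_full_join_has_35_columns(self, primary):
        emb = pd.DataFrame(np.zeros((5, 32)), index=primary.index,
                           columns=feature_names(32))
        table = assemble_feature_table(primary.fillna(2.0), emb)
        assert table.shape == (5, 35)
        assert list(table.columns[:3]) == ["mutation", "expression",
                                           "essentiality"]

    def test_gene_without_embedding_dropped(self, primary):
        emb = pd.DataFrame(np.zeros((4, 8)), index=list("ABCD"),
                           columns=feature_names(8))
        table = assemble_feature_table(primary.fillna(2.0), emb)
        assert "E" not in table.index


class TestStratifiedSplit:
    @pytest.mark.parametrize("n_per_class,expect_train", [(20, 14), (39, 27)])
    def test_per_class_rounding(self, n_per_class, expect_train):
        labels = pd.Series([1] * n_per_class + [0] * n_per_class,
                           index=[f"g{i}" for i in range(2 * n_per_class)])
        split = stratified_split(labels, train_frac=0.7, seed=3)
        for cls in (0, 1):
            n_train = ((split == "train") & (labels == cls)).sum()
            assert n_train == expect_train

    def test_same_seed_same_membership(self):
        labels = pd.Series([1] * 10 + [0] * 10,
                           index=[f"g{i}" for i in range(20)])
        s1 = stratified_split(labels, seed=4)
        s2 = stratified_split(labels, seed=4)
        pd.testing.assert_series_equal(s1, s2)

    def test_tiny_class_rejected(self):
        labels = pd.Series([1, 0, 0, 0], index=list("abcd"))
        with pytest.raises(ValueError, match="class"):
            stratified_split(labels)


class TestBuildDatasets:
    @pytest.fixture(scope="class")
    def built(self):
        genes = [f"g{i}" for i in range(300)]
        rng = np.random.default_rng(0)
        feats = pd.DataFrame(
            {"mutation": rng.random(300) * 0.3,
             "expression": rng.normal(size=300),
             "essentiality": rng.normal(size=300)},
            index=pd.Index(genes, name="gene"))
        positives = genes[:13]
        negs = sample_negative_sets(genes, positives, seed=6)
        return positives, negs, build_datasets(feats, positives, negs, seed=6)

    def test_splits_partition_each_dataset(self, built):
        positives, negs, dsets = built
        assert len(dsets) == 10
        for ds in dsets:
            f = ds.frame
            train = set(f.loc[f["split"] == "train", "gene"])
            test = set(f.loc[f["split"] == "test", "gene"])
            assert train | test == set(f["gene"]) and not train & test
            for split in ("train", "test"):
                sub = f[f["split"] == split]
                assert abs((sub["label"] == 1).sum()
                           - (sub["label"] == 0).sum()) <= 1

    def test_positive_rows_shared_negatives_never_repeat(self, built):
        positives, negs, dsets = built
        neg_seen = set()
        for ds in dsets:
            f = ds.frame
            assert set(f.loc[f["label"] == 1, "gene"]) == set(positives)
            negs_here = set(f.loc[f["label"] == 0, "gene"])
            assert not neg_seen & negs_here
            neg_seen |= negs_here
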