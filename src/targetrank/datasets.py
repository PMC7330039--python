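"""Balanced labeled dataset assembly.

Positive-set construction (drug targets with interaction-type evidence,
extended by driver genes), ten pairwise disjoint negative samples, feature
joining with missing-data filtering, and stratified 70/30 train/test
splitting.  One master seed deterministically expands into per-negative-set
and per-split sub-seeds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .embedding import feature_names

__all__ = ["PRIMARY_FEATURES", "NegativeSetCollection", "LabeledDataset",
           "build_positive_set", "sample_negative_sets",
           "assemble_feature_table", "stratified_split", "build_datasets"]

logger = logging.getLogger(__name__)

PRIMARY_FEATURES = ["mutation", "expression", "essentiality"]


@dataclass(frozen=True)
class NegativeSetCollection:
    """Ten pairwise disjoint non-target gene sets, one per replicate."""

    sets: tuple[frozenset, ...]
    seed: int

    def __post_init__(self) -> None:
        union = set()
        for s in self.sets:
            if union & s:
                raise ValueError("negative sets are not pairwise disjoint")
            union |= s

    @property
    def k(self) -> int:
        return len(self.sets)

    def membership(self, gene: str) -> int | None:
        """Index (0-based) of the set containing ``gene``, or None."""
        for i, s in enumerate(self.sets):
            if gene in s:
                return i
        return None


@dataclass
class LabeledDataset:
    """One balanced replicate: positives plus one negative set.

    ``frame`` has columns gene, label (1 target / 0 non-target), split
    ("train"/"test") and the feature columns.
    """

    frame: pd.DataFrame
    negative_set_index: int
    feature_columns: list[str]

    def part(self, split: str) -> tuple[pd.DataFrame, np.ndarray]:
        sub = self.frame[self.frame["split"] == split]
        return sub[self.feature_columns], sub["label"].to_numpy()


def build_positive_set(drug_target_records: pd.DataFrame,
                       driver_genes=()) -> list[str]:
    """Union of evidenced drug targets and driver genes.

    ``drug_target_records`` needs columns gene, drug, interaction_type;
    only records with non-empty interaction-type information count (this
    excludes untargeted chemotherapies and off-target hits).  Driver genes
    are added as-is; duplicates collapse.
    """
    req = {"gene", "interaction_type"}
    if not req <= set(drug_target_records.columns):
        raise ValueError(f"records must have columns {sorted(req)}")
    it = drug_target_records["interaction_type"]
    has_type = it.notna() & (it.astype(str).str.strip() != "") \
        & (it.astype(str).str.lower() != "no")
    positives = set(drug_target_records.loc[has_type, "gene"]) | set(driver_genes)
    if not positives:
        raise ValueError("positive set is empty: no evidenced targets and "
                         "no driver genes; cannot model")
    return sorted(positives)


def sample_negative_sets(universe, positives, k: int = 10,
                         seed: int = 0) -> NegativeSetCollection:
    """k equally sized negative sets sampled without replacement.

    Each set has the size of the positive set; sets are pairwise disjoint
    and disjoint from the positives.  Deterministic per seed.
    """
    positives = set(positives)
    pool = sorted(set(universe) - positives)
    need = k * len(positives)
    if len(pool) < need:
        raise ValueError(
            f"non-positive pool has {len(pool)} genes but {need} are "
            f"required for {k} disjoint sets of size {len(positives)}")
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(201,)))
    chosen = rng.choice(pool, size=need, replace=False)
    sets = tuple(frozenset(chosen[i * len(positives):(i + 1) * len(positives)])
                 for i in range(k))
    return NegativeSetCollection(sets, seed)


def assemble_feature_table(primary: pd.DataFrame,
                           embedding: pd.DataFrame | None = None,
                           genes=None) -> pd.DataFrame:
    """Inner-join primary features with the network embedding.

    Genes missing any primary feature, or absent from the embedding, are
    dropped with a logged count (this mirrors the attrition from requiring
    complete biological data).  Column order is canonical: the three
    primary features then net_emb_1..net_emb_d.
    """
    table = primary.copy()
    missing_cols = [c for c in PRIMARY_FEATURES if c not in table.columns]
    if missing_cols:
        raise ValueError(f"primary table lacks columns {missing_cols}")
    table = table[PRIMARY_FEATURES]
    if genes is not None:
        table = table.reindex([g for g in genes if g in table.index])
    n0 = len(table)
    table = table.dropna()
    if embedding is not None:
        d = embedding.shape[1]
        embedding = embedding.copy()
        embedding.columns = feature_names(d)
        table = table.join(embedding, how="inner").dropna()
    n_dropped = n0 - len(table)
    if n_dropped:
        logger.info("assemble_feature_table: dropped %d genes with "
                    "incomplete data", n_dropped)
    if len(table) == 0:
        raise ValueError("no genes with complete data survive the join")
    bad = table["mutation"][(table["mutation"] < 0) | (table["mutation"] > 1)]
    if len(bad):
        raise ValueError("mutation rates outside [0, 1]")
    table.index.name = "gene"
    return table


def stratified_split(labels: pd.Series, train_frac: float = 0.7,
                     seed: int = 0) -> pd.Series:
    """Assign "train"/"test" per gene, preserving class balance.

    Per class, round(train_frac * class size) genes (round-half-even) go
    to train.  Deterministic per seed.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(202,)))
    split = pd.Series("test", index=labels.index, name="split")
    for cls, idx in labels.groupby(labels).groups.items():
        n = len(idx)
        if n < 2:
            raise ValueError(f"class {cls!r} has {n} member(s); need >= 2")
        n_train = round(train_frac * n)
        if n_train == 0 or n_train == n:
            raise ValueError("train fraction leaves an empty split")
        chosen = rng.choice(np.asarray(idx, dtype=object), size=n_train,
                            replace=False)
        split.loc[chosen] = "train"
    return split


def build_datasets(features: pd.DataFrame, positives,
                   negatives: NegativeSetCollection, train_frac: float = 0.7,
                   seed: int = 0) -> list[LabeledDataset]:
    """One balanced, split dataset per negative set.

    Positive rows are identical across the replicates; negative rows never
    repeat.  Sub-seeds for each replicate's split derive from the master
    seed.
    """
    positives = [g for g in sorted(set(positives)) if g in features.index]
    if not positives:
        raise ValueError("no positive genes have complete feature data")
    feature_cols = list(features.columns)
    ss = np.random.SeedSequence(seed, spawn_key=(203,))
    sub_seeds = [int(s.generate_state(1)[0] % (2 ** 31)) for s in ss.spawn(negatives.k)]

    out = []
    for i, neg in enumerate(negatives.sets):
        neg_genes = sorted(g for g in neg if g in features.index)
        genes = positives + neg_genes
        frame = features.loc[genes].copy()
        frame.insert(0, "label", np.r_[np.ones(len(positives), dtype=int),
                                       np.zeros(len(neg_genes), dtype=int)])
        frame["split"] = stratified_split(frame["label"], train_frac, sub_seeds[i])
        frame = frame.reset_index()
        out.append(LabeledDataset(frame, i, feature_cols))
    return out
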