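"""Model evaluation, best-method selection and genome-wide prediction.

Each method's ten per-negative-set models are scored by AUROC on their
held-out test splits and the method with the highest mean is retrained on
the full data (train + test) of every replicate, yielding an ensemble of
ten related models.  Genome-wide target probabilities are the ensemble
mean per gene — using only the nine other models for genes that belong to
one of the negative sets — with positives excluded, genes ranked by mean
probability and probabilities additionally standardized to z-scores.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.metrics import roc_auc_score

from .datasets import LabeledDataset, NegativeSetCollection
from .models import TrainedModel, fit
from .stats import bh_adjust

__all__ = ["EvaluationReport", "auroc", "evaluate", "retrain_full",
           "predict_genomewide", "citation_validation", "heldout_rank_test"]

logger = logging.getLogger(__name__)


def auroc(scores, labels) -> float:
    """Probability that a random positive outscores a random negative.

    Tied scores count one half; equals the area under the ROC curve.
    """
    labels = np.asarray(labels)
    if np.unique(labels).size < 2:
        raise ValueError("labels must contain both classes")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


@dataclass
class EvaluationReport:
    """Per-method test AUROCs across the negative-set replicates."""

    table: pd.DataFrame          # methods x negative-set index
    regime: str = "extended"

    @property
    def means(self) -> pd.Series:
        return self.table.mean(axis=1)

    @property
    def best_method(self) -> str:
        return str(self.means.idxmax())


def evaluate(models: dict[str, list[TrainedModel]],
             datasets: list[LabeledDataset],
             regime: str = "extended") -> EvaluationReport:
    """Test-split AUROC for every method and negative-set replicate."""
    rows = {}
    for method, mlist in models.items():
        if len(mlist) != len(datasets):
            raise ValueError(f"{method}: expected one model per negative set")
        scores = []
        for model, ds in zip(mlist, datasets):
            if model.negative_set_index != ds.negative_set_index:
                raise ValueError("model/dataset negative-set indices disagree")
            sub = ds.frame[ds.frame["split"] == "test"]
            p = model.predict_probability(sub[model.feature_names])
            scores.append(auroc(p, sub["label"].to_numpy()))
        rows[method] = scores
    table = pd.DataFrame(rows).T
    table.columns = [ds.negative_set_index for ds in datasets]
    return EvaluationReport(table, regime)


def retrain_full(models: list[TrainedModel],
                 datasets: list[LabeledDataset]) -> list[TrainedModel]:
    """Refit each replicate's tuned model on its full data (train + test)."""
    ensemble = []
    for model, ds in zip(models, datasets):
        if model.negative_set_index != ds.negative_set_index:
            raise ValueError("model/dataset negative-set indices disagree")
        full = LabeledDataset(ds.frame.assign(split="train"),
                              ds.negative_set_index, model.feature_names)
        ensemble.append(fit(full, model.method, model.params, model.seed))
    return ensemble


def predict_genomewide(ensemble: list[TrainedModel], features: pd.DataFrame,
                       positives, negatives: NegativeSetCollection
                       ) -> pd.DataFrame:
    """Ensemble-mean target probability and rank for every scorable gene.

    Genes in the positive set are excluded.  A gene belonging to negative
    set *i* is scored by the nine models that never saw it as a training
    non-target; all other genes use all ten models.  Output columns:
    mean_probability, n_models, zscore (standardized mean probability),
    rank (1 = most probable target; ties broken by gene symbol).
    """
    if len(ensemble) != negatives.k:
        raise ValueError("need exactly one ensemble member per negative set")
    positives = set(positives)
    genes = sorted(g for g in features.index if g not in positives)
    if not genes:
        raise ValueError("no genes left to score after excluding positives")
    sub = features.loc[genes]

    k = negatives.k
    probs = np.column_stack([m.predict_probability(sub[m.feature_names])
                             for m in ensemble])
    mask = np.ones((len(genes), k), dtype=bool)
    for i, s in enumerate(negatives.sets):
        rows = np.fromiter((g in s for g in genes), dtype=bool, count=len(genes))
        mask[rows, i] = False
    n_models = mask.sum(axis=1)
    if (n_models == 0).any():
        raise RuntimeError("gene with no contributing model encountered")
    mean_p = (probs * mask).sum(axis=1) / n_models

    out = pd.DataFrame({"mean_probability": mean_p, "n_models": n_models},
                       index=pd.Index(genes, name="gene"))
    sd = out["mean_probability"].std(ddof=0)
    out["zscore"] = (out["mean_probability"] - out["mean_probability"].mean()) \
        / (sd if sd > 0 else 1.0)
    order = out.sort_values(["mean_probability", "gene"],
                            ascending=[False, True],
                            key=None).index
    out["rank"] = pd.Series(np.arange(1, len(out) + 1), index=order)
    logger.info("predict_genomewide: scored %d genes; %.1f%% above "
                "probability 0.5", len(out),
                100.0 * (out["mean_probability"] > 0.5).mean())
    return out.sort_values("rank")


def citation_validation(ranking: pd.DataFrame, citation_counts: pd.Series,
                        n_sample: int = 1000, seed: int = 0
                        ) -> tuple[float, float]:
    """Spearman correlation of predicted probability with citation counts.

    A random sample of ``n_sample`` ranked genes is used (all genes, with
    a warning, if fewer are available); genes missing from the citation
    table count as 0 citations, logged.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(501,)))
    genes = list(ranking.index)
    if n_sample >= len(genes):
        logger.warning("citation_validation: requested %d genes but only %d "
                       "ranked; using all", n_sample, len(genes))
        sample = genes
    else:
        sample = list(rng.choice(genes, size=n_sample, replace=False))
    counts = citation_counts.reindex(sample)
    n_missing = int(counts.isna().sum())
    if n_missing:
        logger.info("citation_validation: %d genes missing from the citation "
                    "table treated as count 0", n_missing)
    counts = counts.fillna(0.0)
    rho, p = sps.spearmanr(ranking.loc[sample, "mean_probability"].to_numpy(),
                           counts.to_numpy())
    return float(rho), float(p)


def citation_validation_multi(rankings: dict[str, pd.DataFrame],
                              citations: dict[str, pd.Series],
                              n_sample: int = 1000, seed: int = 0
                              ) -> pd.DataFrame:
    """Per-cancer Spearman validation with BH correction across cancers."""
    rows = []
    for label, ranking in rankings.items():
        rho, p = citation_validation(ranking, citations[label], n_sample, seed)
        rows.append((label, rho, p))
    out = pd.DataFrame(rows, columns=["cancer", "rho", "p"]).set_index("cancer")
    out["q"] = bh_adjust(out["p"].to_numpy())
    return out


def heldout_rank_test(ranking: pd.DataFrame, heldout) -> tuple[float, float]:
    """Do withheld true targets score above the background?

    One-sided Mann-Whitney (Wilcoxon rank-sum) test of the held-out
    genes' predicted probabilities against all other ranked genes.
    Returns (median held-out rank fraction, p value).
    """
    heldout = [g for g in heldout if g in ranking.index]
    if not heldout:
        raise ValueError("no held-out genes present in the ranking")
    rest = ranking.index.difference(heldout)
    res = sps.mannwhitneyu(ranking.loc[heldout, "mean_probability"],
                           ranking.loc[rest, "mean_probability"],
                           alternative="greater")
    frac = float(np.median(ranking.loc[heldout, "rank"]) / len(ranking))
    return frac, float(res.pvalue)
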