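"""Permutation-null multivariate feature selection.

A random-forest classifier is fitted on each training split and its
information-gain (entropy impurity decrease) importances are compared to a
null distribution obtained by refitting after shuffling the class labels
(default 100 shuffles).  The comparison is expressed as a z-score per
feature, averaged over the ten negative-set replicates; features with
average z >= 0.5 are retained.  The forest used here is fixed (100 trees,
unlimited depth) rather than tuned — the z statistic is a ratio against
the matched null, so stability matters more than raw accuracy.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from .datasets import LabeledDataset

__all__ = ["ImportanceReport", "rf_importance", "null_distribution",
           "zscores", "select_features", "importance_for_datasets"]

logger = logging.getLogger(__name__)

Z_CAP = 10.0          # stands in for +/- infinity when the null SD is 0
DEFAULT_THRESHOLD = 0.5
DEFAULT_TREES = 100


@dataclass
class ImportanceReport:
    """Per-feature importance vs its permutation null, one negative set."""

    negative_set_index: int
    real: pd.Series                  # real-model importances (sum to 1)
    null_mean: pd.Series
    null_sd: pd.Series
    z: pd.Series

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame({"real": self.real, "null_mean": self.null_mean,
                             "null_sd": self.null_sd, "z": self.z})


def _fit_importances(x: np.ndarray, y: np.ndarray, seed: int,
                     n_trees: int) -> np.ndarray:
    rf = RandomForestClassifier(n_estimators=n_trees, criterion="entropy",
                                n_jobs=1, random_state=seed)
    rf.fit(x, y)
    return rf.feature_importances_


def rf_importance(train: LabeledDataset, seed: int = 0,
                  n_trees: int = DEFAULT_TREES) -> pd.Series:
    """Information-gain importances of a forest fit on the training split."""
    x, y = train.part("train")
    if len(np.unique(y)) < 2:
        raise ValueError("training split is single-class")
    imp = _fit_importances(x.to_numpy(), y, seed, n_trees)
    return pd.Series(imp, index=train.feature_columns, name="importance")


def null_distribution(train: LabeledDataset, n_shuffles: int = 100,
                      seed: int = 0,
                      n_trees: int = DEFAULT_TREES) -> pd.DataFrame:
    """Importances under label shuffling: (n_shuffles x n_features).

    Each shuffle permutes the training labels uniformly at random and
    refits a fresh forest (its own derived seed); deterministic per seed.
    """
    if n_shuffles < 2:
        raise ValueError("n_shuffles must be >= 2 for a null SD")
    x, y = train.part("train")
    xa = x.to_numpy()
    ss = np.random.SeedSequence(seed, spawn_key=(301, train.negative_set_index))
    rng = np.random.default_rng(ss)
    fit_seeds = [int(s.generate_state(1)[0] % (2 ** 31))
                 for s in ss.spawn(n_shuffles)]
    rows = np.empty((n_shuffles, xa.shape[1]))
    for i in range(n_shuffles):
        rows[i] = _fit_importances(xa, rng.permutation(y), fit_seeds[i], n_trees)
    return pd.DataFrame(rows, columns=train.feature_columns)


def zscores(real: pd.Series, null_samples: pd.DataFrame) -> pd.Series:
    """(real - null mean) / null SD per feature.

    A zero null SD would give an infinite z; it is capped at +/-10 (0 if
    the real importance also equals the null mean) and logged.
    """
    if list(real.index) != list(null_samples.columns):
        raise ValueError("feature order of real and null disagree")
    mu = null_samples.mean(axis=0)
    sd = null_samples.std(axis=0, ddof=1)
    z = pd.Series(0.0, index=real.index, name="z")
    ok = sd > 1e-12                      # below: numerically constant null
    z[ok] = (real[ok] - mu[ok]) / sd[ok]
    degenerate = ~ok & (~np.isclose(real, mu, atol=1e-12))
    if degenerate.any():
        logger.warning("zscores: %d features had zero null SD; z capped at "
                       "+/-%g", int(degenerate.sum()), Z_CAP)
        z[degenerate] = np.sign(real[degenerate] - mu[degenerate]) * Z_CAP
    return z.clip(-Z_CAP, Z_CAP)


def importance_for_datasets(datasets: list[LabeledDataset],
                            n_shuffles: int = 100, seed: int = 0,
                            n_trees: int = DEFAULT_TREES
                            ) -> list[ImportanceReport]:
    """One ImportanceReport per negative-set replicate (training data only)."""
    reports = []
    for ds in datasets:
        sub = int(np.random.SeedSequence(
            seed, spawn_key=(302, ds.negative_set_index)).generate_state(1)[0]
            % (2 ** 31))
        real = rf_importance(ds, sub, n_trees)
        null = null_distribution(ds, n_shuffles=n_shuffles, seed=sub,
                                 n_trees=n_trees)
        z = zscores(real, null)
        reports.append(ImportanceReport(ds.negative_set_index, real,
                                        null.mean(axis=0),
                                        null.std(axis=0, ddof=1), z))
    return reports


def select_features(reports: list[ImportanceReport],
                    threshold: float = DEFAULT_THRESHOLD) -> pd.DataFrame:
    """Average z over the replicates and flag features with avg z >= threshold.

    Returns a frame with columns avg_z and selected (bool).  Raises if the
    selection is empty — on such data the feature signal is
    indistinguishable from the label-shuffle null and the threshold (or
    the data) needs review.
    """
    if not reports:
        raise ValueError("no importance reports given")
    order = list(reports[0].z.index)
    for r in reports[1:]:
        if list(r.z.index) != order:
            raise ValueError("reports have differing feature order")
    avg = pd.concat([r.z for r in reports], axis=1).mean(axis=1)
    out = pd.DataFrame({"avg_z": avg, "selected": avg >= threshold})
    if not out["selected"].any():
        raise ValueError(
            "no feature reached the average z threshold "
            f"({threshold}); review the threshold or the input signal")
    return out
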