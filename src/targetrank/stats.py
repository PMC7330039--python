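"""Univariate two-class feature screening.

For each of the 35 features, target and pooled non-target values are
compared with a Mann-Whitney-Wilcoxon test on the full dataset (training
and test rows together, all ten negative sets pooled, positives counted
once); p values are corrected across the features of one cancer type with
the Benjamini-Hochberg step-up procedure.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .datasets import NegativeSetCollection

__all__ = ["mann_whitney", "bh_adjust", "univariate_screen"]


def mann_whitney(pos_values, neg_values) -> tuple[float, float]:
    """Mann-Whitney U (ties counted half) and two-sided p value.

    U is the number of (positive, negative) pairs where the positive value
    is larger, plus half the tied pairs.  The p value uses the
    tie-corrected normal approximation, or exact enumeration for small
    tie-free samples.
    """
    pos = np.asarray(pos_values, dtype=float)
    neg = np.asarray(neg_values, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both groups need at least one value")
    method = "exact" if (pos.size <= 8 and neg.size <= 8) else "asymptotic"
    res = sps.mannwhitneyu(pos, neg, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg adjusted q values, in the input order."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def univariate_screen(features: pd.DataFrame, positives,
                      negatives: NegativeSetCollection,
                      cancer_label: str = "") -> pd.DataFrame:
    """Per-feature U, p and BH q for targets vs pooled non-targets.

    Returns one row per feature column with columns U, p, q, n_pos,
    n_neg.  Negatives are pooled over all sets; each positive gene
    contributes exactly once.
    """
    pos_genes = [g for g in sorted(set(positives)) if g in features.index]
    neg_genes = sorted(g for s in negatives.sets for g in s if g in features.index)
    if not pos_genes or not neg_genes:
        raise ValueError("need feature data for both classes")
    pos = features.loc[pos_genes]
    neg = features.loc[neg_genes]
    rows = []
    for col in features.columns:
        u, p = mann_whitney(pos[col].to_numpy(), neg[col].to_numpy())
        rows.append((col, u, p))
    report = pd.DataFrame(rows, columns=["feature", "U", "p"]).set_index("feature")
    report["q"] = bh_adjust(report["p"].to_numpy())
    report["n_pos"] = len(pos_genes)
    report["n_neg"] = len(neg_genes)
    if cancer_label:
        report["cancer"] = cancer_label
    return report
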