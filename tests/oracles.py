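"""Independent brute-force oracles used to cross-check the statistics.

These deliberately avoid the implementation path (scipy / statsmodels /
sklearn calls inside the package) by direct enumeration over pairs and
the step-up definition of the FDR procedure.
"""

from __future__ import annotations

import numpy as np


def auroc_pairwise(scores, labels) -> float:
    """AUROC by exhaustive pair counting (ties count one half)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return float(wins) / (len(pos) * len(neg))


def mann_whitney_u(pos, neg) -> float:
    """U statistic by exhaustive pair enumeration."""
    pos = np.asarray(pos, dtype=float)
    neg = np.asarray(neg, dtype=float)
    return float(sum((x > y) + 0.5 * (x == y) for x in pos for y in neg))


def bh_stepup(pvals) -> np.ndarray:
    """Benjamini-Hochberg adjusted values straight from the definition:
    q_(i) = min_{j >= i} m * p_(j) / j, clipped at 1, in original order."""
    p = np.asarray(pvals, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    q_sorted = np.empty(m)
    for rank_i in range(m):
        q_sorted[rank_i] = min(
            m * p[order[j]] / (j + 1) for j in range(rank_i, m))
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def spearman_rho(x, y) -> float:
    """Spearman correlation as Pearson correlation of average ranks."""
    def avg_ranks(v):
        v = np.asarray(v, dtype=float)
        order = np.argsort(v, kind="stable")
        ranks = np.empty(v.size)
        i = 0
        sv = v[order]
        while i < v.size:
            j = i
            while j < v.size and sv[j] == sv[i]:
                j += 1
            ranks[order[i:j]] = (i + j - 1) / 2.0 + 1.0
            i = j
        return ranks

    rx, ry = avg_ranks(x), avg_ranks(y)
    rx -= rx.mean()
    ry -= ry.mean()
    return float((rx * ry).sum() / np.sqrt((rx ** 2).sum() * (ry ** 2).sum()))
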