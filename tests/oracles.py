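"""Independent brute-force / closed-form oracles used only by the tests.

These deliberately avoid the package's own code paths: Fisher p by full
hypergeometric enumeration, Welch t by the textbook formula, median-of-ratios
size factors by direct per-gene arithmetic, Spearman rho by the sum of
squared rank differences.
"""

from __future__ import annotations

from math import comb, sqrt

import numpy as np


def fisher_two_sided_enum(tp: int, fn: int, fp: int, tn: int) -> float:
    """Two-sided Fisher p: total probability of tables (fixed margins) at
    most as probable as the observed one, by full enumeration."""
    r1, r2 = tp + fn, fp + tn
    c1 = tp + fp
    n = r1 + r2
    denom = comb(n, c1)
    lo, hi = max(0, c1 - r2), min(r1, c1)
    probs = {x: comb(r1, x) * comb(r2, c1 - x) / denom for x in range(lo, hi + 1)}
    p_obs = probs[tp]
    # small relative epsilon for float ties, matching common implementations
    return sum(p for p in probs.values() if p <= p_obs * (1 + 1e-7))


def welch_t(x, y) -> float:
    """Textbook unequal-variance two-sample t-statistic."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    return (x.mean() - y.mean()) / sqrt(vx / len(x) + vy / len(y))


def median_of_ratios(matrix: np.ndarray) -> np.ndarray:
    """Per-sample size factors by direct computation: per-gene geometric mean
    over genes positive in all samples, then per-sample median ratio."""
    m = np.asarray(matrix, float)
    keep = (m > 0).all(axis=1)
    ref = m[keep]
    geo = np.exp(np.log(ref).mean(axis=1))
    return np.median(ref / geo[:, None], axis=0)


def spearman_d2(x, y) -> float:
    """Spearman rho via 1 - 6*sum(d^2)/(n(n^2-1)); valid without ties."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    rx = np.argsort(np.argsort(x)) + 1
    ry = np.argsort(np.argsort(y)) + 1
    n = len(x)
    d2 = np.sum((rx - ry) ** 2)
    return 1 - 6 * d2 / (n * (n**2 - 1))


def quantile_normalize_oracle(matrix: np.ndarray) -> np.ndarray:
    """Direct order-statistic quantile normalization (no tie handling)."""
    m = np.asarray(matrix, float)
    ref = np.sort(m, axis=0).mean(axis=1)
    out = np.empty_like(m)
    for j in range(m.shape[1]):
        order = np.argsort(m[:, j], kind="stable")
        out[order, j] = ref
    return out


def auc_rank_oracle(scores, labels) -> float:
    """AUC as the tie-credited rank probability, by direct pair counting."""
    s = np.asarray(scores, float)
    y = np.asarray(labels).astype(bool)
    pos, neg = s[y], s[~y]
    wins = sum((p > neg).sum() + 0.5 * (p == neg).sum() for p in pos)
    return wins / (len(pos) * len(neg))
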