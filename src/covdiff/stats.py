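"""Non-parametric screens, effect sizes, and multiple-testing correction."""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps


@dataclass
class EffectSize:
    metric: str            # "cliffs_delta" | "spearman_rho"
    value: float
    interval: str = "overall"


def cliffs_delta(x, y, interval="overall") -> EffectSize:
    """Cliff's delta of x (later level) versus y (earlier level).

    delta = (#{x_i > y_j} - #{x_i < y_j}) / (|x| * |y|); ties contribute 0.
    Positive values mean the later group tends to be larger.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("cliffs_delta requires nonempty inputs")
    # count via sorted y: for each x, #(y < x) - #(y > x)
    ys = np.sort(y)
    gt = np.searchsorted(ys, x, side="left")          # y strictly below x
    lt = y.size - np.searchsorted(ys, x, side="right")  # y strictly above x
    d = float((gt.sum() - lt.sum()) / (x.size * y.size))
    return EffectSize("cliffs_delta", d, interval)


def spearman_rho(x, y, interval="overall"):
    """Spearman rank correlation with the t-approximation p-value.

    Returns (EffectSize, p). Constant input gives a missing (NaN) value.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise ValueError("spearman_rho requires >= 3 pairs")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return EffectSize("spearman_rho", np.nan, interval), np.nan
    rho, p = sps.spearmanr(x, y)
    return EffectSize("spearman_rho", float(rho), interval), float(p)


def _exact_ranksum_p(x, y):
    """Two-sided p by exhaustive enumeration of rank assignments (small n)."""
    from itertools import combinations
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    n1 = len(x)
    obs = ranks[:n1].sum()
    idx = range(len(pooled))
    stats_all = np.array([ranks[list(c)].sum()
                          for c in combinations(idx, n1)])
    center = ranks.sum() * n1 / len(pooled)
    p = np.mean(np.abs(stats_all - center) >= np.abs(obs - center) - 1e-12)
    return float(p)


def wilcoxon_ranksum(x, y, exact_below=10):
    """Two-sided Wilcoxon rank-sum p-value.

    Mean ranks for ties and a tie-corrected normal approximation (no
    continuity correction); exhaustive enumeration when the combined sample
    is smaller than ``exact_below``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("wilcoxon_ranksum requires nonempty groups")
    n1, n2 = len(x), len(y)
    n = n1 + n2
    if n < exact_below:
        return _exact_ranksum_p(x, y)
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    R1 = ranks[:n1].sum()
    mu = n1 * (n + 1) / 2.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(tie_counts ** 3 - tie_counts) / (n * (n - 1))
    var = n1 * n2 / 12.0 * (n + 1 - tie_term)
    if var <= 0:
        return 1.0
    z = (R1 - mu) / np.sqrt(var)
    return float(2 * sps.norm.sf(abs(z)))


def kruskal_wallis(groups):
    """Tie-corrected Kruskal-Wallis p-value (chi-square approximation)."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if any(g.size == 0 for g in groups):
        raise ValueError("kruskal_wallis requires nonempty groups")
    if len(groups) < 2:
        raise ValueError("kruskal_wallis requires >= 2 groups")
    _, p = sps.kruskal(*groups)
    return float(p)


def bh_adjust(pvalues, method="bh"):
    """Multiple-testing adjustment; missing entries pass through as missing.

    ``bh`` is Benjamini-Hochberg step-up; ``holm`` and ``bonferroni`` are the
    family-wise alternatives. q-values are returned in input order, capped at 1.
    """
    p = np.asarray(pvalues, dtype=float)
    out = np.full(p.shape, np.nan)
    ok = ~np.isnan(p)
    pv = p[ok]
    if np.any((pv < 0) | (pv > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = pv.size
    if m == 0:
        return out
    if method == "bonferroni":
        out[ok] = np.minimum(pv * m, 1.0)
        return out
    order = np.argsort(pv, kind="stable")
    q = np.empty(m)
    if method == "bh":
        ranked = pv[order] * m / np.arange(1, m + 1)
        q[order] = np.minimum.accumulate(ranked[::-1])[::-1]
    elif method == "holm":
        ranked = pv[order] * (m - np.arange(m))
        q[order] = np.maximum.accumulate(ranked)
    else:
        raise ValueError(f"unknown adjustment method {method!r}")
    out[ok] = np.minimum(q, 1.0)
    return out


__all__ = ["EffectSize", "cliffs_delta", "spearman_rho", "wilcoxon_ranksum",
           "kruskal_wallis", "bh_adjust"]
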