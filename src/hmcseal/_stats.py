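"""Shared low-level statistics used across modules.

Rank-sum and log-rank are implemented here directly (the pipeline's group
comparisons are its substance and the permutation machinery needs them
vectorizable); Benjamini-Hochberg goes through statsmodels.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = ["bh_adjust", "rank_sum_test", "logrank_statistic"]


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (NaN-tolerant)."""
    p = np.asarray(pvalues, dtype=float)
    out = np.full(p.shape, np.nan)
    ok = np.isfinite(p)
    if ok.any():
        out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return out


def rank_sum_test(x, y, method: str = "asymptotic") -> tuple[float, float]:
    """Two-sample Wilcoxon rank-sum (Mann-Whitney) test.

    Returns ``(U, p)`` where ``U`` is the Mann-Whitney statistic for the
    first sample (number of (x, y) pairs with x > y, ties counted 1/2).

    method="asymptotic": normal approximation with tie correction, no
    continuity correction, two-sided.
    method="exact": full enumeration of the permutation distribution of U
    over all group assignments of the pooled values (handles ties); the
    two-sided p is the probability of a |U - n1*n2/2| at least as large as
    observed.  Enumeration cost is C(n1+n2, n1); intended for small samples.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 == 0 or n2 == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    u = ranks[:n1].sum() - n1 * (n1 + 1) / 2.0

    if method == "exact":
        n = n1 + n2
        order = np.argsort(pooled, kind="mergesort")
        ranks_sorted = stats.rankdata(pooled)  # midranks of pooled values
        center = n1 * n2 / 2.0
        obs_dev = abs(u - center)
        hits = 0
        total = 0
        for idx in combinations(range(n), n1):
            u_perm = ranks_sorted[list(idx)].sum() - n1 * (n1 + 1) / 2.0
            # tolerate float fuzz from midranks
            if abs(u_perm - center) >= obs_dev - 1e-9:
                hits += 1
            total += 1
        del order
        return float(u), hits / total

    if method != "asymptotic":
        raise ValueError(f"unknown method {method!r}")
    n = n1 + n2
    mean_u = n1 * n2 / 2.0
    # tie correction on the variance
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = ((counts**3 - counts).sum()) / (n * (n - 1)) if n > 1 else 0.0
    var_u = n1 * n2 / 12.0 * (n + 1 - tie_term)
    if var_u <= 0:
        return float(u), 1.0
    z = (u - mean_u) / np.sqrt(var_u)
    p = 2.0 * stats.norm.sf(abs(z))
    return float(u), float(min(p, 1.0))


def logrank_statistic(time, event, group) -> tuple[float, float]:
    """Two-group log-rank test.

    At each distinct event time the observed events in group 1 are compared
    with their hypergeometric expectation given the risk sets; the squared
    standardized sum of (O - E) is chi-square with 1 df.

    Returns ``(chi2, p)``.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    group = np.asarray(group)
    labels = np.unique(group)
    if len(labels) != 2:
        raise ValueError("log-rank requires exactly two groups")
    g1 = group == labels[1]
    if event.sum() == 0:
        raise ValueError("no events observed")
    o_minus_e = 0.0
    var = 0.0
    for t in np.unique(time[event == 1]):
        at_risk = time >= t
        n = at_risk.sum()
        n1 = (at_risk & g1).sum()
        d = ((time == t) & (event == 1)).sum()
        d1 = ((time == t) & (event == 1) & g1).sum()
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    if var <= 0:
        return 0.0, 1.0
    chi2 = o_minus_e**2 / var
    return float(chi2), float(stats.chi2.sf(chi2, df=1))
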