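"""Two-sample tests used in the subgroup tables.

Numeric covariates are compared between the AKI and no-AKI groups with the
Wilcoxon rank-sum test (exact enumeration for small samples, tie-corrected
normal approximation otherwise); categorical covariates with Pearson's
chi-squared test of independence, without continuity correction. No
multiple-testing correction is applied to the table.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
from scipy.stats import chi2 as chi2_dist
from scipy.stats import norm, rankdata

from .errors import PreconditionError


def wilcoxon_rank_sum(
    x,
    y,
    exact_max_n: int = 20,
    continuity: bool = True,
) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Returns ``(U, p)`` where U is the Mann-Whitney statistic of ``x``.
    Exact enumeration of rank-sum assignments when the pooled sample has at
    most ``exact_max_n`` observations, otherwise the normal approximation
    with tie correction (and optional continuity correction).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 == 0 or n2 == 0:
        raise PreconditionError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    w = ranks[:n1].sum()  # rank sum of x
    u = w - n1 * (n1 + 1) / 2.0

    n = n1 + n2
    if n <= exact_max_n:
        # enumerate every assignment of n1 ranks out of the observed ranks
        sums = np.fromiter(
            (sum(c) for c in combinations(ranks, n1)), dtype=float
        )
        p = 2.0 * min((sums <= w + 1e-12).mean(), (sums >= w - 1e-12).mean())
        return float(u), float(min(p, 1.0))

    mean_w = n1 * (n + 1) / 2.0
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = (counts**3 - counts).sum() / (n * (n - 1))
    var_w = n1 * n2 / 12.0 * (n + 1 - tie_term)
    if var_w <= 0:  # all observations identical
        return float(u), 1.0
    d = w - mean_w
    if continuity:
        d = np.sign(d) * max(abs(d) - 0.5, 0.0)
    z = d / np.sqrt(var_w)
    return float(u), float(2.0 * norm.sf(abs(z)))


def chi2_independence(table) -> tuple[float, int, float]:
    """Pearson chi-squared test of independence on an r x c count table.

    Returns ``(statistic, dof, p)``; no continuity correction.
    """
    obs = np.asarray(table, dtype=float)
    if obs.ndim != 2 or (obs < 0).any():
        raise PreconditionError("table must be a 2-D array of non-negative counts")
    total = obs.sum()
    if total == 0:
        raise PreconditionError("table must contain at least one observation")
    rows = obs.sum(axis=1, keepdims=True)
    cols = obs.sum(axis=0, keepdims=True)
    expected = rows @ cols / total
    if (expected == 0).any():
        # drop all-zero margins: they contribute no information
        keep_r = rows.ravel() > 0
        keep_c = cols.ravel() > 0
        obs = obs[np.ix_(keep_r, keep_c)]
        rows = obs.sum(axis=1, keepdims=True)
        cols = obs.sum(axis=0, keepdims=True)
        expected = rows @ cols / total
    stat = float(((obs - expected) ** 2 / expected).sum())
    dof = (obs.shape[0] - 1) * (obs.shape[1] - 1)
    if dof <= 0:
        return 0.0, 0, 1.0
    return stat, dof, float(chi2_dist.sf(stat, dof))
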