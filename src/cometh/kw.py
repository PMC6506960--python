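"""Kruskal-Wallis comparison of SMR count/length distributions.

The tie-corrected Kruskal-Wallis H statistic on mid-ranks:

    H = [ 12 / (N (N+1)) * sum_i n_i (rbar_i - (N+1)/2)^2 ] / C
    C = 1 - sum_t (t^3 - t) / (N^3 - N)

with N the pooled size, n_i and rbar_i each group's size and mean rank,
and t running over tie-group sizes.  The tie correction always applies:
SMR CG counts are heavily tied at small values (2, 3, ...), so the
uncorrected statistic would be materially smaller.  The p-value uses the
chi-squared approximation with k-1 degrees of freedom, appropriate at the
group sizes this pipeline sees (thousands of regions per state).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import chi2, rankdata

from .errors import UsageError


@dataclass
class KWResult:
    h_statistic: float
    df: int
    p_value: float
    group_sizes: tuple[int, ...]


def kruskal_wallis(groups: Sequence[np.ndarray]) -> KWResult:
    """Tie-corrected Kruskal-Wallis test over k >= 2 non-empty groups.

    When every pooled value is identical the tie correction degenerates to
    0; the statistic is then defined as 0 with p = 1 (no evidence of any
    difference), not an error.
    """
    groups = [np.asarray(g, dtype=float).ravel() for g in groups]
    if len(groups) < 2:
        raise UsageError("need at least 2 groups")
    if any(g.size == 0 for g in groups):
        raise UsageError("empty group passed to the Kruskal-Wallis test")
    sizes = np.array([g.size for g in groups])
    n_total = int(sizes.sum())
    pooled = np.concatenate(groups)
    ranks = rankdata(pooled)  # mid-ranks for ties
    dof = len(groups) - 1

    # tie correction: 1 - sum(t^3 - t) / (N^3 - N)
    _, tie_counts = np.unique(pooled, return_counts=True)
    correction = 1.0 - (tie_counts**3 - tie_counts).sum() / (n_total**3 - n_total)
    if correction == 0.0:  # all pooled values identical
        return KWResult(0.0, dof, 1.0, tuple(int(s) for s in sizes))

    grand_mean = (n_total + 1) / 2.0
    h = 0.0
    start = 0
    for sz in sizes:
        rbar = ranks[start : start + sz].mean()
        h += sz * (rbar - grand_mean) ** 2
        start += sz
    h *= 12.0 / (n_total * (n_total + 1))
    h /= correction
    return KWResult(
        float(h), dof, float(chi2.sf(h, dof)), tuple(int(s) for s in sizes)
    )


def pairwise_kw(
    groups: Mapping[str, np.ndarray]
) -> dict[tuple[str, str], KWResult]:
    """One two-group test (df = 1) per unordered pair of labelled groups.

    No multiplicity adjustment is applied; see
    :func:`benjamini_hochberg` for an optional FDR adjustment of the
    resulting p-values.
    """
    labels = list(groups)
    if len(labels) < 2:
        raise UsageError("need at least 2 labelled groups")
    return {
        (a, b): kruskal_wallis([groups[a], groups[b]])
        for a, b in itertools.combinations(labels, 2)
    }


def benjamini_hochberg(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (step-up FDR)."""
    from scipy.stats import false_discovery_control

    return false_discovery_control(np.asarray(p_values, dtype=float), method="bh")
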