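"""Shared statistical primitives: Mann-Whitney U, BH FDR, one-sided Fisher.

These are the workhorse tests of the whole analysis: group comparisons use
the Mann-Whitney U test and multiplicity is controlled with the
Benjamini-Hochberg step-up procedure (FDR < 0.05 unless stated otherwise).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = ["StatResult", "mann_whitney", "benjamini_hochberg", "fisher_one_sided"]


@dataclass
class StatResult:
    statistic: float
    p_value: float
    method: str
    n_x: int
    n_y: int

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0 or np.isnan(self.p_value)):
            raise ValueError(f"p-value outside [0,1]: {self.p_value}")


_EXACT_MAX_N = 8


def mann_whitney(x, y, alternative: str = "two-sided") -> StatResult:
    """Mann-Whitney U test between two independent samples.

    The p-value is exact (full enumeration of rank arrangements) when both
    groups have at most 8 observations and there are no ties; otherwise the
    normal approximation with tie and continuity correction is used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("mann_whitney requires nonempty samples")
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < pooled.size
    exact = x.size <= _EXACT_MAX_N and y.size <= _EXACT_MAX_N and not has_ties
    method = "exact" if exact else "asymptotic"
    res = sps.mannwhitneyu(
        x, y, alternative=alternative, method=method, use_continuity=True
    )
    return StatResult(
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        method=f"mann-whitney-{method}",
        n_x=int(x.size),
        n_y=int(y.size),
    )


def benjamini_hochberg(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    q_i = min over j with p_(j) >= p_(i) of m * p_(j) / j, capped at 1;
    the adjustment is monotone in p. NaN entries propagate to NaN.
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    finite = ~np.isnan(p)
    vals = p[finite]
    if vals.size and (np.any(vals < 0) or np.any(vals > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    q = np.full(p.shape, np.nan)
    if vals.size:
        q[finite] = multipletests(vals, method="fdr_bh")[1]
    return q


def fisher_one_sided(in_cat_with_label: int, in_cat_without: int,
                     out_cat_with_label: int, out_cat_without: int) -> tuple[float, float]:
    """One-sided (enrichment) Fisher exact test on a 2x2 table.

    Returns ``(odds_ratio, p)`` where p is the upper hypergeometric tail:
    the probability of drawing at least the observed number of labeled
    features into the category under random assignment.
    """
    table = [[in_cat_with_label, in_cat_without],
             [out_cat_with_label, out_cat_without]]
    odds, p = sps.fisher_exact(table, alternative="greater")
    return float(odds), float(p)
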