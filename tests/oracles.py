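"""Independent brute-force oracles used by the test suite.

Each function re-derives a statistic from first principles (enumeration or
the naive definition) without touching the package's implementation path.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
from scipy import stats as sps


def bh_naive(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values by the O(m^2) definition:
    q_i = min over j with p_(j) >= p_(i) of m * p_(j) / j, capped at 1."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    for i in range(m):
        candidates = [
            m * p[order[j]] / (j + 1)
            for j in range(m)
            if p[order[j]] >= p[i] - 1e-300
        ]
        q[i] = min(1.0, min(candidates))
    return q


def mann_whitney_exact_enum(x, y, alternative: str = "two-sided") -> float:
    """Exact Mann-Whitney p by full enumeration of rank arrangements.

    Requires tie-free data. U is counted for the x sample; the two-sided
    p doubles the smaller tail (capped at 1), matching the exact
    distribution convention.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n, m = len(x), len(y)
    pooled = np.concatenate([x, y])
    assert len(np.unique(pooled)) == n + m, "enumeration oracle needs tie-free data"
    ranks = sps.rankdata(pooled)
    u_obs = ranks[:n].sum() - n * (n + 1) / 2
    total = math.comb(n + m, n)
    us = []
    all_ranks = np.arange(1, n + m + 1)
    for combo in itertools.combinations(range(n + m), n):
        r = all_ranks[list(combo)].sum()
        us.append(r - n * (n + 1) / 2)
    us = np.array(us)
    p_greater = np.mean(us >= u_obs - 1e-9)
    p_less = np.mean(us <= u_obs + 1e-9)
    if alternative == "greater":
        return float(p_greater)
    if alternative == "less":
        return float(p_less)
    return float(min(1.0, 2 * min(p_greater, p_less)))


def fisher_tail_enum(a: int, b: int, c: int, d: int) -> float:
    """One-sided (enrichment) Fisher p as the explicit hypergeometric tail:
    P(X >= a) with margins fixed, summed via binomial coefficients."""
    row1, col1, total = a + b, a + c, a + b + c + d
    denom = math.comb(total, row1)
    p = 0.0
    for k in range(a, min(row1, col1) + 1):
        if col1 - k <= total - row1:
            p += math.comb(col1, k) * math.comb(total - col1, row1 - k) / denom
    return p


def two_way_f_tests(y, gf, seg_codes, n_segments):
    """Term-wise F statistics from explicit design matrices and RSS ratios.

    Returns (F_interaction, F_colonization, F_segment) with the interaction
    tested full-vs-additive and the mains Type II within the additive model.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    seg_dum = np.zeros((n, n_segments - 1))
    for j in range(1, n_segments):
        seg_dum[:, j - 1] = (seg_codes == j)
    one = np.ones((n, 1))
    gf = np.asarray(gf, dtype=float).reshape(-1, 1)
    X_full = np.hstack([one, gf, seg_dum, seg_dum * gf])
    X_add = np.hstack([one, gf, seg_dum])
    X_seg = np.hstack([one, seg_dum])
    X_col = np.hstack([one, gf])

    def rss(X):
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        r = y - X @ beta
        return float(r @ r)

    rss_full, rss_add = rss(X_full), rss(X_add)
    rss_seg, rss_col = rss(X_seg), rss(X_col)
    df_full = n - X_full.shape[1]
    df_add = n - X_add.shape[1]
    g1 = n_segments - 1
    f_int = ((rss_add - rss_full) / g1) / (rss_full / df_full)
    f_col = ((rss_seg - rss_add) / 1) / (rss_add / df_add)
    f_seg = ((rss_col - rss_add) / g1) / (rss_add / df_add)
    return f_int, f_col, f_seg
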