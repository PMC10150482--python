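"""Independent brute-force reference implementations used only by tests.

These deliberately avoid the package's own code paths (and the library
routines those paths call) so that agreement is a genuine cross-check:
Spearman via explicit average ranks + Pearson sums, BH via the hand-written
step-up recursion, the rank-sum test via exhaustive enumeration.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def average_ranks(values) -> np.ndarray:
    v = np.asarray(values, dtype=float)
    order = np.argsort(v, kind="stable")
    ranks = np.empty(v.size, dtype=float)
    i = 0
    sorted_v = v[order]
    while i < v.size:
        j = i
        while j + 1 < v.size and sorted_v[j + 1] == sorted_v[i]:
            j += 1
        ranks[order[i:j + 1]] = (i + j) / 2.0 + 1.0
        i = j + 1
    return ranks


def pearson(x, y) -> float:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    xm, ym = x - x.mean(), y - y.mean()
    denom = math.sqrt((xm * xm).sum() * (ym * ym).sum())
    return float((xm * ym).sum() / denom)


def spearman_rho(x, y) -> float:
    """Pearson correlation of average ranks (handles ties)."""
    return pearson(average_ranks(x), average_ranks(y))


def spearman_rho_no_ties(x, y) -> float:
    """Classic 1 - 6 sum d^2 / (n (n^2 - 1)); valid without ties."""
    rx, ry = average_ranks(x), average_ranks(y)
    d = rx - ry
    n = len(rx)
    return 1.0 - 6.0 * float((d * d).sum()) / (n * (n * n - 1))


def spearman_p_t(rho: float, n: int) -> float:
    """Two-sided p from the t approximation on n - 2 df."""
    from scipy.stats import t as tdist
    if abs(rho) >= 1.0:
        return 0.0
    t = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
    return 2.0 * float(tdist.sf(abs(t), df=n - 2))


def bh_stepup(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, written from scratch."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    adjusted = np.empty(m, dtype=float)
    prev = 1.0
    for rank_from_top in range(m, 0, -1):
        idx = order[rank_from_top - 1]
        value = min(prev, p[idx] * m / rank_from_top)
        adjusted[idx] = value
        prev = value
    return adjusted


def brute_force_network_edges(values: np.ndarray, rho_threshold: float,
                              alpha: float) -> list[tuple[int, int, float]]:
    """All-pairs Spearman + step-up BH; returns (i, j, rho) for kept edges.

    ``values`` is an OTU x sample matrix with no constant rows.
    """
    n_otus, n_samples = values.shape
    pairs = list(itertools.combinations(range(n_otus), 2))
    rhos, ps = [], []
    for i, j in pairs:
        rho = spearman_rho(values[i], values[j])
        rhos.append(rho)
        ps.append(spearman_p_t(rho, n_samples))
    adjusted = bh_stepup(ps)
    kept = []
    for (i, j), rho, adj in zip(pairs, rhos, adjusted):
        if abs(rho) > rho_threshold and adj < alpha:
            kept.append((i, j, rho))
    return kept


def rank_sum_exact_p(a, b) -> float:
    """Exact two-sided Mann-Whitney p by exhausting all group assignments.

    Two-sided tail: arrangements whose U statistic is at least as far from
    the null mean n_a n_b / 2 as the observed one.
    """
    a = list(map(float, a))
    b = list(map(float, b))
    combined = a + b
    n_a, n = len(a), len(combined)
    ranks = average_ranks(combined)

    def u_stat(idx_a):
        rank_sum = sum(ranks[i] for i in idx_a)
        return rank_sum - n_a * (n_a + 1) / 2.0

    observed = u_stat(range(n_a))
    center = n_a * (n - n_a) / 2.0
    obs_dev = abs(observed - center)
    count = total = 0
    for idx_a in itertools.combinations(range(n), n_a):
        total += 1
        if abs(u_stat(idx_a) - center) >= obs_dev - 1e-12:
            count += 1
    return count / total


def ols_normal_equations(x, y) -> tuple[float, float, float]:
    """(slope, intercept, R^2) by solving the normal equations directly."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    design = np.column_stack([np.ones_like(x), x])
    beta = np.linalg.solve(design.T @ design, design.T @ y)
    fitted = design @ beta
    ss_res = float(((y - fitted) ** 2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    return float(beta[1]), float(beta[0]), 1.0 - ss_res / ss_tot
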