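"""Independent brute-force oracles used by the unit and acceptance tests.

Each function re-derives a quantity from first principles (enumeration,
quadrature, naive loops) without touching the package's implementation,
so agreement between the two is a meaningful check.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
from scipy import integrate, stats


def background_posterior_mean_quadrature(o: float, mu: float, sigma: float,
                                         alpha: float) -> float:
    """E[s | o] for o = s + n, s ~ Exp(alpha), n ~ N(mu, sigma^2), by
    numerical integration of the truncated posterior."""

    def unnorm(s: float) -> float:
        return math.exp(-alpha * s) * stats.norm.pdf(o - s, loc=mu, scale=sigma)

    upper = o + 10 * sigma
    num, _ = integrate.quad(lambda s: s * unnorm(s), 0.0, upper, limit=400)
    den, _ = integrate.quad(unnorm, 0.0, upper, limit=400)
    return num / den


def quantile_normalize_naive(x: np.ndarray) -> np.ndarray:
    """Rank/sort-based quantile normalisation for tie-free matrices."""
    target = np.sort(x, axis=0).mean(axis=1)
    out = np.empty_like(x, dtype=float)
    for j in range(x.shape[1]):
        order = np.argsort(x[:, j])
        for rank, i in enumerate(order):
            out[i, j] = target[rank]
    return out


def median_polish_naive(x: np.ndarray, n_sweeps: int = 64):
    """Plain row-then-column median sweep loop; returns (overall, row, col,
    residuals, objective trace)."""
    r = np.array(x, dtype=float)
    nr, nc = r.shape
    overall = 0.0
    row = [0.0] * nr
    col = [0.0] * nc
    objectives = [float(np.abs(r).sum())]
    for _ in range(n_sweeps):
        for i in range(nr):
            m = float(np.median(r[i, :]))
            row[i] += m
            r[i, :] -= m
        m = float(np.median(col))
        overall += m
        col = [c - m for c in col]
        for j in range(nc):
            m = float(np.median(r[:, j]))
            col[j] += m
            r[:, j] -= m
        m = float(np.median(row))
        overall += m
        row = [v - m for v in row]
        objectives.append(float(np.abs(r).sum()))
    return overall, np.array(row), np.array(col), r, objectives


def pooled_t_closed_form(case: np.ndarray, control: np.ndarray):
    """Textbook pooled two-sample t with the incomplete-beta tail."""
    n1, n2 = len(case), len(control)
    df = n1 + n2 - 2
    sp2 = (np.sum((case - case.mean()) ** 2)
           + np.sum((control - control.mean()) ** 2)) / df
    t = (case.mean() - control.mean()) / math.sqrt(sp2 * (1 / n1 + 1 / n2))
    from scipy.special import betainc
    p = betainc(df / 2.0, 0.5, df / (df + t * t))
    return t, p


def bh_stepup_naive(p: list[float]) -> list[float]:
    """min over j >= i of p_(j) * n / j, mapped back to input order."""
    n = len(p)
    order = sorted(range(n), key=lambda i: p[i])
    adjusted = [0.0] * n
    running = 1.0
    for rank in range(n - 1, -1, -1):
        i = order[rank]
        running = min(running, p[i] * n / (rank + 1))
        adjusted[i] = running
    return adjusted


def average_linkage_naive(points: np.ndarray, metric) -> list[float]:
    """Agglomerative average linkage by exhaustive pairwise-mean
    recomputation; returns the sorted merge heights."""
    clusters: list[list[int]] = [[i] for i in range(len(points))]
    d = {(i, j): metric(points[i], points[j])
         for i in range(len(points)) for j in range(i + 1, len(points))}

    def cdist(a: list[int], b: list[int]) -> float:
        vals = [d[(min(i, j), max(i, j))] for i in a for j in b]
        return sum(vals) / len(vals)

    heights = []
    while len(clusters) > 1:
        best = None
        for ai in range(len(clusters)):
            for bi in range(ai + 1, len(clusters)):
                h = cdist(clusters[ai], clusters[bi])
                if best is None or h < best[0]:
                    best = (h, ai, bi)
        h, ai, bi = best
        heights.append(h)
        merged = clusters[ai] + clusters[bi]
        clusters = [c for k, c in enumerate(clusters) if k not in (ai, bi)]
        clusters.append(merged)
    return sorted(heights)


def spearman_naive(x, y) -> float:
    """Average ranks computed by explicit sorting, then the Pearson
    formula."""

    def avg_ranks(v):
        order = sorted(range(len(v)), key=lambda i: v[i])
        ranks = [0.0] * len(v)
        i = 0
        while i < len(v):
            j = i
            while j + 1 < len(v) and v[order[j + 1]] == v[order[i]]:
                j += 1
            mean_rank = (i + j) / 2.0 + 1.0
            for k in range(i, j + 1):
                ranks[order[k]] = mean_rank
            i = j + 1
        return ranks

    rx, ry = avg_ranks(list(x)), avg_ranks(list(y))
    mx, my = sum(rx) / len(rx), sum(ry) / len(ry)
    num = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    den = math.sqrt(sum((a - mx) ** 2 for a in rx)
                    * sum((b - my) ** 2 for b in ry))
    return num / den


def spearman_exact_p_naive(x, y) -> float:
    """Two-sided permutation p-value by looping over every permutation."""
    rho_obs = abs(spearman_naive(x, y))
    y = list(y)
    count = total = 0
    for perm in itertools.permutations(y):
        total += 1
        if abs(spearman_naive(x, perm)) >= rho_obs - 1e-12:
            count += 1
    return count / total


def hypergeom_tail_enumeration(k: int, n: int, K: int, N: int) -> float:
    """P(X >= k) for drawing n from N with K successes, by enumerating
    all C(N, n) draws.  Only feasible for tiny N."""
    population = [1] * K + [0] * (N - K)
    hits = total = 0
    for draw in itertools.combinations(range(N), n):
        total += 1
        if sum(population[i] for i in draw) >= k:
            hits += 1
    return hits / total


def pwm_relative_score_naive(weights: np.ndarray, window: str) -> float:
    """Relative score by explicit per-position lookup and min/max sums."""
    alphabet = "ACGU"
    s = sum(weights[i][alphabet.index(c)] for i, c in enumerate(window))
    s_min = sum(min(row) for row in weights)
    s_max = sum(max(row) for row in weights)
    return (s - s_min) / (s_max - s_min)
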