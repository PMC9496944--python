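"""Independent reference implementations used as test oracles.

Everything here is deliberately written by the most literal route available
(enumeration, step-by-step loops, exact rational arithmetic) and stays
independent of the package's vectorized code paths.
"""

from __future__ import annotations

import itertools
import math
from fractions import Fraction

import numpy as np


def fisher_enumeration(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by brute-force enumeration with exact fractions.

    Walks every 2x2 table with the observed margins, computes each table's
    hypergeometric probability from the factorial formula as an exact
    Fraction, and sums the probabilities of tables no more probable than
    the observed one.
    """
    n = a + b + c + d
    r1, r2, c1, c2 = a + b, c + d, a + c, b + d
    f = math.factorial
    denom_const = f(n)

    def prob(x: int) -> Fraction:
        y, z, w = r1 - x, c1 - x, r2 - (c1 - x)
        if min(y, z, w) < 0:
            return Fraction(0)
        return Fraction(
            f(r1) * f(r2) * f(c1) * f(c2),
            denom_const * f(x) * f(y) * f(z) * f(w),
        )

    observed = prob(a)
    total = Fraction(0)
    for x in range(0, min(r1, c1) + 1):
        p = prob(x)
        if p > 0 and p <= observed:
            total += p
    return float(total)


def mannwhitney_enumeration(x, y) -> tuple[float, float]:
    """Exact two-sided Mann-Whitney p by enumerating group assignments.

    The U statistic is computed pairwise (wins + half-ties), not from
    ranks; extremeness is distance of U from its null mean.
    """
    x = list(map(float, x))
    y = list(map(float, y))
    n1, n2 = len(x), len(y)
    pooled = x + y

    def u_of(group1_idx: tuple[int, ...]) -> float:
        g1 = [pooled[i] for i in group1_idx]
        g2 = [pooled[i] for i in range(n1 + n2) if i not in set(group1_idx)]
        u = 0.0
        for a in g1:
            for b in g2:
                if a > b:
                    u += 1.0
                elif a == b:
                    u += 0.5
        return u

    u_obs = u_of(tuple(range(n1)))
    mu = n1 * n2 / 2.0
    dist = abs(u_obs - mu)
    hits = total = 0
    for comb in itertools.combinations(range(n1 + n2), n1):
        total += 1
        if abs(u_of(comb) - mu) >= dist - 1e-9:
            hits += 1
    return u_obs, hits / total


def gsva_reference(M, pathways, kcdf="ecdf", tau=1.0, es_mode="mx_diff", seed=0):
    """Step-by-step GSVA-style scores with plain Python loops.

    ``M`` is a samples x genes pandas DataFrame; returns a dict
    (pathway, sample) -> ES.  Shares only the documented tie-break contract
    with the implementation: a single ``default_rng(seed)`` permutation of
    the gene order.
    """
    from scipy.stats import norm, poisson

    samples = list(M.index)
    genes = list(M.columns)
    m, n = len(samples), len(genes)
    X = M.to_numpy(dtype=float)

    # kernel CDF per gene, one value per sample
    Z = [[0.0] * n for _ in range(m)]
    for j in range(n):
        col = [X[i][j] for i in range(m)]
        sd = float(np.std(col, ddof=1))
        for i in range(m):
            if kcdf == "ecdf" or (kcdf == "gaussian" and sd == 0.0):
                Z[i][j] = sum(1 for v in col if v <= col[i]) / m
            elif kcdf == "gaussian":
                h = sd / 4.0
                Z[i][j] = sum(norm.cdf((col[i] - v) / h) for v in col) / m
            elif kcdf == "poisson":
                Z[i][j] = sum(poisson.cdf(col[i], v + 0.5) for v in col) / m
            else:
                raise ValueError(kcdf)

    # documented tie-break contract: sort by (-z, shuffle[j])
    shuffle = np.random.default_rng(seed).permutation(n)
    out = {}
    for si, s in enumerate(samples):
        order = sorted(range(n), key=lambda j: (-Z[si][j], shuffle[j]))
        rank = {j: p + 1 for p, j in enumerate(order)}
        for name, gene_set in pathways.items():
            members = {j for j, g in enumerate(genes) if g in gene_set}
            if not members or len(members) == n:
                continue
            weights = {j: abs(n / 2.0 - rank[j]) ** tau for j in members}
            wsum = sum(weights.values()) or 1.0
            dec = 1.0 / (n - len(members))
            level = 0.0
            path = []
            for j in order:
                if j in members:
                    level += weights[j] / wsum
                else:
                    level -= dec
                path.append(level)
            mx, mn = max(path), min(path)
            if es_mode == "mx_diff":
                es = max(mx, 0.0) + min(mn, 0.0)
            else:
                es = mx if mx >= -mn else mn
            out[(name, s)] = es
    return out


def youden_exhaustive(scores, labels) -> tuple[float, float]:
    """Best (cutoff, J) by looping over every candidate threshold."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    distinct = np.unique(s)
    candidates = [-np.inf] + [
        (a + b) / 2.0 for a, b in zip(distinct[:-1], distinct[1:])
    ] + [np.inf]
    best = None
    for t in candidates:
        sens = ((s > t) & (y == 1)).sum() / (y == 1).sum()
        spec = ((s <= t) & (y == 0)).sum() / (y == 0).sum()
        j = sens + spec - 1.0
        if best is None or j > best[1] + 1e-12:
            best = (t, j)
    return best


def auc_mann_whitney(scores, labels) -> float:
    """AUC via the rank-sum estimator U / (n_pos * n_neg)."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    pos = s[y == 1]
    neg = s[y == 0]
    wins = sum((p > neg).sum() + 0.5 * (p == neg).sum() for p in pos)
    return float(wins) / (len(pos) * len(neg))


def logrank_hand(times, events, group):
    """Log-rank O/E/V life-table computation with explicit loops."""
    times = list(map(float, times))
    events = list(map(int, events))
    group = list(map(int, group))
    o_minus_e = 0.0
    var = 0.0
    for t in sorted({t for t, e in zip(times, events) if e == 1}):
        at_risk = [i for i, ti in enumerate(times) if ti >= t]
        n = len(at_risk)
        n1 = sum(1 for i in at_risk if group[i] == 1)
        deaths = [i for i, (ti, ei) in enumerate(zip(times, events)) if ti == t and ei == 1]
        d = len(deaths)
        d1 = sum(1 for i in deaths if group[i] == 1)
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    if var == 0:
        return 0.0
    return o_minus_e**2 / var
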