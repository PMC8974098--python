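"""Independent brute-force oracles used to check the vectorized code.

Everything here is a deliberately naive, loop-by-loop transcription of
the defining formulas, kept free of any call into the package under
test.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def naive_depth2(values: np.ndarray) -> list[float]:
    """Triple-loop evaluation of the ITH score definition.

    For each sample: per-gene absolute z against the cohort mean/SD
    (t−1 denominator), then the SD (m−1 denominator) of those absolute
    z values.  Zero-variance genes are skipped, mirroring the drop rule.
    """
    m, t = values.shape
    scores = []
    for j in range(t):
        zs = []
        for i in range(m):
            mean_i = sum(values[i, l] for l in range(t)) / t
            sd_i = math.sqrt(
                sum((values[i, l] - mean_i) ** 2 for l in range(t)) / (t - 1)
            )
            if sd_i <= 1e-12:
                continue
            zs.append(abs(values[i, j] - mean_i) / sd_i)
        mp = len(zs)
        zbar = sum(zs) / mp
        scores.append(math.sqrt(sum((z - zbar) ** 2 for z in zs) / (mp - 1)))
    return scores


def _average_ranks(vals: list[float]) -> list[float]:
    """Ascending average ranks (1-based), ties share the mean rank."""
    n = len(vals)
    ranks = [0.0] * n
    order = sorted(range(n), key=lambda i: vals[i])
    i = 0
    while i < n:
        j = i
        while j + 1 < n and vals[order[j + 1]] == vals[order[i]]:
            j += 1
        avg = (i + j) / 2 + 1
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def ssgsea_reference(
    expr: dict[str, float], gene_set: set[str], weight: float
) -> float:
    """Step-by-step running-sum enrichment score for one sample.

    Walk genes in descending-expression order (gene id breaks ties);
    at each step add the weighted in-set CDF minus the uniform
    out-of-set CDF.  In-set weights are the ascending average rank of
    the gene's expression raised to ``weight``, normalized to sum 1.
    """
    genes = sorted(expr, key=lambda g: (-expr[g], g))
    rank_of = dict(zip(list(expr), _average_ranks(list(expr.values()))))
    in_w = {g: rank_of[g] ** weight for g in genes if g in gene_set}
    total_in = sum(in_w.values())
    n_out = sum(1 for g in genes if g not in gene_set)
    es = 0.0
    cum_in = 0.0
    cum_out = 0
    for g in genes:
        if g in gene_set:
            cum_in += in_w[g]
        else:
            cum_out += 1
        es += cum_in / total_in - cum_out / n_out
    return es


def mw_enumerate_p(a, b, alternative: str = "greater") -> float:
    """Exact one-sided Mann–Whitney p by enumerating all group splits.

    Assumes no ties.  U counts pairs (x in a, y in b) with x > y; the
    p-value is the fraction of equally-likely label assignments whose U
    is at least (``greater``) / at most (``less``) as extreme.
    """

    def u_stat(xs, ys):
        return sum(1 for x in xs for y in ys if x > y)

    pooled = list(a) + list(b)
    na = len(a)
    u_obs = u_stat(a, b)
    us = [
        u_stat([pooled[i] for i in comb],
               [pooled[i] for i in range(len(pooled)) if i not in comb])
        for comb in itertools.combinations(range(len(pooled)), na)
    ]
    if alternative == "greater":
        hits = sum(1 for u in us if u >= u_obs)
    else:
        hits = sum(1 for u in us if u <= u_obs)
    return hits / len(us)


def bh_stepup(pvals: list[float]) -> list[float]:
    """Benjamini–Hochberg adjusted p-values by the step-up rule."""
    n = len(pvals)
    order = sorted(range(n), key=lambda i: pvals[i])
    adj = [0.0] * n
    running_min = 1.0
    for rank_from_top in range(n, 0, -1):
        i = order[rank_from_top - 1]
        running_min = min(running_min, pvals[i] * n / rank_from_top)
        adj[i] = running_min
    return adj


def logrank_hand(times, events, in_a) -> tuple[float, float, float]:
    """Log-rank O−E and variance for group a via explicit 2×2 tables.

    Returns (observed_a − expected_a, variance, chi-square statistic).
    """
    times = list(map(float, times))
    events = list(map(int, events))
    in_a = list(map(bool, in_a))
    o_minus_e = 0.0
    var = 0.0
    for tt in sorted({t for t, e in zip(times, events) if e == 1}):
        at_risk = [i for i, t in enumerate(times) if t >= tt]
        n = len(at_risk)
        na = sum(1 for i in at_risk if in_a[i])
        deaths = [i for i, (t, e) in enumerate(zip(times, events)) if t == tt and e == 1]
        d = len(deaths)
        da = sum(1 for i in deaths if in_a[i])
        o_minus_e += da - d * na / n
        if n > 1:
            var += d * (n - d) * na * (n - na) / (n**2 * (n - 1))
    chi2 = o_minus_e**2 / var if var > 0 else 0.0
    return o_minus_e, var, chi2


def km_no_censoring(times) -> dict[float, float]:
    """Empirical survival function: S(t) = fraction with time > t."""
    n = len(times)
    return {t: sum(1 for x in times if x > t) / n for t in sorted(set(times))}
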