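"""Independent brute-force oracles used to check the package's computations.

Everything here is deliberately written as plain Python loops over dicts,
with no shared code with the package: these implementations are slow and
obvious, which is the point.
"""
from __future__ import annotations

import itertools
import math


def tei_oracle(params: dict[str, float], weights: dict[str, list[float]], n_stages: int) -> list[float]:
    """Per-stage weighted mean of params, looping gene by gene."""
    genes = [g for g in weights if g in params]
    out = []
    for s in range(n_stages):
        num = 0.0
        den = 0.0
        for g in genes:
            num += params[g] * weights[g][s]
            den += weights[g][s]
        out.append(num / den)
    return out


def delta_em_oracle(tei: list[float], periods: list[str]) -> float:
    early = [x for x, p in zip(tei, periods) if p == "early"]
    middle = [x for x, p in zip(tei, periods) if p == "middle"]
    return sum(early) / len(early) - sum(middle) / len(middle)


def tau_oracle(values: list[float]) -> float:
    x = [max(v, 0.0) for v in values]
    m = max(x)
    if m == 0:
        raise ValueError("gene not expressed in any tissue")
    return sum(1.0 - v / m for v in x) / (len(x) - 1)


def pleiotropy_oracle(
    calls: dict[str, list[bool]], breadth_threshold: float
) -> tuple[dict[str, bool], list[int], list[int], float]:
    """Flags, per-stage expressed totals, pleiotropic counts and chi-square."""
    n_stages = len(next(iter(calls.values())))
    flags = {
        g: (sum(row) / n_stages) > breadth_threshold for g, row in calls.items()
    }
    n_expressed = [sum(calls[g][s] for g in calls) for s in range(n_stages)]
    n_pleio = [sum(calls[g][s] and flags[g] for g in calls) for s in range(n_stages)]
    total_p = sum(n_pleio)
    total_e = sum(n_expressed)
    chi2 = 0.0
    for obs, e_tot in zip(n_pleio, n_expressed):
        expected = total_p * e_tot / total_e
        chi2 += (obs - expected) ** 2 / expected
    return flags, n_expressed, n_pleio, chi2


def spearman_oracle(x: list[float], y: list[float]) -> float:
    """Pearson correlation of average ranks (the tie-correct Spearman rho)."""

    def ranks(v: list[float]) -> list[float]:
        order = sorted(range(len(v)), key=lambda i: v[i])
        r = [0.0] * len(v)
        i = 0
        while i < len(order):
            j = i
            while j + 1 < len(order) and v[order[j + 1]] == v[order[i]]:
                j += 1
            avg = (i + j) / 2 + 1
            for k in range(i, j + 1):
                r[order[k]] = avg
            i = j + 1
        return r

    rx, ry = ranks(x), ranks(y)
    n = len(x)
    mx = sum(rx) / n
    my = sum(ry) / n
    num = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    den = math.sqrt(sum((a - mx) ** 2 for a in rx) * sum((b - my) ** 2 for b in ry))
    return num / den


def mannwhitney_exact_oracle(a: list[float], b: list[float]) -> tuple[float, float]:
    """U of group a and the exact two-sided p by enumerating rank assignments.

    Assumes no ties.  p = fraction of group-a position choices whose U is at
    least as extreme (two-sided: min tail doubled, capped at 1).
    """
    pooled = sorted(a + b)
    rank = {v: i + 1 for i, v in enumerate(pooled)}
    n1, n2 = len(a), len(b)
    u_obs = sum(rank[v] for v in a) - n1 * (n1 + 1) / 2
    us = []
    for combo in itertools.combinations(range(1, n1 + n2 + 1), n1):
        us.append(sum(combo) - n1 * (n1 + 1) / 2)
    lo = sum(u <= u_obs for u in us) / len(us)
    hi = sum(u >= u_obs for u in us) / len(us)
    return u_obs, min(1.0, 2 * min(lo, hi))


def bootstrap_tei_oracle(
    params: dict[str, float],
    weights: dict[str, list[float]],
    n_stages: int,
    resample: list[str],
) -> list[float]:
    """TEI of one explicit bootstrap resample (gene ids with repetition)."""
    out = []
    for s in range(n_stages):
        num = sum(params[g] * weights[g][s] for g in resample)
        den = sum(weights[g][s] for g in resample)
        out.append(num / den)
    return out
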