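"""Independent reference implementations used only to check the package.

Each oracle is written as a direct, step-by-step transcription of the
underlying definition (loops, exact integer arithmetic, exhaustive
enumeration) and shares no code with the implementation it validates.
"""

from __future__ import annotations

import math
from fractions import Fraction
from itertools import combinations


def dl_oracle(y: list[float], v: list[float]) -> dict[str, float]:
    """Scalar step-by-step DerSimonian-Laird pooling of k effects."""
    k = len(y)
    w = [1.0 / vi for vi in v]
    sw = sum(w)
    y_fe = sum(wi * yi for wi, yi in zip(w, y)) / sw
    q = sum(wi * (yi - y_fe) ** 2 for wi, yi in zip(w, y))
    if k == 1:
        tau2 = 0.0
    else:
        c = sw - sum(wi**2 for wi in w) / sw
        tau2 = max(0.0, (q - (k - 1)) / c)
    ws = [1.0 / (vi + tau2) for vi in v]
    sws = sum(ws)
    mu = sum(wi * yi for wi, yi in zip(ws, y)) / sws
    se = sws**-0.5
    z = mu / se
    p = math.erfc(abs(z) / math.sqrt(2.0))  # two-sided normal tail
    return {
        "mu": mu,
        "se": se,
        "z": z,
        "p": p,
        "tau2": tau2,
        "q": q,
        "ci_lo": mu - 1.959964 * se,
        "ci_hi": mu + 1.959964 * se,
    }


def bh_oracle(pvals: list[float]) -> list[float]:
    """Step-up Benjamini-Hochberg adjusted p-values, input order preserved."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    adjusted = [0.0] * m
    running_min = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running_min = min(running_min, pvals[i] * m / rank)
        adjusted[i] = running_min
    return adjusted


def hypergeom_pmf(k: int, N: int, K: int, n: int) -> Fraction:
    """Exact P(X = k) for X ~ Hypergeom(N, K, n)."""
    if k < max(0, n - (N - K)) or k > min(K, n):
        return Fraction(0)
    return Fraction(math.comb(K, k) * math.comb(N - K, n - k), math.comb(N, n))


def fisher_greater_oracle(a: int, b: int, c: int, d: int) -> float:
    """One-sided (greater) Fisher p: brute-force summation of the upper tail.

    X ~ Hypergeom(N=a+b+c+d, K=a+c, n=a+b); p = P(X >= a).  Exact integer
    arithmetic throughout, one division at the end.
    """
    N, K, n = a + b + c + d, a + c, a + b
    numerator = 0
    for k in range(a, min(K, n) + 1):
        if k < max(0, n - (N - K)):
            continue
        numerator += math.comb(K, k) * math.comb(N - K, n - k)
    p = Fraction(numerator, math.comb(N, n))
    return float(min(p, Fraction(1)))


def fisher_two_sided_oracle(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p: sum of tables at most as probable as the observed.

    Follows the conditional-test convention of including tables whose
    probability is within a (1 + 1e-7) relative tie window of the observed
    table, matching how floating-point implementations treat ties.
    """
    N, K, n = a + b + c + d, a + c, a + b
    p_obs = hypergeom_pmf(a, N, K, n)
    threshold = p_obs * Fraction(10**7 + 1, 10**7)
    total = Fraction(0)
    for k in range(max(0, n - (N - K)), min(K, n) + 1):
        pk = hypergeom_pmf(k, N, K, n)
        if pk <= threshold:
            total += pk
    return float(min(total, Fraction(1)))


def wilcoxon_two_sided_oracle(x: list[float], y: list[float]) -> tuple[float, float]:
    """Exact two-sided rank-sum p by full enumeration of group assignments.

    Computes the Mann-Whitney U of ``x`` from ranks of the pooled sample and
    enumerates all C(n1+n2, n1) assignments of the pooled values to the first
    group; p = 2 * min(P(U <= u), P(U >= u)) capped at 1.
    """
    pooled = sorted(x + y)
    n1, n2 = len(x), len(y)

    def u_stat(group_a: list[float], group_b: list[float]) -> float:
        u = 0.0
        for xi in group_a:
            for yj in group_b:
                if xi > yj:
                    u += 1.0
                elif xi == yj:
                    u += 0.5
        return u

    u_obs = u_stat(x, y)
    idx = range(n1 + n2)
    n_le = n_ge = n_total = 0
    for chosen in combinations(idx, n1):
        chosen_set = set(chosen)
        ga = [pooled[i] for i in chosen]
        gb = [pooled[i] for i in idx if i not in chosen_set]
        u = u_stat(ga, gb)
        n_total += 1
        if u <= u_obs + 1e-12:
            n_le += 1
        if u >= u_obs - 1e-12:
            n_ge += 1
    p = 2.0 * min(n_le, n_ge) / n_total
    return u_obs, min(p, 1.0)


def top_fraction_oracle(
    gene_ids: list[str], means: list[float], fraction: float
) -> list[str]:
    """Sort-based selection of the top fraction of genes by mean expression."""
    n_top = math.ceil(fraction * len(gene_ids))
    ranked = sorted(zip(gene_ids, means), key=lambda gm: (-gm[1], gm[0]))
    return [g for g, _ in ranked[:n_top]]
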