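"""Independent brute-force oracles used by the test suite.

Everything here is written as literally as possible (explicit loops, no
shared code with the package) so it can serve as an independent check of
the vectorized implementations.
"""

from __future__ import annotations

import math


def filter_keep_bruteforce(
    counts_row: list[int],
    groups: dict[str, list[int]],
    min_count: int,
    min_samples: int,
) -> bool:
    """Literal gene-retention rule: >= min_count reads in >= min_samples samples
    of at least one group (groups map name -> column indices)."""
    for cols in groups.values():
        n_ok = 0
        for j in cols:
            if counts_row[j] >= min_count:
                n_ok += 1
        if n_ok >= min_samples:
            return True
    return False


def _rank_average_ties(values: list[float]) -> list[float]:
    ranks = []
    for v in values:
        smaller = sum(1 for u in values if u < v)
        ties = sum(1 for u in values if u == v)
        ranks.append(smaller + (ties + 1) / 2.0)
    return ranks


def _quantile_type7(values: list[float], p: float) -> float:
    xs = sorted(values)
    h = (len(xs) - 1) * p
    lo = math.floor(h)
    hi = min(lo + 1, len(xs) - 1)
    return xs[lo] + (h - lo) * (xs[hi] - xs[lo])


def tmm_factors_bruteforce(
    counts: list[list[int]], trim_m: float = 0.3, trim_a: float = 0.05
) -> list[float]:
    """Literal trimmed-mean-of-M-values computation on a genes x samples table."""
    n_genes = len(counts)
    n_samples = len(counts[0])
    lib = [sum(counts[g][j] for g in range(n_genes)) for j in range(n_samples)]
    # reference: upper-quartile count rate closest to the mean upper quartile
    uq = [
        _quantile_type7([counts[g][j] / lib[j] for g in range(n_genes)], 0.75)
        for j in range(n_samples)
    ]
    mean_uq = sum(uq) / n_samples
    ref = min(range(n_samples), key=lambda j: abs(uq[j] - mean_uq))

    raw = []
    for j in range(n_samples):
        ms, as_, vs = [], [], []
        for g in range(n_genes):
            o, r = counts[g][j], counts[g][ref]
            if o > 0 and r > 0:
                po, pr = o / lib[j], r / lib[ref]
                ms.append(math.log2(po / pr))
                as_.append(0.5 * math.log2(po * pr))
                vs.append((lib[j] - o) / (lib[j] * o) + (lib[ref] - r) / (lib[ref] * r))
        if max(abs(m) for m in ms) < 1e-6:
            raw.append(1.0)
            continue
        n = len(ms)
        lo_m = math.floor(n * trim_m) + 1
        hi_m = n + 1 - lo_m
        lo_a = math.floor(n * trim_a) + 1
        hi_a = n + 1 - lo_a
        rm = _rank_average_ties(ms)
        ra = _rank_average_ties(as_)
        num = den = 0.0
        for i in range(n):
            if lo_m <= rm[i] <= hi_m and lo_a <= ra[i] <= hi_a:
                num += ms[i] / vs[i]
                den += 1.0 / vs[i]
        raw.append(2.0 ** (num / den))
    log_mean = sum(math.log(f) for f in raw) / n_samples
    return [f / math.exp(log_mean) for f in raw]


def hypergeom_tail_bruteforce(k: int, big_n: int, big_k: int, n: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n) by summing the exact pmf."""
    total = math.comb(big_n, n)
    acc = 0
    for j in range(k, min(big_k, n) + 1):
        acc += math.comb(big_k, j) * math.comb(big_n - big_k, n - j)
    return acc / total


def hypergeom_tail_enumeration(k: int, universe: list[str], members: set[str], n: int) -> float:
    """Same tail probability by enumerating every possible size-n draw."""
    from itertools import combinations

    hits = total = 0
    for draw in combinations(universe, n):
        total += 1
        if sum(1 for g in draw if g in members) >= k:
            hits += 1
    return hits / total
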