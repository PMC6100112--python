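"""Independent brute-force oracles used by the test suite.

These deliberately avoid the code paths (and the scipy routines) they are
checking: exact integer combinatorics via math.comb and explicit enumeration.
"""

from __future__ import annotations

from itertools import combinations
from math import comb


def fisher_greater_oracle(a: int, b: int, c: int, d: int) -> float:
    """One-sided p for table [[a, b], [c, d]] by hypergeometric enumeration.

    With margins fixed, enumerate every table at least as extreme as observed
    in the direction of row-1/column-1 excess and sum their probabilities.
    """
    r1, r2, s = a + b, c + d, a + c
    total = comb(r1 + r2, s)
    if total == 0:
        return 1.0
    lo, hi = max(0, s - r2), min(r1, s)
    num = sum(comb(r1, k) * comb(r2, s - k) for k in range(max(a, lo), hi + 1))
    return num / total


def fisher_oracle_all_tables(max_margin: int):
    """Yield (a, b, c, d, p) for every table with both row sums <= max_margin.

    Per (row sums, C total) the hypergeometric pmf is computed once and
    suffix-summed, so the full enumeration stays cheap.
    """
    for r1 in range(max_margin + 1):
        for r2 in range(max_margin + 1):
            for s in range(r1 + r2 + 1):
                total = comb(r1 + r2, s)
                lo, hi = max(0, s - r2), min(r1, s)
                pmf = [comb(r1, k) * comb(r2, s - k) for k in range(lo, hi + 1)]
                tail = 0
                tails = [0] * len(pmf)
                for i in range(len(pmf) - 1, -1, -1):
                    tail += pmf[i]
                    tails[i] = tail
                for i, k in enumerate(range(lo, hi + 1)):
                    p = tails[i] / total if total else 1.0
                    yield k, r1 - k, s - k, r2 - (s - k), p


def ranksum_oracle(x, y, alternative: str = "two-sided") -> float:
    """Exact rank-sum p by enumerating all C(n1+n2, n1) group assignments.

    Uses midranks for ties; the p-value is the proportion of assignments whose
    rank-sum statistic is at least as extreme as the observed one.
    """
    pooled = sorted(list(x) + list(y))
    # midranks
    ranks = {}
    i = 0
    while i < len(pooled):
        j = i
        while j < len(pooled) and pooled[j] == pooled[i]:
            j += 1
        mid = (i + 1 + j) / 2.0
        ranks[pooled[i]] = mid
        i = j
    all_ranks = [ranks[v] for v in pooled]
    n1 = len(x)
    obs = sum(ranks[v] for v in x)
    mean = n1 * (len(pooled) + 1) / 2.0
    ge = le = extreme = 0
    ntot = 0
    for idx in combinations(range(len(pooled)), n1):
        s = sum(all_ranks[i] for i in idx)
        ntot += 1
        if s >= obs - 1e-9:
            ge += 1
        if s <= obs + 1e-9:
            le += 1
        if abs(s - mean) >= abs(obs - mean) - 1e-9:
            extreme += 1
    if alternative == "greater":
        return ge / ntot
    if alternative == "less":
        return le / ntot
    return min(1.0, extreme / ntot)


def hypergeom_overlap_tail(n_in_regions: int, n_candidates: int, n_sites: int,
                           observed: int) -> float:
    """P(overlap >= observed) when sites are drawn uniformly without
    replacement from candidates of which ``n_in_regions`` lie inside regions."""
    total = comb(n_candidates, n_sites)
    num = 0
    for k in range(observed, min(n_in_regions, n_sites) + 1):
        num += comb(n_in_regions, k) * comb(n_candidates - n_in_regions, n_sites - k)
    return num / total
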