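"""Permutation test for overlap of called sites with genomic region sets.

Single-base calls are validated against an independent region set (for
example peaks from an enrichment-based 5hmU map) by comparing the observed
number of calls falling inside the regions with a null distribution in which
the same number of sites is placed uniformly at random over the candidate
positions — the T positions of the chromosome, since calls can only occur
at Ts.  The empirical p-value uses the add-one Monte-Carlo estimator
``p = (1 + #{null >= observed}) / (1 + n_perm)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = ["IntervalSet", "OverlapTest", "overlap_count", "permute_sites", "permutation_pvalue"]


@dataclass(frozen=True)
class IntervalSet:
    """Half-open intervals on one reference sequence."""

    ref: str
    intervals: tuple[tuple[int, int], ...]
    length: int

    def __init__(self, ref: str, intervals, length: int):
        ivs = tuple((int(s), int(e)) for s, e in intervals)
        for s, e in ivs:
            if not 0 <= s < e <= length:
                raise ValueError(
                    f"interval ({s}, {e}) invalid on {ref!r} of length {length}"
                )
        object.__setattr__(self, "ref", ref)
        object.__setattr__(self, "intervals", ivs)
        object.__setattr__(self, "length", int(length))

    def merged(self) -> "IntervalSet":
        """Sort and merge overlapping/adjacent intervals."""
        if not self.intervals:
            return self
        ivs = sorted(self.intervals)
        out = [list(ivs[0])]
        for s, e in ivs[1:]:
            if s <= out[-1][1]:
                out[-1][1] = max(out[-1][1], e)
            else:
                out.append([s, e])
        return IntervalSet(self.ref, [tuple(iv) for iv in out], self.length)


@dataclass(frozen=True)
class OverlapTest:
    observed: int
    null_counts: np.ndarray = field(repr=False)
    p_value: float
    n_perm: int
    seed: int

    @property
    def null_mean(self) -> float:
        return float(np.mean(self.null_counts))

    @property
    def null_sd(self) -> float:
        return float(np.std(self.null_counts, ddof=1)) if self.n_perm > 1 else float("nan")


def _merged_arrays(regions: IntervalSet) -> tuple[np.ndarray, np.ndarray]:
    m = regions.merged()
    if not m.intervals:
        return np.array([], dtype=np.int64), np.array([], dtype=np.int64)
    arr = np.asarray(m.intervals, dtype=np.int64)
    return arr[:, 0], arr[:, 1]


def _count_in(positions: np.ndarray, starts: np.ndarray, ends: np.ndarray) -> np.ndarray:
    """Count of positions inside any merged interval, per row of ``positions``."""
    if starts.size == 0:
        return np.zeros(positions.shape[:-1] or (), dtype=np.int64)
    idx = np.searchsorted(starts, positions, side="right") - 1
    inside = (idx >= 0) & (positions < ends[np.clip(idx, 0, len(ends) - 1)])
    return inside.sum(axis=-1)


def overlap_count(sites: Sequence[int], regions: IntervalSet) -> int:
    """Number of sites falling inside any (merged) region."""
    pos = np.asarray(list(sites), dtype=np.int64)
    if pos.size and (pos.min() < 0 or pos.max() >= regions.length):
        bad = pos[(pos < 0) | (pos >= regions.length)]
        raise ValueError(
            f"site position(s) {bad[:5].tolist()} outside [0, {regions.length})"
        )
    starts, ends = _merged_arrays(regions)
    return int(_count_in(pos, starts, ends))


def permute_sites(
    sites: Sequence[int],
    candidates: Sequence[int],
    n_perm: int,
    seed: int,
) -> np.ndarray:
    """Null site sets: |sites| positions drawn uniformly without replacement
    from the candidate positions, once per permutation.  Shape (n_perm, |sites|)."""
    k = len(sites)
    cand = np.asarray(list(candidates), dtype=np.int64)
    if cand.size < k:
        raise ValueError(f"{cand.size} candidate positions < {k} sites")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(np.random.SeedSequence((int(seed), 505)))
    out = np.empty((n_perm, k), dtype=np.int64)
    for i in range(n_perm):
        out[i] = rng.choice(cand, size=k, replace=False)
    return out


def permutation_pvalue(
    sites: Sequence[int],
    regions: IntervalSet,
    candidates: Sequence[int],
    n_perm: int = 10_000,
    seed: int = 0,
) -> OverlapTest:
    """One-sided (enrichment) empirical overlap p-value with add-one correction."""
    observed = overlap_count(sites, regions)
    perms = permute_sites(sites, candidates, n_perm, seed)
    starts, ends = _merged_arrays(regions)
    null_counts = _count_in(perms, starts, ends)
    p = (1 + int(np.count_nonzero(null_counts >= observed))) / (1 + n_perm)
    return OverlapTest(
        observed=observed,
        null_counts=null_counts,
        p_value=float(p),
        n_perm=int(n_perm),
        seed=int(seed),
    )
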