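"""Per-T-site base-composition signal from amplicon reads or count tables.

The pileup is positional: amplicon reads are full-length copies of the
reference, so column ``i`` of every read aligns to reference position ``i``.
At each T position the reads are tallied into (T, C, other) and converted
into the proportions %T, %C, %other and the conversion signal %C/(C+T).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .simdata import COUNTS_COLUMNS, _as_ref_dict

__all__ = [
    "BaseCounts",
    "SiteSignal",
    "SiteSummary",
    "count_bases",
    "signal",
    "signals_table",
    "aggregate_replicates",
    "aggregate_table",
    "SIGNAL_COLUMNS",
]

log = logging.getLogger(__name__)

SIGNAL_COLUMNS = [
    "ref",
    "pos0",
    "refbase",
    "strand",
    "condition",
    "replicate",
    "depth",
    "pct_T",
    "pct_C",
    "pct_other",
    "c_over_ct",
]


@dataclass(frozen=True)
class BaseCounts:
    """Read-base tally at one reference position."""

    ref: str
    pos0: int
    refbase: str
    strand: str
    n_T: int
    n_C: int
    n_other: int

    def __post_init__(self) -> None:
        if min(self.n_T, self.n_C, self.n_other) < 0:
            raise ValueError("counts must be non-negative")
        if self.refbase not in "ACGT":
            raise ValueError(f"refbase must be one of ACGT, got {self.refbase!r}")

    @property
    def depth(self) -> int:
        return self.n_T + self.n_C + self.n_other


@dataclass(frozen=True)
class SiteSignal:
    """Base-composition proportions at one site, one condition/replicate.

    ``c_over_ct`` is NaN (and ``defined`` False) when no C or T reads exist;
    a zero-depth site is flagged missing rather than raising.
    """

    ref: str
    pos0: int
    refbase: str
    strand: str
    condition: str | None
    replicate: int | None
    depth: int
    pct_T: float
    pct_C: float
    pct_other: float
    c_over_ct: float

    @property
    def defined(self) -> bool:
        return self.depth > 0 and not math.isnan(self.c_over_ct)


def count_bases(
    reads: Iterable,
    reference,
    reverse_positions: Sequence[int] = (),
) -> list[BaseCounts]:
    """Positional pileup of full-length amplicon reads over one reference.

    Reads whose length differs from the reference are dropped (and logged).
    Forward T positions count read T / C / anything-else; positions listed in
    ``reverse_positions`` must be reference A and count A as the T-equivalent
    and G as the C-equivalent (strand symmetry of the T-to-C chemistry).
    """
    refs = _as_ref_dict(reference)
    if len(refs) != 1:
        raise ValueError("count_bases takes a single reference sequence")
    (ref_name, seq), = refs.items()
    if not seq:
        raise ValueError("reference sequence is empty")
    L = len(seq)

    read_strs = [str(getattr(r, "seq", r)).upper() for r in reads]
    kept = [r for r in read_strs if len(r) == L]
    dropped = len(read_strs) - len(kept)
    if dropped:
        log.warning(
            "dropped %d/%d reads with length != reference (%d nt)",
            dropped,
            len(read_strs),
            L,
        )

    rev = set(int(p) for p in reverse_positions)
    for p in rev:
        if not 0 <= p < L or seq[p] != "A":
            raise ValueError(f"reverse-strand position {p} is not an A in the reference")
    fwd = [i for i, b in enumerate(seq) if b == "T"]
    positions = sorted(set(fwd) | rev)
    if not positions:
        raise ValueError("reference contains no T positions (or configured A positions)")

    if kept:
        mat = np.frombuffer("".join(kept).encode("ascii"), dtype="S1").reshape(
            len(kept), L
        )
    else:
        mat = np.empty((0, L), dtype="S1")

    out = []
    for p in positions:
        col = mat[:, p]
        if p in rev:
            n_t = int(np.count_nonzero(col == b"A"))
            n_c = int(np.count_nonzero(col == b"G"))
            strand = "-"
        else:
            n_t = int(np.count_nonzero(col == b"T"))
            n_c = int(np.count_nonzero(col == b"C"))
            strand = "+"
        out.append(
            BaseCounts(
                ref=ref_name,
                pos0=p,
                refbase=seq[p],
                strand=strand,
                n_T=n_t,
                n_C=n_c,
                n_other=len(kept) - n_t - n_c,
            )
        )
    return out


def counts_to_table(
    counts: Iterable[BaseCounts], condition: str, replicate: int
) -> pd.DataFrame:
    """BaseCounts list -> the package's standard count-table schema."""
    rows = [
        (
            c.ref,
            c.pos0,
            c.refbase,
            c.strand,
            condition,
            replicate,
            c.n_T,
            c.n_C,
            c.n_other,
            c.depth,
        )
        for c in counts
    ]
    return pd.DataFrame(rows, columns=COUNTS_COLUMNS)


def signal(
    counts: BaseCounts,
    condition: str | None = None,
    replicate: int | None = None,
) -> SiteSignal:
    """Proportions and %C/(C+T) for one site; zero depth yields NaNs."""
    d = counts.depth
    if d == 0:
        pct_t = pct_c = pct_o = float("nan")
    else:
        pct_t = counts.n_T / d
        pct_c = counts.n_C / d
        pct_o = counts.n_other / d
    ct = counts.n_C + counts.n_T
    c_over_ct = counts.n_C / ct if ct > 0 else float("nan")
    return SiteSignal(
        ref=counts.ref,
        pos0=counts.pos0,
        refbase=counts.refbase,
        strand=counts.strand,
        condition=condition,
        replicate=replicate,
        depth=d,
        pct_T=pct_t,
        pct_C=pct_c,
        pct_other=pct_o,
        c_over_ct=c_over_ct,
    )


def signals_table(counts: pd.DataFrame, min_depth: int = 0) -> pd.DataFrame:
    """Vectorised :func:`signal` over a standard count table.

    Sites below ``min_depth`` are excluded from downstream analysis.
    """
    df = counts.copy()
    df = df[df["depth"] >= min_depth].reset_index(drop=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        depth = df["depth"].to_numpy(dtype=float)
        ct = (df["n_C"] + df["n_T"]).to_numpy(dtype=float)
        df["pct_T"] = np.where(depth > 0, df["n_T"] / depth, np.nan)
        df["pct_C"] = np.where(depth > 0, df["n_C"] / depth, np.nan)
        df["pct_other"] = np.where(depth > 0, df["n_other"] / depth, np.nan)
        df["c_over_ct"] = np.where(ct > 0, df["n_C"] / ct, np.nan)
    return df[SIGNAL_COLUMNS]


@dataclass(frozen=True)
class SiteSummary:
    """Replicate mean +/- sample SD of the per-site proportions."""

    ref: str
    pos0: int
    strand: str
    condition: str | None
    n: int
    mean_pct_T: float
    sd_pct_T: float
    mean_pct_C: float
    sd_pct_C: float
    mean_pct_other: float
    sd_pct_other: float
    mean_c_over_ct: float
    sd_c_over_ct: float


def aggregate_replicates(signals: Sequence[SiteSignal]) -> SiteSummary:
    """Mean and sample SD (n-1) across technical replicates of one site.

    All signals must address the same site and condition; a single replicate
    reports SD as NaN (missing).
    """
    sigs = list(signals)
    if not sigs:
        raise ValueError("no signals to aggregate")
    keys = {(s.ref, s.pos0, s.strand) for s in sigs}
    if len(keys) != 1:
        raise ValueError(f"signals span multiple sites: {sorted(keys)}")
    conds = {s.condition for s in sigs}
    if len(conds) != 1:
        raise ValueError(f"signals mix conditions {sorted(map(str, conds))}")

    def mean_sd(vals: list[float]) -> tuple[float, float]:
        arr = np.asarray(vals, dtype=float)
        m = float(np.mean(arr))
        sd = float(np.std(arr, ddof=1)) if len(arr) > 1 else float("nan")
        return m, sd

    mt, st = mean_sd([s.pct_T for s in sigs])
    mc, sc = mean_sd([s.pct_C for s in sigs])
    mo, so = mean_sd([s.pct_other for s in sigs])
    mr, sr = mean_sd([s.c_over_ct for s in sigs])
    s0 = sigs[0]
    return SiteSummary(
        ref=s0.ref,
        pos0=s0.pos0,
        strand=s0.strand,
        condition=s0.condition,
        n=len(sigs),
        mean_pct_T=mt,
        sd_pct_T=st,
        mean_pct_C=mc,
        sd_pct_C=sc,
        mean_pct_other=mo,
        sd_pct_other=so,
        mean_c_over_ct=mr,
        sd_c_over_ct=sr,
    )


def aggregate_table(signals: pd.DataFrame) -> pd.DataFrame:
    """Per-site, per-condition replicate mean +/- SD over a signal table."""
    def sd(x):
        return x.std(ddof=1) if len(x) > 1 else float("nan")

    grouped = signals.groupby(["ref", "pos0", "refbase", "strand", "condition"])
    agg = grouped.agg(
        n=("replicate", "size"),
        mean_pct_T=("pct_T", "mean"),
        sd_pct_T=("pct_T", sd),
        mean_pct_C=("pct_C", "mean"),
        sd_pct_C=("pct_C", sd),
        mean_pct_other=("pct_other", "mean"),
        sd_pct_other=("pct_other", sd),
        mean_c_over_ct=("c_over_ct", "mean"),
        sd_c_over_ct=("c_over_ct", sd),
    )
    return agg.reset_index().sort_values(["ref", "pos0", "condition"]).reset_index(
        drop=True
    )
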