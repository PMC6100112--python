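"""Site calling: treated vs. no-oxidation-control tests with FDR control.

Genome mode pools technical replicates by summing counts and tests each T
site with a one-sided Fisher's exact test on the 2x2 table
``[[treated C, treated T], [control C, control T]]`` (alternative: C excess
in the treated arm, the direction the oxidation chemistry produces), then
adjusts across sites with Benjamini-Hochberg.  Amplicon (ODN) experiments
additionally use a replicate-level exact Wilcoxon rank-sum test comparing
%C at the modified sites against proximal unmodified Ts.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "site_test",
    "site_test_vec",
    "bh_fdr",
    "call_sites",
    "replicate_rank_test",
    "fold_change",
    "significant_bed",
    "CALLS_COLUMNS",
]

log = logging.getLogger(__name__)

CALLS_COLUMNS = [
    "ref",
    "pos0",
    "refbase",
    "strand",
    "treated_n_C",
    "treated_n_T",
    "control_n_C",
    "control_n_T",
    "p_value",
    "q_value",
    "fold_change",
    "significant",
]


def site_test_vec(
    treated_c: np.ndarray,
    treated_t: np.ndarray,
    control_c: np.ndarray,
    control_t: np.ndarray,
) -> np.ndarray:
    """Vectorised one-sided Fisher exact p-values (treated C enrichment).

    With margins fixed, the one-sided Fisher p-value is the upper tail of the
    hypergeometric law of the treated C count: P(X >= treated_c) for X drawn
    from Hypergeom(total reads, total C, treated reads).
    """
    tc = np.asarray(treated_c, dtype=np.int64)
    tt = np.asarray(treated_t, dtype=np.int64)
    cc = np.asarray(control_c, dtype=np.int64)
    ct = np.asarray(control_t, dtype=np.int64)
    if np.any((tc < 0) | (tt < 0) | (cc < 0) | (ct < 0)):
        raise ValueError("counts must be non-negative")
    total = tc + tt + cc + ct
    n_c = tc + cc
    n_treated = tc + tt
    # degenerate margins (all-zero table, no C anywhere, empty arm) -> p = 1
    safe = total > 0
    p = np.ones(np.shape(total), dtype=float)
    if np.any(safe):
        p_safe = stats.hypergeom.sf(
            tc[safe] - 1, total[safe], n_c[safe], n_treated[safe]
        )
        p[safe] = np.clip(p_safe, 0.0, 1.0)
    return p


def site_test(
    treated: tuple[int, int],
    control: tuple[int, int],
) -> float:
    """One-sided Fisher exact p for one site; ``treated``/``control`` are (n_C, n_T)."""
    return float(
        site_test_vec(
            np.array([treated[0]]),
            np.array([treated[1]]),
            np.array([control[0]]),
            np.array([control[1]]),
        )[0]
    )


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return np.array([], dtype=float)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def fold_change(treated, control, pseudocount: float = 0.5) -> float:
    """Ratio of treated to control %C/(C+T) with a pseudocount.

    Accepts (n_C, n_T) pairs or any objects exposing ``n_C``/``n_T``.  The
    pseudocount keeps the ratio finite when either arm has no C reads.
    """
    def rate(x) -> float:
        n_c, n_t = (x.n_C, x.n_T) if hasattr(x, "n_C") else (x[0], x[1])
        return (n_c + pseudocount) / (n_c + n_t + 2 * pseudocount)

    return rate(treated) / rate(control)


def _pool(counts: pd.DataFrame) -> pd.DataFrame:
    return (
        counts.groupby(["ref", "pos0", "refbase", "strand"], as_index=False)[
            ["n_T", "n_C", "n_other", "depth"]
        ]
        .sum()
    )


def call_sites(
    treated: pd.DataFrame,
    control: pd.DataFrame,
    fdr: float = 0.1,
    min_depth: int = 100,
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """Call modified T sites from matched treated and control count tables.

    Replicates are pooled by summing counts per condition; sites present in
    only one condition, or below ``min_depth`` pooled coverage in either
    condition, are excluded (and logged).  Returns one row per tested site,
    sorted by position, with ``significant`` flagging q < ``fdr``.
    """
    t = _pool(treated).rename(
        columns={"n_T": "treated_n_T", "n_C": "treated_n_C", "depth": "treated_depth"}
    )
    c = _pool(control).rename(
        columns={"n_T": "control_n_T", "n_C": "control_n_C", "depth": "control_depth"}
    )
    keys = ["ref", "pos0", "refbase", "strand"]
    merged = t.merge(c, on=keys, how="inner")
    n_only = len(t) + len(c) - 2 * len(merged)
    if n_only:
        log.warning("excluded %d sites present in only one condition", n_only)

    deep = (merged["treated_depth"] >= min_depth) & (merged["control_depth"] >= min_depth)
    if (~deep).any():
        log.info("excluded %d sites below min_depth=%d", int((~deep).sum()), min_depth)
    merged = merged[deep].sort_values(["ref", "pos0"]).reset_index(drop=True)

    if merged.empty:
        return pd.DataFrame(columns=CALLS_COLUMNS)

    p = site_test_vec(
        merged["treated_n_C"].to_numpy(),
        merged["treated_n_T"].to_numpy(),
        merged["control_n_C"].to_numpy(),
        merged["control_n_T"].to_numpy(),
    )
    q = bh_fdr(p)
    psc = pseudocount
    fc = (
        (merged["treated_n_C"] + psc)
        / (merged["treated_n_C"] + merged["treated_n_T"] + 2 * psc)
    ) / (
        (merged["control_n_C"] + psc)
        / (merged["control_n_C"] + merged["control_n_T"] + 2 * psc)
    )
    out = merged[keys + ["treated_n_C", "treated_n_T", "control_n_C", "control_n_T"]].copy()
    out["p_value"] = p
    out["q_value"] = q
    out["fold_change"] = fc
    out["significant"] = q < fdr
    return out[CALLS_COLUMNS]


def replicate_rank_test(
    modified_signals: Sequence[float],
    unmodified_signals: Sequence[float],
    alternative: str = "two-sided",
) -> float:
    """Wilcoxon rank-sum (Mann-Whitney) p-value for replicate-level %C.

    Exact enumeration when both groups have <= 12 untied values; otherwise
    the normal approximation with tie correction.  Two identical constant
    groups carry no ordering information and return p = 1.
    """
    x = np.asarray(list(modified_signals), dtype=float)
    y = np.asarray(list(unmodified_signals), dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each group needs at least 2 values")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return 1.0
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (not has_ties and len(x) <= 12 and len(y) <= 12) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative=alternative, method=method)
    return float(min(res.pvalue, 1.0))


def significant_bed(calls: pd.DataFrame) -> pd.DataFrame:
    """Significant calls as BED rows (name column carries the q-value)."""
    sig = calls[calls["significant"]].reset_index(drop=True)
    return pd.DataFrame(
        {
            "ref": sig["ref"],
            "start": sig["pos0"],
            "end": sig["pos0"] + 1,
            "name": sig["q_value"].map(lambda q: f"q={q:.3g}"),
            "score": np.minimum(
                1000, (-10 * np.log10(np.maximum(sig["q_value"], 1e-100))).astype(int)
            ),
            "strand": sig["strand"],
        }
    )
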