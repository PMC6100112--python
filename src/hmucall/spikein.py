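"""Titration and sequence-context characterisation of the conversion signal.

Two spike-in style analyses:

* a titration of 5hmU incorporation levels (0-26%) at fixed coverage,
  measuring linearity of %C/(C+T) versus level and the smallest level the
  fold-change-vs-control rule still detects; and
* a trinucleotide-context scan over all 16 N1-T-N2 flanking-base
  combinations around a fully modified site.

A level (or context) is flagged *detected* when the pooled treated counts
show fold-change > ``fc_threshold`` over the matched no-oxidation control
AND the one-sided Fisher test reaches BH q < ``fdr`` within the series.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import caller, simdata
from .simdata import ConversionModel, SimulatedExperiment

__all__ = [
    "TitrationResult",
    "titrate",
    "detection_limit_distribution",
    "simulate_context_experiment",
    "context_signal",
]

_CONTEXTS = [(n1, n2) for n1 in "ACGT" for n2 in "ACGT"]


@dataclass(frozen=True)
class TitrationResult:
    """Per-level signal, detection flags, and the linear fit of signal on level."""

    table: pd.DataFrame = field(repr=False)
    slope: float
    intercept: float
    r2: float
    detection_limit: float | None  # smallest detected level; None if none detected

    @property
    def levels(self) -> np.ndarray:
        return self.table["level"].to_numpy()


def titrate(
    levels: Sequence[float],
    model: ConversionModel,
    depth: int = 100,
    replicates: int = 3,
    seed: int = 0,
    fc_threshold: float = 2.0,
    fdr: float = 0.1,
) -> TitrationResult:
    """Simulate a titration series and locate the detection limit.

    Each level is one sample: treated and control arms are drawn from the
    generative model at that incorporation level, ``replicates`` technical
    replicates of ``depth`` reads each.  The fit is ordinary least squares of
    the replicate-mean treated %C/(C+T) on level.
    """
    lv = np.asarray(sorted(levels), dtype=float)
    if lv.size < 2 or np.unique(lv).size < 2:
        raise ValueError("titration needs at least 2 distinct levels for the linear fit")
    if np.any((lv < 0) | (lv > 1)):
        raise ValueError("levels must lie in [0, 1]")
    if depth < 1:
        raise ValueError("depth must be >= 1")
    rng = np.random.default_rng(np.random.SeedSequence((int(seed), 404)))

    rows = []
    for level in lv:
        tr = simdata.draw_site_counts(level, model, "treated", depth, replicates, rng)
        co = simdata.draw_site_counts(level, model, "control", depth, replicates, rng)
        with np.errstate(invalid="ignore", divide="ignore"):
            tr_sig = tr[:, 1] / (tr[:, 1] + tr[:, 0])
            co_sig = co[:, 1] / (co[:, 1] + co[:, 0])
        tr_pool = tr.sum(axis=0)
        co_pool = co.sum(axis=0)
        rows.append(
            {
                "level": level,
                "treated_mean": float(np.nanmean(tr_sig)),
                "treated_sd": float(np.nanstd(tr_sig, ddof=1)) if replicates > 1 else np.nan,
                "control_mean": float(np.nanmean(co_sig)),
                "control_sd": float(np.nanstd(co_sig, ddof=1)) if replicates > 1 else np.nan,
                "treated_n_C": int(tr_pool[1]),
                "treated_n_T": int(tr_pool[0]),
                "control_n_C": int(co_pool[1]),
                "control_n_T": int(co_pool[0]),
            }
        )
    table = pd.DataFrame(rows)
    table["fold_change"] = [
        caller.fold_change((r.treated_n_C, r.treated_n_T), (r.control_n_C, r.control_n_T))
        for r in table.itertuples()
    ]
    table["p_value"] = caller.site_test_vec(
        table["treated_n_C"].to_numpy(),
        table["treated_n_T"].to_numpy(),
        table["control_n_C"].to_numpy(),
        table["control_n_T"].to_numpy(),
    )
    table["q_value"] = caller.bh_fdr(table["p_value"])
    table["detected"] = (table["fold_change"] > fc_threshold) & (table["q_value"] < fdr)

    fit = stats.linregress(table["level"], table["treated_mean"])
    detected_levels = table.loc[table["detected"], "level"]
    limit = float(detected_levels.min()) if not detected_levels.empty else None
    return TitrationResult(
        table=table,
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r2=float(fit.rvalue**2),
        detection_limit=limit,
    )


def detection_limit_distribution(
    model: ConversionModel,
    n_seeds: int = 200,
    base_seed: int = 0,
    levels: Sequence[float] | None = None,
    depth: int = 100,
    replicates: int = 3,
    fc_threshold: float = 2.0,
    fdr: float = 0.1,
) -> tuple[Counter, float | None]:
    """Repeat :func:`titrate` over seeds; return (limit counts, modal limit).

    The detection limit at shallow coverage is a stochastic quantity, so it is
    summarised by its mode over independent simulations; series where nothing
    was detected are tallied under the key ``None``.  Ties in the mode break
    toward the smaller level.
    """
    if levels is None:
        levels = np.round(np.arange(0.0, 0.2601, 0.01), 4)
    rng = np.random.default_rng(int(base_seed))
    seeds = rng.integers(0, 2**31 - 1, size=n_seeds)
    limits = Counter()
    for s in seeds:
        res = titrate(
            levels,
            model,
            depth=depth,
            replicates=replicates,
            seed=int(s),
            fc_threshold=fc_threshold,
            fdr=fdr,
        )
        limits[res.detection_limit] += 1
    observed = [k for k in limits if k is not None]
    if not observed:
        return limits, None
    top = max(limits[k] for k in observed)
    modal = min(k for k in observed if limits[k] == top)
    return limits, modal


# ---------------------------------------------------------------------------
# trinucleotide context


def simulate_context_experiment(
    model: ConversionModel,
    depth: int = 2000,
    replicates: int = 3,
    seed: int = 0,
    multipliers: Mapping[tuple[str, str], float] | None = None,
) -> SimulatedExperiment:
    """Simulate the 16-context amplicon panel (one modified site per variant).

    ``multipliers`` scales the conversion probability of specific (N1, N2)
    contexts, letting the context analysis be exercised under both the
    context-uniform null and injected context bias.
    """
    records, profile = simdata.make_odn("ODN3", seed=seed)
    if multipliers:
        entries = []
        for e in profile:
            n1, n2 = e.ref[-2], e.ref[-1]
            m = multipliers.get((n1, n2))
            entries.append(
                simdata.ModSite(e.ref, e.pos0, e.strand, e.level,
                                model.with_conversion_multiplier(m) if m else None)
            )
        profile = simdata.ModificationProfile(entries)
    return simdata.simulate_experiment(
        records, profile, model, depth=depth, replicates=replicates, seed=seed
    )


def context_signal(
    experiment: SimulatedExperiment | None = None,
    *,
    treated: pd.DataFrame | None = None,
    control: pd.DataFrame | None = None,
    profile: simdata.ModificationProfile | None = None,
    references: Mapping[str, str] | None = None,
    fc_threshold: float = 2.0,
    fdr: float = 0.1,
) -> pd.DataFrame:
    """Per-trinucleotide-context conversion signal and detectability.

    Accepts either a :class:`SimulatedExperiment` or explicit treated/control
    count tables with their truth profile and reference sequences.  Returns
    exactly 16 rows keyed by (N1, N2); a missing context raises an error
    naming the absent pair.
    """
    if experiment is not None:
        treated, control = experiment.treated, experiment.control
        profile, references = experiment.profile, experiment.references
    if treated is None or control is None or profile is None or references is None:
        raise ValueError("need an experiment, or treated+control+profile+references")

    by_context: dict[tuple[str, str], simdata.ModSite] = {}
    for e in profile:
        seq = references[e.ref]
        ctx = (seq[e.pos0 - 1], seq[e.pos0 + 1])
        if ctx in by_context:
            raise ValueError(f"context {ctx[0]}-T-{ctx[1]} appears more than once")
        by_context[ctx] = e

    rows = []
    for n1, n2 in _CONTEXTS:
        e = by_context.get((n1, n2))
        if e is None:
            raise ValueError(f"missing trinucleotide context ({n1}, {n2})")
        tsub = treated[(treated["ref"] == e.ref) & (treated["pos0"] == e.pos0)]
        csub = control[(control["ref"] == e.ref) & (control["pos0"] == e.pos0)]
        if tsub.empty or csub.empty:
            raise ValueError(f"no counts for context ({n1}, {n2}) at {e.ref}:{e.pos0}")
        t_c, t_t = int(tsub["n_C"].sum()), int(tsub["n_T"].sum())
        c_c, c_t = int(csub["n_C"].sum()), int(csub["n_T"].sum())
        rows.append(
            {
                "N1": n1,
                "N2": n2,
                "treated_signal": t_c / (t_c + t_t) if t_c + t_t else np.nan,
                "control_signal": c_c / (c_c + c_t) if c_c + c_t else np.nan,
                "treated_n_C": t_c,
                "treated_n_T": t_t,
                "control_n_C": c_c,
                "control_n_T": c_t,
                "fold_change": caller.fold_change((t_c, t_t), (c_c, c_t)),
            }
        )
    out = pd.DataFrame(rows)
    out["p_value"] = caller.site_test_vec(
        out["treated_n_C"].to_numpy(),
        out["treated_n_T"].to_numpy(),
        out["control_n_C"].to_numpy(),
        out["control_n_T"].to_numpy(),
    )
    out["q_value"] = caller.bh_fdr(out["p_value"])
    out["detected"] = (out["fold_change"] > fc_threshold) & (out["q_value"] < fdr)
    return out
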