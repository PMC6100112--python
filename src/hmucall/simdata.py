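"""Synthetic references, modification truth sets, and converted sequencing data.

The generative model mirrors chemical-conversion 5hmU sequencing: genomic
5hmU is oxidised to 5fU, whose ionised form base-pairs with G during primer
extension, so a modified T position reads out as C in a fraction of the
molecules.  Each read base over a T site is therefore a three-way draw
(T, C, other), with rates set by the condition (treated vs. no-oxidation
control), the site's 5hmU incorporation level, and a :class:`ConversionModel`.

Default rates come from triplicate amplicon sequencing of a synthetic
oligonucleotide carrying two fully modified 5hmU sites: treated-condition
conversion of 39.4% / 30.3% at the two sites, ~1.4% C background at
unmodified Ts, and 2.2% / 2.7% residual C signal in the no-oxidation control.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, replace
from itertools import product
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "ConversionModel",
    "ModSite",
    "ModificationProfile",
    "SimulatedExperiment",
    "PRESETS",
    "preset",
    "site_rates",
    "draw_site_counts",
    "make_odn",
    "make_genome",
    "simulate_counts",
    "simulate_experiment",
    "reads_from_counts",
    "truth_bed",
    "CONDITIONS",
]

CONDITIONS = ("treated", "control")
_CONDITION_CODE = {"treated": 1, "control": 2}

#: schema of the per-position count table shared across the package
COUNTS_COLUMNS = [
    "ref",
    "pos0",
    "refbase",
    "strand",
    "condition",
    "replicate",
    "n_T",
    "n_C",
    "n_other",
    "depth",
]


@dataclass(frozen=True)
class ConversionModel:
    """Generative readout rates at a T position.

    Parameters
    ----------
    p_conv
        Probability that a read over a fully modified 5hmU site reports C in
        the treated (oxidised) condition.
    p_other_mod
        Probability of a non-T, non-C event at a fully modified site in the
        treated condition (A, G, insertion and deletion collapsed).
    p_bg_c, p_bg_other
        Background C / other rates at unmodified Ts (any condition).
    p_ctrl_c, p_ctrl_other
        C / other rates at a fully modified site in the no-oxidation control,
        where 5hmU is never converted to 5fU and reads out mostly as T.
    """

    p_conv: float
    p_other_mod: float
    p_bg_c: float = 0.014
    p_bg_other: float = 0.004
    p_ctrl_c: float = 0.022
    p_ctrl_other: float = 0.005

    def __post_init__(self) -> None:
        for name in (
            "p_conv",
            "p_other_mod",
            "p_bg_c",
            "p_bg_other",
            "p_ctrl_c",
            "p_ctrl_other",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v!r} outside [0, 1]")
        for a, b in (
            ("p_conv", "p_other_mod"),
            ("p_bg_c", "p_bg_other"),
            ("p_ctrl_c", "p_ctrl_other"),
        ):
            if getattr(self, a) + getattr(self, b) > 1.0 + 1e-12:
                raise ValueError(f"{a} + {b} exceeds 1")

    def with_conversion_multiplier(self, m: float) -> "ConversionModel":
        """Scale ``p_conv`` by ``m`` (used for sequence-context effects)."""
        return replace(self, p_conv=self.p_conv * m)


#: rate presets for the two fully modified sites of the ODN1 amplicon model
PRESETS: dict[str, ConversionModel] = {
    "ODN1_site1": ConversionModel(
        p_conv=0.394, p_other_mod=0.099, p_ctrl_c=0.022, p_ctrl_other=0.005
    ),
    "ODN1_site2": ConversionModel(
        p_conv=0.303, p_other_mod=0.046, p_ctrl_c=0.027, p_ctrl_other=0.013
    ),
}


def preset(name: str) -> ConversionModel:
    """Return a named :class:`ConversionModel` preset."""
    try:
        return PRESETS[name]
    except KeyError:
        raise ValueError(
            f"unknown preset {name!r}; available: {sorted(PRESETS)}"
        ) from None


@dataclass(frozen=True)
class ModSite:
    """One modified position: ``level`` is the 5hmU incorporation fraction."""

    ref: str
    pos0: int
    strand: str = "+"
    level: float = 1.0
    model: ConversionModel | None = None  # per-site rate override

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if not 0.0 <= self.level <= 1.0:
            raise ValueError(f"incorporation level {self.level!r} outside [0, 1]")


@dataclass(frozen=True)
class ModificationProfile:
    """Ground-truth modified positions with incorporation levels."""

    entries: tuple[ModSite, ...]

    def __init__(self, entries: Iterable[ModSite]):
        object.__setattr__(self, "entries", tuple(entries))

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def by_ref(self) -> dict[str, list[ModSite]]:
        out: dict[str, list[ModSite]] = {}
        for e in self.entries:
            out.setdefault(e.ref, []).append(e)
        return out

    def validate(self, references: Mapping[str, str]) -> None:
        """Check every entry addresses a T (forward) or A (reverse strand)."""
        for e in self.entries:
            if e.ref not in references:
                raise ValueError(f"profile entry references unknown sequence {e.ref!r}")
            seq = references[e.ref]
            if not 0 <= e.pos0 < len(seq):
                raise ValueError(
                    f"profile position {e.ref}:{e.pos0} outside reference of length {len(seq)}"
                )
            base = seq[e.pos0].upper()
            want = "T" if e.strand == "+" else "A"
            if base != want:
                raise ValueError(
                    f"profile position {e.ref}:{e.pos0} ({e.strand}) is {base!r}, "
                    f"expected {want!r}"
                )


@dataclass(frozen=True)
class SimulatedExperiment:
    """Matched treated + no-oxidation-control count tables over one truth set."""

    references: dict[str, str]
    profile: ModificationProfile
    model: ConversionModel
    depth: int
    replicates: int
    seed: int
    treated: pd.DataFrame = field(repr=False)
    control: pd.DataFrame = field(repr=False)

    def counts(self, condition: str) -> pd.DataFrame:
        if condition == "treated":
            return self.treated
        if condition == "control":
            return self.control
        raise ValueError(f"condition must be one of {CONDITIONS}, got {condition!r}")


# ---------------------------------------------------------------------------
# rates


def site_rates(
    level: float, model: ConversionModel, condition: str
) -> tuple[float, float, float]:
    """(p_T, p_C, p_other) at a site with the given incorporation level.

    The level mixes modified-molecule rates with background rates
    multiplicatively: a sample at 26% incorporation behaves as a 26:74 mixture
    of fully modified and unmodified molecules.
    """
    if condition not in CONDITIONS:
        raise ValueError(f"condition must be one of {CONDITIONS}, got {condition!r}")
    if condition == "treated":
        p_c = level * model.p_conv + (1.0 - level) * model.p_bg_c
        p_o = level * model.p_other_mod + (1.0 - level) * model.p_bg_other
    else:
        p_c = level * model.p_ctrl_c + (1.0 - level) * model.p_bg_c
        p_o = level * model.p_ctrl_other + (1.0 - level) * model.p_bg_other
    return 1.0 - p_c - p_o, p_c, p_o


def draw_site_counts(
    level: float,
    model: ConversionModel,
    condition: str,
    depth: int,
    replicates: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw ``(replicates, 3)`` trinomial counts ``(n_T, n_C, n_other)``."""
    p = site_rates(level, model, condition)
    return rng.multinomial(depth, p, size=replicates)


# ---------------------------------------------------------------------------
# reference construction

_ODN_IDS = ("ODN1", "ODN2", "ODN3")


def _random_seq(rng: np.random.Generator, length: int, alphabet: str = "ACG") -> list[str]:
    return [alphabet[i] for i in rng.integers(0, len(alphabet), size=length)]


def make_odn(
    model_id: str,
    seed: int = 0,
    levels: Sequence[float] | None = None,
) -> tuple[list[SeqRecord], ModificationProfile]:
    """Build a synthetic oligonucleotide amplicon model and its truth profile.

    ``ODN1``: one 80 nt amplicon, 9 T sites of which two are fully modified
    (the two sites carry the ``ODN1_site1`` / ``ODN1_site2`` rate presets).
    ``ODN2``: same layout with two partially modified sites; ``levels`` sets
    their incorporation (default ``(0.26, 0.13)``, the titration range end
    and midpoint).
    ``ODN3``: 16 variants of a 41 nt amplicon enumerating every N1-T-N2
    trinucleotide context around a single fully modified site.
    """
    if model_id not in _ODN_IDS:
        raise ValueError(f"unknown ODN model {model_id!r}; expected one of {_ODN_IDS}")
    rng = np.random.default_rng(np.random.SeedSequence((int(seed), 101)))

    if model_id in ("ODN1", "ODN2"):
        length = 80
        chars = _random_seq(rng, length)
        # 9 T sites on a 3 nt grid: guaranteed separation, 7 stay unmodified
        slots = np.arange(6, 76, 3)
        t_pos = np.sort(rng.choice(slots, size=9, replace=False))
        for p in t_pos:
            chars[p] = "T"
        seqstr = "".join(chars)
        rec = SeqRecord(Seq(seqstr), id=model_id, description="synthetic amplicon")
        mod_positions = (int(t_pos[2]), int(t_pos[6]))
        if model_id == "ODN1":
            entries = [
                ModSite(model_id, mod_positions[0], "+", 1.0, PRESETS["ODN1_site1"]),
                ModSite(model_id, mod_positions[1], "+", 1.0, PRESETS["ODN1_site2"]),
            ]
        else:
            lv = tuple(levels) if levels is not None else (0.26, 0.13)
            if len(lv) != 2:
                raise ValueError("ODN2 takes exactly two incorporation levels")
            entries = [
                ModSite(model_id, mod_positions[0], "+", float(lv[0])),
                ModSite(model_id, mod_positions[1], "+", float(lv[1])),
            ]
        profile = ModificationProfile(entries)
        profile.validate({model_id: seqstr})
        return [rec], profile

    # ODN3: one modified T, randomised flanking bases, all 16 contexts
    length, mod_pos = 41, 20
    base = _random_seq(rng, length)
    for p in (5, 11, 33):  # unmodified background Ts shared by all variants
        base[p] = "T"
    records, entries = [], []
    for n1, n2 in product("ACGT", repeat=2):
        chars = list(base)
        chars[mod_pos - 1], chars[mod_pos], chars[mod_pos + 1] = n1, "T", n2
        name = f"ODN3_{n1}{n2}"
        records.append(
            SeqRecord(Seq("".join(chars)), id=name, description="synthetic context amplicon")
        )
        entries.append(ModSite(name, mod_pos, "+", 1.0))
    profile = ModificationProfile(entries)
    profile.validate({r.id: str(r.seq) for r in records})
    return records, profile


def make_genome(
    length: int = 20_000,
    n_sites: int = 10,
    level: float = 1.0,
    seed: int = 0,
    name: str = "chr_sim",
    site_model: ConversionModel | None = None,
) -> tuple[list[SeqRecord], ModificationProfile]:
    """Random synthetic chromosome with ``n_sites`` modified T positions."""
    rng = np.random.default_rng(np.random.SeedSequence((int(seed), 202)))
    chars = np.array(list("ACGT"))[rng.integers(0, 4, size=length)]
    t_pos = np.flatnonzero(chars == "T")
    if len(t_pos) < n_sites:
        raise ValueError(f"only {len(t_pos)} Ts in a {length} nt sequence; cannot place {n_sites} sites")
    chosen = np.sort(rng.choice(t_pos, size=n_sites, replace=False))
    seqstr = "".join(chars)
    rec = SeqRecord(Seq(seqstr), id=name, description="synthetic chromosome")
    profile = ModificationProfile(
        ModSite(name, int(p), "+", float(level), site_model) for p in chosen
    )
    return [rec], profile


# ---------------------------------------------------------------------------
# count simulation


def _as_ref_dict(references) -> dict[str, str]:
    if isinstance(references, SeqRecord):
        return {references.id: str(references.seq).upper()}
    if isinstance(references, Mapping):
        return {k: str(v).upper() for k, v in references.items()}
    return {r.id: str(r.seq).upper() for r in references}


def simulate_counts(
    references,
    profile: ModificationProfile,
    model: ConversionModel,
    depth: int,
    replicates: int,
    condition: str,
    seed: int,
    poisson_depth: bool = False,
) -> pd.DataFrame:
    """Simulate a per-position count table for one condition.

    Every forward-strand T (plus any reverse-strand modified A) is scored; at
    each site and replicate the (T, C, other) counts are one trinomial draw of
    size ``depth`` (or Poisson(depth) when ``poisson_depth``).  Unmodified Ts
    use background rates in both conditions; modified sites use treated
    conversion rates only in the treated condition.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    if condition not in CONDITIONS:
        raise ValueError(f"condition must be one of {CONDITIONS}, got {condition!r}")
    refs = _as_ref_dict(references)
    profile.validate(refs)
    mod = {(e.ref, e.pos0): e for e in profile}

    rng = np.random.default_rng(
        np.random.SeedSequence((int(seed), _CONDITION_CODE[condition]))
    )

    rows_ref: list[str] = []
    rows_pos: list[int] = []
    rows_base: list[str] = []
    rows_strand: list[str] = []
    pvals: list[tuple[float, float, float]] = []
    for ref_name, seq in refs.items():
        arr = np.frombuffer(seq.encode("ascii"), dtype="S1")
        positions = sorted(
            set(np.flatnonzero(arr == b"T").tolist())
            | {e.pos0 for e in profile if e.ref == ref_name and e.strand == "-"}
        )
        for p in positions:
            e = mod.get((ref_name, p))
            level = e.level if e is not None else 0.0
            m = (e.model or model) if e is not None else model
            strand = e.strand if e is not None else "+"
            rows_ref.append(ref_name)
            rows_pos.append(p)
            rows_base.append(seq[p])
            rows_strand.append(strand)
            pvals.append(site_rates(level, m, condition))

    n_sites = len(rows_pos)
    if n_sites == 0:
        raise ValueError("reference contains no T positions to score")
    p_arr = np.asarray(pvals)

    frames = []
    for rep in range(1, replicates + 1):
        if poisson_depth:
            n = np.maximum(rng.poisson(depth, size=n_sites), 1)
        else:
            n = depth
        counts = rng.multinomial(n, p_arr)  # (n_sites, 3) as (T, C, other)
        frames.append(
            pd.DataFrame(
                {
                    "ref": rows_ref,
                    "pos0": rows_pos,
                    "refbase": rows_base,
                    "strand": rows_strand,
                    "condition": condition,
                    "replicate": rep,
                    "n_T": counts[:, 0],
                    "n_C": counts[:, 1],
                    "n_other": counts[:, 2],
                    "depth": counts.sum(axis=1),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)[COUNTS_COLUMNS]


def simulate_experiment(
    references,
    profile: ModificationProfile,
    model: ConversionModel,
    depth: int,
    replicates: int,
    seed: int,
    poisson_depth: bool = False,
) -> SimulatedExperiment:
    """Simulate matched treated + control tables sharing reference and truth."""
    refs = _as_ref_dict(references)
    kwargs = dict(
        references=refs,
        profile=profile,
        model=model,
        depth=depth,
        replicates=replicates,
        poisson_depth=poisson_depth,
    )
    treated = simulate_counts(condition="treated", seed=seed, **kwargs)
    control = simulate_counts(condition="control", seed=seed, **kwargs)
    return SimulatedExperiment(
        references=refs,
        profile=profile,
        model=model,
        depth=depth,
        replicates=replicates,
        seed=seed,
        treated=treated,
        control=control,
    )


# ---------------------------------------------------------------------------
# read emission


def reads_from_counts(
    reference,
    counts: pd.DataFrame,
    seed: int,
) -> dict[int, list[str]]:
    """Realise a count table as full-length amplicon reads, exactly.

    Each replicate's reads are full-length copies of the reference; at every
    scored site exactly ``n_C`` reads carry the C-equivalent base, ``n_other``
    the collapsed other event (realised as G on the forward strand), assigned
    to reads uniformly at random.  A pileup of the emitted reads therefore
    reproduces the input counts bit for bit.
    """
    refs = _as_ref_dict(reference)
    if len(refs) != 1:
        raise ValueError("reads_from_counts takes a single reference sequence")
    (ref_name, seq), = refs.items()
    sub = counts[counts["ref"] == ref_name]
    if sub.empty:
        raise ValueError(f"count table has no rows for reference {ref_name!r}")
    if sub["condition"].nunique() != 1:
        raise ValueError("count table mixes conditions; emit one condition at a time")
    rng = np.random.default_rng(np.random.SeedSequence((int(seed), 303)))

    out: dict[int, list[str]] = {}
    for rep, grp in sub.groupby("replicate"):
        depths = grp["depth"].unique()
        if len(depths) != 1:
            raise ValueError(
                f"replicate {rep} has non-uniform depth {sorted(depths)}; "
                "full-length amplicon reads need one depth per replicate"
            )
        d = int(depths[0])
        mat = np.tile(np.array(list(seq), dtype="<U1"), (d, 1))
        for row in grp.itertuples(index=False):
            if row.n_T + row.n_C + row.n_other != d:
                raise ValueError(f"counts at {ref_name}:{row.pos0} do not sum to depth")
            order = rng.permutation(d)
            if row.strand == "+":
                c_base, other_base = "C", "G"
            else:  # reverse-strand site on a forward A: C-equivalent is G
                c_base, other_base = "G", "C"
            mat[order[: row.n_C], row.pos0] = c_base
            mat[order[row.n_C : row.n_C + row.n_other], row.pos0] = other_base
        out[int(rep)] = ["".join(r) for r in mat]
    return out


def truth_bed(profile: ModificationProfile) -> pd.DataFrame:
    """Truth positions as BED rows (0-based half-open, score = level x 1000)."""
    return pd.DataFrame(
        {
            "ref": [e.ref for e in profile],
            "start": [e.pos0 for e in profile],
            "end": [e.pos0 + 1 for e in profile],
            "name": [f"5hmU_{i+1}" for i in range(len(profile))],
            "score": [int(round(e.level * 1000)) for e in profile],
            "strand": [e.strand for e in profile],
        }
    )
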