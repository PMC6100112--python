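# Methods

## Generative model

A sequencing read over a reference T position is modelled as one draw from a
three-outcome distribution (T, C, other), independent across reads and
positions. "Other" collapses A, G, insertion and deletion events into a
single outcome; when reads are emitted as FASTQ it is realised as a G
substitution, which is sufficient because no downstream statistic ever
distinguishes the non-T, non-C outcomes.

A `ConversionModel` carries six rates, all probabilities in [0, 1]:

| parameter | meaning | default |
|---|---|---|
| `p_conv` | C readout at a fully modified site, treated arm | 0.394 (site-1 preset) / 0.303 (site-2 preset) |
| `p_other_mod` | other readout at a fully modified site, treated | 0.099 / 0.046 |
| `p_bg_c` | C background at unmodified T, either arm | 0.014 |
| `p_bg_other` | other background at unmodified T | 0.004 |
| `p_ctrl_c` | C at a modified site, no-oxidation control | 0.022 / 0.027 |
| `p_ctrl_other` | other at a modified site, control | 0.005 / 0.013 |

The two presets are the measured triplicate readout of a two-site synthetic
amplicon; the `p_bg_other` and site-1 `p_ctrl_other` defaults are set so the
three proportions sum to the measured %T (the source table reports those
cells only as "<1%").

A site's **incorporation level** ℓ ∈ [0, 1] (the fraction of molecules
carrying 5hmU) mixes modified and background rates linearly, e.g. the treated
C rate is ℓ·p_conv + (1−ℓ)·p_bg_c. Expected %C/(C+T) is therefore affine in
ℓ, which is what the titration analysis exploits. Reverse-strand sites are
simulated and piled up as A→G on the forward reference, by complementarity of
the T→C change.

Depth is fixed per position by default (a Poisson mode is available); this
makes recovery checks tight while keeping coverage variation accessible.
All randomness flows from one integer seed; treated and control arms use
deterministic, distinct child streams, so a `SimulatedExperiment` is
bit-for-bit reproducible.

### What the simulator does and does not emulate

It reproduces the *statistical* structure of the real experiments: per-site
conversion at the measured rates, low and symmetric background, technical
triplicates, and a control arm in which modified sites look like background.
It does not model PCR duplicates, strand- or quality-dependent errors,
alignment ambiguity, coverage autocorrelation, or context-dependent
chemistry (context effects enter only through explicit per-context
multipliers on `p_conv`). Passing tests therefore demonstrate correctness of
the statistical machinery under the stated model, not robustness to real
library artefacts; on real data, alignment and duplicate handling must happen
upstream (genome-scale input is accepted as a precomputed count TSV for this
reason — alignment is deliberately out of scope).

The synthetic oligo sequences are structural analogues (site counts, context
coverage, level ranges match the experimental designs) generated from a
documented seed, not the original oligo sequences; every analysis depends
only on rates and site structure, not on the literal bases.

## Site calling

Replicates are pooled by summing counts (amplicon rank tests instead keep
replicates separate). Each site with pooled depth ≥ `min_depth` (default
100) in both arms is tested with a one-sided Fisher's exact test on
[[treated C, treated T], [control C, control T]], alternative = C excess in
the treated arm — one-sided because the chemistry can only create C signal.
The implementation evaluates the equivalent hypergeometric upper tail
(`scipy.stats.hypergeom.sf`), which vectorises over thousands of sites;
tests verify exact agreement with both `fisher_exact` and an independent
full-enumeration oracle. Degenerate tables (no reads, no C anywhere) return
p = 1 by convention. Benjamini–Hochberg is applied across tested sites and a
site is significant at q < `fdr` (default 0.1). The per-site test is exact at
low depth, directional, and assumption-light; it is the package's documented
choice where a specific normalisation procedure is not prescribed.

Fold-change is the ratio of pseudocounted conversion fractions
((n_C+ψ)/(n_C+n_T+2ψ), ψ = 0.5), finite for any counts.

The replicate-level Wilcoxon rank-sum test uses exact enumeration when both
groups have ≤ 12 untied values and the tie-corrected normal approximation
otherwise; two identical constant groups return p = 1 (no ordering
information). With 3 replicate %C values at a modified site against 7
proximal Ts × 3 replicates, complete separation gives one-sided
p = 1/C(10,3) ≈ 0.0083.

## Titration and detection limit

`spikein.titrate` simulates one site per incorporation level (default grid
0–26% in 1% steps), treated and control, 3 replicates of `depth` reads
(default 100×, the coverage at which the detection limit is assessed). A
level is **detected** when pooled fold-change > 2 *and* BH q < 0.1 within the
series; the detection limit is the smallest detected level. Both thresholds
are exposed; the rule is the package's interpretation of a
fold-change-versus-control criterion. Because the limit at 100× is
stochastic, it is summarised as the mode over (default) 200 independent
series, ties breaking toward the smaller level, with the full distribution
returned. Linearity is quantified by ordinary least squares of the
replicate-mean treated %C/(C+T) on level; in the noiseless limit the slope
approaches `p_conv` and the intercept 0.

## Context scan

Sixteen amplicon variants place one fully modified T in every N1-T-N2
flanking context. Per context, pooled %C/(C+T) is reported for both arms
with the same detection rule as the titration. Context bias is injected (and
recovered) as a multiplier on `p_conv`; since the "other" rate is unchanged,
the expected %C/(C+T) ratio between contexts equals the multiplier exactly.

## Overlap permutation test

Called sites are compared with a region set (e.g. enrichment-based peaks) by
counting sites inside the merged regions and permuting: each null draw
samples |sites| positions uniformly *without replacement from the T positions
of the chromosome* — calls can only occur at Ts, so permuting over all bases
would overstate significance. The one-sided empirical p-value uses the
add-one estimator p = (1 + #{null ≥ observed})/(1 + n_perm), bounded below by
1/(1+n_perm); under this null the overlap count is hypergeometric, which the
tests use as a closed-form cross-check. GC- or coverage-matched nulls and
multi-chromosome joint testing are out of scope (run per reference).

## Numerical and design notes

- Coordinates are 0-based half-open internally and in all BED output.
- TSV is the interchange format between stages (diffable, stable schemas);
  every run writes its resolved configuration and seed next to its outputs.
- %C/(C+T) is undefined (NaN, flagged) when C+T = 0; zero-depth sites are
  flagged missing rather than raising.
- Sample SD uses the n−1 denominator; a single replicate reports SD as
  missing.
- BH q-values map many p-values to one adjusted value; code relies only on
  q ∈ [0, 1] and step-up monotonicity.
- Problem sizes in the test suite and acceptance analyses (8 kb synthetic
  chromosomes with ~2000 Ts, 100 genomes for the FDR calibration, 200
  titration series) are the package's desk-scale study conditions; all
  scale linearly if larger runs are wanted.

## Known limitations

- No estimation of absolute 5hmU stoichiometry: %C understates ℓ because
  conversion is incomplete (at ℓ = 1 only ~39% of reads convert); the package
  reports signal, not stoichiometry.
- The amplicon pileup is positional and indel-blind by design; reads of the
  wrong length are dropped, not aligned.
- At very shallow depth the Fisher test is conservative (discreteness), so
  realised false-discovery proportions run below the nominal threshold.
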