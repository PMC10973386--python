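# Methods

This note documents the models behind each `mipscan` component, the
parameters that matter, the numerical choices, and what the synthetic
benchmarks do and do not demonstrate.

## Motif grammars and scanning

Grammars are dash-separated PROSITE-style strings: single residues, bracket
classes, and wildcard gaps `X`, `X(n)`, `X(n,m)`. A compiled pattern carries
span bounds as the sums of per-element minima and maxima; for the Mn unit
signature `[TS]-[TS]-X(4)-[YF]` this gives a fixed 7-residue window, and for
the long ELLEn grammar bounds of (75, 89). The ELLEn literature describes the
module as covering "approximately 70 residues", which is looser than the
computed minimum of 75; the package always reports the computed bounds and
treats the prose figure as a rounding. The exclusion classes (`{..}`) and
anchors (`<`, `>`) of full PROSITE are deliberately unsupported — none of the
MIP grammars use them.

Matching is a small backtracking automaton, one start position at a time,
with gap lengths expanded shortest-first. This makes output deterministic and
cheap to verify: the test suite checks exact agreement with a brute-force
enumerator over every (start, gap-assignment) combination on random
sequences. Two scan modes exist: `all-overlapping` (every satisfying
(start, end) window) and `leftmost-nonoverlapping` (greedy left-to-right with
the shortest expansion), the latter used for array calling so units are
counted once. Coordinates are 1-based inclusive everywhere, matching the
residue-range convention of the structural literature. The unknown residue
`X` in a subject satisfies wildcard gaps but never a residue class — a
conservative choice that avoids spurious class matches in masked regions.

The registry stores the published grammars verbatim. PYG and GFG are
exceptions: their publications name the conserved residues (Pro-Tyr-Gly;
Gly-Phe-Gly within a ~31-residue tandem unit) but print no spacing string.
The registry encodes PYG as the gapped triplet `P-X(0,2)-Y-X(0,2)-G` and GFG
as the bare triplet, both flagged `reconstructed`; array-level structure
(spacing, copy number) is handled by the module caller, not the unit grammar.

## Sequence weighting, PSSMs, and the prediction score

Training alignments are weighted with the Henikoff & Henikoff position-based
scheme: a row's raw weight is the sum over columns of `1/(r·s)` (`r` distinct
residues in the column, `s` the count of the row's residue), normalized to
sum 1. Foreground probabilities use one background-proportional pseudocount
mass: `q = (weighted count + c·b) / (1 + c)` with pseudocount weight `c = 1`
by default; scores are `log2(q/b)`. Cells that would be `-inf` (only possible
at `c = 0`) are floored at `log2(1e-9 / b)`; the floor also scores `X`.
The background defaults to uniform 1/20 and is user-configurable.

The **prediction score** of a window is the plain sum of per-position
log2-odds. The working threshold for reporting Mn-unit predictions is
score > 19 (strict), the published operating point; because that number
originates from an external sampler whose score formula is not public, the
package documents its own score definition and ships
`calibrate_threshold`, which re-derives an equivalent cutoff as a quantile of
the max-window-score distribution on shuffled sequences. Under the default
background a 12-position consensus-only match scores `12·log2(20) ≈ 51.9`,
so the threshold sits well below perfect matches but far above the null
(expected window score under background is `-Σ KL(b‖q) ≤ 0`).

## Gibbs site sampler

De novo discovery uses a one-occurrence-per-sequence (OOPS) site sampler with
the motif length default of 12: starts initialized uniformly at random
(seeded), then sweeps in which each sequence is held out, a Henikoff-weighted
PSSM is built from the rest, and the held-out start is resampled with
probability proportional to `2**score`. After every sweep a **phase-shift
move** slides the entire configuration by up to ±(L−1) and keeps the best
offset by information content; without it the sampler reliably locks onto
alignments displaced by one or two residues from the optimum, a well-known
failure mode of pure site samplers. The best configuration seen (summed
information content `Σ q·log2(q/b)`) is returned. Everything is driven by a
single `numpy` generator, so results are bitwise reproducible per seed. On
the packaged benchmark (20 sequences of 100 residues, one identical implanted
12-mer, 500 sweeps) the sampler recovers 20/20 implant positions.

There is no simulated-annealing schedule and no multi-occurrence (ZOOPS/TCM)
model; the OOPS assumption matches the training-set usage the sampler exists
for. The Mn training alignment shipped for demonstrations is reconstructed
from the printed consensus plus synthetic divergence and is labeled as such.

## Tandem-repeat detection

For each candidate period `p` the detector computes the self-comparison
diagonal `d[i] = M(s[i], s[i+p])` (BLOSUM62 by default, via Biopython) and
takes the maximal-scoring contiguous run (Kadane). Significance comes from a
seeded permutation null: each shuffle's statistic is the **maximum** run
score across all candidate periods, and a call requires the observed score
to exceed the `1−α` quantile of that max-statistic null. Using the maximum
rather than a per-period null is a Westfall–Young-style correction; it keeps
the family-wise false-call rate on random sequences at the nominal α even
though ~60 periods are tested at once (measured ≤ 2α over 200 seeded
trials). Empirical p-values use the standard `(1 + #{null ≥ obs}) / (N + 1)`
estimator.

The run's endpoints define the repeat region (Kadane's optimum never carries
net-negative flanks, which implements end-trimming); copy number is
`floor(region length / period)`. A perfect period-`p` array also scores
highly at `2p`, `3p`, …, so overlapping calls are resolved to the smallest
empirical p, then to the smallest period whose score is within 95% of the
best — the divisor-ambiguity rule. This detector is a deliberate
simplification of profile-based repeat finders: it has no insertion/deletion
model, so it suits the fixed-length units of MIP repeat families (the
~31-residue GFG unit is the reference case) rather than highly gapped
repeats.

## Composite module calling and family assignment

- **NWE triad**: each NWE match claims the first two unused Mn-unit matches
  starting after its end; the triad is called when the full span (NWE start
  to second Mn end) is at most `max_module_span = 100` residues, otherwise
  the motif is reported as `NWE_ONLY`. Whether intervening Mn units should
  disqualify a triad is not defined anywhere; first-two-downstream is the
  implemented reading.
- **Arrays**: maximal chains of same-pattern matches with start-to-start
  spacing ≤ `max_inter_gap = 60` residues and ≥ `min_copies = 2` units.
  Isolated Mn units are kept visible as `MN_UNIT_ISOLATED` but never drive a
  family label.
- **SNYG module**: the motif plus two flanking windows of
  `snyg_flank_window = 4` residues; both flanks must average at least
  `snyg_hydropathy_threshold = 1.5` on the Kyte–Doolittle scale (Biopython's
  table). This hydropathy heuristic replaces secondary-structure prediction
  of the associated helix. Windows truncated by a terminus are evaluated on
  the available residues and flagged. The 1.5 default separates the
  synthetic hydrophobic flanks (L/I/V, mean ≈ 4) from charged or mixed
  background (uniform-background expectation ≈ −0.5) with a wide margin.
- **Family labels** follow a fixed precedence: `NWE_TRIAD → "NWE + Mn"`,
  `NWE_ONLY → "NWE only"`, `MN_ARRAY + PYG_ARRAY → "Mn + PYG"`, then the
  single-module labels, else `"unassigned"`. Assignment is a pure function
  of the call multiset. The DM10 family is fixture-driven only: a folded
  PH-like β-domain has no useful linear grammar, so DM10 membership comes
  from the packaged family table, never from scanning.

## Reciprocal-search validation

A forward hit is reliable iff its E-value is **strictly** below the cutoff
(0.01) and the target's reciprocal search recovers the original query
strictly below the same cutoff. The source prose prints both "E = 0.01" and
"(E < 0.01)"; the parenthetical is taken as operative. Optional family-aware
recapitulation accepts any member of the query's family. Every verdict
carries a reason code (`passed`, `forward_above_cutoff`,
`no_reciprocal_search`, `reciprocal_missed_query`). The packaged PYG
fixtures transcribe the membership of the published search summary; their
numeric E-values are synthetic placeholders (none are printed) and marked as
such in the file headers. No rank cutoff is applied beyond the E-value rule.

## Presence/absence profiling

Presence is detection-based (≥ 1 protein of the species carries the family),
not orthology-based. Concordance with ciliation uses the one-sided
hypergeometric upper tail — the probability, with margins fixed, of at least
the observed number of ciliated species among family-positive species — plus
an odds ratio with a Haldane 0.5 correction applied to all cells whenever any
cell is zero. A perfect 10-ciliated/10-non-ciliated split gives
p = 1/C(20,10) = 1/184756. The packaged taxa panel is synthetic and
illustrative; the published per-genome chart prints neither its species list
nor its cells, so real analyses require a user-supplied table.

## Synthetic data: what it shows and what it does not

The generator produces i.i.d. background (uniform residue frequencies by
default), implants concrete grammar instances (class members uniform, gaps
shortest by default) with per-position i.i.d. substitution at a stated
divergence, and builds family benchmarks of positives plus motif-free decoys
in a fixed 1:1 ratio, hosts of length 300. Ground truth is exact by
construction: benchmark hosts are rejection-sampled until module-free, and at
zero divergence each positive is verified to realize exactly the intended
architecture (chance background hits can otherwise extend an array or add a
spurious label); verification is skipped at divergence > 0, where degraded
detection is the point. Retries are bounded (cap 1000) and all randomness
flows through one seeded generator, so outputs are byte-identical per seed.

Passing these benchmarks shows the scanners, callers and samplers implement
their definitions correctly and degrade sensibly with substitution noise. It
does **not** show performance on real proteomes: real MIPs have biased
composition, indels, compositional low-complexity regions and correlated
substitutions, none of which the generator emulates (no indel model, no
domain shuffling, no phylogenetic correlation).

## Problem sizes used by the shipped checks

The default suite and the acceptance script run at desk scale: 1000 random
cases for scanner-vs-oracle equivalence, a 20×100-residue Gibbs benchmark at
500 sweeps, 100–200 seeded trials for repeat-detector robustness and null
calibration (100–200 permutations per detection), and 6–20 proteins per
family recipe. These sizes give stable pass/fail behavior at fixed seeds
while keeping a full run in the low minutes on one CPU.
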