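# Methods

## Overview

`metamerge` reconciles draft genome assemblies pairwise and progressively.
Each round takes the current metassembly as the *primary* and the next
input as the *secondary*, aligns them genome-to-genome, reduces the
alignment to a one-to-one mapping, scans every primary scaffold for
discrepancies, and decides each one with the compression–expansion (CE)
statistic derived from a jumping library. Aligned primary sequence is
always kept verbatim; the secondary only ever contributes at places where
the primary is locally implausible.

Coordinates are 0-based half-open everywhere internally; 1-based inclusive
conventions (MUMmer coords, SAM) are converted at the format boundary.
Sequences are uppercased on read and IUPAC ambiguity codes other than N
are collapsed to N — the algorithm only distinguishes gap from non-gap.

## The CE statistic

With library insert mean μ and s.d. σ, and n_i inserts spanning position i
with mean length Y_i,

    CE_i = (Y_i − μ*) / (σ / √n_i),     μ* = μ + σ²/μ.

μ* rather than μ: the pairs spanning a fixed position are a length-biased
sample of the library (a fragment covers the position with probability
proportional to its length), so under a correct assembly E[Y_i] = μ + σ²/μ.
Using μ directly shifts every CE by +(σ/μ)√n — about +0.63 for a
2.5 kb ± 250 bp library at 40× physical coverage — which inflates the null
|CE| > 3 rate from ~0.3 % to ~1 % of positions. With the corrected
reference the measured null rate is 0.24–0.40 % across seeds, matching the
nominal two-sided 3σ level of a z-statistic.

n_i and Y_i are computed for every base by a single plane sweep: each span
contributes (+1, +insert) at its start and (−1, −insert) at its end;
prefix sums over the sorted event positions give piecewise-constant count
and insert-sum tracks queried by binary search. Insert size is the outer
distance between the outermost mapped coordinates of the pair; mate
orientation is an intake filter only (default `any`, since jumping-library
chemistry varies) and never enters the statistic. Positions inside N-runs
carry CE like any other position — spanning pairs bridge gaps, and gap
decisions need CE at gap interiors. Pairs are neither deduplicated nor
weighted.

### Library model

μ and σ are estimated from the per-pair inserts inside the 1 %/99 %
empirical quantiles (robust to chimeras and mis-mappings); the trimmed
standard deviation is divided by the truncated-normal s.d. factor (≈0.938
for a 1 % trim) to undo the truncation bias, assuming normally distributed
inserts — without this the ~6 % downward bias in σ̂ inflates every CE by
~7 %. The model may instead be supplied explicitly (`--mu/--sigma`), in
which case the values are used as given. In a progressive run the library
is estimated once, from the first round's primary mapping, and held fixed:
the insert distribution is a property of the reads, not of any assembly.

### Inferred post-edit CE

Replacing P primary bases by S secondary bases changes each spanning insert
by S − P, so the post-edit local mean is Y* = Y − P + S and CE* follows
from the same formula with unchanged n and library. CE* assumes the edit
is interior to the spanning pairs, which holds for interblock discrepancies
and gap closures; at scaffold termini no pair can span the whole replaced
region, so n there is (almost always) zero and the condition is vacuous.

## Whole-genome alignment

Two intake routes produce the same block representation (primary interval,
secondary interval in forward coordinates, orientation, identity):

* **MUMmer**: `show-coords -H -T -l -c -r` tab output is parsed directly;
  reverse-strand rows (E2 < S2) are normalised.
* **Built-in anchor aligner**: k-mers (k = 21 by default, ≥ 11) unique in
  the primary and unique across both strands of the secondary are chained
  when they share a record pair, strand and exact diagonal and are at most
  200 bp apart; each maximal run becomes one block with identity = anchored
  bases ÷ span, discarding blocks shorter than 2k. Exact-match anchoring
  is intended for simulated or small genomes; it has no mismatch model.

Anchor chains can extend a few bases past a true edit boundary when the
divergent sequence coincidentally matches, creating tiny (< k) overlaps
between otherwise compatible blocks; these are resolved by trimming the
lighter block on both axes in step before filtering. Without this, a 2 bp
overlap can make the exact filter discard a 100 kb block.

### One-to-one filtering

The kept subset maximises total weight (length × identity) subject to no
two blocks overlapping on the primary axis or on the secondary axis. The
conflict graph decomposes into connected components; each component is
solved *exactly* by branch and bound (deterministic order, include-branch
first, suffix-sum pruning). A component larger than 40 blocks — a dense
repeat tangle beyond what the built-in aligner produces on draft
assemblies — falls back to two exact per-axis weighted-interval-scheduling
passes, primary axis first, mirroring the sequential behaviour of MUMmer's
delta-filter. The filter deliberately does **not** enforce co-linearity:
crossing (rearranged) block pairs that conflict on neither axis are both
kept, and the merge walk breaks chains at them instead, so rearrangement
evidence is preserved but never substituted across.

Sequences with no surviving alignment are dropped from both assemblies
(optionally retained above a minimum length).

## Discrepancy classification and decisions

Each primary scaffold is walked along its filtered blocks. Consecutive
blocks on the same secondary scaffold, same orientation, and monotone
secondary coordinates bracket an *interblock* discrepancy carrying both
unaligned lengths (possibly zero — a pure insertion point). Chain breaks
(different secondary scaffold, inconsistent orientation, or non-monotone
coordinates) leave the intervening primary sequence untouched: orientation
conflict signals an inversion, which this algorithm does not adjudicate.
Unaligned scaffold termini become *overhang* discrepancies carrying
however much unclaimed secondary sequence extends beyond the terminal
block — but only when that secondary side is a true terminus; a region
bounded by another primary's block is an interior junction reserved for
the scaffold-link step, so junction sequence is never consumed twice.

Breakpoint CE values are read at the midpoint of the discrepancy interval
on each assembly (clamped to the sequence; the flanking base for
zero-length sides). Decisions:

* **Interblock** → replace with (orientation-corrected) secondary sequence
  iff conditions 1–4 all hold; undefined CE_p fails condition 1, undefined
  CE_s fails condition 4, and condition 3 is vacuous when no insert spans
  the primary breakpoint.
* **Primary gap** (the discrepancy overlaps a primary gap segment, and the
  corresponding secondary span contains no secondary gap segment) →
  close under conditions 3–4 only: an N-run is known to be unresolved, so
  no CE evidence *against* the primary is demanded. A secondary span that
  itself contains a gap segment is never a closure donor.
* **Overhang** → extend under conditions 3–4 with primary length = the
  unaligned terminus, secondary length = the overhang.

Gap segments are found by seeding on every maximal N-run of length ≥ t and
greedily absorbing adjacent N-runs (with the intervening sequence) while
the segment N-fraction stays ≥ p, alternating directions until neither can
grow; overlapping seed results are unioned. The growth rule applies the
fraction test at every extension step, which is our resolution of an
ambiguity in how isolated Ns join into one unit; segments always begin and
end on N. Primary gaps use t = 50, p = 0.65; secondary gaps use the
permissive t = 10, p = 0.10 so that marginal secondary sequence never
closes a gap.

Every event records its breakpoint CE values, the inferred CE*, and a
per-condition trace; output is assembled left-to-right per scaffold from
the decisions (equivalent to right-to-left in-place substitution, without
coordinate bookkeeping), and each output scaffold carries a provenance
list whose concatenation reproduces it byte-exactly.

## Scaffold linking

For each secondary scaffold, consecutive blocks from two different primary
scaffolds — each the outermost alignment of the relevant end of its
scaffold — nominate a link. The junction is the secondary interval between
them; a candidate survives when the mean spanning-insert (physical)
coverage over the junction is ≥ 20. Candidates are applied greedily by
descending coverage, maintaining chains of oriented scaffolds; a whole
chain may be flipped to honour a link's orientation, a single member may
not, and conflicting or cyclic links are rejected. The junction is filled
with the secondary junction sequence (a contig join), or with
max(junction span, 10) Ns when the junction contains a secondary gap
segment (a scaffold join) — the N count preserves the estimated distance
while marking it unresolved.

## Progressive merging

Assemblies are ranked best-first — by contig N50 (default, contigs split
at every N), scaffold N50, or user order, ties broken by label — and the
pairwise merge is folded over the ranking. Mates are re-mapped to both
inputs every round; profiles of a freshly merged sequence cannot be
inherited. The built-in mapper places error-free reads only at a unique
exact occurrence across both strands, dropping ambiguous or gap-crossing
reads, so repeats lose pairs rather than gaining wrong ones; real data
should be mapped externally and supplied as per-round SAM files.

## Evaluation utilities

N50/NG50 (largest L with cumulative length ≥ x × denominator; 0 when an
NG target is unreachable), per-assembly summaries, and an overall Z score
that sums per-metric z-scores across assemblies (sample s.d., n−1;
zero-spread metrics contribute 0; lower-is-better metrics sign-flipped,
directions always explicit). A CE-delta report re-evaluates |CE| at each
modified position on the re-mapped merged assembly and returns
|CE before| − |CE after| per event.

## Synthetic data

The generator emulates the error classes of draft assemblies relative to
their source genome: scaffold gaps (true sequence → an N-run whose length
mis-estimates the truth by a multiplicative factor), expansions (inserted
random sequence), contractions (deletions), dropped regions (deletion +
scaffold break) and plain breaks. Event loci are non-overlapping and at
least 2×(μ+3σ) (default 6500 bp) from scaffold ends and each other so CE
is measurable at every breakpoint. Every event is recorded in a truth
table sufficient to invert it; `reconstruct_truth` is the tested inverse.
Reads are error-free (what the exact mapper requires); an optional uniform
substitution rate exists for external-mapper workflows. All randomness
derives from one seed through labelled sub-seeds.

The three-assembly fixture (`make_three_assembly_fixture`) builds a 1 Mb truth
genome, a 2.5 kb ± 250 bp library at 40× physical coverage (16,000 pairs),
and three assemblies whose defects are complementary by construction:
private gaps, one expansion or contraction each, one scaffold break each,
one *pair-shared* gap per assembly pair (defeating that pairwise merge),
and one locus gapped in all three (closable by no order). Gap-size errors
differ per assembly (×1.3/×1.15/×1.45) so the surviving N-run identifies
the lead assembly and merge orderings produce distinct finals. One
scaffold is stored reverse-complemented, as draft scaffolds are, to
exercise reverse-orientation merging and link flipping. These defaults are
the package's documented study conditions; the fixture scales down (the
layout is proportional) for quick tests.

What the simulations do not model: sequencing errors in reads, coverage
biases, chimeric pairs, repeat-induced mis-joins, quality scores, and real
inversions. Passing tests therefore demonstrate the correctness of the
statistics, decision rules and bookkeeping under the stated model, not
performance on real libraries — for which the external-aligner and
external-mapper routes exist.

## Numerical and procedural choices

* Exact one-to-one optimisation (not a heuristic) so the filter is
  testable against an exhaustive oracle; floating-point weight ties break
  deterministically by the branch order.
* Problem sizes in the test and acceptance runs: 1 Mb truth genome for the
  reconstruction, permutation and null studies (CE values decorrelate over
  ~one insert length, so ~400 independent blocks stabilise rate
  estimates); 120–400 kb for unit-level scenarios.
* The CE track treats segments between span endpoints as constant (exact,
  not sampled); bedGraph export writes one row per segment.
* Scaffold-link junction coverage over an empty junction (abutting blocks)
  is read from the flanking base.
* Self-merge of an assembly with itself is the identity on sequence
  content; this is asserted in the suite.

## Known limitations

Inversions are never corrected. No base-level consensus within aligned
blocks. One library per round; no multi-library mixtures. The built-in
aligner's identity model is exact-match only, so it under-reports identity
for diverged genomes — use MUMmer there. Linking cannot flip a single
scaffold inside an already-built chain; such conflicted links are skipped
rather than re-optimised globally.
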