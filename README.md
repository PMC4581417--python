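# metamerge

Progressive reconciliation of multiple de novo genome assemblies into a
single, superior metassembly.

## The problem

Different assemblers make different mistakes on the same data: one produces
long scaffolds riddled with mis-sized gaps, another shorter but cleaner
contigs. No single program wins on every metric, yet each assembly is
usually locally best somewhere. `metamerge` merges two or more draft
assemblies by keeping one assembly (the *primary*) as the backbone and
mining each further assembly (the *secondary*) for local corrections —
fixing insertion/deletion errors, closing scaffold gaps, extending scaffold
ends, and linking scaffolds — then iterating with the merged result and the
next assembly, best-first.

The arbiter between two conflicting sequences is the **compression–expansion
(CE) statistic** computed from a jumping (mate-pair) library mapped to each
assembly. With library insert mean μ and standard deviation σ, and with
*n<sub>i</sub>* inserts spanning position *i* with local mean length
*Y<sub>i</sub>*,

> CE<sub>i</sub> = (Y<sub>i</sub> − μ\*) / (σ / √n<sub>i</sub>),  μ\* = μ + σ²/μ

a one-sample z-statistic (μ\* is the null expectation of a spanning-insert
mean; spanning pairs are a length-biased sample). CE ≪ 0 signals
*compression* (sequence missing at *i*); CE ≫ 0 signals *expansion*
(sequence erroneously inserted). CE is computed at every base by a plane
sweep over span endpoints.

At each discrepancy between the aligned assemblies, the primary sequence is
replaced by the secondary only if all four conditions hold (z = 3, d = 2 by
default):

1. **poor primary** — |CE<sub>p</sub>| > z at the primary breakpoint;
2. **better secondary** — |CE<sub>p</sub>| − |CE<sub>s</sub>| > d;
3. **improved result** — the inferred post-edit statistic CE\*, computed
   from Y\* = Y − (primary length) + (secondary length), satisfies
   |CE\*| < z (skipped when no insert spans the breakpoint);
4. **clean secondary** — |CE<sub>s</sub>| < z.

A scaffold gap in the primary (an N-dominated segment seeded by ≥ t = 50
contiguous Ns at ≥ p = 0.65 N-fraction) that is spanned by gap-free
secondary sequence is closed under conditions 3–4 alone; secondary
overhangs past a scaffold end are handled the same way; and two primary
scaffolds aligning contiguously to one secondary scaffold are linked when
the spanning-insert coverage over the junction is ≥ 20 — into one contig,
or one scaffold if the secondary junction itself contains a gap.

Whole-genome alignment comes either from MUMmer (`show-coords -H -T -l -c -r`
output is parsed directly) or from a built-in exact-k-mer anchor aligner
suitable for small genomes and simulation studies. Either way the blocks
are reduced to a one-to-one mapping by an exact maximum-weight selection
(weight = length × identity) with no overlap on either assembly axis,
which removes repeat-induced ambiguity before merging.

## Worked example

The package ships a synthetic-data module that generates a truth genome,
corrupted assemblies with a complete truth table, and a simulated jumping
library, so the whole pipeline runs without external data:

```python
from metamerge.metrics import assembly_stats
from metamerge.progressive import order_assemblies, progressive_merge
from metamerge.synthetic import make_three_assembly_fixture

fix = make_three_assembly_fixture(seed=3, truth_len=400_000)   # 3 assemblies, 2.5 kb library, 40x
ordered = order_assemblies(fix.assemblies, "ctg_n50")
result = progressive_merge(ordered, fix.reads)
```

Printing the per-round summaries:

```
merge order: A -> C -> B
  A: 2 scaffolds, scaffold N50 321,440, contig N50 80,000, 3,640 gap bases
  C: 2 scaffolds, scaffold N50 301,860, contig N50 79,400, 4,060 gap bases
  B: 2 scaffolds, scaffold N50 339,920, contig N50 60,000, 3,220 gap bases
round 1 (+C): 4 corrections, 1 links -> 1 scaffold(s), scaffold N50 400,360, 1,560 gap bases
round 2 (+B): 1 corrections, 0 links -> 1 scaffold(s), scaffold N50 400,180, 780 gap bases
final: 1 scaffold, span 400,180, 780 gap bases
```

Round 1 closes A's private gaps, removes its 600 bp expansion, and links
A's two scaffolds through C; the two gaps that remain are the loci where
both A and C carry a gap. Round 2 closes the one that B resolves; the
single surviving 780 N run marks the locus gapped in *all three* inputs,
which no merge order can close. Every modification is recorded in a
per-event log (breakpoint coordinates, CE values, which of conditions 1–4
passed) and every output scaffold carries provenance — the list of source
intervals whose concatenation reproduces it byte-for-byte.

The same pipeline is available from the shell:

```bash
metamerge simulate --length 200000 --seed 7 --out sim/
metamerge metassemble --fasta a1.fa --fasta a2.fa --fasta a3.fa \
    --reads mates_1.fq mates_2.fq --order ctg_n50 --out meta/
metamerge ce-profile --fasta asm.fa --sam mapped.sam --out ce.bedgraph
metamerge stats --fasta meta/metassembly.fa
metamerge params --init params.yaml      # all thresholds, editable
```

For real data, align with nucmer and pass `--coords` (the
`show-coords -H -T -l -c -r` table), and map the jumping library with any
read mapper, passing SAM files.

## Limitations

Inversions are detected (as orientation-inconsistent alignments) but never
corrected — the primary sequence is kept. Aligned primary sequence is kept
verbatim; there is no base-level polishing. One jumping library is used per
merge round. The built-in aligner and mapper are exact-match tools for
error-free simulated reads and small genomes; real data should come in
through MUMmer coords and external SAM files. See `docs/methods.md` for the
full model description and design rationale.
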