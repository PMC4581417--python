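"""Synthetic truth genomes, corrupted assemblies and simulated jumping libraries.

The generator emulates the error classes a draft assembly accumulates
relative to the genome it was assembled from: scaffold gaps (true sequence
replaced by an N-run whose length mis-estimates the truth), expansions
(spurious inserted sequence), contractions (deleted sequence), dropped
regions (missing sequence that also breaks the scaffold) and plain scaffold
breaks.  Every corruption is recorded in a truth table precise enough to
score any later merge decision, and is invertible: applying the recorded
inverse edits reproduces the truth genome byte for byte.

Mate pairs are drawn from the truth genome with normally distributed insert
sizes and are error-free by default, which is what the exact built-in mapper
requires; an optional uniform substitution rate exists only for workflows
that map with an external aligner.  All randomness flows from a single seed
through derived per-operation seeds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from .core import Assembly, SequenceRecord, revcomp
from .mapping import ReadPairSet

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _derive_seed(seed: int, tag: str) -> int:
    """Stable sub-seed below 2^31 derived from a master seed and a label."""
    h = np.uint64(seed & 0x7FFFFFFF)
    for ch in tag:
        h = np.uint64((int(h) * 1000003 + ord(ch)) % (2**31 - 1))
    return int(h)


def random_sequence(length: int, rng: np.random.Generator, gc: float = 0.5) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    draws = rng.choice(4, size=length, p=p)
    return _BASES[draws].tobytes().decode()


def simulate_genome(
    length: int,
    gc: float = 0.5,
    repeat_spec: Optional[tuple[int, int]] = None,
    seed: int = 0,
    name: str = "truth",
) -> SequenceRecord:
    """I.i.d. random genome at a given GC, optionally carrying an exact repeat family.

    repeat_spec = (family_length, copies) pastes `copies` verbatim copies of
    one random family sequence at random non-overlapping loci.
    """
    rng = np.random.default_rng(_derive_seed(seed, "genome"))
    seq = list(random_sequence(length, rng, gc))
    if repeat_spec is not None:
        fam_len, copies = repeat_spec
        family = random_sequence(fam_len, rng, gc)
        placed: list[tuple[int, int]] = []
        attempts = 0
        while len(placed) < copies:
            attempts += 1
            if attempts > 1000 * copies:
                raise ValueError("cannot place repeat copies without overlap")
            start = int(rng.integers(0, length - fam_len))
            if any(start < e and s < start + fam_len for s, e in placed):
                continue
            placed.append((start, start + fam_len))
            seq[start : start + fam_len] = family
    return SequenceRecord(name, "".join(seq))


@dataclass(frozen=True)
class CorruptionEvent:
    """One planned edit in truth coordinates.

    kind: gap | expansion | contraction | dropped | break
    start/end: truth interval consumed by the event (equal for expansion/break)
    length: inserted length for expansion; N-run length for gap (0 = derive
    from size_error); ignored otherwise.
    """

    kind: str
    start: int
    end: int
    length: int = 0


@dataclass
class CorruptionSpec:
    """Counts and length distributions of the random corruption classes.

    Event loci are drawn non-overlapping and at least `margin` bases from
    scaffold ends and from each other, so the CE statistic is measurable at
    every breakpoint (margin defaults to 2 x (mu + 3 sigma) of the standard
    2.5 kb library).
    """

    n_scaffold_breaks: int = 0
    n_gaps: int = 0
    gap_len: tuple[int, int] = (300, 800)
    gap_size_error: float = 1.0      # N-run length = round(true length x this)
    n_expansions: int = 0
    expansion_len: tuple[int, int] = (300, 800)
    n_contractions: int = 0
    contraction_len: tuple[int, int] = (300, 800)
    n_dropped: int = 0
    dropped_len: tuple[int, int] = (1000, 3000)
    margin: int = 6500
    seed: int = 0
    events: Optional[list[CorruptionEvent]] = None  # explicit plan overrides counts


@dataclass
class TruthRow:
    """One corruption with enough information to invert it."""

    kind: str
    truth_start: int
    truth_end: int
    scaffold_id: Optional[str]
    asm_start: int
    asm_end: int
    size_delta: int            # assembly length minus truth length at the locus
    true_seq: str = ""         # truth sequence removed/obscured by the event


@dataclass(frozen=True)
class ScaffoldRange:
    """Truth interval covered by one scaffold; orientation of the stored sequence."""

    scaffold_id: str
    truth_start: int
    truth_end: int
    orientation: str = "forward"


@dataclass
class TruthTable:
    rows: list[TruthRow] = field(default_factory=list)
    # truth interval covered by each scaffold, in genome order
    scaffold_ranges: list[ScaffoldRange] = field(default_factory=list)

    def __iter__(self):
        return iter(self.rows)

    def __len__(self) -> int:
        return len(self.rows)

    def gaps(self) -> list[TruthRow]:
        return [r for r in self.rows if r.kind == "gap"]

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("kind\ttruth_start\ttruth_end\tscaffold\tasm_start\tasm_end\tsize_delta\n")
            for r in self.rows:
                fh.write(f"{r.kind}\t{r.truth_start}\t{r.truth_end}\t{r.scaffold_id}\t"
                         f"{r.asm_start}\t{r.asm_end}\t{r.size_delta}\n")


class CorruptionError(ValueError):
    pass


def _draw_events(truth_len: int, spec: CorruptionSpec) -> list[CorruptionEvent]:
    rng = np.random.default_rng(_derive_seed(spec.seed, "corrupt"))
    plan: list[tuple[str, int]] = []  # (kind, consumed truth length)
    for _ in range(spec.n_gaps):
        plan.append(("gap", int(rng.integers(*spec.gap_len))))
    for _ in range(spec.n_expansions):
        plan.append(("expansion", 0))
    for _ in range(spec.n_contractions):
        plan.append(("contraction", int(rng.integers(*spec.contraction_len))))
    for _ in range(spec.n_dropped):
        plan.append(("dropped", int(rng.integers(*spec.dropped_len))))
    for _ in range(spec.n_scaffold_breaks):
        plan.append(("break", 0))
    if not plan:
        return []
    rng.shuffle(plan)
    n = len(plan)
    max_len = max(l for _, l in plan)
    needed = 2 * spec.margin + n * (spec.margin + max_len)
    if needed > truth_len:
        raise CorruptionError(
            f"{n} events with margin {spec.margin} do not fit a {truth_len} bp genome"
        )
    for _ in range(1000):
        starts = np.sort(rng.integers(spec.margin, truth_len - spec.margin - max_len, size=n))
        if n == 1 or np.all(np.diff(starts) >= spec.margin + max_len):
            break
    else:
        raise CorruptionError("could not place non-overlapping event loci; reduce counts")
    events = []
    exp_rng = np.random.default_rng(_derive_seed(spec.seed, "expansion_len"))
    for (kind, consumed), start in zip(plan, starts.tolist()):
        if kind == "expansion":
            events.append(CorruptionEvent(kind, start, start,
                                          int(exp_rng.integers(*spec.expansion_len))))
        elif kind == "break":
            events.append(CorruptionEvent(kind, start, start))
        else:
            events.append(CorruptionEvent(kind, start, start + consumed))
    return events


def corrupt_assembly(
    truth: SequenceRecord,
    spec: CorruptionSpec,
    label: str = "asm",
) -> tuple[Assembly, TruthTable]:
    """Apply a corruption plan to the truth genome, returning assembly + truth table."""
    events = spec.events if spec.events is not None else _draw_events(len(truth.seq), spec)
    events = sorted(events, key=lambda e: (e.start, e.end))
    for a, b in zip(events, events[1:]):
        if b.start < a.end:
            raise CorruptionError(f"overlapping corruption events at {a.start} and {b.start}")
    rng = np.random.default_rng(_derive_seed(spec.seed, "insert_seq"))

    table = TruthTable()
    scaffolds: list[SequenceRecord] = []
    parts: list[str] = []
    cur_len = 0
    t_lo = 0
    pending_rows: list[TruthRow] = []
    cursor = 0
    scf_idx = 0

    def close_scaffold(t_hi: int) -> None:
        nonlocal parts, cur_len, t_lo, pending_rows, scf_idx
        seq = "".join(parts)
        if seq:
            sid = f"{label}_scf{scf_idx:02d}"
            scf_idx += 1
            scaffolds.append(SequenceRecord(sid, seq))
            table.scaffold_ranges.append(ScaffoldRange(sid, t_lo, t_hi))
            for row in pending_rows:
                row.scaffold_id = sid
                table.rows.append(row)
        elif pending_rows:
            raise CorruptionError("corruption produced an empty scaffold carrying events")
        parts, cur_len, pending_rows = [], 0, []

    def emit(s: str) -> None:
        nonlocal cur_len
        if s:
            parts.append(s)
            cur_len += len(s)

    for ev in events:
        emit(truth.seq[cursor:ev.start])
        cursor = ev.start
        true_len = ev.end - ev.start
        if ev.kind == "break":
            close_scaffold(ev.start)
            t_lo = ev.start
        elif ev.kind == "gap":
            n_len = ev.length if ev.length > 0 else max(1, round(true_len * spec.gap_size_error))
            pending_rows.append(TruthRow("gap", ev.start, ev.end, None,
                                         cur_len, cur_len + n_len, n_len - true_len,
                                         true_seq=truth.seq[ev.start:ev.end]))
            emit("N" * n_len)
            cursor = ev.end
        elif ev.kind == "expansion":
            ins = random_sequence(ev.length, rng)
            pending_rows.append(TruthRow("expansion", ev.start, ev.start, None,
                                         cur_len, cur_len + ev.length, ev.length))
            emit(ins)
        elif ev.kind == "contraction":
            pending_rows.append(TruthRow("contraction", ev.start, ev.end, None,
                                         cur_len, cur_len, -true_len,
                                         true_seq=truth.seq[ev.start:ev.end]))
            cursor = ev.end
        elif ev.kind == "dropped":
            close_scaffold(ev.start)
            table.rows.append(TruthRow("dropped", ev.start, ev.end, None, 0, 0,
                                       -true_len, true_seq=truth.seq[ev.start:ev.end]))
            t_lo = ev.end
            cursor = ev.end
        else:
            raise CorruptionError(f"unknown corruption kind {ev.kind!r}")
    emit(truth.seq[cursor:])
    close_scaffold(len(truth.seq))
    if not scaffolds:
        raise CorruptionError("corruption removed the whole genome")
    return Assembly(scaffolds, label=label), table


def flip_scaffold(asm: Assembly, table: TruthTable, sid: str) -> tuple[Assembly, TruthTable]:
    """Reverse-complement one scaffold (orientation is arbitrary in a draft assembly).

    Truth-table rows keep their coordinates in the forward frame; only the
    scaffold-range orientation flips, and reconstruction un-flips first.
    """
    records = [SequenceRecord(r.id, revcomp(r.seq)) if r.id == sid else r
               for r in asm.records]
    ranges = [ScaffoldRange(r.scaffold_id, r.truth_start, r.truth_end,
                            "reverse" if r.scaffold_id == sid and r.orientation == "forward"
                            else ("forward" if r.scaffold_id == sid else r.orientation))
              for r in table.scaffold_ranges]
    return Assembly(records, label=asm.label), TruthTable(table.rows, ranges)


def reconstruct_truth(asm: Assembly, table: TruthTable) -> str:
    """Invert every recorded corruption; the result must equal the truth genome."""
    pieces: list[tuple[int, str]] = []
    for rng_ in table.scaffold_ranges:
        sid, t_lo = rng_.scaffold_id, rng_.truth_start
        seq = asm[sid].seq
        if rng_.orientation == "reverse":
            seq = revcomp(seq)
        rows = sorted((r for r in table.rows if r.scaffold_id == sid),
                      key=lambda r: r.asm_start, reverse=True)
        for r in rows:
            if r.kind == "gap" or r.kind == "contraction":
                seq = seq[: r.asm_start] + r.true_seq + seq[r.asm_end :]
            elif r.kind == "expansion":
                seq = seq[: r.asm_start] + seq[r.asm_end :]
        pieces.append((t_lo, seq))
    for r in table.rows:
        if r.kind == "dropped":
            pieces.append((r.truth_start, r.true_seq))
    pieces.sort()
    return "".join(seq for _, seq in pieces)


def simulate_matepairs(
    truth: SequenceRecord,
    n: int,
    mu: float,
    sigma: float,
    read_len: int = 100,
    seed: int = 0,
    error_rate: float = 0.0,
) -> ReadPairSet:
    """Simulate n error-free mate pairs from the truth genome.

    Fragment starts are uniform; inserts are round(Normal(mu, sigma))
    truncated to [read_len + 1, genome length].  Mate 1 is the forward
    prefix of the fragment, mate 2 the reverse complement of its suffix
    (outward-sequenced ends of a long jumping fragment behave identically
    for insert-size purposes).
    """
    L = len(truth.seq)
    if mu + 4 * sigma >= L:
        raise ValueError("genome too short for this insert distribution")
    rng = np.random.default_rng(_derive_seed(seed, "matepairs"))
    inserts = np.rint(rng.normal(mu, sigma, size=n)).astype(np.int64)
    inserts = np.clip(inserts, read_len + 1, L)
    starts = (rng.random(size=n) * (L - inserts + 1)).astype(np.int64)
    err_rng = np.random.default_rng(_derive_seed(seed, "readerr")) if error_rate > 0 else None
    pairs = []
    for i in range(n):
        s, ins = int(starts[i]), int(inserts[i])
        r1 = truth.seq[s : s + read_len]
        r2 = revcomp(truth.seq[s + ins - read_len : s + ins])
        if err_rng is not None:
            r1 = _mutate(r1, error_rate, err_rng)
            r2 = _mutate(r2, error_rate, err_rng)
        pairs.append((f"mp{i:06d}", r1, r2))
    return ReadPairSet(pairs)


def _mutate(read: str, rate: float, rng: np.random.Generator) -> str:
    out = list(read)
    hits = np.flatnonzero(rng.random(len(read)) < rate)
    for i in hits:
        out[i] = "ACGT"[int(rng.integers(4))]
    return "".join(out)


@dataclass
class ThreeAssemblyFixture:
    """Truth genome, three complementarily corrupted assemblies, one library.

    shared_gap_loci maps each assembly pair to the truth locus where both
    members carry a gap (defeating that pairwise merge); unclosable_locus is
    gapped in all three assemblies, so it survives every merge order with
    the first assembly's N-run length — which differs between assemblies.
    """

    truth: SequenceRecord
    assemblies: list[Assembly]
    reads: ReadPairSet
    truth_tables: dict[str, TruthTable]
    mu: float
    sigma: float
    read_len: int
    shared_gap_loci: dict[tuple[str, str], tuple[int, int]]
    unclosable_locus: tuple[int, int]
    unclosable_n_len: dict[str, int]


def make_three_assembly_fixture(
    seed: int = 0,
    truth_len: int = 1_000_000,
    mu: float = 2500.0,
    sigma: float = 250.0,
    read_len: int = 100,
    coverage: float = 40.0,
) -> ThreeAssemblyFixture:
    """Three assemblies whose defects are complementary but pairwise insufficient.

    Every truth base is error-free in at least one assembly, and for every
    pair of assemblies there is one locus where both members carry a gap, so
    no pairwise merge can reconstruct the truth while the three-way
    progressive merge can.  Defect loci scale with truth_len; the defaults
    (1 Mb truth, 2.5 kb +/- 250 bp library at 40x physical coverage) are the
    evaluation conditions used throughout this package.
    """
    truth = simulate_genome(truth_len, seed=_derive_seed(seed, "trio_truth"))
    u = truth_len // 20  # layout unit

    def gap(start, length=600):
        return CorruptionEvent("gap", start, start + length)

    shared_ab = 8 * u
    shared_bc = 9 * u
    shared_ac = 10 * u
    shared_all = 11 * u

    events_a = [
        gap(1 * u), gap(4 * u, 400),
        CorruptionEvent("expansion", 5 * u, 5 * u, 600),
        gap(shared_ab), gap(shared_ac), gap(shared_all),
        CorruptionEvent("break", 16 * u, 16 * u),
    ]
    events_b = [
        gap(2 * u), gap(6 * u, 400),
        CorruptionEvent("contraction", 12 * u, 12 * u + 500),
        gap(shared_ab), gap(shared_bc), gap(shared_all),
        CorruptionEvent("break", 17 * u, 17 * u),
    ]
    events_c = [
        gap(3 * u), gap(7 * u, 400),
        CorruptionEvent("expansion", 13 * u, 13 * u, 600),
        gap(shared_bc), gap(shared_ac), gap(shared_all),
        CorruptionEvent("break", 15 * u, 15 * u),
    ]

    # distinct gap-size mis-estimates: the N-run left at the jointly gapped
    # locus identifies which assembly led the merge
    size_errors = {"A": 1.3, "B": 1.15, "C": 1.45}

    assemblies = []
    tables = {}
    for label, events in (("A", events_a), ("B", events_b), ("C", events_c)):
        spec = CorruptionSpec(seed=_derive_seed(seed, f"fix{label}"),
                              gap_size_error=size_errors[label], events=events)
        asm, table = corrupt_assembly(truth, spec, label=label)
        if label == "C":
            # one scaffold stored reverse-complemented, as draft assemblies do
            asm, table = flip_scaffold(asm, table, "C_scf01")
        assemblies.append(asm)
        tables[label] = table

    n_pairs = int(coverage * truth_len / mu)
    reads = simulate_matepairs(truth, n_pairs, mu, sigma, read_len,
                               seed=_derive_seed(seed, "trio_reads"))
    shared = {
        ("A", "B"): (shared_ab, shared_ab + 600),
        ("B", "C"): (shared_bc, shared_bc + 600),
        ("A", "C"): (shared_ac, shared_ac + 600),
    }
    n_lens = {lbl: round(600 * err) for lbl, err in size_errors.items()}
    return ThreeAssemblyFixture(truth, assemblies, reads, tables,
                                mu, sigma, read_len, shared,
                                (shared_all, shared_all + 600), n_lens)
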