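"""Sequence data model, FASTA I/O, contig decomposition and scaffold-gap detection.

All coordinates in this package are 0-based, half-open.  Conversions to and
from 1-based inclusive conventions (MUMmer coords files, SAM) happen only at
the format boundary.

Sequences are normalised on read: uppercased, with every IUPAC ambiguity code
other than N collapsed to N.  The merging algorithm only ever distinguishes
gap (N) from non-gap sequence, so retaining partial ambiguity information
would buy nothing.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

ALPHABET = frozenset("ACGTN")

# IUPAC nucleotide ambiguity codes that collapse to N (plus N itself).
_AMBIGUOUS = "RYSWKMBDHVN"
_NORMALISE = str.maketrans(_AMBIGUOUS.lower() + _AMBIGUOUS + "acgt", "N" * 22 + "ACGT")

_VALID_RE = re.compile(r"^[ACGTN]+$")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class FastaParseError(ValueError):
    """Raised when an input FASTA file violates the data model."""


def revcomp(seq: str) -> str:
    """Reverse complement of an A/C/G/T/N string."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class SequenceRecord:
    """One named scaffold (or contig) over the alphabet {A, C, G, T, N}."""

    id: str
    seq: str

    def __post_init__(self) -> None:
        if not self.id or any(c.isspace() for c in self.id):
            raise ValueError(f"invalid sequence id: {self.id!r}")
        if len(self.seq) < 1:
            raise ValueError(f"empty sequence for record {self.id!r}")
        if not _VALID_RE.match(self.seq):
            bad = sorted(set(self.seq) - ALPHABET)
            raise ValueError(f"record {self.id!r} contains non-nucleotide characters {bad}")

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class Assembly:
    """An ordered collection of uniquely named scaffolds."""

    records: list[SequenceRecord]
    label: str = ""
    _index: dict[str, SequenceRecord] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self._index = {}
        for rec in self.records:
            if rec.id in self._index:
                raise ValueError(f"duplicate sequence id {rec.id!r} in assembly {self.label!r}")
            self._index[rec.id] = rec

    def __iter__(self) -> Iterator[SequenceRecord]:
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)

    def __contains__(self, seq_id: str) -> bool:
        return seq_id in self._index

    def __getitem__(self, seq_id: str) -> SequenceRecord:
        return self._index[seq_id]

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    @property
    def span(self) -> int:
        """Total number of bases (including Ns) across all records."""
        return sum(len(r) for r in self.records)

    def relabel(self, label: str) -> "Assembly":
        return Assembly(self.records, label=label)

    def subset(self, keep_ids: Iterable[str]) -> "Assembly":
        keep = set(keep_ids)
        return Assembly([r for r in self.records if r.id in keep], label=self.label)


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open [start, end) interval on a named sequence."""

    seq_id: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0 or self.end <= self.start:
            raise ValueError(f"invalid interval {self.seq_id}:{self.start}-{self.end}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.seq_id == other.seq_id
            and self.start < other.end
            and other.start < self.end
        )

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


@dataclass(frozen=True)
class MergeParams:
    """Thresholds driving every merge decision.

    z : CE significance threshold; a breakpoint is called mis-assembled when
        |CE| exceeds it (default 3).
    d : minimum margin by which the primary breakpoint must look worse than
        the secondary one, |CE_p| - |CE_s| > d (default 2).
    t_primary_gap, p_primary_gap : a primary scaffold gap needs an N-run of
        at least t contiguous Ns and an overall N fraction of at least p
        (defaults 50 and 0.65).
    t_secondary_gap, p_secondary_gap : the permissive gap definition applied
        to the secondary assembly (defaults 10 and 0.10), chosen loose so
        that dubious secondary sequence never closes a gap.
    link_coverage : minimum mean spanning-insert coverage over a secondary
        junction for two primary scaffolds to be linked (default 20).
    min_anchor : k-mer length of the built-in anchor aligner (default 21).
    keep_unaligned_min_len : when set, unaligned sequences at least this long
        survive the alignment filter instead of being discarded.
    """

    z: float = 3.0
    d: float = 2.0
    t_primary_gap: int = 50
    p_primary_gap: float = 0.65
    t_secondary_gap: int = 10
    p_secondary_gap: float = 0.10
    link_coverage: float = 20.0
    min_anchor: int = 21
    keep_unaligned_min_len: int | None = None

    def __post_init__(self) -> None:
        if self.z <= 0:
            raise ValueError("z must be positive")
        if self.d < 0:
            raise ValueError("d must be non-negative")
        for name in ("p_primary_gap", "p_secondary_gap"):
            p = getattr(self, name)
            if not 0 < p <= 1:
                raise ValueError(f"{name} must be in (0, 1]")
        for name in ("t_primary_gap", "t_secondary_gap"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")

    def with_updates(self, **kwargs) -> "MergeParams":
        return replace(self, **kwargs)


def read_fasta(path: str | Path, label: str | None = None) -> Assembly:
    """Read a (multi-)FASTA file into an :class:`Assembly`.

    Sequences are uppercased and IUPAC ambiguity codes other than N are
    collapsed to N.  Any other character is a parse error naming the record.
    """
    path = Path(path)
    records: list[SequenceRecord] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).translate(_NORMALISE)
        try:
            records.append(SequenceRecord(rec.id, seq))
        except ValueError as exc:
            raise FastaParseError(f"{path}: {exc}") from exc
    if not records:
        raise FastaParseError(f"{path}: no FASTA records found")
    try:
        return Assembly(records, label=label if label is not None else path.stem)
    except ValueError as exc:
        raise FastaParseError(f"{path}: {exc}") from exc


def write_fasta(asm: Assembly | Iterable[SequenceRecord], path: str | Path, width: int = 70) -> None:
    """Write an assembly as wrapped FASTA; round-trips through read_fasta."""
    records = asm.records if isinstance(asm, Assembly) else list(asm)
    bio = [SeqRecord(Seq(r.seq), id=r.id, description="") for r in records]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(bio)


def n_runs(seq: str) -> list[tuple[int, int]]:
    """Maximal runs of N as (start, end) half-open tuples, in order."""
    return [(m.start(), m.end()) for m in re.finditer(r"N+", seq)]


def split_into_contigs(rec: SequenceRecord, min_run: int = 1) -> list[GenomicInterval]:
    """Decompose a scaffold into contigs by splitting at N-runs of length >= min_run.

    Runs shorter than min_run remain inside the flanking contig interval.
    With min_run=1 the intervals are exactly the maximal non-N stretches.
    """
    splitters = [(s, e) for s, e in n_runs(rec.seq) if e - s >= min_run]
    out: list[GenomicInterval] = []
    pos = 0
    for s, e in splitters:
        if s > pos:
            out.append(GenomicInterval(rec.id, pos, s))
        pos = e
    if pos < len(rec.seq):
        out.append(GenomicInterval(rec.id, pos, len(rec.seq)))
    return out


def find_scaffold_gaps(rec: SequenceRecord, t: int, p: float) -> list[GenomicInterval]:
    """Find scaffold-gap segments: N-dominated stretches seeded by long N-runs.

    A segment is seeded on every maximal N-run of length >= t, then greedily
    extended by absorbing adjacent N-runs (of any length, together with the
    intervening non-N sequence) for as long as the segment's overall N
    fraction stays >= p.  Extension alternates leftward and rightward until
    neither direction can absorb another run; segments grown from different
    seeds that overlap are unioned.  Every returned segment starts and ends
    on an N base.
    """
    if t < 1 or not 0 < p <= 1:
        raise ValueError("require t >= 1 and 0 < p <= 1")
    runs = n_runs(rec.seq)
    if not runs:
        return []
    run_len = [e - s for s, e in runs]
    segments: list[tuple[int, int]] = []  # as (lo_run_idx, hi_run_idx) inclusive
    for i, (s, e) in enumerate(runs):
        if e - s < t:
            continue
        lo = hi = i
        n_bases = run_len[i]
        while True:
            grown = False
            # leftward
            if lo > 0:
                cand_n = n_bases + run_len[lo - 1]
                span = runs[hi][1] - runs[lo - 1][0]
                if cand_n / span >= p:
                    lo -= 1
                    n_bases = cand_n
                    grown = True
            # rightward
            if hi + 1 < len(runs):
                cand_n = n_bases + run_len[hi + 1]
                span = runs[hi + 1][1] - runs[lo][0]
                if cand_n / span >= p:
                    hi += 1
                    n_bases = cand_n
                    grown = True
            if not grown:
                break
        segments.append((runs[lo][0], runs[hi][1]))
    if not segments:
        return []
    # union overlapping/touching segments from different seeds
    segments.sort()
    merged: list[list[int]] = [list(segments[0])]
    for s, e in segments[1:]:
        if s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [GenomicInterval(rec.id, s, e) for s, e in merged]


def write_bed3(intervals: Iterable[GenomicInterval], path: str | Path) -> None:
    """Write intervals (e.g. gap segments) as BED3."""
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.seq_id}\t{iv.start}\t{iv.end}\n")
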