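"""Exact placement of error-free reads on an assembly.

A deliberately simple mapper for simulated, error-free reads: every mate is
placed only if it has exactly one exact occurrence across both strands of
the whole assembly, so repeat-induced ambiguity drops pairs instead of
mis-placing them.  Reads overlapping an N gap never match (N matches
nothing).  Real data should be mapped externally and ingested as SAM.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, NamedTuple

import numpy as np

from .core import Assembly, revcomp

_ENC = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _ENC[_b] = _i

_SEED_K = 31


class ReadHit(NamedTuple):
    seq_id: str
    start: int
    end: int
    reverse: bool


@dataclass
class ReadPairSet:
    """Named mate pairs as plain strings; mate 2 is stored as sequenced."""

    pairs: list[tuple[str, str, str]]

    def __len__(self) -> int:
        return len(self.pairs)

    def __iter__(self) -> Iterator[tuple[str, str, str]]:
        return iter(self.pairs)

    def write_fastq(self, path1: str | Path, path2: str | Path) -> None:
        """Write the /1 and /2 mates as FASTQ with constant quality."""
        with open(path1, "w") as f1, open(path2, "w") as f2:
            for name, r1, r2 in self.pairs:
                f1.write(f"@{name}/1\n{r1}\n+\n{'I' * len(r1)}\n")
                f2.write(f"@{name}/2\n{r2}\n+\n{'I' * len(r2)}\n")


def read_fastq_pairs(path1: str | Path, path2: str | Path) -> ReadPairSet:
    pairs = []
    with open(path1) as f1, open(path2) as f2:
        while True:
            h1 = f1.readline()
            if not h1:
                break
            s1 = f1.readline().strip().upper()
            f1.readline(); f1.readline()
            h2 = f2.readline()
            s2 = f2.readline().strip().upper()
            f2.readline(); f2.readline()
            name = h1.strip().lstrip("@").rsplit("/", 1)[0]
            pairs.append((name, s1, s2))
    return ReadPairSet(pairs)


def _encode(seq: str) -> np.ndarray:
    return _ENC[np.frombuffer(seq.encode(), dtype=np.uint8)]


def _kmer_codes(enc: np.ndarray, k: int) -> np.ndarray:
    n = len(enc) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    codes = np.zeros(n, dtype=np.int64)
    invalid = np.zeros(n, dtype=bool)
    for j in range(k):
        window = enc[j : j + n].astype(np.int64)
        codes = (codes << 2) | (window & 3)
        invalid |= window == 4
    codes[invalid] = -1
    return codes


class _SeedIndex:
    """Sorted seed-k-mer index over the forward strand of an assembly."""

    def __init__(self, asm: Assembly, k: int):
        self.k = k
        self.asm = asm
        self.stride = max(len(r) for r in asm.records) + 1
        all_codes = []
        all_pos = []
        for i, rec in enumerate(asm.records):
            codes = _kmer_codes(_encode(rec.seq), k)
            valid = codes >= 0
            all_codes.append(codes[valid])
            all_pos.append(np.flatnonzero(valid).astype(np.int64) + i * self.stride)
        codes = np.concatenate(all_codes) if all_codes else np.empty(0, dtype=np.int64)
        pos = np.concatenate(all_pos) if all_pos else np.empty(0, dtype=np.int64)
        order = np.argsort(codes, kind="stable")
        self.codes = codes[order]
        self.pos = pos[order]

    def candidates(self, code: int) -> np.ndarray:
        lo = np.searchsorted(self.codes, code, side="left")
        hi = np.searchsorted(self.codes, code, side="right")
        return self.pos[lo:hi]

    def occurrences(self, read: str) -> list[tuple[int, int]]:
        """All exact forward-strand occurrences as (record_index, offset)."""
        if len(read) < self.k or "N" in read[: self.k]:
            return []
        code = 0
        enc = _encode(read[: self.k])
        if (enc == 4).any():
            return []
        for b in enc:
            code = (code << 2) | int(b)
        out = []
        for tagged in self.candidates(code):
            ridx, off = divmod(int(tagged), self.stride)
            rec = self.asm.records[ridx]
            if off + len(read) <= len(rec.seq) and rec.seq[off : off + len(read)] == read:
                out.append((ridx, off))
        return out


def place_reads_unique(reads: list[str], asm: Assembly, seed_k: int | None = None) -> list[ReadHit | None]:
    """Place each read at its unique exact occurrence, or None.

    A read counts as placed only when its total number of exact occurrences,
    summed over both strands and all scaffolds, is exactly one.
    """
    if not reads:
        return []
    k = seed_k if seed_k is not None else min(_SEED_K, min(len(r) for r in reads))
    index = _SeedIndex(asm, k)
    hits: list[ReadHit | None] = []
    for read in reads:
        fwd = index.occurrences(read)
        rev = index.occurrences(revcomp(read))
        if len(fwd) + len(rev) != 1:
            hits.append(None)
            continue
        if fwd:
            ridx, off = fwd[0]
            hits.append(ReadHit(asm.records[ridx].id, off, off + len(read), False))
        else:
            ridx, off = rev[0]
            hits.append(ReadHit(asm.records[ridx].id, off, off + len(read), True))
    return hits
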