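"""Whole-genome alignment intake, the built-in anchor aligner, and 1-to-1 filtering.

Two alignment sources are supported: a MUMmer ``show-coords -H -T -l -c -r``
tab file produced externally (the route for real data), and a built-in
exact-k-mer anchor aligner that is adequate for small genomes and for the
synthetic fixtures, so no external binary is ever required.

Either way the blocks are reduced to a one-to-one mapping by an exact
max-weight selection (weight = length x identity) subject to no overlap on
either assembly axis, which removes repeat-induced ambiguity before
merging.
"""

from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np

from .core import Assembly, GenomicInterval, revcomp

Orientation = Literal["forward", "reverse"]


class CoordsParseError(ValueError):
    """Raised on malformed or inconsistent coords input."""


@dataclass(frozen=True)
class AlignmentBlock:
    """One gapless-ish alignment between a primary and a secondary interval.

    The secondary interval is always stored in forward coordinates; reverse-
    strand alignments carry orientation="reverse".  The selection weight is
    length x identity, so long, clean alignments dominate filtering.
    """

    primary: GenomicInterval
    secondary: GenomicInterval
    orientation: Orientation
    identity: float

    def __post_init__(self) -> None:
        if not 0 < self.identity <= 1:
            raise ValueError(f"identity must be in (0, 1], got {self.identity}")

    @property
    def length(self) -> int:
        return len(self.primary)

    @property
    def weight(self) -> float:
        return self.length * self.identity


@dataclass
class AlignmentSet:
    blocks: list[AlignmentBlock] = field(default_factory=list)
    is_one_to_one: bool = False

    def __iter__(self):
        return iter(self.blocks)

    def __len__(self) -> int:
        return len(self.blocks)

    def total_weight(self) -> float:
        return sum(b.weight for b in self.blocks)

    def blocks_for_primary(self, seq_id: str) -> list[AlignmentBlock]:
        out = [b for b in self.blocks if b.primary.seq_id == seq_id]
        out.sort(key=lambda b: (b.primary.start, b.primary.end))
        return out

    def primary_ids(self) -> set[str]:
        return {b.primary.seq_id for b in self.blocks}

    def secondary_ids(self) -> set[str]:
        return {b.secondary.seq_id for b in self.blocks}


def parse_coords(path: str | Path, primary: Assembly, secondary: Assembly) -> AlignmentSet:
    """Parse a headerless show-coords tab file (``show-coords -H -T -l -c -r``).

    Expected columns: S1 E1 S2 E2 LEN1 LEN2 %IDY LENR LENQ COVR COVQ TAGR
    TAGQ.  Coordinates are 1-based inclusive; E2 < S2 marks a reverse-strand
    alignment, which is normalised to a forward secondary interval with
    orientation="reverse".
    """
    blocks: list[AlignmentBlock] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 13:
                raise CoordsParseError(
                    f"{path}:{lineno}: expected 13 tab-separated columns, got {len(fields)}"
                )
            try:
                s1, e1, s2, e2 = (int(fields[i]) for i in range(4))
                idy = float(fields[6]) / 100.0
            except ValueError as exc:
                raise CoordsParseError(f"{path}:{lineno}: {exc}") from exc
            tag_r, tag_q = fields[-2], fields[-1]
            if tag_r not in primary:
                raise CoordsParseError(f"{path}:{lineno}: unknown primary sequence id {tag_r!r}")
            if tag_q not in secondary:
                raise CoordsParseError(f"{path}:{lineno}: unknown secondary sequence id {tag_q!r}")
            if e2 >= s2:
                sec = GenomicInterval(tag_q, s2 - 1, e2)
                orient: Orientation = "forward"
            else:
                sec = GenomicInterval(tag_q, e2 - 1, s2)
                orient = "reverse"
            pri = GenomicInterval(tag_r, s1 - 1, e1)
            if pri.end > len(primary[tag_r]) or sec.end > len(secondary[tag_q]):
                raise CoordsParseError(
                    f"{path}:{lineno}: interval exceeds sequence length"
                )
            blocks.append(AlignmentBlock(pri, sec, orient, min(idy, 1.0)))
    return AlignmentSet(blocks)


# ---------------------------------------------------------------------------
# built-in anchor aligner

_ENC = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _ENC[_b] = _i


def _encode(seq: str) -> np.ndarray:
    return _ENC[np.frombuffer(seq.encode(), dtype=np.uint8)]


def _kmer_codes(seq: str, k: int) -> np.ndarray:
    """Integer codes of all k-mers; -1 where the window contains an N."""
    enc = _encode(seq)
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


def _unique_kmer_table(parts: list[tuple[int, str]], k: int) -> tuple[np.ndarray, np.ndarray]:
    """Sorted (codes, tagged positions) for k-mers occurring exactly once.

    `parts` pairs an integer position tag base with a sequence; the returned
    position for a k-mer at offset j in a part is tag_base + j.
    """
    all_codes = []
    all_pos = []
    for base, seq in parts:
        codes = _kmer_codes(seq, k)
        valid = codes >= 0
        all_codes.append(codes[valid])
        all_pos.append(np.flatnonzero(valid).astype(np.int64) + base)
    if not all_codes:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    codes = np.concatenate(all_codes)
    pos = np.concatenate(all_pos)
    order = np.argsort(codes, kind="stable")
    codes, pos = codes[order], pos[order]
    uniq_mask = np.ones(len(codes), dtype=bool)
    dup = codes[1:] == codes[:-1]
    uniq_mask[1:] &= ~dup
    uniq_mask[:-1] &= ~dup
    return codes[uniq_mask], pos[uniq_mask]


def anchor_align(
    primary: Assembly,
    secondary: Assembly,
    k: int = 21,
    chain_gap: int = 200,
) -> AlignmentSet:
    """Align two assemblies from k-mers unique in both (both secondary strands).

    Anchors sharing a record pair, strand and exact diagonal are chained into
    maximal runs (breaking where consecutive anchors are more than chain_gap
    apart); each run becomes one block with identity = anchored bases / span.
    Blocks spanning less than 2k bases are discarded.  Intended for fixtures
    and small genomes; real data should come in through parse_coords.
    """
    if k < 11:
        raise ValueError("anchor k-mer length must be >= 11")

    # tagged coordinate spaces: record index * stride + offset
    p_stride = max(len(r) for r in primary.records) + 1
    p_parts = [(i * p_stride, rec.seq) for i, rec in enumerate(primary.records)]
    p_codes, p_pos = _unique_kmer_table(p_parts, k)

    # secondary: both strands share one uniqueness census
    s_stride = max(len(r) for r in secondary.records) + 1
    s_parts: list[tuple[int, str]] = []
    n_s = len(secondary.records)
    for i, rec in enumerate(secondary.records):
        s_parts.append((i * s_stride, rec.seq))
        # reverse strand tagged after all forward parts
        s_parts.append(((n_s + i) * s_stride, revcomp(rec.seq)))
    s_codes, s_pos = _unique_kmer_table(s_parts, k)

    common, ip, isec = np.intersect1d(p_codes, s_codes, assume_unique=True, return_indices=True)
    if len(common) == 0:
        return AlignmentSet([])

    ppos = p_pos[ip]
    spos_tag = s_pos[isec]
    p_rec = ppos // p_stride
    p_off = ppos % p_stride
    s_tag_rec = spos_tag // s_stride
    s_off_raw = spos_tag % s_stride
    is_rev = s_tag_rec >= n_s
    s_rec = np.where(is_rev, s_tag_rec - n_s, s_tag_rec)
    s_len = np.array([len(r) for r in secondary.records], dtype=np.int64)
    # forward-strand start coordinate of the anchor on the secondary
    s_off = np.where(is_rev, s_len[s_rec] - s_off_raw - k, s_off_raw)
    diag = np.where(is_rev, p_off + s_off, p_off - s_off)

    order = np.lexsort((p_off, diag, is_rev.astype(np.int64), s_rec, p_rec))
    p_rec, p_off, s_rec, s_off, is_rev, diag = (
        a[order] for a in (p_rec, p_off, s_rec, s_off, is_rev, diag)
    )

    same = (
        (p_rec[1:] == p_rec[:-1])
        & (s_rec[1:] == s_rec[:-1])
        & (is_rev[1:] == is_rev[:-1])
        & (diag[1:] == diag[:-1])
        & (p_off[1:] - p_off[:-1] <= chain_gap)
    )
    breaks = np.flatnonzero(~same) + 1
    starts = np.concatenate(([0], breaks))
    ends = np.concatenate((breaks, [len(p_off)]))

    blocks: list[AlignmentBlock] = []
    for a, b in zip(starts, ends):
        p_first, p_last = int(p_off[a]), int(p_off[b - 1])
        span = p_last + k - p_first
        if span < 2 * k:
            continue
        offs = p_off[a:b]
        matched = int(np.minimum(np.diff(offs), k).sum()) + k
        pri = GenomicInterval(primary.records[int(p_rec[a])].id, p_first, p_first + span)
        d = int(diag[a])
        sid = secondary.records[int(s_rec[a])].id
        if is_rev[a]:
            sec = GenomicInterval(sid, d - p_last, d - p_first + k)
            orient: Orientation = "reverse"
        else:
            sec = GenomicInterval(sid, p_first - d, p_last + k - d)
            orient = "forward"
        blocks.append(AlignmentBlock(pri, sec, orient, matched / span))
    return AlignmentSet(_trim_small_overlaps(blocks, k))


def _trim_block(blk: AlignmentBlock, side: str, amount: int) -> AlignmentBlock | None:
    """Shrink a block by `amount` bases on one primary side, both axes in step."""
    p = blk.primary
    s = blk.secondary
    if amount >= len(p) or amount >= len(s):
        return None
    if side == "start":
        p2 = GenomicInterval(p.seq_id, p.start + amount, p.end)
        if blk.orientation == "forward":
            s2 = GenomicInterval(s.seq_id, s.start + amount, s.end)
        else:
            s2 = GenomicInterval(s.seq_id, s.start, s.end - amount)
    else:
        p2 = GenomicInterval(p.seq_id, p.start, p.end - amount)
        if blk.orientation == "forward":
            s2 = GenomicInterval(s.seq_id, s.start, s.end - amount)
        else:
            s2 = GenomicInterval(s.seq_id, s.start + amount, s.end)
    return AlignmentBlock(p2, s2, blk.orientation, blk.identity)


def _trim_small_overlaps(blocks: list[AlignmentBlock], k: int) -> list[AlignmentBlock]:
    """Trim overlaps shorter than k between blocks on either axis.

    Anchor chains can extend a few bases past a true edit boundary when the
    divergent sequence happens to match, producing tiny overlaps between
    otherwise compatible blocks; trimming the lighter block resolves them.
    Overlaps of k or more signal genuine repeat structure and are left for
    the one-to-one filter to adjudicate.  Blocks trimmed below 2k are
    dropped.
    """
    blocks = list(blocks)
    for _ in range(4):  # axes interact; a couple of passes reach a fixed point
        changed = False
        for axis in ("primary", "secondary"):
            get = (lambda b: b.primary) if axis == "primary" else (lambda b: b.secondary)
            blocks.sort(key=lambda b: (get(b).seq_id, get(b).start, get(b).end))
            out: list[AlignmentBlock | None] = list(blocks)
            for i in range(len(out) - 1):
                a, b = out[i], out[i + 1]
                if a is None or b is None:
                    continue
                ia, ib = get(a), get(b)
                if ia.seq_id != ib.seq_id or ib.start >= ia.end:
                    continue
                overlap = min(ia.end, ib.end) - ib.start
                if overlap >= k:
                    continue
                changed = True
                if a.weight <= b.weight:
                    # trim a on the side facing b along this axis
                    side = "end" if axis == "primary" or a.orientation == "forward" else "start"
                    out[i] = _trim_block(a, side, overlap)
                else:
                    side = "start" if axis == "primary" or b.orientation == "forward" else "end"
                    out[i + 1] = _trim_block(b, side, overlap)
            blocks = [b for b in out if b is not None and b.length >= 2 * k and len(b.secondary) >= 2 * k]
        if not changed:
            break
    return blocks


# ---------------------------------------------------------------------------
# one-to-one filtering

def _select_axis(blocks: list[AlignmentBlock], axis: str) -> list[AlignmentBlock]:
    """Exact max-weight subset of blocks with no overlap on the given axis.

    Solved per sequence by weighted interval scheduling (sort by interval
    end, binary-search latest compatible predecessor, dynamic program).
    Exact weight ties during traceback keep the block under consideration,
    which under the deterministic sort prefers later-ending blocks.
    """
    groups: dict[str, list[AlignmentBlock]] = {}
    for blk in blocks:
        iv = blk.primary if axis == "primary" else blk.secondary
        groups.setdefault(iv.seq_id, []).append(blk)

    kept: list[AlignmentBlock] = []
    for seq_id in sorted(groups):
        grp = groups[seq_id]
        ivs = [(b.primary if axis == "primary" else b.secondary) for b in grp]
        order = sorted(
            range(len(grp)),
            key=lambda i: (ivs[i].end, ivs[i].start, -grp[i].weight, grp[i].primary.seq_id, grp[i].primary.start),
        )
        grp = [grp[i] for i in order]
        ivs = [ivs[i] for i in order]
        ends = [iv.end for iv in ivs]
        n = len(grp)
        # pred[i]: rightmost j < i with ends[j] <= ivs[i].start, else -1
        pred = [bisect_right(ends, ivs[i].start) - 1 for i in range(n)]
        dp = [0.0] * (n + 1)
        for i in range(n):
            incl = grp[i].weight + dp[pred[i] + 1]
            dp[i + 1] = max(incl, dp[i])
        # traceback
        i = n - 1
        chosen: list[AlignmentBlock] = []
        while i >= 0:
            incl = grp[i].weight + dp[pred[i] + 1]
            excl = dp[i]
            if incl >= excl - 1e-12:
                chosen.append(grp[i])
                i = pred[i]
            else:
                i -= 1
        kept.extend(chosen)
    return kept


_EXACT_COMPONENT_LIMIT = 40


def _conflict(a: AlignmentBlock, b: AlignmentBlock) -> bool:
    return a.primary.overlaps(b.primary) or a.secondary.overlaps(b.secondary)


def _mwis_exact(blocks: list[AlignmentBlock], adj: list[int]) -> tuple[float, int]:
    """Exact max-weight independent set by branch and bound over a bitmask.

    adj[i] is the conflict-neighbour bitmask of block i.  Deterministic:
    blocks are branched in their given order, include-branch first.
    """
    n = len(blocks)
    weights = [b.weight for b in blocks]
    suffix = [0.0] * (n + 1)
    for i in range(n - 1, -1, -1):
        suffix[i] = suffix[i + 1] + weights[i]
    best_w = -1.0
    best_mask = 0

    def rec(i: int, alive: int, w: float, mask: int) -> None:
        nonlocal best_w, best_mask
        while i < n and not alive >> i & 1:
            i += 1
        if i == n:
            if w > best_w + 1e-12:
                best_w, best_mask = w, mask
            return
        if w + suffix[i] <= best_w + 1e-12:
            return  # even taking everything left cannot beat the incumbent
        rec(i + 1, alive & ~adj[i] & ~(1 << i), w + weights[i], mask | 1 << i)
        rec(i + 1, alive & ~(1 << i), w, mask)

    rec(0, (1 << n) - 1, 0.0, 0)
    return best_w, best_mask


def filter_one_to_one(aln: AlignmentSet) -> AlignmentSet:
    """Reduce an alignment set to a one-to-one mapping.

    The kept subset maximises total weight (length x identity) subject to no
    two blocks overlapping on the primary axis or on the secondary axis.
    Conflicts decompose into connected components, each solved exactly by
    branch and bound; a component larger than 40 blocks (a dense repeat
    tangle, far beyond what built-in alignment of draft assemblies
    produces) falls back to two exact per-axis passes (primary first),
    mirroring delta-filter's sequential behaviour.
    """
    blocks = sorted(
        aln.blocks,
        key=lambda b: (-b.weight, -b.length, b.primary.seq_id, b.primary.start),
    )
    n = len(blocks)
    # connected components of the conflict graph
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    pairs: list[tuple[int, int]] = []
    for i in range(n):
        for j in range(i + 1, n):
            if _conflict(blocks[i], blocks[j]):
                pairs.append((i, j))
                parent[find(i)] = find(j)
    comps: dict[int, list[int]] = {}
    for i in range(n):
        comps.setdefault(find(i), []).append(i)

    kept: list[AlignmentBlock] = []
    for comp in comps.values():
        if len(comp) == 1:
            kept.append(blocks[comp[0]])
            continue
        sub = [blocks[i] for i in comp]
        index = {g: l for l, g in enumerate(comp)}
        adj = [0] * len(comp)
        for i, j in pairs:
            if i in index and j in index:
                adj[index[i]] |= 1 << index[j]
                adj[index[j]] |= 1 << index[i]
        if len(comp) <= _EXACT_COMPONENT_LIMIT:
            _, mask = _mwis_exact(sub, adj)
            kept.extend(b for l, b in enumerate(sub) if mask >> l & 1)
        else:
            part = _select_axis(sub, "primary")
            kept.extend(_select_axis(part, "secondary"))
    kept.sort(key=lambda b: (b.primary.seq_id, b.primary.start, b.primary.end))
    return AlignmentSet(kept, is_one_to_one=True)


def discard_unaligned(
    primary: Assembly,
    secondary: Assembly,
    aln: AlignmentSet,
    keep_min_len: int | None = None,
) -> tuple[Assembly, Assembly]:
    """Drop sequences with no surviving alignment from both assemblies.

    Sequences of length >= keep_min_len are retained regardless when that
    option is set.
    """
    p_ids = aln.primary_ids()
    s_ids = aln.secondary_ids()

    def keep(rec, aligned_ids):
        if rec.id in aligned_ids:
            return True
        return keep_min_len is not None and len(rec) >= keep_min_len

    p_keep = [r.id for r in primary.records if keep(r, p_ids)]
    s_keep = [r.id for r in secondary.records if keep(r, s_ids)]
    return primary.subset(p_keep), secondary.subset(s_keep)


def overlap_count(aln: AlignmentSet, axis: str) -> int:
    """Number of overlapping block pairs on one axis (0 after filtering)."""
    ivs = sorted(
        ((b.primary if axis == "primary" else b.secondary) for b in aln.blocks),
        key=lambda iv: (iv.seq_id, iv.start),
    )
    count = 0
    for a, b in zip(ivs, ivs[1:]):
        if a.seq_id == b.seq_id and b.start < a.end:
            count += 1
    return count
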