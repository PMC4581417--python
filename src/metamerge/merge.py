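"""Pairwise merging: walk the 1-to-1 alignment, decide each discrepancy, emit the metassembly.

Every aligned segment of the primary is kept verbatim.  Where the two
assemblies disagree, the CE statistic at the breakpoint decides which
sequence enters the metassembly:

* insertion/deletion discrepancies are replaced by the secondary sequence
  only when all four conditions hold —
  (1) |CE_p| > z (the primary breakpoint looks mis-assembled),
  (2) |CE_p| - |CE_s| > d (the secondary looks better by a margin),
  (3) if inserts span the primary breakpoint, the inferred post-edit
      statistic satisfies |CE*| < z (the edit would actually fix it),
  (4) |CE_s| < z (the secondary breakpoint looks clean);
* a primary scaffold gap spanned by gap-free secondary sequence is closed
  when conditions (3) and (4) hold — no evidence against the primary is
  required because an N-run is known to be unresolved;
* secondary overhangs past a primary scaffold end are handled like gap
  closures, extending the scaffold when (3) and (4) hold;
* two primary scaffolds aligning contiguously to one secondary scaffold with
  enough spanning-insert coverage over the junction are linked, into a
  contig when the secondary junction is gap-free and into a scaffold (N-run
  preserved) otherwise.

Breakpoint CE values are evaluated at the midpoint between the bracketing
alignment blocks' inner edges on each assembly.  Discrepancies bracketed by
blocks of inconsistent orientation or on different secondary scaffolds are
never substituted: an orientation conflict signals an inversion, which this
algorithm does not adjudicate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Optional

from .ce import CEEvidence
from .core import (
    Assembly,
    GenomicInterval,
    MergeParams,
    SequenceRecord,
    find_scaffold_gaps,
    revcomp,
)
from .wga import AlignmentBlock, AlignmentSet

EventKind = Literal[
    "keep_aligned", "keep_primary", "replace_indel", "close_gap",
    "extend_overhang", "scaffold_link",
]


@dataclass
class Discrepancy:
    """An unaligned stretch bracketed by (or terminal to) chained blocks."""

    kind: Literal["interblock", "primary_gap", "overhang_start", "overhang_end"]
    primary_seq: str
    primary_start: int
    primary_end: int            # == start for a pure insertion point
    secondary_seq: Optional[str]
    secondary_start: int
    secondary_end: int
    orientation: Literal["forward", "reverse"]
    p_ce_pos: int = 0           # breakpoint position for CE on the primary
    s_ce_pos: int = 0           # breakpoint position for CE on the secondary

    @property
    def primary_len(self) -> int:
        return self.primary_end - self.primary_start

    @property
    def secondary_len(self) -> int:
        return self.secondary_end - self.secondary_start


@dataclass
class AlignedSegment:
    block: AlignmentBlock


@dataclass
class UnalignedSegment:
    """Primary sequence kept verbatim because no consistent chain brackets it."""

    seq_id: str
    start: int
    end: int
    why: str = "no_alignment"


Condition = tuple[Optional[bool], Optional[float]]  # (passed, value) ; (None, None) = not evaluated


@dataclass
class MergeEvent:
    kind: EventKind
    primary_seq: str
    primary_start: int
    primary_end: int
    secondary_seq: Optional[str] = None
    secondary_start: int = 0
    secondary_end: int = 0
    orientation: str = "forward"
    ce_primary: Optional[float] = None
    ce_secondary: Optional[float] = None
    ce_inferred: Optional[float] = None
    conditions: dict[str, Condition] = field(default_factory=dict)
    note: str = ""
    out_seq_id: Optional[str] = None
    out_start: Optional[int] = None
    out_end: Optional[int] = None

    @property
    def reason(self) -> str:
        parts = []
        for name in ("c1", "c2", "c3", "c4"):
            if name not in self.conditions:
                continue
            ok, val = self.conditions[name]
            if ok is None:
                parts.append(f"{name}:na")
            else:
                sval = "nan" if val is None else f"{val:+.2f}"
                parts.append(f"{name}:{'pass' if ok else 'fail'}({sval})")
        if self.note:
            parts.append(self.note)
        return ";".join(parts)

    @property
    def modifies(self) -> bool:
        return self.kind in ("replace_indel", "close_gap", "extend_overhang")


@dataclass
class ProvenanceItem:
    kind: Literal["sequence", "gap"]
    label: Optional[str] = None        # source assembly label
    seq_id: Optional[str] = None
    start: int = 0
    end: int = 0
    orientation: str = "forward"
    length: int = 0                    # for kind == "gap"

    def materialise(self, sources: dict[str, Assembly]) -> str:
        if self.kind == "gap":
            return "N" * self.length
        seq = sources[self.label][self.seq_id].seq[self.start : self.end]
        return revcomp(seq) if self.orientation == "reverse" else seq


@dataclass
class MergedSequence:
    record: SequenceRecord
    provenance: list[ProvenanceItem]

    def reconstruct(self, sources: dict[str, Assembly]) -> str:
        return "".join(item.materialise(sources) for item in self.provenance)


@dataclass
class MergeResult:
    assembly: Assembly
    events: list[MergeEvent]
    sequences: list[MergedSequence]

    def __iter__(self):
        # (assembly, events) unpacking convenience
        return iter((self.assembly, self.events))


class MergeInputError(ValueError):
    pass


# ---------------------------------------------------------------------------
# block walking

def _chainable(prev: AlignmentBlock, nxt: AlignmentBlock) -> bool:
    if prev.secondary.seq_id != nxt.secondary.seq_id:
        return False
    if prev.orientation != nxt.orientation:
        return False
    if prev.orientation == "forward":
        return nxt.secondary.start >= prev.secondary.end
    return nxt.secondary.end <= prev.secondary.start


def _midpoint(start: int, end: int, limit: int) -> int:
    pos = (start + end) // 2
    return max(0, min(pos, limit - 1))


def walk_blocks(
    primary_rec: SequenceRecord,
    aln: AlignmentSet,
    secondary: Assembly,
) -> list[AlignedSegment | UnalignedSegment | Discrepancy]:
    """Classify one primary scaffold into aligned segments and discrepancies.

    Consecutive blocks on the same secondary scaffold with the same
    orientation and monotone secondary coordinates bracket an interblock
    discrepancy; a broken chain leaves the intervening primary sequence as a
    plain keep-verbatim segment.  Unaligned primary termini become overhang
    discrepancies carrying however much unclaimed secondary sequence extends
    beyond the terminal block (clipped at the nearest alignment block of any
    other primary sequence, so nothing is ever taken twice).
    """
    if not aln.is_one_to_one:
        raise MergeInputError("walk_blocks requires a one-to-one alignment set")
    blocks = aln.blocks_for_primary(primary_rec.id)
    L = len(primary_rec.seq)
    if not blocks:
        return [UnalignedSegment(primary_rec.id, 0, L)]

    # per secondary scaffold: sorted starts of all blocks (to clip overhangs)
    sec_blocks: dict[str, list[AlignmentBlock]] = {}
    for b in aln.blocks:
        sec_blocks.setdefault(b.secondary.seq_id, []).append(b)
    for lst in sec_blocks.values():
        lst.sort(key=lambda b: b.secondary.start)

    def secondary_free_before(block: AlignmentBlock) -> int:
        """Start of the free secondary region ending at block.secondary.start.

        When another block lies before this one on the secondary, the region
        between them is an interior junction: it belongs to the scaffold-link
        step, so no overhang may consume it (returns an empty region).
        """
        for other in sec_blocks[block.secondary.seq_id]:
            if other is not block and other.secondary.start < block.secondary.start:
                return block.secondary.start  # interior: reserved for linking
        return 0

    def secondary_free_after(block: AlignmentBlock) -> int:
        s_len = len(secondary[block.secondary.seq_id])
        for other in sec_blocks[block.secondary.seq_id]:
            if other is not block and other.secondary.start >= block.secondary.end:
                return block.secondary.end  # interior: reserved for linking
        return s_len

    segments: list[AlignedSegment | UnalignedSegment | Discrepancy] = []

    # leading terminus
    first = blocks[0]
    p0 = first.primary.start
    if first.orientation == "forward":
        s_lo, s_hi = secondary_free_before(first), first.secondary.start
    else:
        s_lo, s_hi = first.secondary.end, secondary_free_after(first)
    if p0 > 0 or s_hi > s_lo:
        s_len = len(secondary[first.secondary.seq_id])
        segments.append(Discrepancy(
            kind="overhang_start",
            primary_seq=primary_rec.id, primary_start=0, primary_end=p0,
            secondary_seq=first.secondary.seq_id,
            secondary_start=s_lo, secondary_end=s_hi,
            orientation=first.orientation,
            p_ce_pos=_midpoint(0, p0, L),
            s_ce_pos=_midpoint(s_lo, s_hi, s_len) if s_hi > s_lo else _midpoint(s_lo, s_lo, s_len),
        ))

    for prev, nxt in zip(blocks, blocks[1:]):
        segments.append(AlignedSegment(prev))
        g_start, g_end = prev.primary.end, nxt.primary.start
        if _chainable(prev, nxt):
            if prev.orientation == "forward":
                s_lo, s_hi = prev.secondary.end, nxt.secondary.start
            else:
                s_lo, s_hi = nxt.secondary.end, prev.secondary.start
            if g_end == g_start and s_hi == s_lo:
                continue  # blocks abut on both axes: nothing to decide
            s_len = len(secondary[prev.secondary.seq_id])
            segments.append(Discrepancy(
                kind="interblock",
                primary_seq=primary_rec.id, primary_start=g_start, primary_end=g_end,
                secondary_seq=prev.secondary.seq_id,
                secondary_start=s_lo, secondary_end=s_hi,
                orientation=prev.orientation,
                p_ce_pos=_midpoint(g_start, g_end, L),
                s_ce_pos=_midpoint(s_lo, s_hi, s_len),
            ))
        elif g_end > g_start:
            segments.append(UnalignedSegment(primary_rec.id, g_start, g_end, why="chain_break"))

    last = blocks[-1]
    segments.append(AlignedSegment(last))
    pe = last.primary.end
    if last.orientation == "forward":
        s_lo, s_hi = last.secondary.end, secondary_free_after(last)
    else:
        s_lo, s_hi = secondary_free_before(last), last.secondary.start
    if pe < L or s_hi > s_lo:
        s_len = len(secondary[last.secondary.seq_id])
        segments.append(Discrepancy(
            kind="overhang_end",
            primary_seq=primary_rec.id, primary_start=pe, primary_end=L,
            secondary_seq=last.secondary.seq_id,
            secondary_start=s_lo, secondary_end=s_hi,
            orientation=last.orientation,
            p_ce_pos=_midpoint(pe, L, L),
            s_ce_pos=_midpoint(s_lo, s_hi, s_len),
        ))
    return segments


# ---------------------------------------------------------------------------
# decision rules

def _abs_or_none(x: Optional[float]) -> Optional[float]:
    return None if x is None else abs(x)


def resolve_indel(
    disc: Discrepancy,
    ce_p: CEEvidence,
    ce_s: CEEvidence,
    params: MergeParams,
) -> MergeEvent:
    """Decide one insertion/deletion discrepancy by conditions (1)-(4)."""
    cep = ce_p.ce(disc.primary_seq, disc.p_ce_pos)
    ces = ce_s.ce(disc.secondary_seq, disc.s_ce_pos) if disc.secondary_seq else None
    conds: dict[str, Condition] = {}

    c1 = cep is not None and abs(cep) > params.z
    conds["c1"] = (bool(c1), cep)

    if cep is not None and ces is not None:
        c2 = abs(cep) - abs(ces) > params.d
        conds["c2"] = (bool(c2), abs(cep) - abs(ces))
    else:
        c2 = False
        conds["c2"] = (None, None)

    n_p = ce_p.n(disc.primary_seq, disc.p_ce_pos)
    if n_p > 0:
        ce_star = ce_p.ce_after_edit(disc.primary_seq, disc.p_ce_pos,
                                     disc.primary_len, disc.secondary_len)
        c3 = ce_star is not None and abs(ce_star) < params.z
        conds["c3"] = (bool(c3), ce_star)
    else:
        ce_star = None
        c3 = True  # vacuous: no insert evidence against the edit
        conds["c3"] = (True, None)

    c4 = ces is not None and abs(ces) < params.z
    conds["c4"] = (bool(c4), ces)

    kind: EventKind = "replace_indel" if (c1 and c2 and c3 and c4) else "keep_primary"
    return MergeEvent(
        kind=kind,
        primary_seq=disc.primary_seq, primary_start=disc.primary_start,
        primary_end=disc.primary_end,
        secondary_seq=disc.secondary_seq, secondary_start=disc.secondary_start,
        secondary_end=disc.secondary_end, orientation=disc.orientation,
        ce_primary=cep, ce_secondary=ces, ce_inferred=ce_star, conditions=conds,
        note="indel",
    )


def _gap_style_decision(
    disc: Discrepancy,
    ce_p: CEEvidence,
    ce_s: CEEvidence,
    params: MergeParams,
    accept_kind: EventKind,
    note: str,
) -> MergeEvent:
    """Shared conditions (3) and (4) check for gap closure and overhangs."""
    cep = ce_p.ce(disc.primary_seq, disc.p_ce_pos)
    ces = ce_s.ce(disc.secondary_seq, disc.s_ce_pos) if disc.secondary_seq else None
    conds: dict[str, Condition] = {}

    n_p = ce_p.n(disc.primary_seq, disc.p_ce_pos)
    if n_p > 0:
        ce_star = ce_p.ce_after_edit(disc.primary_seq, disc.p_ce_pos,
                                     disc.primary_len, disc.secondary_len)
        c3 = ce_star is not None and abs(ce_star) < params.z
        conds["c3"] = (bool(c3), ce_star)
    else:
        ce_star = None
        c3 = True
        conds["c3"] = (True, None)

    c4 = ces is not None and abs(ces) < params.z
    conds["c4"] = (bool(c4), ces)

    kind: EventKind = accept_kind if (c3 and c4) else "keep_primary"
    return MergeEvent(
        kind=kind,
        primary_seq=disc.primary_seq, primary_start=disc.primary_start,
        primary_end=disc.primary_end,
        secondary_seq=disc.secondary_seq, secondary_start=disc.secondary_start,
        secondary_end=disc.secondary_end, orientation=disc.orientation,
        ce_primary=cep, ce_secondary=ces, ce_inferred=ce_star, conditions=conds,
        note=note,
    )


def resolve_gap(
    disc: Discrepancy,
    gaps_p: list[GenomicInterval],
    gaps_s: list[GenomicInterval],
    ce_p: CEEvidence,
    ce_s: CEEvidence,
    params: MergeParams,
) -> MergeEvent:
    """Decide a gap-closure candidate (primary gap spanned by the secondary).

    The candidate must overlap a primary gap segment and the secondary span
    must contain no secondary gap segment; the closure itself needs only
    conditions (3) and (4).
    """
    overlaps_gap = any(
        g.start < disc.primary_end and disc.primary_start < g.end for g in gaps_p
    ) or any(
        disc.primary_start == disc.primary_end and g.start <= disc.primary_start <= g.end
        for g in gaps_p
    )
    if not overlaps_gap:
        raise MergeInputError("resolve_gap called on a discrepancy outside any primary gap")
    if _secondary_has_gap(disc, gaps_s):
        ev = MergeEvent(
            kind="keep_primary",
            primary_seq=disc.primary_seq, primary_start=disc.primary_start,
            primary_end=disc.primary_end,
            secondary_seq=disc.secondary_seq, secondary_start=disc.secondary_start,
            secondary_end=disc.secondary_end, orientation=disc.orientation,
            note="gap_closure;secondary_gap_present",
        )
        return ev
    return _gap_style_decision(disc, ce_p, ce_s, params, "close_gap", "gap_closure")


def _secondary_has_gap(disc: Discrepancy, gaps_s: list[GenomicInterval]) -> bool:
    if disc.secondary_seq is None or disc.secondary_len == 0:
        return False
    return any(
        g.seq_id == disc.secondary_seq
        and g.start < disc.secondary_end and disc.secondary_start < g.end
        for g in gaps_s
    )


def resolve_overhang(
    disc: Discrepancy,
    ce_p: CEEvidence,
    ce_s: CEEvidence,
    params: MergeParams,
) -> MergeEvent:
    """Decide a terminal overhang: a gap-closure-style extension of the scaffold."""
    if disc.kind not in ("overhang_start", "overhang_end"):
        raise MergeInputError("resolve_overhang requires an overhang discrepancy")
    if disc.secondary_len == 0:
        return MergeEvent(
            kind="keep_primary",
            primary_seq=disc.primary_seq, primary_start=disc.primary_start,
            primary_end=disc.primary_end,
            secondary_seq=disc.secondary_seq, secondary_start=disc.secondary_start,
            secondary_end=disc.secondary_end, orientation=disc.orientation,
            note="overhang;no_secondary_extension",
        )
    return _gap_style_decision(disc, ce_p, ce_s, params, "extend_overhang", "overhang")


# ---------------------------------------------------------------------------
# scaffold linking

@dataclass
class LinkCandidate:
    secondary_seq: str
    junction_start: int
    junction_end: int
    a_primary: str               # upstream primary scaffold (secondary order)
    a_orientation: str           # orientation of a's blocks on the secondary
    b_primary: str
    b_orientation: str
    coverage: float
    has_secondary_gap: bool


def _terminal_block_ok(block: AlignmentBlock, side: str, aln: AlignmentSet) -> bool:
    """True when `block` is the outermost alignment of its primary scaffold on `side`."""
    pid = block.primary.seq_id
    for other in aln.blocks:
        if other.primary.seq_id != pid or other is block:
            continue
        if side == "right" and other.primary.start >= block.primary.end:
            return False
        if side == "left" and other.primary.end <= block.primary.start:
            return False
    return True


def link_scaffolds(
    primary: Assembly,
    aln: AlignmentSet,
    ce_s: CEEvidence,
    params: MergeParams,
    secondary: Assembly | None = None,
) -> list[LinkCandidate]:
    """Find pairs of primary scaffolds joinable through one secondary scaffold.

    Adjacent blocks (no third primary in between) from two different primary
    scaffolds, each being the outermost alignment of the relevant end of its
    scaffold, form a candidate; it survives when the mean spanning-insert
    coverage over the secondary junction reaches params.link_coverage.
    """
    if not aln.is_one_to_one:
        raise MergeInputError("link_scaffolds requires a one-to-one alignment set")
    by_sec: dict[str, list[AlignmentBlock]] = {}
    for b in aln.blocks:
        by_sec.setdefault(b.secondary.seq_id, []).append(b)

    gap_cache: dict[str, list[GenomicInterval]] = {}

    def sec_gaps(seq_id: str) -> list[GenomicInterval]:
        if secondary is None:
            return []
        if seq_id not in gap_cache:
            gap_cache[seq_id] = find_scaffold_gaps(
                secondary[seq_id], params.t_secondary_gap, params.p_secondary_gap
            )
        return gap_cache[seq_id]

    candidates: list[LinkCandidate] = []
    for sec_id, blocks in by_sec.items():
        blocks.sort(key=lambda b: b.secondary.start)
        for b1, b2 in zip(blocks, blocks[1:]):
            if b1.primary.seq_id == b2.primary.seq_id:
                continue
            # junction sides: increasing secondary leaves b1's scaffold and
            # enters b2's; forward orientation puts the junction at the
            # right (high-coordinate) end of the scaffold, reverse at the left.
            a_side = "right" if b1.orientation == "forward" else "left"
            b_side = "left" if b2.orientation == "forward" else "right"
            if not _terminal_block_ok(b1, a_side, aln):
                continue
            if not _terminal_block_ok(b2, b_side, aln):
                continue
            j_start, j_end = b1.secondary.end, b2.secondary.start
            if j_end < j_start:
                continue
            cov_lo = max(j_start - 1, 0)
            coverage = ce_s.profile.mean_coverage(sec_id, cov_lo, max(j_end, cov_lo + 1))
            if coverage < params.link_coverage:
                continue
            has_gap = any(
                g.start < j_end and j_start < g.end for g in sec_gaps(sec_id)
            )
            candidates.append(LinkCandidate(
                secondary_seq=sec_id, junction_start=j_start, junction_end=j_end,
                a_primary=b1.primary.seq_id, a_orientation=b1.orientation,
                b_primary=b2.primary.seq_id, b_orientation=b2.orientation,
                coverage=coverage, has_secondary_gap=has_gap,
            ))
    candidates.sort(key=lambda c: (-c.coverage, c.secondary_seq, c.junction_start))
    return candidates


# ---------------------------------------------------------------------------
# pairwise merge orchestration

class _Chain:
    """A growing chain of oriented merged scaffolds joined by link fills."""

    def __init__(self, sid: str):
        self.items: list[tuple[str, bool]] = [(sid, False)]  # (scaffold id, flipped)
        self.fills: list[tuple[str, list[ProvenanceItem]]] = []  # between items

    def flip(self) -> None:
        self.items = [(sid, not f) for sid, f in reversed(self.items)]
        self.fills = [(_revcomp_fill(seq), _flip_provenance(prov))
                      for seq, prov in reversed(self.fills)]


def _revcomp_fill(seq: str) -> str:
    return revcomp(seq)


def _flip_provenance(items: list[ProvenanceItem]) -> list[ProvenanceItem]:
    out = []
    for item in reversed(items):
        if item.kind == "gap":
            out.append(item)
        else:
            out.append(ProvenanceItem(
                kind="sequence", label=item.label, seq_id=item.seq_id,
                start=item.start, end=item.end,
                orientation="reverse" if item.orientation == "forward" else "forward",
            ))
    return out


def pairwise_merge(
    primary: Assembly,
    secondary: Assembly,
    aln: AlignmentSet,
    ce_p: CEEvidence,
    ce_s: CEEvidence,
    params: MergeParams | None = None,
) -> MergeResult:
    """One full pairwise merge round: decisions, substitutions, then links."""
    if params is None:
        params = MergeParams()
    if not aln.is_one_to_one:
        raise MergeInputError("pairwise_merge requires a one-to-one alignment set")
    for b in aln.blocks:
        if b.primary.seq_id not in primary:
            raise MergeInputError(f"alignment references unknown primary sequence {b.primary.seq_id!r}")
        if b.secondary.seq_id not in secondary:
            raise MergeInputError(f"alignment references unknown secondary sequence {b.secondary.seq_id!r}")

    p_label = primary.label or "primary"
    s_label = secondary.label or "secondary"
    if p_label == s_label:
        s_label = s_label + "_2"

    gaps_p = {r.id: find_scaffold_gaps(r, params.t_primary_gap, params.p_primary_gap)
              for r in primary.records}
    gaps_s = {r.id: find_scaffold_gaps(r, params.t_secondary_gap, params.p_secondary_gap)
              for r in secondary.records}

    events: list[MergeEvent] = []
    # per primary scaffold: (sequence string, provenance items)
    built: dict[str, tuple[str, list[ProvenanceItem]]] = {}

    for rec in primary.records:
        parts: list[str] = []
        prov: list[ProvenanceItem] = []
        out_len = 0

        def emit_primary(start: int, end: int) -> tuple[int, int]:
            nonlocal out_len
            if end <= start:
                return (out_len, out_len)
            parts.append(rec.seq[start:end])
            prov.append(ProvenanceItem("sequence", p_label, rec.id, start, end, "forward"))
            span = (out_len, out_len + end - start)
            out_len += end - start
            return span

        def emit_secondary(seq_id: str, start: int, end: int, orientation: str) -> tuple[int, int]:
            nonlocal out_len
            if end <= start:
                return (out_len, out_len)
            s = secondary[seq_id].seq[start:end]
            if orientation == "reverse":
                s = revcomp(s)
            parts.append(s)
            prov.append(ProvenanceItem("sequence", s_label, seq_id, start, end, orientation))
            span = (out_len, out_len + end - start)
            out_len += end - start
            return span

        for seg in walk_blocks(rec, aln, secondary):
            if isinstance(seg, AlignedSegment):
                blk = seg.block
                span = emit_primary(blk.primary.start, blk.primary.end)
                events.append(MergeEvent(
                    kind="keep_aligned",
                    primary_seq=rec.id, primary_start=blk.primary.start,
                    primary_end=blk.primary.end,
                    secondary_seq=blk.secondary.seq_id,
                    secondary_start=blk.secondary.start, secondary_end=blk.secondary.end,
                    orientation=blk.orientation,
                    out_seq_id=rec.id, out_start=span[0], out_end=span[1],
                ))
            elif isinstance(seg, UnalignedSegment):
                span = emit_primary(seg.start, seg.end)
                events.append(MergeEvent(
                    kind="keep_primary", primary_seq=rec.id,
                    primary_start=seg.start, primary_end=seg.end, note=seg.why,
                    out_seq_id=rec.id, out_start=span[0], out_end=span[1],
                ))
            else:
                ev = _decide(seg, gaps_p[rec.id], gaps_s, ce_p, ce_s, params)
                if ev.modifies:
                    span = emit_secondary(seg.secondary_seq, seg.secondary_start,
                                          seg.secondary_end, seg.orientation)
                else:
                    span = emit_primary(seg.primary_start, seg.primary_end)
                ev.out_seq_id, ev.out_start, ev.out_end = rec.id, span[0], span[1]
                events.append(ev)

        built[rec.id] = ("".join(parts), prov)

    # scaffold links, greedy by descending junction coverage
    link_events, chains = _apply_links(built, primary, secondary, aln, ce_s, params, s_label)
    events.extend(link_events)

    records = []
    sequences = []
    # sid -> (final scaffold id, offset of sid's built string, flipped, built length)
    placement: dict[str, tuple[str, int, bool, int]] = {}
    for chain in chains:
        seq_parts: list[str] = []
        prov: list[ProvenanceItem] = []
        ids = [sid for sid, _ in chain.items]
        out_id = "+".join(ids)
        offset = 0
        for idx, (sid, flipped) in enumerate(chain.items):
            if idx > 0:
                fill_seq, fill_prov = chain.fills[idx - 1]
                seq_parts.append(fill_seq)
                prov.extend(fill_prov)
                offset += len(fill_seq)
            s, p = built[sid]
            placement[sid] = (out_id, offset, flipped, len(s))
            if flipped:
                seq_parts.append(revcomp(s))
                prov.extend(_flip_provenance(p))
            else:
                seq_parts.append(s)
                prov.extend(p)
            offset += len(s)
        seq = "".join(seq_parts)
        if not seq:
            continue
        rec = SequenceRecord(out_id, seq)
        records.append(rec)
        sequences.append(MergedSequence(rec, prov))

    # remap event output coordinates into the final (possibly linked) scaffolds
    for ev in events:
        if ev.out_seq_id is None or ev.out_seq_id not in placement:
            continue
        out_id, offset, flipped, blen = placement[ev.out_seq_id]
        if flipped:
            ev.out_start, ev.out_end = (offset + blen - ev.out_end,
                                        offset + blen - ev.out_start)
        else:
            ev.out_start, ev.out_end = offset + ev.out_start, offset + ev.out_end
        ev.out_seq_id = out_id

    out_label = f"{p_label}.{s_label}"
    asm = Assembly(records, label=out_label)
    return MergeResult(asm, events, sequences)


def _decide(disc, gaps_p_rec, gaps_s, ce_p, ce_s, params) -> MergeEvent:
    if disc.kind in ("overhang_start", "overhang_end"):
        return resolve_overhang(disc, ce_p, ce_s, params)
    overlaps_gap = any(
        g.start < disc.primary_end and disc.primary_start < g.end for g in gaps_p_rec
    )
    if overlaps_gap:
        disc.kind = "primary_gap"
        return resolve_gap(disc, gaps_p_rec, gaps_s.get(disc.secondary_seq, []),
                           ce_p, ce_s, params)
    return resolve_indel(disc, ce_p, ce_s, params)


def _apply_links(
    built, primary, secondary, aln, ce_s, params, s_label
) -> tuple[list[MergeEvent], list["_Chain"]]:
    """Greedily apply link candidates; return the link events and final chains."""
    candidates = link_scaffolds(primary, aln, ce_s, params, secondary=secondary)

    order: list[str] = []
    chain_of: dict[str, _Chain] = {}
    for rec in primary.records:
        if rec.id in built:
            chain_of[rec.id] = _Chain(rec.id)
            order.append(rec.id)

    events: list[MergeEvent] = []
    for cand in candidates:
        ca = chain_of.get(cand.a_primary)
        cb = chain_of.get(cand.b_primary)
        if ca is None or cb is None or ca is cb:
            continue
        need_flip_a = cand.a_orientation == "reverse"
        need_flip_b = cand.b_orientation == "reverse"
        # a must sit at the right end of its chain with the required flip
        # state; flipping the whole chain is free, flipping one member is not
        if ca.items[-1][0] == cand.a_primary and ca.items[-1][1] == need_flip_a:
            pass
        elif ca.items[0][0] == cand.a_primary and ca.items[0][1] != need_flip_a:
            ca.flip()
        else:
            continue  # end consumed by an earlier link, or orientation conflict
        # b must sit at the left end of its chain with the required flip state
        if cb.items[0][0] == cand.b_primary and cb.items[0][1] == need_flip_b:
            pass
        elif cb.items[-1][0] == cand.b_primary and cb.items[-1][1] != need_flip_b:
            cb.flip()
        else:
            continue

        # junction fill
        j_span = cand.junction_end - cand.junction_start
        if cand.has_secondary_gap:
            n_len = max(j_span, 10)
            fill_seq = "N" * n_len
            fill_prov = [ProvenanceItem("gap", length=n_len)]
            join_kind = "scaffold"
        else:
            fill_seq = secondary[cand.secondary_seq].seq[cand.junction_start:cand.junction_end]
            fill_prov = ([ProvenanceItem("sequence", s_label, cand.secondary_seq,
                                         cand.junction_start, cand.junction_end, "forward")]
                         if j_span > 0 else [])
            join_kind = "contig"

        ca.items.extend(cb.items)
        ca.fills.append((fill_seq, fill_prov))
        ca.fills.extend(cb.fills)
        for sid, _ in cb.items:
            chain_of[sid] = ca

        events.append(MergeEvent(
            kind="scaffold_link",
            primary_seq=cand.a_primary, primary_start=0, primary_end=0,
            secondary_seq=cand.secondary_seq,
            secondary_start=cand.junction_start, secondary_end=cand.junction_end,
            orientation="forward",
            note=f"link:{cand.a_primary}~{cand.b_primary};{join_kind};cov={cand.coverage:.1f}",
        ))

    uniq: list[_Chain] = []
    seen: set[int] = set()
    for sid in order:
        ch = chain_of[sid]
        if id(ch) not in seen:
            seen.add(id(ch))
            uniq.append(ch)
    return events, uniq


# ---------------------------------------------------------------------------
# event log export

def write_event_log(events: Iterable[MergeEvent], path: str | Path) -> None:
    cols = ["kind", "primary", "secondary", "orientation",
            "ce_primary", "ce_secondary", "ce_inferred", "reason", "out"]
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for ev in events:
            pri = f"{ev.primary_seq}:{ev.primary_start}-{ev.primary_end}"
            sec = (f"{ev.secondary_seq}:{ev.secondary_start}-{ev.secondary_end}"
                   if ev.secondary_seq else ".")
            out = (f"{ev.out_seq_id}:{ev.out_start}-{ev.out_end}"
                   if ev.out_seq_id is not None else ".")
            fmt = lambda x: "." if x is None else f"{x:.3f}"
            fh.write("\t".join([
                ev.kind, pri, sec, ev.orientation,
                fmt(ev.ce_primary), fmt(ev.ce_secondary), fmt(ev.ce_inferred),
                ev.reason or ".", out,
            ]) + "\n")
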