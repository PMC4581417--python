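"""Decision rules, block walking, scaffold linking, and full pairwise merges."""

import numpy as np
import pytest

from metamerge.ce import CEEvidence, LibraryModel, MatePairObservation, build_span_index
from metamerge.core import Assembly, GenomicInterval, MergeParams, SequenceRecord, revcomp
from metamerge.merge import (
    AlignedSegment,
    Discrepancy,
    MergeInputError,
    UnalignedSegment,
    link_scaffolds,
    pairwise_merge,
    resolve_gap,
    resolve_indel,
    resolve_overhang,
    walk_blocks,
)
from metamerge.synthetic import simulate_genome, simulate_matepairs
from metamerge.wga import AlignmentBlock, AlignmentSet, anchor_align, filter_one_to_one

LIB = LibraryModel(2500.0, 100.0)


def evidence(entries, lib=LIB):
    """CEEvidence whose CE at (seq, pos) approximates the requested value.

    entries: list of (seq_id, pos, n, ce_target); each contributes n identical
    spans centred on pos with insert spanning_mu + ce*sigma/sqrt(n).
    """
    obs = []
    for seq, pos, n, ce in entries:
        insert = int(round(lib.spanning_mu + ce * lib.sigma / np.sqrt(n)))
        start = max(0, pos - insert // 2)
        obs.extend(MatePairObservation(seq, start, start + insert) for _ in range(n))
    return CEEvidence(build_span_index(obs), lib)


def disc_interblock(p_len, s_len, p_pos=5000, s_pos=5000):
    return Discrepancy(
        kind="interblock", primary_seq="p", primary_start=p_pos, primary_end=p_pos + p_len,
        secondary_seq="s", secondary_start=s_pos, secondary_end=s_pos + s_len,
        orientation="forward",
        p_ce_pos=p_pos + p_len // 2, s_ce_pos=s_pos + max(s_len // 2, 0),
    )


class TestResolveIndel:
    params = MergeParams()

    def test_expansion_replaced_when_all_conditions_hold(self):
        # primary carries a 600 bp spurious insertion: CE_p ~ +4.2, CE* ~ 0
        n = 16
        ce_star_shift = 600 / (LIB.sigma / np.sqrt(n))  # CE drop caused by the edit
        ce_p = evidence([("p", 5300, n, ce_star_shift - 0.1)])
        ce_s = evidence([("s", 5000, n, 0.3)])
        ev = resolve_indel(disc_interblock(600, 0), ce_p, ce_s, self.params)
        assert ev.kind == "replace_indel"
        assert ev.conditions["c1"][0] and ev.conditions["c2"][0]
        assert ev.conditions["c3"][0] and ev.conditions["c4"][0]
        assert abs(ev.ce_inferred) < 3 < ev.ce_primary

    def test_small_ce_keeps_primary(self):
        ce_p = evidence([("p", 5000, 9, 0.5)])
        ce_s = evidence([("s", 5000, 9, 0.0)])
        ev = resolve_indel(disc_interblock(100, 100), ce_p, ce_s, self.params)
        assert ev.kind == "keep_primary"
        assert ev.conditions["c1"][0] is False

    def test_margin_condition_boundary(self):
        # |CE_p| - |CE_s| = 4.0 - 2.5 = 1.5 <= d = 2 -> keep
        ce_p = evidence([("p", 5050, 16, 4.0)])
        ce_s = evidence([("s", 5050, 16, 2.5)])
        ev = resolve_indel(disc_interblock(100, 100), ce_p, ce_s, self.params)
        assert ev.kind == "keep_primary"
        assert ev.conditions["c1"][0] is True
        assert ev.conditions["c2"][0] is False

    def test_compression_chooses_longer_secondary(self):
        # primary compressed by 500 (CE_p < -3); secondary insertion longer
        n = 16
        shift = -500 / (LIB.sigma / np.sqrt(n))
        ce_p = evidence([("p", 5050, n, shift + 0.4)])
        ce_s = evidence([("s", 5300, n, 0.2)])
        ev = resolve_indel(disc_interblock(100, 600), ce_p, ce_s, self.params)
        assert ev.kind == "replace_indel"
        assert ev.ce_primary < -3

    def test_inferred_ce_vetoes_bad_edit(self):
        # large CE_p but the proposed edit would overshoot: |CE*| >= z
        ce_p = evidence([("p", 5050, 16, 8.0)])
        ce_s = evidence([("s", 5050, 16, 0.1)])
        ev = resolve_indel(disc_interblock(100, 100), ce_p, ce_s, self.params)  # no-op edit
        assert ev.kind == "keep_primary"
        assert ev.conditions["c3"][0] is False

    def test_dirty_secondary_vetoes(self):
        n = 16
        shift = 600 / (LIB.sigma / np.sqrt(n))
        ce_p = evidence([("p", 5300, n, shift)])
        ce_s = evidence([("s", 5000, n, 5.0)])
        ev = resolve_indel(disc_interblock(600, 0), ce_p, ce_s, self.params)
        assert ev.kind == "keep_primary"
        assert ev.conditions["c4"][0] is False

    def test_undefined_primary_ce_fails_condition_1(self):
        ce_p = evidence([])  # no coverage anywhere
        ce_s = evidence([("s", 5000, 4, 0.0)])
        ev = resolve_indel(disc_interblock(100, 100), ce_p, ce_s, self.params)
        assert ev.kind == "keep_primary"
        assert ev.ce_primary is None and ev.conditions["c1"][0] is False
        # without spanning inserts condition 3 is vacuously satisfied
        assert ev.conditions["c3"][0] is True


class TestResolveGap:
    params = MergeParams()
    gap_p = [GenomicInterval("p", 5000, 5780)]

    # an oversized N-run (780 Ns for 600 true bases) inflates local inserts
    # by 180 bp; with n=16 and sigma=100 that is CE ~ +7.2
    inflated = 180 / (LIB.sigma / 4) + 0.3

    def test_clean_spanning_secondary_closes(self):
        ce_p = evidence([("p", 5390, 16, self.inflated)])
        ce_s = evidence([("s", 5300, 16, 0.4)])
        disc = disc_interblock(780, 600)
        ev = resolve_gap(disc, self.gap_p, [], ce_p, ce_s, self.params)
        assert ev.kind == "close_gap"
        assert "c1" not in ev.conditions and "c2" not in ev.conditions
        assert abs(ev.ce_inferred) < 3

    def test_secondary_gap_blocks_closure(self):
        ce_p = evidence([("p", 5390, 16, self.inflated)])
        ce_s = evidence([("s", 5300, 16, 0.4)])
        disc = disc_interblock(780, 600)
        gaps_s = [GenomicInterval("s", 5100, 5140)]
        ev = resolve_gap(disc, self.gap_p, gaps_s, ce_p, ce_s, self.params)
        assert ev.kind == "keep_primary"
        assert "secondary_gap_present" in ev.note

    def test_dirty_secondary_blocks_closure(self):
        ce_p = evidence([("p", 5390, 16, self.inflated)])
        ce_s = evidence([("s", 5300, 16, 5.1)])
        ev = resolve_gap(disc_interblock(780, 600), self.gap_p, [], ce_p, ce_s, self.params)
        assert ev.kind == "keep_primary"
        assert ev.conditions["c4"][0] is False

    def test_wrong_size_closure_vetoed_by_inferred_ce(self):
        # closing a gap with far too little secondary sequence would compress
        ce_p = evidence([("p", 5390, 16, self.inflated)])
        ce_s = evidence([("s", 5050, 16, 0.4)])
        ev = resolve_gap(disc_interblock(780, 100), self.gap_p, [], ce_p, ce_s, self.params)
        assert ev.kind == "keep_primary"
        assert ev.conditions["c3"][0] is False

    def test_outside_gap_is_an_error(self):
        ce = evidence([("p", 5390, 4, 0.0)])
        with pytest.raises(MergeInputError):
            resolve_gap(disc_interblock(780, 600, p_pos=20_000), self.gap_p, [], ce, ce, self.params)


class TestResolveOverhang:
    params = MergeParams()

    def _disc(self, p_len, s_len):
        return Discrepancy(
            kind="overhang_end", primary_seq="p", primary_start=10_000 - p_len,
            primary_end=10_000, secondary_seq="s", secondary_start=7000,
            secondary_end=7000 + s_len, orientation="forward",
            p_ce_pos=10_000 - max(p_len // 2, 1), s_ce_pos=7000 + s_len // 2,
        )

    def test_clean_extension_accepted(self):
        # scaffold ends carry no spanning inserts (a mate past the end cannot
        # map), so condition 3 is vacuous and the secondary junction decides
        ce_p = evidence([("p", 5000, 8, 0.2)])
        ce_s = evidence([("s", 7150, 8, 0.1)])
        ev = resolve_overhang(self._disc(0, 300), ce_p, ce_s, self.params)
        assert ev.kind == "extend_overhang"

    def test_dirty_junction_rejected(self):
        ce_p = evidence([("p", 5000, 8, 0.2)])
        ce_s = evidence([("s", 7150, 8, 4.0)])
        ev = resolve_overhang(self._disc(0, 300), ce_p, ce_s, self.params)
        assert ev.kind == "keep_primary"

    def test_zero_length_overhang_is_noop(self):
        ce = evidence([("p", 9900, 8, 0.0)])
        ev = resolve_overhang(self._disc(50, 0), ce, ce, self.params)
        assert ev.kind == "keep_primary" and "no_secondary_extension" in ev.note

    def test_requires_overhang_kind(self):
        ce = evidence([])
        with pytest.raises(MergeInputError):
            resolve_overhang(disc_interblock(10, 10), ce, ce, self.params)


class TestWalkBlocks:
    def test_identical_sequences_single_aligned_segment(self):
        rec = simulate_genome(20_000, seed=40, name="p")
        p = Assembly([rec], label="P")
        s = Assembly([SequenceRecord("s", rec.seq)], label="S")
        aln = filter_one_to_one(anchor_align(p, s))
        segs = walk_blocks(rec, aln, s)
        assert [type(x) for x in segs] == [AlignedSegment]

    def test_interblock_discrepancy_lengths(self):
        truth = simulate_genome(20_000, seed=41)
        a, b = truth.seq[:10_000], truth.seq[10_000:]
        rng = np.random.default_rng(1)
        from metamerge.synthetic import random_sequence
        x, y = random_sequence(600, rng), random_sequence(100, rng)
        p = Assembly([SequenceRecord("p", a + x + b)], label="P")
        s = Assembly([SequenceRecord("s", a + y + b)], label="S")
        aln = filter_one_to_one(anchor_align(p, s))
        discs = [d for d in walk_blocks(p["p"], aln, s) if isinstance(d, Discrepancy)]
        assert len(discs) == 1
        d = discs[0]
        k = 21
        assert d.kind == "interblock"
        assert abs(d.primary_len - 600) <= 2 * k
        assert abs(d.secondary_len - 100) <= 2 * k

    def test_terminal_overhang_detected(self):
        truth = simulate_genome(20_000, seed=42)
        p = Assembly([SequenceRecord("p", truth.seq[:19_700])], label="P")
        s = Assembly([SequenceRecord("s", truth.seq)], label="S")
        aln = filter_one_to_one(anchor_align(p, s))
        over = [d for d in walk_blocks(p["p"], aln, s)
                if isinstance(d, Discrepancy) and d.kind == "overhang_end"]
        assert len(over) == 1
        assert over[0].primary_len <= 21
        assert abs(over[0].secondary_len - 300) <= 21

    def test_requires_one_to_one(self):
        rec = SequenceRecord("p", "A" * 100)
        with pytest.raises(MergeInputError):
            walk_blocks(rec, AlignmentSet([]), Assembly([SequenceRecord("s", "A" * 100)]))

    def test_unaligned_scaffold_kept_verbatim(self):
        rec = SequenceRecord("p", "ACGT" * 100)
        segs = walk_blocks(rec, AlignmentSet([], is_one_to_one=True),
                           Assembly([SequenceRecord("s", "A" * 100)]))
        assert len(segs) == 1 and isinstance(segs[0], UnalignedSegment)
        assert (segs[0].start, segs[0].end) == (0, 400)


def _junction_coverage_evidence(seq_id, lo, hi, n, lib=LIB):
    insert = int(lib.mu)
    span_lo = max(0, (lo + hi) // 2 - insert // 2)
    obs = [MatePairObservation(seq_id, span_lo, span_lo + insert) for _ in range(n)]
    return CEEvidence(build_span_index(obs), lib)


class TestLinkScaffolds:
    def _fixture(self, junction_seq, coverage_n):
        rng = np.random.default_rng(50)
        from metamerge.synthetic import random_sequence
        left = random_sequence(5000, rng)
        right = random_sequence(5000, rng)
        sec = Assembly([SequenceRecord("s", left + junction_seq + right)], label="S")
        pri = Assembly([SequenceRecord("p1", left), SequenceRecord("p2", right)], label="P")
        j_lo, j_hi = 5000, 5000 + len(junction_seq)
        aln = AlignmentSet([
            AlignmentBlock(GenomicInterval("p1", 0, 5000), GenomicInterval("s", 0, 5000), "forward", 1.0),
            AlignmentBlock(GenomicInterval("p2", 0, 5000), GenomicInterval("s", j_hi, j_hi + 5000), "forward", 1.0),
        ], is_one_to_one=True)
        ce_s = _junction_coverage_evidence("s", j_lo, j_hi, coverage_n)
        return pri, sec, aln, ce_s

    def test_link_above_coverage_threshold(self):
        pri, sec, aln, ce_s = self._fixture("ACGT" * 100, coverage_n=25)
        cands = link_scaffolds(pri, aln, ce_s, MergeParams(), secondary=sec)
        assert len(cands) == 1
        c = cands[0]
        assert {c.a_primary, c.b_primary} == {"p1", "p2"}
        assert not c.has_secondary_gap

    def test_no_link_below_threshold(self):
        pri, sec, aln, ce_s = self._fixture("ACGT" * 100, coverage_n=5)
        assert link_scaffolds(pri, aln, ce_s, MergeParams(), secondary=sec) == []

    def test_gap_in_junction_gives_scaffold_join(self):
        pri, sec, aln, ce_s = self._fixture("ACGT" * 10 + "N" * 100 + "ACGT" * 10, coverage_n=25)
        cands = link_scaffolds(pri, aln, ce_s, MergeParams(), secondary=sec)
        assert len(cands) == 1 and cands[0].has_secondary_gap

    def test_applied_link_joins_with_fill(self):
        pri, sec, aln, ce_s = self._fixture("ACGT" * 100, coverage_n=25)
        ce_p = _junction_coverage_evidence("p1", 0, 5000, 25)
        res = pairwise_merge(pri, sec, aln, ce_p, ce_s, MergeParams())
        assert len(res.assembly) == 1
        assert res.assembly.records[0].seq == sec["s"].seq
        kinds = [e.kind for e in res.events]
        assert "scaffold_link" in kinds

    def test_applied_gap_link_inserts_ns(self):
        pri, sec, aln, ce_s = self._fixture("N" * 100, coverage_n=25)
        ce_p = _junction_coverage_evidence("p1", 0, 5000, 25)
        res = pairwise_merge(pri, sec, aln, ce_p, ce_s, MergeParams())
        assert len(res.assembly) == 1
        out = res.assembly.records[0].seq
        assert "N" * 100 in out and out == sec["s"].seq


class TestPairwiseMerge:
    def test_self_merge_is_identity(self):
        rec = simulate_genome(30_000, seed=60, name="g")
        p = Assembly([rec], label="P")
        s = Assembly([SequenceRecord("g2", rec.seq)], label="S")
        reads = simulate_matepairs(rec, 600, 2500, 250, 100, seed=61)
        from metamerge.ce import estimate_library, map_mates_exact
        obs_p = map_mates_exact(reads, p)
        obs_s = map_mates_exact(reads, s)
        lib = estimate_library(obs_p)
        ce_p = CEEvidence(build_span_index(obs_p), lib)
        ce_s = CEEvidence(build_span_index(obs_s), lib)
        aln = filter_one_to_one(anchor_align(p, s))
        res = pairwise_merge(p, s, aln, ce_p, ce_s)
        assert len(res.assembly) == 1
        assert res.assembly.records[0].seq == rec.seq
        assert all(e.kind in ("keep_aligned", "keep_primary") for e in res.events)

    def test_scenario_decisions_and_sequence(self, small_scenario):
        sc = small_scenario
        res = pairwise_merge(sc["primary"], sc["secondary"], sc["aln"],
                             sc["ce_p"], sc["ce_s"])
        kinds = sorted(e.kind for e in res.events if e.modifies)
        assert kinds == ["close_gap", "replace_indel", "replace_indel"]
        assert len(res.assembly) == 1
        assert res.assembly.records[0].seq == sc["truth"].seq

    def test_provenance_reconstruction(self, small_scenario):
        sc = small_scenario
        res = pairwise_merge(sc["primary"], sc["secondary"], sc["aln"],
                             sc["ce_p"], sc["ce_s"])
        sources = {"P": sc["primary"], "S": sc["secondary"]}
        for ms in res.sequences:
            assert ms.reconstruct(sources) == ms.record.seq

    def test_condition_traces_self_consistent(self, small_scenario):
        """Recorded decisions re-derive from their stored condition outcomes."""
        sc = small_scenario
        res = pairwise_merge(sc["primary"], sc["secondary"], sc["aln"],
                             sc["ce_p"], sc["ce_s"])
        for ev in res.events:
            if ev.kind == "replace_indel":
                assert all(ev.conditions[c][0] for c in ("c1", "c2", "c3", "c4"))
            elif ev.kind in ("close_gap", "extend_overhang"):
                assert ev.conditions["c3"][0] and ev.conditions["c4"][0]

    def test_event_intervals_tile_output(self, small_scenario):
        sc = small_scenario
        res = pairwise_merge(sc["primary"], sc["secondary"], sc["aln"],
                             sc["ce_p"], sc["ce_s"])
        by_out = {}
        for ev in res.events:
            if ev.out_seq_id is not None:
                by_out.setdefault(ev.out_seq_id, []).append((ev.out_start, ev.out_end))
        for rec in res.assembly.records:
            ivs = sorted(by_out[rec.id])
            pos = 0
            for s, e in ivs:
                assert s == pos
                pos = e
            assert pos == len(rec.seq)

    def test_reverse_complement_secondary_corrects_expansion(self):
        """Corrections work when the secondary scaffold is stored reversed."""
        truth = simulate_genome(40_000, seed=62)
        rng = np.random.default_rng(63)
        from metamerge.synthetic import random_sequence
        bad = truth.seq[:20_000] + random_sequence(600, rng) + truth.seq[20_000:]
        p = Assembly([SequenceRecord("p", bad)], label="P")
        s = Assembly([SequenceRecord("s", revcomp(truth.seq))], label="S")
        reads = simulate_matepairs(truth, 800, 2500, 250, 100, seed=64)
        from metamerge.ce import estimate_library, map_mates_exact
        obs_p = map_mates_exact(reads, p)
        obs_s = map_mates_exact(reads, s)
        lib = estimate_library(obs_p)
        ce_p = CEEvidence(build_span_index(obs_p), lib)
        ce_s = CEEvidence(build_span_index(obs_s), lib)
        aln = filter_one_to_one(anchor_align(p, s))
        assert all(b.orientation == "reverse" for b in aln.blocks)
        res = pairwise_merge(p, s, aln, ce_p, ce_s)
        assert res.assembly.records[0].seq == truth.seq
        assert any(e.kind == "replace_indel" for e in res.events)

    def test_inconsistent_alignment_rejected(self):
        p = Assembly([SequenceRecord("p", "A" * 100)], label="P")
        s = Assembly([SequenceRecord("s", "A" * 100)], label="S")
        bad = AlignmentSet([AlignmentBlock(GenomicInterval("ghost", 0, 50),
                                           GenomicInterval("s", 0, 50), "forward", 1.0)],
                           is_one_to_one=True)
        ce = evidence([])
        with pytest.raises(MergeInputError, match="ghost"):
            pairwise_merge(p, s, bad, ce, ce)
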