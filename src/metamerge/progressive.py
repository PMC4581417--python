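"""Ordering heuristics and the progressive fold of pairwise merges.

Each round merges the current metassembly (primary) with the next input
assembly (secondary).  The jumping library is re-mapped to both inputs every
round — CE profiles of a freshly merged sequence cannot be inherited — and
the library model is estimated once, from the first round's primary mapping,
then held fixed, since the library is a property of the data rather than of
any particular assembly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Optional, Sequence

from .ce import (
    CEEvidence,
    LibraryModel,
    build_span_index,
    collect_inserts,
    estimate_library,
    map_mates_exact,
)
from .core import Assembly, MergeParams, split_into_contigs, write_fasta
from .mapping import ReadPairSet
from .merge import MergeEvent, MergeResult, pairwise_merge
from .metrics import AssemblyStats, assembly_stats, nx_size
from .wga import anchor_align, discard_unaligned, filter_one_to_one

logger = logging.getLogger(__name__)

OrderMode = Literal["ctg_n50", "scf_n50", "given"]


def order_assemblies(assemblies: Sequence[Assembly], mode: OrderMode = "ctg_n50") -> list[Assembly]:
    """Rank assemblies best-first: by contig N50, scaffold N50, or user order.

    Ties break on the label, lexicographically.
    """
    if len(assemblies) < 2:
        raise ValueError("need at least two assemblies to order")
    if mode == "given":
        return list(assemblies)
    if mode == "ctg_n50":
        def key(a: Assembly) -> tuple:
            contigs = [len(c) for r in a.records for c in split_into_contigs(r, 1)]
            return (-nx_size(contigs) if contigs else 0, a.label)
    elif mode == "scf_n50":
        def key(a: Assembly) -> tuple:
            return (-nx_size([len(r) for r in a.records]), a.label)
    else:
        raise ValueError(f"unknown ordering mode {mode!r}")
    return sorted(assemblies, key=key)


@dataclass
class RoundReport:
    round: int
    secondary_label: str
    events: list[MergeEvent]
    stats: AssemblyStats
    result: MergeResult
    primary_used: Assembly       # post-filter inputs of this round, for
    secondary_used: Assembly     # provenance verification and audits


@dataclass
class ProgressiveResult:
    assembly: Assembly
    rounds: list[RoundReport]
    library: LibraryModel

    @property
    def per_round_events(self) -> list[list[MergeEvent]]:
        return [r.events for r in self.rounds]

    @property
    def per_round_stats(self) -> list[AssemblyStats]:
        return [r.stats for r in self.rounds]


def _evidence(asm: Assembly, reads: ReadPairSet, lib: Optional[LibraryModel]) -> tuple[CEEvidence, LibraryModel]:
    obs = map_mates_exact(reads, asm)
    if lib is None:
        lib = estimate_library(obs)
    return CEEvidence(build_span_index(obs), lib), lib


def progressive_merge(
    ordered: Sequence[Assembly],
    reads: Optional[ReadPairSet] = None,
    params: Optional[MergeParams] = None,
    library: Optional[LibraryModel] = None,
    sam_per_round: Optional[Sequence[tuple[str, str]]] = None,
    workdir: Optional[str | Path] = None,
) -> ProgressiveResult:
    """Fold pairwise_merge over the ordered assemblies.

    Mate evidence comes either from the built-in exact mapper applied to
    `reads` each round, or from externally produced per-round SAM pairs
    (primary SAM, secondary SAM), one tuple per merge round.
    """
    if len(ordered) < 2:
        raise ValueError("progressive merge needs at least two assemblies")
    if reads is None and sam_per_round is None:
        raise ValueError("provide either a read set or per-round SAM paths")
    params = params or MergeParams()
    workdir = Path(workdir) if workdir is not None else None
    if workdir is not None:
        workdir.mkdir(parents=True, exist_ok=True)

    current = ordered[0]
    lib = library
    rounds: list[RoundReport] = []
    for r, nxt in enumerate(ordered[1:], start=1):
        if sam_per_round is not None:
            if r - 1 >= len(sam_per_round):
                raise ValueError(f"missing SAM pair for merge round {r}")
            sam_p, sam_s = sam_per_round[r - 1]
            obs_p = collect_inserts(sam_p, current)
            obs_s = collect_inserts(sam_s, nxt)
            if lib is None:
                lib = estimate_library(obs_p)
            ce_p = CEEvidence(build_span_index(obs_p), lib)
            ce_s = CEEvidence(build_span_index(obs_s), lib)
        else:
            ce_p, lib = _evidence(current, reads, lib)
            ce_s, _ = _evidence(nxt, reads, lib)

        aln = filter_one_to_one(anchor_align(current, nxt, k=params.min_anchor))
        pri, sec = discard_unaligned(current, nxt, aln, params.keep_unaligned_min_len)
        result = pairwise_merge(pri, sec, aln, ce_p, ce_s, params)
        merged = result.assembly.relabel(f"meta{r}")
        stats = assembly_stats(merged)
        n_mod = sum(1 for e in result.events if e.modifies)
        logger.info("round %d (+%s): %d events, %d modifications, scaffold N50 %d",
                    r, nxt.label, len(result.events), n_mod, stats.scaffold_n50)
        if workdir is not None:
            write_fasta(merged, workdir / f"round{r:02d}.fa")
        rounds.append(RoundReport(r, nxt.label, result.events, stats, result, pri, sec))
        current = merged

    assert lib is not None
    return ProgressiveResult(current, rounds, lib)
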