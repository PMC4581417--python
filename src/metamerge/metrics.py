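"""Contiguity statistics (N50/NG50), per-assembly summaries, Z-score ranking, CE deltas."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .ce import CEEvidence
from .core import Assembly, split_into_contigs
from .merge import MergeEvent


def nx_size(
    lengths: Sequence[int],
    x: float = 0.5,
    genome_size: Optional[int] = None,
) -> int:
    """Nx (or NGx when genome_size is given): the largest L such that
    sequences of length >= L jointly cover x of the denominator.

    Returns 0 in NG mode when the assembly is too small to reach the target.
    """
    if not lengths:
        raise ValueError("nx_size requires a non-empty length list")
    denom = genome_size if genome_size is not None else sum(lengths)
    target = x * denom
    cum = 0
    for L in sorted(lengths, reverse=True):
        cum += L
        if cum >= target:
            return L
    return 0


@dataclass(frozen=True)
class AssemblyStats:
    label: str
    scaffold_count: int
    span: int
    gap_bases: int
    scaffold_n50: int
    contig_n50: int
    contig_count: int


def assembly_stats(asm: Assembly) -> AssemblyStats:
    """Exact contiguity summary; contigs split at every N-run (min_run = 1)."""
    scaffold_lengths = [len(r) for r in asm.records]
    contig_lengths: list[int] = []
    gap_bases = 0
    for rec in asm.records:
        contigs = split_into_contigs(rec, min_run=1)
        contig_lengths.extend(len(c) for c in contigs)
        gap_bases += len(rec) - sum(len(c) for c in contigs)
    return AssemblyStats(
        label=asm.label,
        scaffold_count=len(scaffold_lengths),
        span=sum(scaffold_lengths),
        gap_bases=gap_bases,
        scaffold_n50=nx_size(scaffold_lengths),
        contig_n50=nx_size(contig_lengths) if contig_lengths else 0,
        contig_count=len(contig_lengths),
    )


def zscore_table(
    metric_table: pd.DataFrame | Mapping[str, Mapping[str, float]],
    directions: Mapping[str, str],
) -> pd.Series:
    """Overall Z score per assembly: sum over metrics of the per-metric z-score.

    metric_table: rows = assemblies, columns = metrics.  directions maps each
    metric to "higher_better" or "lower_better"; lower-is-better metrics are
    sign-flipped so a larger overall Z is always better.  Z-scores use the
    sample standard deviation (n - 1); metrics with zero spread contribute 0.
    The overall Z values sum to ~0 across assemblies by construction.
    """
    df = pd.DataFrame(metric_table).astype(float)
    if df.shape[0] < 2:
        raise ValueError("zscore_table needs at least two assemblies")
    unknown = set(df.columns) - set(directions)
    if unknown:
        raise ValueError(f"no direction given for metrics: {sorted(unknown)}")
    total = pd.Series(0.0, index=df.index)
    for col in df.columns:
        sd = df[col].std(ddof=1)
        if sd == 0 or np.isnan(sd):
            continue
        z = (df[col] - df[col].mean()) / sd
        if directions[col] == "lower_better":
            z = -z
        elif directions[col] != "higher_better":
            raise ValueError(f"direction for {col!r} must be higher_better or lower_better")
        total += z
    return total


@dataclass(frozen=True)
class CEDelta:
    kind: str
    out_seq_id: str
    out_pos: int
    ce_before: float
    ce_after: Optional[float]

    @property
    def delta(self) -> Optional[float]:
        if self.ce_after is None:
            return None
        return abs(self.ce_before) - abs(self.ce_after)


def ce_delta_report(events: Iterable[MergeEvent], post_ce: CEEvidence) -> list[CEDelta]:
    """|CE before| - |CE after| at each corrected position, on the merged assembly.

    Only sequence-modifying events (replace_indel, close_gap, extend_overhang)
    with a recorded breakpoint CE are reported; the post-merge CE is read at
    the event's landing position in the merged assembly.
    """
    out: list[CEDelta] = []
    for ev in events:
        if not ev.modifies or ev.ce_primary is None or ev.out_seq_id is None:
            continue
        pos = (ev.out_start + ev.out_end) // 2
        ce_after = post_ce.ce(ev.out_seq_id, pos)
        out.append(CEDelta(ev.kind, ev.out_seq_id, pos, ev.ce_primary, ce_after))
    return out


def median_ce_delta(report: Sequence[CEDelta]) -> float:
    deltas = [d.delta for d in report if d.delta is not None]
    if not deltas:
        raise ValueError("no scored CE deltas")
    return float(np.median(deltas))


def stats_frame(assemblies: Iterable[Assembly]) -> pd.DataFrame:
    rows = [assembly_stats(a).__dict__ for a in assemblies]
    return pd.DataFrame(rows).set_index("label")
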