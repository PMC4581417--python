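"""Mate-pair intake, library model estimation, and the compression-expansion statistic.

The CE statistic at a position i is a one-sample z-test comparing the mean
insert size Y_i of the mate pairs physically spanning i against its null
expectation under the library model:

    CE_i = (Y_i - mu_span) / (sigma / sqrt(n_i)),   mu_span = mu + sigma^2/mu

where n_i is the number of spanning inserts and mu_span accounts for the
length bias of spanning sampling (see LibraryModel).  Strongly negative values flag
compression (sequence missing at i), strongly positive values expansion
(sequence erroneously inserted).  Y_i and n_i are computed for every base by
a single plane sweep over the 2x|observations| span endpoints per scaffold.

Insert size is the outer distance between the outermost mapped coordinates of
a pair; mate orientation is an intake filter only (jumping-library chemistry
varies) and does not enter the statistic.  Positions inside N-gaps carry CE
values like any other position, because spanning pairs bridge gaps and gap
closure decisions need CE at gap flanks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pysam

from .core import Assembly, GenomicInterval
from .mapping import ReadPairSet, place_reads_unique


class MatePairError(ValueError):
    """Raised when no usable mate pairs can be recovered."""


@dataclass(frozen=True)
class MatePairObservation:
    """Outermost span of one mate pair on one scaffold."""

    seq_id: str
    start: int
    end: int

    @property
    def insert(self) -> int:
        return self.end - self.start

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(self.seq_id, self.start, self.end)


@dataclass(frozen=True)
class LibraryModel:
    """Global insert-size model of one jumping library (bp).

    mu and sigma describe the per-pair insert distribution.  The CE test
    compares the local mean against `spanning_mu`, not mu: pairs spanning a
    fixed position are a length-biased sample (a fragment covers the
    position with probability proportional to its length), so under a
    correct assembly the expected local mean is mu + sigma^2/mu, slightly
    above mu.  Referencing mu directly would shift every CE value by
    +(sigma/mu)*sqrt(n) and inflate the null false-positive rate several
    fold at typical coverage.
    """

    mu: float
    sigma: float
    trim_lo: float = 0.0
    trim_hi: float = 1.0

    def __post_init__(self) -> None:
        if self.mu <= 0 or self.sigma <= 0:
            raise ValueError("library model requires mu > 0 and sigma > 0")

    @property
    def spanning_mu(self) -> float:
        """Null expectation of the mean insert of pairs spanning a position."""
        return self.mu + self.sigma**2 / self.mu


def _truncation_sd_factor(lo: float, hi: float) -> float:
    """SD of a standard normal truncated to its [lo, hi] quantiles.

    The trimmed-sample standard deviation underestimates the library sigma
    (by ~6% for a 1%/99% trim); dividing by this factor undoes the bias
    under the normal insert-size model.
    """
    from scipy.stats import norm

    a, b = norm.ppf(lo), norm.ppf(hi)
    mass = norm.cdf(b) - norm.cdf(a)
    mean = (norm.pdf(a) - norm.pdf(b)) / mass
    var = 1.0 + (a * norm.pdf(a) - b * norm.pdf(b)) / mass - mean**2
    return float(np.sqrt(var))


def estimate_library(
    obs: Sequence[MatePairObservation],
    trim: tuple[float, float] = (0.01, 0.99),
) -> LibraryModel:
    """Estimate mu and sigma from inserts inside the [lo, hi] empirical quantiles.

    The default 1% trim on each tail makes the estimate robust to chimeric
    pairs and mis-mappings with wild insert sizes; the standard deviation of
    the trimmed sample is rescaled to undo the truncation bias, assuming
    normally distributed inserts.
    """
    lo, hi = trim
    if not 0 <= lo < hi <= 1:
        raise ValueError("trim quantiles must satisfy 0 <= lo < hi <= 1")
    inserts = np.array([o.insert for o in obs], dtype=float)
    if len(inserts) == 0:
        raise MatePairError("no mate-pair observations to estimate the library from")
    qlo, qhi = np.quantile(inserts, [lo, hi])
    kept = inserts[(inserts >= qlo) & (inserts <= qhi)]
    if len(kept) < 100:
        raise MatePairError(
            f"only {len(kept)} observations after trimming; need >= 100 for a stable model"
        )
    mu = float(np.mean(kept))
    sigma = float(np.std(kept, ddof=1))
    if sigma <= 0:
        raise MatePairError("degenerate library: insert sizes have zero spread")
    if lo > 0 or hi < 1:
        sigma /= _truncation_sd_factor(lo, hi)
    return LibraryModel(mu=mu, sigma=sigma, trim_lo=lo, trim_hi=hi)


def collect_inserts(
    sam: str | Path,
    asm: Assembly,
    orientation: Literal["fr", "rf", "any"] = "any",
    insert_bounds: tuple[int, int] | None = None,
) -> list[MatePairObservation]:
    """Collect mate-pair spans from a SAM/BAM of paired reads mapped to asm.

    One observation per read pair with both mates mapped to the same
    scaffold.  Spans are recomputed from the two mates' positions (flags and
    TLEN are not trusted).  Pairs failing the orientation filter or the
    optional insert sanity bounds, and pairs with unmapped or cross-scaffold
    mates, are skipped and counted in the returned list's companion stats
    (see :func:`collect_inserts_with_stats`).
    """
    obs, _ = collect_inserts_with_stats(sam, asm, orientation, insert_bounds)
    return obs


def collect_inserts_with_stats(
    sam: str | Path,
    asm: Assembly,
    orientation: Literal["fr", "rf", "any"] = "any",
    insert_bounds: tuple[int, int] | None = None,
) -> tuple[list[MatePairObservation], dict[str, int]]:
    stats = {"pairs": 0, "cross_scaffold": 0, "unpaired_or_unmapped": 0,
             "orientation_fail": 0, "bounds_fail": 0}
    # first mate seen per read name: (ref, start, end, is_reverse)
    pending: dict[str, tuple[str, int, int, bool]] = {}
    obs: list[MatePairObservation] = []
    with pysam.AlignmentFile(str(sam), check_sq=False) as fh:
        for read in fh:
            if read.is_unmapped or read.is_secondary or read.is_supplementary:
                continue
            name = read.query_name
            entry = (read.reference_name, read.reference_start, read.reference_end, read.is_reverse)
            if name not in pending:
                pending[name] = entry
                continue
            mate = pending.pop(name)
            stats["pairs"] += 1
            if mate[0] != entry[0]:
                stats["cross_scaffold"] += 1
                continue
            if mate[0] not in asm:
                stats["unpaired_or_unmapped"] += 1
                continue
            left, right = (mate, entry) if mate[1] <= entry[1] else (entry, mate)
            if orientation == "fr" and (left[3] or not right[3]):
                stats["orientation_fail"] += 1
                continue
            if orientation == "rf" and (not left[3] or right[3]):
                stats["orientation_fail"] += 1
                continue
            start, end = left[1], max(left[2], right[2])
            if end <= start:
                stats["bounds_fail"] += 1
                continue
            if insert_bounds is not None and not insert_bounds[0] <= end - start <= insert_bounds[1]:
                stats["bounds_fail"] += 1
                continue
            obs.append(MatePairObservation(mate[0], start, end))
    stats["unpaired_or_unmapped"] += len(pending)
    if not obs:
        raise MatePairError(
            "no valid mate pairs recovered; review the orientation filter and insert bounds"
        )
    return obs, stats


def map_mates_exact(reads: ReadPairSet, asm: Assembly) -> list[MatePairObservation]:
    """Place error-free mate pairs at their unique exact occurrences in asm.

    Each mate must occur exactly once across both strands of the whole
    assembly; pairs with an ambiguous or absent mate, or with mates on
    different scaffolds, are dropped.  Equivalent to collect_inserts on the
    SAM an ideal exact mapper would emit.
    """
    hits1 = place_reads_unique([r1 for _, r1, _ in reads.pairs], asm)
    hits2 = place_reads_unique([r2 for _, _, r2 in reads.pairs], asm)
    obs: list[MatePairObservation] = []
    for h1, h2 in zip(hits1, hits2):
        if h1 is None or h2 is None:
            continue
        if h1.seq_id != h2.seq_id:
            continue
        start = min(h1.start, h2.start)
        end = max(h1.end, h2.end)
        if end > start:
            obs.append(MatePairObservation(h1.seq_id, start, end))
    return obs


@dataclass
class _ScaffoldIndex:
    """Piecewise-constant n_i and sum-of-inserts over one scaffold."""

    bounds: np.ndarray  # breakpoints, starts at 0
    n: np.ndarray       # spanning-insert count on [bounds[j], bounds[j+1])
    total: np.ndarray   # sum of insert sizes of those spans


@dataclass
class CEProfile:
    """Per-base spanning-insert index for one assembly, built by plane sweep."""

    scaffolds: dict[str, _ScaffoldIndex] = field(default_factory=dict)

    def _locate(self, seq_id: str, pos: int) -> tuple[_ScaffoldIndex, int] | None:
        idx = self.scaffolds.get(seq_id)
        if idx is None or len(idx.bounds) == 0:
            return None
        j = int(np.searchsorted(idx.bounds, pos, side="right")) - 1
        if j < 0 or j >= len(idx.n):
            return None
        return idx, j

    def n_at(self, seq_id: str, pos: int) -> int:
        loc = self._locate(seq_id, pos)
        return 0 if loc is None else int(loc[0].n[loc[1]])

    def mean_insert_at(self, seq_id: str, pos: int) -> float | None:
        loc = self._locate(seq_id, pos)
        if loc is None:
            return None
        idx, j = loc
        n = idx.n[j]
        if n == 0:
            return None
        return float(idx.total[j] / n)

    def mean_coverage(self, seq_id: str, start: int, end: int) -> float:
        """Mean spanning-insert count over [start, end) (physical coverage)."""
        if end <= start:
            return 0.0
        idx = self.scaffolds.get(seq_id)
        if idx is None or len(idx.bounds) == 0:
            return 0.0
        edges = np.clip(idx.bounds, start, end)
        seg = np.diff(np.append(edges, end))
        seg = seg[: len(idx.n)]
        return float((seg * idx.n[: len(seg)]).sum() / (end - start))


def build_span_index(obs: Sequence[MatePairObservation]) -> CEProfile:
    """Plane-sweep the span endpoints into per-base n_i and Y_i.

    Each observation contributes +1/+insert at its start and -1/-insert at
    its end; prefix sums over the sorted event positions yield the count and
    insert-sum on every inter-event segment.
    """
    by_scaffold: dict[str, list[MatePairObservation]] = {}
    for o in obs:
        by_scaffold.setdefault(o.seq_id, []).append(o)
    profile = CEProfile()
    for seq_id, group in by_scaffold.items():
        starts = np.array([o.start for o in group], dtype=np.int64)
        ends = np.array([o.end for o in group], dtype=np.int64)
        inserts = (ends - starts).astype(np.float64)
        pos = np.concatenate((starts, ends))
        dn = np.concatenate((np.ones(len(group)), -np.ones(len(group))))
        dt = np.concatenate((inserts, -inserts))
        order = np.argsort(pos, kind="stable")
        pos, dn, dt = pos[order], dn[order], dt[order]
        bounds, first = np.unique(pos, return_index=True)
        n_steps = np.add.reduceat(dn, first)
        t_steps = np.add.reduceat(dt, first)
        n = np.cumsum(n_steps)
        total = np.cumsum(t_steps)
        n = np.rint(n).astype(np.int64)
        if bounds[0] != 0:
            bounds = np.concatenate(([0], bounds))
            n = np.concatenate(([0], n))
            total = np.concatenate(([0.0], total))
        profile.scaffolds[seq_id] = _ScaffoldIndex(bounds, n, total)
    return profile


def ce_value(y: float | None, n: int, lib: LibraryModel) -> float | None:
    """One-sample z-statistic of a local spanning mean against the library."""
    if n < 1 or y is None:
        return None
    return float((y - lib.spanning_mu) / (lib.sigma / np.sqrt(n)))


def ce_at(profile: CEProfile, lib: LibraryModel, seq_id: str, pos: int) -> float | None:
    """CE statistic at one position; None where no insert spans it."""
    n = profile.n_at(seq_id, pos)
    if n < 1:
        return None
    return ce_value(profile.mean_insert_at(seq_id, pos), n, lib)


def infer_ce_after_edit(
    profile: CEProfile,
    lib: LibraryModel,
    seq_id: str,
    pos: int,
    primary_len: int,
    secondary_len: int,
) -> float | None:
    """Inferred CE after replacing primary_len bases by secondary_len bases.

    The local mean insert becomes Y* = Y - primary_len + secondary_len while
    n and the library model are unchanged; None when no insert spans pos.
    """
    n = profile.n_at(seq_id, pos)
    if n < 1:
        return None
    y = profile.mean_insert_at(seq_id, pos)
    return ce_value(y - primary_len + secondary_len, n, lib)


@dataclass(frozen=True)
class CEEvidence:
    """A CE profile paired with its library model (one assembly, one library)."""

    profile: CEProfile
    lib: LibraryModel

    def ce(self, seq_id: str, pos: int) -> float | None:
        return ce_at(self.profile, self.lib, seq_id, pos)

    def n(self, seq_id: str, pos: int) -> int:
        return self.profile.n_at(seq_id, pos)

    def ce_after_edit(self, seq_id: str, pos: int, primary_len: int, secondary_len: int) -> float | None:
        return infer_ce_after_edit(self.profile, self.lib, seq_id, pos, primary_len, secondary_len)


def write_bedgraph(profile: CEProfile, lib: LibraryModel, path: str | Path) -> None:
    """Export the CE track as bedGraph (segments without coverage are skipped)."""
    with open(path, "w") as fh:
        for seq_id in sorted(profile.scaffolds):
            idx = profile.scaffolds[seq_id]
            for j in range(len(idx.n)):
                if idx.n[j] < 1:
                    continue
                start = int(idx.bounds[j])
                end = int(idx.bounds[j + 1]) if j + 1 < len(idx.bounds) else start + 1
                ce = ce_value(float(idx.total[j] / idx.n[j]), int(idx.n[j]), lib)
                fh.write(f"{seq_id}\t{start}\t{end}\t{ce:.4f}\n")
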