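"""Independent brute-force oracles shared by unit and acceptance tests."""

import itertools

import numpy as np

from metamerge.core import GenomicInterval
from metamerge.wga import AlignmentBlock, AlignmentSet


def random_block_instance(rng: np.random.Generator, n_blocks: int) -> AlignmentSet:
    """Random, possibly conflicting blocks on one primary/secondary pair."""
    blocks = []
    for _ in range(n_blocks):
        ps = int(rng.integers(0, 5000))
        pl = int(rng.integers(100, 2000))
        ss = int(rng.integers(0, 5000))
        blocks.append(AlignmentBlock(
            GenomicInterval("p1", ps, ps + pl),
            GenomicInterval("s1", ss, ss + pl),
            "forward" if rng.random() < 0.8 else "reverse",
            float(rng.uniform(0.7, 1.0)),
        ))
    return AlignmentSet(blocks)


def brute_force_one_to_one_weight(blocks) -> float:
    """Exhaustive max-weight subset with no overlap on either axis (n <= 12)."""
    best = 0.0
    n = len(blocks)
    for mask in range(1 << n):
        chosen = [blocks[i] for i in range(n) if mask >> i & 1]
        ok = all(
            not a.primary.overlaps(b.primary) and not a.secondary.overlaps(b.secondary)
            for a, b in itertools.combinations(chosen, 2)
        )
        if ok:
            best = max(best, sum(b.weight for b in chosen))
    return best


def brute_force_span_stats(observations, pos: int):
    """Direct per-position recount of spanning inserts and their mean."""
    spanning = [o for o in observations if o.start <= pos < o.end]
    n = len(spanning)
    y = sum(o.insert for o in spanning) / n if n else None
    return n, y
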