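"""Shared fixtures: small synthetic merge scenarios and the heavy three-assembly runs."""

from __future__ import annotations

from itertools import permutations

import pytest

from metamerge import Assembly, SequenceRecord
from metamerge.ce import CEEvidence, build_span_index, estimate_library, map_mates_exact
from metamerge.progressive import progressive_merge
from metamerge.synthetic import (
    CorruptionEvent,
    CorruptionSpec,
    corrupt_assembly,
    make_three_assembly_fixture,
    simulate_genome,
    simulate_matepairs,
)
from metamerge.wga import anchor_align, filter_one_to_one

MU, SIGMA, READ_LEN = 2500.0, 250.0, 100


@pytest.fixture(scope="session")
def small_truth():
    """120 kb truth genome for quick pairwise-merge scenarios."""
    return simulate_genome(120_000, seed=11)


@pytest.fixture(scope="session")
def small_scenario(small_truth):
    """Primary with an expansion, a short-for-long indel, and a gap; clean secondary.

    The three defect classes exercise each decision path: the expansion at
    30 kb should be excised (large positive CE), the 100-for-600 replacement
    at 60 kb chosen from the secondary (large negative CE), and the gap at
    90 kb closed.
    """
    truth = small_truth
    spec = CorruptionSpec(seed=2, gap_size_error=1.3, events=[
        CorruptionEvent("expansion", 30_000, 30_000, 600),
        CorruptionEvent("contraction", 60_000, 60_600),
        CorruptionEvent("expansion", 60_600, 60_600, 100),
        CorruptionEvent("gap", 90_000, 90_600),
    ])
    primary, table = corrupt_assembly(truth, spec, label="P")
    secondary = Assembly([SequenceRecord("S_scf00", truth.seq)], label="S")
    reads = simulate_matepairs(truth, 1920, MU, SIGMA, READ_LEN, seed=13)  # 40x physical
    obs_p = map_mates_exact(reads, primary)
    obs_s = map_mates_exact(reads, secondary)
    lib = estimate_library(obs_p)
    ce_p = CEEvidence(build_span_index(obs_p), lib)
    ce_s = CEEvidence(build_span_index(obs_s), lib)
    aln = filter_one_to_one(anchor_align(primary, secondary))
    return {
        "truth": truth, "primary": primary, "secondary": secondary,
        "table": table, "reads": reads, "lib": lib,
        "ce_p": ce_p, "ce_s": ce_s, "aln": aln,
    }


@pytest.fixture(scope="session")
def trio():
    """The full-scale three-assembly reconstruction fixture (1 Mb truth, 40x)."""
    return make_three_assembly_fixture(seed=1)


@pytest.fixture(scope="session")
def trio_runs(trio):
    """Progressive merges of all 6 orderings of the three-assembly fixture."""
    runs = {}
    for order in permutations(trio.assemblies):
        labels = tuple(a.label for a in order)
        runs[labels] = progressive_merge(list(order), trio.reads)
    return runs
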