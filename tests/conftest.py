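from __future__ import annotations

import numpy as np
import pytest

import rdcnv


@pytest.fixture(scope="session")
def small_genome() -> rdcnv.GenomeLayout:
    return rdcnv.GenomeLayout((("chr1", 2_000_000), ("chr2", 1_500_000)))


@pytest.fixture(scope="session")
def recovery_run():
    """10 Mb genome at 30X-equivalent depth with 20 implanted events.

    Shared by caller recovery tests and the acceptance suite; the dict
    carries the truth set and the filtered calls.
    """
    genome = rdcnv.make_genome(1, 10_000_000, seed=1)
    truth = rdcnv.implant_cnvs(genome, 20, seed=2, size_range=(1_000, 200_000))
    depth = rdcnv.simulate_depth(
        genome, truth, coverage=30, read_length=150, bin_size=100,
        gc_amplitude=0.1, seed=3,
    )
    raw = rdcnv.run_caller(depth)
    filtered = rdcnv.apply_filters(raw)
    return {
        "genome": genome,
        "truth": truth,
        "raw": raw,
        "filtered": filtered,
        "bin_size": 100,
    }


@pytest.fixture(scope="session")
def event_free_fp_counts():
    """Post-filter call counts on event-free 10 Mb simulations (3 seeds)."""
    genome = rdcnv.GenomeLayout((("chr1", 10_000_000),))
    counts = []
    for seed in (11, 12, 13):
        depth = rdcnv.simulate_depth(
            genome, [], coverage=30, read_length=150, bin_size=100,
            gc_amplitude=0.1, seed=seed,
        )
        counts.append(len(rdcnv.apply_filters(rdcnv.run_caller(depth))))
    return counts


def match_truth(truth, calls, bin_size):
    """Recovery bookkeeping: per truth event, correct-type hit and the
    breakpoint error (bins) of the best-overlapping call."""
    results = []
    for t in truth:
        want = rdcnv.DELETION if t.copy_number < 2 else rdcnv.DUPLICATION
        hits = [
            c for c in calls
            if c.type == want and c.start < t.end and c.end > t.start
        ]
        if not hits:
            results.append({"recovered": False, "bp_error": np.inf})
            continue
        best = max(hits, key=lambda c: min(c.end, t.end) - max(c.start, t.start))
        err = max(abs(best.start - t.start), abs(best.end - t.end)) / bin_size
        results.append({"recovered": True, "bp_error": err})
    return results
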