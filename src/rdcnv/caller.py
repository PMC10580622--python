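"""Mean-shift segmentation of the normalized RD signal and CNV calling.

The partitioner is a multi-scale mean-shift procedure: at each bandwidth
``h`` every bin is assigned a shift direction toward the kernel-weighted
mean position of its neighbours within ±``h`` bins whose RD lies within one
noise standard deviation of its own.  A bin left of a copy-number step is
attracted to its own (left) side and shifts negative; the first bin right
of the step shifts positive, so candidate breakpoints are placed at
negative-to-positive sign flips.  Candidates are pooled over the bandwidth
schedule and then re-merged: adjacent segments whose means differ by less
than the noise sd always merge, with the threshold inflated by
``MERGE_Z * sqrt(1/n1 + 1/n2)`` for short segments so noise fragments
collapse; sub-bandwidth spikes are absorbed into the nearer-mean
neighbour.

Calls are emitted per segment: mean normalized RD below ``del_threshold``
is a deletion, above ``dup_threshold`` a duplication; significance is a
two-sided one-sample t-test of the segment's bin RD values against the
genome mean RD.
"""

from __future__ import annotations

import heapq
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .depth import BinnedDepth, gc_correct, normalized_rd

DEFAULT_BANDWIDTHS = (2, 4, 8, 16, 32, 64, 128)
DEFAULT_DEL_THRESHOLD = 0.75
DEFAULT_DUP_THRESHOLD = 1.25

DELETION = "deletion"
DUPLICATION = "duplication"


@dataclass(frozen=True)
class Segment:
    """A maximal run of bins with homogeneous RD (inclusive bin indices)."""

    first_bin: int
    last_bin: int
    mean_rd: float
    chrom: str = ""

    def __post_init__(self) -> None:
        if self.first_bin > self.last_bin:
            raise ValueError("first_bin must not exceed last_bin")

    @property
    def n_bins(self) -> int:
        return self.last_bin - self.first_bin + 1


@dataclass(frozen=True)
class CNVCall:
    """One deletion/duplication call in 0-based half-open bp coordinates."""

    chrom: str
    start: int
    end: int
    type: str
    normalized_rd: float
    p_value: float
    q0: float

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("call must have positive size")
        if self.type not in (DELETION, DUPLICATION):
            raise ValueError(f"unknown call type {self.type!r}")
        if self.type == DELETION and not self.normalized_rd < 1:
            raise ValueError("a deletion must have normalized RD < 1")
        if self.type == DUPLICATION and not self.normalized_rd > 1:
            raise ValueError("a duplication must have normalized RD > 1")
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p_value must lie in [0, 1]")

    @property
    def size(self) -> int:
        return self.end - self.start


def estimate_noise_sd(rd: np.ndarray) -> float:
    """Per-bin noise sd from first differences (robust to true CNV steps)."""
    rd = np.asarray(rd, dtype=float)
    if rd.size < 2:
        return 0.0
    return float(np.std(np.diff(rd)) / math.sqrt(2.0))


def _shift_direction(rd: np.ndarray, h: int, noise_sd: float) -> np.ndarray:
    """Sign of the mean-shift vector at bandwidth h for every bin."""
    n = len(rd)
    shift = np.zeros(n)
    sigma = h / 2.0
    for d in range(1, h + 1):
        w = math.exp(-0.5 * (d / sigma) ** 2)
        right = np.abs(rd[d:] - rd[:-d]) <= noise_sd
        shift[:-d] += w * d * right
        shift[d:] -= w * d * right
    return shift


MERGE_Z = 5.0  # significance scale for short-segment mean comparisons


def _merge_pass(segs: list[list[int]], rd_csum: np.ndarray, tol: float) -> bool:
    """One closest-pair-first agglomeration of adjacent segments.

    A pair merges when its mean difference is below
    ``tol * max(1, MERGE_Z * sqrt(1/n1 + 1/n2))``: long segments merge on
    the plain noise-sd floor, short ones on a t-like scale so that noise
    fragments (whose means are extreme *because* they are short) collapse
    while genuine copy-number steps (|delta RD| >= 0.5) survive.
    Mutates ``segs`` (list of [start, end) pairs); returns True if merged.
    """
    k = len(segs)
    if k < 2:
        return False
    seg_start = [s for s, _ in segs]
    seg_end = [e for _, e in segs]
    prev = list(range(-1, k - 1))
    nxt = list(range(1, k + 1))
    nxt[-1] = -1
    alive = [True] * k

    def mean(i: int) -> float:
        return (rd_csum[seg_end[i]] - rd_csum[seg_start[i]]) / (seg_end[i] - seg_start[i])

    def ratio(i: int, j: int) -> float:
        n_i = seg_end[i] - seg_start[i]
        n_j = seg_end[j] - seg_start[j]
        thresh = tol * max(1.0, MERGE_Z * math.sqrt(1.0 / n_i + 1.0 / n_j))
        return abs(mean(i) - mean(j)) / thresh

    heap = [(ratio(i, i + 1), i, i + 1) for i in range(k - 1)]
    heapq.heapify(heap)
    merged_any = False
    while heap:
        _, a, b = heapq.heappop(heap)
        if not (alive[a] and alive[b]) or nxt[a] != b:
            continue
        if ratio(a, b) >= 1.0:  # stale key: re-checked, dropped; re-inserted
            continue            # if a neighbouring merge changes it
        seg_end[a] = seg_end[b]
        alive[b] = False
        nxt[a] = nxt[b]
        merged_any = True
        if nxt[a] != -1:
            prev[nxt[a]] = a
            heapq.heappush(heap, (ratio(a, nxt[a]), a, nxt[a]))
        if prev[a] != -1:
            heapq.heappush(heap, (ratio(prev[a], a), prev[a], a))

    segs[:] = [[seg_start[i], seg_end[i]] for i in range(k) if alive[i]]
    return merged_any


def _absorb_pass(segs: list[list[int]], rd_csum: np.ndarray, min_len: int) -> bool:
    """Dissolve segments shorter than ``min_len`` bins into the adjacent
    segment with the closer mean (noise spikes below the smallest bandwidth
    cannot be genuine events).  Returns True if anything was absorbed."""
    if len(segs) < 2:
        return False

    def mean(seg: list[int]) -> float:
        return (rd_csum[seg[1]] - rd_csum[seg[0]]) / (seg[1] - seg[0])

    out: list[list[int]] = []
    changed = False
    for i, seg in enumerate(segs):
        if seg[1] - seg[0] >= min_len or (not out and i == len(segs) - 1):
            out.append(seg)
            continue
        right = segs[i + 1] if i + 1 < len(segs) else None
        if out and (
            right is None
            or abs(mean(out[-1]) - mean(seg)) <= abs(mean(right) - mean(seg))
        ):
            out[-1][1] = seg[1]  # absorb left
        else:
            right[0] = seg[0]  # absorb right (mutates upcoming segment)
        changed = True
    segs[:] = out
    return changed


def _refine_segments(
    bounds: list[int], rd: np.ndarray, tol: float, min_len: int
) -> list[tuple[int, int]]:
    """Alternate close-mean merging and sub-bandwidth spike absorption to a
    fixpoint; the result tiles [0, len(rd))."""
    csum = np.concatenate([[0.0], np.cumsum(rd)])
    segs = [[s, e] for s, e in zip(bounds[:-1], bounds[1:])]
    for _ in range(100):  # converges in a handful of rounds
        merged = _merge_pass(segs, csum, tol)
        absorbed = _absorb_pass(segs, csum, min_len)
        if not (merged or absorbed):
            break
    return [(s, e) for s, e in segs]


def mean_shift_partition(
    rd: Sequence[float] | np.ndarray,
    bandwidth_schedule: Sequence[int] = DEFAULT_BANDWIDTHS,
    noise_sd: float | None = None,
    chrom: str = "",
) -> list[Segment]:
    """Partition an RD vector into homogeneous segments tiling the vector."""
    rd = np.asarray(rd, dtype=float)
    if rd.size == 0:
        raise ValueError("cannot partition an empty RD vector")
    if not np.all(np.isfinite(rd)):
        raise ValueError("RD vector must be finite")
    if noise_sd is None:
        noise_sd = estimate_noise_sd(rd)
    n = len(rd)
    if n == 1 or noise_sd == 0.0:
        # constant or single-bin signal: breaks only at genuine jumps
        jumps = np.flatnonzero(np.diff(rd) != 0) + 1
        bounds = [0, *jumps.tolist(), n]
    else:
        breaks: set[int] = set()
        h_min = None
        for h in bandwidth_schedule:
            if h < 1 or h >= n:
                continue
            h_min = h if h_min is None else min(h_min, h)
            sign = _shift_direction(rd, h, noise_sd)
            flips = np.flatnonzero((sign[:-1] < 0) & (sign[1:] > 0)) + 1
            breaks.update(flips.tolist())
        if h_min is not None:
            # a bin with no RD-similar neighbour within +-h_min is an isolated
            # spike: cut it out so the absorb pass can dissolve it cleanly
            n_accepted = np.zeros(n)
            for d in range(1, h_min + 1):
                acc = np.abs(rd[d:] - rd[:-d]) <= noise_sd
                n_accepted[:-d] += acc
                n_accepted[d:] += acc
            for i in np.flatnonzero(n_accepted == 0):
                breaks.update((int(i), int(i) + 1))
        bounds = sorted(b for b in {0, n, *breaks} if 0 <= b <= n)
    if noise_sd > 0:
        min_len = max(1, min(h for h in bandwidth_schedule if h >= 1))
        merged = _refine_segments(bounds, rd, noise_sd, min_len)
    else:
        merged = [(s, e) for s, e in zip(bounds[:-1], bounds[1:])]
    return [
        Segment(first_bin=s, last_bin=e - 1, mean_rd=float(rd[s:e].mean()), chrom=chrom)
        for s, e in merged
    ]


def segment_p_value(seg_rd: np.ndarray, genome_mean: float) -> float:
    """Two-sided one-sample t-test p of the segment bins against genome mean."""
    seg_rd = np.asarray(seg_rd, dtype=float)
    if seg_rd.size < 2:
        return 1.0
    sd = seg_rd.std(ddof=1)
    if sd == 0.0:
        return 1.0 if seg_rd[0] == genome_mean else 0.0
    res = stats.ttest_1samp(seg_rd, popmean=genome_mean)
    return float(res.pvalue)


def call_segments(
    segments: Sequence[Segment],
    rd: np.ndarray,
    q0: np.ndarray,
    bin_size: int,
    chrom: str = "",
    genome_mean_rd: float = 1.0,
    del_threshold: float = DEFAULT_DEL_THRESHOLD,
    dup_threshold: float = DEFAULT_DUP_THRESHOLD,
) -> list[CNVCall]:
    """Turn segments into deletion/duplication calls with p and q0 attributes."""
    if not del_threshold < 1 < dup_threshold:
        raise ValueError("thresholds must satisfy del_threshold < 1 < dup_threshold")
    rd = np.asarray(rd, dtype=float)
    q0 = np.asarray(q0, dtype=float)
    calls: list[CNVCall] = []
    for seg in segments:
        if seg.last_bin >= len(rd):
            raise ValueError("segment extends beyond the RD vector")
        if seg.mean_rd < del_threshold:
            kind = DELETION
        elif seg.mean_rd > dup_threshold:
            kind = DUPLICATION
        else:
            continue
        lo, hi = seg.first_bin, seg.last_bin + 1
        calls.append(
            CNVCall(
                chrom=seg.chrom or chrom,
                start=seg.first_bin * bin_size,
                end=(seg.last_bin + 1) * bin_size,
                type=kind,
                normalized_rd=seg.mean_rd,
                p_value=segment_p_value(rd[lo:hi], genome_mean_rd),
                q0=float(q0[lo:hi].mean()),
            )
        )
    return calls


def run_caller(
    depth: BinnedDepth,
    bandwidth_schedule: Sequence[int] = DEFAULT_BANDWIDTHS,
    del_threshold: float = DEFAULT_DEL_THRESHOLD,
    dup_threshold: float = DEFAULT_DUP_THRESHOLD,
) -> list[CNVCall]:
    """GC-correct (if needed), normalize, partition and call, per chromosome."""
    needs_correction = any(c.corrected_count is None for c in depth.chroms.values())
    if needs_correction and depth.chroms:
        depth = gc_correct(depth)
    if not depth.chroms:
        return []
    rd_by_chrom = normalized_rd(depth)
    genome_rd = np.concatenate([
        rd[depth._usable_mask(depth.chroms[name])]
        for name, rd in rd_by_chrom.items()
    ])
    genome_mean = float(genome_rd.mean())
    noise_sd = estimate_noise_sd(genome_rd)
    calls: list[CNVCall] = []
    for name, c in depth.chroms.items():
        rd = rd_by_chrom[name]
        if rd.size == 0:
            continue
        segs = mean_shift_partition(rd, bandwidth_schedule, noise_sd=noise_sd, chrom=name)
        calls.extend(
            call_segments(
                segs, rd, c.q0_fraction, depth.bin_size, chrom=name,
                genome_mean_rd=genome_mean,
                del_threshold=del_threshold, dup_threshold=dup_threshold,
            )
        )
    calls.sort(key=lambda c: (c.chrom, c.start, c.end))
    return calls
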