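"""Binned read-depth signal: rebinning, GC-wave correction and bin-size selection.

The read-depth (RD) signal is the per-bin count of mapped reads in fixed,
non-overlapping windows.  Downstream calling works on the *normalized* RD
(corrected count divided by the genome-wide mean corrected count), so a
diploid region sits at 1.0, a heterozygous deletion near 0.5 and a
single-copy gain near 1.5 regardless of sequencing coverage.

Two systematic artefacts of short-read data are modelled here:

* *GC waves* — depth depends smoothly on local GC content.  Correction
  rescales each bin by the mean count of its 1%-wide GC stratum so every
  stratum ends up at the genome-wide mean.
* *Unmappable bins* — bins whose reads all carry zero mapping quality
  (``q0_fraction == 1``) are excluded from genome-wide statistics so dead
  zones do not deflate the mean.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, NamedTuple, Sequence

import numpy as np

GC_STRATUM_WIDTH = 0.01
MIN_STRATUM_BINS = 100


@dataclass
class ChromDepth:
    """Per-chromosome bin vectors (equal length)."""

    raw_count: np.ndarray
    gc_fraction: np.ndarray
    q0_fraction: np.ndarray
    corrected_count: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.raw_count = np.asarray(self.raw_count, dtype=float)
        self.gc_fraction = np.asarray(self.gc_fraction, dtype=float)
        self.q0_fraction = np.asarray(self.q0_fraction, dtype=float)
        n = len(self.raw_count)
        if len(self.gc_fraction) != n or len(self.q0_fraction) != n:
            raise ValueError("per-chromosome vectors must have equal length")
        if np.any(self.raw_count < 0):
            raise ValueError("counts must be non-negative")
        if np.any((self.gc_fraction < 0) | (self.gc_fraction > 1)):
            raise ValueError("gc_fraction must lie in [0, 1]")

    @property
    def n_bins(self) -> int:
        return len(self.raw_count)

    @property
    def best_count(self) -> np.ndarray:
        return self.corrected_count if self.corrected_count is not None else self.raw_count


@dataclass
class BinnedDepth:
    """Genome-wide binned depth: one :class:`ChromDepth` per chromosome."""

    bin_size: int
    chroms: dict[str, ChromDepth] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.bin_size <= 0:
            raise ValueError("bin_size must be positive")

    def items(self) -> Iterator[tuple[str, ChromDepth]]:
        return iter(self.chroms.items())

    @property
    def n_bins(self) -> int:
        return sum(c.n_bins for c in self.chroms.values())

    def _usable_mask(self, chrom: ChromDepth) -> np.ndarray:
        return chrom.q0_fraction < 1.0

    def genome_counts(self, corrected: bool | None = None) -> np.ndarray:
        """Concatenated counts over usable (mappable) bins of all chromosomes."""
        parts = []
        for c in self.chroms.values():
            vec = c.best_count if corrected is None else (
                c.corrected_count if corrected else c.raw_count)
            if vec is None:
                raise ValueError("corrected counts requested but not computed")
            parts.append(vec[self._usable_mask(c)])
        if not parts:
            return np.empty(0)
        return np.concatenate(parts)

    def mean_count(self, corrected: bool | None = None) -> float:
        counts = self.genome_counts(corrected)
        if counts.size == 0:
            raise ValueError("empty depth signal")
        return float(counts.mean())


class BinSizeChoice(NamedTuple):
    """Outcome of the mean/sd bin-size rule, with the ratio at every candidate."""

    bin_size: int
    ratio: float
    ratios: dict[int, float]


def rebin(depth: BinnedDepth, factor: int) -> BinnedDepth:
    """Coarsen the binning by an integer factor.

    Counts are summed over consecutive groups of ``factor`` bins; GC and q0
    fractions are averaged (bins have equal width so the length-weighted
    average is the plain mean).  A trailing partial group is dropped.
    """
    if factor <= 0:
        raise ValueError("rebin factor must be a positive integer")
    if factor == 1:
        return depth
    out: dict[str, ChromDepth] = {}
    for name, c in depth.chroms.items():
        n = (c.n_bins // factor) * factor
        shape = (-1, factor)
        out[name] = ChromDepth(
            raw_count=c.raw_count[:n].reshape(shape).sum(axis=1),
            gc_fraction=c.gc_fraction[:n].reshape(shape).mean(axis=1),
            q0_fraction=c.q0_fraction[:n].reshape(shape).mean(axis=1),
        )
    return BinnedDepth(bin_size=depth.bin_size * factor, chroms=out)


def gc_correct(depth: BinnedDepth) -> BinnedDepth:
    """Remove GC waves by stratified rescaling to the genome-wide mean.

    Each bin is scaled by ``global_mean / stratum_mean`` where its stratum is
    the 1%-wide GC band containing it.  Strata with fewer than
    ``MIN_STRATUM_BINS`` usable bins borrow the nearest populated stratum's
    mean.  A final uniform rescale pins the genome-wide mean of the corrected
    counts to the raw mean exactly, so correction is idempotent and
    mean-preserving.
    """
    raw_all = depth.genome_counts(corrected=False)
    if raw_all.size == 0 or raw_all.sum() == 0:
        raise ValueError("cannot GC-correct an all-zero or empty depth signal")
    global_mean = raw_all.mean()

    n_strata = int(round(1.0 / GC_STRATUM_WIDTH)) + 1
    sums = np.zeros(n_strata)
    counts = np.zeros(n_strata, dtype=int)
    strat_of: dict[str, np.ndarray] = {}
    for name, c in depth.chroms.items():
        strat = np.clip((c.gc_fraction / GC_STRATUM_WIDTH).astype(int), 0, n_strata - 1)
        strat_of[name] = strat
        usable = depth._usable_mask(c)
        np.add.at(sums, strat[usable], c.raw_count[usable])
        np.add.at(counts, strat[usable], 1)

    populated = counts >= MIN_STRATUM_BINS
    if not populated.any():
        # genome too small for stratification: every stratum borrows the
        # global mean, i.e. correction degenerates to the identity
        stratum_mean = np.full(n_strata, global_mean)
    else:
        stratum_mean = np.full(n_strata, np.nan)
        stratum_mean[populated] = sums[populated] / counts[populated]
        pop_idx = np.flatnonzero(populated)
        for s in np.flatnonzero(~populated):
            nearest = pop_idx[np.argmin(np.abs(pop_idx - s))]
            stratum_mean[s] = stratum_mean[nearest]
    stratum_mean = np.where(stratum_mean > 0, stratum_mean, global_mean)

    out: dict[str, ChromDepth] = {}
    for name, c in depth.chroms.items():
        corrected = c.raw_count * (global_mean / stratum_mean[strat_of[name]])
        out[name] = ChromDepth(
            raw_count=c.raw_count,
            gc_fraction=c.gc_fraction,
            q0_fraction=c.q0_fraction,
            corrected_count=corrected,
        )
    result = BinnedDepth(bin_size=depth.bin_size, chroms=out)
    # uniform rescale: exact mean preservation even when strata borrowed
    scale = global_mean / result.mean_count(corrected=True)
    for c in result.chroms.values():
        c.corrected_count = c.corrected_count * scale
    return result


def normalized_rd(depth: BinnedDepth) -> dict[str, np.ndarray]:
    """Corrected count divided by the genome-wide mean corrected count.

    Diploid baseline is 1.0.  Falls back to raw counts when no correction
    has been applied.
    """
    mean = depth.mean_count()
    if mean == 0:
        raise ValueError("zero mean depth")
    return {name: c.best_count / mean for name, c in depth.chroms.items()}


def select_bin_size(depth: BinnedDepth, candidates: Sequence[int]) -> BinSizeChoice:
    """Pick the bin size whose genome-wide mean(RD)/sd(RD) lies in [4, 5].

    ``depth`` must be binned at the smallest candidate; every other candidate
    must be an integer multiple of it (candidates are multiples of 100 bp by
    convention).  Returns the smallest qualifying candidate, or — when none
    lands in the band — the candidate whose ratio is nearest to 4.5.  For
    Poisson counts of mean λ the ratio is √λ, so e.g. a 30X-like mean of 20
    reads per 100 bp bin gives √20 ≈ 4.47 and keeps the 100 bp binning,
    while a 10X-like mean of 2 needs a ×10 rebin to qualify.
    """
    if not candidates:
        raise ValueError("candidate list must be non-empty")
    base = min(candidates)
    if depth.bin_size != base:
        raise ValueError(
            f"depth is binned at {depth.bin_size} bp but the smallest candidate is {base}")
    ratios: dict[int, float] = {}
    for cand in sorted(set(candidates)):
        if cand % base != 0:
            raise ValueError(f"candidate {cand} is not a multiple of the base bin {base}")
        counts = rebin(depth, cand // base).genome_counts(corrected=False)
        sd = counts.std()
        ratios[cand] = float(counts.mean() / sd) if sd > 0 else float("inf")
    for cand in sorted(ratios):
        if 4.0 <= ratios[cand] <= 5.0:
            return BinSizeChoice(cand, ratios[cand], ratios)
    best = min(ratios, key=lambda c: (abs(ratios[c] - 4.5), c))
    return BinSizeChoice(best, ratios[best], ratios)
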