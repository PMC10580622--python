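"""Synthetic genomes, ground-truth CNVs, binned depth and toy annotations.

Every generator is a pure function of its seed (``numpy.random.default_rng``)
so downstream stages can be tested end-to-end with known ground truth.

The depth model is the one a read-depth caller assumes: the count in a bin
of width ``b`` at diploid copy number is Poisson with mean
``coverage * b / read_length``; a region at copy number ``c`` scales that
mean by ``c / 2``; GC content multiplies it by a smooth unimodal wave
``g(gc)`` equal to 1 at the genome-median GC; and localized zero-MAPQ
hotspots mimic repetitive sequence where mapping confidence collapses.
An optional overdispersion knob switches the count noise to a
gamma-Poisson mixture to stress significance testing.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .caller import DELETION, DUPLICATION, CNVCall
from .depth import BinnedDepth, ChromDepth
from .genome import GenomeLayout, TruthCNV
from .annotate import GeneRecord

DEFAULT_BIN = 100
GC_WAVE_HALFRANGE = 0.15  # gc distance at which the wave reaches 1 - amplitude


def make_genome(
    n_chrom: int,
    mean_length: int,
    seed: int,
    bin_size: int = DEFAULT_BIN,
) -> GenomeLayout:
    """Chromosome lengths drawn uniformly in [0.7, 1.3] x mean, bin-aligned."""
    if n_chrom < 1:
        raise ValueError("n_chrom must be >= 1")
    if mean_length < 10 * bin_size:
        raise ValueError(f"mean_length must cover at least 10 bins of {bin_size} bp")
    rng = np.random.default_rng(seed)
    lengths = rng.uniform(0.7, 1.3, size=n_chrom) * mean_length
    lengths = np.maximum((lengths // bin_size).astype(int), 10) * bin_size
    return GenomeLayout(
        chromosomes=tuple((f"chr{i + 1}", int(l)) for i, l in enumerate(lengths))
    )


def implant_cnvs(
    genome: GenomeLayout,
    n_events: int,
    deletion_fraction: float = 0.65,
    size_range: tuple[int, int] = (5_000, 4_900_000),
    seed: int = 0,
    bin_size: int = DEFAULT_BIN,
    max_attempts_per_event: int = 1_000,
) -> list[TruthCNV]:
    """Non-overlapping ground-truth events with log-uniform sizes.

    Events are bin-aligned so boundary recovery can be scored in bins.
    Deletions get copy number 1 (70%) or 0; duplications 3 (70%) or 4.
    Raises when the requested events cannot be packed without overlap.
    """
    if not 0 <= deletion_fraction <= 1:
        raise ValueError("deletion_fraction must lie in [0, 1]")
    lo, hi = size_range
    if not 0 < lo <= hi:
        raise ValueError("invalid size_range")
    if n_events < 0:
        raise ValueError("n_events must be >= 0")
    rng = np.random.default_rng(seed)
    chrom_names = genome.names
    chrom_lengths = np.array([genome.length_of(c) for c in chrom_names], dtype=float)
    weights = chrom_lengths / chrom_lengths.sum()
    placed: dict[str, list[tuple[int, int]]] = {c: [] for c in chrom_names}
    out: list[TruthCNV] = []
    for _ in range(n_events):
        is_del = rng.random() < deletion_fraction
        cn = (1 if rng.random() < 0.7 else 0) if is_del else (3 if rng.random() < 0.7 else 4)
        for attempt in range(max_attempts_per_event):
            size = int(np.exp(rng.uniform(np.log(lo), np.log(hi))))
            size = max(bin_size, (size // bin_size) * bin_size)
            ci = rng.choice(len(chrom_names), p=weights)
            chrom = chrom_names[ci]
            clen = int(chrom_lengths[ci])
            if size > clen:
                continue
            start = int(rng.integers(0, (clen - size) // bin_size + 1)) * bin_size
            end = start + size
            if all(end <= s or start >= e for s, e in placed[chrom]):
                placed[chrom].append((start, end))
                out.append(TruthCNV(chrom=chrom, start=start, end=end, copy_number=cn))
                break
        else:
            raise RuntimeError(
                f"could not place event {len(out) + 1}/{n_events} without overlap; "
                "genome too small for the requested packing")
    out.sort()
    return out


def _gc_track(rng: np.random.Generator, n_bins: int) -> np.ndarray:
    """Smooth GC landscape: gaussian-filtered noise around 0.45."""
    raw = rng.normal(0.0, 1.0, size=n_bins)
    smooth = gaussian_filter1d(raw, sigma=25, mode="reflect") if n_bins > 1 else raw
    sd = smooth.std()
    if sd > 0:
        smooth = smooth / sd
    # typical mammalian short-bin GC range; the wave half-range coincides
    # with the clip half-width so gc_amplitude is the depression at the edge
    return np.clip(0.45 + 0.08 * smooth, 0.3, 0.6)


def gc_multiplier(gc: np.ndarray, median_gc: float, amplitude: float) -> np.ndarray:
    """Quadratic unimodal depth wave: 1 at median GC, 1 - amplitude at the half-range."""
    g = 1.0 - amplitude * ((gc - median_gc) / GC_WAVE_HALFRANGE) ** 2
    return np.clip(g, 0.05, None)


def simulate_depth(
    genome: GenomeLayout,
    truth: Sequence[TruthCNV],
    coverage: float,
    read_length: int = 150,
    bin_size: int = DEFAULT_BIN,
    gc_amplitude: float = 0.0,
    q0_hotspots: Sequence[tuple[str, int, int]] = (),
    seed: int = 0,
    overdispersion: float = 0.0,
) -> BinnedDepth:
    """Binned Poisson (or gamma-Poisson) depth with implanted truth events."""
    if coverage <= 0:
        raise ValueError("coverage must be positive")
    if read_length <= 0 or bin_size <= 0:
        raise ValueError("read_length and bin_size must be positive")
    for t in truth:
        if t.chrom not in genome or t.end > genome.length_of(t.chrom):
            raise ValueError(f"truth event {t} lies outside the genome")
    rng = np.random.default_rng(seed)
    base_mean = coverage * bin_size / read_length

    gc_by_chrom = {
        name: _gc_track(rng, length // bin_size) for name, length in genome.chromosomes
    }
    all_gc = np.concatenate(list(gc_by_chrom.values())) if gc_by_chrom else np.empty(0)
    median_gc = float(np.median(all_gc)) if all_gc.size else 0.45

    chroms: dict[str, ChromDepth] = {}
    for name, length in genome.chromosomes:
        n_bins = length // bin_size
        gc = gc_by_chrom[name]
        cn = np.full(n_bins, 2.0)
        for t in truth:
            if t.chrom == name:
                cn[t.start // bin_size: t.end // bin_size] = t.copy_number
        mean = base_mean * (cn / 2.0) * gc_multiplier(gc, median_gc, gc_amplitude)
        if overdispersion > 0:
            shape = 1.0 / overdispersion
            lam = np.where(mean > 0, rng.gamma(shape, 1.0, size=n_bins) * overdispersion * mean, 0.0)
            counts = rng.poisson(lam)
        else:
            counts = rng.poisson(mean)
        q0 = np.zeros(n_bins)
        for hc, hs, he in q0_hotspots:
            if hc == name:
                sl = slice(hs // bin_size, -(-he // bin_size))
                q0[sl] = rng.uniform(0.55, 1.0, size=len(q0[sl]))
        chroms[name] = ChromDepth(
            raw_count=counts.astype(float), gc_fraction=gc, q0_fraction=q0
        )
    return BinnedDepth(bin_size=bin_size, chroms=chroms)


def synth_callset(
    genome: GenomeLayout,
    n_calls: int,
    deletion_fraction: float = 0.65,
    seed: int = 0,
    size_range: tuple[int, int] = (1_000, 1_000_000),
) -> list[CNVCall]:
    """Raw call-shaped records that may overlap (feeds merge/compare stages).

    Attributes are drawn consistently with the call type: deletions at
    normalized RD 0.1-0.7, duplications at 1.3-2.5; p log-uniform in
    [1e-12, 1e-3]; q0 uniform in [0, 0.3].
    """
    if not 0 <= deletion_fraction <= 1:
        raise ValueError("deletion_fraction must lie in [0, 1]")
    if n_calls < 0:
        raise ValueError("n_calls must be >= 0")
    rng = np.random.default_rng(seed)
    names = genome.names
    lengths = np.array([genome.length_of(c) for c in names], dtype=float)
    weights = lengths / lengths.sum()
    lo, hi = size_range
    out: list[CNVCall] = []
    for _ in range(n_calls):
        ci = int(rng.choice(len(names), p=weights))
        clen = int(lengths[ci])
        size = min(int(np.exp(rng.uniform(np.log(lo), np.log(hi)))), clen)
        start = int(rng.integers(0, clen - size + 1))
        is_del = rng.random() < deletion_fraction
        out.append(
            CNVCall(
                chrom=names[ci],
                start=start,
                end=start + size,
                type=DELETION if is_del else DUPLICATION,
                normalized_rd=float(rng.uniform(0.1, 0.7) if is_del else rng.uniform(1.3, 2.5)),
                p_value=float(10 ** rng.uniform(-12, -3)),
                q0=float(rng.uniform(0.0, 0.3)),
            )
        )
    out.sort(key=lambda c: (c.chrom, c.start, c.end))
    return out


def make_annotation(
    genome: GenomeLayout,
    n_genes: int,
    seed: int = 0,
    size_range: tuple[int, int] = (1_000, 100_000),
) -> list[GeneRecord]:
    """Random non-degenerate gene intervals with stable sequential ids."""
    if n_genes < 0:
        raise ValueError("n_genes must be >= 0")
    rng = np.random.default_rng(seed)
    names = genome.names
    lengths = np.array([genome.length_of(c) for c in names], dtype=float)
    weights = lengths / lengths.sum()
    lo, hi = size_range
    out: list[GeneRecord] = []
    for i in range(n_genes):
        ci = int(rng.choice(len(names), p=weights))
        clen = int(lengths[ci])
        size = min(int(np.exp(rng.uniform(np.log(lo), np.log(hi)))), clen)
        start = int(rng.integers(0, clen - size + 1))
        out.append(
            GeneRecord(
                gene_id=f"GENE{i + 1:06d}",
                chrom=names[ci],
                start=start,
                end=start + size,
                name=f"gene{i + 1}",
            )
        )
    out.sort(key=lambda g: (g.chrom, g.start, g.end))
    return out
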