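"""Gene/CNVR intersection, 1 Mb gene-density tracks and longest-CNVR reports.

Gene coordinates are half-open internally (GTF's 1-based inclusive records
are converted on read, see :mod:`rdcnv.io`).  Strand is ignored: copy-number
events are unstranded.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .cnvr import CNVR
from .genome import GenomeLayout


@dataclass(frozen=True)
class GeneRecord:
    gene_id: str
    chrom: str
    start: int
    end: int
    name: str = ""

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("gene interval must be non-degenerate")


@dataclass(frozen=True)
class DensityTrack:
    """Per-chromosome windowed gene counts and genes-per-Mb densities."""

    window_size: int
    window_counts: Mapping[str, np.ndarray]  # a gene counts in every window it touches
    chrom_totals: Mapping[str, int]          # each gene counted exactly once
    density_per_mb: Mapping[str, float]      # total / (chrom length in Mb)


def gene_density(
    genes: Sequence[GeneRecord],
    genome: GenomeLayout,
    window: int = 1_000_000,
) -> DensityTrack:
    """Windowed gene counts plus per-chromosome genes/Mb.

    A gene increments every window its span intersects (for the track) but
    counts once for the chromosome total; per-chromosome density divides
    that total by the chromosome length in Mb.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    window_counts: dict[str, np.ndarray] = {}
    totals: dict[str, int] = {}
    for name, length in genome.chromosomes:
        n_win = -(-length // window)
        window_counts[name] = np.zeros(n_win, dtype=int)
        totals[name] = 0
    for g in genes:
        if g.chrom not in window_counts:
            raise ValueError(f"gene {g.gene_id} lies on unknown chromosome {g.chrom!r}")
        wc = window_counts[g.chrom]
        first = g.start // window
        last = (g.end - 1) // window
        wc[first:min(last, len(wc) - 1) + 1] += 1
        totals[g.chrom] += 1
    density = {
        name: totals[name] / (length / 1e6) for name, length in genome.chromosomes
    }
    return DensityTrack(
        window_size=window,
        window_counts=window_counts,
        chrom_totals=totals,
        density_per_mb=density,
    )


def genes_in_regions(
    regions: Sequence[CNVR],
    genes: Sequence[GeneRecord],
) -> dict[CNVR, list[str]]:
    """Map each region to the sorted gene ids intersecting it by >= 1 bp.

    Book-ended genes (gene ends where the region starts, or vice versa)
    have zero-length intersection and are not reported.
    """
    by_chrom: dict[str, list[GeneRecord]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    for lst in by_chrom.values():
        lst.sort(key=lambda g: g.start)
    out: dict[CNVR, list[str]] = {}
    for region in sorted(regions, key=lambda r: (r.chrom, r.start, r.end)):
        hits = [
            g.gene_id
            for g in by_chrom.get(region.chrom, [])
            if g.start < region.end and g.end > region.start
        ]
        out[region] = sorted(hits)
    return out


def longest_cnvrs(
    cnvrs: Sequence[CNVR],
    k: int,
    genes: Sequence[GeneRecord] = (),
) -> list[tuple[CNVR, int, list[str]]]:
    """Top-k CNVRs by length (ties by (chrom, start)), with their genes."""
    if k < 1:
        raise ValueError("k must be >= 1")
    ranked = sorted(cnvrs, key=lambda r: (-r.size, r.chrom, r.start))[:k]
    gene_map = genes_in_regions(ranked, genes) if genes else {r: [] for r in ranked}
    return [(r, r.size, gene_map[r]) for r in ranked]


def shared_genes(per_population: Mapping[str, set[str]]) -> set[str]:
    """Gene ids present in every population's set (exact intersection)."""
    if not per_population:
        raise ValueError("at least one population is required")
    sets = iter(per_population.values())
    out = set(next(sets))
    for s in sets:
        out &= s
    return out


def density_table(
    genome: GenomeLayout,
    genes: Sequence[GeneRecord],
    cnvr_sets: Mapping[str, Sequence[CNVR]] = {},
    window: int = 1_000_000,
) -> str:
    """Per-chromosome TSV: length (Mb), gene count, density, CNVR counts.

    One CNVR-count column per entry of ``cnvr_sets`` (population/coverage
    label -> CNVR list), mirroring per-breed per-coverage report tables.
    """
    track = gene_density(genes, genome, window)
    labels = list(cnvr_sets)
    counts = {
        lab: {name: 0 for name in genome.names} for lab in labels
    }
    for lab, cnvrs in cnvr_sets.items():
        for r in cnvrs:
            if r.chrom in counts[lab]:
                counts[lab][r.chrom] += 1
    header = ["chrom", "size_mb", "gene_count", "gene_density_per_mb", *labels]
    lines = ["\t".join(header)]
    for name, length in genome.chromosomes:
        row = [
            name,
            f"{length / 1e6:.2f}",
            str(track.chrom_totals[name]),
            f"{track.density_per_mb[name]:.2f}",
            *(str(counts[lab][name]) for lab in labels),
        ]
        lines.append("\t".join(row))
    return "\n".join(lines)


def ideogram_report(
    genome: GenomeLayout,
    genes: Sequence[GeneRecord],
    cnvrs: Sequence[CNVR],
    window: int = 1_000_000,
) -> str:
    """Plain-text per-window gene and CNVR counts (an ideogram without ink)."""
    track = gene_density(genes, genome, window)
    cnvr_counts = {
        name: np.zeros(len(track.window_counts[name]), dtype=int)
        for name in genome.names
    }
    for r in cnvrs:
        if r.chrom not in cnvr_counts:
            continue
        wc = cnvr_counts[r.chrom]
        first = r.start // window
        last = (r.end - 1) // window
        wc[first:min(last, len(wc) - 1) + 1] += 1
    lines = ["chrom\twindow_start\tgene_count\tcnvr_count"]
    for name in genome.names:
        for w, (gc, cc) in enumerate(zip(track.window_counts[name], cnvr_counts[name])):
            lines.append(f"{name}\t{w * window}\t{gc}\t{cc}")
    return "\n".join(lines)
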