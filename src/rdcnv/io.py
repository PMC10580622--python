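"""Readers and writers for all on-disk formats, plus the run configuration.

Coordinate conventions are confined to this module: BED and the binned
depth TSV are 0-based half-open; GTF/GFF and the caller text dialect are
1-based inclusive.  Everything in memory is 0-based half-open.

The caller text dialect is whitespace-separated::

    type  chrom:start-end  size  normalized_RD  p1  p2  p3  p4  q0

with 1-based inclusive coordinates and scientific notation tolerated in
the numeric columns.  This package computes a single t-test p-value and
writes it to all four p columns; the reader exposes all four and lets the
caller pick which one feeds the p filter (first by default).
"""

from __future__ import annotations

import os
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from .annotate import GeneRecord
from .caller import CNVCall
from .cnvr import CNVR
from .depth import BinnedDepth, ChromDepth
from .genome import GenomeLayout, TruthCNV

# ---------------------------------------------------------------- chrom.sizes


def write_chrom_sizes(genome: GenomeLayout, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, length in genome.chromosomes:
            fh.write(f"{name}\t{length}\n")


def read_chrom_sizes(path: str | Path) -> GenomeLayout:
    chroms = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            name, length = line.split()[:2]
            chroms.append((name, int(length)))
    return GenomeLayout(chromosomes=tuple(chroms))


# ---------------------------------------------------------------- depth TSV


def write_depth_tsv(depth: BinnedDepth, path: str | Path) -> None:
    """Columns: chrom, bin_start (0-based), raw_count, gc_fraction, q0_fraction
    (+ corrected_count when present); bin size in a header line."""
    has_corrected = all(
        c.corrected_count is not None for c in depth.chroms.values()
    ) and depth.chroms
    with open(path, "w") as fh:
        fh.write(f"# bin_size={depth.bin_size}\n")
        cols = "chrom\tbin_start\traw_count\tgc_fraction\tq0_fraction"
        fh.write(cols + ("\tcorrected_count\n" if has_corrected else "\n"))
        for name, c in depth.chroms.items():
            for i in range(c.n_bins):
                row = (
                    f"{name}\t{i * depth.bin_size}\t{c.raw_count[i]:g}"
                    f"\t{c.gc_fraction[i]:.6f}\t{c.q0_fraction[i]:.6f}"
                )
                if has_corrected:
                    row += f"\t{c.corrected_count[i]:.6f}"
                fh.write(row + "\n")


def read_depth_tsv(path: str | Path) -> BinnedDepth:
    bin_size = None
    data: dict[str, dict[str, list[float]]] = {}
    has_corrected = False
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("#"):
                if "bin_size=" in line:
                    bin_size = int(line.split("bin_size=")[1].split()[0])
                continue
            if line.startswith("chrom\t"):
                has_corrected = "corrected_count" in line
                continue
            if not line.strip():
                continue
            parts = line.split("\t")
            chrom = parts[0]
            d = data.setdefault(
                chrom, {"raw": [], "gc": [], "q0": [], "corr": []}
            )
            d["raw"].append(float(parts[2]))
            d["gc"].append(float(parts[3]))
            d["q0"].append(float(parts[4]))
            if has_corrected:
                d["corr"].append(float(parts[5]))
    if bin_size is None:
        raise ValueError(f"{path}: missing '# bin_size=' header line")
    chroms = {
        name: ChromDepth(
            raw_count=np.array(d["raw"]),
            gc_fraction=np.array(d["gc"]),
            q0_fraction=np.array(d["q0"]),
            corrected_count=np.array(d["corr"]) if has_corrected else None,
        )
        for name, d in data.items()
    }
    return BinnedDepth(bin_size=bin_size, chroms=chroms)


# ------------------------------------------------------- caller text dialect


def write_calls_native(calls: Sequence[CNVCall], path: str | Path) -> None:
    """1-based inclusive `type chrom:start-end size RD p1 p2 p3 p4 q0` lines."""
    with open(path, "w") as fh:
        for c in calls:
            region = f"{c.chrom}:{c.start + 1}-{c.end}"
            p = f"{c.p_value:.6g}"
            fh.write(
                f"{c.type}\t{region}\t{c.size}\t{c.normalized_rd:.6g}"
                f"\t{p}\t{p}\t{p}\t{p}\t{c.q0:.6g}\n"
            )


def read_calls_native(path: str | Path, p_column: int = 0) -> list[CNVCall]:
    """Parse the caller dialect; ``p_column`` in 0..3 picks the p filter source."""
    if not 0 <= p_column <= 3:
        raise ValueError("p_column must be in 0..3")
    out: list[CNVCall] = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split()
            kind, region = parts[0], parts[1]
            chrom, span = region.rsplit(":", 1)
            s1, e1 = span.split("-")
            ps = [float(x) for x in parts[4:8]]
            out.append(
                CNVCall(
                    chrom=chrom,
                    start=int(s1) - 1,
                    end=int(e1),
                    type=kind,
                    normalized_rd=float(parts[3]),
                    p_value=ps[p_column],
                    q0=float(parts[8]),
                )
            )
    return out


# ------------------------------------------------------------------- BED


def write_calls_bed(calls: Sequence[CNVCall], path: str | Path) -> None:
    """0-based half-open BED: chrom, start, end, type, RD, p, q0."""
    with open(path, "w") as fh:
        for c in calls:
            fh.write(
                f"{c.chrom}\t{c.start}\t{c.end}\t{c.type}"
                f"\t{c.normalized_rd:.6g}\t{c.p_value:.6g}\t{c.q0:.6g}\n"
            )


def read_calls_bed(path: str | Path) -> list[CNVCall]:
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            chrom, start, end, kind, rd, p, q0 = line.split("\t")[:7]
            out.append(
                CNVCall(
                    chrom=chrom, start=int(start), end=int(end), type=kind,
                    normalized_rd=float(rd), p_value=float(p), q0=float(q0),
                )
            )
    return out


def write_cnvrs_bed(cnvrs: Sequence[CNVR], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in cnvrs:
            fh.write(
                f"{r.chrom}\t{r.start}\t{r.end}\t{r.type}\t{r.n_members}\t{r.population}\n"
            )


def read_cnvrs_bed(path: str | Path) -> list[CNVR]:
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            parts = line.rstrip("\n").split("\t")
            chrom, start, end, kind, n_members = parts[:5]
            pop = parts[5] if len(parts) > 5 else ""
            out.append(
                CNVR(chrom=chrom, start=int(start), end=int(end), type=kind,
                     n_members=int(n_members), population=pop)
            )
    return out


def write_truth_bed(truth: Sequence[TruthCNV], path: str | Path) -> None:
    with open(path, "w") as fh:
        for t in truth:
            fh.write(f"{t.chrom}\t{t.start}\t{t.end}\t{t.copy_number}\n")


def read_truth_bed(path: str | Path) -> list[TruthCNV]:
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            chrom, start, end, cn = line.split("\t")[:4]
            out.append(TruthCNV(chrom=chrom, start=int(start), end=int(end),
                                copy_number=int(cn)))
    return out


# ------------------------------------------------------------------- GTF/GFF


def write_gtf(genes: Sequence[GeneRecord], path: str | Path) -> None:
    """One 1-based inclusive `gene` feature per record."""
    with open(path, "w") as fh:
        fh.write("##format: gtf\n")
        for g in genes:
            attrs = f'gene_id "{g.gene_id}"; gene_name "{g.name or g.gene_id}";'
            fh.write(
                f"{g.chrom}\trdcnv\tgene\t{g.start + 1}\t{g.end}\t.\t+\t.\t{attrs}\n"
            )


def read_annotation(path: str | Path) -> list[GeneRecord]:
    """GTF/GFF3 reader (gffutils-backed); prefers `gene` features, falling
    back to the per-gene_id union of transcripts when absent."""
    import gffutils

    with open(path) as fh:
        has_features = any(
            line.strip() and not line.startswith("#") for line in fh
        )
    if not has_features:
        return []
    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    genes: dict[str, GeneRecord] = {}

    def add(feature, gid: str, name: str) -> None:
        start0, end1 = feature.start - 1, feature.end
        if gid in genes:
            old = genes[gid]
            genes[gid] = GeneRecord(
                gene_id=gid, chrom=old.chrom,
                start=min(old.start, start0), end=max(old.end, end1),
                name=old.name or name,
            )
        else:
            genes[gid] = GeneRecord(
                gene_id=gid, chrom=feature.seqid, start=start0, end=end1, name=name
            )

    gene_feats = list(db.features_of_type("gene"))
    if gene_feats:
        for f in gene_feats:
            gid = f.attributes.get("gene_id", [f.id])[0]
            name = f.attributes.get("gene_name", f.attributes.get("Name", [""]))[0]
            add(f, gid, name)
    else:
        for ftype in ("transcript", "mRNA", "exon"):
            for f in db.features_of_type(ftype):
                gid = f.attributes.get("gene_id", [f.id])[0]
                name = f.attributes.get("gene_name", [""])[0]
                add(f, gid, name)
            if genes:
                break
    return sorted(genes.values(), key=lambda g: (g.chrom, g.start, g.gene_id))


# ------------------------------------------------------------------- config


@dataclass
class RunConfig:
    """Validated, fully serializable configuration for a pipeline run."""

    out_dir: str = "rdcnv_out"
    seed: int = 0
    bin_size_candidates: list[int] = field(default_factory=lambda: [100, 1000])
    del_threshold: float = 0.75
    dup_threshold: float = 1.25
    p_max: float = 0.01
    q0_max: float = 0.5
    min_size: int = 1_000
    max_size: int = 5_000_000
    coverage_denominator_bp: int | None = None
    populations: list[str] = field(default_factory=lambda: ["popA"])
    coverages: list[float] = field(default_factory=lambda: [30.0])
    read_length: int = 150

    def __post_init__(self) -> None:
        if not self.bin_size_candidates:
            raise ValueError("bin_size_candidates must be non-empty")
        if not self.del_threshold < 1 < self.dup_threshold:
            raise ValueError("caller thresholds must bracket 1.0")
        if not 0 < self.p_max <= 1:
            raise ValueError("p_max must lie in (0, 1]")

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def echo_into(self, out_dir: str | Path) -> None:
        os.makedirs(out_dir, exist_ok=True)
        self.to_yaml(Path(out_dir) / "effective_config.yaml")
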