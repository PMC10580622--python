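"""Concatenation of overlapping CNV calls into typed CNV regions (CNVRs).

Calls from one population that overlap by at least one base pair are merged
transitively into a CNVR spanning from the leftmost start to the rightmost
end of its members.  Book-ended calls (one ends exactly where the next
starts, zero-length intersection) are *not* merged.  A CNVR is typed
``deletion`` or ``duplication`` when all members agree and ``mixed`` when
both event types contribute.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

from .caller import DELETION, DUPLICATION, CNVCall
from .genome import GenomeLayout

MIXED = "mixed"


@dataclass(frozen=True)
class CNVR:
    chrom: str
    start: int
    end: int
    type: str
    n_members: int
    population: str = ""

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("CNVR must have positive length")
        if self.type not in (DELETION, DUPLICATION, MIXED):
            raise ValueError(f"unknown CNVR type {self.type!r}")
        if self.n_members < 1:
            raise ValueError("a CNVR needs at least one member call")

    @property
    def size(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class CNVRSummary:
    n_total: int
    n_deletion: int
    n_duplication: int
    n_mixed: int
    mean_length: float
    genomic_coverage_pct: float
    loss_gain_ratio: float


def merge_to_cnvrs(calls: Sequence[CNVCall], population: str = "") -> list[CNVR]:
    """Transitive closure of the >=1 bp overlap relation, per chromosome.

    Single left-to-right sweep over start-sorted calls: a call starting
    strictly before the running end extends the open cluster; a call
    starting at or after it closes the cluster (book-ends do not merge).
    """
    out: list[CNVR] = []
    ordered = sorted(calls, key=lambda c: (c.chrom, c.start, c.end))
    cluster: list[CNVCall] = []
    cur_end = -1

    def flush() -> None:
        if not cluster:
            return
        types = {c.type for c in cluster}
        kind = MIXED if len(types) == 2 else types.pop()
        out.append(
            CNVR(
                chrom=cluster[0].chrom,
                start=min(c.start for c in cluster),
                end=cur_end,
                type=kind,
                n_members=len(cluster),
                population=population,
            )
        )

    for call in ordered:
        if cluster and call.chrom == cluster[0].chrom and call.start < cur_end:
            cluster.append(call)
            cur_end = max(cur_end, call.end)
        else:
            flush()
            cluster = [call]
            cur_end = call.end
    flush()
    return out


def cnvr_summary(
    cnvrs: Sequence[CNVR],
    genome: GenomeLayout,
    denominator_bp: int | None = None,
) -> CNVRSummary:
    """Counts by type, mean length and percent genomic coverage.

    ``denominator_bp`` overrides the genome total as the coverage
    denominator (assemblies and their published totals sometimes disagree;
    the choice is the caller's).
    """
    denom = denominator_bp if denominator_bp is not None else genome.total_length
    if denom <= 0:
        raise ValueError("coverage denominator must be positive")
    n_del = sum(1 for r in cnvrs if r.type == DELETION)
    n_dup = sum(1 for r in cnvrs if r.type == DUPLICATION)
    n_mix = sum(1 for r in cnvrs if r.type == MIXED)
    lengths = [r.size for r in cnvrs]
    total_len = sum(lengths)
    return CNVRSummary(
        n_total=len(lengths),
        n_deletion=n_del,
        n_duplication=n_dup,
        n_mixed=n_mix,
        mean_length=total_len / len(lengths) if lengths else 0.0,
        genomic_coverage_pct=100.0 * total_len / denom,
        loss_gain_ratio=n_del / n_dup if n_dup > 0 else math.nan,
    )
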