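"""Cross-population overlap / unique / common statistics for CNVs and CNVRs.

Semantics mirror interval-intersection bookkeeping as done with bedtools:

* a *hit* is one ordered pair (i in A, j in B) intersecting by >= 1 bp —
  pairwise counting, so one coarse interval overlapping many fine ones
  contributes one hit per partner;
* an interval is *unique* to its set when it has no partner at all;
* a pair is *common* when chromosome, start and end are all identical
  (type is not compared).

The pairwise comparison grid used to report two-coverage studies puts the
same population's coverage-A-vs-coverage-B comparison on the diagonal,
population-vs-population at coverage A in the upper triangle and at
coverage B in the lower triangle.
"""

from __future__ import annotations

import heapq
import math
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

Interval = tuple[str, int, int]


def as_intervals(items: Iterable) -> list[Interval]:
    """Normalize CNVCall/CNVR objects or (chrom, start, end) tuples."""
    out: list[Interval] = []
    for it in items:
        if hasattr(it, "chrom"):
            out.append((it.chrom, int(it.start), int(it.end)))
        else:
            chrom, start, end = it[0], int(it[1]), int(it[2])
            out.append((chrom, start, end))
    return out


def _check_sorted(intervals: list[Interval], label: str) -> None:
    keys = [(c, s) for c, s, _ in intervals]
    if keys != sorted(keys):
        raise ValueError(
            f"interval set {label!r} is not sorted by (chrom, start); "
            "sort it before calling overlap()")


@dataclass(frozen=True)
class OverlapResult:
    n_hits: int
    n_unique_a: int
    n_unique_b: int
    n_common: int
    pct_perfect: float  # 100 * n_common / |A|; NaN when A is empty


def overlap(a: Iterable, b: Iterable) -> OverlapResult:
    """Pairwise >=1 bp intersection, uniqueness and exact-coordinate counts.

    Single sweep in start order per chromosome with end-ordered active
    heaps; equivalent to (and tested against) the all-pairs scan.
    """
    ia = as_intervals(a)
    ib = as_intervals(b)
    _check_sorted(ia, "a")
    _check_sorted(ib, "b")

    n_hits = 0
    a_hit = [False] * len(ia)
    b_hit = [False] * len(ib)

    # merge the two start-sorted streams chromosome by chromosome
    events = [(c, s, e, 0, i) for i, (c, s, e) in enumerate(ia)]
    events += [(c, s, e, 1, i) for i, (c, s, e) in enumerate(ib)]
    events.sort(key=lambda t: (t[0], t[1], t[3]))

    active: list[list[tuple[int, int]]] = [[], []]  # per side: heap of (end, idx)
    hit_flags = [a_hit, b_hit]
    cur_chrom: str | None = None
    for chrom, start, end, side, idx in events:
        if chrom != cur_chrom:
            active = [[], []]
            cur_chrom = chrom
        other = 1 - side
        while active[other] and active[other][0][0] <= start:
            heapq.heappop(active[other])
        if active[other]:
            n_hits += len(active[other])
            hit_flags[side][idx] = True
            for _, j in active[other]:
                hit_flags[other][j] = True
        heapq.heappush(active[side], (end, idx))

    coords_b = Counter(ib)
    n_common = sum(coords_b[iv] for iv in ia)
    return OverlapResult(
        n_hits=n_hits,
        n_unique_a=sum(1 for h in a_hit if not h),
        n_unique_b=sum(1 for h in b_hit if not h),
        n_common=n_common,
        pct_perfect=100.0 * n_common / len(ia) if ia else math.nan,
    )


def perfect_match_pct(a: Iterable, b: Iterable, basis: str = "a") -> float:
    """Percent of exact-coordinate matches.

    ``basis='a'`` (default): 100 * n_common / |A| — by convention A is the
    lower-coverage set.  ``basis='union'``: denominator is the number of
    distinct coordinates in A union B.  Empty denominator yields NaN.
    """
    ia, ib = as_intervals(a), as_intervals(b)
    res = overlap(sorted(ia), sorted(ib))
    if basis == "a":
        denom = len(ia)
    elif basis == "union":
        denom = len(set(ia) | set(ib))
    else:
        raise ValueError("basis must be 'a' or 'union'")
    return 100.0 * res.n_common / denom if denom else math.nan


@dataclass(frozen=True)
class ComparisonMatrix:
    populations: tuple[str, ...]
    cells: Mapping[tuple[str, str], OverlapResult]

    def cell(self, row: str, col: str) -> OverlapResult:
        return self.cells[(row, col)]

    def render(self) -> str:
        """Text table in the 'hits (unique of row set)' style."""
        lines = ["\t".join(["Breeds", *self.populations])]
        for r in self.populations:
            row = [r]
            for c in self.populations:
                res = self.cells[(r, c)]
                row.append(f"{res.n_hits} ({res.n_unique_a})")
            lines.append("\t".join(row))
        return "\n".join(lines)

    def to_tsv(self) -> str:
        lines = ["row\tcol\tn_hits\tn_unique_row\tn_unique_col\tn_common"]
        for r in self.populations:
            for c in self.populations:
                res = self.cells[(r, c)]
                lines.append(
                    f"{r}\t{c}\t{res.n_hits}\t{res.n_unique_a}\t{res.n_unique_b}\t{res.n_common}")
        return "\n".join(lines)


def build_matrix(
    callsets: Mapping[str, tuple[Sequence, Sequence]],
) -> ComparisonMatrix:
    """Pairwise grid over populations with (coverage A, coverage B) sets.

    Diagonal: A_i vs B_i (same population across coverages); upper triangle
    (row before column): A_i vs A_j; lower triangle: B_i vs B_j.
    """
    if not callsets:
        raise ValueError("at least one population is required")
    pops = tuple(callsets)
    prepared = {
        p: (sorted(as_intervals(av)), sorted(as_intervals(bv)))
        for p, (av, bv) in callsets.items()
    }
    cells: dict[tuple[str, str], OverlapResult] = {}
    for i, r in enumerate(pops):
        for j, c in enumerate(pops):
            if i == j:
                cells[(r, c)] = overlap(prepared[r][0], prepared[r][1])
            elif i < j:
                cells[(r, c)] = overlap(prepared[r][0], prepared[c][0])
            else:
                cells[(r, c)] = overlap(prepared[r][1], prepared[c][1])
    return ComparisonMatrix(populations=pops, cells=cells)
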