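"""Independent brute-force oracles for interval machinery.

Every oracle here is deliberately naive — all-pairs scans, union-find,
direct sweep over sorted endpoints — and shares no code with the package's
sweep-line implementations it is used to check.
"""

from __future__ import annotations

from collections import Counter

import numpy as np

Interval = tuple[str, int, int]


def brute_force_overlap(a: list[Interval], b: list[Interval]):
    """All-pairs hit/unique/common counts (numpy outer comparisons)."""
    n_hits = 0
    a_hit = np.zeros(len(a), dtype=bool)
    b_hit = np.zeros(len(b), dtype=bool)
    chroms = {c for c, _, _ in a} | {c for c, _, _ in b}
    for chrom in chroms:
        ai = [i for i, iv in enumerate(a) if iv[0] == chrom]
        bi = [i for i, iv in enumerate(b) if iv[0] == chrom]
        if not ai or not bi:
            continue
        a_s = np.array([a[i][1] for i in ai])
        a_e = np.array([a[i][2] for i in ai])
        b_s = np.array([b[i][1] for i in bi])
        b_e = np.array([b[i][2] for i in bi])
        inter = (a_s[:, None] < b_e[None, :]) & (a_e[:, None] > b_s[None, :])
        n_hits += int(inter.sum())
        a_hit[np.array(ai)[inter.any(axis=1)]] = True
        b_hit[np.array(bi)[inter.any(axis=0)]] = True
    cb = Counter(b)
    n_common = sum(cb[iv] for iv in a)
    return {
        "n_hits": n_hits,
        "n_unique_a": int((~a_hit).sum()),
        "n_unique_b": int((~b_hit).sum()),
        "n_common": n_common,
    }


def union_find_merge(intervals: list[Interval]) -> list[Interval]:
    """Transitive >=1 bp overlap closure by explicit union-find over all pairs."""
    n = len(intervals)
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(n):
        ci, si, ei = intervals[i]
        for j in range(i + 1, n):
            cj, sj, ej = intervals[j]
            if ci == cj and si < ej and sj < ei:
                parent[find(i)] = find(j)
    groups: dict[int, list[Interval]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(intervals[i])
    merged = [
        (g[0][0], min(s for _, s, _ in g), max(e for _, _, e in g))
        for g in groups.values()
    ]
    return sorted(merged)


def sweep_union_length(intervals: list[Interval]) -> int:
    """Total length of the interval union via endpoint sweep per chromosome."""
    total = 0
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for c, s, e in intervals:
        by_chrom.setdefault(c, []).append((s, e))
    for ivs in by_chrom.values():
        ivs.sort()
        cur_s, cur_e = ivs[0]
        for s, e in ivs[1:]:
            if s > cur_e:
                total += cur_e - cur_s
                cur_s, cur_e = s, e
            else:
                cur_e = max(cur_e, e)
        total += cur_e - cur_s
    return total


def random_intervals(
    rng: np.random.Generator,
    n: int,
    n_chrom: int = 3,
    span: int = 1_000_000,
    max_len: int = 50_000,
) -> list[Interval]:
    out: list[Interval] = []
    for _ in range(n):
        chrom = f"chr{rng.integers(1, n_chrom + 1)}"
        start = int(rng.integers(0, span))
        length = int(rng.integers(1, max_len))
        out.append((chrom, start, start + length))
    return sorted(out)
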