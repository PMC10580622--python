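"""Cross-population overlap statistics at two sequencing coverages.

The comparison grid mirrors two-coverage study reports: the diagonal
compares one population's low- vs high-coverage callsets, the upper
triangle compares populations at the low coverage, the lower triangle at
the high coverage.  Cells print as 'hits (unique of the row set)'.
"""

import rdcnv

genome = rdcnv.make_genome(1, 5_000_000, seed=30)
callsets = {}
for i, pop in enumerate(["murrah", "surti", "jaffarabadi"]):
    low = rdcnv.synth_callset(genome, 60, seed=31 + 2 * i,
                              size_range=(5_000, 60_000))
    high = rdcnv.synth_callset(genome, 180, seed=32 + 2 * i,
                               size_range=(1_000, 30_000))
    callsets[pop] = (low, high)

matrix = rdcnv.build_matrix(callsets)
print(matrix.render())
diag = matrix.cell("murrah", "murrah")
print(f"\nmurrah low vs high coverage: {diag.n_hits} overlapping pairs, "
      f"{diag.n_unique_a} low-coverage calls with no partner, "
      f"{diag.n_common} coordinate-identical.")
pct = rdcnv.perfect_match_pct(callsets["murrah"][0], callsets["murrah"][1])
print(f"perfect-match percent (low-coverage basis): {pct:.2f}%")
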