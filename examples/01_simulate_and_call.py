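"""Simulate read depth over a small diploid genome and call CNVs.

Builds a 10 Mb genome with 20 implanted deletions/duplications, simulates
30X binned Poisson depth with a GC wave, then runs GC correction,
mean-shift segmentation and filtering, and reports how many implanted
events were recovered.
"""

import rdcnv

genome = rdcnv.make_genome(n_chrom=1, mean_length=10_000_000, seed=1)
truth = rdcnv.implant_cnvs(genome, n_events=20, seed=2,
                           size_range=(1_000, 200_000))
depth = rdcnv.simulate_depth(genome, truth, coverage=30, read_length=150,
                             bin_size=100, gc_amplitude=0.1, seed=3)

calls = rdcnv.apply_filters(rdcnv.run_caller(depth))

n_recovered = sum(
    1 for t in truth
    if any(c.start < t.end and c.end > t.start
           and c.type == ("deletion" if t.copy_number < 2 else "duplication")
           for c in calls)
)
print(f"implanted events : {len(truth)}")
print(f"filtered calls   : {len(calls)}")
print(f"recovered        : {n_recovered}/{len(truth)}")
print("first call       :", calls[0])
# 'recovered' counts truth events overlapped by a call of the correct type;
# at 30X nearly every event spanning >= 10 bins should be found.
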