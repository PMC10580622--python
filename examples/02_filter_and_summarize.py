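"""Apply the post-calling quality filters and summarize a callset.

A call survives when p < 0.01 (t-test), q0 <= 0.5 and 1 kb <= size <= 5 Mb.
The loss/gain ratio is the deletion/duplication count ratio; in cattle and
buffalo resequencing studies it typically lands well above 1.
"""

import rdcnv

genome = rdcnv.make_genome(2, 5_000_000, seed=10)
raw = rdcnv.synth_callset(genome, n_calls=2_000, deletion_fraction=0.65,
                          seed=11)

kept = rdcnv.apply_filters(raw, rdcnv.FilterPolicy())
s = rdcnv.summarize(kept)

print(f"raw calls        : {len(raw)}")
print(f"after filters    : {s.n_total}")
print(f"deletions        : {s.n_deletion}")
print(f"duplications     : {s.n_duplication}")
print(f"loss/gain ratio  : {s.loss_gain_ratio:.2f}")
print(f"mean size (bp)   : {s.mean_size:,.0f}")
# the ratio tracks the 0.65 deletion fraction used by the generator
# (0.65/0.35 = 1.86) up to binomial noise.
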