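# rdcnv

Read-depth CNV calling, CNVR construction and cross-population comparison
for whole-genome resequencing studies — with a synthetic-data module that
makes every stage testable against known ground truth.

## The problem

Copy number variants (CNVs) — deletions and duplications from ~1 kb up to
a few Mb — are a major source of structural variation in livestock and
other diploid genomes. The standard way to map them from short-read WGS is
the *read-depth* approach: bin the genome into fixed non-overlapping
windows, count mapped reads per bin, and look for runs of bins whose depth
departs from the diploid expectation. `rdcnv` implements that pipeline as
a small, fully tested Python library:

1. **Binned depth.** The RD signal in a bin of width *b* at coverage *c*
   and read length *ℓ* has expectation λ = *c·b/ℓ* at copy number 2; a
   region at copy number *k* scales it by *k*/2. The working bin size is
   chosen so that mean(RD)/sd(RD) lands in the recommended band [4, 5]
   (for Poisson counts the ratio is √λ, so e.g. ~20 reads/bin qualifies).
2. **GC-wave correction.** Depth covaries smoothly with local GC. Each bin
   is rescaled by `global_mean / stratum_mean` over 1%-wide GC strata, which
   flattens the wave while preserving the genome-wide mean.
3. **Mean-shift segmentation.** Each bin receives a shift direction toward
   the kernel-weighted mean of RD-similar neighbours within ±*h* bins,
   over a multi-scale bandwidth schedule; breakpoints fall where the
   direction flips. Segments are then re-merged unless their means differ
   significantly relative to the noise sd.
4. **Calling and filtering.** Segments with mean normalized RD < 0.75
   become deletions, > 1.25 duplications, with a one-sample t-test p-value
   against the genome mean and a zero-mapping-quality (q0) fraction.
   Filters: p < 0.01, q0 ≤ 0.5, 1 kb ≤ size ≤ 5 Mb.
5. **CNVRs.** Per population, calls overlapping by ≥ 1 bp are concatenated
   transitively into CNV regions typed deletion / duplication / mixed, with
   mean length and percent genomic coverage summaries.
6. **Comparison.** Overlapping (≥ 1 bp), unique (no partner) and common
   (identical coordinates) counts within and across populations and
   coverages, in a bedtools-equivalent sweep-line implementation.
7. **Annotation.** Gene–CNVR intersection from GTF/GFF, gene density in
   1 Mb windows, longest-CNVR reports and cross-population shared genes.

## Worked example

`examples/01_simulate_and_call.py` implants 20 CNVs in a simulated 10 Mb
genome, generates 30X binned depth with a GC wave, and runs the full
caller:

```
implanted events : 20
filtered calls   : 20
recovered        : 20/20
first call       : CNVCall(chrom='chr1', start=572100, end=578700,
                   type='deletion', normalized_rd=0.56, p_value=2.5e-27, q0=0.0)
```

All 20 implanted events are recovered by a call of the correct type; the
first is a heterozygous deletion (normalized RD ≈ 0.5, i.e. one copy lost)
whose boundaries match the implanted event to within a bin or two. The
other examples cover filtering summaries, CNVR merging, the two-coverage
comparison matrix, and gene annotation.

The same pipeline is available as a CLI for file-based runs:

```bash
rdcnv all -o run_dir --seed 1        # simulate → call → filter → cnvr → annotate
```

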