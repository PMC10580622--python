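# Methods

This note records the models, parameter choices and numerical conventions
behind `rdcnv`, and what the synthetic-data tests do and do not establish
about behaviour on real sequencing data.

## Depth model

A bin of width *b* (bp) at sequencing coverage *c* and read length *ℓ*
receives a Poisson count with mean

    λ = (c · b / ℓ) · (k / 2) · g(GC)

where *k* is the local copy number (2 = diploid) and *g* is the GC-wave
multiplier. The Poisson assumption is the one read-depth callers make
after PCR-duplicate removal; an optional `overdispersion` parameter
switches to a gamma–Poisson mixture (variance = λ(1 + od·λ)) for stress
testing the significance stage. At the study-like settings — 30X with
150 bp reads and 100 bp bins, or 10X with 250 bp reads and 1000 bp bins —
λ is about 20 and 40 reads per bin respectively.

The GC multiplier is a quadratic centred at the genome-median GC,

    g(gc) = 1 − a · ((gc − gc_med) / 0.15)²   (clipped below at 0.05),

so `gc_amplitude` *a* is exactly the fractional depth depression at the
edge of the simulated GC range. The simulated GC landscape is
Gaussian-filtered noise (sd 0.08 around 0.45, clipped to [0.30, 0.60]),
which matches the bulk GC spread of mammalian short bins; it does not
reproduce isochore-scale structure or extreme-GC promoter islands.

Zero-mapping-quality (q0) hotspots assign each bin inside a declared
region a q0 fraction drawn uniformly above 0.5; all other bins have q0 = 0.
This is a per-bin caricature of repeat-driven mapping ambiguity — there is
no read-level mapping model — but it is sufficient to exercise the q0
filter and the convention that bins with q0 = 1 (dead zones) are excluded
from genome-wide statistics so they cannot deflate the mean.

## Bin-size rule

`select_bin_size` rebins the base signal by integer factors and returns
the smallest candidate whose genome-wide mean(RD)/sd(RD) falls in [4, 5],
or, if none does, the candidate nearest to 4.5 (ties to the smaller
candidate). For Poisson counts the ratio is √(λ·factor), so the analytic
prediction is testable exactly. The ratio is interpreted as mean/sd — the
only reading under which a target band of 4–5 is dimensionally sensible
for count data of this magnitude.

## GC correction

Stratified rescaling in 1%-wide GC strata: every bin is multiplied by
`global_mean / stratum_mean`; strata with fewer than 100 usable bins
borrow the nearest populated stratum's mean; a final uniform rescale pins
the corrected genome-wide mean to the raw mean exactly. This makes the
correction idempotent and mean-preserving by construction. The stratum
width and the 100-bin occupancy floor follow the standard practice of
read-depth callers; they are not sensitive choices at ≥10⁴ bins.

## Segmentation

Mean-shift partitioning runs over a bandwidth schedule of
(2, 4, 8, 16, 32, 64, 128) bins. At bandwidth *h*, bin *i*'s shift is
Σ_d w(d)·d over neighbours at offset d ∈ [−h, h] whose RD lies within one
noise sd of rd_i, with Gaussian positional weights (sd = h/2). Candidate
breakpoints are the −→+ sign flips, pooled over all bandwidths; a bin with
no RD-similar neighbour at the smallest bandwidth is cut out as an
isolated spike.

The noise sd is estimated as sd(first differences)/√2, which is immune to
genuine copy-number steps (each step contributes one outlying difference).

Candidate segments are then refined to a fixpoint by alternating two
passes:

* **merge** — adjacent segments merge when their mean difference is below
  `σ · max(1, Z·√(1/n₁ + 1/n₂))` with Z = 5, closest pair first. The plain
  σ floor governs long segments; the √(1/n) inflation is needed because
  small-bandwidth sign flips *select* short fragments for extreme means —
  under a fixed-σ rule, noise never collapses and long events shatter into
  fragments that the minimum-size filter then deletes piecemeal. Z = 5
  leaves a genuine one-copy step (|ΔRD| = 0.5) detectable down to ~10 bins
  at 30X-like noise (σ ≈ 0.22) while suppressing spurious short segments.
* **absorb** — segments shorter than the smallest bandwidth dissolve into
  the neighbour with the closer mean; events below the detection scale
  cannot be genuine and would otherwise block merging across them.

Segments always tile the input vector. Calling uses normalized RD
thresholds 0.75 (deletion) and 1.25 (duplication) — midway between the
diploid baseline and a single-copy change (0.5 / 1.5) — and a two-sided
one-sample t-test of the segment's bin RDs against the genome mean RD.
One-sample is the minimal reading of "t-test significance" for a segment
against its genome; single-bin segments get p = 1 (no within-segment
variance to test against). Adjacent same-direction calls are *not* joined
by the caller; concatenation is the CNVR stage's job, keeping the two
stages independently testable.

## Filters

Defaults: p < 0.01 (strict), q0 ≤ 0.5 (a call at exactly 0.5 survives),
1 kb ≤ size ≤ 5 Mb (inclusive at both bounds, so exactly-1 kb and
exactly-5 Mb calls survive). The boundary semantics are isolated in a
single predicate and unit-tested explicitly; the q0-at-exactly-0.5 choice
is the literal reading of "a q0 filter of 0.5" and can be changed in one
place if a stricter convention is wanted.

## CNVRs and comparison

CNVR merging is the transitive closure of the ≥1 bp overlap relation per
chromosome (one left-to-right sweep over start-sorted calls). Book-ended
calls — zero-length intersection — do not merge. Typing is strict:
deletion/duplication when all members agree, mixed otherwise; no
frequency-weighted (e.g. 80%) rules. Genomic coverage divides the summed
CNVR lengths by the chromosome-sizes total; the denominator is
configurable because published assembly totals and the round figures
quoted alongside them frequently disagree.

Overlap statistics count *pairs*: one coarse low-coverage interval
overlapping ten fine high-coverage intervals contributes ten hits. This
pairwise convention is the only one under which within-study hit counts
can exceed the smaller set's size, as two-coverage comparisons routinely
report. "Unique" counts intervals with no partner; "common" requires
identical chrom/start/end (type ignored). The perfect-match percent
defaults to the smaller-coverage set as denominator and can be switched to
the union basis. The rendered matrix places the within-population
cross-coverage comparison on the diagonal, low-coverage pairs in the upper
triangle and high-coverage pairs in the lower; the parenthesised unique
count is that of the row-label set.

## Annotation

GTF/GFF records (1-based inclusive) are converted to half-open on read;
`gene` features are preferred, with a fallback to the per-`gene_id` union
of transcript/mRNA/exon features. Strand is ignored (CNVs are
unstranded). Gene density uses 1 Mb windows; a gene increments every
window its span intersects but counts once in per-chromosome totals — both
tallies are available since either convention appears in published
density tables.

## Synthetic data: scope of the guarantees

The generators are pure functions of their seeds. Ground-truth events are
non-overlapping and bin-aligned by construction, so recovery experiments
measure the caller, not placement ambiguity; overlapping inputs for the
CNVR/comparison stages come from `synth_callset`, which draws call-shaped
records directly. Default event sizes are log-uniform, with deletions at
65% — the upper end of what resequencing CNV studies in bovids report.

Problem sizes in the test and acceptance runs: a 10 Mb single-chromosome
genome at 30X (10⁵ bins of 100 bp) with 20 implanted events for recovery;
three event-free 10 Mb simulations for the false-positive rate; 2×10⁵-bin
Poisson signals for the bin-size rule; 10⁵ bins for GC-wave checks. These
complete in seconds while keeping every per-bin statistic in its
large-sample regime.

Passing tests establish correctness of the algorithms under the stated
depth model. They do not establish performance on real BAMs: mappability
structure, reference errors, segmental duplications, dispersed repeats
and library artefacts are outside the model, and the caller's text-dialect
reader exists precisely so calls from a production read-depth caller can
be fed into the downstream (filter → CNVR → comparison → annotation)
stages instead.

## Known limitations

* No read-level simulation (FASTQ/BAM) and no BAM ingestion; the binned
  depth TSV is the contract.
* The significance model reproduces the *shape* of a read-depth caller's
  t-test, not any specific tool's e-values or Gaussian-tail corrections.
* Breakpoint resolution is bounded by the bin size; sub-bin precision is
  not attempted.
* Mixed-type CNVRs inherit no quantitative dosage estimate; members'
  normalized RD values are not propagated into the region record.
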