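"""Gene annotation of CNVRs: density track, overlapped genes, longest regions.

Gene density uses 1 Mb windows (a gene counts in every window it touches,
once per chromosome total); the longest-CNVR report lists the top regions
by length with the genes they harbour.
"""

import rdcnv

genome = rdcnv.make_genome(2, 5_000_000, seed=40)
genes = rdcnv.make_annotation(genome, n_genes=200, seed=41)
calls = rdcnv.synth_callset(genome, n_calls=120, seed=42)
cnvrs = rdcnv.merge_to_cnvrs(calls, population="pandharpuri")

track = rdcnv.gene_density(genes, genome, window=1_000_000)
for chrom, dens in track.density_per_mb.items():
    print(f"{chrom}: {track.chrom_totals[chrom]} genes, "
          f"{dens:.2f} genes/Mb")

print("\ntop 3 longest CNVRs and their genes:")
for region, length, ids in rdcnv.longest_cnvrs(cnvrs, 3, genes):
    shown = ", ".join(ids[:4]) + ("..." if len(ids) > 4 else "")
    print(f"  {region.chrom}:{region.start}-{region.end} "
          f"({length:,} bp, {region.type}): {shown or 'no genes'}")

per_pop = {
    "popA": set(g for ids in rdcnv.genes_in_regions(cnvrs, genes).values()
                for g in ids),
    "popB": {g.gene_id for g in genes[:100]},
}
print(f"\ngenes shared by all populations: {len(rdcnv.shared_genes(per_pop))}")
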