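"""Rediscover a methyltransferase specificity without a reference genome.

Simulates an E. coli-like genome methylated only at CCWGG (second C, the Dcm
specificity), deconvolves the reads, and runs the k-mer enrichment pipeline:
8-mer contexts around each cytosine call, exact binomial test against the
background methylation level with Bonferroni correction, average-linkage
clustering of the enriched 8-mers, and IUPAC consensus per cluster.  The two
clusters should read CCAGG and CCTGG, merging to CCWGG.
"""

import methylsnp as ms

genome = ms.generate_genome(50_000, gc=0.5, seed=21, name="ecoli_like")
truth = ms.assign_methylation(
    genome,
    ms.MethylationModel("motif", motifs=[("CCWGG", 1, 1.0)]),
    seed=22,
)
config = ms.SimConfig(
    n_fragments=4_000, read_length=150, conversion_rate=0.99, seed=23
)
pairs = ms.simulate_read_pairs(genome, truth, config)
results, _, _ = ms.deconvolve_batch(
    ((p.id, p.r1_seq, p.r1_qual, p.r2_seq, p.r2_qual) for p in pairs),
    trim=False,
)
reads = [(r.sequence, r.methylation) for r in results if r.status == "deconvolved"]

enrichment, clusters = ms.discover_motifs(reads, n_clusters=2, seed=24)
print(f"methylated sites in truth : {len(truth)}")
print(f"background level P0       : {enrichment.p0:.4f}")
print(f"8-mers tested             : {enrichment.m}")
print(f"significantly enriched    : {len(enrichment.significant)}")
for cl in clusters:
    print(
        f"  cluster of {len(cl.kmers):>3} 8-mers -> consensus {cl.consensus}"
        f"  (core positions 3-7: {cl.consensus[2:7]})"
    )
union = ms.consensus_motif([m for cl in clusters for m in cl.members])
print(f"merged consensus          : {union.consensus[2:7]} (W = A or T)")
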