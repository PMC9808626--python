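# methylsnp

Analysis toolkit for **hairpin dual-readout bisulfite sequencing** — libraries
in which each genomic fragment is read as a linked pair: Read1 is the
bisulfite-converted original strand (methylation readout) and Read2 is a
conversion-resistant copy synthesized with 5-methyl-dCTP (four-base sequence
readout). Because both readouts come from the same molecule, methylation and
genetic variation can be phased at single-molecule resolution, and
methylation can be called with no reference genome at all.

The package is aimed at epigenomics analysts working with such libraries (or
developing protocols for them): it covers the complete computational path
from raw paired FASTQ to per-site, per-region and per-allele methylation
tables and reference-free methyltransferase motif calls, together with a
protocol-faithful simulator that provides exact ground truth for validation.

## What it computes

**Read deconvolution.** After adapter trimming, each pair is compared cycle
by cycle. With b₁ the Read1 base and b₂ the Read2 base:

| b₁ / b₂ | call |
|---|---|
| C / C | methylated cytosine (5mC) |
| T / C | unmethylated cytosine (converted) |
| b₁ = b₂ (non-C) | agreement, base confirmed |
| anything else | disagreement (bisulfite damage, nick-translation or sequencing error) |

The output is a four-base read, a methylation-call string in the Bismark XM
alphabet (`Z/z` CpG, `X/x` CHG, `H/h` CHH, `U/u` unknown context, `.`
elsewhere) and an adjusted quality string. At disagreements the Read1 base
is kept; its quality is set to 0 (reference-free mode) or to an empirical
Phred score Q = round(−10·log₁₀(1−p)) where p = (x+1)/(N+2) is the posterior
probability that the Read1 base is correct, learned per (reference base,
substitution type, cycle bin) stratum from a first-pass alignment
(reference-dependent mode). Pairs with a disagreement fraction above 10%
(configurable) are rejected as undeconvolvable.

**Alignment filtering.** Unique-mapping selection (AS tag present without
XS, or AS ≠ XS), PCR-duplicate removal (same oriented position *and* same
sequence), XM tagging of alignments from the deconvolution report, and
removal of reads with ≥ 3 methylated non-CpG calls (incomplete conversion).

**Methylation quantification.** Per-site pileups (X methylated of N calls),
bisulfite conversion rate `100·Σ(N−X)/ΣN` on an unmethylated spike-in or on
non-CpG contexts, region-level methylation `ΣX/ΣN` over CpG calls in BED
intervals (regions under 50 calls are reported as filtered out, not as 0),
and allele-specific methylation: reads are split by the base they carry at a
heterozygous SNP and each group is exported as a DSS-format count table
(`chr pos N X`).

**Motif discovery (reference-free).** Every cytosine call is embedded in its
8-mer context (3 nt up, 4 nt down, the assayed C at index 3; reads with more
than one methylated call are excluded). Per distinct 8-mer with k methylated
out of n calls, the P-value is `1 − BinomCDF(k; n, P0)` with P0 = Σk/Σn the
background methylation level, Bonferroni-corrected at α = 10⁻⁴. Enriched
8-mers are clustered (average linkage, Hamming distance) and summarized as
position frequency matrices and IUPAC consensus motifs.

**Simulator.** `generate_genome` / `assign_methylation` /
`simulate_read_pairs` emulate the wet protocol: fragmentation, strand
copying, bisulfite conversion of the original strand (default 97.5%
conversion), sequencing errors, optional hairpin-adapter read-through and a
configurable fraction of conventional (undeconvolvable) bisulfite pairs —
with exact per-site and per-read ground truth, so every downstream stage is
testable without any data download.

## Worked example

`examples/03_motif_discovery.py` simulates a bacterial genome methylated
only at CCWGG (second C — the *E. coli* Dcm specificity), deconvolves the
reads and reruns the discovery pipeline:

```
methylated sites in truth : 206
background level P0       : 0.0114
8-mers tested             : 10026
significantly enriched    : 64
  cluster of  32 8-mers -> consensus HBCCAGGN  (core positions 3-7: CCAGG)
  cluster of  32 8-mers -> consensus DVCCTGGS  (core positions 3-7: CCTGG)
merged consensus          : CCWGG (W = A or T)
```

The 64 enriched 8-mers split into a CCAGG and a CCTGG context cluster;
merging them recovers the degenerate Dcm site CCWGG (W = A/T). P0 ≈ 0.011
is the background: ~1% of unmethylated cytosines escape conversion and read
as methylated. The other examples show the deconvolution summary
(`01_deconvolve_simulated_library.py`), conversion-rate estimation from an
unmethylated spike-in (`02_conversion_rate_spikein.py`, recovers 97.52% for
a simulated 97.50%) and allele-specific methylation phased across a het SNP
(`04_allele_specific_methylation.py`, 82% vs 2% CpG methylation on the two
alleles).

A `methylsnp` command-line interface wraps the same functions
(`simulate`, `deconvolve`, `filter-sam`, `pileup`, `region-meth`,
`allele-split`, `motif`); run `methylsnp --help`.

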