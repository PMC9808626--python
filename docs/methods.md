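# Methods

This note documents the models, conventions and numerical choices behind
`methylsnp`, and what the simulator does and does not emulate.

## The measurement model

A hairpin dual-readout library links each original DNA strand to a
conversion-resistant copy of itself. After bisulfite treatment and
paired-end sequencing, Read1 reports the original strand with every
unmethylated C deaminated to T (methylated C is retained), while Read2
reports the copy with all four bases intact. The two mates are compared at
the same sequencing cycle, which presumes they are cycle-aligned: both
start at the fragment's 5′ end on the same strand sense. The per-cycle
classification is a total partition of {A,C,G,T,N}²:

- `C/C → methylated C`, `T/C → unmethylated C` (the two informative cases),
- `b/b (b ≠ C) → agreement`,
- any `N → ambiguous` (emitted as N, quality 0, no methylation call),
- everything else `→ mismatch`.

Mismatches arise from bisulfite damage, nick-translation misincorporation,
PCR and sequencing errors, and cannot be attributed to either mate from the
pair alone. The Read1 base is kept (the convention of the protocol: Read1
carries the strand the methylation call refers to) and the uncertainty is
pushed into the quality string.

### Cytosine context

The context of each called cytosine is taken from the deconvolved read
itself: `CpG` if the next base is G, else `CHG`/`CHH` by the second
downstream base. Cytosines within 2 nt of the read end — and cytosines whose
downstream window contains N — get the Unknown context (`U/u`). Unknown
calls still carry a methylation state but are excluded from pileups and
k-mer extraction (no context to interpret them in).

### Quality model

- Agreement (and the two cytosine cases): the minimum of the two mate
  qualities, a conservative consensus of two concordant observations.
- Ambiguous: 0.
- Mismatch, reference-free: 0, so downstream callers ignore the base.
- Mismatch, reference-dependent: the read is first deconvolved
  reference-free and aligned; for each mismatch observed in a uniquely
  aligned read the stratum (reference base r, Read1 base a, Read2 base b,
  cycle bin) records whether a equaled r. Under a uniform Beta(1,1) prior
  the posterior that the Read1 base is correct is p = (x+1)/(N+2), emitted
  as Q = round(−10·log₁₀(1−p)), capped at 41 (the printable modern Illumina
  scale); an unobserved stratum falls back to the prior mean (p = ½, Q = 3).
  Cycle bins are 10 cycles wide to keep strata populated at modest depth.
  When the caller cannot supply a reference base at application time the
  lookup marginalizes the stratum over r; with the reference available the
  scheme reduces to "trust Read1 where it matches the reference",
  smoothed by the prior at small N — which is exactly the information a
  reference adds at an unresolvable disagreement.

### Undeconvolvable pairs

Library molecules that escaped the exonuclease cleanup behave as
conventional bisulfite pairs: both mates converted, mapping as flanking
mates rather than cycle-aligned copies. Against a four-base copy they
produce a high disagreement rate, so a pair is rejected when its mismatch
fraction exceeds 0.10 (configurable). Real libraries show 10–15% such
molecules; the simulator reproduces the mechanism and the package rejects
them rather than attempting rescue.

### Adapter trimming

Both mates are trimmed for the 46-nt hairpin adapter
(`CCACGACGACGACGACGAGCGTTAGGCTCGTCGTCGTCGTCGTGGT`, the deoxyuridine read as
T) and the Illumina adapter, 3′-anchored with a 10% mismatch allowance and
minimum overlap 3 (below 10 nt of overlap the budget rounds to zero, i.e.
exact). Because Read1 has been through conversion, the C-to-T-converted form
of each adapter is searched as its own sequence on that mate. Candidate
positions are pre-screened with an exact 8-mer seed; with the converted
adapter enumerated explicitly the seed loses essentially no sensitivity and
keeps trimming O(L) per read. After trimming, both mates are truncated to
the shorter mate and pairs under 30 nt are dropped.

## Alignment filters

Alignment itself is delegated to any external single-end aligner. The four
post-alignment steps, in fixed order: (1) unique-mapping selection — keep
records with an AS tag and either no XS tag or AS ≠ XS; (2) PCR-duplicate
removal — records sharing contig, oriented 5′ coordinate, strand and the
full sequence are one molecule; the highest-mean-quality record is kept,
ties broken by read name, making the operation deterministic and
idempotent; (3) XM tagging from the deconvolution report (offsets are
read-oriented, so the string is reversed for minus-strand alignments);
(4) non-conversion filtering — a read with ≥ 3 methylated non-CpG calls
(X/H) likely escaped conversion; CpG calls never count. The threshold 3 is
the convention of the tool this filter mirrors.

Tests and the acceptance script generate alignments directly from the
simulator's per-read truth coordinates (a "perfect aligner" SAM writer),
which exercises the SAM-consuming stages deterministically.

## Quantification conventions

Pileups are per (contig, 1-based position, strand); minus-strand cytosines
are reported at their own coordinate, not collapsed onto the plus-strand
CpG partner — the protocol reads only the original strand of each molecule,
so the two strands of a dyad are distinct observations. CpG and non-CpG
contexts are tallied separately. The conversion-rate estimator
`100·Σ(N−X)/ΣN` runs either on named spike-in contigs (all contexts) or
genome-wide on CHG+CHH. Region methylation is `ΣX/ΣN` over CpG calls in a
0-based half-open BED interval; "coverage" is the number of CpG calls in
the region and regions with fewer than 50 (≥-comparison) are reported
filtered-out — an uncovered region is missing data, not 0% methylation.
Allele splitting assigns each read overlapping a heterozygous SNV by the
base it carries there; any other base, N, or a deletion leaves the read
unassigned, so REF/ALT/unassigned partition the overlapping reads. The
per-allele tables use the DSS four-column input format; the differential
test itself (typical thresholds delta = 0.1, p = 0.05) is external.

## Motif discovery

2% of deconvolved reads (seed-deterministic Bernoulli sample) suffice at
production scale; small simulations use fraction 1. Reads with more than
one methylated call in any context are excluded so a single molecule cannot
multiply-count a motif region. Each remaining cytosine call with ≥ 3 read
bases upstream and ≥ 4 downstream contributes its 8-mer (N-containing
windows skipped). The exact binomial upper tail `1 − CDF(k; n, P0)`
(strictly beyond k, as published; `tail="geq"` gives the conventional
P(X ≥ k)) is tested per 8-mer with n ≥ 5 against P0 = Σk/Σn, Bonferroni
threshold α/m with α = 10⁻⁴ and m the number of tested 8-mers. Requiring
n ≥ 5 avoids degenerate single-observation significances; m counts only
tested 8-mers.

Enriched 8-mers are clustered by average-linkage agglomeration on Hamming
distance, cut to the user-chosen cluster count (cluster number is a manual
choice, as in heatmap-guided practice; no automatic criterion is
implemented). Input order independence comes from lexicographic
pre-sorting. Consensus columns weight each member by its methylated count
k; a base enters a column's IUPAC code at frequency ≥ 0.2 and flanking
all-N columns are trimmed. Note the statistical behavior at fully
degenerate positions: with ~30–100 weighted members, a uniform column's
base frequencies scatter around 0.25, so one base can fall below 0.2 and
the column reads as a 3-fold code (H/B/D/V) rather than N. The specific
positions of a motif are recovered exactly; the degenerate flanks are
recovered up to that sampling effect. Validation therefore checks
position-wise IUPAC compatibility rather than string equality on flanks.

## The simulator

What it emulates: fragmentation (normal fragment lengths, default
300 ± 50 bp, truncated below at the read length), strand-symmetric fragment
sampling, the copy/convert asymmetry of the two mates, per-C conversion of
unmethylated cytosines (default 97.5%), optional failure to retain
methylated cytosines, uniform substitution sequencing errors (Q37 baseline,
Q11 at injected errors), hairpin read-through past short fragments, and a
configurable fraction of conventional bisulfite pairs. Methylomes are
either rate-mode — each CpG dyad methylated independently at `cpg_rate`,
symmetrically on both strands as in mammalian genomes — or motif-mode —
every IUPAC-pattern occurrence on either strand methylated at a stated
offset and efficiency, as for bacterial methyltransferases.

What it does not emulate: indels, PCR/GC bias, quality decay along the
read, hemimethylation (the protocol destroys it: the copy strand is
synthesized, so dyad asymmetry is unobservable), nick-translation
misincorporation as a separate channel (folded into the sequencing error
rate), and chimeric molecules. Passing tests on simulated data therefore
demonstrate the correctness of the algorithms under the protocol's
generative model, not robustness to every artifact of real libraries.

## Problem sizes and statistical checks

The validation suite runs at desk scale: round-trip identity on 50,000
error-free pairs from a 200-kb genome; conversion-rate recovery on a
48.5-kb unmethylated spike-in (~20,000 pairs, failure 1/40); global CpG
level on a 200-kb genome at the 45.3% dyad rate (~30,000 pairs; the
acceptance script uses 500 kb and ~100,000 pairs); motif recovery on
50-kb genomes with ~4,000 pairs each. Stochastic recoveries are asserted
within 3 binomial standard deviations of the expectation *conditional on
the realized methylome*: with ~99% conversion an unmethylated call reads
methylated with probability 0.01, so the apparent CpG level exceeds the
true level by (1 − level)·(1 − conversion) (≈ +0.55 points at 45.3%) — the
same inflation bisulfite assays show in practice — and the finite number of
CpG sites makes the realized truth level itself scatter around the nominal
rate. Conditioning on truth makes the remaining variation exactly binomial.
Null control of the enrichment test uses conversion-failure noise only
(unmethylated genome at 90% conversion), which makes every call an iid
Bernoulli event — the actual null of the binomial model; site-level
methylomes at deep coverage are overdispersed relative to that null, which
is precisely why genuinely methylated motifs are detectable.

## Known limitations

- The calibration scheme conditions on the reference base; on diverged
  samples it inherits reference bias at variant positions.
- The duplicate rule requires identical sequences, so a duplicate pair
  differing by a sequencing error is not collapsed (matching the stated
  rule, not picard-style coordinate-only marking).
- Pileups assume gapless alignments in the truth-SAM path; CIGARs with
  indels are handled through the aligned-pairs interface but are untested
  against real aligner output.
- Motif discovery assumes a single methylated position per motif; enzymes
  methylating both strands of asymmetric sites appear as two motifs.
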