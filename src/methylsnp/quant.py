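"""Methylation quantification from XM-tagged alignments.

Aggregates per-read methylation calls into per-site pileups, estimates the
bisulfite conversion rate (spike-in contigs or non-CpG contexts), computes
region-level methylation over e.g. CpG islands, and splits reads by the
allele carried at a heterozygous SNP for allele-specific methylation (ASM),
exporting per-allele count tables in the four-column format consumed by DSS.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence
import warnings

import pandas as pd
import pysam

__all__ = [
    "Region",
    "HetSNP",
    "pileup_methylation",
    "conversion_rate",
    "region_methylation",
    "split_by_allele",
    "allele_methylation_tables",
    "read_bed",
    "read_het_snps",
    "write_bedgraph",
]

_CONTEXT = {"Z": "CpG", "z": "CpG", "X": "CHG", "x": "CHG", "H": "CHH", "h": "CHH"}

PILEUP_COLUMNS = ["chrom", "pos", "strand", "context", "X", "N"]


@dataclass(frozen=True)
class Region:
    """0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int
    name: str = "."

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError(
                f"malformed interval {self.chrom}:{self.start}-{self.end}"
            )


@dataclass(frozen=True)
class HetSNP:
    """A biallelic heterozygous SNV (1-based position)."""

    chrom: str
    pos: int
    ref: str
    alt: str

    def __post_init__(self):
        if len(self.ref) != 1 or len(self.alt) != 1 or self.ref == self.alt:
            raise ValueError(f"not a biallelic SNV: {self.ref}>{self.alt}")


def pileup_methylation(
    records: Iterable[pysam.AlignedSegment],
) -> pd.DataFrame:
    """Per-site methylation counts from XM-tagged alignments.

    Each non-'.' XM symbol contributes one call at its mapped coordinate:
    uppercase increments both X (methylated) and N, lowercase N only.
    Unknown-context calls (U/u) are excluded.  Returns a DataFrame with
    columns (chrom, pos [1-based], strand, context, X, N), one row per
    (chrom, pos, strand).
    """
    counts: dict[tuple, list] = {}
    for rec in records:
        if rec.is_unmapped:
            continue
        if not rec.has_tag("XM"):
            raise ValueError(f"record {rec.query_name!r} has no XM tag")
        xm = rec.get_tag("XM")
        if len(xm) != rec.query_length:
            raise ValueError(
                f"XM length {len(xm)} != sequence length {rec.query_length} "
                f"for read {rec.query_name!r}"
            )
        strand = "-" if rec.is_reverse else "+"
        chrom = rec.reference_name
        for qpos, rpos in rec.get_aligned_pairs(matches_only=True):
            sym = xm[qpos]
            ctx = _CONTEXT.get(sym)
            if ctx is None:  # '.', U or u
                continue
            key = (chrom, rpos + 1, strand)
            row = counts.get(key)
            if row is None:
                row = counts[key] = [ctx, 0, 0]
            row[1] += sym.isupper()
            row[2] += 1
    rows = [
        (chrom, pos, strand, ctx, x, n)
        for (chrom, pos, strand), (ctx, x, n) in counts.items()
    ]
    df = pd.DataFrame(rows, columns=PILEUP_COLUMNS)
    return df.sort_values(["chrom", "pos", "strand"], ignore_index=True)


def conversion_rate(
    pileup: pd.DataFrame,
    control_contigs: Sequence[str] | None = None,
    contexts: Sequence[str] | None = None,
) -> float:
    """Bisulfite conversion rate in percent: 100 x sum(N-X)/sum(N).

    Select calls either on named (unmethylated spike-in) contigs, all
    contexts, or genome-wide in the given contexts (typically CHG+CHH).
    """
    if control_contigs is None and contexts is None:
        contexts = ("CHG", "CHH")
    sel = pileup
    if control_contigs is not None:
        sel = sel[sel["chrom"].isin(control_contigs)]
    if contexts is not None:
        sel = sel[sel["context"].isin(contexts)]
    n = int(sel["N"].sum())
    if n == 0:
        raise ValueError("no methylation calls in the selected rows")
    return 100.0 * (n - int(sel["X"].sum())) / n


def region_methylation(
    pileup: pd.DataFrame,
    regions: Sequence[Region],
    min_coverage: int = 50,
) -> pd.DataFrame:
    """Region-level CpG methylation: sum(X)/sum(N) over CpG calls inside.

    Regions whose total CpG call count is below ``min_coverage`` — including
    regions containing no CpG calls at all — are reported with
    ``passed=False`` and a missing level rather than zero.
    """
    cpg = pileup[pileup["context"] == "CpG"]
    rows = []
    for reg in regions:
        inside = cpg[
            (cpg["chrom"] == reg.chrom)
            & (cpg["pos"] > reg.start)
            & (cpg["pos"] <= reg.end)
        ]
        n = int(inside["N"].sum())
        x = int(inside["X"].sum())
        passed = n >= min_coverage
        rows.append(
            (reg.chrom, reg.start, reg.end, reg.name, n, x,
             x / n if passed else float("nan"), passed)
        )
    return pd.DataFrame(
        rows,
        columns=["chrom", "start", "end", "name", "N", "X", "level", "passed"],
    )


def split_by_allele(
    records: Iterable[pysam.AlignedSegment],
    snp: HetSNP,
) -> tuple[list, list, list]:
    """Partition reads overlapping a het SNP by the base they carry there.

    Reads with any base other than REF/ALT, or a deletion at the site, go to
    the unassigned group.  Only reads overlapping the SNP are considered.
    """
    ref_group: list = []
    alt_group: list = []
    unassigned: list = []
    target = snp.pos - 1  # 0-based
    n_overlap = 0
    for rec in records:
        if rec.is_unmapped or rec.reference_name != snp.chrom:
            continue
        if not (rec.reference_start <= target < rec.reference_end):
            continue
        n_overlap += 1
        base = None
        for qpos, rpos in rec.get_aligned_pairs(matches_only=True):
            if rpos == target:
                base = rec.query_sequence[qpos].upper()
                break
        if base == snp.ref:
            ref_group.append(rec)
        elif base == snp.alt:
            alt_group.append(rec)
        else:  # third base, N, or deletion at the site
            unassigned.append(rec)
    if n_overlap == 0:
        warnings.warn(
            f"no reads overlap SNP {snp.chrom}:{snp.pos}", stacklevel=2
        )
    return ref_group, alt_group, unassigned


def allele_methylation_tables(
    ref_group: Sequence[pysam.AlignedSegment],
    alt_group: Sequence[pysam.AlignedSegment],
    contexts: Sequence[str] = ("CpG",),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-allele count tables in DSS input format (chr, pos, N, X).

    The downstream differential test (delta and p-value thresholds) is run
    externally; this only produces its input.
    """

    def table(group):
        if not group:
            return pd.DataFrame(columns=["chr", "pos", "N", "X"])
        pile = pileup_methylation(group)
        pile = pile[pile["context"].isin(contexts)]
        out = pile[["chrom", "pos", "N", "X"]].rename(columns={"chrom": "chr"})
        return out.reset_index(drop=True)

    return table(ref_group), table(alt_group)


# ---------------------------------------------------------------------------
# standard-format I/O

def read_bed(path) -> list[Region]:
    """Read BED intervals (0-based half-open) into Region objects."""
    regions = []
    with open(path) as f:
        for ln, line in enumerate(f, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{ln}: fewer than 3 BED columns")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as e:
                raise ValueError(f"{path}:{ln}: non-integer BED interval") from e
            name = parts[3] if len(parts) > 3 else "."
            regions.append(Region(parts[0], start, end, name))
    return regions


def read_het_snps(path) -> list[HetSNP]:
    """Biallelic heterozygous SNVs from a VCF.

    Multiallelic records, indels and (when genotypes are present) homozygous
    calls are skipped.
    """
    snps = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            if len(rec.alts or ()) != 1:
                continue
            ref, alt = rec.ref, rec.alts[0]
            if len(ref) != 1 or len(alt) != 1:
                continue
            if rec.samples:
                gt = rec.samples[0].get("GT")
                if gt is not None and len(set(a for a in gt if a is not None)) < 2:
                    continue
            snps.append(HetSNP(rec.chrom, rec.pos, ref.upper(), alt.upper()))
    return snps


def write_bedgraph(pileup: pd.DataFrame, path, contexts=("CpG",)) -> None:
    """Per-site percent methylation as bedGraph (0-based starts)."""
    sel = pileup[pileup["context"].isin(contexts)]
    with open(path, "w") as f:
        for row in sel.itertuples(index=False):
            pct = 100.0 * row.X / row.N
            f.write(f"{row.chrom}\t{row.pos - 1}\t{row.pos}\t{pct:.6g}\n")
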