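"""Shared fixtures and helpers: simulated mini-libraries and SAM builders."""

from __future__ import annotations

import pysam
import pytest

import methylsnp as ms

#: IUPAC letter -> base set, for compatibility checks in motif tests
IUPAC_SET = {
    "A": {"A"}, "C": {"C"}, "G": {"G"}, "T": {"T"},
    "R": {"A", "G"}, "Y": {"C", "T"}, "S": {"C", "G"}, "W": {"A", "T"},
    "K": {"G", "T"}, "M": {"A", "C"},
    "B": {"C", "G", "T"}, "D": {"A", "G", "T"}, "H": {"A", "C", "T"},
    "V": {"A", "C", "G"}, "N": {"A", "C", "G", "T"},
}


def iupac_compatible(consensus: str, expected: str) -> bool:
    """True when every consensus letter set is a subset of the expected
    pattern's letter set (the discovered motif never claims a base the true
    motif forbids)."""
    if len(consensus) != len(expected):
        return False
    return all(
        IUPAC_SET[c] <= IUPAC_SET[e] for c, e in zip(consensus, expected)
    )


def expected_window(pattern: str, offset: int, up: int = 3, down: int = 4) -> str:
    """The 8-position IUPAC pattern around the methylated C of a motif."""
    left = "N" * max(0, up - offset) + pattern[max(0, offset - up):offset]
    right = pattern[offset:offset + down + 1]
    right += "N" * (down + 1 - len(right))
    return left + right


def make_record(
    header: pysam.AlignmentHeader,
    name: str,
    seq: str,
    contig: str = "chr1",
    pos: int = 0,
    reverse: bool = False,
    quals=None,
    AS=None,
    XS=None,
    xm: str | None = None,
    mapped: bool = True,
) -> pysam.AlignedSegment:
    rec = pysam.AlignedSegment(header)
    rec.query_name = name
    rec.query_sequence = seq
    rec.query_qualities = quals if quals is not None else [30] * len(seq)
    if mapped:
        rec.flag = 16 if reverse else 0
        rec.reference_id = header.get_tid(contig)
        rec.reference_start = pos
        rec.cigarstring = f"{len(seq)}M"
        rec.mapping_quality = 42
    else:
        rec.flag = 4
    if AS is not None:
        rec.set_tag("AS", AS, "i")
    if XS is not None:
        rec.set_tag("XS", XS, "i")
    if xm is not None:
        rec.set_tag("XM", xm, "Z")
    return rec


@pytest.fixture(scope="session")
def header():
    return pysam.AlignmentHeader.from_references(["chr1", "chr2"], [10_000, 10_000])


def simulate_library(
    genome_len=50_000,
    gc=0.5,
    model=None,
    n_fragments=2_000,
    read_length=100,
    conversion_rate=1.0,
    seq_error_rate=0.0,
    undeconvolvable_fraction=0.0,
    seed=1,
    name="chr1",
):
    """Genome + truth + pairs + reference-free deconvolution results."""
    genome = ms.generate_genome(genome_len, gc, seed=seed, name=name)
    if model is None:
        model = ms.MethylationModel("rate", cpg_rate=0.5)
    truth = ms.assign_methylation(genome, model, seed=seed + 1)
    config = ms.SimConfig(
        n_fragments=n_fragments,
        read_length=read_length,
        conversion_rate=conversion_rate,
        seq_error_rate=seq_error_rate,
        undeconvolvable_fraction=undeconvolvable_fraction,
        seed=seed + 2,
    )
    pairs = ms.simulate_read_pairs(genome, truth, config)
    results, trimmed, summary = ms.deconvolve_batch(
        ((p.id, p.r1_seq, p.r1_qual, p.r2_seq, p.r2_qual) for p in pairs),
        trim=False,
    )
    return genome, truth, pairs, results, summary


def filtered_pileup(genome, pairs, results, tmp_path, min_non_cpg_meth=10**9):
    """Truth-coordinate SAM -> filters -> pileup DataFrame."""
    sam_path = str(tmp_path / "aln.sam")
    ms.write_truth_sam({r.id: r for r in results}, pairs, genome, sam_path)
    calls = {
        r.id: [(o, c, s) for _, o, c, s in ms.methylation_report_rows(r)]
        for r in results
        if r.status == "deconvolved"
    }
    out_path = str(tmp_path / "filt.sam")
    ms.run_filters(sam_path, out_path, calls, min_non_cpg_meth)
    with pysam.AlignmentFile(out_path) as sam:
        return ms.pileup_methylation(sam)
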