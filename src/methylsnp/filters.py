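"""Post-alignment filters for deconvolved reads.

The four custom steps applied to single-end alignments of deconvolved reads,
in pipeline order: (1) keep unique mappings (AS tag present without XS, or
AS != XS), (2) remove PCR duplicates (same oriented position and identical
sequence), (3) attach the Bismark-style XM methylation-call string from the
deconvolution report, (4) remove reads showing incomplete bisulfite
conversion (too many methylated non-CpG calls).
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import pysam

__all__ = [
    "mark_unique",
    "mark_duplicates",
    "add_xm_tag",
    "filter_non_conversion",
    "run_filters",
]

_XM_SYMBOL = {
    ("CpG", "methylated"): "Z", ("CpG", "unmethylated"): "z",
    ("CHG", "methylated"): "X", ("CHG", "unmethylated"): "x",
    ("CHH", "methylated"): "H", ("CHH", "unmethylated"): "h",
    ("Unknown", "methylated"): "U", ("Unknown", "unmethylated"): "u",
}


def mark_unique(
    records: Iterable[pysam.AlignedSegment],
) -> tuple[list[pysam.AlignedSegment], int]:
    """Keep uniquely mapping primary records.

    A record is unique when it carries only an AS tag, or its AS differs
    from its XS (second-best score).  Unmapped, secondary and supplementary
    records are dropped.  A record with XS but no AS is malformed.
    """
    kept: list[pysam.AlignedSegment] = []
    removed = 0
    for rec in records:
        if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
            removed += 1
            continue
        has_as, has_xs = rec.has_tag("AS"), rec.has_tag("XS")
        if has_xs and not has_as:
            raise ValueError(
                f"record {rec.query_name!r} has XS but no AS tag"
            )
        if has_as and (not has_xs or rec.get_tag("AS") != rec.get_tag("XS")):
            kept.append(rec)
        else:
            removed += 1
    return kept, removed


def _dup_key(rec: pysam.AlignedSegment):
    # 5' oriented coordinate: leftmost for forward, rightmost for reverse
    pos = rec.reference_end if rec.is_reverse else rec.reference_start
    strand = "-" if rec.is_reverse else "+"
    return (rec.reference_name, pos, strand, rec.query_sequence)


def _mean_quality(rec: pysam.AlignedSegment) -> float:
    q = rec.query_qualities
    return float(sum(q)) / len(q) if q else 0.0


def mark_duplicates(
    records: Iterable[pysam.AlignedSegment],
) -> tuple[list[pysam.AlignedSegment], int]:
    """Collapse PCR duplicates: same position, same strand, same sequence.

    Within each group the record with the highest mean base quality is kept
    (ties broken by lexicographically smallest read name); input order of the
    kept records is preserved.
    """
    records = list(records)
    best: dict = {}
    for idx, rec in enumerate(records):
        key = _dup_key(rec)
        rank = (-_mean_quality(rec), rec.query_name)
        if key not in best or rank < best[key][0]:
            best[key] = (rank, idx)
    keep_idx = {idx for _, idx in best.values()}
    kept = [rec for i, rec in enumerate(records) if i in keep_idx]
    return kept, len(records) - len(kept)


def add_xm_tag(
    rec: pysam.AlignedSegment,
    calls_by_id: Mapping[str, Sequence[tuple[int, str, str]]],
) -> pysam.AlignedSegment:
    """Attach the XM methylation-call string from the deconvolution report.

    Report offsets are in read orientation; for a minus-strand alignment the
    string is reversed so XM position i annotates mapped base i.
    """
    calls = calls_by_id.get(rec.query_name)
    if calls is None:
        raise KeyError(
            f"read {rec.query_name!r} absent from the methylation report"
        )
    L = rec.query_length
    xm = ["."] * L
    for offset, context, state in calls:
        if not 0 <= offset < L:
            raise ValueError(
                f"report offset {offset} out of range for read "
                f"{rec.query_name!r} (length {L})"
            )
        xm[offset] = _XM_SYMBOL[(context, state)]
    if rec.is_reverse:
        xm.reverse()
    rec.set_tag("XM", "".join(xm), "Z")
    return rec


def filter_non_conversion(
    records: Iterable[pysam.AlignedSegment],
    min_non_cpg_meth: int = 3,
) -> tuple[list[pysam.AlignedSegment], int]:
    """Drop reads with apparently incomplete bisulfite conversion.

    A read is removed when its XM string carries at least
    ``min_non_cpg_meth`` methylated non-CpG calls (X or H symbols); CpG
    calls never count.
    """
    kept: list[pysam.AlignedSegment] = []
    removed = 0
    for rec in records:
        if not rec.has_tag("XM"):
            raise ValueError(f"record {rec.query_name!r} has no XM tag")
        xm = rec.get_tag("XM")
        n = sum(1 for c in xm if c in "XH")
        if n >= min_non_cpg_meth:
            removed += 1
        else:
            kept.append(rec)
    return kept, removed


def run_filters(
    in_path: str,
    out_path: str,
    calls_by_id: Mapping[str, Sequence[tuple[int, str, str]]],
    min_non_cpg_meth: int = 3,
) -> dict:
    """Apply the four filters in order to a SAM/BAM file; return counts."""
    with pysam.AlignmentFile(in_path) as sam:
        records = list(sam)
        header = sam.header
    uniq, n_multi = mark_unique(records)
    dedup, n_dup = mark_duplicates(uniq)
    tagged = [add_xm_tag(rec, calls_by_id) for rec in dedup]
    final, n_nonconv = filter_non_conversion(tagged, min_non_cpg_meth)
    mode = "wb" if str(out_path).endswith(".bam") else "w"
    with pysam.AlignmentFile(out_path, mode, header=header) as out:
        for rec in final:
            out.write(rec)
    return {
        "input": len(records),
        "non_unique_or_unmapped": n_multi,
        "duplicates": n_dup,
        "non_conversion": n_nonconv,
        "output": len(final),
    }
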