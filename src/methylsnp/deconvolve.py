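"""Hairpin read-pair deconvolution.

Each trimmed pair is compared cycle by cycle: Read1 carries the bisulfite
converted original strand, Read2 the conversion-resistant four-base copy.  A
T in Read1 over a C in Read2 is an unmethylated cytosine; C over C is a
methylated cytosine; any other disagreement is a potential error.  The result
is a four-base deconvolved read, an adjusted quality string, and a
Bismark-style per-base methylation-call string (Z/z CpG, X/x CHG, H/h CHH,
U/u unknown context, '.' elsewhere).

Two quality-adjustment modes exist for disagreeing positions: reference-free
(quality set to 0) and reference-dependent, where an empirical posterior that
the Read1 base is correct — stratified by reference base, substitution type
and sequencing-cycle bin — is converted to a Phred score.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

import numpy as np

from .simulate import HAIRPIN_ADAPTER, revcomp

__all__ = [
    "PairClass",
    "HairpinConfig",
    "ReadPair",
    "DeconvolvedRead",
    "CalibrationTable",
    "classify_position",
    "trim_read",
    "trim_pair",
    "deconvolve_pair",
    "build_calibration_table",
    "calibrate_pair",
    "deconvolve_batch",
    "deconvolution_summary",
    "methylation_report_rows",
    "write_methylation_report",
    "load_methylation_report",
]

ILLUMINA_ADAPTER = "AGATCGGAAGAGC"

#: XM symbol for (context, methylated) — Bismark alphabet.
_SYMBOL = {
    ("CpG", True): "Z", ("CpG", False): "z",
    ("CHG", True): "X", ("CHG", False): "x",
    ("CHH", True): "H", ("CHH", False): "h",
    ("Unknown", True): "U", ("Unknown", False): "u",
}
_CONTEXT_OF = {v: k[0] for k, v in _SYMBOL.items()}
_STATE_OF = {v: k[1] for k, v in _SYMBOL.items()}


class PairClass(Enum):
    """Per-cycle classification of a (Read1, Read2) base pair."""

    AGREE = "agree"          # b1 == b2, not C
    METH_C = "meth_c"        # C over C: methylated cytosine
    UNMETH_C = "unmeth_c"    # T over C: converted, unmethylated cytosine
    MISMATCH = "mismatch"    # any other disagreement
    AMBIGUOUS = "ambiguous"  # either base is N


def classify_position(b1: str, b2: str) -> PairClass:
    """Classify one cycle.  Total over {A,C,G,T,N} x {A,C,G,T,N}."""
    if b1 == "N" or b2 == "N":
        return PairClass.AMBIGUOUS
    if b2 == "C":
        if b1 == "C":
            return PairClass.METH_C
        if b1 == "T":
            return PairClass.UNMETH_C
        return PairClass.MISMATCH
    if b1 == b2:
        return PairClass.AGREE
    return PairClass.MISMATCH


@dataclass
class HairpinConfig:
    """Adapter trimming parameters.

    The hairpin adapter is searched both as published and fully
    C-to-T-converted, because Read1 has been through bisulfite treatment.
    Matching is 3'-anchored with 10% mismatches allowed and a minimum
    overlap of 3 nt.
    """

    hairpin: str = HAIRPIN_ADAPTER
    illumina_adapters: tuple[str, ...] = (ILLUMINA_ADAPTER,)
    min_length: int = 30
    max_len_diff: int = 0
    max_error_rate: float = 0.10
    min_overlap: int = 3

    def adapters_for_mate(self, mate: int) -> tuple[str, ...]:
        ads = [self.hairpin] + list(self.illumina_adapters)
        if mate == 1:  # converted strand also carries converted adapters
            ads += [a.replace("C", "T") for a in ads]
        return tuple(dict.fromkeys(ads))


@dataclass
class ReadPair:
    """A trimmed pair ready for deconvolution."""

    id: str
    r1_seq: str
    r1_qual: str
    r2_seq: str
    r2_qual: str
    trimmed: bool = False


@dataclass
class DeconvolvedRead:
    """Four-base read, adjusted qualities and methylation-call string."""

    id: str
    sequence: str
    quality: str
    methylation: str
    status: str = "deconvolved"  # or "rejected"
    n_mismatch: int = 0
    class_counts: dict = field(default_factory=dict)


def _find_adapter(
    seq: str, adapter: str, max_error_rate: float, min_overlap: int
) -> int:
    """Return the position where a 3'-anchored adapter match begins, or -1.

    An occurrence starting at i must extend to the read end (or cover the
    whole adapter) with at most ``floor(len * max_error_rate)`` mismatches.
    An exact 8-mer seed pre-screens candidate start positions; short
    3'-terminal overlaps (< 10 nt, where the mismatch budget is zero anyway)
    are checked exactly.
    """
    L = len(seq)
    seed = adapter[:8]
    starts: list[int] = []
    if len(seed) == 8:
        j = seq.find(seed)
        while j != -1:
            starts.append(j)
            j = seq.find(seed, j + 1)
    for i in sorted(starts):
        m = min(len(adapter), L - i)
        if m < min_overlap:
            continue
        window = seq[i : i + m]
        mism = sum(a != b for a, b in zip(window, adapter))
        if mism <= math.floor(m * max_error_rate):
            return i
    # short suffix overlaps: exact (floor(m * 0.1) == 0 for m < 10)
    for m in range(min(9, len(adapter), L), min_overlap - 1, -1):
        if seq.endswith(adapter[:m]):
            return L - m
    return -1


def trim_read(seq: str, adapters: Sequence[str], cfg: HairpinConfig) -> int:
    """Length of the read after removing the first adapter hit, if any."""
    cut = len(seq)
    for ad in adapters:
        i = _find_adapter(seq, ad, cfg.max_error_rate, cfg.min_overlap)
        if i != -1:
            cut = min(cut, i)
    return cut


def trim_pair(
    rid: str,
    r1_seq: str,
    r1_qual: str,
    r2_seq: str,
    r2_qual: str,
    cfg: HairpinConfig | None = None,
) -> ReadPair | None:
    """Trim hairpin/Illumina adapters from both mates, truncate to the
    shorter mate, and drop pairs below the minimum retained length.
    """
    if cfg is None:
        cfg = HairpinConfig()
    if len(r1_seq) != len(r1_qual) or len(r2_seq) != len(r2_qual):
        raise ValueError(f"malformed FASTQ record {rid!r}: seq/qual length differ")
    c1 = trim_read(r1_seq.upper(), cfg.adapters_for_mate(1), cfg)
    c2 = trim_read(r2_seq.upper(), cfg.adapters_for_mate(2), cfg)
    L = min(c1, c2)
    if L < cfg.min_length:
        return None
    return ReadPair(
        id=rid,
        r1_seq=r1_seq[:L].upper(),
        r1_qual=r1_qual[:L],
        r2_seq=r2_seq[:L].upper(),
        r2_qual=r2_qual[:L],
        trimmed=True,
    )


def _context_symbol(seq: str, i: int, methylated: bool) -> str:
    """Bismark context symbol for the cytosine at ``i`` of ``seq``.

    Cytosines with fewer than two downstream bases get the Unknown context.
    """
    if i >= len(seq) - 2:
        ctx = "Unknown"
    else:
        b1, b2 = seq[i + 1], seq[i + 2]
        if b1 == "G":
            ctx = "CpG"
        elif b1 == "N" or b2 == "N":
            ctx = "Unknown"
        elif b2 == "G":
            ctx = "CHG"
        else:
            ctx = "CHH"
    return _SYMBOL[(ctx, methylated)]


_B1 = {c: np.uint8(ord(c)) for c in "ACGTN"}


def deconvolve_pair(
    pair: ReadPair,
    reject_frac: float = 0.10,
    calibration: "CalibrationTable | None" = None,
    ref_bases: str | None = None,
    max_len_diff: int = 0,
) -> DeconvolvedRead:
    """Resolve one pair into a deconvolved read.

    Reference-free mode (``calibration=None``) sets the quality of every
    disagreeing (MISMATCH) position to 0; with a calibration table the
    stratum's empirical Phred score is used instead (``ref_bases``, when
    given, is the read-oriented reference sequence from the pass-1 alignment
    used to pick the stratum).  Pairs whose MISMATCH fraction exceeds
    ``reject_frac`` are returned with status ``"rejected"``.
    """
    if abs(len(pair.r1_seq) - len(pair.r2_seq)) > max_len_diff:
        return DeconvolvedRead(
            pair.id, "", "", "", status="rejected", n_mismatch=0,
            class_counts={"length_mismatch": 1},
        )
    L = min(len(pair.r1_seq), len(pair.r2_seq))
    a1 = np.frombuffer(pair.r1_seq[:L].encode(), dtype=np.uint8)
    a2 = np.frombuffer(pair.r2_seq[:L].encode(), dtype=np.uint8)
    q1 = np.frombuffer(pair.r1_qual[:L].encode(), dtype=np.uint8).astype(int) - 33
    q2 = np.frombuffer(pair.r2_qual[:L].encode(), dtype=np.uint8).astype(int) - 33

    amb = (a1 == _B1["N"]) | (a2 == _B1["N"])
    meth = ~amb & (a1 == _B1["C"]) & (a2 == _B1["C"])
    unmeth = ~amb & (a1 == _B1["T"]) & (a2 == _B1["C"])
    agree = ~amb & (a1 == a2) & ~meth
    mismatch = ~(amb | meth | unmeth | agree)

    seq = a1.copy()
    seq[unmeth] = _B1["C"]
    seq[amb] = _B1["N"]
    qual = np.minimum(q1, q2)
    qual[amb] = 0
    # cytosine qualities come from the informative mates: Read1 carries the
    # call, Read2 confirms the C; keep the min like AGREE positions.
    n_mismatch = int(mismatch.sum())

    if calibration is None:
        qual[mismatch] = 0
    else:
        for i in np.nonzero(mismatch)[0]:
            r = ref_bases[i] if ref_bases is not None else None
            qual[i] = calibration.phred(
                r, pair.r1_seq[i], pair.r2_seq[i], int(i)
            )

    seq_s = seq.tobytes().decode()
    xm = ["."] * L
    for i in np.nonzero(meth | unmeth)[0]:
        xm[i] = _context_symbol(seq_s, int(i), bool(meth[i]))

    counts = {
        "agree": int(agree.sum()),
        "meth_c": int(meth.sum()),
        "unmeth_c": int(unmeth.sum()),
        "mismatch": n_mismatch,
        "ambiguous": int(amb.sum()),
    }
    status = "rejected" if L and n_mismatch / L > reject_frac else "deconvolved"
    return DeconvolvedRead(
        id=pair.id,
        sequence=seq_s,
        quality=(qual + 33).astype(np.uint8).tobytes().decode(),
        methylation="".join(xm),
        status=status,
        n_mismatch=n_mismatch,
        class_counts=counts,
    )


def calibrate_pair(
    pair: ReadPair,
    table: "CalibrationTable",
    ref_bases: str | None = None,
    reject_frac: float = 0.10,
) -> DeconvolvedRead:
    """Reference-dependent second pass: mismatch qualities from the table."""
    return deconvolve_pair(
        pair, reject_frac=reject_frac, calibration=table, ref_bases=ref_bases
    )


class CalibrationTable:
    """Empirical posterior that the Read1 base is correct at disagreements.

    Strata are keyed by (reference base, Read1 base, Read2 base, cycle bin).
    With x successes (Read1 base equals the reference) out of N trials the
    posterior under a uniform Beta(1,1) prior is p = (x+1)/(N+2) and the
    assigned quality is Q = round(-10 log10(1-p)), capped at 41.  A stratum
    never observed falls back to the prior mean, p = 1/2 (Q = 3).  When the
    reference base is unknown at application time the lookup marginalizes
    over it.
    """

    Q_CAP = 41

    def __init__(self, bin_width: int = 10):
        if bin_width <= 0:
            raise ValueError("bin_width must be positive")
        self.bin_width = bin_width
        self.strata: dict[tuple[str, str, str, int], list[int]] = {}

    def _key(self, r: str, a: str, b: str, cycle: int):
        return (r, a, b, cycle // self.bin_width)

    def add(self, r: str, a: str, b: str, cycle: int, success: bool) -> None:
        s = self.strata.setdefault(self._key(r, a, b, cycle), [0, 0])
        s[0] += int(success)
        s[1] += 1

    def _counts(self, r: str | None, a: str, b: str, cycle: int) -> tuple[int, int]:
        if r is not None:
            return tuple(self.strata.get(self._key(r, a, b, cycle), (0, 0)))
        x = n = 0
        for base in "ACGT":
            xs, ns = self.strata.get(self._key(base, a, b, cycle), (0, 0))
            x += xs
            n += ns
        return x, n

    def posterior(self, r: str | None, a: str, b: str, cycle: int) -> float:
        x, n = self._counts(r, a, b, cycle)
        return (x + 1) / (n + 2)

    def phred(self, r: str | None, a: str, b: str, cycle: int) -> int:
        p = self.posterior(r, a, b, cycle)
        return min(self.Q_CAP, round(-10.0 * math.log10(1.0 - p)))


def build_calibration_table(
    pairs: Mapping[str, ReadPair] | Iterable[ReadPair],
    sam_path: str,
    reference,
    bin_width: int = 10,
) -> CalibrationTable:
    """Learn the quality calibration from pass-1 alignments.

    ``reference`` is a pysam.FastaFile, a path to an indexed/plain FASTA, or
    a mapping contig -> sequence.  Only uniquely aligned primary records are
    used (AS present without XS, or AS != XS).  For each MISMATCH position
    the stratum (reference base, Read1 base, Read2 base, cycle bin) is
    incremented, counting a success when the Read1 base equals the reference.
    """
    import pysam

    if not isinstance(pairs, Mapping):
        pairs = {p.id: p for p in pairs}
    if isinstance(reference, (str, bytes)):
        reference = pysam.FastaFile(str(reference))

    def ref_seq(contig: str, start: int, end: int) -> str:
        if hasattr(reference, "fetch"):
            return reference.fetch(contig, start, end).upper()
        try:
            seq = reference[contig]
        except KeyError as e:
            raise KeyError(f"reference contig {contig!r} not found") from e
        return seq[start:end].upper()

    table = CalibrationTable(bin_width=bin_width)
    with pysam.AlignmentFile(sam_path) as sam:
        for rec in sam:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            if not rec.has_tag("AS"):
                continue
            if rec.has_tag("XS") and rec.get_tag("XS") == rec.get_tag("AS"):
                continue
            pair = pairs.get(rec.query_name)
            if pair is None:
                continue
            L = rec.query_length
            rstart, rend = rec.reference_start, rec.reference_end
            ref = ref_seq(rec.reference_name, rstart, rend)
            for qpos, rpos in rec.get_aligned_pairs(matches_only=True):
                # read-oriented index (sequencing cycle)
                i = L - 1 - qpos if rec.is_reverse else qpos
                b1, b2 = pair.r1_seq[i], pair.r2_seq[i]
                if classify_position(b1, b2) is not PairClass.MISMATCH:
                    continue
                rbase = ref[rpos - rstart]
                if rec.is_reverse:
                    rbase = revcomp(rbase)
                if rbase not in "ACGT":
                    continue
                table.add(rbase, b1, b2, i, success=(b1 == rbase))
    return table


# ---------------------------------------------------------------------------
# batch driver and reporting

def deconvolve_batch(
    raw_pairs: Iterable[tuple[str, str, str, str, str]],
    cfg: HairpinConfig | None = None,
    reject_frac: float = 0.10,
    calibration: CalibrationTable | None = None,
    ref_bases_by_id: Mapping[str, str] | None = None,
    trim: bool = True,
) -> tuple[list[DeconvolvedRead], list[ReadPair], dict]:
    """Trim and deconvolve a batch of raw (id, s1, q1, s2, q2) tuples.

    Returns (results incl. rejected, trimmed pairs, summary counts).
    """
    if cfg is None:
        cfg = HairpinConfig()
    results: list[DeconvolvedRead] = []
    kept_pairs: list[ReadPair] = []
    n_total = n_dropped = 0
    for rid, s1, q1, s2, q2 in raw_pairs:
        n_total += 1
        if trim:
            pair = trim_pair(rid, s1, q1, s2, q2, cfg)
        else:
            L = min(len(s1), len(s2))
            pair = ReadPair(rid, s1[:L].upper(), q1[:L], s2[:L].upper(), q2[:L])
        if pair is None:
            n_dropped += 1
            continue
        kept_pairs.append(pair)
        ref = None
        if ref_bases_by_id is not None:
            ref = ref_bases_by_id.get(rid)
        results.append(
            deconvolve_pair(
                pair, reject_frac=reject_frac, calibration=calibration,
                ref_bases=ref,
            )
        )
    summary = deconvolution_summary(results, n_total=n_total, n_dropped=n_dropped)
    return results, kept_pairs, summary


def deconvolution_summary(
    results: Iterable[DeconvolvedRead],
    n_total: int | None = None,
    n_dropped: int = 0,
) -> dict:
    """Batch counts: totals, outcome split, and per-class position tallies."""
    n_dec = n_rej = 0
    classes = {k: 0 for k in ("agree", "meth_c", "unmeth_c", "mismatch", "ambiguous")}
    for d in results:
        if d.status == "deconvolved":
            n_dec += 1
        else:
            n_rej += 1
        for k in classes:
            classes[k] += d.class_counts.get(k, 0)
    if n_total is None:
        n_total = n_dec + n_rej + n_dropped
    return {
        "total": n_total,
        "deconvolved": n_dec,
        "rejected": n_rej,
        "dropped_in_trim": n_dropped,
        "position_classes": classes,
    }


def methylation_report_rows(read: DeconvolvedRead):
    """Yield (read_id, offset, context, state) rows for one read."""
    for i, sym in enumerate(read.methylation):
        if sym == ".":
            continue
        yield (
            read.id,
            i,
            _CONTEXT_OF[sym],
            "methylated" if _STATE_OF[sym] else "unmethylated",
        )


def write_methylation_report(reads: Iterable[DeconvolvedRead], path) -> None:
    with open(path, "w") as f:
        f.write("read_id\toffset\tcontext\tstate\n")
        for read in reads:
            if read.status != "deconvolved":
                continue
            for rid, off, ctx, state in methylation_report_rows(read):
                f.write(f"{rid}\t{off}\t{ctx}\t{state}\n")


def load_methylation_report(path) -> dict[str, list[tuple[int, str, str]]]:
    """Read a report TSV back into id -> [(offset, context, state), ...]."""
    calls: dict[str, list[tuple[int, str, str]]] = {}
    with open(path) as f:
        header = f.readline()
        if not header.startswith("read_id"):
            raise ValueError(f"not a methylation report: {path}")
        for line in f:
            rid, off, ctx, state = line.rstrip("\n").split("\t")
            calls.setdefault(rid, []).append((int(off), ctx, state))
    return calls
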