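"""Protocol-faithful read-pair simulator with per-site and per-read ground truth.

Emulates the hairpin dual-readout library: a genomic fragment is copied with
conversion-resistant cytosines, so Read2 reports the original four-base
sequence while Read1 reports the bisulfite-converted original strand.  Both
mates are emitted cycle-aligned (same strand sense, same start), matching the
per-cycle comparison the deconvolver performs.  A configurable fraction of
pairs is instead emitted as conventional bisulfite mates (both converted,
read from opposite fragment ends), modelling undeconvolutable library
molecules.

Everything is reproducible from the seed, and every emitted pair carries its
fragment coordinates and true per-cytosine methylation states so downstream
stages can be scored exactly.
"""

from __future__ import annotations

import gzip
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "SimGenome",
    "MethylationModel",
    "MethylationTruth",
    "SimConfig",
    "SimulatedPair",
    "generate_genome",
    "assign_methylation",
    "simulate_read_pairs",
    "write_fastq",
    "write_genome_fasta",
    "write_truth_sites",
    "write_truth_reads",
    "write_truth_sam",
]

_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")

#: IUPAC nucleotide codes -> the set of bases each matches.
IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}

# Published 46-nt hairpin adapter with the deoxyuridine read as T (post-PCR).
HAIRPIN_ADAPTER = "CCACGACGACGACGACGAGCGTTAGGCTCGTCGTCGTCGTCGTGGT"


def revcomp(seq: str) -> str:
    """Reverse complement of an ACGTN string."""
    return seq.translate(_COMP)[::-1]


@dataclass
class SimGenome:
    """A small in-memory genome: contig name -> ACGT string."""

    contigs: dict[str, str]
    origin: str = "random"

    def __post_init__(self) -> None:
        for name, seq in self.contigs.items():
            if not seq:
                raise ValueError(f"contig {name!r} is empty")
            if set(seq) - set("ACGT"):
                raise ValueError(f"contig {name!r} contains non-ACGT characters")


@dataclass
class MethylationModel:
    """Where 5mC lives on the genome.

    ``rate`` mode methylates each CpG dyad independently with probability
    ``cpg_rate``, symmetrically on both strands as in mammalian genomes
    (reads sample either strand of a site, so an asymmetric methylome would
    halve the apparent CpG level).  ``motif`` mode
    methylates every occurrence of each IUPAC pattern, on both strands, at the
    stated 0-based offset with the stated efficiency (the bacterial
    methyltransferase regime, e.g. Dcm's CCWGG with the second C methylated).
    """

    mode: str = "rate"
    cpg_rate: float = 0.453
    motifs: Sequence[tuple[str, int, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.mode not in ("rate", "motif"):
            raise ValueError(f"unknown methylation mode {self.mode!r}")
        if not 0.0 <= self.cpg_rate <= 1.0:
            raise ValueError("cpg_rate must be in [0, 1]")
        for pattern, offset, eff in self.motifs:
            if not 0 <= offset < len(pattern):
                raise ValueError(f"offset {offset} outside motif {pattern!r}")
            if "C" not in IUPAC[pattern[offset].upper()]:
                raise ValueError(
                    f"motif {pattern!r} offset {offset} is not a C-compatible position"
                )
            if not 0.0 <= eff <= 1.0:
                raise ValueError("motif efficiency must be in [0, 1]")


class MethylationTruth:
    """Ground-truth methylation: the set of methylated (contig, pos, strand).

    Positions are 0-based on the forward (plus) strand of the contig; a
    minus-strand entry marks the cytosine whose forward-strand base is G.
    Every cytosine not listed is unmethylated.
    """

    def __init__(self, methylated: Iterable[tuple[str, int, str]] = ()):
        self.methylated: set[tuple[str, int, str]] = set(methylated)

    def is_methylated(self, contig: str, pos: int, strand: str) -> bool:
        return (contig, pos, strand) in self.methylated

    def __len__(self) -> int:
        return len(self.methylated)

    def __iter__(self):
        return iter(sorted(self.methylated))


@dataclass
class SimConfig:
    """Study conditions for one simulated library.

    conversion_rate
        Probability that an unmethylated C on the original strand reads as T
        (real libraries typically convert at ~97.5%).
    methylated_retention
        Probability a methylated C survives conversion (1 - inappropriate
        conversion rate).
    undeconvolvable_fraction
        Probability a pair is emitted as a conventional bisulfite pair; real
        libraries show 10-15% such molecules.
    """

    n_fragments: int = 10_000
    fragment_mean: float = 300.0
    fragment_sd: float = 50.0
    read_length: int = 100
    conversion_rate: float = 0.975
    methylated_retention: float = 1.0
    seq_error_rate: float = 0.0
    adapter_readthrough: bool = False
    undeconvolvable_fraction: float = 0.0
    hairpin: str = HAIRPIN_ADAPTER
    base_quality: int = 37
    error_quality: int = 11
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "conversion_rate",
            "methylated_retention",
            "seq_error_rate",
            "undeconvolvable_fraction",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.n_fragments < 0:
            raise ValueError("n_fragments must be non-negative")
        if self.read_length <= 0:
            raise ValueError("read_length must be positive")


@dataclass
class SimulatedPair:
    """One emitted pair plus its ground truth."""

    id: str
    r1_seq: str
    r1_qual: str
    r2_seq: str
    r2_qual: str
    contig: str
    start: int          # 0-based fragment start on the forward strand
    strand: str         # strand the original (Read1) molecule came from
    frag_len: int
    deconvolvable: bool
    meth_offsets: tuple[int, ...]  # read offsets (Read2 coords) of methylated Cs


def generate_genome(
    length: int, gc: float, seed: int, name: str = "chr1"
) -> SimGenome:
    """Random genome of one contig with the requested GC fraction."""
    if length <= 0:
        raise ValueError(f"genome length must be positive, got {length}")
    if not 0.0 <= gc <= 1.0:
        raise ValueError("gc must be in [0, 1]")
    rng = np.random.default_rng(seed)
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    bases = rng.choice(np.frombuffer(b"ACGT", dtype="S1"), size=length, p=p)
    return SimGenome({name: bases.tobytes().decode()}, origin="random")


def _iter_motif_sites(seq: str, pattern: str, offset: int):
    """Yield 0-based positions of the methylatable C for each plus-strand
    occurrence of an IUPAC pattern (overlapping occurrences included)."""
    sets = [IUPAC[c.upper()] for c in pattern]
    m = len(pattern)
    for i in range(len(seq) - m + 1):
        window = seq[i : i + m]
        if all(b in s for b, s in zip(window, sets)):
            if window[offset] == "C":
                yield i + offset


def assign_methylation(
    genome: SimGenome, model: MethylationModel, seed: int
) -> MethylationTruth:
    """Draw a ground-truth methylome under the model.

    Rate mode methylates CpG dyads symmetrically (the top-strand C at the
    dyad position on '+' and the bottom-strand C, one base downstream, on
    '-'); motif mode methylates matched offsets on both strands (a
    minus-strand occurrence is a match of the pattern to the reverse
    complement).
    """
    rng = np.random.default_rng(seed)
    meth: set[tuple[str, int, str]] = set()
    for contig, seq in genome.contigs.items():
        if model.mode == "rate":
            if model.cpg_rate == 0.0:
                continue
            sites = [
                i
                for i in range(len(seq) - 1)
                if seq[i] == "C" and seq[i + 1] == "G"
            ]
            if not sites:
                continue
            draws = rng.random(len(sites))
            for pos, u in zip(sites, draws):
                if u < model.cpg_rate:
                    meth.add((contig, pos, "+"))
                    meth.add((contig, pos + 1, "-"))
        else:
            for pattern, offset, eff in model.motifs:
                plus = list(_iter_motif_sites(seq, pattern, offset))
                # minus-strand occurrence at forward position i..i+m-1 of the
                # reverse-complement window; the methylated C sits at forward
                # coordinate i + (m - 1 - offset), strand '-'.
                rc = revcomp(seq)
                m = len(pattern)
                n = len(seq)
                minus = [
                    n - 1 - p for p in _iter_motif_sites(rc, pattern, offset)
                ]
                for pos, strand in [(p, "+") for p in plus] + [
                    (p, "-") for p in minus
                ]:
                    if eff >= 1.0 or rng.random() < eff:
                        meth.add((contig, pos, strand))
    return MethylationTruth(meth)


def _apply_seq_errors(
    seq: np.ndarray, rng: np.random.Generator, rate: float
) -> np.ndarray:
    """Substitute random different bases at Bernoulli(rate) positions.

    Returns a boolean mask of error positions; mutates ``seq`` in place.
    """
    if rate <= 0.0:
        return np.zeros(len(seq), dtype=bool)
    mask = rng.random(len(seq)) < rate
    idx = np.nonzero(mask)[0]
    if len(idx):
        alphabet = np.frombuffer(b"ACGT", dtype="S1")
        shift = rng.integers(1, 4, size=len(idx))
        codes = {b"A": 0, b"C": 1, b"G": 2, b"T": 3}
        old = np.array([codes[seq[i].tobytes()] for i in idx])
        seq[idx] = alphabet[(old + shift) % 4]
    return mask


def _qual_string(length: int, err_mask: np.ndarray, hi: int, lo: int) -> str:
    q = np.full(length, hi + 33, dtype=np.uint8)
    q[err_mask[:length]] = lo + 33
    return q.tobytes().decode()


def simulate_read_pairs(
    genome: SimGenome, truth: MethylationTruth, config: SimConfig
) -> list[SimulatedPair]:
    """Simulate the library: fragment, copy, convert, and read out.

    Read2 is the four-base readout of the fragment's first ``read_length``
    bases; Read1 is the same bases after bisulfite conversion of the original
    strand.  Fragment lengths are normal(mean, sd) truncated below at
    ``read_length`` (or at 1 when adapter read-through is enabled, which
    appends hairpin sequence past the fragment end to exercise the trimmer).
    """
    rng = np.random.default_rng(config.seed)
    names = list(genome.contigs)
    lens = np.array([len(genome.contigs[n]) for n in names], dtype=float)
    rl = config.read_length
    usable = lens >= max(rl, 1)
    if not usable.any():
        raise ValueError("no contig is long enough to sample fragments from")
    weights = np.where(usable, lens, 0.0)
    weights /= weights.sum()

    min_frag = 1 if config.adapter_readthrough else rl
    pairs: list[SimulatedPair] = []
    n_skipped = 0

    contig_idx = rng.choice(len(names), size=config.n_fragments, p=weights)
    frag_lens = rng.normal(config.fragment_mean, config.fragment_sd, config.n_fragments)
    frag_lens = np.maximum(np.rint(frag_lens).astype(int), min_frag)
    strands = np.where(rng.random(config.n_fragments) < 0.5, "+", "-")
    conventional = rng.random(config.n_fragments) < config.undeconvolvable_fraction

    hp = config.hairpin
    hp_conv = hp.replace("C", "T")

    for j in range(config.n_fragments):
        contig = names[contig_idx[j]]
        seq = genome.contigs[contig]
        fl = int(frag_lens[j])
        if fl > len(seq):
            n_skipped += 1
            continue
        start = int(rng.integers(0, len(seq) - fl + 1))
        strand = strands[j]
        frag = seq[start : start + fl]
        if strand == "-":
            frag = revcomp(frag)

        if conventional[j]:
            pair = _conventional_pair(
                f"sim{j}", frag, contig, start, strand, fl, config, rng
            )
        else:
            pair = _hairpin_pair(
                f"sim{j}", frag, contig, start, strand, fl, config, rng,
                truth, hp, hp_conv,
            )
        pairs.append(pair)

    if n_skipped:
        warnings.warn(
            f"skipped {n_skipped} fragments longer than their contig",
            stacklevel=2,
        )
    return pairs


def _hairpin_pair(
    rid, frag, contig, start, strand, fl, config, rng, truth, hp, hp_conv
) -> SimulatedPair:
    rl = config.read_length
    insert = frag[:rl]
    n_ins = len(insert)

    # true methylation state per read position
    meth_offsets = []
    is_meth = np.zeros(n_ins, dtype=bool)
    for i, b in enumerate(insert):
        if b == "C":
            gpos = start + i if strand == "+" else start + fl - 1 - i
            if truth.is_methylated(contig, gpos, strand):
                is_meth[i] = True
                meth_offsets.append(i)

    arr2 = np.frombuffer(insert.encode(), dtype="S1").copy()
    arr1 = arr2.copy()
    is_c = arr1 == b"C"
    u = rng.random(n_ins)
    conv_unmeth = is_c & ~is_meth & (u < config.conversion_rate)
    conv_meth = is_c & is_meth & (u < 1.0 - config.methylated_retention)
    arr1[conv_unmeth | conv_meth] = b"T"

    # adapter read-through past a short fragment
    if n_ins < rl:
        pad = rl - n_ins
        arr2 = np.concatenate(
            [arr2, np.frombuffer(hp[:pad].encode().ljust(pad, b"A"), dtype="S1")]
        )
        arr1 = np.concatenate(
            [arr1, np.frombuffer(hp_conv[:pad].encode().ljust(pad, b"A"), dtype="S1")]
        )

    e1 = _apply_seq_errors(arr1, rng, config.seq_error_rate)
    e2 = _apply_seq_errors(arr2, rng, config.seq_error_rate)
    return SimulatedPair(
        id=rid,
        r1_seq=arr1.tobytes().decode(),
        r1_qual=_qual_string(len(arr1), e1, config.base_quality, config.error_quality),
        r2_seq=arr2.tobytes().decode(),
        r2_qual=_qual_string(len(arr2), e2, config.base_quality, config.error_quality),
        contig=contig,
        start=start,
        strand=strand,
        frag_len=fl,
        deconvolvable=True,
        meth_offsets=tuple(meth_offsets),
    )


def _conventional_pair(
    rid, frag, contig, start, strand, fl, config, rng
) -> SimulatedPair:
    """A non-hairpin molecule: both mates bisulfite converted, read from
    opposite fragment ends as ordinary flanking paired-end mates."""
    rl = config.read_length

    def convert(s: str) -> np.ndarray:
        a = np.frombuffer(s.encode(), dtype="S1").copy()
        c = a == b"C"
        a[c & (rng.random(len(a)) < config.conversion_rate)] = b"T"
        return a

    r1 = convert(frag[:rl].ljust(rl, "A"))
    r2 = convert(revcomp(frag)[:rl].ljust(rl, "A"))
    e1 = _apply_seq_errors(r1, rng, config.seq_error_rate)
    e2 = _apply_seq_errors(r2, rng, config.seq_error_rate)
    return SimulatedPair(
        id=rid,
        r1_seq=r1.tobytes().decode(),
        r1_qual=_qual_string(len(r1), e1, config.base_quality, config.error_quality),
        r2_seq=r2.tobytes().decode(),
        r2_qual=_qual_string(len(r2), e2, config.base_quality, config.error_quality),
        contig=contig,
        start=start,
        strand=strand,
        frag_len=fl,
        deconvolvable=False,
        meth_offsets=(),
    )


# ---------------------------------------------------------------------------
# writers

def _open_out(path: str | Path):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, "wt")
    return open(path, "w")


def write_fastq(pairs: Iterable[SimulatedPair], prefix: str | Path) -> tuple[str, str]:
    """Write `<prefix>_R1.fastq.gz` and `<prefix>_R2.fastq.gz`."""
    p1, p2 = f"{prefix}_R1.fastq.gz", f"{prefix}_R2.fastq.gz"
    with _open_out(p1) as f1, _open_out(p2) as f2:
        for p in pairs:
            f1.write(f"@{p.id}\n{p.r1_seq}\n+\n{p.r1_qual}\n")
            f2.write(f"@{p.id}\n{p.r2_seq}\n+\n{p.r2_qual}\n")
    return p1, p2


def write_genome_fasta(genome: SimGenome, path: str | Path, width: int = 70) -> None:
    with _open_out(path) as f:
        for name, seq in genome.contigs.items():
            f.write(f">{name}\n")
            for i in range(0, len(seq), width):
                f.write(seq[i : i + width] + "\n")


def write_truth_sites(truth: MethylationTruth, path: str | Path) -> None:
    """TSV of methylated sites: contig, 0-based position, strand."""
    with _open_out(path) as f:
        f.write("contig\tpos\tstrand\tmethylated\n")
        for contig, pos, strand in truth:
            f.write(f"{contig}\t{pos}\t{strand}\tTrue\n")


def write_truth_reads(pairs: Iterable[SimulatedPair], path: str | Path) -> None:
    with _open_out(path) as f:
        f.write(
            "read_id\tcontig\tstart\tstrand\tfragment_length\t"
            "deconvolvable\tmeth_offsets\n"
        )
        for p in pairs:
            offs = ",".join(map(str, p.meth_offsets))
            f.write(
                f"{p.id}\t{p.contig}\t{p.start}\t{p.strand}\t{p.frag_len}\t"
                f"{p.deconvolvable}\t{offs}\n"
            )


def write_truth_sam(
    decon_reads,
    pairs: Sequence[SimulatedPair],
    genome: SimGenome,
    path: str | Path,
    alignment_score: int = 0,
) -> int:
    """Write deconvolved reads as SAM records at their true coordinates.

    Alignment is out of scope for this package; this writer plays the role of
    a perfect aligner for simulated data, so the SAM-consuming stages
    (filters, calibration, pileup) can run without an external mapper.  Reads
    from minus-strand fragments are stored reverse-complemented with
    ``flag 16``, as an aligner would.  Every record carries an ``AS`` tag and
    no ``XS`` tag (unique alignments).  Returns the number of records written.
    """
    import pysam

    if not isinstance(decon_reads, dict):
        decon_reads = {d.id: d for d in decon_reads}
    header = pysam.AlignmentHeader.from_references(
        list(genome.contigs), [len(s) for s in genome.contigs.values()]
    )
    n = 0
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for p in pairs:
            d = decon_reads.get(p.id)
            if d is None or getattr(d, "status", "deconvolved") != "deconvolved":
                continue
            if not p.deconvolvable:
                continue
            L = len(d.sequence)
            a = pysam.AlignedSegment(header)
            a.query_name = p.id
            if p.strand == "+":
                a.flag = 0
                a.reference_start = p.start
                a.query_sequence = d.sequence
                a.query_qualities = pysam.qualitystring_to_array(d.quality)
            else:
                a.flag = 16
                a.reference_start = p.start + p.frag_len - L
                a.query_sequence = revcomp(d.sequence)
                a.query_qualities = pysam.qualitystring_to_array(d.quality[::-1])
            a.reference_id = out.get_tid(p.contig)
            a.mapping_quality = 42
            a.cigarstring = f"{L}M"
            a.set_tag("AS", alignment_score, "i")
            out.write(a)
            n += 1
    return n
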