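"""Reference-free methyltransferase-specificity discovery.

From deconvolved reads alone: every cytosine call is embedded in its 8-mer
sequence context (3 nt upstream, 4 nt downstream, the assayed C at index 3);
per distinct 8-mer the methylated count k and total count n feed an exact
binomial enrichment test against the background methylation level P0 =
sum(k)/sum(n), with Bonferroni control of the family-wise error.  Enriched
8-mers are grouped by average-linkage hierarchical clustering on Hamming
distance and summarized as position frequency matrices and IUPAC consensus
motifs (e.g. the E. coli Dcm specificity CCWGG).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist
from scipy.stats import binom

__all__ = [
    "KmerCount",
    "EnrichmentResult",
    "MotifCluster",
    "sample_reads",
    "extract_context_kmers",
    "count_kmers",
    "enrichment_test",
    "cluster_kmers",
    "consensus_motif",
    "discover_motifs",
    "write_meme",
]

UPSTREAM = 3
DOWNSTREAM = 4
KMER_LENGTH = UPSTREAM + 1 + DOWNSTREAM  # assayed C at index 3

_METH_SYMBOLS = frozenset("ZXHU")
_CALL_SYMBOLS = frozenset("ZXHUzxhu")

#: base set (as a sorted tuple) -> IUPAC letter
_IUPAC_OF = {
    ("A",): "A", ("C",): "C", ("G",): "G", ("T",): "T",
    ("A", "G"): "R", ("C", "T"): "Y", ("C", "G"): "S", ("A", "T"): "W",
    ("G", "T"): "K", ("A", "C"): "M",
    ("C", "G", "T"): "B", ("A", "G", "T"): "D", ("A", "C", "T"): "H",
    ("A", "C", "G"): "V", ("A", "C", "G", "T"): "N",
}


@dataclass
class KmerCount:
    """An 8-mer context: k methylated out of n total central-C calls."""

    sequence: str
    k: int = 0
    n: int = 0

    def __post_init__(self):
        if len(self.sequence) != KMER_LENGTH:
            raise ValueError(f"k-mer must be {KMER_LENGTH} nt: {self.sequence!r}")
        if self.sequence[UPSTREAM] != "C":
            raise ValueError(f"index {UPSTREAM} of {self.sequence!r} is not C")
        if not 0 <= self.k <= self.n:
            raise ValueError("need 0 <= k <= n")


@dataclass
class EnrichmentResult:
    """Binomial enrichment over all counted k-mers.

    ``table`` columns: kmer, k, n, p_value, tested, significant.  The
    significance cut is the Bonferroni threshold alpha/m over the m tested
    k-mers (those with n >= min_n).
    """

    table: pd.DataFrame
    p0: float
    alpha: float
    m: int

    @property
    def significant(self) -> pd.DataFrame:
        return self.table[self.table["significant"]]


@dataclass
class MotifCluster:
    kmers: list[str]
    weights: np.ndarray
    pfm: np.ndarray          # 4 x 8, columns sum to 1; row order A,C,G,T
    consensus: str           # full 8-position IUPAC string
    core: str                # consensus with flanking N positions trimmed
    members: list[KmerCount] = field(default_factory=list)


def sample_reads(reads: Sequence, fraction: float = 0.02, seed: int = 0) -> list:
    """Seed-deterministic Bernoulli subsample of the read list."""
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must be in (0, 1]")
    if fraction == 1.0:
        return list(reads)
    rng = np.random.default_rng(seed)
    keep = rng.random(len(reads)) < fraction
    return [r for r, k in zip(reads, keep) if k]


def extract_context_kmers(
    sequence: str,
    methylation: str,
    up: int = UPSTREAM,
    down: int = DOWNSTREAM,
) -> list[tuple[str, bool]]:
    """(8-mer, methylated) for each scorable cytosine call of one read.

    Reads carrying more than one methylated call are excluded entirely (they
    would over-weight their contexts); cytosines with fewer than ``up``
    bases upstream or ``down`` downstream, and k-mers containing N, are
    skipped.
    """
    if len(sequence) != len(methylation):
        raise ValueError("methylation string length differs from sequence")
    n_meth = sum(1 for c in methylation if c in _METH_SYMBOLS)
    if n_meth > 1:
        return []
    out = []
    L = len(sequence)
    for i, sym in enumerate(methylation):
        if sym not in _CALL_SYMBOLS:
            if sym != ".":
                raise ValueError(f"unknown methylation symbol {sym!r}")
            continue
        if sequence[i] != "C":
            raise ValueError(
                f"methylation call at offset {i} does not sit on a C"
            )
        if i < up or i + down >= L:
            continue
        kmer = sequence[i - up : i + down + 1]
        if "N" in kmer:
            continue
        out.append((kmer, sym.isupper()))
    return out


def count_kmers(stream: Iterable[tuple[str, bool]]) -> dict[str, KmerCount]:
    """Tally k and n per distinct 8-mer."""
    counts: dict[str, KmerCount] = {}
    for kmer, methylated in stream:
        c = counts.get(kmer)
        if c is None:
            c = counts[kmer] = KmerCount(kmer)
        c.n += 1
        c.k += methylated
    return counts


def enrichment_test(
    counts: dict[str, KmerCount] | Iterable[KmerCount],
    alpha: float = 0.0001,
    min_n: int = 5,
    p0: float | None = None,
    tail: str = "paper",
) -> EnrichmentResult:
    """Exact binomial enrichment of per-k-mer methylation over background.

    The background P0 defaults to the average methylation level
    sum(k)/sum(n) over all counted k-mers.  The published upper tail is
    1 - BinomCDF(k; n, P0), i.e. P(X > k), which is what ``tail="paper"``
    computes; ``tail="geq"`` gives the conventional P(X >= k).  Only k-mers
    with n >= min_n are tested, and m (for Bonferroni) counts tested k-mers
    only.
    """
    if isinstance(counts, dict):
        counts = list(counts.values())
    else:
        counts = list(counts)
    if not counts:
        raise ValueError("no k-mer counts to test")
    total_n = sum(c.n for c in counts)
    if total_n == 0:
        raise ValueError("all k-mer counts are empty")
    if p0 is None:
        p0 = sum(c.k for c in counts) / total_n
    if tail not in ("paper", "geq"):
        raise ValueError("tail must be 'paper' or 'geq'")

    counts = sorted(counts, key=lambda c: c.sequence)
    ks = np.array([c.k for c in counts])
    ns = np.array([c.n for c in counts])
    tested = ns >= min_n
    m = int(tested.sum())
    if tail == "paper":
        pvals = 1.0 - binom.cdf(ks, ns, p0)
    else:
        pvals = binom.sf(ks - 1, ns, p0)
    significant = tested & (pvals < alpha / max(m, 1))
    table = pd.DataFrame(
        {
            "kmer": [c.sequence for c in counts],
            "k": ks,
            "n": ns,
            "p_value": pvals,
            "tested": tested,
            "significant": significant,
        }
    )
    return EnrichmentResult(table=table, p0=float(p0), alpha=alpha, m=m)


def _encode(kmers: Sequence[str]) -> np.ndarray:
    return np.array([[ord(c) for c in k] for k in kmers], dtype=np.uint8)


def cluster_kmers(
    kmers: Sequence[str], n_clusters: int
) -> list[list[str]]:
    """Average-linkage hierarchical clustering on Hamming distance.

    Deterministic: k-mers are sorted lexicographically before linkage.
    Returns ``n_clusters`` member lists, ordered by each cluster's first
    k-mer.
    """
    kmers = sorted(set(kmers))
    if len(kmers) < n_clusters:
        raise ValueError(
            f"{len(kmers)} distinct k-mers cannot form {n_clusters} clusters"
        )
    if n_clusters == 1 or len(kmers) == 1:
        return [list(kmers)] if n_clusters == 1 else [[k] for k in kmers]
    X = _encode(kmers)
    dist = pdist(X, metric="hamming") * X.shape[1]
    Z = linkage(dist, method="average")
    labels = fcluster(Z, t=n_clusters, criterion="maxclust")
    groups: dict[int, list[str]] = {}
    for kmer, lab in zip(kmers, labels):
        groups.setdefault(lab, []).append(kmer)
    return sorted(groups.values(), key=lambda g: g[0])


def consensus_motif(
    members: Sequence[KmerCount] | Sequence[str],
    iupac_threshold: float = 0.2,
) -> MotifCluster:
    """PFM and IUPAC consensus of one cluster.

    Columns are weighted by each member's methylated count k (falling back
    to equal weights when all k are zero).  A base enters the consensus code
    of a column when its frequency reaches ``iupac_threshold``; flanking
    all-degenerate (N) columns are trimmed from the reported core.
    """
    members = list(members)
    if not members:
        raise ValueError("empty cluster")
    if isinstance(members[0], str):
        members = [KmerCount(s, k=1, n=1) for s in members]
    weights = np.array([float(c.k) for c in members])
    if weights.sum() == 0:
        weights = np.ones(len(members))
    pfm = np.zeros((4, KMER_LENGTH))
    base_idx = {"A": 0, "C": 1, "G": 2, "T": 3}
    for c, w in zip(members, weights):
        for j, b in enumerate(c.sequence):
            pfm[base_idx[b], j] += w
    pfm /= pfm.sum(axis=0, keepdims=True)

    letters = []
    for j in range(KMER_LENGTH):
        bases = tuple(
            b for b, i in sorted(base_idx.items()) if pfm[i, j] >= iupac_threshold
        )
        if not bases:  # threshold above every frequency: take the max base
            bases = (max(base_idx, key=lambda b: pfm[base_idx[b], j]),)
        letters.append(_IUPAC_OF[tuple(sorted(bases))])
    consensus = "".join(letters)
    core = consensus.strip("N")
    return MotifCluster(
        kmers=[c.sequence for c in members],
        weights=weights,
        pfm=pfm,
        consensus=consensus,
        core=core,
        members=members,
    )


def discover_motifs(
    reads: Sequence[tuple[str, str]],
    n_clusters: int,
    fraction: float = 1.0,
    seed: int = 0,
    alpha: float = 0.0001,
    min_n: int = 5,
) -> tuple[EnrichmentResult, list[MotifCluster]]:
    """End-to-end pipeline over (sequence, methylation-string) reads."""
    sampled = sample_reads(reads, fraction=fraction, seed=seed)
    stream: list[tuple[str, bool]] = []
    for seq, xm in sampled:
        stream.extend(extract_context_kmers(seq, xm))
    counts = count_kmers(stream)
    result = enrichment_test(counts, alpha=alpha, min_n=min_n)
    sig = result.significant["kmer"].tolist()
    groups = cluster_kmers(sig, n_clusters)
    by_seq = {c.sequence: c for c in counts.values()}
    clusters = [consensus_motif([by_seq[k] for k in g]) for g in groups]
    return result, clusters


def write_meme(clusters: Sequence[MotifCluster], path) -> None:
    """Minimal MEME motif format export of the cluster PFMs."""
    with open(path, "w") as f:
        f.write("MEME version 4\n\nALPHABET= ACGT\n\n")
        f.write("strands: + -\n\n")
        f.write("Background letter frequencies\nA 0.25 C 0.25 G 0.25 T 0.25\n\n")
        for i, cl in enumerate(clusters, 1):
            nsites = int(sum(c.n for c in cl.members)) or len(cl.kmers)
            f.write(f"MOTIF {cl.core} cluster_{i}\n")
            f.write(
                f"letter-probability matrix: alength= 4 w= {cl.pfm.shape[1]} "
                f"nsites= {nsites} E= 0\n"
            )
            for j in range(cl.pfm.shape[1]):
                f.write(" ".join(f"{cl.pfm[i2, j]:.6f}" for i2 in range(4)) + "\n")
            f.write("\n")
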