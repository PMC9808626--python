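"""Small I/O helpers shared by the CLI and examples."""

from __future__ import annotations

import gzip
from typing import Iterator


def _open(path):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path)


def iter_fastq(path) -> Iterator[tuple[str, str, str]]:
    """Yield (id, sequence, quality) records from a FASTQ file (gz ok)."""
    with _open(path) as f:
        while True:
            header = f.readline()
            if not header:
                return
            seq = f.readline().rstrip("\n")
            plus = f.readline()
            qual = f.readline().rstrip("\n")
            if not header.startswith("@") or not plus.startswith("+"):
                raise ValueError(f"malformed FASTQ record near {header!r}")
            if len(seq) != len(qual):
                raise ValueError(
                    f"sequence/quality length mismatch for {header[1:].split()[0]!r}"
                )
            yield header[1:].split()[0], seq.upper(), qual


def iter_fastq_pairs(r1_path, r2_path) -> Iterator[tuple[str, str, str, str, str]]:
    """Yield (id, s1, q1, s2, q2) from two synchronized FASTQ files."""
    for (id1, s1, q1), (id2, s2, q2) in zip(
        iter_fastq(r1_path), iter_fastq(r2_path), strict=True
    ):
        base1 = id1.split("/")[0]
        if base1 != id2.split("/")[0]:
            raise ValueError(f"read pair out of sync: {id1!r} vs {id2!r}")
        yield base1, s1, q1, s2, q2


def write_fastq_records(records, path) -> None:
    """Write (id, seq, qual) triples as FASTQ."""
    op = gzip.open(str(path), "wt") if str(path).endswith(".gz") else open(path, "w")
    with op as f:
        for rid, seq, qual in records:
            f.write(f"@{rid}\n{seq}\n+\n{qual}\n")
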