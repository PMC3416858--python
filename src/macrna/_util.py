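"""Shared sequence helpers: complement tables, random DNA, FASTA/FASTQ I/O."""

from __future__ import annotations

import gzip
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqIO.QualityIO import FastqGeneralIterator
from Bio.SeqRecord import SeqRecord

_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")
_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N-safe)."""
    return seq.translate(_COMP)[::-1]


def random_dna(rng: np.random.Generator, n: int, gc: float = 0.5) -> str:
    """Random DNA of length `n` with the given GC fraction (A/T and G/C split evenly)."""
    if n <= 0:
        return ""
    p = np.array([(1.0 - gc) / 2, gc / 2, gc / 2, (1.0 - gc) / 2])
    idx = rng.choice(4, size=n, p=p)
    return _BASES[idx].tobytes().decode("ascii")


def tile(unit: str, n: int, anchor: str = "start") -> str:
    """Tile `unit` to exactly `n` nt.

    anchor="start": partial repeat at the far end; anchor="end": the string ends on a
    unit boundary, with the partial repeat at its beginning.
    """
    reps = unit * (n // len(unit) + 2)
    return reps[:n] if anchor == "start" else reps[-n:] if n else ""


def _open_text(path: str | Path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    with _open_text(path) as fh:
        return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(fh, "fasta")]


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path,
                descriptions: dict[str, str] | None = None) -> None:
    recs = [
        SeqRecord(Seq(seq), id=rid,
                  description=(descriptions or {}).get(rid, ""))
        for rid, seq in records
    ]
    with _open_text(path, "wt") as fh:
        SeqIO.write(recs, fh, "fasta")


def iter_fastq(path: str | Path) -> Iterator[tuple[str, str, str]]:
    """Yield (title, sequence, quality) from a possibly gzipped FASTQ."""
    with _open_text(path) as fh:
        yield from FastqGeneralIterator(fh)


def iter_fastq_pairs(path1: str | Path, path2: str | Path) -> Iterator[tuple[str, str]]:
    """Yield (seq1, seq2) mate pairs from two FASTQ files in lock-step."""
    for (_, s1, _), (_, s2, _) in zip(iter_fastq(path1), iter_fastq(path2), strict=True):
        yield s1.upper(), s2.upper()
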