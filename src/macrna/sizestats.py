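"""Length histograms, per-position nucleotide frequencies, abundant subsets.

All statistics run on distinct sequences by default (one vote per sequence no
matter how many times it was read), the convention that controls for the
heavy amplification of macronuclear nanochromosomes; count-weighted variants
are available behind a flag.
"""

from __future__ import annotations

from typing import Collection, Mapping

import numpy as np
import pandas as pd

from .readprep import DistinctReadSet

HIST_RANGE = range(18, 31)
RNA_COLUMNS = ["U", "A", "C", "G"]
_DNA2RNA = {"T": "U", "A": "A", "C": "C", "G": "G"}


def length_histogram(reads: DistinctReadSet,
                     mapped: Collection[str] | Mapping[str, object]
                     ) -> pd.DataFrame:
    """Distinct-read counts per length 18-30, split by macronuclear mappability.

    `mapped` is the collection of sequences with at least one hit on the
    macronuclear reference (chr1 or chr2; chrM does not count as mapped).
    """
    mapped = set(mapped)
    rows = {length: {"length": length, "distinct": 0, "mapped_distinct": 0}
            for length in HIST_RANGE}
    for seq in reads.counts:
        L = len(seq)
        if L in rows:
            rows[L]["distinct"] += 1
            if seq in mapped:
                rows[L]["mapped_distinct"] += 1
    return pd.DataFrame([rows[k] for k in sorted(rows)])


def modal_mapped_length(hist: pd.DataFrame) -> int:
    """Length with the most mapped distinct reads."""
    idx = int(hist["mapped_distinct"].idxmax())
    return int(hist.loc[idx, "length"])


def position_freq(reads: DistinctReadSet, length: int,
                  weighted: bool = False) -> pd.DataFrame:
    """Per-position nucleotide frequency matrix for one size class.

    Rows are positions 1..length, columns U/A/C/G (RNA alphabet, T reported
    as U); each row sums to 1.  Distinct sequences count once unless
    `weighted`, in which case occurrence counts apply.
    """
    seqs = [(s, c) for s, c in reads.counts.items() if len(s) == length]
    if not seqs:
        raise ValueError(f"no sequences of length {length}")
    counts = np.zeros((length, 4))
    col = {b: i for i, b in enumerate("TACG")}  # T maps to the U column
    for seq, c in seqs:
        w = c if weighted else 1
        for pos, base in enumerate(seq):
            counts[pos, col[base]] += w
    freqs = counts / counts.sum(axis=1, keepdims=True)
    df = pd.DataFrame(freqs, columns=RNA_COLUMNS)
    df.insert(0, "position", np.arange(1, length + 1))
    return df


def five_prime_u_fraction(reads: DistinctReadSet, length: int,
                          weighted: bool = False) -> float:
    return float(position_freq(reads, length, weighted=weighted)["U"].iloc[0])


def abundant_subset(reads: DistinctReadSet, min_count: int = 10,
                    max_count: int | None = None) -> DistinctReadSet:
    """Sequences with min_count <= count (<= max_count when given)."""
    keep = {s: c for s, c in reads.counts.items()
            if c >= min_count and (max_count is None or c <= max_count)}
    return DistinctReadSet(keep, reads.label)
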