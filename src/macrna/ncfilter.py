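"""Non-coding-RNA filter: decoy reference construction and read partitioning.

Before genome mapping, reads matching known non-coding RNAs (rRNA, tRNA,
snRNA, telomerase RNA) or the telomeric repeat are removed.  The telomeric
decoy is five concatenated copies of the telomere unit (40 nt for GGGGTTTT),
catching any read derived from the telomeres themselves.  Matching is lenient
(up to 3 substitutions anywhere, either strand, no indels) and runs through
the same alignment core as genome mapping.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from ._util import read_fasta
from .aligncore import AlignPolicy, align_to_concat
from .readprep import DistinctReadSet
from .refbuild import ConcatReference, build_concat

TELOMERE_DECOY_ID = "telomere_repeat_x5"
TELOMERE_DECOY_COPIES = 5


@dataclass
class FilterSet:
    """Named decoy sequences plus the lenient mismatch policy."""

    sequences: dict[str, str]
    max_mismatches: int = 3
    _ref: ConcatReference | None = field(default=None, repr=False, compare=False)

    @property
    def policy(self) -> AlignPolicy:
        return AlignPolicy(max_mismatches=self.max_mismatches)

    def reference(self) -> ConcatReference:
        if self._ref is None:
            self._ref = build_concat(list(self.sequences.items()), name="ncfilter")
        return self._ref


def build_filter_set(source: str | Path | list[tuple[str, str]] | None,
                     telomere_unit: str = "GGGGTTTT",
                     max_mismatches: int = 3) -> FilterSet:
    """Assemble the filter from an ncRNA FASTA (or record list) plus the decoy."""
    if source is None:
        records: list[tuple[str, str]] = []
    elif isinstance(source, (str, Path)):
        records = read_fasta(source)
    else:
        records = list(source)
    seqs: dict[str, str] = {}
    for rid, seq in records:
        if rid in seqs:
            raise ValueError(f"duplicate ncRNA id {rid!r}")
        seqs[rid] = seq.upper()
    if not seqs:
        warnings.warn("empty ncRNA input; filter contains only the telomeric decoy")
    if TELOMERE_DECOY_ID in seqs:
        raise ValueError(f"reserved id {TELOMERE_DECOY_ID!r} present in input")
    seqs[TELOMERE_DECOY_ID] = telomere_unit * TELOMERE_DECOY_COPIES
    return FilterSet(seqs, max_mismatches=max_mismatches)


def partition_reads(reads: DistinctReadSet, fs: FilterSet
                    ) -> tuple[DistinctReadSet, DistinctReadSet]:
    """Split reads into (ncRNA-matching, surviving) sets.

    A read is ncRNA iff it aligns to any filter sequence, on either strand,
    with at most max_mismatches substitutions.  The partition is exhaustive
    and exclusive on both distinct and total counts.
    """
    ref = fs.reference()
    policy = fs.policy
    nc: dict[str, int] = {}
    surv: dict[str, int] = {}
    for seq, count in reads.counts.items():
        try:
            matched = bool(align_to_concat(seq, ref, policy, first_only=True))
        except ValueError:
            matched = False  # read too short for the pigeonhole at this policy
        (nc if matched else surv)[seq] = count
    return (DistinctReadSet(nc, reads.label), DistinctReadSet(surv, reads.label))


def filter_summary(reads: DistinctReadSet, ncrna: DistinctReadSet,
                   surviving: DistinctReadSet) -> pd.DataFrame:
    """One Table-1-style row of ncRNA filter accounting (total-read basis)."""
    total = reads.total_reads
    row = {
        "Library": reads.label,
        "Bidirectional Identical Reads": total,
        "Matches to ncRNA Filter": ncrna.total_reads,
        "ncRNA%": round(100.0 * ncrna.total_reads / total, 2) if total else 0.0,
        "Not ncRNA": surviving.total_reads,
        "Not ncRNA%": round(100.0 * surviving.total_reads / total, 2) if total
        else 0.0,
    }
    return pd.DataFrame([row])
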