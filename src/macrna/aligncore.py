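"""Bounded-mismatch short-read alignment with complete site enumeration.

Reads in the small-RNA range (16-45 nt) are aligned to both strands of a
reference with at most `max_mismatches` substitutions and no indels - a
deterministic, quality-free surrogate for the seed-based heuristics of
classical short-read mappers.  Enumeration is exact: the read is cut into
max_mismatches + 1 disjoint segments, at least one of which must match the
reference exactly (pigeonhole), candidate sites are collected from a k-mer
position table and then verified by direct comparison.  Sites overlapping an
N (the spacers of a concatenated reference) are excluded, which also makes
cross-record alignments impossible.

Two-pass orchestration mirrors the original study design: reads are first
aligned to the complete-nanochromosome reference (plus the mitochondrial
genome when given); only the leftovers proceed to the partial contigs.  For
statistics a single random site per multi-mapping read can be retained
(report_mode="random_one"); for track export all sites are kept.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pysam

from ._util import revcomp
from .readprep import DistinctReadSet
from .refbuild import ConcatReference

MAX_SEED = 12


@dataclass
class AlignPolicy:
    max_mismatches: int = 1       # "stringent"; the ncRNA filter uses 3 ("lenient")
    multi_cap: int = 10           # >= this many sites -> the ">=10" class
    report_mode: str = "all_sites"  # or "random_one"

    def __post_init__(self) -> None:
        if self.max_mismatches < 0:
            raise ValueError("max_mismatches must be >= 0")
        if self.report_mode not in ("all_sites", "random_one"):
            raise ValueError(f"unknown report_mode {self.report_mode!r}")


STRINGENT = AlignPolicy(max_mismatches=1)
LENIENT = AlignPolicy(max_mismatches=3)


@dataclass(frozen=True)
class AlignmentHit:
    """One placement of a read: record, 0-based leftmost start, strand, mismatches."""

    read: str
    record_id: str
    start: int
    strand: str
    mismatches: int

    @property
    def five_prime_pos(self) -> int:
        """Local coordinate of the read's 5' end on its own strand."""
        if self.strand == "+":
            return self.start
        return self.start + len(self.read) - 1

    @property
    def end(self) -> int:
        return self.start + len(self.read)


class SeqIndex:
    """k-mer position table over one sequence, built lazily per seed length."""

    def __init__(self, seq: str, name: str = "ref"):
        self.seq = seq.upper()
        self.name = name
        self._tables: dict[int, dict[str, list[int]]] = {}

    def table(self, q: int) -> dict[str, list[int]]:
        tab = self._tables.get(q)
        if tab is None:
            tab = defaultdict(list)
            seq = self.seq
            for i in range(len(seq) - q + 1):
                kmer = seq[i:i + q]
                if "N" not in kmer:
                    tab[kmer].append(i)
            tab = dict(tab)
            self._tables[q] = tab
        return tab


def _segments(read_len: int, max_mm: int) -> tuple[int, list[int]]:
    q = min(read_len // (max_mm + 1), MAX_SEED)
    if q < 4:
        raise ValueError(
            f"read of {read_len} nt too short for {max_mm} mismatches "
            "(pigeonhole segment would be < 4 nt)")
    return q, [i * q for i in range(max_mm + 1)]


def _mismatches(a: str, b: str, cap: int) -> int:
    mm = 0
    for x, y in zip(a, b):
        if x != y:
            mm += 1
            if mm > cap:
                return mm
    return mm


def _sites_one_strand(read: str, index: SeqIndex, max_mm: int) -> list[tuple[int, int]]:
    q, offsets = _segments(len(read), max_mm)
    tab = index.table(q)
    seq, L, n = index.seq, len(read), len(index.seq)
    cands: set[int] = set()
    for o in offsets:
        for pos in tab.get(read[o:o + q], ()):
            s = pos - o
            if 0 <= s <= n - L:
                cands.add(s)
    hits = []
    for s in sorted(cands):
        window = seq[s:s + L]
        if "N" in window:
            continue
        mm = _mismatches(read, window, max_mm)
        if mm <= max_mm:
            hits.append((s, mm))
    return hits


def align_read_all_sites(read: str, index: SeqIndex, policy: AlignPolicy,
                         first_only: bool = False) -> list[AlignmentHit]:
    """Enumerate every placement of `read` on both strands of `index`.

    A minus-strand hit means the reverse complement of the read matches the
    forward reference at that window.  Hits come back sorted by
    (record_id, start, strand) for deterministic downstream selection.
    """
    read = read.upper()
    hits: list[AlignmentHit] = []
    for strand, r in (("+", read), ("-", revcomp(read))):
        for s, mm in _sites_one_strand(r, index, policy.max_mismatches):
            hits.append(AlignmentHit(read, index.name, s, strand, mm))
            if first_only:
                return hits
    hits.sort(key=lambda h: (h.record_id, h.start, h.strand))
    return hits


def align_to_concat(read: str, ref: ConcatReference, policy: AlignPolicy,
                    first_only: bool = False) -> list[AlignmentHit]:
    """Align against a concatenated reference, reporting per-record coordinates."""
    out = []
    for h in align_read_all_sites(read, ref.index(), policy, first_only=first_only):
        loc = ref.global_to_local(h.start)
        rid, local = loc  # spacer-overlapping windows were excluded via N
        out.append(AlignmentHit(h.read, rid, local, h.strand, h.mismatches))
    out.sort(key=lambda h: (h.record_id, h.start, h.strand))
    return out


@dataclass
class MappingSummary:
    """Distinct- and total-read mapping multiplicity accounting (Table-1 style)."""

    label: str = ""
    input_distinct: int = 0
    input_total: int = 0
    unmapped_distinct: int = 0
    unmapped_total: int = 0
    unique_distinct: int = 0
    unique_total: int = 0
    multi_2to9_distinct: int = 0
    multi_2to9_total: int = 0
    multi_ge10_distinct: int = 0
    multi_ge10_total: int = 0
    chrm_only_distinct: int = 0

    @property
    def mapped_distinct(self) -> int:
        return (self.unique_distinct + self.multi_2to9_distinct +
                self.multi_ge10_distinct)

    @property
    def mapped_total(self) -> int:
        return self.unique_total + self.multi_2to9_total + self.multi_ge10_total

    @property
    def mapped_pct(self) -> float:
        return 100.0 * self.mapped_total / self.input_total if self.input_total \
            else 0.0

    @property
    def conserved(self) -> bool:
        return (self.unique_distinct + self.multi_2to9_distinct +
                self.multi_ge10_distinct + self.unmapped_distinct
                == self.input_distinct)

    def to_row(self) -> dict:
        return {
            "Library": self.label,
            "Input Reads": self.input_total,
            "No macronuclear match": self.unmapped_total,
            "Mapped to Macronucleus": self.mapped_total,
            "Mapped to Macronucleus%": round(self.mapped_pct, 2),
            ">=10 Map Sites": self.multi_ge10_distinct,
            "<10 Multi Map Sites": self.multi_2to9_distinct,
            "Unique Map Sites": self.unique_distinct,
        }


def run_two_pass(reads: DistinctReadSet, chr1: ConcatReference,
                 chr2: ConcatReference | None = None,
                 chrm: ConcatReference | None = None,
                 policy: AlignPolicy = STRINGENT,
                 seed: int = 0) -> tuple[dict[str, list[AlignmentHit]],
                                         MappingSummary]:
    """chr1(+chrM) first; only pass-1-unmapped reads go on to chr2.

    Multiplicity (unique / 2-9 / >=10 sites) is counted within the pass that
    mapped the read.  In random_one mode a single site per read is retained,
    drawn uniformly from the sorted hit list with a seeded generator, so
    reruns are bit-identical.
    """
    rng = np.random.default_rng(seed)
    summary = MappingSummary(label=reads.label,
                             input_distinct=reads.distinct_reads,
                             input_total=reads.total_reads)
    pass1 = [chr1] + ([chrm] if chrm is not None else [])
    pass2 = [chr2] if chr2 is not None else []
    hits_by_read: dict[str, list[AlignmentHit]] = {}
    for seq in reads.sequences():
        count = reads.counts[seq]
        hits: list[AlignmentHit] = []
        for target_set in (pass1, pass2):
            if not target_set:
                continue
            for ref in target_set:
                hits.extend(align_to_concat(seq, ref, policy))
            if hits:
                break
        if not hits:
            summary.unmapped_distinct += 1
            summary.unmapped_total += count
            continue
        n = len(hits)
        if n == 1:
            summary.unique_distinct += 1
            summary.unique_total += count
        elif n < policy.multi_cap:
            summary.multi_2to9_distinct += 1
            summary.multi_2to9_total += count
        else:
            summary.multi_ge10_distinct += 1
            summary.multi_ge10_total += count
        if chrm is not None and all(h.record_id in set(chrm.record_ids)
                                    for h in hits):
            summary.chrm_only_distinct += 1
        if policy.report_mode == "random_one":
            hits = [hits[int(rng.integers(n))]]
        hits_by_read[seq] = hits
    return hits_by_read, summary


# ----------------------------------------------------------------------------
# track export
# ----------------------------------------------------------------------------

def _sq_header(refs: Sequence[ConcatReference]) -> dict:
    sq = []
    for ref in refs:
        for rid, length in zip(ref.record_ids, ref.record_lengths):
            sq.append({"SN": rid, "LN": length})
    return {"HD": {"VN": "1.6", "SO": "unsorted"}, "SQ": sq}


def export_sam(hits_by_read: Mapping[str, Iterable[AlignmentHit]],
               reads: DistinctReadSet, refs: Sequence[ConcatReference],
               path: str | Path) -> None:
    """SAM with 1-based POS, FLAG 16 on minus hits, and NM mismatch tags.

    SEQ is given in reference orientation (reverse-complemented for minus
    hits) per SAM convention; the read count travels in the XC tag.
    """
    header = pysam.AlignmentHeader.from_dict(_sq_header(refs))
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for i, seq in enumerate(sorted(hits_by_read)):
            for hit in hits_by_read[seq]:
                a = pysam.AlignedSegment(header)
                a.query_name = f"dr{i + 1:07d}"
                a.query_sequence = seq if hit.strand == "+" else revcomp(seq)
                a.flag = 0 if hit.strand == "+" else 16
                a.reference_id = header.get_tid(hit.record_id)
                a.reference_start = hit.start
                a.mapping_quality = 255
                a.cigarstring = f"{len(seq)}M"
                a.set_tag("NM", hit.mismatches)
                a.set_tag("XC", reads.counts.get(seq, 1))
                out.write(a)


def export_bedgraph(hits_by_read: Mapping[str, Iterable[AlignmentHit]],
                    reads: DistinctReadSet, path_plus: str | Path,
                    path_minus: str | Path) -> None:
    """Per-strand bedGraph of 5'-end counts (count-weighted), one line per position."""
    acc = {"+": defaultdict(int), "-": defaultdict(int)}
    for seq, hits in hits_by_read.items():
        c = reads.counts.get(seq, 1)
        for h in hits:
            acc[h.strand][(h.record_id, h.five_prime_pos)] += c
    for strand, path in (("+", path_plus), ("-", path_minus)):
        with open(path, "w") as fh:
            for (rid, pos), val in sorted(acc[strand].items()):
                fh.write(f"{rid}\t{pos}\t{pos + 1}\t{val}\n")
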