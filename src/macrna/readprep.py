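"""Paired-end read preparation: adapter trimming and bidirectional-identity collapse.

Small-RNA inserts (15-45 nt) are much shorter than the 100 bp reads, so both
mates sequence the whole insert.  A pair is kept only when the two mates,
after adapter trimming, are exact complements of each other ("identical in
both directions") - the high-confidence sequence unit of the whole pipeline.
Kept inserts are deduplicated into a DistinctReadSet, the currency of every
downstream statistic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from ._util import revcomp, iter_fastq_pairs

_ALPHABET = frozenset("ACGT")


@dataclass
class PrepConfig:
    adapter3: str = "TGGAATTCTCGGGTGCCAAGG"
    min_len: int = 16
    max_len: int = 45
    min_adapter_overlap: int = 6

    def __post_init__(self) -> None:
        if self.min_len < 1 or self.min_len > self.max_len:
            raise ValueError("require 1 <= min_len <= max_len")
        if self.min_adapter_overlap > len(self.adapter3):
            raise ValueError("min_adapter_overlap exceeds adapter length")


def trim_adapter(read: str, cfg: PrepConfig) -> str | None:
    """Return the insert preceding the leftmost adapter occurrence, or None.

    Accepts a full adapter match anywhere, or a partial match of at least
    min_adapter_overlap bases running off the 3' end of the read.  Reads with
    no adapter evidence are rejected: their insert extends beyond the read and
    the mate-identity test would be meaningless.  Non-ACGTN characters reject.
    """
    if not read:
        return None
    if set(read) - set("ACGTN"):
        return None
    idx = read.find(cfg.adapter3)
    if idx >= 0:
        return read[:idx]
    for k in range(min(len(cfg.adapter3) - 1, len(read)),
                   cfg.min_adapter_overlap - 1, -1):
        if read.endswith(cfg.adapter3[:k]):
            return read[:len(read) - k]
    return None


def collapse_pair(insert1: str | None, insert2: str | None) -> str | None:
    """Keep insert1 iff it equals the reverse-complement-normalized mate exactly.

    insert2 is given in mate-2 orientation (reverse strand of the template);
    100% identity over the full, equal length is required.
    """
    if insert1 is None or insert2 is None or not insert1:
        return None
    return insert1 if insert1 == revcomp(insert2) else None


@dataclass
class PrepStats:
    """Per-pair accounting; input = kept + rejected (adapter/identity/length)."""

    input_pairs: int = 0
    kept: int = 0
    rejected_adapter: int = 0
    rejected_identity: int = 0
    rejected_length: int = 0

    @property
    def conserved(self) -> bool:
        return self.input_pairs == (self.kept + self.rejected_adapter +
                                    self.rejected_identity + self.rejected_length)

    @property
    def kept_pct(self) -> float:
        return 100.0 * self.kept / self.input_pairs if self.input_pairs else 0.0


@dataclass
class DistinctReadSet:
    """Deduplicated sequences with occurrence counts for one library."""

    counts: dict[str, int] = field(default_factory=dict)
    label: str = ""

    @property
    def total_reads(self) -> int:
        return sum(self.counts.values())

    @property
    def distinct_reads(self) -> int:
        return len(self.counts)

    def sequences(self) -> list[str]:
        return sorted(self.counts)

    def subset(self, keep: Iterable[str], label: str | None = None
               ) -> "DistinctReadSet":
        keep = set(keep)
        return DistinctReadSet(
            {s: c for s, c in self.counts.items() if s in keep},
            label if label is not None else self.label)

    def restrict_lengths(self, lo: int, hi: int) -> "DistinctReadSet":
        return DistinctReadSet(
            {s: c for s, c in self.counts.items() if lo <= len(s) <= hi},
            self.label)

    def write_fasta(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for i, seq in enumerate(self.sequences()):
                fh.write(f">seq{i + 1:06d} count={self.counts[seq]}\n{seq}\n")

    @classmethod
    def read_fasta(cls, path: str | Path, label: str = "") -> "DistinctReadSet":
        counts: dict[str, int] = {}
        seq_lines: list[str] = []
        count = 1
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if line.startswith(">"):
                    if seq_lines:
                        counts["".join(seq_lines)] = count
                        seq_lines = []
                    count = 1
                    for tok in line[1:].split():
                        if tok.startswith("count="):
                            count = int(tok[6:])
                elif line:
                    seq_lines.append(line)
        if seq_lines:
            counts["".join(seq_lines)] = count
        return cls(counts, label)


def collapse_pairs(pairs: Iterable[tuple[str, str]], cfg: PrepConfig
                   ) -> tuple[Iterator[str], PrepStats]:
    """Trim and identity-collapse mate pairs; returns (kept inserts, stats).

    Mate 2 is reverse-complemented back into template orientation before
    trimming (TruSeq geometry), then handed to collapse_pair in its own
    orientation.  Length selection [min_len, max_len] is applied here so the
    stats partition the input exactly.
    """
    stats = PrepStats()
    kept: list[str] = []
    for r1, r2 in pairs:
        stats.input_pairs += 1
        i1 = trim_adapter(r1, cfg)
        i2_template = trim_adapter(revcomp(r2), cfg)
        if i1 is None or i2_template is None:
            stats.rejected_adapter += 1
            continue
        insert = collapse_pair(i1, revcomp(i2_template))
        if insert is None:
            stats.rejected_identity += 1
            continue
        if not cfg.min_len <= len(insert) <= cfg.max_len:
            stats.rejected_length += 1
            continue
        stats.kept += 1
        kept.append(insert)
    return iter(kept), stats


def build_distinct_set(sequences: Iterable[str], cfg: PrepConfig,
                       label: str = "") -> DistinctReadSet:
    """Deduplicate kept inserts; enforces length window and ACGT alphabet."""
    counts: dict[str, int] = {}
    for seq in sequences:
        if not cfg.min_len <= len(seq) <= cfg.max_len:
            continue
        if set(seq) - _ALPHABET:
            continue
        counts[seq] = counts.get(seq, 0) + 1
    return DistinctReadSet(counts, label)


def prep_fastq_pair(path1: str | Path, path2: str | Path, cfg: PrepConfig,
                    label: str = "") -> tuple[DistinctReadSet, PrepStats]:
    """FASTQ pair -> DistinctReadSet, the whole read-preparation stage."""
    kept, stats = collapse_pairs(iter_fastq_pairs(path1, path2), cfg)
    return build_distinct_set(kept, cfg, label), stats
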