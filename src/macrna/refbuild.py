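"""Concatenated macronuclear reference construction and telomere annotation.

Nanochromosomes are short (~2.2 kb), so the reference joins them into one
long sequence per chromosome file with 50-N spacers between records (chr1 for
complete, telomere-to-telomere nanochromosomes; chr2 for partial contigs).
The N spacers make cross-record alignments impossible while keeping a single
coordinate system, inverted exactly by the offsets table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from ._util import read_fasta, revcomp, tile

SPACER = "spacer"  # sentinel returned by global_to_local inside a spacer

DEFAULT_TELOMERE_UNIT = "GGGGTTTT"
DEFAULT_MIN_RUN = 12


@dataclass
class ConcatReference:
    """One chromosome file: records joined by N spacers, plus offset arithmetic."""

    name: str
    record_ids: list[str]
    record_lengths: list[int]
    offsets: list[int]
    sequence: str
    spacer_len: int = 50
    _index: object = field(default=None, repr=False, compare=False)

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def n_records(self) -> int:
        return len(self.record_ids)

    def global_to_local(self, gpos: int) -> tuple[str, int] | str:
        """Invert the offset arithmetic; spacer positions return SPACER."""
        if not 0 <= gpos < len(self.sequence):
            raise IndexError(f"global position {gpos} out of range")
        import bisect
        k = bisect.bisect_right(self.offsets, gpos) - 1
        local = gpos - self.offsets[k]
        if local >= self.record_lengths[k]:
            return SPACER
        return self.record_ids[k], local

    def local_to_global(self, record_id: str, pos: int) -> int:
        k = self.record_ids.index(record_id)
        if not 0 <= pos < self.record_lengths[k]:
            raise IndexError(f"local position {pos} out of range for {record_id}")
        return self.offsets[k] + pos

    def record_seq(self, record_id: str) -> str:
        k = self.record_ids.index(record_id)
        off = self.offsets[k]
        return self.sequence[off: off + self.record_lengths[k]]

    def offsets_table(self) -> pd.DataFrame:
        return pd.DataFrame({"id": self.record_ids,
                             "length": self.record_lengths,
                             "offset": self.offsets})

    def index(self):
        """Lazily built alignment index over the concatenated sequence."""
        if self._index is None:
            from .aligncore import SeqIndex
            self._index = SeqIndex(self.sequence, name=self.name)
        return self._index


def build_concat(records: list[tuple[str, str]] | str | Path,
                 spacer_len: int = 50, name: str = "chr1") -> ConcatReference:
    """Concatenate records with `spacer_len` Ns between them.

    Duplicate ids and records containing N are errors; a single record gets no
    spacer.  global_offset(k+1) = global_offset(k) + length(k) + spacer_len.
    """
    if isinstance(records, (str, Path)):
        records = read_fasta(records)
    if not records:
        raise ValueError("no records to concatenate")
    ids = [r[0] for r in records]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate record ids in reference input")
    parts, offsets, lengths = [], [], []
    pos = 0
    spacer = "N" * spacer_len
    for i, (rid, seq) in enumerate(records):
        seq = seq.upper()
        if "N" in seq:
            raise ValueError(f"record {rid} contains N")
        if i:
            parts.append(spacer)
            pos += spacer_len
        offsets.append(pos)
        lengths.append(len(seq))
        parts.append(seq)
        pos += len(seq)
    return ConcatReference(name, ids, lengths, offsets, "".join(parts), spacer_len)


def _end_run(seq: str, unit: str, end: str) -> int:
    """Maximal end-anchored run of `unit` (any phase, partial repeats allowed)."""
    u, L = len(unit), len(seq)
    best = 0
    for phase in range(u):
        run = 0
        if end == "3":
            # pattern aligned so seq[-1] corresponds to unit[(phase - 1) % u]
            while run < L and seq[L - 1 - run] == unit[(phase - 1 - run) % u]:
                run += 1
        else:
            while run < L and seq[run] == unit[(phase + run) % u]:
                run += 1
        best = max(best, run)
    return best


def locate_telomeres(seq: str, unit: str = DEFAULT_TELOMERE_UNIT,
                     min_run: int = DEFAULT_MIN_RUN) -> tuple[int, int]:
    """(tel5, tel3): maximal end-anchored telomere runs, 0 when below min_run.

    The 5' end of the plus strand carries the reverse-complement unit, the 3'
    end the unit itself.
    """
    tel5 = _end_run(seq, revcomp(unit), "5")
    tel3 = _end_run(seq, unit, "3")
    return (tel5 if tel5 >= min_run else 0, tel3 if tel3 >= min_run else 0)


def annotate_reference(records: list[tuple[str, str]],
                       unit: str = DEFAULT_TELOMERE_UNIT,
                       min_run: int = DEFAULT_MIN_RUN) -> pd.DataFrame:
    """Telomere annotation per record; `complete` = both ends carry a run."""
    rows = []
    for rid, seq in records:
        t5, t3 = locate_telomeres(seq, unit, min_run)
        rows.append({"id": rid, "length": len(seq), "tel5": t5, "tel3": t3,
                     "complete": bool(t5 and t3)})
    return pd.DataFrame(rows)


def split_by_completeness(records: list[tuple[str, str]],
                          unit: str = DEFAULT_TELOMERE_UNIT,
                          min_run: int = DEFAULT_MIN_RUN
                          ) -> tuple[list[tuple[str, str]], list[tuple[str, str]]]:
    """Partition records into (complete nanochromosomes, partial contigs).

    Complete records (both telomeres detected) go to the chr1 collection; the
    rest are the chr2 class.
    """
    ann = annotate_reference(records, unit, min_run)
    complete = set(ann.loc[ann["complete"], "id"])
    chr1 = [r for r in records if r[0] in complete]
    chr2 = [r for r in records if r[0] not in complete]
    return chr1, chr2


def write_offsets_table(ref: ConcatReference, annotation: pd.DataFrame | None,
                        path: str | Path) -> None:
    df = ref.offsets_table()
    if annotation is not None:
        df = df.merge(annotation[["id", "tel5", "tel3"]], on="id", how="left")
    df.to_csv(path, sep="\t", index=False)


def rebuild_from_offsets(records: list[tuple[str, str]], table: pd.DataFrame,
                         spacer_len: int = 50, name: str = "chr1") -> str:
    """Reassemble the concatenated sequence from an offsets table (round-trip check)."""
    seqs = dict(records)
    total = int(table["offset"].iloc[-1] + table["length"].iloc[-1])
    out = ["N"] * total
    for _, row in table.iterrows():
        off = int(row["offset"])
        seq = seqs[row["id"]]
        out[off: off + len(seq)] = seq
    return "".join(out)
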