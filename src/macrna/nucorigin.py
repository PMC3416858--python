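"""Micronuclear-vs-macronuclear origin classification of 26-28 nt reads.

Each distinct read is aligned (both strands, exact by default) to the
micronuclear and macronuclear versions of a gene pair and assigned to the
Venn regions: intersection (present in both), micro-only (IES or MDS/IES
junction sequence, absent from the somatic genome) or macro-only (spanning an
MDS/MDS junction beyond both copies of the pointer, a configuration that only
exists after IES removal).  An excess of macro-only over micro-only reads is
the signature of a parental-macronucleus origin.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .aligncore import AlignPolicy, SeqIndex, align_read_all_sites
from .readprep import DistinctReadSet
from .synthdata import MacroGene, MicroLocus, reconstruct_macro

VENN_POLICY = AlignPolicy(max_mismatches=0)
READ_BAND = (26, 28)


@dataclass
class GenePair:
    """Trimmed micronuclear/macronuclear sequence pair for one gene.

    Both sequences are trimmed so the macronuclear sequence is fully contained
    in the micronuclear clone: the only differences left are IESs and the
    duplicated pointers (micro_len = macro_len + sum(IES) + sum(pointer)).
    """

    name: str
    micro: str
    macro: str
    n_mds: int = 0
    scrambled: bool = False
    decomposition: MicroLocus | None = None

    @classmethod
    def from_synth(cls, gene: MacroGene, locus: MicroLocus) -> "GenePair":
        return cls(gene.id, locus.micro_sequence, gene.interior,
                   n_mds=locus.n_mds, scrambled=locus.scrambled,
                   decomposition=locus)


def validate_gene_pair(pair: GenePair) -> dict:
    """Check the pair's internal consistency; report-only, never raises.

    With a decomposition: verifies the length identity
    micro = macro + sum(IES) + sum(pointer) and the exact round-trip
    (IES removal + pointer dedup + unscrambling reproduces the macro
    sequence), reporting the first mismatch position on failure.  Without
    one: greedy shared-anchor walk measuring what fraction of the macro
    sequence is covered by long exact matches to the micro clone.
    """
    report: dict = {"gene": pair.name, "ok": True, "errors": []}
    loc = pair.decomposition
    if loc is not None:
        expected = len(pair.macro) + sum(len(i) for i in loc.ies_seqs) + \
            sum(loc.pointer_lens)
        if len(pair.micro) != expected:
            report["ok"] = False
            report["errors"].append(
                f"length identity fails: micro {len(pair.micro)} != "
                f"macro {len(pair.macro)} + IES + pointers = {expected}")
        try:
            rebuilt = reconstruct_macro(loc)
        except ValueError as exc:
            report["ok"] = False
            report["errors"].append(str(exc))
            return report
        if rebuilt != pair.macro:
            first = next((i for i, (a, b) in enumerate(zip(rebuilt, pair.macro))
                          if a != b), min(len(rebuilt), len(pair.macro)))
            report["ok"] = False
            report["errors"].append(
                f"reassembly mismatch at macro position {first}")
        return report
    # anchor-based report for pairs without a decomposition
    anchor = 20
    idx = SeqIndex(pair.micro, name="micro")
    covered = 0
    pos = 0
    while pos + anchor <= len(pair.macro):
        probe = pair.macro[pos:pos + anchor]
        if align_read_all_sites(probe, idx, AlignPolicy(max_mismatches=0),
                                first_only=True):
            covered += anchor
            pos += anchor
        else:
            pos += 1
    frac = covered / max(len(pair.macro), 1)
    report["anchor_coverage"] = round(frac, 4)
    report["ok"] = frac > 0.9
    return report


@dataclass
class VennCounts:
    """Distinct-read Venn membership for one gene pair.

    Union = Xsect + OnlyMicro + OnlyMacro; Micro = Xsect + OnlyMicro;
    Macro = Xsect + OnlyMacro; percentages are of the union.
    """

    gene: str
    micro_count: int = 0
    macro_count: int = 0
    xsect_count: int = 0
    only_micro_count: int = 0
    only_macro_count: int = 0

    @property
    def union_count(self) -> int:
        return self.xsect_count + self.only_micro_count + self.only_macro_count

    def _pct(self, x: int) -> float:
        return round(100.0 * x / self.union_count, 2) if self.union_count else 0.0

    @property
    def xsect_pct(self) -> float:
        return self._pct(self.xsect_count)

    @property
    def only_micro_pct(self) -> float:
        return self._pct(self.only_micro_count)

    @property
    def only_macro_pct(self) -> float:
        return self._pct(self.only_macro_count)

    def __add__(self, other: "VennCounts") -> "VennCounts":
        return VennCounts(self.gene,
                          self.micro_count + other.micro_count,
                          self.macro_count + other.macro_count,
                          self.xsect_count + other.xsect_count,
                          self.only_micro_count + other.only_micro_count,
                          self.only_macro_count + other.only_macro_count)


def classify_venn(reads: DistinctReadSet, pair: GenePair,
                  policy: AlignPolicy = VENN_POLICY) -> VennCounts:
    """Venn-classify every distinct 26-28 nt read against one gene pair.

    Each read is tested on both strands of both versions with all mappings
    retained; membership is existence of any site within the mismatch policy.
    """
    micro_idx = SeqIndex(pair.micro, name="micro")
    macro_idx = SeqIndex(pair.macro, name="macro")
    vc = VennCounts(pair.name)
    lo, hi = READ_BAND
    for seq in reads.counts:
        if not lo <= len(seq) <= hi:
            continue
        in_micro = bool(align_read_all_sites(seq, micro_idx, policy,
                                             first_only=True))
        in_macro = bool(align_read_all_sites(seq, macro_idx, policy,
                                             first_only=True))
        if in_micro:
            vc.micro_count += 1
        if in_macro:
            vc.macro_count += 1
        if in_micro and in_macro:
            vc.xsect_count += 1
        elif in_micro:
            vc.only_micro_count += 1
        elif in_macro:
            vc.only_macro_count += 1
    return vc


def classify_venn_pooled(read_sets: Sequence[DistinctReadSet], pair: GenePair,
                         policy: AlignPolicy = VENN_POLICY,
                         mode: str = "sum_per_library") -> VennCounts:
    """Pool several libraries for one gene.

    mode="sum_per_library" (default): classify each library's distinct reads
    separately and add the counts, so a sequence present in k libraries
    contributes k.  mode="distinct_union": classify the union of distinct
    sequences once.
    """
    if mode == "sum_per_library":
        total = VennCounts(pair.name)
        for rs in read_sets:
            total = total + classify_venn(rs, pair, policy)
        return total
    if mode == "distinct_union":
        union: dict[str, int] = {}
        for rs in read_sets:
            for s, c in rs.counts.items():
                union[s] = union.get(s, 0) + c
        return classify_venn(DistinctReadSet(union, "pooled"), pair, policy)
    raise ValueError(f"unknown pooling mode {mode!r}")


def tabulate_venn(pairs: Sequence[GenePair], counts: Sequence[VennCounts]
                  ) -> pd.DataFrame:
    """Assemble the per-gene Venn table in the conventional column layout."""
    rows = []
    for pair, vc in zip(pairs, counts, strict=True):
        rows.append({
            "Gene": pair.name,
            "Micro Length": len(pair.micro),
            "Macro Length": len(pair.macro),
            "MDSs": pair.n_mds,
            "Scrambled?": "Yes" if pair.scrambled else "No",
            "MicroCount": vc.micro_count,
            "MacroCount": vc.macro_count,
            "UnionCount": vc.union_count,
            "XsectCount": vc.xsect_count,
            "XsectPct": f"{vc.xsect_pct:.2f}%",
            "OnlyMicroCount": vc.only_micro_count,
            "OnlyMicroPct": f"{vc.only_micro_pct:.2f}%",
            "OnlyMacroCount": vc.only_macro_count,
            "OnlyMacroPct": f"{vc.only_macro_pct:.2f}%",
        })
    return pd.DataFrame(rows)
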