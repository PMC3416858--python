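"""Synthetic ciliate genomes and small-RNA libraries with ground-truth labels.

This module emulates the genome architecture of stichotrichous ciliates such as
*Oxytricha trifallax*: a somatic macronucleus made of gene-sized nanochromosomes
(~2.2 kb on average) capped by telomeric repeats at both ends, and a germline
micronucleus in which each gene is interrupted by internally eliminated
sequences (IESs) flanked by short duplicated "pointer" repeats, with the
macronuclear-destined segments (MDSs) possibly permuted and strand-inverted
("scrambled").

On top of the genomes it simulates a mating-induced small-RNA population:
bidirectional production from both nanochromosome strands, discrete length
classes (20/21/22 nt vegetative, 26-28 nt mating), a strong 5'-uridine bias,
highly non-uniform per-position production rates (gamma-distributed hotspots),
depletion of reads overlapping the subtelomeric zone, non-coding-RNA
contamination, and paired-end 100 bp sequencing in which read 2 may disagree
with read 1.  Every simulated read carries a ground-truth origin label so each
downstream pipeline stage can be scored exactly.
"""

from __future__ import annotations

import gzip
import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from ._util import random_dna, revcomp, tile

VEGETATIVE_WEIGHTS = {20: 0.3, 21: 0.4, 22: 0.3}
MATING_WEIGHTS = {26: 0.1, 27: 0.8, 28: 0.1}


class ConfigError(ValueError):
    """Raised when a GeneratorConfig violates its invariants."""


@dataclass
class GeneratorConfig:
    """All tunable knobs of the simulator.

    Defaults describe a mating library: 200 nanochromosomes of mean length
    2,200 nt (SD 800, clipped at 500), 20-nt telomeres built from the
    GGGGTTTT repeat, ~1,000 reads per nanochromosome (lognormal dispersion
    across genes emulating differential nanochromosome amplification),
    26:27:28 length weights of 0.1:0.8:0.1, a 0.97 probability that the 5'
    base is U, gamma hotspot shape 0.05 (smaller = spikier), an 8-fold
    depletion of reads overlapping the 30 nt immediately interior to each
    telomere, equal strand output, 15% ncRNA contamination, and a 0.5% per-base
    chance that read 2 disagrees with read 1.
    """

    seed: int = 0
    n_nano: int = 200
    nano_len_mean: float = 2200.0
    nano_len_sd: float = 800.0
    telomere_unit: str = "GGGGTTTT"
    telomere_len: int = 20
    gc: float = 0.5
    mode: str = "mating"
    class_weights: dict[int, float] | None = None
    reads_per_nano_mean: float = 1000.0
    reads_per_nano_sigma: float = 1.0
    strand_p: float = 0.5
    hotspot_shape: float = 0.05
    deplete_zone: int = 30
    deplete_factor: float = 8.0
    u5_bias: float = 0.97
    n_ncrna_decoys: int = 20
    ncrna_contam_frac: float = 0.15
    micro_only_frac: float = 0.0
    pair_error_rate: float = 0.005
    adapter3: str = "TGGAATTCTCGGGTGCCAAGG"

    @property
    def weights(self) -> dict[int, float]:
        if self.class_weights is not None:
            return self.class_weights
        return MATING_WEIGHTS if self.mode == "mating" else VEGETATIVE_WEIGHTS

    @property
    def min_nano_len(self) -> int:
        return 2 * self.telomere_len + 2 * self.deplete_zone + 100

    def validate(self) -> None:
        probs = {
            "gc": self.gc, "strand_p": self.strand_p, "u5_bias": self.u5_bias,
            "ncrna_contam_frac": self.ncrna_contam_frac,
            "micro_only_frac": self.micro_only_frac,
            "pair_error_rate": self.pair_error_rate,
        }
        for name, p in probs.items():
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {p}")
        if self.telomere_len <= 0:
            raise ConfigError("telomere_len must be positive")
        if set(self.telomere_unit) - set("ACGT"):
            raise ConfigError("telomere_unit must be ACGT only")
        if self.mode not in ("vegetative", "mating"):
            raise ConfigError(f"unknown mode {self.mode!r}")
        if self.nano_len_mean < self.min_nano_len:
            raise ConfigError(
                f"nano_len_mean {self.nano_len_mean} admits sequences shorter than "
                f"the minimum {self.min_nano_len} "
                "(2*telomere_len + 2*deplete_zone + 100)")
        if abs(sum(self.weights.values()) - 1.0) > 1e-9:
            raise ConfigError("class_weights must sum to 1")
        if self.deplete_factor < 1.0:
            raise ConfigError("deplete_factor must be >= 1")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass
class MacroGene:
    """A macronuclear nanochromosome: telomere - interior - telomere."""

    id: str
    sequence: str
    tel5_len: int
    tel3_len: int

    @property
    def interior(self) -> str:
        return self.sequence[self.tel5_len: len(self.sequence) - self.tel3_len]

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class MDSDescriptor:
    """One macronuclear-destined segment.

    Macro coordinates are on the nanochromosome interior, 0-based half-open;
    adjacent MDSs overlap by their shared pointer.  micro_order_index gives the
    segment's position in the micronuclear locus and `inverted` whether it
    appears there reverse-complemented.
    """

    macro_start: int
    macro_end: int
    micro_order_index: int
    inverted: bool
    micro_start: int = -1
    micro_end: int = -1


@dataclass
class MicroLocus:
    """Micronuclear precursor of a macronuclear gene.

    micro_sequence = MDS segments (in micronuclear order, possibly inverted)
    interleaved with IESs.  Each pointer is present twice here (once at each
    flank of its IES) but only once in the macronuclear product, so
    len(micro) = len(macro interior) + sum(IES) + sum(pointer).
    """

    gene_id: str
    mds_list: list[MDSDescriptor]          # in macronuclear order
    ies_seqs: list[str]                    # in micronuclear slot order
    pointer_lens: list[int]                # in macronuclear junction order
    micro_sequence: str
    scrambled: bool = False

    @property
    def n_mds(self) -> int:
        return len(self.mds_list)

    @property
    def ies_intervals_micro(self) -> list[tuple[int, int]]:
        """0-based half-open intervals of the IESs on the micronuclear sequence."""
        out, pos = [], 0
        in_micro_order = sorted(self.mds_list, key=lambda d: d.micro_order_index)
        for i, d in enumerate(in_micro_order):
            pos = d.micro_end
            if i < len(self.ies_seqs):
                out.append((pos, pos + len(self.ies_seqs[i])))
        return out

    @property
    def macro_junctions(self) -> list[tuple[int, int]]:
        """(cut position on the macro interior, pointer length) per junction."""
        return [(d.macro_end, p)
                for d, p in zip(self.mds_list[:-1], self.pointer_lens)]


def reconstruct_macro(locus: MicroLocus) -> str:
    """Undo IES removal, pointer deduplication and unscrambling.

    Independent of how the locus was built: reads MDS segments back out of the
    micronuclear sequence, reverse-complements inverted ones, reorders them by
    macronuclear coordinate and joins them, keeping a single pointer copy per
    junction.  Must reproduce the macronuclear interior byte-for-byte.
    """
    segs = []
    for d in locus.mds_list:
        s = locus.micro_sequence[d.micro_start: d.micro_end]
        if d.inverted:
            s = revcomp(s)
        segs.append((d.macro_start, s))
    segs.sort()
    out = [segs[0][1]]
    for (_, seg), plen in zip(segs[1:], locus.pointer_lens):
        if plen and seg[:plen] != out[-1][-plen:]:
            raise ValueError("pointer copies disagree; corrupt locus")
        out.append(seg[plen:])
    return "".join(out)


@dataclass
class SmallRNARecord:
    sequence: str
    gene_id: str
    strand: str          # "+" or "-" on the source sequence
    start: int           # 0-based 5'-end position on the source plus strand
    length_class: int
    origin: str          # macro | micro_only | ncrna


@dataclass
class SmallRNAPool:
    records: list[SmallRNARecord] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    def counts_by_origin(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for r in self.records:
            out[r.origin] = out.get(r.origin, 0) + 1
        return out


# ----------------------------------------------------------------------------
# genome generation
# ----------------------------------------------------------------------------

def _has_telomere_run(seq: str, unit: str, min_run: int = 12) -> bool:
    doubled = unit * (min_run // len(unit) + 2)
    probes = {doubled[i:i + min_run] for i in range(len(unit))}
    probes |= {revcomp(p) for p in probes}
    return any(p in seq for p in probes)


def gen_macro_gene(cfg: GeneratorConfig, rng: np.random.Generator,
                   gene_id: str = "nano0001") -> MacroGene:
    """Draw one nanochromosome.

    The plus strand begins with reverse-complement telomere repeats
    (CCCCAAAA... for the GGGGTTTT unit) and ends with the unit itself, the
    single-stranded FASTA representation of a double-stranded telomere.  The
    interior is random DNA at the configured GC, re-drawn if it accidentally
    contains a telomere-like run, and its border bases are adjusted so the
    annotated telomere run does not extend into the interior.
    """
    cfg.validate()
    length = int(round(rng.normal(cfg.nano_len_mean, cfg.nano_len_sd)))
    length = max(length, 500, cfg.min_nano_len)
    tl = cfg.telomere_len
    unit = cfg.telomere_unit
    # 5' cap is the reverse complement of a 5'-anchored unit run, so for
    # GGGGTTTT the plus strand starts CCCCAAAA... and ends ...GGGGTTTT
    tel5 = revcomp(tile(unit, tl, anchor="start"))
    tel3 = tile(unit, tl, anchor="end")
    for _ in range(50):
        interior = random_dna(rng, length - 2 * tl, cfg.gc)
        if not _has_telomere_run(interior, unit):
            break
    else:  # pragma: no cover - astronomically unlikely
        raise RuntimeError("could not draw a telomere-free interior")
    # prevent the terminal runs from extending into the interior: the char
    # that would continue each periodic cap is tel5[tl - u] (period u) after
    # the 5' cap, and tel3[u - 1] before the 3' cap
    u = len(unit)
    ext5 = tel5[tl - u] if tl >= u else tile(revcomp(unit), tl + 1)[-1]
    ext3 = tel3[u - 1] if tl >= u else tile(unit, tl + 1, anchor="end")[0]
    alphabet = "ACGT"
    if interior[0] == ext5:
        interior = alphabet[(alphabet.index(ext5) + 1) % 4] + interior[1:]
    if interior[-1] == ext3:
        interior = interior[:-1] + alphabet[(alphabet.index(ext3) + 1) % 4]
    return MacroGene(gene_id, tel5 + interior + tel3, tl, tl)


def gen_genome(cfg: GeneratorConfig, rng: np.random.Generator | None = None
               ) -> list[MacroGene]:
    rng = rng if rng is not None else cfg.rng()
    return [gen_macro_gene(cfg, rng, gene_id=f"nano{i + 1:05d}")
            for i in range(cfg.n_nano)]


_MIN_MDS = 25  # minimum macro span of one MDS, keeps junctions well separated


def gen_micro_locus(gene: MacroGene, n_mds: int, scrambled: bool,
                    rng: np.random.Generator,
                    ies_lens: Sequence[int] | None = None,
                    pointer_lens: Sequence[int] | None = None,
                    gc: float = 0.5) -> MicroLocus:
    """Build a micronuclear precursor for `gene` with `n_mds` segments.

    Pointers are the actual macronuclear subsequence at each junction
    (2-20 nt); IES lengths default to 20-80 nt.  IES border bases are re-drawn
    when they would extend a pointer match across the junction, so the MDS/IES
    decomposition is unambiguous and reconstruction is exact.  When
    `scrambled`, the micronuclear MDS order is a non-identity permutation and
    each MDS may be strand-inverted.
    """
    macro = gene.interior
    G = len(macro)
    if n_mds < 1:
        raise ValueError("n_mds must be >= 1")
    if n_mds == 1:
        d = MDSDescriptor(0, G, 0, False, 0, G)
        return MicroLocus(gene.id, [d], [], [], macro, scrambled=False)
    J = n_mds - 1
    if G < n_mds * _MIN_MDS:
        raise ValueError(f"interior of {G} nt cannot host {n_mds} MDSs")
    if pointer_lens is None:
        pointer_lens = rng.integers(2, 21, size=J).tolist()
    pointer_lens = list(pointer_lens)
    if ies_lens is None:
        ies_lens = rng.integers(20, 81, size=J).tolist()
    ies_lens = list(ies_lens)
    if len(ies_lens) != J or len(pointer_lens) != J:
        raise ValueError("need n_mds - 1 IES and pointer lengths")

    for _ in range(200):
        slack = G - n_mds * _MIN_MDS
        cuts = np.sort(rng.choice(slack + 1, size=J, replace=False)) if slack >= J \
            else np.arange(J)
        cuts = (cuts + _MIN_MDS * np.arange(1, J + 1)).tolist()
        pointers = [macro[c - l: c] for c, l in zip(cuts, pointer_lens)]
        if len(set(pointers)) == J and all(len(p) == l for p, l
                                           in zip(pointers, pointer_lens)):
            break
    else:
        raise ValueError("could not place distinct pointers; interior too short")

    # macro-order MDS intervals; adjacent intervals overlap by the pointer
    bounds = [0] + cuts + [G]
    descriptors = []
    for k in range(n_mds):
        start = bounds[k] - (pointer_lens[k - 1] if k > 0 else 0)
        descriptors.append(MDSDescriptor(start, bounds[k + 1], k, False))

    order = list(range(n_mds))
    inverted = [False] * n_mds
    if scrambled:
        while order == list(range(n_mds)):
            order = rng.permutation(n_mds).tolist()
        inverted = (rng.random(n_mds) < 0.5).tolist()
        if not any(inverted):
            inverted[int(rng.integers(n_mds))] = True
    for micro_idx, macro_idx in enumerate(order):
        descriptors[macro_idx].micro_order_index = micro_idx
        descriptors[macro_idx].inverted = inverted[macro_idx]

    # IESs, with border bases that cannot extend the flanking pointers
    ies_seqs = []
    for j, (c, l) in enumerate(zip(cuts, pointer_lens)):
        after, before = macro[c] if c < G else "", macro[c - l - 1] if c - l > 0 else ""
        for _ in range(50):
            ies = random_dna(rng, ies_lens[j], gc)
            if ies[0] != after and ies[-1] != before:
                break
        ies_seqs.append(ies)

    # assemble micronuclear sequence in micro order, recording intervals
    by_micro = sorted(descriptors, key=lambda d: d.micro_order_index)
    parts, pos = [], 0
    for i, d in enumerate(by_micro):
        seg = macro[d.macro_start: d.macro_end]
        if d.inverted:
            seg = revcomp(seg)
        d.micro_start, d.micro_end = pos, pos + len(seg)
        parts.append(seg)
        pos += len(seg)
        if i < J:
            parts.append(ies_seqs[i])
            pos += len(ies_seqs[i])
    locus = MicroLocus(gene.id, descriptors, ies_seqs, pointer_lens,
                       "".join(parts), scrambled=scrambled)
    if reconstruct_macro(locus) != macro:  # pragma: no cover - construction bug
        raise AssertionError("micronuclear locus failed round-trip reconstruction")
    return locus


def gen_ncrna_decoys(cfg: GeneratorConfig, rng: np.random.Generator
                     ) -> list[tuple[str, str]]:
    """Random decoy ncRNAs (rRNA/tRNA/snRNA stand-ins), 70-160 nt each."""
    out = []
    for i in range(cfg.n_ncrna_decoys):
        n = int(rng.integers(70, 161))
        out.append((f"ncrna{i + 1:04d}", random_dna(rng, n, cfg.gc)))
    return out


# ----------------------------------------------------------------------------
# small-RNA production
# ----------------------------------------------------------------------------

def _strand_rates(seq: str, positions: np.ndarray, strand: str,
                  cfg: GeneratorConfig, rng: np.random.Generator) -> np.ndarray:
    """Gamma hotspot rates per candidate 5'-end position, 5'-U reweighted.

    The 5'-U bias is imposed by reweighting candidate start positions (U-start
    positions carry total weight u5_bias), never by mutating sequence, so
    every read stays an exact genome substring.
    """
    w = rng.gamma(cfg.hotspot_shape, 1.0, size=len(positions))
    w = np.maximum(w, 1e-300)
    base = "T" if strand == "+" else "A"  # minus-strand 5' base U <=> plus-strand A
    is_u = np.frombuffer(seq.encode(), dtype="S1")[positions] == base.encode()
    b = cfg.u5_bias
    s_u, s_n = w[is_u].sum(), w[~is_u].sum()
    if s_u > 0 and s_n > 0:
        w[is_u] *= b / s_u
        w[~is_u] *= (1.0 - b) / s_n
    elif s_u == 0 and b > 0:
        warnings.warn(f"no U-start positions available on strand {strand}")
    return w / w.sum()


def _sample_gene_reads(gene: MacroGene, n_reads: int, cfg: GeneratorConfig,
                       rng: np.random.Generator) -> list[SmallRNARecord]:
    seq = gene.sequence
    L = len(seq)
    lengths = np.array(sorted(cfg.weights))
    lw = np.array([cfg.weights[int(l)] for l in lengths])
    lmax = int(lengths.max())
    lo5, hi3 = gene.tel5_len, L - gene.tel3_len
    pos_plus = np.arange(lo5, hi3 - lmax + 1)
    pos_minus = np.arange(lo5 + lmax - 1, hi3)
    if len(pos_plus) == 0 or len(pos_minus) == 0:
        warnings.warn(f"gene {gene.id} too short for any valid read; skipped")
        return []
    w_plus = _strand_rates(seq, pos_plus, "+", cfg, rng)
    w_minus = _strand_rates(seq, pos_minus, "-", cfg, rng)

    zones = [(lo5, lo5 + cfg.deplete_zone),
             (hi3 - cfg.deplete_zone, hi3)]

    def overlaps_zone(start: np.ndarray, end: np.ndarray) -> np.ndarray:
        m = np.zeros(len(start), dtype=bool)
        for zs, ze in zones:
            m |= (start < ze) & (end > zs)
        return m

    is_plus = rng.random(n_reads) < cfg.strand_p
    fivep = np.empty(n_reads, dtype=np.int64)
    rlen = np.empty(n_reads, dtype=np.int64)
    todo = np.arange(n_reads)
    while len(todo):
        tp = is_plus[todo]
        if tp.any():
            fivep[todo[tp]] = rng.choice(pos_plus, size=int(tp.sum()), p=w_plus)
        if (~tp).any():
            fivep[todo[~tp]] = rng.choice(pos_minus, size=int((~tp).sum()),
                                          p=w_minus)
        rlen[todo] = lengths[rng.choice(len(lengths), size=len(todo), p=lw)]
        start = np.where(is_plus[todo], fivep[todo], fivep[todo] - rlen[todo] + 1)
        end = start + rlen[todo]
        # reads overlapping the subtelomeric zone survive with prob 1/deplete_factor
        reject = overlaps_zone(start, end) & \
            (rng.random(len(todo)) >= 1.0 / cfg.deplete_factor)
        todo = todo[reject]

    out = []
    for p, l, plus in zip(fivep, rlen, is_plus):
        p, l = int(p), int(l)
        if plus:
            s, raw = p, seq[p: p + l]
        else:
            s, raw = p - l + 1, revcomp(seq[p - l + 1: p + 1])
        out.append(SmallRNARecord(raw, gene.id, "+" if plus else "-", s, l, "macro"))
    return out


def _sample_micro_only(loci: Sequence[MicroLocus], n: int, cfg: GeneratorConfig,
                       rng: np.random.Generator) -> list[SmallRNARecord]:
    """Reads forced to overlap IES-interior positions: absent from any macro gene."""
    lengths = np.array(sorted(cfg.weights))
    lw = np.array([cfg.weights[int(l)] for l in lengths])
    eligible = [(loc, iv) for loc in loci for iv in loc.ies_intervals_micro]
    out: list[SmallRNARecord] = []
    if not eligible:
        return out
    while len(out) < n:
        loc, (zs, ze) = eligible[int(rng.integers(len(eligible)))]
        l = int(lengths[rng.choice(len(lengths), p=lw)])
        lo = max(0, zs - l + 3)
        hi = min(len(loc.micro_sequence) - l, ze - 3)
        if hi < lo:
            continue
        s = int(rng.integers(lo, hi + 1))
        raw = loc.micro_sequence[s: s + l]
        if rng.random() < 0.5:
            out.append(SmallRNARecord(raw, loc.gene_id, "+", s, l, "micro_only"))
        else:
            out.append(SmallRNARecord(revcomp(raw), loc.gene_id, "-", s, l,
                                      "micro_only"))
    return out


def _sample_ncrna(decoys: Sequence[tuple[str, str]], n: int, cfg: GeneratorConfig,
                  rng: np.random.Generator) -> list[SmallRNARecord]:
    lengths = np.array(sorted(cfg.weights))
    lw = np.array([cfg.weights[int(l)] for l in lengths])
    out: list[SmallRNARecord] = []
    while len(out) < n:
        did, dseq = decoys[int(rng.integers(len(decoys)))]
        l = int(lengths[rng.choice(len(lengths), p=lw)])
        if len(dseq) < l:
            continue
        s = int(rng.integers(0, len(dseq) - l + 1))
        raw = dseq[s: s + l]
        strand = "+" if rng.random() < 0.5 else "-"
        out.append(SmallRNARecord(raw if strand == "+" else revcomp(raw),
                                  did, strand, s, l, "ncrna"))
    return out


def gen_small_rna_pool(genes: Sequence[MacroGene], loci: Sequence[MicroLocus],
                       cfg: GeneratorConfig, rng: np.random.Generator,
                       decoys: Sequence[tuple[str, str]] | None = None
                       ) -> SmallRNAPool:
    """Simulate the full small-RNA population for one library.

    Per-gene expected totals are lognormal around reads_per_nano_mean
    (emulating nanochromosome copy-number spread), strands are chosen with
    probability strand_p, positions follow per-strand gamma hotspot rates with
    the 5'-U reweighting, and reads overlapping the subtelomeric depletion
    zone are thinned by deplete_factor.  ncRNA contamination (and, when
    micro_only_frac > 0, germline-only reads from IESs) are appended on top.
    """
    if not genes:
        raise ValueError("need at least one gene")
    cfg.validate()
    records: list[SmallRNARecord] = []
    mu = cfg.reads_per_nano_mean * rng.lognormal(
        -cfg.reads_per_nano_sigma ** 2 / 2, cfg.reads_per_nano_sigma,
        size=len(genes))
    for gene, m in zip(genes, mu):
        n = int(rng.poisson(m))
        if n:
            records.extend(_sample_gene_reads(gene, n, cfg, rng))
    n_macro = len(records)
    other = cfg.ncrna_contam_frac + cfg.micro_only_frac
    if other > 0 and n_macro:
        total = n_macro / (1.0 - other)
        n_nc = int(round(total * cfg.ncrna_contam_frac))
        n_mi = int(round(total * cfg.micro_only_frac))
        if n_nc:
            if decoys is None:
                decoys = gen_ncrna_decoys(cfg, rng)
            records.extend(_sample_ncrna(decoys, n_nc, cfg, rng))
        if n_mi:
            records.extend(_sample_micro_only(loci, n_mi, cfg, rng))
    return SmallRNAPool(records)


# ----------------------------------------------------------------------------
# paired-end FASTQ emission
# ----------------------------------------------------------------------------

READ_LEN = 100


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hit = np.nonzero(rng.random(len(arr)) < rate)[0]
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    for i in hit:
        choices = bases[bases != arr[i]]
        arr[i] = choices[int(rng.integers(3))]
    return arr.tobytes().decode()


def emit_paired_fastq(pool: SmallRNAPool, cfg: GeneratorConfig,
                      path1: str | Path, path2: str | Path,
                      rng: np.random.Generator) -> None:
    """Write the pool as two 100 bp paired-end FASTQ files.

    Read 1 is insert + 3' adapter + random filler; read 2 is the reverse
    complement of the same template with per-base disagreement at
    pair_error_rate.  Ground-truth labels ride in the comment field.
    """
    def opener(p):
        p = Path(p)
        return gzip.open(p, "wt") if p.suffix == ".gz" else open(p, "w")

    qual = "I" * READ_LEN
    with opener(path1) as f1, opener(path2) as f2:
        for i, rec in enumerate(pool.records):
            pad = READ_LEN - len(rec.sequence) - len(cfg.adapter3)
            template = rec.sequence + cfg.adapter3 + random_dna(rng, max(pad, 0))
            template = template[:READ_LEN]
            read2 = _mutate(revcomp(template), cfg.pair_error_rate, rng)
            name = f"r{i:07d}"
            tag = (f"gene={rec.gene_id} strand={rec.strand} start={rec.start} "
                   f"len={rec.length_class} origin={rec.origin}")
            f1.write(f"@{name} {tag}\n{template}\n+\n{qual}\n")
            f2.write(f"@{name} {tag}\n{read2}\n+\n{qual}\n")


def write_truth_table(pool: SmallRNAPool, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("read_id\tgene_id\tstrand\tstart\tclass\torigin\n")
        for i, r in enumerate(pool.records):
            fh.write(f"r{i:07d}\t{r.gene_id}\t{r.strand}\t{r.start}\t"
                     f"{r.length_class}\t{r.origin}\n")


def write_config_echo(cfg: GeneratorConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(asdict(cfg), fh, indent=2, default=str)
        fh.write("\n")
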