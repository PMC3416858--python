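"""Strand balance, coverage uniformity and telomere-proximal density statistics.

Three observations characterize the mating-induced 26-28 nt class on
macronuclear nanochromosomes:

* the two strands of a nanochromosome produce closely correlated read counts
  (Pearson r, plus a binomial 2-SD envelope: under a fair per-read coin the
  plus/minus split of n reads has SD sqrt(n)/2, so |plus - minus| <=
  2*sqrt(plus + minus) should hold for ~95% of nanochromosomes);
* the per-position density of read 5' ends is highly non-uniform (coverage
  coefficient of variation, population SD / mean, peaking near 6 in the
  original data);
* a ~30 nt zone immediately interior to each telomere is strongly depleted
  (end-anchored 500-position windows, normalized per record to its own mean
  density, averaged across records and binned 20 x 25 nt).
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .aligncore import AlignmentHit

READ_BAND = (26, 28)


@dataclass
class EnvelopeConfig:
    k_sd: float = 2.0
    min_per_strand: int = 10
    band_quantile: float = 0.95

    def __post_init__(self) -> None:
        if self.k_sd <= 0:
            raise ValueError("k_sd must be positive")


@dataclass
class ProfileConfig:
    window: int = 500
    bin: int = 25
    zone: int = 30
    min_record_len: int = 500
    read_band: tuple[int, int] = READ_BAND
    read_len_shade: int = 27

    def __post_init__(self) -> None:
        if self.window % self.bin:
            raise ValueError("window must be divisible by bin")
        if self.min_record_len < self.window:
            raise ValueError("min_record_len must be >= window")

    @property
    def shaded_zone_len(self) -> int:
        """Usable zone length at the shaded end.

        At the end where a strand's 5' ends sit at least one read length from
        the record edge, the first shade positions are structurally empty and
        the trailing edge of the zone mixes depleted and non-depleted reads of
        different lengths; trimming the length-band spread (plus the two
        boundary positions) leaves positions that are depleted for every read
        length and reachable by every read length.
        """
        lo, hi = self.read_band
        return max(self.zone - (hi - lo) - 2, 1)


def filter_hits_by_length(hits_by_read: Mapping[str, Sequence[AlignmentHit]],
                          band: tuple[int, int] = READ_BAND
                          ) -> dict[str, list[AlignmentHit]]:
    lo, hi = band
    return {s: list(h) for s, h in hits_by_read.items() if lo <= len(s) <= hi}


# ----------------------------------------------------------------------------
# strand balance
# ----------------------------------------------------------------------------

def strand_count_table(hits_by_read: Mapping[str, Sequence[AlignmentHit]],
                       counts: Mapping[str, int],
                       record_ids: Iterable[str] | None = None,
                       cfg: EnvelopeConfig = EnvelopeConfig()) -> pd.DataFrame:
    """Per-nanochromosome plus/minus counts, total and distinct.

    Only records with at least cfg.min_per_strand 26-28 nt reads on BOTH
    strands qualify.  Pass record_ids to restrict to the complete
    (chr1-class) nanochromosomes.
    """
    keep = set(record_ids) if record_ids is not None else None
    total = defaultdict(lambda: [0, 0])
    distinct = defaultdict(lambda: [0, 0])
    for seq, hits in filter_hits_by_length(hits_by_read).items():
        c = counts.get(seq, 1)
        seen: set[tuple[str, str]] = set()
        for h in hits:
            if keep is not None and h.record_id not in keep:
                continue
            i = 0 if h.strand == "+" else 1
            total[h.record_id][i] += c
            if (h.record_id, h.strand) not in seen:
                distinct[h.record_id][i] += 1
                seen.add((h.record_id, h.strand))
    rows = []
    for rid in sorted(total):
        pt, mt = total[rid]
        pdist, mdist = distinct[rid]
        if pt >= cfg.min_per_strand and mt >= cfg.min_per_strand:
            rows.append({"record_id": rid, "plus_total": pt, "minus_total": mt,
                         "plus_distinct": pdist, "minus_distinct": mdist})
    return pd.DataFrame(rows, columns=["record_id", "plus_total", "minus_total",
                                       "plus_distinct", "minus_distinct"])


def pearson_r(rows: pd.DataFrame, basis: str = "total") -> float:
    """Product-moment correlation of (plus, minus) counts; NaN if degenerate."""
    if basis not in ("total", "distinct"):
        raise ValueError("basis must be 'total' or 'distinct'")
    if len(rows) < 2:
        raise ValueError("need at least two rows")
    x = rows[f"plus_{basis}"].to_numpy(float)
    y = rows[f"minus_{basis}"].to_numpy(float)
    if x.std() == 0 or y.std() == 0:
        return float("nan")
    return float(stats.pearsonr(x, y).statistic)


def envelope_inside(plus, minus, cfg: EnvelopeConfig = EnvelopeConfig()):
    """|plus - minus| <= k_sd * sqrt(plus + minus); boundary and 0+0 are inside.

    This is the +-k_sd locus of Binomial(n = plus + minus, 1/2), which has
    mean n/2 and SD sqrt(n)/2.
    """
    p = np.asarray(plus, dtype=float)
    m = np.asarray(minus, dtype=float)
    inside = np.abs(p - m) <= cfg.k_sd * np.sqrt(p + m)
    inside = inside | ((p + m) == 0)
    return bool(inside) if inside.ndim == 0 else inside


def envelope_inside_fraction(plus, minus,
                             cfg: EnvelopeConfig = EnvelopeConfig()) -> float:
    return float(np.mean(envelope_inside(plus, minus, cfg)))


def simulate_balanced_null(n_records: int, total_lo: int, total_hi: int,
                           rng: np.random.Generator, p: float = 0.5
                           ) -> tuple[np.ndarray, np.ndarray]:
    """Balanced-strand null: totals uniform on [lo, hi], per-read fair coin."""
    totals = rng.integers(total_lo, total_hi + 1, size=n_records)
    plus = rng.binomial(totals, p)
    return plus, totals - plus


def empirical_band(rows: pd.DataFrame, basis: str = "total",
                   cfg: EnvelopeConfig = EnvelopeConfig()) -> float:
    """Scale factor k such that |p - m| <= k*sqrt(p + m) holds for band_quantile
    of the rows (the measured analogue of the theoretical 2-SD envelope)."""
    if len(rows) < 20:
        raise ValueError("need at least 20 rows for an empirical band")
    p = rows[f"plus_{basis}"].to_numpy(float)
    m = rows[f"minus_{basis}"].to_numpy(float)
    n = p + m
    z = np.abs(p - m)[n > 0] / np.sqrt(n[n > 0])
    return float(np.quantile(z, cfg.band_quantile))


# ----------------------------------------------------------------------------
# coverage uniformity
# ----------------------------------------------------------------------------

def start_position_counts(hits_by_read: Mapping[str, Sequence[AlignmentHit]],
                          counts: Mapping[str, int], record_id: str,
                          record_len: int, strands: str = "both"
                          ) -> np.ndarray:
    """Counts of read 5' ends per position of one record (count-weighted).

    Each read is counted at its own-strand 5' position; strands "both"
    (pooled, the default), "+" or "-".
    """
    arr = np.zeros(record_len, dtype=float)
    for seq, hits in hits_by_read.items():
        c = counts.get(seq, 1)
        for h in hits:
            if h.record_id != record_id:
                continue
            if strands != "both" and h.strand != strands:
                continue
            arr[h.five_prime_pos] += c
    return arr


def coverage_cv(start_counts: np.ndarray) -> float:
    """Population SD of per-position 5'-end counts divided by their mean.

    Uniform coverage gives 0; all reads on one of L positions gives
    sqrt(L - 1).  Telomeric positions are included (their near-zero counts
    are part of the observed non-uniformity).
    """
    arr = np.asarray(start_counts, dtype=float)
    mean = arr.mean()
    if mean == 0:
        raise ValueError("record has no hits; CV undefined")
    return float(arr.std() / mean)


def cv_table(hits_by_read: Mapping[str, Sequence[AlignmentHit]],
             counts: Mapping[str, int],
             record_lengths: Mapping[str, int],
             strands: str = "both") -> pd.DataFrame:
    """Coverage CV per record, 26-28 nt reads, both strands pooled by default."""
    band_hits = filter_hits_by_length(hits_by_read)
    per_record: dict[str, np.ndarray] = {}
    for seq, hits in band_hits.items():
        c = counts.get(seq, 1)
        for h in hits:
            if h.record_id not in record_lengths:
                continue
            if strands != "both" and h.strand != strands:
                continue
            arr = per_record.get(h.record_id)
            if arr is None:
                arr = per_record.setdefault(
                    h.record_id, np.zeros(record_lengths[h.record_id]))
            arr[h.five_prime_pos] += c
    rows = [{"record_id": rid, "n_reads": int(arr.sum()),
             "cv": coverage_cv(arr)}
            for rid, arr in sorted(per_record.items()) if arr.sum() > 0]
    return pd.DataFrame(rows, columns=["record_id", "n_reads", "cv"])


# ----------------------------------------------------------------------------
# telomere-proximal density profile
# ----------------------------------------------------------------------------

@dataclass
class EndProfile:
    """End-anchored mean relative 5'-end density, per record end.

    positions[end][x] is the mean over records of (5'-end count at distance x
    from that record end) / (the record's own mean density over the window),
    so a uniform distribution gives 1.0 everywhere.  For the depletion-fold
    estimate, zone_mean/base_mean accumulate each record's mean raw count over
    its depletion zone (anchored at the interior edge of the annotated
    telomere, shifted past the read-length shade where geometry forces
    emptiness) and over the undepleted remainder of the window; pooling the
    raw means weighs records by depth, which keeps the fold estimate stable
    under the heavy-tailed hotspot landscape.
    """

    strand: str
    cfg: ProfileConfig
    n_records: int
    positions: dict[str, np.ndarray]             # end -> length-window array
    zone_mean: dict[str, float] = field(default_factory=dict)
    base_mean: dict[str, float] = field(default_factory=dict)
    mean_telomere: float = 0.0

    def binned(self) -> pd.DataFrame:
        rows = []
        nb = self.cfg.window // self.cfg.bin
        for end in ("five_prime", "three_prime"):
            arr = self.positions[end]
            for b in range(nb):
                chunk = arr[b * self.cfg.bin:(b + 1) * self.cfg.bin]
                rows.append({"end": end, "strand": self.strand,
                             "bin_start": b * self.cfg.bin,
                             "bin_end": (b + 1) * self.cfg.bin,
                             "relative_density": float(chunk.mean())})
        return pd.DataFrame(rows)


def _window_from_end(arr: np.ndarray, end: str, window: int) -> np.ndarray:
    return arr[:window] if end == "five_prime" else arr[::-1][:window]


def telomere_end_profile(hits_by_read: Mapping[str, Sequence[AlignmentHit]],
                         counts: Mapping[str, int],
                         record_lengths: Mapping[str, int],
                         annotations: pd.DataFrame,
                         cfg: ProfileConfig = ProfileConfig(),
                         strand: str = "+") -> EndProfile:
    """End-anchored relative density of 26-28 nt 5' ends for one strand.

    For every complete record of at least cfg.min_record_len, count the
    requested strand's 5' ends over the cfg.window positions anchored at each
    record end, normalize by the record's own window mean, then average
    across records.  The depletion zone per record starts at the interior
    edge of its annotated telomere; at the end where the strand's reads
    cannot place a 5' end for geometric reasons (plus strand at the 3' end,
    minus strand at the 5' end) the zone is shifted a further
    cfg.read_len_shade positions inward, past the shaded gap.
    """
    ann = annotations.set_index("id")
    band_hits = filter_hits_by_length(hits_by_read)
    per_record: dict[str, np.ndarray] = {}
    for seq, hits in band_hits.items():
        c = counts.get(seq, 1)
        for h in hits:
            rid = h.record_id
            if rid not in record_lengths or h.strand != strand:
                continue
            if record_lengths[rid] < cfg.min_record_len:
                continue
            arr = per_record.get(rid)
            if arr is None:
                arr = per_record.setdefault(rid, np.zeros(record_lengths[rid]))
            arr[h.five_prime_pos] += c

    sums = {e: np.zeros(cfg.window) for e in ("five_prime", "three_prime")}
    nrec = {e: 0 for e in sums}
    zone_sum = {e: 0.0 for e in sums}
    base_sum = {e: 0.0 for e in sums}
    shade_end = "three_prime" if strand == "+" else "five_prime"
    tel_used = []
    for rid, arr in sorted(per_record.items()):
        if rid not in ann.index:
            continue
        tels = {"five_prime": int(ann.loc[rid, "tel5"]),
                "three_prime": int(ann.loc[rid, "tel3"])}
        for end in sums:
            win = _window_from_end(arr, end, cfg.window)
            mean = win.mean()
            if mean == 0:
                continue
            sums[end] += win / mean
            nrec[end] += 1
            if end == shade_end:
                z0, zlen = tels[end] + cfg.read_len_shade, cfg.shaded_zone_len
            else:
                z0, zlen = tels[end], cfg.zone
            b0 = tels[end] + cfg.read_len_shade + cfg.zone  # past every depressed position
            zone_sum[end] += float(win[z0:z0 + zlen].mean())
            base_sum[end] += float(win[b0:].mean())
            tel_used.append(tels[end])
    if not any(nrec.values()):
        raise ValueError("no qualifying records for the end profile")
    positions = {e: (sums[e] / nrec[e] if nrec[e] else sums[e]) for e in sums}
    return EndProfile(strand=strand, cfg=cfg,
                      n_records=max(nrec.values()), positions=positions,
                      zone_mean=zone_sum, base_mean=base_sum,
                      mean_telomere=float(np.mean(tel_used)) if tel_used else 0.0)


def depletion_fold(profiles: EndProfile | Sequence[EndProfile]
                   ) -> dict[str, float]:
    """Fold depletion of the subtelomeric zone relative to undepleted density.

    fold = (pooled mean density over the undepleted window positions) /
    (pooled mean density over the zone positions immediately interior to the
    annotated telomere, shade-shifted at the geometrically empty end).
    Reported per end and pooled; passing profiles for both strands pools
    them.  A zone with zero density reports inf.
    """
    if isinstance(profiles, EndProfile):
        profiles = [profiles]
    out: dict[str, float] = {}
    ztot = btot = 0.0
    for end in ("five_prime", "three_prime"):
        z = sum(p.zone_mean.get(end, 0.0) for p in profiles)
        b = sum(p.base_mean.get(end, 0.0) for p in profiles)
        ztot += z
        btot += b
        out[end] = float("inf") if z == 0 else b / z
    out["pooled"] = float("inf") if ztot == 0 else btot / ztot
    return out
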