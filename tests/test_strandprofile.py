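"""Strand balance envelope, coverage CV, and telomere-proximal profiles."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from macrna.aligncore import AlignmentHit
from macrna.strandprofile import (EnvelopeConfig, ProfileConfig, coverage_cv,
                                  cv_table, depletion_fold, empirical_band,
                                  envelope_inside, envelope_inside_fraction,
                                  pearson_r, simulate_balanced_null,
                                  strand_count_table, telomere_end_profile)


class TestEnvelope:
    def test_boundary_counts_as_inside(self):
        assert envelope_inside(60, 40)          # |20| == 2*sqrt(100)
        assert not envelope_inside(65, 35)      # 30 > 20
        assert envelope_inside(0, 0)            # inside by convention

    def test_calibration_under_balanced_null(self):
        """~95% of balanced nanochromosomes fall inside the 2-SD envelope."""
        rng = np.random.default_rng(2012)
        plus, minus = simulate_balanced_null(10_000, 20, 2000, rng)
        frac = envelope_inside_fraction(plus, minus)
        assert 0.94 <= frac <= 0.97

    def test_empirical_band_near_normal_quantile(self):
        rng = np.random.default_rng(3)
        plus, minus = simulate_balanced_null(20_000, 20, 2000, rng)
        rows = pd.DataFrame({"plus_total": plus, "minus_total": minus})
        assert empirical_band(rows) == pytest.approx(1.96, abs=0.1)

    def test_balanced_rows_have_zero_band(self):
        rows = pd.DataFrame({"plus_total": [50] * 30, "minus_total": [50] * 30})
        assert empirical_band(rows) == 0.0

    def test_band_needs_twenty_rows(self):
        rows = pd.DataFrame({"plus_total": [5] * 5, "minus_total": [5] * 5})
        with pytest.raises(ValueError):
            empirical_band(rows)

    def test_overdispersed_counts_exceed_binomial_band(self):
        """Piles of duplicated reads (total-count basis) widen the band
        beyond the binomial 1.96, mirroring the total-vs-distinct contrast."""
        rng = np.random.default_rng(4)
        n = rng.integers(20, 2000, size=5000)
        # each "pile" contributes 8 identical reads to one strand
        plus = 8 * rng.binomial(n // 8, 0.5)
        minus = n // 8 * 8 - plus
        rows = pd.DataFrame({"plus_total": plus, "minus_total": minus})
        assert empirical_band(rows) > 2.0


class TestPearson:
    def test_perfectly_balanced_is_one(self):
        rows = pd.DataFrame({"plus_total": [10, 50, 400],
                             "minus_total": [10, 50, 400]})
        assert pearson_r(rows) == pytest.approx(1.0)

    def test_anti_balanced_is_minus_one(self):
        minus = np.arange(10, 110, 10)
        rows = pd.DataFrame({"plus_total": 200 - minus, "minus_total": minus})
        assert pearson_r(rows) == pytest.approx(-1.0)

    def test_zero_variance_reported_as_nan(self):
        rows = pd.DataFrame({"plus_total": [5, 5], "minus_total": [3, 9]})
        assert np.isnan(pearson_r(rows))


def _seq27(i: int) -> str:
    """Deterministic distinct 27-mer for synthetic hit construction."""
    return np.base_repr(i, 4).translate(
        str.maketrans("0123", "ACGT")).rjust(27, "A")


class TestStrandCountTable:
    def _hits(self, spec):
        """spec: {record: (n_plus, n_minus)} -> hits dict of distinct 27-mers."""
        hits, counts, i = {}, {}, 0
        for rid, (np_, nm) in spec.items():
            for k in range(np_):
                seq = _seq27(i)
                i += 1
                hits[seq] = [AlignmentHit(seq, rid, 100 + k, "+", 0)]
                counts[seq] = 1
            for k in range(nm):
                seq = _seq27(i)
                i += 1
                hits[seq] = [AlignmentHit(seq, rid, 300 + k, "-", 0)]
                counts[seq] = 1
        return hits, counts

    def test_min_per_strand_threshold(self):
        hits, counts = self._hits({"r1": (9, 50), "r2": (10, 10)})
        rows = strand_count_table(hits, counts)
        assert list(rows["record_id"]) == ["r2"]
        assert rows.iloc[0]["plus_total"] == 10

    def test_totals_weighted_distincts_not(self):
        seq_p = "A" * 27
        seq_m = "C" * 27
        hits = {seq_p: [AlignmentHit(seq_p, "r", 30, "+", 0)],
                seq_m: [AlignmentHit(seq_m, "r", 60, "-", 0)]}
        counts = {seq_p: 40, seq_m: 11}
        rows = strand_count_table(hits, counts)
        row = rows.iloc[0]
        assert (row["plus_total"], row["minus_total"]) == (40, 11)
        assert (row["plus_distinct"], row["minus_distinct"]) == (1, 1)


class TestCoverageCV:
    def test_uniform_coverage_is_zero(self):
        assert coverage_cv(np.ones(500)) == 0.0

    def test_single_spike_closed_form(self):
        for L in (100, 1000):
            arr = np.zeros(L)
            arr[17] = 5
            assert coverage_cv(arr) == pytest.approx(np.sqrt(L - 1))

    def test_spike_on_100_positions_value(self):
        arr = np.zeros(100)
        arr[0] = 1
        assert coverage_cv(arr) == pytest.approx(9.9499, abs=1e-4)

    def test_scale_invariance(self):
        rng = np.random.default_rng(5)
        arr = rng.poisson(3.0, size=400).astype(float) + 1
        assert coverage_cv(arr) == pytest.approx(coverage_cv(arr * 17.0))

    def test_zero_coverage_undefined(self):
        with pytest.raises(ValueError):
            coverage_cv(np.zeros(100))

    def test_cv_table_counts_five_prime_ends(self):
        seq = "A" * 27
        hits = {seq: [AlignmentHit(seq, "r", 10, "+", 0)]}
        tab = cv_table(hits, {seq: 3}, {"r": 200})
        assert tab.iloc[0]["n_reads"] == 3
        assert tab.iloc[0]["cv"] == pytest.approx(np.sqrt(199))


def _uniform_world(n_records=30, length=1200, per_pos=1, strand="+"):
    """Hand-built hits: one 27-mer 5' end on every geometrically valid
    interior position (plus reads fit before the 3' telomere and vice versa,
    so the two strands' valid 5'-end ranges mirror each other exactly)."""
    hits, counts = {}, {}
    ann_rows = []
    lengths = {}
    i = 0
    if strand == "+":
        fivep_range = range(20, length - 47)
    else:
        fivep_range = range(47, length - 20)
    for r in range(n_records):
        rid = f"n{r:03d}"
        lengths[rid] = length
        ann_rows.append({"id": rid, "length": length, "tel5": 20, "tel3": 20,
                         "complete": True})
        for pos in fivep_range:
            seq = _seq27(i)
            i += 1
            start = pos if strand == "+" else pos - 26
            hits[seq] = [AlignmentHit(seq, rid, start, strand, 0)]
            counts[seq] = per_pos
    return hits, counts, lengths, pd.DataFrame(ann_rows)


class TestEndProfile:
    def test_uniform_production_gives_flat_bins(self):
        hits, counts, lengths, ann = _uniform_world(n_records=5)
        prof = telomere_end_profile(hits, counts, lengths, ann, strand="+")
        binned = prof.binned()
        # within each end, every interior bin carries the same density (the
        # absolute level differs between ends because each window is
        # normalized over its own 500 positions, empty edge included)
        for end in ("five_prime", "three_prime"):
            interior = binned[(binned["end"] == end)
                              & (binned["bin_start"] >= 75)]
            assert np.allclose(interior["relative_density"],
                               interior["relative_density"].iloc[-1],
                               rtol=0.01)

    def test_record_window_normalization_means_one(self):
        hits, counts, lengths, ann = _uniform_world(n_records=1)
        prof = telomere_end_profile(hits, counts, lengths, ann, strand="+")
        for end in ("five_prime", "three_prime"):
            assert prof.positions[end].mean() == pytest.approx(1.0, abs=1e-9)

    def test_mirror_symmetry_between_strands(self):
        hp, cp, lengths, ann = _uniform_world(n_records=4, strand="+")
        hm, cm, _, _ = _uniform_world(n_records=4, strand="-")
        prof_p = telomere_end_profile(hp, cp, lengths, ann, strand="+")
        prof_m = telomere_end_profile(hm, cm, lengths, ann, strand="-")
        np.testing.assert_allclose(prof_p.positions["five_prime"],
                                   prof_m.positions["three_prime"],
                                   atol=1e-9)
        np.testing.assert_allclose(prof_p.positions["three_prime"],
                                   prof_m.positions["five_prime"],
                                   atol=1e-9)

    def test_no_qualifying_records_raises(self):
        hits, counts, lengths, ann = _uniform_world(n_records=1, length=1200)
        short = {k: 300 for k in lengths}
        with pytest.raises(ValueError, match="no qualifying"):
            telomere_end_profile(hits, counts, short, ann,
                                 ProfileConfig(min_record_len=500), "+")

    def test_no_depletion_gives_fold_near_one(self):
        hits, counts, lengths, ann = _uniform_world(n_records=8)
        prof = telomere_end_profile(hits, counts, lengths, ann, strand="+")
        fold = depletion_fold(prof)
        assert fold["pooled"] == pytest.approx(1.0, abs=0.1)

    def test_constructed_eightfold_zone_recovered(self):
        """Thin the subtelomeric 5'-end positions to 1/8 by counts and
        remeasure.  For plus-strand reads the depressed 5'-end positions are
        [tel, tel+30) at the 5' end and, shifted by the read length,
        [tel+27, tel+57) at the 3' end."""
        hits, counts, lengths, ann = _uniform_world(n_records=6, per_pos=8)
        for seq, hh in hits.items():
            h = hh[0]
            L = lengths[h.record_id]
            x5, x3 = h.five_prime_pos, L - 1 - h.five_prime_pos
            if 20 <= x5 < 50 or 47 <= x3 < 77:
                counts[seq] = 1
        prof = telomere_end_profile(hits, counts, lengths, ann, strand="+")
        fold = depletion_fold(prof)
        assert fold["five_prime"] == pytest.approx(8.0, rel=0.05)
        assert fold["three_prime"] == pytest.approx(8.0, rel=0.05)
        assert fold["pooled"] == pytest.approx(8.0, rel=0.05)
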