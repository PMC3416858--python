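"""Alignment core: site enumeration vs brute force, two-pass logic, exports."""

from __future__ import annotations

import numpy as np
import pysam
import pytest

from oracles import brute_force_sites, rc

from macrna._util import random_dna
from macrna.aligncore import (AlignPolicy, SeqIndex, align_read_all_sites,
                              align_to_concat, export_bedgraph, export_sam,
                              run_two_pass)
from macrna.readprep import DistinctReadSet
from macrna.refbuild import build_concat


def _hits_as_tuples(hits):
    return sorted((h.start, h.strand, h.mismatches) for h in hits)


class TestSiteEnumeration:
    def test_unique_planted_read(self):
        rng = np.random.default_rng(0)
        ref = random_dna(rng, 2000)
        read = ref[500:527]
        hits = align_read_all_sites(read, SeqIndex(ref), AlignPolicy())
        plus = [h for h in hits if h.strand == "+"]
        assert [(h.start, h.mismatches) for h in plus] == [(500, 0)]

    def test_revcomp_read_hits_minus_strand(self):
        rng = np.random.default_rng(1)
        ref = random_dna(rng, 2000)
        read = rc(ref[700:727])
        hits = align_read_all_sites(read, SeqIndex(ref), AlignPolicy())
        assert any(h.strand == "-" and h.start == 700 and h.mismatches == 0
                   for h in hits)
        assert all(h.five_prime_pos == h.start + len(read) - 1
                   for h in hits if h.strand == "-")

    def test_read_planted_at_twelve_sites(self):
        rng = np.random.default_rng(2)
        probe = random_dna(rng, 27)
        parts = [probe + random_dna(rng, 60) for _ in range(12)]
        ref = "".join(parts)
        hits = align_read_all_sites(probe, SeqIndex(ref),
                                    AlignPolicy(max_mismatches=0))
        assert len([h for h in hits if h.strand == "+"]) == 12

    def test_sites_overlapping_n_excluded(self):
        ref = "ACGTACGTACGTACGTACGT" + "N" * 5 + "ACGTACGTACGTACGTACGT"
        read = "ACGTACGTACGTACGT"
        hits = align_read_all_sites(read, SeqIndex(ref),
                                    AlignPolicy(max_mismatches=1))
        assert all("N" not in ref[h.start:h.start + len(read)] for h in hits)

    def test_too_short_read_raises(self):
        with pytest.raises(ValueError, match="too short"):
            align_read_all_sites("ACGTACGTACG", SeqIndex("ACGT" * 100),
                                 AlignPolicy(max_mismatches=3))

    @pytest.mark.parametrize("max_mm", [0, 1, 2, 3])
    def test_matches_brute_force_on_random_instances(self, max_mm):
        rng = np.random.default_rng(10 + max_mm)
        ref = random_dna(rng, 10_000)
        idx = SeqIndex(ref)
        policy = AlignPolicy(max_mismatches=max_mm)
        for _ in range(50):
            L = int(rng.integers(16, 46))
            if rng.random() < 0.7:   # planted, possibly mutated
                s = int(rng.integers(0, len(ref) - L))
                read = list(ref[s:s + L])
                for pos in rng.choice(L, size=int(rng.integers(0, max_mm + 1)),
                                      replace=False):
                    read[pos] = "ACGT"[int(rng.integers(4))]
                read = "".join(read)
                if rng.random() < 0.5:
                    read = rc(read)
            else:
                read = random_dna(rng, L)
            got = _hits_as_tuples(align_read_all_sites(read, idx, policy))
            assert got == brute_force_sites(read, ref, max_mm)

    def test_strand_symmetry(self):
        rng = np.random.default_rng(20)
        ref = random_dna(rng, 5000)
        idx = SeqIndex(ref)
        policy = AlignPolicy(max_mismatches=2)
        for _ in range(10):
            read = ref[int(rng.integers(0, 4000)):][:30]
            fwd = align_read_all_sites(read, idx, policy)
            rev = align_read_all_sites(rc(read), idx, policy)
            flip = {"+": "-", "-": "+"}
            assert sorted((h.start, flip[h.strand], h.mismatches) for h in fwd) \
                == sorted((h.start, h.strand, h.mismatches) for h in rev)


class TestTwoPass:
    @pytest.fixture()
    def refs(self):
        rng = np.random.default_rng(30)
        recs1 = [(f"c{i}", random_dna(rng, 400)) for i in range(4)]
        recs2 = [(f"p{i}", random_dna(rng, 300)) for i in range(3)]
        return (build_concat(recs1, name="chr1"),
                build_concat(recs2, name="chr2"), recs1, recs2)

    def test_read_in_both_reported_from_pass_one_only(self, refs):
        chr1, chr2, recs1, recs2 = refs
        shared = recs1[0][1][50:77]
        chr2b = build_concat(recs2 + [("extra", shared + recs2[0][1][:100])],
                             name="chr2")
        reads = DistinctReadSet({shared: 3})
        hits, summary = run_two_pass(reads, chr1, chr2b,
                                     policy=AlignPolicy(max_mismatches=0))
        assert {h.record_id for h in hits[shared]} == {"c0"}
        assert summary.unique_distinct == 1

    def test_pass_two_catches_chr2_only_reads(self, refs):
        chr1, chr2, _, recs2 = refs
        read = recs2[1][1][10:38]
        hits, summary = run_two_pass(DistinctReadSet({read: 1}), chr1, chr2)
        assert {h.record_id for h in hits[read]} == {"p1"}
        assert summary.unique_distinct == 1

    def test_absent_read_is_unmapped(self, refs):
        chr1, chr2, _, _ = refs
        read = "TTAACCGGTTAACCGGTTAACCGGTTA"
        hits, summary = run_two_pass(DistinctReadSet({read: 5}), chr1, chr2,
                                     policy=AlignPolicy(max_mismatches=0))
        assert read not in hits
        assert summary.unmapped_distinct == 1 and summary.unmapped_total == 5

    def test_multiplicity_accounting_conserves(self, refs):
        chr1, chr2, recs1, recs2 = refs
        rng = np.random.default_rng(31)
        reads = {}
        for _ in range(30):
            src = recs1[int(rng.integers(4))][1]
            s = int(rng.integers(0, 350))
            reads[src[s:s + 27]] = int(rng.integers(1, 10))
        reads["G" * 27] = 2
        ds = DistinctReadSet(reads)
        _, summary = run_two_pass(ds, chr1, chr2)
        assert summary.conserved
        assert summary.input_distinct == ds.distinct_reads

    def test_random_one_is_deterministic_given_seed(self, refs):
        chr1, _, recs1, _ = refs
        probe = recs1[2][1][100:127]
        doubled = build_concat([("c0", recs1[0][1] + probe + recs1[1][1]),
                                ("c1", probe + recs1[2][1])], name="chr1")
        reads = DistinctReadSet({probe: 1})
        policy = AlignPolicy(max_mismatches=0, report_mode="random_one")
        picks = {run_two_pass(reads, doubled, policy=policy, seed=5)[0][probe][0]
                 for _ in range(3)}
        assert len(picks) == 1


class TestTrackExport:
    @pytest.fixture()
    def scenario(self):
        rng = np.random.default_rng(40)
        recs = [("n1", random_dna(rng, 400)), ("n2", random_dna(rng, 300))]
        ref = build_concat(recs, name="chr1")
        plus_read = recs[0][1][99:126]
        minus_read = rc(recs[1][1][50:77])
        reads = DistinctReadSet({plus_read: 4, minus_read: 2})
        hits = {s: align_to_concat(s, ref, AlignPolicy(max_mismatches=0))
                for s in reads.counts}
        return ref, reads, hits, plus_read, minus_read

    def test_sam_positions_flags_and_tags(self, scenario, tmp_path):
        ref, reads, hits, plus_read, minus_read = scenario
        sam = tmp_path / "hits.sam"
        export_sam(hits, reads, [ref], sam)
        text = sam.read_text()
        assert "@SQ\tSN:n1\tLN:400" in text
        with pysam.AlignmentFile(str(sam)) as fh:
            by_seq = {}
            for a in fh:
                key = a.query_sequence if not a.is_reverse else \
                    rc(a.query_sequence)
                by_seq[key] = a
        a_plus = by_seq[plus_read]
        assert a_plus.reference_start == 99 and a_plus.flag == 0
        assert a_plus.get_tag("NM") == 0 and a_plus.get_tag("XC") == 4
        # 1-based POS in the raw text: 0-based 99 -> POS 100
        pos_field = next(l for l in text.splitlines()
                         if not l.startswith("@") and "\tn1\t" in l).split("\t")[3]
        assert pos_field == "100"
        assert by_seq[minus_read].flag == 16

    def test_bedgraph_conserves_per_strand_totals(self, scenario, tmp_path):
        ref, reads, hits, plus_read, minus_read = scenario
        p, m = tmp_path / "p.bg", tmp_path / "m.bg"
        export_bedgraph(hits, reads, p, m)

        def total(path):
            return sum(int(line.split("\t")[3])
                       for line in path.read_text().splitlines())

        assert total(p) == 4 and total(m) == 2
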