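"""ORF scanner, bidirectional pairs, strand support and UTR overlap."""

import numpy as np
import pytest

from glaucokit.io_formats import GeneModel, SeqRecord
from glaucokit import orf_screen as orf

from _oracles import brute_orfs


def _hits_as_tuples(hits):
    return {
        (h.strand, h.frame, h.start, h.end, h.aa_len, h.truncated)
        for h in hits
    }


class TestFindOrfs:
    def test_minimal_atg_to_stop(self):
        hits = orf.find_orfs(SeqRecord("x", "ATGAAATAA"), min_aa=2)
        assert len(hits) == 1
        h = hits[0]
        assert (h.strand, h.start, h.end, h.aa_len) == ("+", 0, 9, 2)
        assert not h.truncated

    def test_minus_strand_empty_for_this_sequence(self):
        hits = orf.find_orfs(SeqRecord("x", "ATGAAATAA"), min_aa=2)
        assert all(h.strand == "+" for h in hits)

    def test_minus_strand_coordinates_reported_forward(self):
        # revcomp of ATGAAATAA placed on the minus strand
        seq = "TTATTTCAT"
        hits = orf.find_orfs(SeqRecord("x", seq), min_aa=2)
        assert len(hits) == 1
        h = hits[0]
        assert (h.strand, h.start, h.end, h.aa_len) == ("-", 0, 9, 2)

    def test_truncated_orf_flagged(self):
        hits = orf.find_orfs(SeqRecord("x", "ATGAAAAAA"), min_aa=3)
        assert len(hits) == 1
        assert hits[0].truncated and hits[0].aa_len == 3

    def test_n_codon_is_neither_start_nor_stop(self):
        # TAN is not a stop, ATN not a start
        hits = orf.find_orfs(SeqRecord("x", "ATGTANAAATAA"), min_aa=3)
        assert len(hits) == 1
        assert hits[0].aa_len == 3

    def test_empty_sequence_rejected_at_construction(self):
        from glaucokit.io_formats import FormatError

        with pytest.raises(FormatError, match="empty"):
            SeqRecord("x", "")

    @pytest.mark.parametrize("mode", ["atg_to_stop", "stop_to_stop"])
    def test_matches_bruteforce_on_random_sequences(self, mode, rng):
        for _ in range(20):
            seq = "".join(
                rng.choice(list("ACGT"), p=[0.25, 0.25, 0.25, 0.25], size=600)
            )
            rec = SeqRecord("r", seq)
            for min_aa in (5, 20):
                assert _hits_as_tuples(orf.find_orfs(rec, min_aa, mode)) == \
                    brute_orfs(seq, min_aa, mode)

    def test_strand_symmetry(self, rng):
        for _ in range(10):
            seq = "".join(rng.choice(list("ACGTN"), size=501))
            fwd = orf.find_orfs(SeqRecord("r", seq), min_aa=5)
            rev = orf.find_orfs(SeqRecord("r", orf.revcomp(seq)), min_aa=5)
            n = len(seq)
            reflected = {
                ("-" if h.strand == "+" else "+", n - h.end, n - h.start,
                 h.aa_len, h.truncated)
                for h in rev
            }
            assert {
                (h.strand, h.start, h.end, h.aa_len, h.truncated) for h in fwd
            } == reflected

    def test_min_aa_monotonicity(self, rng):
        seq = "".join(rng.choice(list("ACGT"), size=2000))
        rec = SeqRecord("r", seq)
        prev = None
        for min_aa in (5, 10, 20, 50):
            cur = _hits_as_tuples(orf.find_orfs(rec, min_aa))
            if prev is not None:
                assert cur <= prev
            prev = cur


class TestBidirectionalPairs:
    def _hit(self, strand, start, end):
        return orf.OrfHit(
            seq_id="t", strand=strand, frame=0, start=start, end=end,
            aa_len=(end - start) // 3 - 1,
        )

    def test_partial_overlap(self):
        pairs = orf.detect_bidirectional_pairs(
            [self._hit("+", 0, 900), self._hit("-", 300, 1200)]
        )
        assert len(pairs) == 1
        assert pairs[0].overlap_nt == 600
        assert pairs[0].overlap_class == "partial"

    def test_complete_overlap(self):
        pairs = orf.detect_bidirectional_pairs(
            [self._hit("+", 0, 1200), self._hit("-", 150, 1050)]
        )
        assert pairs[0].overlap_class == "complete"

    def test_same_strand_never_pairs(self):
        pairs = orf.detect_bidirectional_pairs(
            [self._hit("+", 0, 900), self._hit("+", 300, 1200)]
        )
        assert pairs == []

    def test_disjoint_never_pairs(self):
        pairs = orf.detect_bidirectional_pairs(
            [self._hit("+", 0, 300), self._hit("-", 300, 600)]
        )
        assert pairs == []

    def test_mixed_transcripts_rejected(self):
        a = self._hit("+", 0, 900)
        b = orf.OrfHit(seq_id="u", strand="-", frame=0, start=0, end=900,
                       aa_len=299)
        with pytest.raises(ValueError):
            orf.detect_bidirectional_pairs([a, b])


class TestStrandSupport:
    def _pair(self):
        plus = orf.OrfHit("t", "+", 0, 0, 90, 29)
        minus = orf.OrfHit("t", "-", 0, 30, 120, 29)
        return orf.detect_bidirectional_pairs([plus, minus])[0]

    def test_unsupported_minus(self):
        sup = orf.strand_support(self._pair(), np.ones(200), np.zeros(200))
        assert sup.minus_cov_fraction == 0.0
        assert sup.label == "unsupported_minus"

    def test_full_support_both(self):
        sup = orf.strand_support(self._pair(), np.ones(200), np.ones(200))
        assert sup.plus_cov_fraction == 1.0
        assert sup.minus_cov_fraction == 1.0
        assert sup.label == "supported"

    def test_fraction_matches_per_base_count(self, rng):
        pair = self._pair()
        plus = rng.integers(0, 3, size=200)
        minus = rng.integers(0, 3, size=200)
        sup = orf.strand_support(pair, plus, minus, min_depth=1)
        expect_plus = sum(
            1 for i in range(pair.plus.start, pair.plus.end) if plus[i] >= 1
        ) / (pair.plus.end - pair.plus.start)
        assert sup.plus_cov_fraction == pytest.approx(expect_plus)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            orf.strand_support(self._pair(), np.ones(200), np.ones(150))


class TestUtrOverlap:
    def test_convergent_shared_utr(self):
        a = GeneModel("gA", "c", "+", exons=[(0, 3000)], utr3=(2800, 3000))
        b = GeneModel("gB", "c", "-", exons=[(2900, 6000)], utr3=(2900, 3100))
        rep = orf.utr_overlap(a, b)
        assert rep is not None
        assert rep.length == 100
        assert (rep.start, rep.end) == (2900, 3000)

    def test_divergent_orientation_no_report(self):
        # minus gene to the left, plus gene to the right: 5' ends adjacent
        a = GeneModel("gA", "c", "-", exons=[(0, 3000)], utr3=(0, 200))
        b = GeneModel("gB", "c", "+", exons=[(2900, 6000)], utr3=(5800, 6000))
        assert orf.utr_overlap(a, b) is None

    def test_same_strand_no_report(self):
        a = GeneModel("gA", "c", "+", exons=[(0, 3000)], utr3=(2800, 3000))
        b = GeneModel("gB", "c", "+", exons=[(2900, 6000)], utr3=(5800, 6000))
        assert orf.utr_overlap(a, b) is None

    def test_different_contigs_no_report(self):
        a = GeneModel("gA", "c1", "+", exons=[(0, 3000)], utr3=(2800, 3000))
        b = GeneModel("gB", "c2", "-", exons=[(2900, 6000)], utr3=(2900, 3100))
        assert orf.utr_overlap(a, b) is None

    def test_terminus_fallback(self):
        a = GeneModel("gA", "c", "+", exons=[(0, 3000)])
        b = GeneModel("gB", "c", "-", exons=[(3100, 6000)])
        assert orf.utr_overlap(a, b) is None  # no UTRs, fallback off
        rep = orf.utr_overlap(a, b, use_termini=True)
        assert rep is not None and rep.length == 100
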