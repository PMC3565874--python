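"""Retrocopy scan evidence operations and filter cascade."""

import math

import pytest

from retrointron.core import AlignmentBlockSet, GenomicInterval
from retrointron.scan import (
    RetrocopyCandidate,
    ScanThresholds,
    apply_filters,
    count_missing_introns,
    detect_polyA,
    repeat_overlap_fraction,
)


class TestPolyA:
    def test_tail_detected(self):
        assert detect_polyA("A" * 20 + "CGTCGTCGTA")

    def test_all_non_a_window_negative(self):
        assert not detect_polyA("CGT" * 10)

    def test_random_sequence_rarely_positive(self):
        """P(>=12 A in 30) at p=0.25 is ~0.051 (exact binomial), so the
        detector fires on only a small minority of random windows while
        always firing on a genuine tail."""
        p = sum(math.comb(30, k) * 0.25 ** k * 0.75 ** (30 - k)
                for k in range(12, 31))
        assert p == pytest.approx(0.0507, abs=0.0005)
        rng = __import__("numpy").random.default_rng(0)
        from retrointron.simulate import random_seq
        frac = sum(detect_polyA(random_seq(rng, 30)) for _ in range(400)) / 400
        assert frac < 0.12

    def test_truncated_window_uses_available_bases(self):
        # only 15 bases available, 12 of them A
        assert detect_polyA("A" * 12 + "CGT")
        assert not detect_polyA("A" * 11 + "CGT")


class TestMissingIntrons:
    def _alignment(self, blocks):
        return AlignmentBlockSet(
            query_id="parent01",
            target=GenomicInterval("chr2", blocks[0][1][0], blocks[-1][1][1], "+"),
            blocks=blocks, identity=99.0, coverage=1.0)

    def test_contiguous_junctions_count_as_absent(self, fixture_data):
        """On the fixture every injected retrocopy shows all parental
        introns absent (clean splicing by construction)."""
        from retrointron.mechanism import GenomeIndex, seed_and_extend
        data = fixture_data
        row = data.dataset.truth.query("mechanism == 'none' and ~is_decoy").iloc[0]
        parent = data.parents[row.parent_id]
        tid = parent.transcript_ids[0]
        cds = parent.cds_sequence(data.genome, tid)
        hits = seed_and_extend(cds, data.genome, query_id=row.parent_id,
                               exclude=parent.locus())
        target = [h for h in hits
                  if h.target.chrom == row.chrom
                  and min(h.target.start, h.target.end) >= row.start - 50
                  and max(h.target.start, h.target.end) <= row.end + 50]
        assert target, "retrocopy locus must be rediscovered"
        n = count_missing_introns(target[0], parent, tid)
        assert n == parent.n_introns(tid)

    def test_decoy_with_introns_shows_none_absent(self, fixture_data):
        from retrointron.mechanism import seed_and_extend
        data = fixture_data
        decoy = data.dataset.truth.query("is_decoy").iloc[0]
        parent = data.parents[decoy.parent_id]
        tid = parent.transcript_ids[0]
        cds = parent.cds_sequence(data.genome, tid)
        hits = seed_and_extend(cds, data.genome, query_id=decoy.parent_id,
                               exclude=parent.locus())
        target = [h for h in hits
                  if h.target.chrom == decoy.chrom
                  and min(h.target.start, h.target.end) >= decoy.start - 50]
        assert target
        assert count_missing_introns(target[0], parent, tid) == 0

    def test_partial_alignment_misses_junctions(self):
        from retrointron.core import GeneModel
        parent = GeneModel("p", "chr1", "+", exons={
            "t": [GenomicInterval("chr1", 0, 100),
                  GenomicInterval("chr1", 200, 300)]})
        # alignment covers only query 0..50 (inside exon 1)
        aln = self._alignment([((0, 50), (1000, 1050))])
        assert count_missing_introns(aln, parent, "t") == 0


class TestFilterCascade:
    def _candidate(self, **kw):
        defaults = dict(identity=95.0, coverage=0.95)
        aln = AlignmentBlockSet(
            query_id="p", target=GenomicInterval("chr2", 0, 1000, "+"),
            blocks=[((0, 1000), (0, 1000))],
            identity=kw.pop("identity", defaults["identity"]),
            coverage=kw.pop("coverage", defaults["coverage"]),
            evalue=kw.pop("evalue", None))
        cand = RetrocopyCandidate(alignment=aln, parent_id="p",
                                  introns_absent=5, parent_intron_count=6)
        for key, value in kw.items():
            setattr(cand, key, value)
        return cand

    def test_identity_just_below_cutoff(self):
        cand = self._candidate(identity=39.9)
        assert apply_filters(cand) == "discarded:identity"

    def test_low_coverage(self):
        cand = self._candidate(coverage=0.69)
        assert apply_filters(cand) == "discarded:coverage"

    def test_few_introns_high_ks_no_polya(self):
        cand = self._candidate(introns_absent=2, ks_to_parent=2.5,
                               polya_evidence=False)
        assert apply_filters(cand) == "discarded:duplication-evidence"

    def test_few_introns_rescued_by_polya(self):
        cand = self._candidate(introns_absent=2, ks_to_parent=None,
                               polya_evidence=True)
        assert apply_filters(cand) == "retained"

    def test_three_introns_with_small_ks_retained(self):
        cand = self._candidate(introns_absent=3, ks_to_parent=0.5)
        assert apply_filters(cand) == "retained"

    def test_zero_introns_absent_fails_evidence(self):
        cand = self._candidate(introns_absent=0, ks_to_parent=0.1,
                               polya_evidence=True)
        assert apply_filters(cand) == "discarded:duplication-evidence"

    def test_repeat_overlap(self):
        cand = self._candidate(repeat_overlap=0.6)
        assert apply_filters(cand) == "discarded:repeat"

    def test_evalue_filter_when_present(self):
        cand = self._candidate(evalue=1e-5)
        assert apply_filters(cand) == "discarded:evalue"

    def test_first_failure_recorded_in_order(self):
        cand = self._candidate(identity=30.0, coverage=0.1, repeat_overlap=0.9)
        assert apply_filters(cand) == "discarded:identity"

    def test_relaxing_thresholds_never_shrinks_retained_set(self):
        cands = [
            self._candidate(identity=45.0),
            self._candidate(identity=39.0),
            self._candidate(coverage=0.65),
            self._candidate(introns_absent=2, ks_to_parent=2.5),
            self._candidate(repeat_overlap=0.55),
        ]
        strict = ScanThresholds()
        relaxed = [
            ScanThresholds(identity_min=35.0),
            ScanThresholds(coverage_min=0.6),
            ScanThresholds(ks_max=3.0),
            ScanThresholds(repeat_max=0.6),
        ]
        def retained_set(th):
            return {i for i, c in enumerate(cands)
                    if apply_filters(c, th) == "retained"}
        base = retained_set(strict)
        for th in relaxed:
            assert retained_set(th) >= base


class TestRepeatOverlap:
    def test_merged_fraction(self):
        span = GenomicInterval("chr1", 0, 100)
        reps = [GenomicInterval("chr1", 0, 30),
                GenomicInterval("chr1", 20, 50),
                GenomicInterval("chr1", 90, 200)]
        assert repeat_overlap_fraction(span, reps) == pytest.approx(0.6)

    def test_no_overlap(self):
        span = GenomicInterval("chr1", 0, 100)
        assert repeat_overlap_fraction(
            span, [GenomicInterval("chr2", 0, 100)]) == 0.0
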