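"""Conservation metrics: alignments, blocks, tracks, site-level scores."""

import numpy as np
import pytest

from crmcooc.conservation import (
    ConservationConfig,
    ConservationTrack,
    PairwiseAlignment,
    block_conservation_score,
    build_report,
    classify_by_peak,
    conserved_fraction,
    extract_conserved_blocks,
    mean_track_score,
    pairwise_align,
    peak_window_score,
    site_conserved,
    tfbs_mismatch_rate,
    tfbs_presence,
)
from crmcooc.missing import MISSING, is_missing
from crmcooc.motif_scan import MotifHit, MotifModel


def hit(start, end, motif="m", strand="+", seq="A"):
    return MotifHit(
        seq_id="ref", start=start, end=end, motif_name=motif,
        strand=strand, score=float(end - start), site_seq=seq * (end - start),
    )


def identity_aln(seq, ref_start=0):
    return PairwiseAlignment(
        ref_id="ref", alt_id="alt", ref_row=seq, alt_row=seq, ref_start=ref_start
    )


class TestPairwiseAlign:
    def test_identity(self):
        aln = pairwise_align("ACGT", "ACGT")
        assert aln.ref_row == aln.alt_row == "ACGT"
        assert aln.identity_columns().all()

    def test_single_deletion_lands_on_the_c(self):
        aln = pairwise_align("ACGT", "AGT")
        assert aln.ref_row == "ACGT"
        assert aln.alt_row == "A-GT"

    def test_prohibitive_gap_costs_force_mismatch_columns(self):
        aln = pairwise_align("AAAA", "TTTT", gap_open=-100, gap_extend=-100)
        assert aln.ref_row == "AAAA" and aln.alt_row == "TTTT"
        assert not aln.identity_columns().any()

    def test_empty_sequence_is_an_error(self):
        with pytest.raises(ValueError):
            pairwise_align("", "ACGT")

    def test_gap_gap_column_rejected(self):
        with pytest.raises(ValueError):
            PairwiseAlignment("r", "a", "A-C", "A-C")


class TestConservedFraction:
    def test_identity_alignment_is_one(self):
        assert conserved_fraction(identity_aln("ACGTACGT"), (0, 8)) == 1.0

    def test_three_of_four_identical(self):
        aln = PairwiseAlignment("r", "a", "ACGT", "ACCT")
        assert conserved_fraction(aln, (0, 4)) == 0.75

    def test_unaligned_half_counts_as_nonconserved(self):
        # region [0, 8); only [4, 8) is aligned, fully identical
        aln = identity_aln("ACGT", ref_start=4)
        assert conserved_fraction(aln, (0, 8)) == 0.5

    def test_zero_length_region_is_an_error(self):
        with pytest.raises(ValueError):
            conserved_fraction(identity_aln("ACGT"), (2, 2))

    def test_gap_columns_are_nonconserved(self):
        aln = PairwiseAlignment("r", "a", "ACGT", "A--T")
        assert conserved_fraction(aln, (0, 4)) == 0.5


class TestConservedBlocks:
    def test_identity_alignment_is_one_block(self):
        aln = identity_aln("A" * 100)
        (b,) = extract_conserved_blocks(aln)
        assert (b.col_start, b.col_end, b.identity) == (0, 100, 1.0)

    def test_short_runs_filtered(self):
        # gap-free runs of length 3 < block_min_len 6
        aln = PairwiseAlignment("r", "a", "ACG-ACG-ACG", "ACGA-CGA-CG")
        assert extract_conserved_blocks(aln) == []

    def test_low_identity_run_filtered(self):
        # run 1 trims to 9 identical columns; run 2 trims to identity 0.2
        run1_ref, run1_alt = "ACGTACGTAC", "ACGTACGTAT"
        run2_ref, run2_alt = "AAAAAAAAAA", "ATTTTTTTTA"
        aln = PairwiseAlignment(
            "r", "a", run1_ref + "-" + run2_ref, run1_alt + "A" + run2_alt
        )
        blocks = extract_conserved_blocks(aln)
        assert len(blocks) == 1
        assert (blocks[0].col_start, blocks[0].col_end) == (0, 9)
        assert blocks[0].identity == 1.0

    def test_blocks_trimmed_to_identical_boundaries(self):
        aln = PairwiseAlignment("r", "a", "TTACGTACGTTT", "AAACGTACGTAA")
        (b,) = extract_conserved_blocks(aln)
        assert (b.col_start, b.col_end) == (2, 10)
        assert b.identity == 1.0


class TestBlockConservationScore:
    def test_identity_alignment_scores_one(self):
        aln = identity_aln("ACGT" * 10)
        assert block_conservation_score((0, 40), [hit(5, 10)], aln) == 1.0

    def test_hand_counted_fixture(self):
        # layout: block A (20 identical cols, contains hit1), a ref-gap
        # column, 30 fully mismatched aligned columns, a ref-gap column,
        # block B (50 identical cols, contains hit2).  The span holds 100
        # aligned reference bases, 70 inside conserved blocks -> 0.7
        rng = np.random.default_rng(0)
        block_a = "ACGTACGTACGTACGTACGT"  # ref [0, 20)
        middle_ref = "".join(rng.choice(list("ACGT"), 30))  # ref [20, 50)
        middle_alt = "".join({"A": "C", "C": "A", "G": "T", "T": "G"}[c] for c in middle_ref)
        block_b = "ACGTACGTAC" * 5  # ref [50, 100)
        ref = block_a + "-" + middle_ref + "-" + block_b
        alt = block_a + "A" + middle_alt + "A" + block_b
        aln = PairwiseAlignment("r", "a", ref, alt)
        score = block_conservation_score((0, 100), [hit(2, 10), hit(80, 90)], aln)
        assert score == pytest.approx(0.7)

    def test_span_trimmed_to_site_bearing_blocks(self):
        # conserved blocks beyond the last site-containing block are ignored
        block = "ACGTACGTACGT"  # 12 identical columns
        junk_ref = "AAAACCCCGGGG"
        junk_alt = "TTTTGGGGTTTT"
        ref = block + "-" + junk_ref + "-" + block + "-" + junk_ref + "-" + block
        alt = block + "A" + junk_alt + "A" + block + "A" + junk_alt + "A" + block
        aln = PairwiseAlignment("r", "a", ref, alt)
        # ref coords: blocks at [0,12), [24,36), [48,60); hits in first two
        score = block_conservation_score((0, 60), [hit(0, 6), hit(26, 32)], aln)
        assert score == pytest.approx(24 / 36)

    def test_no_site_bearing_block_is_missing(self):
        # conserved block exists but no hit overlaps it
        ref = "ACGTACGTACGT" + "AAAACCCC"
        alt = "ACGTACGTACGT" + "TTTTGGGG"
        aln = PairwiseAlignment("r", "a", ref, alt)
        assert is_missing(block_conservation_score((0, 20), [hit(14, 18)], aln))

    def test_invariant_to_flank_extension_without_qualifying_blocks(self):
        rng = np.random.default_rng(1)
        core_ref = "ACGTACGTACGTACGTACGT"
        flank = "".join(rng.choice(list("ACGT"), 40))
        flank_alt = "".join({"A": "C", "C": "A", "G": "T", "T": "G"}[c] for c in flank)
        small = PairwiseAlignment("r", "a", core_ref, core_ref, ref_start=40)
        big = PairwiseAlignment(
            "r", "a", flank + core_ref + flank, flank_alt + core_ref + flank_alt
        )
        h = [hit(45, 55)]
        assert block_conservation_score((40, 60), h, small) == \
            block_conservation_score((40, 60), h, big)


class TestTrackMetrics:
    def test_constant_track_mean(self):
        t = ConservationTrack("s", 0, np.full(100, 0.5))
        assert mean_track_score(t, (10, 60)) == 0.5

    def test_two_base_mean(self):
        t = ConservationTrack("s", 0, np.array([0.0, 1.0]))
        assert mean_track_score(t, (0, 2)) == 0.5

    def test_mean_matches_direct_summation(self):
        rng = np.random.default_rng(3)
        scores = rng.random(1000)
        t = ConservationTrack("s", 0, scores)
        direct = sum(scores[100:900]) / 800
        assert mean_track_score(t, (100, 900)) == pytest.approx(direct, abs=1e-12)

    def test_uncovered_region_is_an_error(self):
        t = ConservationTrack("s", 50, np.full(10, 0.5))
        with pytest.raises(ValueError):
            mean_track_score(t, (45, 55))

    def test_peak_constant_track(self):
        t = ConservationTrack("s", 0, np.full(50, 0.4))
        assert peak_window_score(t, (0, 50), 10) == pytest.approx(0.4)

    def test_peak_enumerates_both_windows(self):
        t = ConservationTrack("s", 0, np.array([0.0, 1.0, 0.0]))
        assert peak_window_score(t, (0, 3), 2) == 0.5

    def test_region_shorter_than_window_is_missing(self):
        t = ConservationTrack("s", 0, np.full(400, 0.9))
        assert is_missing(peak_window_score(t, (0, 400), 500))

    def test_window_equal_to_region_length_equals_mean(self):
        rng = np.random.default_rng(4)
        t = ConservationTrack("s", 0, rng.random(120))
        region = (10, 110)
        assert peak_window_score(t, region, 100) == pytest.approx(
            mean_track_score(t, region)
        )

    def test_peak_matches_brute_force_on_random_tracks(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            n = int(rng.integers(20, 200))
            t = ConservationTrack("s", 0, rng.random(n))
            w = int(rng.integers(1, n + 1))
            brute = max(t.scores[s:s + w].mean() for s in range(n - w + 1))
            assert peak_window_score(t, (0, n), w) == pytest.approx(brute, abs=1e-12)

    def test_invalid_window_is_an_error(self):
        t = ConservationTrack("s", 0, np.full(10, 0.5))
        with pytest.raises(ValueError):
            peak_window_score(t, (0, 10), 0)


class TestClassifyByPeak:
    @pytest.mark.parametrize(
        "score,cutoff,expected",
        [(0.6431, 0.13, True), (0.13, 0.13, True), (0.12, 0.13, False)],
    )
    def test_threshold_convention(self, score, cutoff, expected):
        assert classify_by_peak(score, cutoff) is expected

    def test_missing_classifies_false(self):
        assert classify_by_peak(MISSING, 0.13) is False


class TestSiteConservation:
    motif = MotifModel(name="m", consensus="CART")  # R: A or G

    def test_identical_ortholog_site_is_conserved(self):
        aln = identity_aln("TTCAATTT")
        assert site_conserved(hit(2, 6), aln, self.motif)

    def test_gap_in_site_breaks_conservation(self):
        aln = PairwiseAlignment("r", "a", "TTCAATTT", "TTC-ATTT")
        assert not site_conserved(hit(2, 6), aln, self.motif)

    def test_substitution_within_degenerate_position_still_conserved(self):
        # ortholog has G at the R position where the reference has A
        aln = PairwiseAlignment("r", "a", "TTCAATTT", "TTCAGTTT")
        assert site_conserved(hit(2, 6), aln, self.motif)

    def test_threshold_breaking_substitution_not_conserved(self):
        aln = PairwiseAlignment("r", "a", "TTCAATTT", "TTGAATTT")
        assert not site_conserved(hit(2, 6), aln, self.motif)

    def test_site_outside_aligned_span_not_conserved(self):
        aln = identity_aln("CAAT", ref_start=100)
        assert not site_conserved(hit(2, 6), aln, self.motif)


class TestSiteSummaries:
    def test_presence_counts_conserved_classes(self):
        m1 = MotifModel(name="m1", consensus="CAAT")
        m2 = MotifModel(name="m2", consensus="GGGG")
        # m2's ortholog site matches on neither orientation
        aln = PairwiseAlignment("r", "a", "CAATGGGG", "CAATCCCA")
        region_hits = {"m1": [hit(0, 4, "m1")], "m2": [hit(4, 8, "m2")]}
        motifs = {"m1": m1, "m2": m2}
        assert tfbs_presence(region_hits, aln, motifs) == 0.5

    def test_presence_all_and_none(self):
        m = MotifModel(name="m1", consensus="CAAT")
        aln = identity_aln("CAATTTTT")
        assert tfbs_presence({"m1": [hit(0, 4)]}, aln, {"m1": m}) == 1.0
        assert tfbs_presence({"m1": []}, aln, {"m1": m}) == 0.0

    def test_mismatch_identity_is_zero(self):
        aln = identity_aln("ACGTACGTAC")
        assert tfbs_mismatch_rate({"m": [hit(0, 10)]}, aln) == 0.0

    def test_mismatch_pooled_across_sites(self):
        # 10 bp site with 2 substitutions + 5 bp site with 1 gap column
        ref = "ACGTACGTAC" + "TTTT" + "GGGGG"
        alt = "ACGTAGGTAT" + "TTTT" + "GG-GG"
        aln = PairwiseAlignment("r", "a", ref, alt)
        rate = tfbs_mismatch_rate({"m": [hit(0, 10), hit(14, 19)]}, aln)
        assert rate == pytest.approx(3 / 15)

    def test_no_site_in_span_is_missing(self):
        aln = identity_aln("ACGT", ref_start=100)
        assert is_missing(tfbs_mismatch_rate({"m": [hit(0, 4)]}, aln))


class TestBuildReport:
    def test_all_perfect_case(self):
        seq = "CAAT" + "ACGTACGTACGTACGTACGT" * 2 + "CAAT"
        aln = identity_aln(seq)
        m = MotifModel(name="m1", consensus="CAAT")
        region = (0, len(seq))
        track = ConservationTrack("ref", 0, np.full(len(seq), 0.8))
        region_hits = {"m1": [hit(0, 4, "m1"), hit(len(seq) - 4, len(seq), "m1")]}
        cfg = ConservationConfig(peak_windows=(8, 16))
        rep = build_report("r1", region, region_hits, {"m1": m}, aln, aln, track, cfg)
        assert rep.avid_fraction == 1.0
        assert rep.block_score == 1.0
        assert rep.track_mean == pytest.approx(0.8)
        assert rep.peak_score[8] == pytest.approx(0.8)
        assert rep.tfbs_presence == 1.0
        assert rep.tfbs_mismatch == 0.0

    def test_short_region_leaves_window_cell_missing(self):
        track = ConservationTrack("ref", 0, np.full(400, 0.5))
        cfg = ConservationConfig(peak_windows=(100, 500))
        rep = build_report("r1", (0, 400), None, None, None, None, track, cfg)
        assert rep.peak_score[100] == pytest.approx(0.5)
        assert is_missing(rep.peak_score[500])

    def test_no_alignment_gives_nd_semantics(self):
        track = ConservationTrack("ref", 0, np.full(600, 0.5))
        cfg = ConservationConfig(peak_windows=(100,))
        rep = build_report("DME4", (0, 600), None, None, None, None, track, cfg)
        assert is_missing(rep.avid_fraction)
        assert is_missing(rep.block_score)
        assert is_missing(rep.tfbs_presence)
        assert is_missing(rep.tfbs_mismatch)
        assert rep.track_mean == pytest.approx(0.5)
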