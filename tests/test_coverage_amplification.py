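"""Binning, mode normalization, Rc and breakpoint detection."""

import numpy as np
import pytest

from oriterscan.core_genome import ChromosomeMap, GenomicSegment
from oriterscan.coverage_amplification import (
    CoverageTrack,
    bin_coverage,
    classify_pattern,
    compute_rc,
    detect_breakpoints,
    log2_histogram_mode,
    mode_normalize,
)
from oriterscan.synthetic_data import PopulationSpec, gen_population_coverage


def _track(chrom, counts, width=200):
    counts = np.asarray(counts)
    n = -(-chrom.length_bp // width)
    partial = np.zeros(n, dtype=bool)
    if chrom.length_bp % width:
        partial[-1] = True
    return CoverageTrack(chrom=chrom, width_bp=width, counts=counts, partial=partial)


class TestBinCoverage:
    def test_all_reads_in_first_bin(self):
        chrom = ChromosomeMap(length_bp=1000)
        track = bin_coverage([5, 17, 199], chrom, width_bp=200)
        assert track.counts.tolist() == [3, 0, 0, 0, 0]

    def test_boundary_read_goes_to_next_bin(self):
        chrom = ChromosomeMap(length_bp=1000)
        track = bin_coverage([200], chrom, width_bp=200)
        assert track.counts.tolist() == [0, 1, 0, 0, 0]

    def test_matches_bruteforce_histogram(self):
        chrom = ChromosomeMap(length_bp=10_000)
        rng = np.random.default_rng(1)
        pos = rng.integers(0, 10_000, size=10_000)
        track = bin_coverage(pos, chrom, width_bp=200)
        brute, _ = np.histogram(pos, bins=np.arange(0, 10_001, 200))
        assert (track.counts == brute).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bin_coverage([1000], ChromosomeMap(length_bp=1000), 200)


class TestModeNormalize:
    def test_constant_track(self):
        chrom = ChromosomeMap(length_bp=4000)
        norm = mode_normalize(_track(chrom, np.full(20, 100)))
        # mode factor within one 0.1-wide log2 cell of count + 1
        assert abs(np.log2(norm.mode_factor) - np.log2(101)) <= 0.1
        assert np.abs(norm.log2_values).max() <= 0.06

    def test_bimodal_track_mode_tracks_majority(self):
        chrom = ChromosomeMap(length_bp=200_000)
        counts = np.concatenate([np.full(600, 100), np.full(400, 180)])
        norm = mode_normalize(_track(chrom, counts))
        lin = norm.linear_values
        assert lin[:600].mean() == pytest.approx(1.0, abs=0.05)
        assert lin[600:].mean() == pytest.approx(1.8, abs=0.1)

    def test_scale_invariance_of_log2_values(self):
        chrom = ChromosomeMap(length_bp=200_000)
        rng = np.random.default_rng(2)
        counts = rng.poisson(100, size=1000)
        n1 = mode_normalize(_track(chrom, counts))
        n4 = mode_normalize(_track(chrom, counts * 4))
        # normalized values agree within one histogram cell
        assert np.abs(n1.log2_values - n4.log2_values).max() <= 0.1 + 0.05

    def test_all_zero_counts_rejected(self):
        chrom = ChromosomeMap(length_bp=4000)
        with pytest.raises(ValueError):
            mode_normalize(_track(chrom, np.zeros(20, dtype=int)))

    def test_restrict_to_uses_only_that_segment(self):
        # amplified majority would drag the global mode; restriction avoids it
        chrom = ChromosomeMap(length_bp=200_000)
        counts = np.concatenate([np.full(700, 200), np.full(300, 100)])
        restrict = GenomicSegment(700 * 200, 0)  # the 100-level tail, wraps
        norm = mode_normalize(_track(chrom, counts), restrict_to=restrict)
        assert abs(np.log2(norm.mode_factor) - np.log2(101)) <= 0.1


def test_log2_histogram_mode_ties_to_lower_cell():
    # two equally full cells: 2^0.55-1 ~ 0.46 cell [0.5,0.6), 2^0.65-1 cell [0.6,0.7)
    lo = np.full(5, 3)   # log2(4)=2.0 -> cell 20
    hi = np.full(5, 5)   # log2(6)=2.585 -> cell 25
    mode = log2_histogram_mode(np.concatenate([lo, hi]))
    assert mode == pytest.approx(2 ** 2.05)


class TestComputeRc:
    def test_uniform_track_rc_one(self, full_chrom, full_dup):
        spec = PopulationSpec(
            chrom=full_chrom, dup_segment=full_dup, prevalence=0.0, seed=11
        )
        norm = mode_normalize(gen_population_coverage(spec))
        rc = compute_rc(norm, full_dup)
        assert rc.rc == pytest.approx(1.0, abs=0.02)

    def test_noiseless_two_fold_segment(self):
        chrom = ChromosomeMap(length_bp=200_000)
        counts = np.full(1000, 100)
        seg = GenomicSegment(0, 80_000)  # bins 0..399
        counts[:400] = 201  # (201+1)/(100+1) = 2 exactly on the +1 scale
        rc = compute_rc(mode_normalize(_track(chrom, counts)), seg)
        assert rc.rc == pytest.approx(2.0, rel=1e-12)

    def test_degenerate_segment_rejected(self):
        chrom = ChromosomeMap(length_bp=4000)
        norm = mode_normalize(_track(chrom, np.full(20, 100)))
        with pytest.raises(ValueError):
            compute_rc(norm, GenomicSegment(0, 4000))

    def test_rc_monotone_in_prevalence(self, full_chrom, full_dup):
        rcs = []
        for f in [0.0, 0.25, 0.5, 0.8, 1.0]:
            spec = PopulationSpec(
                chrom=full_chrom, dup_segment=full_dup, prevalence=f, seed=3
            )
            norm = mode_normalize(gen_population_coverage(spec))
            rcs.append(compute_rc(norm, full_dup).rc)
        assert all(b > a for a, b in zip(rcs, rcs[1:]))

    def test_rc_scale_invariant(self, desk_chrom, desk_dup):
        spec = PopulationSpec(
            chrom=desk_chrom, dup_segment=desk_dup, prevalence=0.5, seed=4
        )
        track = gen_population_coverage(spec)
        rc1 = compute_rc(mode_normalize(track), desk_dup).rc
        scaled = CoverageTrack(
            chrom=track.chrom,
            width_bp=track.width_bp,
            counts=track.counts * 3,
            partial=track.partial,
        )
        rc3 = compute_rc(mode_normalize(scaled), desk_dup).rc
        assert rc3 == pytest.approx(rc1, rel=0.02)


class TestDetectBreakpoints:
    def test_planted_boundaries_recovered(self, desk_chrom, desk_dup):
        spec = PopulationSpec(
            chrom=desk_chrom, dup_segment=desk_dup, prevalence=0.8, seed=5
        )
        norm = mode_normalize(gen_population_coverage(spec))
        rc = detect_breakpoints(norm)
        assert abs(rc.boundary_1 - desk_dup.start) <= 200
        assert abs(rc.boundary_2 - desk_dup.end) <= 200

    def test_null_track_rc_near_one(self, desk_chrom, desk_dup):
        spec = PopulationSpec(
            chrom=desk_chrom, dup_segment=desk_dup, prevalence=0.0, seed=6
        )
        norm = mode_normalize(gen_population_coverage(spec))
        rc = detect_breakpoints(norm)
        assert 0.98 <= rc.rc <= 1.05

    def test_rotation_equivariance(self):
        chrom = ChromosomeMap(length_bp=40_000)
        rng = np.random.default_rng(7)
        counts = rng.poisson(100, size=200)
        counts[40:120] = rng.poisson(200, size=80)
        rc = detect_breakpoints(mode_normalize(_track(chrom, counts)))
        shift_bins = 37
        rolled = np.roll(counts, shift_bins)
        rc_shift = detect_breakpoints(mode_normalize(_track(chrom, rolled)))
        L = chrom.length_bp
        assert rc_shift.boundary_1 == (rc.boundary_1 + shift_bins * 200) % L
        assert rc_shift.boundary_2 == (rc.boundary_2 + shift_bins * 200) % L

    def test_candidate_search_prefers_truth_over_decoys(self):
        chrom = ChromosomeMap(length_bp=40_000)
        counts = np.full(200, 100)
        counts[40:120] = 200  # noiseless planted segment
        norm = mode_normalize(_track(chrom, counts))
        cands = [40 * 200, 120 * 200, 10 * 200, 170 * 200]
        rc = detect_breakpoints(norm, candidates=cands)
        assert {rc.boundary_1, rc.boundary_2} == {8000, 24_000}
        # exhaustive search over all bins agrees
        rc_ex = detect_breakpoints(norm, mode="exhaustive")
        assert {rc_ex.boundary_1, rc_ex.boundary_2} == {8000, 24_000}

    def test_too_few_candidates_rejected(self, desk_chrom, desk_dup):
        spec = PopulationSpec(
            chrom=desk_chrom, dup_segment=desk_dup, prevalence=0.8, seed=8
        )
        norm = mode_normalize(gen_population_coverage(spec))
        with pytest.raises(ValueError):
            detect_breakpoints(norm, candidates=[100])


@pytest.mark.parametrize(
    "rc,expected", [(1.8, True), (1.02, False), (1.5, True)]
)
def test_classify_pattern_threshold_inclusive(rc, expected):
    assert classify_pattern(rc) is expected
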