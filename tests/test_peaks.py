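"""Ter-peak statistics: height, spc increase, marker ratios, flatness."""

import numpy as np
import pytest

from termfa.coverage import CoverageTrack, build_grid
from termfa.genome import Locus
from termfa.peaks import (
    PeakRegion,
    flatness_test,
    marker_ratio,
    peak_height,
    region_copy_ratio,
    ter_peak_increase,
)
from termfa.profile import MfaProfile


def _profile(loess, length=700):
    loess = np.asarray(loess, float)
    n = len(loess)
    centers = (np.arange(n) + 0.5) * (length / n)
    return MfaProfile(
        window_centers=centers, log2_ratio=loess.copy(), loess=loess, span=0.5
    )


class TestPeakHeight:
    def test_flat_profile_scores_zero(self):
        profile = _profile(np.zeros(7))
        assert peak_height(profile, PeakRegion(200, 500, flank_width=2)) == 0.0

    def test_constructed_example(self):
        profile = _profile([0, 0, 0.5, 0.8, 0.5, 0, 0])
        # region covers the middle three windows, flank the last two
        assert peak_height(profile, PeakRegion(200, 500, flank_width=2)) == pytest.approx(0.8)

    def test_invariant_to_constant_shift(self):
        base = np.array([0, 0, 0.5, 0.8, 0.5, 0, 0])
        region = PeakRegion(200, 500, flank_width=2)
        h0 = peak_height(_profile(base), region)
        h1 = peak_height(_profile(base + 3.3), region)
        assert h1 == pytest.approx(h0)

    def test_flank_wraps_around_origin(self):
        loess = np.r_[np.zeros(2), np.full(6, 1.0), np.zeros(2)]
        profile = _profile(loess, length=1000)
        # region at the end of the chromosome; flank wraps to the start
        h = peak_height(profile, PeakRegion(200, 800, flank_width=3))
        assert h == pytest.approx(1.0)

    def test_empty_region_rejected(self):
        with pytest.raises(ValueError):
            peak_height(_profile(np.zeros(7)), PeakRegion(10, 20, flank_width=1))


class TestTerPeakIncrease:
    def test_identical_profiles_give_zero(self):
        p = _profile([0, 0, 0.5, 0.8, 0.5, 0, 0])
        assert ter_peak_increase(p, p, PeakRegion(200, 500, flank_width=2)) == 0.0

    def test_constructed_difference(self):
        pre = _profile([0, 0, 0.3, 0.5, 0.3, 0, 0])
        post = _profile([0, 0, 0.5, 0.8, 0.5, 0, 0])
        region = PeakRegion(200, 500, flank_width=2)
        assert ter_peak_increase(pre, post, region) == pytest.approx(0.3)

    def test_antisymmetric(self):
        pre = _profile([0, 0.1, 0.3, 0.6, 0.2, 0.05, 0])
        post = _profile([0, 0.2, 0.7, 0.9, 0.4, 0.1, 0])
        region = PeakRegion(100, 500, flank_width=2)
        assert ter_peak_increase(pre, post, region) == pytest.approx(
            -ter_peak_increase(post, pre, region)
        )

    def test_grid_mismatch_rejected(self):
        with pytest.raises(ValueError):
            ter_peak_increase(
                _profile(np.zeros(7)), _profile(np.zeros(10)), PeakRegion(1, 2)
            )


class TestMarkerRatio:
    def test_flat_track_ratio_near_one(self, rng):
        counts = rng.poisson(500, size=200)
        track = CoverageTrack(bounds=build_grid(200_000, 200), counts=counts)
        r = marker_ratio(track, Locus("a", 50_000), Locus("b", 150_000), w=3)
        assert r == pytest.approx(1.0, abs=0.15)

    def test_recovers_known_copy_ratio(self):
        """Ground-truth 2.5x copy difference, depth 500: within 10% (50 reps)."""
        from termfa.simulate import sample_counts

        expected = np.ones(400)
        expected[90:110] = 2.5
        locus_a, locus_b = Locus("a", 100_000), Locus("b", 300_000)
        estimates = []
        for seed in range(50):
            rng = np.random.default_rng(1000 + seed)
            track = sample_counts(expected, depth=500.0, rng=rng, length=400_000)
            estimates.append(marker_ratio(track, locus_a, locus_b, w=2))
        ok = [abs(e - 2.5) / 2.5 <= 0.10 for e in estimates]
        assert np.mean(ok) >= 0.9

    def test_profile_variant_uses_smoothed_copy(self):
        loess = np.zeros(100)
        loess[20:30] = 1.0  # 2-fold in log2
        profile = _profile(loess, length=100_000)
        r = marker_ratio(profile, Locus("a", 25_000), Locus("b", 75_000), w=1)
        assert r == pytest.approx(2.0)

    def test_missing_signal_without_pseudocount_rejected(self):
        track = CoverageTrack(bounds=build_grid(1000, 10), counts=np.zeros(10, dtype=int))
        with pytest.raises(ZeroDivisionError):
            marker_ratio(track, Locus("a", 100), Locus("b", 900), w=0)


class TestRegionCopyRatio:
    def test_no_amplification_is_unity(self, rng):
        track = CoverageTrack(
            bounds=build_grid(500_000, 500), counts=rng.poisson(500, size=500)
        )
        r = region_copy_ratio(track, (100_000, 200_000), Locus("ref", 400_000), w=5)
        assert r == pytest.approx(1.0, abs=0.05)

    @pytest.mark.parametrize("fold", [1.3, 4.9])
    def test_recovers_injected_fold(self, fold):
        from termfa.simulate import sample_counts

        expected = np.ones(500)
        expected[100:200] *= fold
        rng = np.random.default_rng(17)
        track = sample_counts(expected, depth=500.0, rng=rng, length=500_000)
        r = region_copy_ratio(track, (100_000, 200_000), Locus("ref", 400_000), w=5)
        assert r == pytest.approx(fold, rel=0.10)


class TestFlatnessTest:
    def test_all_zero_profile_is_flat(self):
        flat, score = flatness_test(_profile(np.zeros(50)), PeakRegion(100, 400), threshold=0.1)
        assert flat and score == 0.0

    def test_explicit_threshold(self):
        profile = _profile(np.r_[np.zeros(20), np.full(10, 1.0), np.zeros(20)], length=500)
        region = PeakRegion(200, 300, flank_width=5)
        flat, score = flatness_test(profile, region, threshold=0.5)
        assert not flat and score == pytest.approx(1.0)

    def test_control_profile_sets_threshold(self, rng):
        noise = rng.normal(0, 0.01, size=200)
        control = _profile(noise, length=2000)
        flat, _ = flatness_test(_profile(noise * 0.5, length=2000),
                                PeakRegion(500, 1000, flank_width=20), control=control)
        peaked = np.zeros(200)
        peaked[60:80] = 1.0
        not_flat, _ = flatness_test(_profile(peaked, length=2000),
                                    PeakRegion(500, 1000, flank_width=20), control=control)
        assert flat and not not_flat
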