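"""Generative-model behavior: oriC gradient, RLDR trapping, Poisson sampling."""

from dataclasses import replace

import numpy as np
import pytest

from termfa.coverage import build_grid
from termfa.genome import innermost_ter_pair
from termfa.simulate import (
    SCENARIOS,
    SimulationConfig,
    default_map,
    effective_map,
    expected_copy_profile,
    make_scenario,
    sample_counts,
    simulate_rldr_events,
    simulate_track,
)


class TestConfig:
    def test_validation(self):
        with pytest.raises(ValueError):
            SimulationConfig(rldr_rate=-1)
        with pytest.raises(ValueError):
            SimulationConfig(rereplication_prob=1.5)
        with pytest.raises(ValueError):
            SimulationConfig(depth=0)

    def test_yaml_round_trip(self, tmp_path):
        config = make_scenario("topA_topB_inv", seed=9)
        path = tmp_path / "c.yaml"
        config.to_yaml(path)
        assert SimulationConfig.from_yaml(path) == config

    def test_spc_variant_flattens_and_keeps_rldr(self):
        config = make_scenario("topA_topB")
        spc = config.spc_variant(runoff_factor=2.0)
        assert spc.spc and spc.rldr_rate == 2 * config.rldr_rate


class TestExpectedCopyProfile:
    def test_ori_ter_ratio_closed_form(self, ecoli_map):
        """c_over_tau = 1, no RLDR: copy(oriC) / copy(last-replicated) = 2."""
        config = SimulationConfig(c_over_tau=1.0, rldr_rate=0.0)
        profile = expected_copy_profile(config, ecoli_map, 2000)
        assert profile.max() / profile.min() == pytest.approx(2.0, rel=1e-3)

    def test_spc_profile_is_flat_ones(self, ecoli_map):
        config = SimulationConfig(c_over_tau=1.0, rldr_rate=0.0, spc=True)
        profile = expected_copy_profile(config, ecoli_map, 1000)
        assert np.allclose(profile, 1.0)

    def test_mean_normalized_to_one(self, ecoli_map):
        for name in SCENARIOS:
            config = replace(make_scenario(name, seed=2), n_cells=200)
            profile = expected_copy_profile(config, ecoli_map, 500)
            assert profile.mean() == pytest.approx(1.0, abs=1e-9)
            assert (profile > 0).all()

    def test_tus_null_rldr_profile_is_flat(self, ecoli_map):
        """No barriers, uniform origins: max/min window ratio < 1.2 under spc."""
        config = SimulationConfig(
            spc=True, tus=False, rldr_rate=5.0, n_cells=10_000, seed=8
        )
        profile = expected_copy_profile(config, ecoli_map, 200)
        assert profile.max() / profile.min() < 1.2

    def test_trap_interval_exceeds_flanks_only_with_tus(self, ecoli_map):
        left, right = innermost_ter_pair(ecoli_map)
        bounds = build_grid(ecoli_map.length, 2000)
        centers = (bounds[:-1] + bounds[1:]) / 2
        inside = (centers >= left.position) & (centers < right.position)
        i_hi = np.searchsorted(centers, right.position)
        i_lo = np.searchsorted(centers, left.position)
        flanks = np.r_[i_lo - 100 : i_lo, i_hi : i_hi + 100]

        base = SimulationConfig(spc=True, rldr_rate=2.0, n_cells=4000, seed=3)
        with_tus = expected_copy_profile(base, ecoli_map, 2000)
        assert with_tus[inside].mean() > with_tus[flanks].mean()

        no_tus_means = []
        for seed in range(6):
            p = expected_copy_profile(
                replace(base, tus=False, seed=20 + seed), ecoli_map, 2000
            )
            no_tus_means.append(p[inside].mean() - p[flanks].mean())
        mc_se = np.std(no_tus_means, ddof=1) / np.sqrt(len(no_tus_means))
        assert abs(np.mean(no_tus_means)) < 3 * mc_se + 1e-3

    def test_spc_removes_oric_gradient(self, ecoli_map):
        """Regressing log2(expected) on oriC distance outside Ter: slope ~ 0."""
        config = SimulationConfig(spc=True, tus=False, rldr_rate=1.0, n_cells=4000, seed=5)
        profile = expected_copy_profile(config, ecoli_map, 1000)
        bounds = build_grid(ecoli_map.length, 1000)
        centers = (bounds[:-1] + bounds[1:]) / 2
        left, right = innermost_ter_pair(ecoli_map)
        outside = ~((centers >= left.position - 3e5) & (centers < right.position + 3e5))
        dist = np.array([ecoli_map.circ_distance(int(c), ecoli_map.oriC) for c in centers])
        slope = np.polyfit(dist[outside] / 1e6, np.log2(profile[outside]), 1)[0]
        no_spc = expected_copy_profile(replace(config, spc=False), ecoli_map, 1000)
        slope_ref = np.polyfit(dist[outside] / 1e6, np.log2(no_spc[outside]), 1)[0]
        assert abs(slope) < 0.1 * abs(slope_ref)

    def test_inversion_relocates_maximum(self, ecoli_map):
        """After inverting the TerB segment the peak sits in TerB'-TerG."""
        config = replace(
            make_scenario("topA_topB_inv", seed=6), spc=True, amplification=None
        )
        profile = expected_copy_profile(config, ecoli_map, 2000)
        bounds = build_grid(ecoli_map.length, 2000)
        centers = (bounds[:-1] + bounds[1:]) / 2
        argmax = centers[np.argmax(profile)]
        emap = effective_map(config, ecoli_map)
        left, right = innermost_ter_pair(emap)
        assert left.position <= argmax < right.position
        old_left, old_right = innermost_ter_pair(ecoli_map)
        assert not (old_left.position <= argmax < 1_680_000)


class TestRldrEvents:
    def test_rate_zero_gives_no_events(self, ecoli_map, rng):
        assert simulate_rldr_events(SimulationConfig(rldr_rate=0.0), ecoli_map, rng) == []

    def test_tus_false_never_traps(self, ecoli_map, rng):
        config = SimulationConfig(rldr_rate=2.0, tus=False, n_cells=500)
        events = simulate_rldr_events(config, ecoli_map, rng)
        assert events
        assert all(e.trapped_left is None and e.trapped_right is None for e in events)
        assert all(e.extra_copies == 0 for e in events)

    def test_origin_inside_trap_arrests_both_forks(self, ecoli_map, rng):
        """Long runs from inside TerA-TerB always end on the two barriers."""
        config = SimulationConfig(
            rldr_rate=1.0, rldr_run_mean=1e9, n_cells=200, rereplication_prob=0.0
        )
        events = simulate_rldr_events(config, ecoli_map, rng)
        inside = [e for e in events if 1_340_000 < e.origin < 1_680_000]
        assert inside
        for e in inside:
            assert e.trapped_left.name == "TerA" and e.trapped_right.name == "TerB"
            assert e.left_end == 1_340_000 and e.right_end == 1_680_000

    def test_event_count_scales_with_rate(self, ecoli_map, rng):
        config = SimulationConfig(rldr_rate=3.0, n_cells=2000)
        events = simulate_rldr_events(config, ecoli_map, rng)
        assert len(events) == pytest.approx(6000, rel=0.1)


class TestSampleCounts:
    def test_poisson_moments(self):
        rng = np.random.default_rng(1)
        track = sample_counts(np.ones(10_000), depth=100.0, rng=rng)
        mean = track.counts.mean()
        assert 97 <= mean <= 103
        assert 0.9 <= track.counts.var() / mean <= 1.1

    def test_zero_expectation_gives_zero_counts(self, rng):
        track = sample_counts(np.r_[np.zeros(5), np.ones(5)], depth=50.0, rng=rng)
        assert (track.counts[:5] == 0).all()

    def test_negative_depth_rejected(self, rng):
        with pytest.raises(ValueError):
            sample_counts(np.ones(10), depth=-1.0, rng=rng)

    def test_same_seed_bit_identical(self, ecoli_map):
        config = make_scenario("topA_topB", seed=14)
        t1 = simulate_track(config, ecoli_map, 500)
        t2 = simulate_track(config, ecoli_map, 500)
        assert np.array_equal(t1.counts, t2.counts)


class TestScenarios:
    def test_wild_type_has_no_rldr_or_amplification(self):
        config = make_scenario("wild_type")
        assert config.rldr_rate == 0.0 and config.amplification is None

    def test_topA_topB_presets(self):
        config = make_scenario("topA_topB")
        assert config.rldr_rate > 0 and config.rereplication_gain > 0
        (region, fold) = config.amplification
        assert fold == pytest.approx(4.9)

    def test_tus_variant_differs_only_in_tus(self):
        a, b = make_scenario("topA_topB"), make_scenario("topA_topB_tus")
        assert replace(b, tus=True) == a

    def test_unknown_scenario_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            make_scenario("rnhA")
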