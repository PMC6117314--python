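"""Adaptation rule: profile shape, clamping, pairing semantics."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import dendrosim as ds
from dendrosim.plasticity import (AdaptationRule, adaptive_link_update,
                                  apply_adaptation, collect_adaptation_pairs,
                                  delta_profile)

RULE = AdaptationRule(amplitude=0.05, noise_amplitude=0.0)


class TestDeltaProfile:
    @pytest.mark.parametrize("d, expected", [
        (0.0, 0.0),
        (15.0, 0.05 * math.exp(-1.0)),
        (-60.0, 0.0),
        (50.0, 0.05 * math.exp(-50.0 / 15.0)),
        (50.001, 0.0),
    ])
    def test_exponential_values(self, d, expected):
        assert delta_profile(d, RULE) == pytest.approx(expected)

    def test_two_level_is_a_signed_step(self):
        rule = AdaptationRule(amplitude=0.05, profile_kind="two_level")
        assert delta_profile(10.0, rule) == 0.05
        assert delta_profile(-49.0, rule) == -0.05
        assert delta_profile(51.0, rule) == 0.0

    @given(st.floats(-200, 200, allow_nan=False))
    @settings(max_examples=200, deadline=None)
    def test_odd_and_bounded(self, d):
        v = delta_profile(d, RULE)
        assert v + delta_profile(-d, RULE) == pytest.approx(0.0, abs=1e-15)
        assert abs(v) <= RULE.amplitude + 1e-15

    def test_unknown_profile_rejected(self):
        with pytest.raises(ValueError):
            AdaptationRule(profile_kind="linear")


class TestApplyAdaptation:
    @pytest.mark.parametrize("j, delta, expected", [
        (1.0, 0.05, 1.05),
        (1.0, 0.0, 1.0),
        (10.0, 0.05, 10.0),       # clamped at the ceiling
        (1e-6, -0.5, 1e-6),       # clamped at the floor
    ])
    def test_update_and_clamp(self, j, delta, expected):
        assert apply_adaptation(j, delta, RULE) == pytest.approx(expected)

    def test_bounds_hold_over_many_random_steps(self):
        """J never leaves [1e-6, 10] across 10^6 random adaptation steps."""
        rng = np.random.default_rng(0)
        deltas = rng.uniform(-0.05, 0.05, size=1_000_000)
        etas = (rng.random(1_000_000) - 0.5) * 1e-3
        j = 1.0
        lo = hi = j
        for i in range(0, 1_000_000, 1000):
            block_d = deltas[i:i + 1000]
            block_e = etas[i:i + 1000]
            for d, e in zip(block_d, block_e):
                j = min(10.0, max(1e-6, j * (1.0 + d) + e))
            lo, hi = min(lo, j), max(hi, j)
        assert 1e-6 <= lo and hi <= 10.0

    def test_multiplicative_character(self):
        """Without noise, log J+ - log J depends only on delta."""
        for j in (0.01, 1.0, 5.0):
            d = 0.03
            assert math.log(apply_adaptation(j, d, RULE)) - math.log(j) == \
                pytest.approx(math.log(1 + d))

    def test_frozen_without_amplitude_and_noise(self):
        net = ds.build_feedforward(n_inputs=15, k_terminals=3, seed=2)
        stim = ds.make_stimulus("periodic_simultaneous", 10.0, n_inputs=15,
                                rate_hz=5.0)
        lif = ds.LifParams(dt_ms=1.0, f_c_hz=math.inf)
        rule = AdaptationRule(amplitude=0.0, noise_amplitude=0.0)
        res = ds.simulate(net, stim, lif, rule, duration_s=10.0)
        np.testing.assert_array_equal(res.j_final, np.ones((1, 3)))


class TestAdaptiveLinkUpdate:
    def test_identity_and_floor(self):
        assert adaptive_link_update(0.5, 0.0) == 0.5
        assert adaptive_link_update(0.01, -2.0) == 0.0

    def test_repeated_potentiation_grows_geometrically(self):
        w = 0.1
        for _ in range(50):
            w = adaptive_link_update(w, 0.05)
        assert w == pytest.approx(0.1 * 1.05 ** 50)


class TestPairing:
    def test_post_spike_stimulations_potentiate(self):
        spikes = pd.DataFrame({"time_ms": [0.0], "node_id": [0],
                               "terminal_id": [0]})
        stims = pd.DataFrame({"time_ms": [3.0, 5.0], "node_id": [0, 0],
                              "terminal_id": [1, 1], "link": [7, 8]})
        ev = collect_adaptation_pairs(stims, spikes, RULE)
        assert [e.delta_ms for e in ev] == [3.0, 5.0]
        assert all(e.delta_rel > 0 for e in ev)

    def test_pre_spike_stimulations_depress(self):
        spikes = pd.DataFrame({"time_ms": [0.0], "node_id": [0],
                               "terminal_id": [1]})
        stims = pd.DataFrame({"time_ms": [-10.0, -6.0], "node_id": [0, 0],
                              "terminal_id": [0, 0], "link": [1, 2]})
        ev = collect_adaptation_pairs(stims, spikes, RULE)
        assert sorted(e.delta_ms for e in ev) == [-10.0, -6.0]
        assert all(e.delta_rel < 0 for e in ev)

    def test_same_terminal_never_pairs(self):
        spikes = pd.DataFrame({"time_ms": [0.0], "node_id": [0],
                               "terminal_id": [0]})
        stims = pd.DataFrame({"time_ms": [3.0], "node_id": [0],
                              "terminal_id": [0], "link": [0]})
        assert collect_adaptation_pairs(stims, spikes, RULE) == []
        # adaptive-link mode lifts the restriction
        assert len(collect_adaptation_pairs(stims, spikes, RULE,
                                            adaptive_link=True)) == 1

    def test_cutoff_and_coincidence_excluded(self):
        spikes = pd.DataFrame({"time_ms": [0.0], "node_id": [0],
                               "terminal_id": [0]})
        stims = pd.DataFrame({"time_ms": [0.0, 60.0], "node_id": [0, 0],
                              "terminal_id": [1, 1], "link": [1, 1]})
        assert collect_adaptation_pairs(stims, spikes, RULE) == []

    def test_engine_adaptation_matches_offline_pairing(self):
        """The kernel's online J updates equal a replay of the offline
        pairing oracle over the logged events (noiseless, clamp-free)."""
        rng = np.random.default_rng(3)
        n = 9
        net = ds.build_feedforward(n_inputs=n, k_terminals=3, seed=3)
        stim = ds.make_stimulus("periodic_simultaneous", 3.0, n_inputs=n,
                                rate_hz=5.0)
        lif = ds.LifParams(dt_ms=1.0, f_c_hz=math.inf)
        rule = AdaptationRule(amplitude=0.02, noise_amplitude=0.0)
        res = ds.simulate(net, stim, lif, rule, duration_s=3.0,
                          record_stimulations=True, record_adaptation=True)
        events = collect_adaptation_pairs(res.stim_frame.rename(
            columns={"link": "link"}), res.spike_frame(), rule)
        j = np.ones(3)
        for e in events:
            j[e.terminal_id] *= (1.0 + e.delta_rel)
        np.testing.assert_allclose(res.j_final[0], j, rtol=1e-10)
        assert len(events) == len(res.adaptation_frame)
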