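"""Membrane dynamics, spiking, refractoriness and engine-vs-oracle checks."""

import math

import numpy as np
import pytest

import dendrosim as ds
from dendrosim.model_core import (EV_FAIL, EV_SPIKE, LifParams, SpikeLog,
                                  TerminalState, attempt_spike, decay_voltage,
                                  deliver_pulse, simulate)
from dendrosim.builders import Stimulus, build_feedforward

from reference import run_reference, voltage_closed_form


def _single_node(weights, delays, k=3, v_st=0.0, v_th=1.0):
    n = len(weights)
    net = build_feedforward(n_inputs=n, k_terminals=k, seed=0,
                            v_st=v_st, v_th=v_th)
    net.link_w = np.asarray(weights, float) * (v_th - v_st)
    net.link_tau_ms = np.asarray(delays, float)
    net.link_term = np.arange(n, dtype=np.int64) % k
    return net


def _stim(times_ms, sources):
    return Stimulus(np.asarray(times_ms, float), np.asarray(sources, np.int64),
                    np.empty(0), np.empty(0, np.int64))


class TestDecay:
    @pytest.mark.parametrize("v, dt, expected", [
        (0.0, 10.0, 0.0),                       # rest is a fixed point
        (1.0, 20.0, math.exp(-1.0)),            # one time constant
        (0.5, 0.0, 0.5),                        # no elapsed time
    ])
    def test_closed_form(self, v, dt, expected):
        assert decay_voltage(v, dt, LifParams()) == pytest.approx(expected)

    def test_negative_dt_rejected(self):
        with pytest.raises(ValueError):
            decay_voltage(1.0, -1.0, LifParams())

    def test_monotone_toward_rest(self):
        p = LifParams()
        vs = [decay_voltage(1.0, dt, p) for dt in np.linspace(0, 100, 50)]
        assert np.all(np.diff(vs) < 0) and vs[-1] > 0


class TestPulseAndSpike:
    def test_pulse_jump_is_j_times_w(self):
        s = TerminalState(voltage=0.0, weight_j=1.0)
        assert deliver_pulse(s, 0.15).voltage == pytest.approx(0.15)
        s = TerminalState(voltage=0.9, weight_j=2.0)
        assert deliver_pulse(s, 0.15).voltage == pytest.approx(1.2)
        s = TerminalState(voltage=0.3)
        assert deliver_pulse(s, 0.0).voltage == pytest.approx(0.3)

    def test_unbounded_fc_always_spikes(self):
        rng = np.random.default_rng(0)
        p = LifParams(f_c_hz=math.inf)
        for _ in range(50):
            s = TerminalState(voltage=1.2, time_of_last_crossing=0.0)
            assert attempt_spike(s, 0.0, p, rng) == EV_SPIKE

    def test_zero_lag_crossing_always_fails(self):
        rng = np.random.default_rng(0)
        p = LifParams(f_c_hz=15.0)
        s = TerminalState(voltage=1.2, previous_voltage=0.9,
                          time_of_last_crossing=5.0)
        assert attempt_spike(s, 5.0, p, rng) == EV_FAIL
        assert s.voltage == pytest.approx(0.9)

    def test_below_threshold_is_an_error(self):
        with pytest.raises(ValueError):
            attempt_spike(TerminalState(voltage=0.5), 0.0, LifParams(),
                          np.random.default_rng(0))

    def test_periodic_crossings_saturate_at_fc(self):
        """10^5 periodic crossings emit spikes at f_c regardless of the
        crossing interval (rate = P/interval = f_c)."""
        rng = np.random.default_rng(7)
        p = LifParams(f_c_hz=15.0)
        for interval_ms in (1.0, 5.0):
            s = TerminalState()
            n = 100_000
            spikes = 0
            for i in range(n):
                s.voltage = 1.1
                s.previous_voltage = 0.9
                if attempt_spike(s, i * interval_ms, p, rng) == EV_SPIKE:
                    spikes += 1
            rate = spikes / (n * interval_ms / 1000.0)
            assert rate == pytest.approx(15.0, rel=0.05)


class TestEngineSemantics:
    def test_single_suprathreshold_pulse_one_spike(self):
        net = _single_node([1.5, 1.5, 1.5], [5.0, 30.0, 80.0])
        lif = LifParams(dt_ms=1.0, f_c_hz=math.inf)
        res = simulate(net, _stim([0.0], [0]), lif, None, duration_s=0.2)
        assert list(res.spike_time_ms) == [5.0]
        assert list(res.spike_terminal) == [0]

    def test_empty_network_stays_silent(self):
        net = _single_node([0.5], [1.0], k=1)
        res = simulate(net, Stimulus.empty(), LifParams(f_c_hz=math.inf),
                       None, duration_s=0.1)
        assert len(res.spike_time_ms) == 0 and res.n_stimulations == 0

    def test_blind_terminal_ignores_input_but_it_still_pairs(self):
        # terminal 0 spikes at 5 ms; a pulse to it at 6 ms (inside the 2 ms
        # blind window) leaves the voltage unchanged yet is logged as a
        # sub-threshold stimulation
        net = _single_node([1.5, 0.3, 0.3], [5.0, 6.0, 6.0])
        net.link_term = np.array([0, 0, 1], np.int64)
        lif = LifParams(dt_ms=1.0, f_c_hz=math.inf, refractory_ms=2.0)
        res = simulate(net, _stim([0.0, 0.0, 0.0], [0, 1, 2]), lif, None,
                       duration_s=0.05, record_stimulations=True)
        assert list(res.spike_time_ms) == [5.0]
        stims = res.stim_frame
        blind = stims[(stims.time_ms == 6.0) & (stims.terminal_id == 0)]
        assert len(blind) == 1
        # the blind pulse added no voltage: terminal 0 decayed from reset
        assert res.v_final[0, 0] < 0.05

    def test_sibling_keeps_voltage_and_spikes_at_refractory_end(self):
        # terminal 0 spikes at 5 ms; terminal 1 is pushed over threshold at
        # 6 ms, cannot cross during refractoriness, and discharges exactly
        # when the refractory period ends (7 ms)
        net = _single_node([1.5, 1.3], [5.0, 6.0], k=2)
        net.link_term = np.array([0, 1], np.int64)
        lif = LifParams(dt_ms=1.0, f_c_hz=math.inf, refractory_ms=2.0)
        res = simulate(net, _stim([0.0, 0.0], [0, 1]), lif, None,
                       duration_s=0.05)
        assert list(res.spike_time_ms) == [5.0, 7.0]
        assert list(res.spike_terminal) == [0, 1]

    def test_zero_refractory_degenerates_to_no_suppression(self):
        net = _single_node([1.5, 1.3], [5.0, 6.0], k=2)
        net.link_term = np.array([0, 1], np.int64)
        lif = LifParams(dt_ms=1.0, f_c_hz=math.inf, refractory_ms=0.0)
        res = simulate(net, _stim([0.0, 0.0], [0, 1]), lif, None,
                       duration_s=0.05)
        assert list(res.spike_time_ms) == [5.0, 6.0]

    def test_no_node_spike_pair_within_refractory(self):
        """No two spikes of one node are closer than the refractory period."""
        net = build_feedforward(n_inputs=15, k_terminals=3, seed=3)
        stim = ds.make_stimulus("periodic_simultaneous", 20.0, n_inputs=15,
                                rate_hz=5.0)
        lif = LifParams(dt_ms=1.0, f_c_hz=math.inf, refractory_ms=2.0)
        res = simulate(net, stim, lif, ds.AdaptationRule(noise_amplitude=0.0),
                       duration_s=20.0)
        gaps = np.diff(np.sort(res.spike_time_ms))
        assert len(res.spike_time_ms) > 50
        assert gaps.min() >= 2.0

    def test_voltage_matches_event_driven_closed_form(self):
        """Sub-threshold trajectory agrees with the exact decay-plus-jump
        evaluation to within 1e-9 relative error."""
        rng = np.random.default_rng(11)
        times = np.sort(rng.uniform(0, 400, size=30))
        net = _single_node(rng.uniform(0.01, 0.03, size=30).tolist(),
                           times.tolist(), k=1)
        net.link_term[:] = 0
        lif = LifParams(dt_ms=0.1, f_c_hz=math.inf)
        res = simulate(net, _stim(np.zeros(30), np.arange(30)), lif, None,
                       duration_s=0.5)
        bins = np.rint(times / 0.1)  # engine bins delays by rounding
        expected = voltage_closed_form(bins, net.link_w, 4999, dt_ms=0.1)
        assert res.v_final[0, 0] == pytest.approx(expected, rel=1e-9)

    def test_engine_matches_reference_on_random_pulse_trains(self):
        """Deterministic regime (unbounded f_c, no noise): spike times,
        stimulation count and adapted weights agree with the independent
        event-driven reference."""
        rng = np.random.default_rng(5)
        for trial in range(5):
            n_links = 9
            delays = np.sort(rng.uniform(1, 120, size=n_links))
            weights = rng.uniform(0.2, 0.9, size=n_links)
            net = _single_node(weights.tolist(), delays.tolist(), k=3)
            times = np.repeat(np.arange(0, 2000, 200.0), n_links)
            srcs = np.tile(np.arange(n_links), 10)
            lif = LifParams(dt_ms=1.0, f_c_hz=math.inf, refractory_ms=2.0)
            rule = ds.AdaptationRule(amplitude=0.05, noise_amplitude=0.0)
            res = simulate(net, _stim(times, srcs), lif, rule,
                           duration_s=2.2, record_stimulations=True)
            pulses = []
            for t, s in zip(times, srcs):
                # same binning as the engine: emission bin plus delay bins
                b = int(np.floor(t + 1e-9)) + int(np.rint(delays[s]))
                pulses.append((b, int(net.link_term[s]), weights[s]))
            spikes, stims, v_ref, j_ref = run_reference(
                pulses, n_bins=2200, k_terminals=3, dt_ms=1.0,
                rp_bins=2, amp_a=0.05)
            assert [(int(b), int(k)) for b, k in
                    zip(res.spike_time_ms, res.spike_terminal)] == spikes
            assert res.n_stimulations == len(stims)
            np.testing.assert_allclose(res.j_final[0], j_ref, rtol=1e-12)
            np.testing.assert_allclose(res.v_final[0], v_ref, rtol=1e-9,
                                       atol=1e-12)

    def test_scale_invariance_of_spike_times(self):
        """An affinely rescaled problem (rest -70 mV, threshold -54 mV,
        weights scaled by the 16 mV span) reproduces the normalized run's
        spike times exactly."""
        lif = LifParams(dt_ms=1.0, f_c_hz=15.0, refractory_ms=2.0)
        rule = ds.AdaptationRule(amplitude=0.05, noise_amplitude=1e-3)
        stim = ds.make_stimulus("periodic_simultaneous", 30.0, n_inputs=15,
                                rate_hz=5.0)
        runs = []
        for v_st, v_th in [(0.0, 1.0), (-70.0, -54.0)]:
            net = build_feedforward(n_inputs=15, k_terminals=3, seed=9,
                                    v_st=v_st, v_th=v_th)
            runs.append(simulate(net, stim, lif, rule, duration_s=30.0,
                                 seed=12345))
        a, b = runs
        np.testing.assert_array_equal(a.spike_time_ms, b.spike_time_ms)
        np.testing.assert_array_equal(a.spike_terminal, b.spike_terminal)
        np.testing.assert_allclose(a.j_final, b.j_final, rtol=1e-12)

    def test_same_seed_reproduces_run_exactly(self):
        net = build_feedforward(n_inputs=12, k_terminals=3, seed=4)
        stim = ds.make_stimulus("poisson_per_input", 5.0, n_inputs=12,
                                rate_hz=30.0, seed=4)
        lif = LifParams(dt_ms=0.1, f_c_hz=15.0)
        rule = ds.AdaptationRule()
        r1 = simulate(net, stim, lif, rule, duration_s=5.0, seed=77)
        r2 = simulate(net, stim, lif, rule, duration_s=5.0, seed=77)
        np.testing.assert_array_equal(r1.spike_time_ms, r2.spike_time_ms)
        np.testing.assert_array_equal(r1.j_final, r2.j_final)


class TestSpikeLog:
    def test_round_trips_through_csv(self, tmp_path):
        net = _single_node([1.5, 0.3, 0.3], [5.0, 6.0, 7.0])
        lif = LifParams(dt_ms=1.0, f_c_hz=math.inf)
        res = simulate(net, _stim([0.0] * 3, [0, 1, 2]), lif, None,
                       duration_s=0.05, record_stimulations=True,
                       record_failures=True)
        log = res.spike_log()
        assert list(log.frame.time_ms) == sorted(log.frame.time_ms)
        path = tmp_path / "log.csv"
        log.to_csv(path)
        back = SpikeLog.from_csv(path)
        assert len(back) == len(log)
        assert (back.frame.event_kind == log.frame.event_kind).all()

    def test_missing_columns_rejected(self):
        import pandas as pd
        with pytest.raises(ValueError):
            SpikeLog(pd.DataFrame({"time_ms": [1.0]}))
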