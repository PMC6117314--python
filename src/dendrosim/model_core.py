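"""Leaky integrate-and-fire dynamics for nodes with adaptive dendritic terminals.

A *node* integrates its inputs through K independent terminals (dendrites).
Each terminal i carries a scaled voltage V_i obeying

    dV_i/dt = -(V_i - V_st)/T + J_i * sum_m W_m * sum_n delta(t - (t_m(n) + tau_m))

with membrane time constant T, resting potential V_st, adaptive terminal
weight J_i, and static link weights W_m / delays tau_m.  A terminal crossing
the threshold attempts a spike which succeeds with probability
``min(1, dt_cross * f_c)`` where ``dt_cross`` is the time since the
terminal's last crossing and f_c the maximal stationary firing rate; on a
response failure the voltage is reverted to its value just before the pulses
of the crossing step.  After a spike the whole node is refractory: the
evoking terminal discards incoming stimulations for the refractory period,
the other terminals keep integrating but cannot cross, and any terminal
above threshold at the end of the refractory period immediately undergoes a
crossing event.

Simulation is fixed-step (pulses are binned to their arrival step) with an
exact per-step leak factor exp(-dt/T), so the leak carries no Euler bias.
Voltages are stored internally relative to V_st in units of (V_th - V_st);
an affinely rescaled problem (e.g. V_st=-70 mV, V_th=-54 mV with weights
scaled by 16 mV) therefore reproduces the normalized run's spike times.

The hot loop is a single numba kernel (:func:`_kernel`).  The small pure
functions (:func:`decay_voltage`, :func:`deliver_pulse`,
:func:`attempt_spike`) state the per-operation semantics and are what the
test-suite oracles exercise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numba import njit

__all__ = [
    "LifParams",
    "TerminalState",
    "InputLink",
    "SpikeLog",
    "SimResult",
    "decay_voltage",
    "deliver_pulse",
    "attempt_spike",
    "simulate",
]

#: event kinds used in spike logs
EV_SPIKE = "spike"
EV_STIM = "subthreshold_stimulation"
EV_FAIL = "crossing_failure"

# hard bounds on terminal weights (model clamp)
J_MIN = 1e-6
J_MAX = 10.0

# amplitude (in threshold units) of a direct above-threshold node stimulation
NODE_STIM_AMP = 1.3


@dataclass
class LifParams:
    """Membrane and spiking parameters.

    membrane_time_constant
        T in ms; the leak relaxes V toward V_st with this constant.
    v_threshold
        threshold in scaled units (1 by construction).
    refractory_ms
        node-wide refractory period after a spike, ms.
    f_c_hz
        maximal stationary firing rate per terminal in Hz; ``math.inf``
        disables response failures (every crossing spikes).
    dt_ms
        integration step, ms (1 ms for the feedforward experiments,
        0.1 ms for recurrent / random-input runs).
    """

    membrane_time_constant: float = 20.0
    v_threshold: float = 1.0
    refractory_ms: float = 2.0
    f_c_hz: float = 15.0
    dt_ms: float = 1.0

    def __post_init__(self) -> None:
        if self.membrane_time_constant <= 0:
            raise ValueError("membrane time constant must be positive")
        if self.refractory_ms < 0:
            raise ValueError("refractory period must be non-negative")
        if self.dt_ms <= 0:
            raise ValueError("time step must be positive")
        if not (self.f_c_hz > 0):
            raise ValueError("f_c must be positive (use math.inf for unbounded)")

    @property
    def unbounded_fc(self) -> bool:
        return math.isinf(self.f_c_hz)


@dataclass
class TerminalState:
    """State of one dendritic terminal (scaled units: rest 0, threshold 1)."""

    voltage: float = 0.0
    weight_j: float = 1.0
    time_of_last_crossing: float = -math.inf
    time_of_last_spike: float = -math.inf
    previous_voltage: float = 0.0


@dataclass
class InputLink:
    """A static link: ``source`` spikes arrive on ``terminal`` after ``tau_ms``."""

    source: int
    source_is_input: bool
    terminal: int
    weight: float
    tau_ms: float

    def __post_init__(self) -> None:
        if self.weight < 0:
            raise ValueError("link weight must be non-negative")
        if self.tau_ms < 0:
            raise ValueError("link delay must be non-negative")


def decay_voltage(v: float, dt_ms: float, params: LifParams, v_st: float = 0.0) -> float:
    """Exact exponential relaxation of a voltage toward rest over ``dt_ms``."""
    if dt_ms < 0:
        raise ValueError("elapsed time must be non-negative")
    return v_st + (v - v_st) * math.exp(-dt_ms / params.membrane_time_constant)


def deliver_pulse(state: TerminalState, w: float) -> TerminalState:
    """Instantaneous delta-function input: V jumps by J_i * W_m."""
    state.previous_voltage = state.voltage
    state.voltage = state.voltage + state.weight_j * w
    return state


def attempt_spike(state: TerminalState, t_ms: float, params: LifParams,
                  rng: np.random.Generator) -> str:
    """Resolve a threshold crossing at ``t_ms`` into a spike or a response failure.

    The spike probability is ``min(1, dt_cross * f_c)`` with ``dt_cross`` the
    time since the terminal's last crossing (success or failure, both reset
    the clock).  On a spike the voltage resets to rest; on a failure it is
    reverted to its value before the crossing step's pulses.
    """
    if state.voltage < params.v_threshold:
        raise ValueError("attempt_spike called below threshold")
    dt_cross_ms = t_ms - state.time_of_last_crossing
    state.time_of_last_crossing = t_ms
    if params.unbounded_fc:
        fired = True
    else:
        p = min(1.0, dt_cross_ms * params.f_c_hz * 1e-3)
        fired = rng.random() < p
    if fired:
        state.voltage = 0.0
        state.time_of_last_spike = t_ms
        return EV_SPIKE
    state.voltage = state.previous_voltage
    return EV_FAIL


class SpikeLog:
    """Time-ordered event record (spikes, sub-threshold stimulations, failures).

    Backed by a tidy DataFrame with columns
    ``time_ms, node_id, terminal_id, event_kind, effective_weight``.
    """

    COLUMNS = ["time_ms", "node_id", "terminal_id", "event_kind", "effective_weight"]

    def __init__(self, frame: pd.DataFrame):
        missing = [c for c in self.COLUMNS if c not in frame.columns]
        if missing:
            raise ValueError(f"spike log missing columns: {missing}")
        self.frame = frame.sort_values("time_ms", kind="stable").reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.frame)

    def spikes(self) -> pd.DataFrame:
        return self.frame[self.frame.event_kind == EV_SPIKE]

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "SpikeLog":
        return cls(pd.read_csv(path))


# ---------------------------------------------------------------------------
# numba kernel
# ---------------------------------------------------------------------------

_ERRORS = {
    0: "ok",
    1: "pulse ring buffer overflow (raise ring_cap)",
    2: "per-bin delivery buffer overflow (raise deliv_cap)",
    3: "spike log overflow",
    4: "stimulation log overflow",
    5: "adaptation log overflow",
    6: "failure log overflow",
}


@njit(cache=True)
def _kernel(n_bins, dt_ms, n_nodes, K, n_links,
            tau_mem_ms, fc_hz, rp_bins,
            link_mode, two_level, failure_reset, stims_on_failure,
            refrac_mode, blind_stims, refrac_fail_stims,
            amp_a, tau_adapt_ms, cutoff_bins, noise_amp,
            j_min, j_max, w_min, w_max,
            link_tgt, link_term, link_w, link_tau_bins,
            ext_ptr, ext_link, out_ptr, out_link,
            ext_bins, ext_src, nstim_bins, nstim_node, nstim_amp,
            J, V, seed,
            count_start_bin, n_fire, n_nofire, node_spikes, term_spikes,
            snap_every, snap_start_bin, snap_J, snap_w_flag, snap_W,
            log_stims, stim_bin, stim_node, stim_term, stim_link, stim_weff,
            log_adapt, adapt_start_bin,
            ad_bin, ad_node, ad_term, ad_link, ad_jb, ad_ja,
            spike_bin, spike_node, spike_term,
            log_fails, fail_bin, fail_node, fail_term,
            ring_cap, deliv_cap):
    np.random.seed(seed)
    decay = math.exp(-dt_ms / tau_mem_ms)
    theta = 1.0

    max_tau = 0
    for l in range(n_links):
        if link_tau_bins[l] > max_tau:
            max_tau = link_tau_bins[l]
    H = max_tau + rp_bins + 4

    ring_cnt = np.zeros(H, np.int64)
    ring_link = np.empty((H, ring_cap), np.int64)
    rr_cnt = np.zeros(H, np.int64)
    rr_node = np.empty((H, n_nodes), np.int64)

    deliv_link = np.empty(deliv_cap, np.int64)

    prevV = V.copy()
    last_deliv = np.full((n_nodes, K), -1, np.int64)
    last_cross = np.full((n_nodes, K), -(10 ** 14), np.int64)
    term_spike_bin = np.full((n_nodes, K), -1, np.int64)
    term_fail_bin = np.full((n_nodes, K), -1, np.int64)
    term_rfail_bin = np.full((n_nodes, K), -1, np.int64)
    refrac_end = np.zeros(n_nodes, np.int64)
    blind = np.full(n_nodes, -1, np.int64)

    SB = 512  # recent sub-threshold stimulations per terminal (within cutoff)
    PB = 64   # recent spikes per node (within cutoff)
    sb_bin = np.empty((n_nodes, K, SB), np.int64)
    sb_link = np.empty((n_nodes, K, SB), np.int64)
    sb_start = np.zeros((n_nodes, K), np.int64)
    sb_cnt = np.zeros((n_nodes, K), np.int64)
    pb_bin = np.empty((n_nodes, PB), np.int64)
    pb_term = np.empty((n_nodes, PB), np.int64)
    pb_start = np.zeros(n_nodes, np.int64)
    pb_cnt = np.zeros(n_nodes, np.int64)

    touched = np.empty(n_nodes, np.int64)
    touch_bin = np.full(n_nodes, -1, np.int64)
    attempted = np.zeros(K, np.bool_)

    n_sp = 0
    n_st = 0
    n_ad = 0
    n_fl = 0
    snap_idx = 0
    err = 0

    ei = 0
    si = 0
    n_ext_events = ext_bins.shape[0]
    n_nstims = nstim_bins.shape[0]
    n_snap_slots = snap_J.shape[0]

    for b in range(n_bins):
        if err != 0:
            break
        # 1. exact leak
        for n in range(n_nodes):
            for k in range(K):
                V[n, k] *= decay
        n_touched = 0
        n_deliv = 0

        # 2. external input units firing this bin schedule pulses on their links
        while ei < n_ext_events and ext_bins[ei] == b:
            s = ext_src[ei]
            for p in range(ext_ptr[s], ext_ptr[s + 1]):
                l = ext_link[p]
                slot = (b + link_tau_bins[l]) % H
                if ring_cnt[slot] >= ring_cap:
                    err = 1
                else:
                    ring_link[slot, ring_cnt[slot]] = l
                    ring_cnt[slot] += 1
            ei += 1

        # 3. direct above-threshold node stimulations (terminal 0)
        while si < n_nstims and nstim_bins[si] == b:
            n = nstim_node[si]
            if not (b < refrac_end[n] and blind[n] == 0):
                if last_deliv[n, 0] != b:
                    prevV[n, 0] = V[n, 0]
                    last_deliv[n, 0] = b
                V[n, 0] += nstim_amp
                if touch_bin[n] != b:
                    touch_bin[n] = b
                    touched[n_touched] = n
                    n_touched += 1
            si += 1

        # 4. deliver this bin's pulses
        slot = b % H
        for idx in range(ring_cnt[slot]):
            l = ring_link[slot, idx]
            n = link_tgt[l]
            k = link_term[l]
            if b < refrac_end[n] and k == blind[n]:
                # the evoking terminal does not respond to stimulations for
                # the refractory period: the voltage is unaffected.  The
                # arrival is still a sub-threshold stimulation and (with
                # blind_stims) takes part in adaptation pairing.
                if blind_stims == 1:
                    if n_deliv >= deliv_cap:
                        err = 2
                        break
                    deliv_link[n_deliv] = l
                    n_deliv += 1
                else:
                    if b >= count_start_bin:
                        n_nofire[l] += 1
                continue
            if last_deliv[n, k] != b:
                prevV[n, k] = V[n, k]
                last_deliv[n, k] = b
            if link_mode == 1:
                V[n, k] += link_w[l]
            else:
                V[n, k] += J[n, k] * link_w[l]
            if refrac_mode == 3 and b < refrac_end[n] and V[n, k] >= theta:
                # sibling terminals integrate during refractoriness but are
                # held just below threshold ("cannot cross")
                V[n, k] = theta * 0.999999
            if n_deliv >= deliv_cap:
                err = 2
                break
            deliv_link[n_deliv] = l
            n_deliv += 1
            if touch_bin[n] != b:
                touch_bin[n] = b
                touched[n_touched] = n
                n_touched += 1
        ring_cnt[slot] = 0

        # 5. refractory periods ending this bin re-check their node
        for idx in range(rr_cnt[slot]):
            n = rr_node[slot, idx]
            if touch_bin[n] != b:
                touch_bin[n] = b
                touched[n_touched] = n
                n_touched += 1
        rr_cnt[slot] = 0

        # 6. threshold resolution per touched node:
        #    highest voltage first, ties to the lowest terminal index,
        #    one attempt per terminal per bin
        for ti in range(n_touched):
            n = touched[ti]
            if b < refrac_end[n]:
                # refractory: no terminal may spike.  refrac_mode selects how
                # a sibling's would-be crossing is handled: 0 = checks
                # suspended (voltage rides above threshold, re-checked when
                # the refractory period ends); 1/2 = the crossing is annulled
                # as a forced response failure, with (1) or without (2)
                # resetting the crossing clock; 3 = voltage capped below
                # threshold at delivery (handled above)
                if refrac_mode == 1 or refrac_mode == 2:
                    for k in range(K):
                        if k == blind[n] or V[n, k] < theta:
                            continue
                        if refrac_mode == 1:
                            last_cross[n, k] = b
                        if failure_reset == 1:
                            V[n, k] = 0.0
                        else:
                            V[n, k] = prevV[n, k]
                        term_fail_bin[n, k] = b
                        term_rfail_bin[n, k] = b
                        n_fl += 1
                        if log_fails == 1:
                            if n_fl <= fail_bin.shape[0]:
                                fail_bin[n_fl - 1] = b
                                fail_node[n_fl - 1] = n
                                fail_term[n_fl - 1] = k
                            else:
                                err = 6
                continue  # no spikes during refractoriness
            for k in range(K):
                attempted[k] = False
            while True:
                best = -1
                best_v = 0.0
                for k in range(K):
                    if attempted[k] or V[n, k] < theta:
                        continue
                    if best == -1 or V[n, k] > best_v:
                        best = k
                        best_v = V[n, k]
                if best == -1:
                    break
                attempted[best] = True
                dtc_ms = (b - last_cross[n, best]) * dt_ms
                last_cross[n, best] = b
                if fc_hz <= 0.0:
                    fired = True
                else:
                    p = dtc_ms * fc_hz * 1e-3
                    if p > 1.0:
                        p = 1.0
                    fired = np.random.random() < p
                if fired:
                    V[n, best] = 0.0
                    term_spike_bin[n, best] = b
                    if b >= count_start_bin:
                        node_spikes[n] += 1
                        term_spikes[n, best] += 1
                    if n_sp < spike_bin.shape[0]:
                        spike_bin[n_sp] = b
                        spike_node[n_sp] = n
                        spike_term[n_sp] = best
                        n_sp += 1
                    else:
                        err = 3
                    # spike-side adaptation: pair with recent sub-threshold
                    # stimulations (t_sub < t_spike -> depression)
                    for i in range(K):
                        if link_mode == 0 and i == best:
                            continue
                        while sb_cnt[n, i] > 0 and \
                                b - sb_bin[n, i, sb_start[n, i]] > cutoff_bins:
                            sb_start[n, i] = (sb_start[n, i] + 1) % SB
                            sb_cnt[n, i] -= 1
                        for q in range(sb_cnt[n, i]):
                            pos = (sb_start[n, i] + q) % SB
                            tb = sb_bin[n, i, pos]
                            if tb == b:
                                continue
                            lq = sb_link[n, i, pos]
                            if two_level == 1:
                                d = -amp_a
                            else:
                                d = -amp_a * math.exp(-((b - tb) * dt_ms) / tau_adapt_ms)
                            eta = 0.0
                            if noise_amp > 0.0:
                                eta = (np.random.random() - 0.5) * noise_amp
                            if link_mode == 1:
                                wb = link_w[lq]
                                wn = wb * (1.0 + d) + eta
                                if wn < w_min:
                                    wn = w_min
                                elif wn > w_max:
                                    wn = w_max
                                link_w[lq] = wn
                                jb = wb
                                ja = wn
                            else:
                                jb = J[n, i]
                                ja = jb * (1.0 + d) + eta
                                if ja < j_min:
                                    ja = j_min
                                elif ja > j_max:
                                    ja = j_max
                                J[n, i] = ja
                            if log_adapt == 1 and b >= adapt_start_bin:
                                if n_ad < ad_bin.shape[0]:
                                    ad_bin[n_ad] = b
                                    ad_node[n_ad] = n
                                    ad_term[n_ad] = i
                                    ad_link[n_ad] = lq
                                    ad_jb[n_ad] = jb
                                    ad_ja[n_ad] = ja
                                    n_ad += 1
                                else:
                                    err = 5
                    # remember the spike for later stimulation-side pairing
                    if pb_cnt[n] >= PB:
                        pb_start[n] = (pb_start[n] + 1) % PB
                        pb_cnt[n] -= 1
                    pos = (pb_start[n] + pb_cnt[n]) % PB
                    pb_bin[n, pos] = b
                    pb_term[n, pos] = best
                    pb_cnt[n] += 1
                    # schedule outgoing pulses
                    for p in range(out_ptr[n], out_ptr[n + 1]):
                        l2 = out_link[p]
                        slot2 = (b + link_tau_bins[l2]) % H
                        if ring_cnt[slot2] >= ring_cap:
                            err = 1
                        else:
                            ring_link[slot2, ring_cnt[slot2]] = l2
                            ring_cnt[slot2] += 1
                    if rp_bins > 0:
                        refrac_end[n] = b + rp_bins
                        blind[n] = best
                        slot2 = (b + rp_bins) % H
                        rr_node[slot2, rr_cnt[slot2]] = n
                        rr_cnt[slot2] += 1
                        break
                else:
                    # response failure: the crossing is undone.  Either the
                    # voltage reverts to its value before the pulses of the
                    # crossing step (failure_reset=0) or it restarts from
                    # rest and is rebuilt by subsequent stimulations
                    # (failure_reset=1, the repeated rebuild-failure cycles
                    # of the saturated regime)
                    if failure_reset == 1:
                        V[n, best] = 0.0
                    else:
                        V[n, best] = prevV[n, best]
                    term_fail_bin[n, best] = b
                    n_fl += 1
                    if log_fails == 1:
                        if n_fl <= fail_bin.shape[0]:
                            fail_bin[n_fl - 1] = b
                            fail_node[n_fl - 1] = n
                            fail_term[n_fl - 1] = best
                        else:
                            err = 6

        # 7. classify this bin's deliveries; sub-threshold stimulations feed
        #    the pairing buffers (stim-side adaptation: t_sub > t_spike ->
        #    potentiation)
        for di in range(n_deliv):
            l = deliv_link[di]
            n = link_tgt[l]
            k = link_term[l]
            if term_spike_bin[n, k] == b:
                if b >= count_start_bin:
                    n_fire[l] += 1
                continue
            if b >= count_start_bin:
                n_nofire[l] += 1
            if term_fail_bin[n, k] == b and stims_on_failure == 0:
                # rolled back: no sub-threshold event — except, optionally,
                # when the crossing was annulled by the refractory period
                if not (refrac_fail_stims == 1 and term_rfail_bin[n, k] == b):
                    continue
            n_st += 1
            if log_stims == 1:
                if n_st <= stim_bin.shape[0]:
                    stim_bin[n_st - 1] = b
                    stim_node[n_st - 1] = n
                    stim_term[n_st - 1] = k
                    stim_link[n_st - 1] = l
                    if link_mode == 1:
                        stim_weff[n_st - 1] = link_w[l]
                    else:
                        stim_weff[n_st - 1] = link_w[l] * J[n, k]
                else:
                    err = 4
            while pb_cnt[n] > 0 and b - pb_bin[n, pb_start[n]] > cutoff_bins:
                pb_start[n] = (pb_start[n] + 1) % PB
                pb_cnt[n] -= 1
            for q in range(pb_cnt[n]):
                pos = (pb_start[n] + q) % PB
                tb = pb_bin[n, pos]
                if tb == b:
                    continue
                j = pb_term[n, pos]
                if link_mode == 0 and j == k:
                    continue
                if two_level == 1:
                    d = amp_a
                else:
                    d = amp_a * math.exp(-((b - tb) * dt_ms) / tau_adapt_ms)
                eta = 0.0
                if noise_amp > 0.0:
                    eta = (np.random.random() - 0.5) * noise_amp
                if link_mode == 1:
                    wb = link_w[l]
                    wn = wb * (1.0 + d) + eta
                    if wn < w_min:
                        wn = w_min
                    elif wn > w_max:
                        wn = w_max
                    link_w[l] = wn
                    jb = wb
                    ja = wn
                else:
                    jb = J[n, k]
                    ja = jb * (1.0 + d) + eta
                    if ja < j_min:
                        ja = j_min
                    elif ja > j_max:
                        ja = j_max
                    J[n, k] = ja
                if log_adapt == 1 and b >= adapt_start_bin:
                    if n_ad < ad_bin.shape[0]:
                        ad_bin[n_ad] = b
                        ad_node[n_ad] = n
                        ad_term[n_ad] = k
                        ad_link[n_ad] = l
                        ad_jb[n_ad] = jb
                        ad_ja[n_ad] = ja
                        n_ad += 1
                    else:
                        err = 5
            if sb_cnt[n, k] >= SB:
                sb_start[n, k] = (sb_start[n, k] + 1) % SB
                sb_cnt[n, k] -= 1
            pos = (sb_start[n, k] + sb_cnt[n, k]) % SB
            sb_bin[n, k, pos] = b
            sb_link[n, k, pos] = l
            sb_cnt[n, k] += 1

        # 8. state snapshots
        if snap_every > 0 and b >= snap_start_bin and \
                (b - snap_start_bin) % snap_every == 0 and snap_idx < n_snap_slots:
            for n in range(n_nodes):
                for k in range(K):
                    snap_J[snap_idx, n, k] = J[n, k]
            if snap_w_flag == 1:
                for l in range(n_links):
                    snap_W[snap_idx, l] = link_w[l]
            snap_idx += 1

    return n_sp, n_st, n_ad, n_fl, snap_idx, err


# ---------------------------------------------------------------------------
# python wrapper
# ---------------------------------------------------------------------------


@dataclass
class SimResult:
    """Outcome of one :func:`simulate` run.

    Spike times are in ms from simulation start.  ``j_snapshots`` has shape
    (n_snapshots, n_nodes, K); ``w_snapshots`` (adaptive-link mode only)
    has shape (n_snapshots, n_links).
    """

    dt_ms: float
    duration_ms: float
    spike_time_ms: np.ndarray
    spike_node: np.ndarray
    spike_terminal: np.ndarray
    j_final: np.ndarray
    w_final: np.ndarray
    v_final: np.ndarray
    n_fire: np.ndarray
    n_nofire: np.ndarray
    node_spike_counts: np.ndarray
    terminal_spike_counts: np.ndarray
    count_window_ms: tuple
    n_stimulations: int
    n_failures: int
    snapshot_times_ms: np.ndarray = field(default_factory=lambda: np.empty(0))
    j_snapshots: np.ndarray | None = None
    w_snapshots: np.ndarray | None = None
    stim_frame: pd.DataFrame | None = None
    adaptation_frame: pd.DataFrame | None = None
    failure_frame: pd.DataFrame | None = None

    def spike_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "time_ms": self.spike_time_ms,
            "node_id": self.spike_node,
            "terminal_id": self.spike_terminal,
        })

    def spike_log(self) -> SpikeLog:
        """Merge spikes (and logged stimulations / failures) into a SpikeLog."""
        parts = []
        sp = self.spike_frame()
        sp["event_kind"] = EV_SPIKE
        sp["effective_weight"] = np.nan
        parts.append(sp)
        if self.stim_frame is not None:
            st = self.stim_frame.rename(columns={"link": "link_id"}).copy()
            st = st[["time_ms", "node_id", "terminal_id", "effective_weight"]]
            st["event_kind"] = EV_STIM
            parts.append(st)
        if self.failure_frame is not None:
            fl = self.failure_frame.copy()
            fl["event_kind"] = EV_FAIL
            fl["effective_weight"] = np.nan
            parts.append(fl)
        frame = pd.concat(parts, ignore_index=True)[SpikeLog.COLUMNS]
        return SpikeLog(frame)


def simulate(network, stimulus, lif: LifParams, rule=None, duration_s: float = 1.0,
             seed: int = 0, count_window_s: tuple | None = None,
             snapshot_every_s: float = 0.0, snapshot_start_s: float = 0.0,
             snapshot_w: bool = False,
             record_stimulations: bool = False,
             record_adaptation: bool = False, adaptation_start_s: float = 0.0,
             adaptation_capacity: int = 2_000_000,
             record_failures: bool = False,
             failure_reset_to_rest: bool = False,
             stims_on_failure: bool = False,
             refractory_mode: int = 0,
             blind_stimulations: bool = True,
             refractory_failure_stimulations: bool = False,
             ring_cap: int = 8192, deliv_cap: int = 8192) -> SimResult:
    """Run a network for ``duration_s`` seconds under a stimulus schedule.

    ``network`` is a :class:`dendrosim.builders.Network`; ``stimulus`` a
    :class:`dendrosim.builders.Stimulus`.  ``rule`` is an
    :class:`dendrosim.plasticity.AdaptationRule` (``None`` freezes all
    weights).  ``count_window_s`` restricts the per-link firing /
    non-firing counters and per-node spike counters to ``[start, end]``
    seconds (default: whole run).  Returns a :class:`SimResult`.
    """
    dt = lif.dt_ms
    n_bins = int(round(duration_s * 1000.0 / dt))
    n_nodes = network.n_nodes
    K = network.k_terminals
    n_links = network.n_links
    span = network.v_th - network.v_st

    link_tgt = network.link_tgt.astype(np.int64)
    link_term = network.link_term.astype(np.int64)
    link_w = (network.link_w / span).astype(np.float64).copy()
    link_tau_bins = np.rint(network.link_tau_ms / dt).astype(np.int64)
    # node-sourced pulses must land strictly after the emitting bin
    is_node_src = ~network.link_src_is_input
    link_tau_bins[is_node_src] = np.maximum(link_tau_bins[is_node_src], 1)

    # adjacency: external inputs and node outputs
    ext_mask = network.link_src_is_input
    ext_ids = np.where(ext_mask)[0]
    ext_sources = network.link_src[ext_mask]
    ext_ptr = np.zeros(network.n_inputs + 1, np.int64)
    if len(ext_ids):
        order = np.argsort(ext_sources, kind="stable")
        ext_link = ext_ids[order].astype(np.int64)
        counts = np.bincount(ext_sources, minlength=network.n_inputs)
        ext_ptr[1:] = np.cumsum(counts)
    else:
        ext_link = np.empty(0, np.int64)

    node_ids = np.where(is_node_src)[0]
    node_sources = network.link_src[is_node_src]
    out_ptr = np.zeros(n_nodes + 1, np.int64)
    if len(node_ids):
        order = np.argsort(node_sources, kind="stable")
        out_link = node_ids[order].astype(np.int64)
        counts = np.bincount(node_sources, minlength=n_nodes)
        out_ptr[1:] = np.cumsum(counts)
    else:
        out_link = np.empty(0, np.int64)

    # stimulus schedules, binned and time-sorted
    ext_bins = np.floor(stimulus.input_times_ms / dt + 1e-9).astype(np.int64)
    order = np.argsort(ext_bins, kind="stable")
    ext_bins = ext_bins[order]
    ext_src = stimulus.input_ids[order].astype(np.int64)
    nstim_bins = np.floor(stimulus.node_times_ms / dt + 1e-9).astype(np.int64)
    order = np.argsort(nstim_bins, kind="stable")
    nstim_bins = nstim_bins[order]
    nstim_node = stimulus.node_ids[order].astype(np.int64)

    # plasticity configuration
    link_mode = 1 if network.mode == "adaptive_link" else 0
    if rule is None:
        amp_a, tau_adapt, cutoff_ms, noise_amp = 0.0, 15.0, 50.0, 0.0
        two_level = 0
    else:
        amp_a = rule.amplitude
        tau_adapt = rule.decay_ms
        cutoff_ms = rule.cutoff_ms
        noise_amp = rule.noise_amplitude
        two_level = 1 if rule.profile_kind == "two_level" else 0
    cutoff_bins = int(round(cutoff_ms / dt))

    if count_window_s is None:
        count_start_bin = 0
        count_window = (0.0, duration_s * 1000.0)
    else:
        count_start_bin = int(round(count_window_s[0] * 1000.0 / dt))
        count_window = (count_window_s[0] * 1000.0, duration_s * 1000.0)

    # capacities
    n_ext_pulses = int(np.diff(ext_ptr)[ext_src].sum()) if len(ext_src) else 0
    if lif.unbounded_fc:
        spike_cap = n_ext_pulses + len(nstim_bins) + 1024
    else:
        spike_cap = int(n_nodes * K * lif.f_c_hz * duration_s * 2.5) \
            + len(nstim_bins) + 4096
    spike_bin = np.empty(spike_cap, np.int64)
    spike_node = np.empty(spike_cap, np.int64)
    spike_term = np.empty(spike_cap, np.int64)

    stim_cap = (n_ext_pulses + spike_cap * max(1, out_ptr[-1] // max(1, n_nodes))
                + 1024) if record_stimulations else 1
    stim_bin = np.empty(stim_cap, np.int64)
    stim_node = np.empty(stim_cap, np.int64)
    stim_term = np.empty(stim_cap, np.int64)
    stim_link = np.empty(stim_cap, np.int64)
    stim_weff = np.empty(stim_cap, np.float64)

    ad_cap = int(adaptation_capacity) if record_adaptation else 1
    ad_bin = np.empty(ad_cap, np.int64)
    ad_node = np.empty(ad_cap, np.int64)
    ad_term = np.empty(ad_cap, np.int64)
    ad_link = np.empty(ad_cap, np.int64)
    ad_jb = np.empty(ad_cap, np.float64)
    ad_ja = np.empty(ad_cap, np.float64)

    fail_cap = stim_cap + spike_cap if record_failures else 1
    fail_bin = np.empty(fail_cap, np.int64)
    fail_node = np.empty(fail_cap, np.int64)
    fail_term = np.empty(fail_cap, np.int64)

    if snapshot_every_s > 0:
        snap_every = max(1, int(round(snapshot_every_s * 1000.0 / dt)))
        snap_start = int(round(snapshot_start_s * 1000.0 / dt))
        n_snap = max(0, (n_bins - snap_start + snap_every - 1) // snap_every)
        snap_J = np.empty((n_snap, n_nodes, K))
        snap_W = np.empty((n_snap, n_links)) if snapshot_w else np.empty((1, 1))
    else:
        snap_every, snap_start = 0, 0
        snap_J = np.empty((0, n_nodes, K))
        snap_W = np.empty((1, 1))

    n_fire = np.zeros(n_links, np.int64)
    n_nofire = np.zeros(n_links, np.int64)
    node_spk = np.zeros(n_nodes, np.int64)
    term_spk = np.zeros((n_nodes, K), np.int64)

    J = np.array(network.j_init, dtype=np.float64).reshape(n_nodes, K).copy()
    V = np.zeros((n_nodes, K))

    rp_bins = int(round(lif.refractory_ms / dt))
    fc = -1.0 if lif.unbounded_fc else float(lif.f_c_hz)

    n_sp, n_st, n_ad, n_fl, n_snap_done, err = _kernel(
        n_bins, float(dt), n_nodes, K, n_links,
        float(lif.membrane_time_constant), fc, rp_bins,
        link_mode, two_level,
        1 if failure_reset_to_rest else 0, 1 if stims_on_failure else 0,
        int(refractory_mode), 1 if blind_stimulations else 0,
        1 if refractory_failure_stimulations else 0,
        float(amp_a), float(tau_adapt), cutoff_bins, float(noise_amp),
        J_MIN, J_MAX, 0.0, 1e9,
        link_tgt, link_term, link_w, link_tau_bins,
        ext_ptr, ext_link, out_ptr, out_link,
        ext_bins, ext_src, nstim_bins, nstim_node, NODE_STIM_AMP,
        J, V, int(seed) & 0x7FFFFFFF,
        count_start_bin, n_fire, n_nofire, node_spk, term_spk,
        snap_every, snap_start, snap_J, 1 if snapshot_w else 0, snap_W,
        1 if record_stimulations else 0,
        stim_bin, stim_node, stim_term, stim_link, stim_weff,
        1 if record_adaptation else 0,
        int(round(adaptation_start_s * 1000.0 / dt)),
        ad_bin, ad_node, ad_term, ad_link, ad_jb, ad_ja,
        spike_bin, spike_node, spike_term,
        1 if record_failures else 0, fail_bin, fail_node, fail_term,
        ring_cap, deliv_cap)
    if err != 0:
        raise RuntimeError(f"simulation aborted: {_ERRORS.get(err, err)}")

    stim_frame = None
    if record_stimulations:
        stim_frame = pd.DataFrame({
            "time_ms": stim_bin[:n_st] * dt,
            "node_id": stim_node[:n_st],
            "terminal_id": stim_term[:n_st],
            "link": stim_link[:n_st],
            "effective_weight": stim_weff[:n_st] * span,
        })
    adapt_frame = None
    if record_adaptation:
        adapt_frame = pd.DataFrame({
            "time_ms": ad_bin[:n_ad] * dt,
            "node_id": ad_node[:n_ad],
            "terminal_id": ad_term[:n_ad],
            "link": ad_link[:n_ad],
            "j_before": ad_jb[:n_ad],
            "j_after": ad_ja[:n_ad],
        })
        if link_mode == 1:
            adapt_frame[["j_before", "j_after"]] *= span
        adapt_frame["w_link"] = network.link_w[adapt_frame["link"].to_numpy()] \
            if link_mode == 0 else np.nan
    fail_frame = None
    if record_failures:
        fail_frame = pd.DataFrame({
            "time_ms": fail_bin[:n_fl] * dt,
            "node_id": fail_node[:n_fl],
            "terminal_id": fail_term[:n_fl],
        })

    snap_times = (snap_start + snap_every * np.arange(n_snap_done)) * dt \
        if snap_every > 0 else np.empty(0)

    return SimResult(
        dt_ms=dt,
        duration_ms=n_bins * dt,
        spike_time_ms=spike_bin[:n_sp] * dt,
        spike_node=spike_node[:n_sp].copy(),
        spike_terminal=spike_term[:n_sp].copy(),
        j_final=J,
        w_final=link_w * span,
        v_final=network.v_st + V * span,
        n_fire=n_fire,
        n_nofire=n_nofire,
        node_spike_counts=node_spk,
        terminal_spike_counts=term_spk,
        count_window_ms=count_window,
        n_stimulations=n_st,
        n_failures=n_fl,
        snapshot_times_ms=snap_times,
        j_snapshots=snap_J[:n_snap_done] if snap_every > 0 else None,
        w_snapshots=snap_W[:n_snap_done] if (snap_every > 0 and snapshot_w) else None,
        stim_frame=stim_frame,
        adaptation_frame=adapt_frame,
        failure_frame=fail_frame,
    )
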