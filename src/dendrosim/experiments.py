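"""Experiment drivers: terminal-weight dynamics, oscillation fractions,
attractor censuses, and the standard simulation configurations.

The feedforward protocol stimulates all N input units simultaneously at a
common rate (5 Hz unless stated), with unbounded f_c (no response
failures) and noiseless adaptation.  Terminal weights are sampled
stroboscopically at the stimulation period, so a period-one orbit (the
same J value every stimulation cycle) reads as "fixed" while genuine
oscillations — fast (sub-second to a couple of seconds) or slow (up to
hundreds of seconds, with plateaus at the weight clamps) — show up as
variance in the strobed traces.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import comb

from .builders import Network, build_feedforward, make_stimulus
from .model_core import LifParams, SimResult, simulate
from .plasticity import AdaptationRule

__all__ = [
    "DynamicsClass",
    "AttractorSignature",
    "classify_dynamics",
    "oscillation_fraction",
    "fourier_product",
    "same_attractor",
    "count_attractors",
    "attractor_lower_bound",
    "run_feedforward_dynamics",
    "run_single_node_random_input",
    "run_recurrent",
]

# classification thresholds (not dictated by the model; exposed for config)
CV_FIXED = 1e-3           # coefficient of variation below which J is "fixed"
FAST_SLOW_BOUNDARY_S = 2.0
SLOW_RANGE_FRACTION = 0.5


@dataclass
class DynamicsClass:
    """Outcome of classifying a set of terminal-weight traces."""

    label: str                      # fixed | fast_oscillation | slow_oscillation
    dominant_period_s: float | None
    cv_per_terminal: np.ndarray
    relative_range: float
    indeterminate: bool = False

    @property
    def oscillating(self) -> bool:
        return self.label != "fixed"


def fourier_product(traces: np.ndarray, sample_dt_s: float):
    """Element-wise product of the magnitude spectra of the K traces.

    Traces are mean-removed per terminal; returns ``(freqs_hz, product)``
    with the zero-frequency bin dropped.
    """
    traces = np.asarray(traces, dtype=float)
    if traces.ndim != 2:
        raise ValueError("expected an (n_samples, K) trace array")
    x = traces - traces.mean(axis=0, keepdims=True)
    spec = np.abs(np.fft.rfft(x, axis=0))
    freqs = np.fft.rfftfreq(x.shape[0], d=sample_dt_s)
    prod = np.prod(spec, axis=1)
    return freqs[1:], prod[1:]


def classify_dynamics(j_traces: np.ndarray, sample_dt_s: float,
                      cv_fixed: float = CV_FIXED,
                      fast_slow_boundary_s: float = FAST_SLOW_BOUNDARY_S,
                      slow_range_fraction: float = SLOW_RANGE_FRACTION) -> DynamicsClass:
    """Label post-transient terminal-weight traces as fixed / fast / slow.

    Fixed: every terminal's coefficient of variation over the window is
    below ``cv_fixed``.  Otherwise the dominant period of the spectral
    product of the varying traces decides the class: slow oscillations are
    long-period (>= boundary) AND large-amplitude (relative range above
    ``slow_range_fraction`` of the global maximum — the
    plateaus-at-the-clamps phenotype); everything else is fast.  A dominant
    period longer than a quarter of the window is flagged indeterminate:
    within a finite window an unfinished approach to a fixed point and a
    very long oscillation period are operationally indistinguishable, and
    the flag marks labels the window cannot bound.
    """
    traces = np.asarray(j_traces, dtype=float)
    if traces.ndim == 1:
        traces = traces[:, None]
    n = traces.shape[0]
    cv = traces.std(axis=0) / np.maximum(np.abs(traces.mean(axis=0)), 1e-300)
    span = traces.max(axis=0) - traces.min(axis=0)
    varying = cv >= cv_fixed
    tmax = max(traces.max(), 1e-300)  # amplitudes relative to the global max
    if not np.any(varying):
        return DynamicsClass("fixed", None, cv, float(np.max(span / tmax)))
    rel_range = float(np.max(span[varying] / tmax))
    freqs, prod = fourier_product(traces[:, varying], sample_dt_s)
    period = 1.0 / freqs[int(np.argmax(prod))]
    indet = period > n * sample_dt_s / 4.0
    if period >= fast_slow_boundary_s and rel_range > slow_range_fraction:
        label = "slow_oscillation"
    else:
        label = "fast_oscillation"
    return DynamicsClass(label, float(period), cv, rel_range, indeterminate=indet)


# ---------------------------------------------------------------------------
# standard run configurations
# ---------------------------------------------------------------------------


def run_feedforward_dynamics(n_inputs: int = 15, k_terminals: int = 3,
                             rate_hz: float = 5.0, duration_s: float = 400.0,
                             classify_window_s: float = 300.0,
                             rule: AdaptationRule | None = None,
                             seed: int = 0, network: Network | None = None,
                             **sim_kwargs):
    """One feedforward run under simultaneous periodic stimulation.

    Returns ``(result, traces, classification)`` where ``traces`` are the
    strobed terminal weights of the classification window.
    """
    if rule is None:
        rule = AdaptationRule(amplitude=0.05, noise_amplitude=0.0)
    if network is None:
        network = build_feedforward(n_inputs=n_inputs, k_terminals=k_terminals,
                                    seed=seed)
    stim = make_stimulus("periodic_simultaneous", duration_s,
                         n_inputs=network.n_inputs, rate_hz=rate_hz)
    lif = LifParams(dt_ms=1.0, refractory_ms=2.0, f_c_hz=math.inf)
    period_s = 1.0 / rate_hz
    res = simulate(network, stim, lif, rule, duration_s=duration_s, seed=seed,
                   snapshot_every_s=period_s, **sim_kwargs)
    n_window = int(round(classify_window_s / period_s))
    traces = res.j_snapshots[-n_window:, 0, :]
    cls = classify_dynamics(traces, period_s)
    return res, traces, cls


def oscillation_fraction(k_terminals: int = 3, n_per_terminal: int = 3,
                         n_samples: int = 500, seed: int = 0,
                         rate_hz: float = 5.0, duration_s: float = 1000.0,
                         classify_window_s: float = 600.0) -> dict:
    """Fraction of random (W, tau) feedforward configurations per dynamics class.

    Each sample draws fresh uniform weights [0.1, 1.1] and delays [1, 150] ms,
    runs the 5 Hz simultaneous protocol without adaptation noise and with
    unbounded f_c, and classifies the strobed terminal-weight traces.
    Fractions come with binomial standard errors.

    The horizon matters: convergence to a fixed point can take hundreds of
    seconds, and a too-short run misreads the tail of that transient as a
    slow oscillation.  The 1000 s default with a 600 s classification
    window is past the point where the fractions stop drifting.
    """
    if n_samples < 1:
        raise ValueError("need at least one sample")
    n_inputs = k_terminals * n_per_terminal
    ss = np.random.SeedSequence(seed)
    labels = []
    for child in ss.spawn(n_samples):
        kseed = int(child.generate_state(1)[0] & 0x7FFFFFFF)
        net = build_feedforward(n_inputs=n_inputs, k_terminals=k_terminals,
                                seed=np.random.default_rng(child))
        _, _, cls = run_feedforward_dynamics(
            rate_hz=rate_hz, duration_s=duration_s,
            classify_window_s=classify_window_s, network=net, seed=kseed)
        labels.append(cls.label)
    labels = pd.Series(labels)
    out = {"n_samples": n_samples, "labels": labels}
    for name in ("fixed", "fast_oscillation", "slow_oscillation"):
        out[name] = float((labels == name).mean())
    p = 1.0 - out["fixed"]
    out["oscillating"] = p
    out["oscillating_se"] = float(np.sqrt(p * (1 - p) / n_samples))
    return out


def run_single_node_random_input(seed: int = 0, duration_s: float = 800.0,
                                 transient_s: float = 200.0,
                                 k_terminals: int = 2, n_inputs: int = 120,
                                 rate_hz: float = 30.0, amplitude: float = 0.1,
                                 refractory_ms: float = 2.0, f_c_hz: float = 15.0,
                                 dt_ms: float = 0.1,
                                 snapshot_every_s: float = 0.05,
                                 record_adaptation: bool = True,
                                 adaptation_capacity: int = 8_000_000):
    """The random-input single-node configuration.

    One node with K=2 terminals, 60 links per terminal (weights uniform on
    [0.1, 0.2], zero delay — inputs are Poisson so a delay is a pure time
    shift), every input stimulated at K*f_c = 30 Hz on average, adaptation
    amplitude 0.1 and additive noise on.  This is the configuration whose
    stationary state exhibits the log-normal effective-weight distribution,
    the restoring force, and the strong-before-weak spike ordering.

    Returns ``(result, network)``; adaptation events are logged from
    ``transient_s`` onward.
    """
    ss = np.random.SeedSequence(seed)
    c_net, c_stim, c_run = ss.spawn(3)
    net = build_feedforward(n_inputs=n_inputs, k_terminals=k_terminals,
                            weight_range=(0.1, 0.2), delay_range_ms=(0.0, 0.0),
                            seed=np.random.default_rng(c_net))
    stim = make_stimulus("poisson_per_input", duration_s, n_inputs=n_inputs,
                         rate_hz=rate_hz, seed=np.random.default_rng(c_stim))
    lif = LifParams(dt_ms=dt_ms, refractory_ms=refractory_ms, f_c_hz=f_c_hz)
    rule = AdaptationRule(amplitude=amplitude)
    res = simulate(net, stim, lif, rule, duration_s=duration_s,
                   seed=int(c_run.generate_state(1)[0] & 0x7FFFFFFF),
                   snapshot_every_s=snapshot_every_s,
                   record_adaptation=record_adaptation,
                   adaptation_start_s=transient_s,
                   adaptation_capacity=adaptation_capacity)
    return res, net


def run_recurrent(network: Network, seed: int = 0, duration_s: float = 20.0,
                  rate_window_s: tuple = (10.0, 20.0),
                  amplitude: float = 0.05, refractory_ms: float = 2.0,
                  f_c_hz: float = 15.0, dt_ms: float = 0.1,
                  trigger_fraction: float = 0.4,
                  background_rate_hz: float = 0.01,
                  snapshot_every_s: float = 0.1,
                  snapshot_start_s: float | None = None,
                  rule: AdaptationRule | None = None) -> SimResult:
    """Drive a recurrent network from an initial 40% above-threshold trigger
    with 0.01 Hz per-node background, counting spikes over ``rate_window_s``."""
    ss = np.random.SeedSequence(seed)
    c_stim, c_run = ss.spawn(2)
    stim = make_stimulus("initial_trigger_plus_background", duration_s,
                         n_nodes=network.n_nodes,
                         trigger_fraction=trigger_fraction,
                         background_rate_hz=background_rate_hz,
                         seed=np.random.default_rng(c_stim))
    lif = LifParams(dt_ms=dt_ms, refractory_ms=refractory_ms, f_c_hz=f_c_hz)
    if rule is None:
        rule = AdaptationRule(amplitude=amplitude)
    if snapshot_start_s is None:
        snapshot_start_s = max(0.0, duration_s - 2.0)
    return simulate(network, stim, lif, rule, duration_s=duration_s,
                    seed=int(c_run.generate_state(1)[0] & 0x7FFFFFFF),
                    count_window_s=(rate_window_s[0], rate_window_s[1]),
                    snapshot_every_s=snapshot_every_s,
                    snapshot_start_s=snapshot_start_s,
                    snapshot_w=(network.mode == "adaptive_link"))


# ---------------------------------------------------------------------------
# attractor census
# ---------------------------------------------------------------------------


@dataclass
class AttractorSignature:
    """Per-link firing pattern over a fixed observation window."""

    n_fire: np.ndarray     # pulses coinciding with a spike of their terminal
    n_nofire: np.ndarray   # pulses that did not evoke a spike

    def __post_init__(self) -> None:
        self.n_fire = np.asarray(self.n_fire, np.int64)
        self.n_nofire = np.asarray(self.n_nofire, np.int64)
        if np.any(self.n_fire < 0) or np.any(self.n_nofire < 0):
            raise ValueError("event counts must be non-negative")


def same_attractor(sig_a: AttractorSignature, sig_b: AttractorSignature,
                   rel_tol: float = 0.02, low_rate_floor: int = 10) -> bool:
    """Two runs share an attractor when every link's firing count differs by
    less than ``rel_tol`` (relative to the larger count); links with fewer
    than ``low_rate_floor`` firing events in both runs are compared on their
    non-firing counts instead."""
    fa, fb = sig_a.n_fire, sig_b.n_fire
    if fa.shape != fb.shape:
        raise ValueError("signatures cover different link sets")
    low = np.maximum(fa, fb) < low_rate_floor
    a = np.where(low, sig_a.n_nofire, fa).astype(float)
    b = np.where(low, sig_b.n_nofire, fb).astype(float)
    denom = np.maximum(np.maximum(a, b), 1.0)
    return bool(np.all(np.abs(a - b) < rel_tol * denom))


def count_attractors(k_terminals: int = 3, n_per_terminal: int = 3,
                     n_initial_conditions: int = 200, n_delay_sets: int = 10,
                     seed: int = 0, duration_s: float = 300.0,
                     window_s: float = 100.0, rate_hz: float = 5.0,
                     checkpoints: list | None = None) -> pd.DataFrame:
    """Census of stationary firing patterns in the small feedforward net.

    For each of ``n_delay_sets`` fixed delay draws, ``n_initial_conditions``
    random weight draws are simulated and greedily clustered by
    :func:`same_attractor` against the first-seen representative of each
    cluster.  Returns a tidy frame (delay_set, n_ic, n_clusters) evaluated
    at nested checkpoints, from which the saturation curve of the census
    (mean +/- std across delay sets) can be read.
    """
    n_inputs = k_terminals * n_per_terminal
    if checkpoints is None:
        checkpoints = sorted({int(x) for x in np.geomspace(
            1, n_initial_conditions, 12).round()})
    checkpoints = [c for c in checkpoints if c <= n_initial_conditions]
    ss = np.random.SeedSequence(seed)
    rows = []
    rule = AdaptationRule(amplitude=0.05, noise_amplitude=0.0)
    lif = LifParams(dt_ms=1.0, refractory_ms=2.0, f_c_hz=math.inf)
    for ds, child in enumerate(ss.spawn(n_delay_sets)):
        rng = np.random.default_rng(child)
        tau = rng.uniform(1.0, 150.0, size=n_inputs)
        reps: list[AttractorSignature] = []
        counts = []
        for ic in range(n_initial_conditions):
            w = rng.uniform(0.1, 1.1, size=n_inputs)
            net = _feedforward_fixed(w, tau, k_terminals)
            stim = make_stimulus("periodic_simultaneous", duration_s,
                                 n_inputs=n_inputs, rate_hz=rate_hz)
            res = simulate(net, stim, lif, rule, duration_s=duration_s,
                           seed=0, count_window_s=(duration_s - window_s,
                                                   duration_s))
            sig = AttractorSignature(res.n_fire, res.n_nofire)
            for rep in reps:
                if same_attractor(sig, rep):
                    break
            else:
                reps.append(sig)
            counts.append(len(reps))
        for c in checkpoints:
            rows.append({"delay_set": ds, "n_ic": c, "n_clusters": counts[c - 1]})
    return pd.DataFrame(rows)


def _feedforward_fixed(weights: np.ndarray, delays_ms: np.ndarray,
                       k_terminals: int) -> Network:
    """Feedforward net from explicit weights/delays (delay-sorted assignment,
    maximal-delay link re-assigned to terminal 0)."""
    n = len(weights)
    order = np.argsort(delays_ms, kind="stable")
    w = np.asarray(weights, float)[order]
    tau = np.asarray(delays_ms, float)[order]
    per = n // k_terminals
    term = np.repeat(np.arange(k_terminals), per)
    term[-1] = 0
    return Network(
        n_nodes=1, k_terminals=k_terminals, n_inputs=n,
        link_src=np.arange(n, dtype=np.int64),
        link_src_is_input=np.ones(n, bool),
        link_tgt=np.zeros(n, np.int64), link_term=term.astype(np.int64),
        link_w=w, link_tau_ms=tau,
        meta={"topology": "feedforward"},
    )


def attractor_lower_bound(a_n0: float, n_inputs: int, k_terminals: int,
                          n0: int) -> float:
    """Lower bound A(N0) * C(N/K, N0)^K on the attractor count of the full net.

    Each terminal independently selects N0 effective inputs among its N/K,
    and each selection inherits the A(N0) attractors of the reduced problem.
    """
    if n_inputs % k_terminals != 0:
        raise ValueError("N must be divisible by K")
    per = n_inputs // k_terminals
    if not (0 < n0 <= per):
        raise ValueError("need 0 < N0 <= N/K")
    return float(a_n0) * float(comb(per, n0, exact=True)) ** k_terminals
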