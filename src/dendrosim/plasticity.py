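"""Pair-based adaptation of terminal weights.

Every pair of a sub-threshold stimulation arriving via terminal i and a
spike evoked by a *different* terminal of the same node triggers one
adaptation step of the stimulated terminal's weight:

    J_i+ = J_i * (1 + delta) + eta,      delta = A * exp(-|D|/15) * sign(D)

with D = t_sub - t_spike in ms, a hard cutoff at |D| = 50 ms, additive
noise eta ~ U[-0.5, 0.5]*1e-3 (optional), and J clamped to [1e-6, 10].
A stimulation arriving after a spike therefore potentiates its terminal,
one arriving before a spike depresses it.  The simplified two-level
variant replaces the exponential by a step of height +/-A.

The classical adaptive-link baseline applies the same rule to individual
link weights W_m (J fixed at 1), pairing each link's own sub-threshold
arrival times with the node's spikes; W is clamped below at 0.

Adaptation steps are applied online inside the simulation kernel.
:func:`collect_adaptation_pairs` re-derives the same pairing offline from
event logs and serves as the independent oracle in the test-suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "AdaptationRule",
    "AdaptationEvent",
    "delta_profile",
    "apply_adaptation",
    "adaptive_link_update",
    "collect_adaptation_pairs",
]


@dataclass
class AdaptationRule:
    """Parameters of the pair-based adaptation step.

    amplitude
        A, peak relative change per pair (0.05 default; 0.1 for the
        random-input single-node experiment).
    decay_ms
        time constant of the exponential profile (15 ms).
    cutoff_ms
        no adaptation for |t_sub - t_spike| beyond this (50 ms).
    profile_kind
        "exponential" or "two_level" (step of height +/-A).
    noise_amplitude
        full width of the additive uniform noise; eta is drawn from
        [-noise_amplitude/2, +noise_amplitude/2] per adaptation event.
        The default 1e-3 matches eta ~ [-0.5, 0.5]*1e-3; set 0 to disable.
    j_bounds
        hard clamp for terminal weights.
    """

    amplitude: float = 0.05
    decay_ms: float = 15.0
    cutoff_ms: float = 50.0
    profile_kind: str = "exponential"
    noise_amplitude: float = 1e-3
    j_bounds: tuple = (1e-6, 10.0)

    def __post_init__(self) -> None:
        if self.profile_kind not in ("exponential", "two_level"):
            raise ValueError(f"unknown profile kind {self.profile_kind!r}")
        if self.amplitude < 0 or self.decay_ms <= 0 or self.cutoff_ms < 0:
            raise ValueError("invalid adaptation parameters")


@dataclass
class AdaptationEvent:
    """One pairing of a sub-threshold stimulation with a spike."""

    time_ms: float
    node_id: int
    terminal_id: int
    link: int
    delta_ms: float  # t_sub - t_spike
    delta_rel: float  # relative change applied


def delta_profile(delta_ms, rule: AdaptationRule):
    """Signed relative change for time-lag ``delta_ms`` = t_sub - t_spike.

    Odd in its argument, bounded by the amplitude, and zero beyond the
    cutoff.  Accepts scalars or arrays.
    """
    d = np.asarray(delta_ms, dtype=float)
    if rule.profile_kind == "two_level":
        mag = rule.amplitude * np.ones_like(d)
    else:
        mag = rule.amplitude * np.exp(-np.abs(d) / rule.decay_ms)
    out = np.where(np.abs(d) <= rule.cutoff_ms, mag * np.sign(d), 0.0)
    if np.isscalar(delta_ms):
        return float(out)
    return out


def apply_adaptation(j: float, delta: float, rule: AdaptationRule,
                     rng: np.random.Generator | None = None) -> float:
    """One multiplicative-plus-noise update of a terminal weight, clamped."""
    eta = 0.0
    if rng is not None and rule.noise_amplitude > 0:
        eta = (rng.random() - 0.5) * rule.noise_amplitude
    lo, hi = rule.j_bounds
    return float(np.clip(j * (1.0 + delta) + eta, lo, hi))


def adaptive_link_update(w: float, delta: float, eta: float = 0.0) -> float:
    """Adaptive-link baseline step: W+ = W*(1+delta)+eta, clamped below at 0."""
    return max(0.0, w * (1.0 + delta) + eta)


def collect_adaptation_pairs(stims: pd.DataFrame, spikes: pd.DataFrame,
                             rule: AdaptationRule,
                             adaptive_link: bool = False) -> list[AdaptationEvent]:
    """Enumerate adaptation events implied by logged stimulations and spikes.

    ``stims`` needs columns ``time_ms, node_id, terminal_id, link``;
    ``spikes`` needs ``time_ms, node_id, terminal_id``.  For each
    sub-threshold stimulation on terminal i and spike from terminal j != i
    of the same node with |t_sub - t_spike| <= cutoff, one event is emitted
    for terminal i, stamped at the later of the two times (post-spike
    stimulations adapt at stimulation time, pre-spike ones at spike time).
    Exactly-coincident pairs carry sign(0) = 0 and are dropped.  In
    adaptive-link mode the different-terminal restriction is lifted and the
    event targets the stimulated link itself.

    Events are returned ordered as the online engine applies them
    (event time, then stimulation time within a spike's batch).
    """
    events: list[AdaptationEvent] = []
    for node, node_stims in stims.groupby("node_id", sort=True):
        node_spikes = spikes[spikes.node_id == node]
        st = node_stims.sort_values("time_ms", kind="stable")
        sp = node_spikes.sort_values("time_ms", kind="stable")
        for t_sub, term_i, link in zip(st.time_ms.to_numpy(),
                                       st.terminal_id.to_numpy(),
                                       st.link.to_numpy()):
            for t_spk, term_j in zip(sp.time_ms.to_numpy(),
                                     sp.terminal_id.to_numpy()):
                if not adaptive_link and term_i == term_j:
                    continue
                d = t_sub - t_spk
                if d == 0 or abs(d) > rule.cutoff_ms:
                    continue
                events.append(AdaptationEvent(
                    time_ms=max(t_sub, t_spk),
                    node_id=int(node),
                    terminal_id=int(term_i),
                    link=int(link),
                    delta_ms=float(d),
                    delta_rel=float(delta_profile(d, rule)),
                ))
    # online application order: by event time; within a spike-side batch the
    # engine walks stimulation buffers oldest-first, which the secondary key
    # (stimulation time = event time - |delta|) reproduces
    events.sort(key=lambda e: (e.time_ms, e.time_ms - abs(e.delta_ms)))
    return events
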