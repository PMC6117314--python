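"""Event-driven closed-form reference for a single adaptive node.

Independent re-implementation of the deterministic simulation semantics
(unbounded f_c, no adaptation noise) used as an oracle against the compiled
engine: exact exponential decay between pulse bins, per-bin delivery then
threshold resolution (highest voltage first, ties to the lowest terminal),
node-wide refractoriness with a blind evoking terminal, post-refractory
re-check, and online pair-based adaptation with the 50 ms cutoff.
"""

import math
from collections import defaultdict


def run_reference(pulses, n_bins, k_terminals, dt_ms=1.0, tau_mem=20.0,
                  rp_bins=2, amp_a=0.0, tau_adapt=15.0, cutoff_bins=50,
                  two_level=False, j_min=1e-6, j_max=10.0):
    """Simulate one node fed by ``pulses`` = [(bin, terminal, weight), ...].

    Returns ``(spikes, stims, V, J)`` where spikes is a list of
    (bin, terminal), stims a list of (bin, terminal, weight) sub-threshold
    stimulations (blind-window arrivals included), and V/J the final state.
    """
    by_bin = defaultdict(list)
    for b, k, w in pulses:
        by_bin[int(b)].append((int(k), float(w)))
    decay = math.exp(-dt_ms / tau_mem)
    K = k_terminals
    V = [0.0] * K
    J = [1.0] * K
    refrac_end = 0
    blind = -1
    spikes = []
    stims = []
    recent_stims = []   # (bin, terminal, weight)
    recent_spikes = []  # (bin, terminal)

    def adapt(term, delta_bins):
        # delta_bins = t_sub - t_spike in bins; sign carries through
        if delta_bins == 0 or abs(delta_bins) > cutoff_bins:
            return
        mag = amp_a if two_level else \
            amp_a * math.exp(-abs(delta_bins) * dt_ms / tau_adapt)
        d = mag if delta_bins > 0 else -mag
        J[term] = min(j_max, max(j_min, J[term] * (1.0 + d)))

    for b in range(n_bins):
        for k in range(K):
            V[k] *= decay
        delivered = []
        for k, w in by_bin.get(b, []):
            if b < refrac_end and k == blind:
                delivered.append((k, w, True))  # no voltage response
                continue
            V[k] += J[k] * w
            delivered.append((k, w, False))
        spiked_this_bin = set()
        if b >= refrac_end:
            attempted = set()
            while True:
                cands = [(V[k], -k) for k in range(K)
                         if k not in attempted and V[k] >= 1.0]
                if not cands:
                    break
                best = -max(cands)[1]
                attempted.add(best)
                # unbounded f_c: every crossing spikes
                V[best] = 0.0
                spikes.append((b, best))
                spiked_this_bin.add(best)
                # depression: this spike against earlier stims of other terminals
                for (tb, ti, _w) in recent_stims:
                    if ti != best and 0 < b - tb <= cutoff_bins:
                        adapt(ti, tb - b)
                recent_spikes.append((b, best))
                if rp_bins > 0:
                    refrac_end = b + rp_bins
                    blind = best
                    break
        for k, w, was_blind in delivered:
            if k in spiked_this_bin:
                continue
            stims.append((b, k, w))
            for (tb, tj) in recent_spikes:
                if tj != k and 0 < b - tb <= cutoff_bins:
                    adapt(k, b - tb)
            recent_stims.append((b, k, w))
        recent_stims = [s for s in recent_stims if b - s[0] <= cutoff_bins]
        recent_spikes = [s for s in recent_spikes if b - s[0] <= cutoff_bins]
    return spikes, stims, V, J


def voltage_closed_form(pulse_bins, weights, query_bin, dt_ms=1.0,
                        tau_mem=20.0):
    """Voltage of a passive terminal (no threshold) at the end of
    ``query_bin``: sum of pulse jumps decayed exactly from their bins."""
    v = 0.0
    for b, w in zip(pulse_bins, weights):
        if b <= query_bin:
            v += w * math.exp(-(query_bin - b) * dt_ms / tau_mem)
    return v
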