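"""Effective-weight statistics and the spike-ordering analysis.

The quantity of interest is the *effective link weight* W_m * J_i: the
static link weight times the adaptive multiplier of the terminal it feeds.
Under adaptive-node dynamics its population distribution relaxes to a
stationary log-normal while individual effective weights keep moving; the
stabilizing mechanism is a stochastic restoring force carried by a
spontaneous temporal ordering of spike pairs (a spike from a strong
terminal tends to precede one from a weak terminal within a few ms).

Goodness-of-fit note: effective-weight samples pooled over time are
strongly autocorrelated (J moves slowly relative to the sampling
interval), so Kolmogorov-Smirnov p-values here are computed with the
number of *links* as the effective sample size rather than the pooled
count; the pooled count would grossly overstate significance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .builders import Network

__all__ = [
    "EffectiveWeightSample",
    "PairOrderingStats",
    "ForceCurve",
    "effective_weights",
    "effective_weight_distribution",
    "max_min_ratio",
    "classify_strong_weak",
    "spike_pair_ordering",
    "restoring_force",
    "refractory_sweep",
]


def effective_weights(network: Network, j: np.ndarray | None = None) -> np.ndarray:
    """Per-link effective weights W_m * J_i.

    ``j`` is an (n_nodes, K) terminal-weight array (defaults to the
    network's initial weights); in adaptive-link mode J is identically 1
    and the link weights themselves are returned.
    """
    if network.n_links == 0:
        raise ValueError("network has no links")
    if network.mode == "adaptive_link":
        return network.link_w.copy()
    if j is None:
        j = network.j_init
    return network.link_w * j[network.link_tgt, network.link_term]


@dataclass
class EffectiveWeightSample:
    """Log-scale summary of a set of effective weights."""

    values: np.ndarray
    hist_counts: np.ndarray
    hist_edges_log10: np.ndarray
    log_mean: float        # mean of ln(W*J)
    log_std: float         # std of ln(W*J)
    ks_stat: float
    ks_pvalue: float
    n_effective: int


def effective_weight_distribution(values: np.ndarray, n_bins: int = 100,
                                  n_effective: int | None = None) -> EffectiveWeightSample:
    """Histogram (100 log-spaced bins) and log-normal fit of effective weights.

    Fits a normal to ln(values) by maximum likelihood and reports the KS
    statistic of the log-values against the fit; the p-value uses
    ``n_effective`` (see the module note) or the sample count.
    """
    values = np.asarray(values, float).ravel()
    if len(values) == 0:
        raise ValueError("no effective weights supplied")
    if np.any(values <= 0):
        raise ValueError("effective weights must be positive in adaptive-node mode")
    logs = np.log(values)
    mu = float(logs.mean())
    sigma = float(logs.std())
    lo, hi = np.log10(values.min()), np.log10(values.max())
    if hi - lo < 1e-12:
        hi = lo + 1e-12
    counts, edges = np.histogram(np.log10(values), bins=n_bins, range=(lo, hi))
    if sigma == 0:
        d, p = 1.0, 0.0
    else:
        d = float(sps.kstest(logs, sps.norm(mu, sigma).cdf).statistic)
        n_eff = int(n_effective) if n_effective else len(values)
        p = float(sps.kstwo.sf(np.clip(d, 0, 1), n_eff))
    return EffectiveWeightSample(values, counts, edges, mu, sigma, d, p,
                                 n_effective=int(n_effective or len(values)))


def max_min_ratio(weight_traces: np.ndarray, cap: float | None = None,
                  vanish_floor: float = 1e-9) -> np.ndarray:
    """Per-link max/min of the effective weight over an observation window.

    ``weight_traces`` has shape (n_samples, n_links).  In adaptive-link
    mode weights may vanish, so the ratio is computed with a floor on the
    minimum and capped (the histogram cap is 60 in that mode); in
    adaptive-node mode pass ``cap=None`` and the traces must be positive.
    """
    w = np.asarray(weight_traces, float)
    if w.ndim != 2 or w.shape[0] < 1:
        raise ValueError("expected an (n_samples, n_links) trace array")
    if cap is None and np.any(w <= 0):
        raise ValueError("non-positive weights outside adaptive-link mode")
    ratio = w.max(axis=0) / np.maximum(w.min(axis=0), vanish_floor)
    if cap is not None:
        ratio = np.minimum(ratio, cap)
    return ratio


def classify_strong_weak(values: np.ndarray):
    """Percentile bands of weak and strong effective weights.

    Weak weights live in the [1%, 25%] percentile band and strong ones in
    [75%, 99%]: half of the distribution sits between the maximum of the
    weak and the minimum of the strong, and 1% is trimmed at each extreme,
    so each class holds 24% of the weights.

    Returns ``(weak_mask, strong_mask, thresholds)`` with thresholds
    ``(q01, q25, q75, q99)``.
    """
    values = np.asarray(values, float).ravel()
    if len(values) < 100:
        raise ValueError("need at least 100 values for stable percentiles")
    q01, q25, q75, q99 = np.percentile(values, [1, 25, 75, 99])
    weak = (values >= q01) & (values <= q25)
    strong = (values >= q75) & (values <= q99)
    return weak, strong, (q01, q25, q75, q99)


@dataclass
class PairOrderingStats:
    """Ordering statistics of strong/weak spike pairs within a short window."""

    window_ms: float
    n_pairs: int           # all distinct-terminal pairs within the window
    n_sw: int              # strong spike then weak spike
    n_ws: int              # weak spike then strong spike
    p_sw: float
    p_ws: float
    thresholds: tuple

    @property
    def ratio(self) -> float:
        if self.n_ws == 0:
            return np.inf if self.n_sw else np.nan
        return self.n_sw / self.n_ws

    @property
    def z_score(self) -> float:
        """Binomial z of the SW excess under the symmetric null."""
        n = self.n_sw + self.n_ws
        if n == 0:
            return np.nan
        return (self.n_sw - self.n_ws) / np.sqrt(n)


def spike_pair_ordering(spike_times_ms: np.ndarray, spike_terminals: np.ndarray,
                        terminal_weff_times_ms: np.ndarray,
                        terminal_weff: np.ndarray,
                        thresholds: tuple, window_ms: float = 5.0,
                        shuffle_rng: np.random.Generator | None = None) -> PairOrderingStats:
    """Probabilities of strong-then-weak versus weak-then-strong spike pairs.

    Scans consecutive spikes of one node; a pair qualifies when the two
    spikes come from distinct terminals within ``window_ms``.  A terminal
    is strong/weak at pair time when its current mean effective weight
    (interpolated from ``terminal_weff`` sampled at
    ``terminal_weff_times_ms``) falls in the strong/weak percentile band of
    ``thresholds`` = (q01, q25, q75, q99); pairs without one strong and one
    weak terminal are left unclassified but still count toward the pair
    total.  Passing ``shuffle_rng`` randomizes the within-pair order — the
    label-shuffled null under which P_SW and P_WS must agree.
    """
    t = np.asarray(spike_times_ms, float)
    term = np.asarray(spike_terminals)
    if len(t) < 2:
        raise ValueError("need at least two spikes to form pairs")
    order = np.argsort(t, kind="stable")
    t, term = t[order], term[order]
    gap_ok = np.diff(t) <= window_ms
    distinct = term[1:] != term[:-1]
    sel = np.where(gap_ok & distinct)[0]
    q01, q25, q75, q99 = thresholds
    idx = np.searchsorted(terminal_weff_times_ms, t[sel], side="right") - 1
    idx = np.clip(idx, 0, len(terminal_weff_times_ms) - 1)
    n_sw = n_ws = 0
    for i, snap in zip(sel, idx):
        a, b = term[i], term[i + 1]
        if shuffle_rng is not None and shuffle_rng.random() < 0.5:
            a, b = b, a
        wa, wb = terminal_weff[snap, a], terminal_weff[snap, b]

        def band(w):
            if q01 <= w <= q25:
                return "weak"
            if q75 <= w <= q99:
                return "strong"
            return None

        ba, bb = band(wa), band(wb)
        if ba == "strong" and bb == "weak":
            n_sw += 1
        elif ba == "weak" and bb == "strong":
            n_ws += 1
    n_pairs = len(sel)
    if n_pairs == 0:
        raise ValueError("no qualifying spike pairs in the log")
    return PairOrderingStats(window_ms, n_pairs, n_sw, n_ws,
                             n_sw / n_pairs, n_ws / n_pairs,
                             tuple(thresholds))


@dataclass
class ForceCurve:
    """Mean relative adaptation step as a function of W*J, binned."""

    table: pd.DataFrame  # columns: bin_center, force, force_std, n, mean_weff

    def sign_change_weff(self, min_events: int = 100) -> float | None:
        """Effective weight where the force first switches positive->negative."""
        t = self.table[self.table.n >= min_events]
        f = t.force.to_numpy()
        for i in range(len(f) - 1):
            if f[i] > 0 >= f[i + 1]:
                return float(0.5 * (t.bin_center.iloc[i] + t.bin_center.iloc[i + 1]))
        return None


def restoring_force(adaptation_log: pd.DataFrame, bin_width: float = 0.05) -> ForceCurve:
    """Mean relative change in J versus the effective weight at the event.

    ``adaptation_log`` needs columns ``j_before, j_after, w_link``; events
    are binned by W*J (bin width 0.05) and each bin reports
    mean(J+ - J) / <W*J> with the per-bin standard deviation of the raw
    steps.  Empty bins are absent from the table.
    """
    log = adaptation_log
    weff = (log.w_link * log.j_before).to_numpy()
    dj = (log.j_after - log.j_before).to_numpy()
    bins = np.floor(weff / bin_width).astype(np.int64)
    frame = pd.DataFrame({"bin": bins, "weff": weff, "dj": dj})
    grouped = frame.groupby("bin", sort=True)
    agg = grouped.agg(n=("dj", "size"), dj_mean=("dj", "mean"),
                      dj_std=("dj", "std"), mean_weff=("weff", "mean"))
    agg = agg.reset_index()
    agg["bin_center"] = (agg["bin"] + 0.5) * bin_width
    agg["force"] = agg.dj_mean / agg.mean_weff
    agg["force_std"] = agg.dj_std / agg.mean_weff
    return ForceCurve(agg[["bin_center", "force", "force_std", "n", "mean_weff"]])


def refractory_sweep(rp_values_ms, seed: int = 0, duration_s: float = 300.0,
                     transient_s: float = 100.0, dt_ms: float = 0.1,
                     window_ms: float = 5.0, **run_kwargs) -> pd.DataFrame:
    """P_SW/P_WS and distribution stability versus the refractory period.

    Runs the random-input single-node configuration once per refractory
    period and reports the ordering ratio plus collapse diagnostics (median
    effective weight and the fraction of links above threshold at the end;
    the log-normal regime collapses — all effective weights driven above
    threshold — below a critical refractory period).
    """
    from .experiments import run_single_node_random_input

    rows = []
    for rp in rp_values_ms:
        if rp > 0 and rp < dt_ms:
            raise ValueError("refractory period below the simulation step")
        res, net = run_single_node_random_input(
            seed=seed, duration_s=duration_s, transient_s=transient_s,
            refractory_ms=rp, dt_ms=dt_ms, **run_kwargs)
        weff_links = effective_weights(net, res.j_final)
        pooled = _pooled_weff(net, res, transient_s)
        dist = effective_weight_distribution(pooled, n_effective=net.n_links)
        row = {"refractory_ms": rp,
               "median_weff": float(np.median(weff_links)),
               "frac_above_threshold": float(np.mean(weff_links > 1.0)),
               "ks_stat": dist.ks_stat, "ks_pvalue": dist.ks_pvalue,
               "log_mean": dist.log_mean, "log_std": dist.log_std}
        try:
            w_mean = np.array([net.link_w[net.terminal_links(0, k)].mean()
                               for k in range(net.k_terminals)])
            tw = res.j_snapshots[:, 0, :] * w_mean[None, :]
            _, _, thr = classify_strong_weak(pooled)
            mask = res.spike_time_ms >= transient_s * 1000.0
            stats = spike_pair_ordering(
                res.spike_time_ms[mask], res.spike_terminal[mask],
                res.snapshot_times_ms, tw, thr, window_ms=window_ms)
            row.update(p_sw=stats.p_sw, p_ws=stats.p_ws, ratio=stats.ratio,
                       n_pairs=stats.n_pairs)
        except ValueError:
            row.update(p_sw=np.nan, p_ws=np.nan, ratio=np.nan, n_pairs=0)
        rows.append(row)
    return pd.DataFrame(rows)


def _pooled_weff(net: Network, res, transient_s: float) -> np.ndarray:
    """Effective weights pooled over post-transient snapshots."""
    keep = res.snapshot_times_ms >= transient_s * 1000.0
    j = res.j_snapshots[keep]  # (n_snap, n_nodes, K)
    return (net.link_w[None, :]
            * j[:, net.link_tgt, net.link_term]).ravel()
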