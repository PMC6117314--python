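"""Network and stimulus construction.

Three network classes are supported:

* ``feedforward`` — N input units wired by single links (uniform weights
  and delays) onto one output node with K terminals.  Links are sorted by
  increasing delay and assigned to terminals in consecutive blocks of N/K,
  except the maximal-delay link which is re-assigned to the first terminal
  ("closing a loop").
* ``two_pool`` — two pools of equal size; each node receives its in-links
  from partners sampled without replacement from the opposite pool.
* ``random_recurrent`` — every node draws its presynaptic partners
  uniformly from all other nodes (no self-loops).

Recurrent weights are uniform on [0.1, 0.2] and delays normal with mean
100 ms and 2 ms standard deviation (truncated at 0.1 ms); a node's in-links
are partitioned over its K terminals in delay-sorted consecutive blocks.
``mode="adaptive_link"`` builds the classical baseline: a single terminal
per node with J fixed at 1 and plasticity acting on the link weights.

All randomness flows from one seeded generator per build; identical
spec + seed reproduces the network and stimulus exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Network",
    "NetworkSpec",
    "Stimulus",
    "StimulusSpec",
    "build_feedforward",
    "build_two_pool",
    "build_random_recurrent",
    "build_network",
    "make_stimulus",
]


@dataclass
class Network:
    """Flat link-list representation of a network of adaptive nodes."""

    n_nodes: int
    k_terminals: int
    n_inputs: int              # number of external input units
    link_src: np.ndarray       # source index (input unit or node)
    link_src_is_input: np.ndarray
    link_tgt: np.ndarray       # target node
    link_term: np.ndarray      # target terminal on that node
    link_w: np.ndarray
    link_tau_ms: np.ndarray
    mode: str = "adaptive_node"
    v_st: float = 0.0
    v_th: float = 1.0
    j_init: np.ndarray = field(default=None)  # (n_nodes, K)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.j_init is None:
            self.j_init = np.ones((self.n_nodes, self.k_terminals))
        if self.v_th <= self.v_st:
            raise ValueError("threshold must exceed resting potential")

    @property
    def n_links(self) -> int:
        return len(self.link_w)

    def terminal_links(self, node: int, terminal: int) -> np.ndarray:
        """Indices of the links feeding one terminal."""
        return np.where((self.link_tgt == node) & (self.link_term == terminal))[0]

    def edge_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "source": self.link_src,
            "source_is_input": self.link_src_is_input,
            "target_node": self.link_tgt,
            "terminal": self.link_term,
            "W": self.link_w,
            "tau_ms": self.link_tau_ms,
        })

    def to_csv(self, path) -> None:
        self.edge_frame().to_csv(path, index=False)


@dataclass
class NetworkSpec:
    """Declarative network description (see the builder functions)."""

    topology: str = "feedforward"
    n_nodes: int = 1
    k_terminals: int = 3
    n_inputs_per_node: int = 15
    weight_range: tuple = (0.1, 1.1)
    delay_range_ms: tuple = (1.0, 150.0)
    delay_normal_ms: tuple | None = None  # (mean, std) overrides the range
    mode: str = "adaptive_node"
    seed: int = 0


@dataclass
class StimulusSpec:
    kind: str = "periodic_simultaneous"
    rate_hz: float = 5.0
    duration_s: float = 10.0
    trigger_fraction: float = 0.4
    background_rate_hz: float = 0.01
    seed: int = 0


@dataclass
class Stimulus:
    """External drive: input-unit firing times plus direct node triggers."""

    input_times_ms: np.ndarray
    input_ids: np.ndarray
    node_times_ms: np.ndarray
    node_ids: np.ndarray
    meta: dict = field(default_factory=dict)

    @classmethod
    def empty(cls) -> "Stimulus":
        z = np.empty(0)
        zi = np.empty(0, np.int64)
        return cls(z, zi, z.copy(), zi.copy())


def _check_divisible(n: int, k: int) -> None:
    if n % k != 0:
        raise ValueError(f"number of inputs {n} not divisible by K={k}")


def build_feedforward(n_inputs: int = 15, k_terminals: int = 3,
                      weight_range: tuple = (0.1, 1.1),
                      delay_range_ms: tuple = (1.0, 150.0),
                      seed: int | np.random.Generator = 0,
                      v_st: float = 0.0, v_th: float = 1.0) -> Network:
    """One output node with K terminals fed by ``n_inputs`` input units.

    Weights are uniform on ``weight_range`` and delays uniform on
    ``delay_range_ms``.  Links are delay-sorted and assigned to terminals
    in consecutive blocks of N/K; the maximal-delay link is re-assigned to
    the first terminal, closing the loop of arrival order.
    """
    _check_divisible(n_inputs, k_terminals)
    rng = np.random.default_rng(seed)
    w = rng.uniform(*weight_range, size=n_inputs)
    tau = rng.uniform(*delay_range_ms, size=n_inputs)
    order = np.argsort(tau, kind="stable")
    w = w[order]
    tau = tau[order]
    per = n_inputs // k_terminals
    term = np.repeat(np.arange(k_terminals), per)
    term[-1] = 0  # maximal-delay link closes the loop on terminal 0
    scale = v_th - v_st
    return Network(
        n_nodes=1, k_terminals=k_terminals, n_inputs=n_inputs,
        link_src=np.arange(n_inputs, dtype=np.int64),
        link_src_is_input=np.ones(n_inputs, bool),
        link_tgt=np.zeros(n_inputs, np.int64),
        link_term=term.astype(np.int64),
        link_w=w * scale,
        link_tau_ms=tau,
        mode="adaptive_node", v_st=v_st, v_th=v_th,
        meta={"topology": "feedforward", "seed_used": True},
    )


def _recurrent_links(rng, partners_of, n_nodes, in_degree, k_terminals,
                     weight_range, delay_mean_ms, delay_std_ms):
    src = np.empty(n_nodes * in_degree, np.int64)
    tgt = np.empty_like(src)
    term = np.empty_like(src)
    tau = np.empty(n_nodes * in_degree)
    per = in_degree // k_terminals
    for n in range(n_nodes):
        pool = partners_of(n)
        if in_degree > len(pool):
            raise ValueError("in-degree exceeds the available source pool")
        pick = rng.choice(pool, size=in_degree, replace=False)
        # delays normal(mean, std), truncated at 0.1 ms (unphysical below);
        # each node's links are delay-sorted into consecutive terminal blocks
        tau_local = np.maximum(rng.normal(delay_mean_ms, delay_std_ms,
                                          size=in_degree), 0.1)
        order = np.argsort(tau_local, kind="stable")
        sl = slice(n * in_degree, (n + 1) * in_degree)
        src[sl] = pick[order]
        tgt[sl] = n
        tau[sl] = tau_local[order]
        term[sl] = np.repeat(np.arange(k_terminals), per)
    w = rng.uniform(*weight_range, size=n_nodes * in_degree)
    return src, tgt, term, w, tau


def build_two_pool(n_nodes: int = 1000, in_degree: int = 60,
                   k_terminals: int = 3, mode: str = "adaptive_node",
                   weight_range: tuple = (0.1, 0.2),
                   delay_mean_ms: float = 100.0, delay_std_ms: float = 2.0,
                   seed: int | np.random.Generator = 0,
                   v_st: float = 0.0, v_th: float = 1.0) -> Network:
    """Two pools of n_nodes/2 nodes wired bipartitely (no within-pool edges)."""
    if n_nodes % 2 != 0:
        raise ValueError("two-pool network needs an even node count")
    half = n_nodes // 2
    if in_degree > half:
        raise ValueError("in-degree exceeds the opposite pool size")
    if mode == "adaptive_link":
        k_terminals = 1
    _check_divisible(in_degree, k_terminals)
    rng = np.random.default_rng(seed)

    def partners(n):
        return np.arange(half, n_nodes) if n < half else np.arange(half)

    src, tgt, term, w, tau = _recurrent_links(
        rng, partners, n_nodes, in_degree, k_terminals,
        weight_range, delay_mean_ms, delay_std_ms)
    scale = v_th - v_st
    return Network(
        n_nodes=n_nodes, k_terminals=k_terminals, n_inputs=0,
        link_src=src, link_src_is_input=np.zeros(len(src), bool),
        link_tgt=tgt, link_term=term,
        link_w=w * scale, link_tau_ms=tau,
        mode=mode, v_st=v_st, v_th=v_th,
        meta={"topology": "two_pool", "half": half, "in_degree": in_degree},
    )


def build_random_recurrent(n_nodes: int = 1000, in_degree: int = 60,
                           k_terminals: int = 3, mode: str = "adaptive_node",
                           weight_range: tuple = (0.1, 0.2),
                           delay_mean_ms: float = 100.0, delay_std_ms: float = 2.0,
                           seed: int | np.random.Generator = 0,
                           v_st: float = 0.0, v_th: float = 1.0) -> Network:
    """Random recurrent network: partners drawn uniformly, self-loops excluded."""
    if mode == "adaptive_link":
        k_terminals = 1
    _check_divisible(in_degree, k_terminals)
    if in_degree > n_nodes - 1:
        raise ValueError("in-degree exceeds the number of other nodes")
    rng = np.random.default_rng(seed)

    def partners(n):
        return np.concatenate([np.arange(n), np.arange(n + 1, n_nodes)])

    src, tgt, term, w, tau = _recurrent_links(
        rng, partners, n_nodes, in_degree, k_terminals,
        weight_range, delay_mean_ms, delay_std_ms)
    scale = v_th - v_st
    return Network(
        n_nodes=n_nodes, k_terminals=k_terminals, n_inputs=0,
        link_src=src, link_src_is_input=np.zeros(len(src), bool),
        link_tgt=tgt, link_term=term,
        link_w=w * scale, link_tau_ms=tau,
        mode=mode, v_st=v_st, v_th=v_th,
        meta={"topology": "random_recurrent", "in_degree": in_degree},
    )


def build_network(spec: NetworkSpec) -> Network:
    """Dispatch a :class:`NetworkSpec` to the matching builder."""
    if spec.topology == "feedforward":
        return build_feedforward(
            n_inputs=spec.n_inputs_per_node, k_terminals=spec.k_terminals,
            weight_range=spec.weight_range, delay_range_ms=spec.delay_range_ms,
            seed=spec.seed)
    if spec.topology in ("two_pool", "random_recurrent"):
        mean, std = spec.delay_normal_ms or (100.0, 2.0)
        builder = build_two_pool if spec.topology == "two_pool" \
            else build_random_recurrent
        return builder(
            n_nodes=spec.n_nodes, in_degree=spec.n_inputs_per_node,
            k_terminals=spec.k_terminals, mode=spec.mode,
            weight_range=spec.weight_range,
            delay_mean_ms=mean, delay_std_ms=std, seed=spec.seed)
    raise ValueError(f"unknown topology {spec.topology!r}")


def make_stimulus(kind: str, duration_s: float, n_inputs: int = 0,
                  n_nodes: int = 0, rate_hz: float = 5.0,
                  trigger_fraction: float = 0.4,
                  background_rate_hz: float = 0.01,
                  seed: int | np.random.Generator = 0) -> Stimulus:
    """Generate an external drive schedule.

    * ``periodic_simultaneous`` — all inputs fire together at ``rate_hz``.
    * ``poisson_per_input`` — independent homogeneous Poisson trains per
      input at mean ``rate_hz``.
    * ``initial_trigger_plus_background`` — a random ``trigger_fraction``
      of the nodes is stimulated above threshold at t=0, plus independent
      per-node Poisson background at ``background_rate_hz``.
    """
    if rate_hz < 0 or background_rate_hz < 0:
        raise ValueError("rates must be non-negative")
    rng = np.random.default_rng(seed)
    dur_ms = duration_s * 1000.0
    if kind == "periodic_simultaneous":
        if rate_hz == 0:
            return Stimulus.empty()
        times = np.arange(0.0, dur_ms, 1000.0 / rate_hz)
        return Stimulus(
            input_times_ms=np.tile(times, n_inputs),
            input_ids=np.repeat(np.arange(n_inputs, dtype=np.int64), len(times)),
            node_times_ms=np.empty(0), node_ids=np.empty(0, np.int64),
            meta={"kind": kind, "rate_hz": rate_hz},
        )
    if kind == "poisson_per_input":
        t_all, i_all = [], []
        for i in range(n_inputs):
            n_ev = rng.poisson(rate_hz * duration_s)
            t_all.append(np.sort(rng.uniform(0, dur_ms, size=n_ev)))
            i_all.append(np.full(n_ev, i, np.int64))
        times = np.concatenate(t_all) if t_all else np.empty(0)
        ids = np.concatenate(i_all) if i_all else np.empty(0, np.int64)
        return Stimulus(times, ids, np.empty(0), np.empty(0, np.int64),
                        meta={"kind": kind, "rate_hz": rate_hz})
    if kind == "initial_trigger_plus_background":
        n_trig = int(round(trigger_fraction * n_nodes))
        trig = rng.choice(n_nodes, size=n_trig, replace=False)
        t_all = [np.zeros(n_trig)]
        i_all = [trig.astype(np.int64)]
        for n in range(n_nodes):
            n_ev = rng.poisson(background_rate_hz * duration_s)
            if n_ev:
                t_all.append(rng.uniform(0, dur_ms, size=n_ev))
                i_all.append(np.full(n_ev, n, np.int64))
        return Stimulus(np.empty(0), np.empty(0, np.int64),
                        np.concatenate(t_all), np.concatenate(i_all),
                        meta={"kind": kind,
                              "trigger_fraction": trigger_fraction,
                              "background_rate_hz": background_rate_hz})
    raise ValueError(f"unknown stimulus kind {kind!r}")
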