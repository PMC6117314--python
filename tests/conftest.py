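"""Shared simulation fixtures.

The expensive protocol runs (the 2500 s random-input node, the scaled
recurrent network, the two-pool comparison) are session-scoped so the
acceptance checks and property tests share one simulation each.
"""

import numpy as np
import pytest

import dendrosim as ds


@pytest.fixture(scope="session")
def fig4_run():
    """Random-input single node: K=2, N=120, 30 Hz Poisson, A=0.1, 2500 s."""
    res, net = ds.run_single_node_random_input(
        seed=101, duration_s=2500.0, transient_s=200.0,
        adaptation_capacity=16_000_000)
    return res, net


@pytest.fixture(scope="session")
def fig4_pooled(fig4_run):
    """Post-transient effective-weight samples pooled over snapshots."""
    res, net = fig4_run
    keep = res.snapshot_times_ms >= 200_000.0
    j = res.j_snapshots[keep]
    return (net.link_w[None, :] * j[:, net.link_tgt, net.link_term]).ravel()


@pytest.fixture(scope="session")
def recurrent_run():
    """Scaled random recurrent network in its active steady state."""
    net = ds.build_random_recurrent(n_nodes=200, in_degree=60,
                                    k_terminals=3, seed=33)
    res = ds.run_recurrent(net, seed=33, duration_s=240.0,
                           rate_window_s=(220.0, 240.0))
    return res, net


@pytest.fixture(scope="session")
def two_pool_runs():
    """Adaptive-node (50 s) vs adaptive-link (350 s) two-pool runs."""
    net_node = ds.build_two_pool(n_nodes=200, in_degree=60, k_terminals=3,
                                 mode="adaptive_node", seed=55)
    res_node = ds.run_recurrent(net_node, seed=55, duration_s=50.0,
                                rate_window_s=(40.0, 50.0))
    net_link = ds.build_two_pool(n_nodes=200, in_degree=60, k_terminals=3,
                                 mode="adaptive_link", seed=55)
    res_link = ds.run_recurrent(net_link, seed=55, duration_s=350.0,
                                rate_window_s=(300.0, 350.0))
    return (res_node, net_node), (res_link, net_link)


@pytest.fixture(scope="session")
def oscillation_fractions():
    """Oscillating fractions at K=3 for N=9 and N=27, 500 samples each."""
    return {
        9: ds.oscillation_fraction(k_terminals=3, n_per_terminal=3,
                                   n_samples=500, seed=42),
        27: ds.oscillation_fraction(k_terminals=3, n_per_terminal=9,
                                    n_samples=500, seed=42),
    }


@pytest.fixture(scope="session")
def terminal_weff_traces(fig4_run):
    """Per-terminal mean effective weight versus snapshot time."""
    res, net = fig4_run
    w_mean = np.array([net.link_w[net.terminal_links(0, k)].mean()
                       for k in range(net.k_terminals)])
    return res.j_snapshots[:, 0, :] * w_mean[None, :]
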