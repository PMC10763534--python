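import numpy as np
import pytest

import dfcgene as d
from dfcgene.exceptions import (
    AllZeroNetworkError,
    DegenerateSpectrumError,
    FingerprintMismatchError,
    ShapeMismatchError,
)

from conftest import random_network


def _net(w, alpha=0.01, table=None):
    w = np.asarray(w, dtype=float)
    mask = w != 0
    return d.FunctionalNetwork(w, mask, alpha, table)


def test_node_strength_hand_example():
    net = _net([[0, 0.5, -0.2], [0.5, 0, 0.3], [-0.2, 0.3, 0]])
    assert np.allclose(d.node_strength(net), [0.3, 0.8, 0.1])


def test_node_strength_empty_graph():
    net = d.FunctionalNetwork(np.zeros((4, 4)), np.zeros((4, 4), bool), 0.01)
    assert np.allclose(d.node_strength(net), 0)


def test_node_strength_matches_row_sum_oracle(random_net):
    kappa = d.node_strength(random_net)
    n = random_net.n_nodes
    oracle = [
        sum(random_net.weights[i, j] for j in range(n) if j != i) for i in range(n)
    ]
    assert np.allclose(kappa, oracle)


def test_node_strength_linearity(rng):
    mask = rng.random((8, 8)) < 0.5
    mask = mask & mask.T
    np.fill_diagonal(mask, False)

    def make(scale):
        r = np.corrcoef(rng.standard_normal((8, 30))) * scale
        np.fill_diagonal(r, 0)
        return d.FunctionalNetwork(np.where(mask, r, 0), mask, 0.01)

    n1, n2 = make(0.9), make(0.8)
    a, b = 0.3, 0.6
    combo = d.FunctionalNetwork(a * n1.weights + b * n2.weights, mask, 0.01)
    assert np.allclose(
        d.node_strength(combo), a * d.node_strength(n1) + b * d.node_strength(n2)
    )


def test_eigencentrality_complete_graph():
    net = _net([[0, 1, 1], [1, 0, 1], [1, 1, 0]])
    res = d.eigenvector_centrality(net)
    assert res.eigenvalue == pytest.approx(2.0, abs=1e-9)
    assert np.allclose(res.scores, np.full(3, 1 / np.sqrt(3)), atol=1e-8)


def test_eigencentrality_star_graph_closed_form():
    # centre node 0: lambda = sqrt(2), e proportional to (sqrt(2), 1, 1)
    net = _net([[0, 1, 1], [1, 0, 0], [1, 0, 0]])
    res = d.eigenvector_centrality(net)
    assert res.eigenvalue == pytest.approx(np.sqrt(2), abs=1e-9)
    expected = np.array([np.sqrt(2), 1, 1]) / 2.0
    assert np.allclose(res.scores, expected, atol=1e-8)


def test_eigencentrality_matches_dense_oracle(rng):
    for _ in range(25):
        n = int(rng.integers(5, 50))
        net = random_network(n, rng)
        if not np.any(net.weights):
            continue
        res = d.eigenvector_centrality(net)
        w, V = np.linalg.eigh(net.weights)  # independent dense solver
        assert res.eigenvalue == pytest.approx(w[-1], abs=1e-8)
        v = V[:, -1]
        v = v if v.sum() >= 0 else -v
        assert np.allclose(res.scores, v, atol=1e-7) or np.allclose(
            res.scores, -v, atol=1e-7
        )


def test_eigencentrality_fixed_point(random_net):
    res = d.eigenvector_centrality(random_net)
    W = random_net.weights
    assert np.max(np.abs(W @ res.scores - res.eigenvalue * res.scores)) <= 1e-8 * max(
        np.linalg.norm(W), 1.0
    )
    assert np.linalg.norm(res.scores) == pytest.approx(1.0)
    assert res.scores.sum() >= 0


def test_eigencentrality_all_zero_raises():
    net = d.FunctionalNetwork(np.zeros((3, 3)), np.zeros((3, 3), bool), 0.01)
    with pytest.raises(AllZeroNetworkError):
        d.eigenvector_centrality(net)


def test_eigencentrality_degenerate_spectrum_raises():
    # two disconnected identical edges: leading eigenvalue 1 with multiplicity 2
    w = np.zeros((4, 4))
    w[0, 1] = w[1, 0] = 1.0
    w[2, 3] = w[3, 2] = 1.0
    with pytest.raises(DegenerateSpectrumError) as exc:
        d.eigenvector_centrality(_net(w))
    assert exc.value.gap < 1e-9


def test_eigencentrality_deterministic(random_net):
    a = d.eigenvector_centrality(random_net)
    b = d.eigenvector_centrality(random_net)
    assert np.array_equal(a.scores, b.scores)
    assert a.eigenvalue == b.eigenvalue


def test_permutation_equivariance(rng):
    table = d.RegionTable.synthetic(10)
    net = random_network(10, rng, region_table=table)
    perm = rng.permutation(10)
    pnet = d.FunctionalNetwork(
        net.weights[np.ix_(perm, perm)], net.mask[np.ix_(perm, perm)], 0.01
    )
    assert np.allclose(d.node_strength(pnet), d.node_strength(net)[perm])
    e = d.eigenvector_centrality(net).scores
    pe = d.eigenvector_centrality(pnet).scores
    assert np.allclose(pe, e[perm], atol=1e-7)


def _stack_from_ts(ts, delta_t=20, alpha=0.3):
    ref = d.static_network(ts, alpha=alpha)
    return d.dynamic_networks(ts, delta_t, ref)


def test_window_average_single_window(small_ts):
    ref = d.static_network(small_ts, alpha=0.5)
    stack = d.dynamic_networks(small_ts, small_ts.n_timepoints, ref)
    prof = d.window_average(stack, "strength")
    assert prof.level == "subject"
    assert np.allclose(prof.values, d.node_strength(stack.networks[0]))


def test_window_average_matches_recompute_oracle(small_ts):
    stack = _stack_from_ts(small_ts)
    for metric, fn in [
        ("strength", d.node_strength),
        ("eigenvector", lambda n: d.eigenvector_centrality(n).scores),
    ]:
        prof = d.window_average(stack, metric)
        vals = []
        for net in stack.networks:
            try:
                vals.append(fn(net))
            except AllZeroNetworkError:
                pass  # window_average skips undefined windows too
        assert np.allclose(prof.values, np.mean(vals, axis=0))


def test_window_average_skips_failed_windows(rng, region_table5, caplog):
    # first window constant in every region -> all-zero network there
    data = rng.standard_normal((5, 60))
    data[:, :20] = np.arange(5)[:, None]
    ts = d.RegionalTimeSeriesSet("s", "HC", data, region_table5)
    ref = d.static_network(ts, alpha=0.5)
    stack = d.dynamic_networks(ts, 20, ref)
    with caplog.at_level("WARNING", logger="dfcgene"):
        prof = d.window_average(stack, "eigenvector")
    good = [
        d.eigenvector_centrality(n).scores for n in stack.networks[1:] if np.any(n.weights)
    ]
    assert np.allclose(prof.values, np.mean(good, axis=0))


def test_group_average_identity_and_cancellation(region_table5):
    mk = lambda v, g: d.CentralityProfile("strength", v, "subject", region_table5, g)
    v = np.arange(5.0)
    assert np.allclose(d.group_average([mk(v, "HC")]).values, v)
    two = d.group_average([mk(v, "HC"), mk(-v, "HC")])
    assert np.allclose(two.values, 0)
    assert two.level == "group"


def test_group_average_matches_column_mean_oracle(region_table5, rng):
    vs = rng.standard_normal((7, 5))
    profiles = [
        d.CentralityProfile("eigenvector", v, "subject", region_table5, "MCI") for v in vs
    ]
    assert np.allclose(d.group_average(profiles).values, vs.mean(axis=0))


def test_group_average_rejects_mismatched_fingerprints(region_table5):
    other = d.RegionTable.synthetic(5)
    shifted = d.RegionTable(
        tuple(i + 10 for i in other.region_ids), other.names, other.hemispheres
    )
    p1 = d.CentralityProfile("strength", np.ones(5), "subject", region_table5, "HC")
    p2 = d.CentralityProfile("strength", np.ones(5), "subject", shifted, "HC")
    with pytest.raises(FingerprintMismatchError):
        d.group_average([p1, p2])


def test_group_average_empty_list_raises():
    with pytest.raises(ShapeMismatchError):
        d.group_average([])
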