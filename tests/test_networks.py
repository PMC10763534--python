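import numpy as np
import pytest
from hypothesis import given, strategies as st

import dfcgene as d
from dfcgene.exceptions import ShapeMismatchError, ZeroVarianceRegionError

# critical |r| for retention at alpha=0.01, 197 samples, frozen from the
# t-quantile r = t / sqrt(df + t^2) with t the 0.995 quantile at df = 195
CRITICAL_R_197 = 0.18313097764401287


def brute_force_windows(n_timepoints, delta_t):
    """Enumerate all (m, start) with start = m*delta_t/2 fitting the signal."""
    out = []
    m = 0
    while m * delta_t // 2 + delta_t <= n_timepoints:
        out.append((m, m * delta_t // 2))
        m += 1
    return out


@pytest.mark.parametrize(
    "n_t,dt,expected_starts",
    [
        (197, 20, list(range(0, 171, 10))),  # 18 half-overlapping windows
        (20, 20, [0]),
        (40, 20, [0, 10, 20]),
    ],
)
def test_sliding_window_enumeration(n_t, dt, expected_starts):
    wins = d.sliding_windows(n_t, dt)
    assert [w.start for w in wins] == expected_starts
    assert all(w.stop <= n_t for w in wins)
    assert [w.m for w in wins] == list(range(len(wins)))


@given(
    n_t=st.integers(min_value=2, max_value=200),
    dt=st.sampled_from(list(range(2, 41, 2))),
)
def test_window_count_equals_brute_force(n_t, dt):
    if dt > n_t:
        with pytest.raises(ShapeMismatchError):
            d.sliding_windows(n_t, dt)
        return
    wins = d.sliding_windows(n_t, dt)
    assert [(w.m, w.start) for w in wins] == brute_force_windows(n_t, dt)


def test_window_validation_errors():
    with pytest.raises(ShapeMismatchError):
        d.sliding_windows(100, 21)  # odd
    with pytest.raises(ShapeMismatchError):
        d.sliding_windows(10, 20)  # longer than signal


def test_window_duration_is_one_minute_at_tr3():
    assert d.window_duration_minutes(20, tr_seconds=3.0) == pytest.approx(1.0)


def test_critical_correlation_matches_t_quantile():
    assert d.critical_correlation(0.01, 197) == pytest.approx(CRITICAL_R_197, abs=5e-7)


def test_static_network_perfect_correlation_retained(region_table5, rng):
    base = rng.standard_normal(50)
    data = np.vstack([base, base, rng.standard_normal((3, 50))])
    net = d.static_network(
        d.RegionalTimeSeriesSet("s", "HC", data, region_table5), alpha=1e-6
    )
    assert net.mask[0, 1]
    assert net.weights[0, 1] == pytest.approx(1.0)


def test_static_network_zero_variance_raises(region_table5, rng):
    data = rng.standard_normal((5, 40))
    data[2] = 3.14
    ts = d.RegionalTimeSeriesSet("s", "HC", data, region_table5)
    with pytest.raises(ZeroVarianceRegionError) as exc:
        d.static_network(ts)
    assert region_table5.region_ids[2] in exc.value.region_ids


def test_static_network_symmetry_bounds_and_threshold(small_ts):
    net = d.static_network(small_ts, alpha=0.05)
    w = net.weights
    assert np.allclose(w, w.T)
    assert np.all(np.abs(w) <= 1)
    assert np.all(np.diag(w) == 0)
    assert np.all(w[~net.mask] == 0)
    # retained links are exactly those above the critical correlation
    crit = d.critical_correlation(0.05, small_ts.n_timepoints)
    r = np.corrcoef(small_ts.data)
    np.fill_diagonal(r, 0)
    assert np.array_equal(net.mask, np.abs(r) >= crit)


def test_threshold_monotonicity(small_ts):
    counts = [
        d.static_network(small_ts, alpha=a).mask.sum() for a in (0.2, 0.1, 0.05, 0.01)
    ]
    assert counts == sorted(counts, reverse=True)


def test_dynamic_single_full_window_equals_reference(small_ts):
    ref = d.static_network(small_ts, alpha=0.5)
    stack = d.dynamic_networks(small_ts, small_ts.n_timepoints, ref)
    assert stack.n_windows == 1
    assert np.allclose(stack.networks[0].weights, ref.weights)
    assert stack.discarded_fraction == 0.0


def test_dynamic_rule_a_reference_mask_inherited(small_ts):
    ref = d.static_network(small_ts, alpha=0.2)
    stack = d.dynamic_networks(small_ts, 20, ref)
    for net in stack.networks:
        assert not np.any(net.mask & ~ref.mask)


def _per_link_discard_oracle(data, delta_t, ref, mode):
    """Independent per-link reimplementation of the window discard rule."""
    n, n_t = data.shape
    wins = [(m, m * delta_t // 2) for m in range((n_t - delta_t) // (delta_t // 2) + 1)]
    kept = []
    discarded = 0
    for _, start in wins:
        seg = data[:, start : start + delta_t]
        keep = np.zeros((n, n), dtype=bool)
        for i in range(n):
            for j in range(i + 1, n):
                if not ref.mask[i, j]:
                    continue
                rw = np.corrcoef(seg[i], seg[j])[0, 1]
                ok = abs(rw) >= abs(ref.weights[i, j]) if mode == "abs" else rw >= ref.weights[i, j]
                if ok:
                    keep[i, j] = keep[j, i] = True
                else:
                    discarded += 1
        kept.append(keep)
    total = len(wins) * n * (n - 1) // 2
    return kept, discarded / total


@pytest.mark.parametrize("mode", ["abs", "signed"])
def test_dynamic_networks_match_per_link_oracle(mode, rng, region_table5):
    data = rng.standard_normal((5, 80)) + 0.3 * rng.standard_normal((1, 80))
    ts = d.RegionalTimeSeriesSet("s", "AD", data, region_table5)
    ref = d.static_network(ts, alpha=0.3)
    stack = d.dynamic_networks(ts, 20, ref, threshold_mode=mode)
    kept, frac = _per_link_discard_oracle(data, 20, ref, mode)
    for net, keep in zip(stack.networks, kept):
        assert np.array_equal(net.mask, keep)
    assert stack.discarded_fraction == pytest.approx(frac)


def test_dynamic_discard_fraction_strictly_interior_and_reproducible():
    cohort = d.generate_cohort(n_regions=20, n_subjects=1, groups=("AD",), seed=11,
                               gene_sets={"G": 3})
    ts = cohort.timeseries["AD"][0]
    ref = d.static_network(ts)
    f1 = d.dynamic_networks(ts, 20, ref).discarded_fraction
    f2 = d.dynamic_networks(ts, 20, ref).discarded_fraction
    assert 0 < f1 < 1
    assert f1 == f2


def test_dynamic_zero_variance_window_segment_not_fatal(rng, region_table5, caplog):
    data = rng.standard_normal((5, 60))
    data[0, :20] = 7.0  # constant within window 0 only
    ts = d.RegionalTimeSeriesSet("s", "HC", data, region_table5)
    ref = d.static_network(ts, alpha=0.5)
    with caplog.at_level("WARNING", logger="dfcgene"):
        stack = d.dynamic_networks(ts, 20, ref)
    assert np.all(stack.networks[0].weights[0] == 0)
    assert not np.any(stack.networks[0].mask[0])
    assert any("zero-variance" in r.message for r in caplog.records)


def test_retained_fraction_property(random_net):
    n = random_net.n_nodes
    iu = np.triu_indices(n, 1)
    assert random_net.retained_fraction == pytest.approx(random_net.mask[iu].mean())
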