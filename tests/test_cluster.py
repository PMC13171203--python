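"""Cluster-based permutation regression: statistic, clustering, inference."""

import numpy as np
import pytest

from chunklock.cluster import (
    Adjacency,
    build_grid_adjacency,
    build_sensor_adjacency,
    form_clusters,
    level_regression_stat,
    permutation_test,
    T_CAP,
)
from chunklock.geometry import toy_sensor_layout, toy_source_grid


# ------------------------------------------------------------- statistic


def test_regression_stat_matches_ols_oracle(rng):
    """Independent oracle: per-participant OLS slope + one-sample t."""
    P, L, C = 12, 7, 5
    data = rng.normal(size=(P, L, C)) + 0.3 * np.arange(1, L + 1)[None, :, None]
    t_map = level_regression_stat(data)

    levels = np.arange(1, L + 1, dtype=float)
    slopes = np.empty((P, C))
    for p in range(P):
        for c in range(C):
            slopes[p, c] = np.polyfit(levels, data[p, :, c], 1)[0]
    mean = slopes.mean(axis=0)
    sem = slopes.std(axis=0, ddof=1) / np.sqrt(P)
    assert np.allclose(t_map, mean / sem, rtol=1e-10)


def test_regression_stat_zero_variance_branch():
    P, L = 6, 7
    data = np.tile(np.arange(1.0, L + 1), (P, 1))[:, :, None]  # value = level
    t_map = level_regression_stat(data)
    assert np.all(t_map == T_CAP)
    t_zero = level_regression_stat(np.ones((P, L, 1)))
    assert np.all(t_zero == 0.0)


def test_regression_stat_level_permutation_centers_at_zero(rng):
    P, L, C = 10, 7, 50
    data = rng.normal(size=(P, L, C))
    t_map = level_regression_stat(data)
    assert abs(t_map.mean()) < 0.2


def test_regression_stat_scale_invariance(rng):
    data = rng.normal(size=(8, 7, 4))
    assert np.allclose(
        level_regression_stat(data), level_regression_stat(2.0 * data), rtol=1e-12
    )


# ------------------------------------------------------------ clustering


def _chain_adjacency(n):
    return Adjacency(n=n, pairs=np.column_stack([np.arange(n - 1), np.arange(1, n)]))


def test_isolated_channel_pruned():
    stat = np.zeros((5, 4))
    stat[2, 1] = 5.0  # single supra-threshold cell
    clusters = form_clusters(stat, 2.0, _chain_adjacency(5), min_channels=3)
    assert clusters == []


def test_block_cluster_size():
    stat = np.zeros((6, 8))
    stat[1:4, 2:7] = 3.0  # 3 adjacent channels x 5 consecutive samples
    clusters = form_clusters(stat, 2.0, _chain_adjacency(6), min_channels=3)
    assert len(clusters) == 1
    assert len(clusters[0].cells) == 15
    assert clusters[0].cluster_sum == pytest.approx(45.0)
    assert clusters[0].sign == 1


def _flood_fill_oracle(stat, threshold, pairs, min_channels):
    """Exhaustive connected components over supra-threshold same-sign cells."""
    S, T = stat.shape
    neigh = {i: set() for i in range(S)}
    for i, j in pairs:
        neigh[i].add(j)
        neigh[j].add(i)
    seen = set()
    out = []
    for sign in (1, -1):
        cells = {(c, t) for c in range(S) for t in range(T) if sign * stat[c, t] > threshold}
        for start in sorted(cells):
            if start in seen:
                continue
            comp, stack = set(), [start]
            while stack:
                cur = stack.pop()
                if cur in comp:
                    continue
                comp.add(cur)
                c, t = cur
                nxt = [(cc, t) for cc in neigh[c]] + [(c, t - 1), (c, t + 1)]
                stack.extend(x for x in nxt if x in cells and x not in comp)
            seen |= comp
            if len({c for c, _ in comp}) >= min_channels:
                out.append((sign, frozenset(comp), sum(stat[c, t] for c, t in comp)))
    return out


def test_checkerboard_signs_match_flood_fill_oracle(rng):
    """Brute-force oracle on small instances including sign separation."""
    for trial in range(5):
        S, T = 4, 4
        stat = rng.normal(scale=3.0, size=(S, T))
        pairs = np.column_stack([np.arange(S - 1), np.arange(1, S)])
        clusters = form_clusters(stat, 1.0, _chain_adjacency(S), min_channels=1)
        got = {
            (c.sign, frozenset(map(tuple, c.cells)), round(c.cluster_sum, 9))
            for c in clusters
        }
        want = {
            (sign, comp, round(total, 9))
            for sign, comp, total in _flood_fill_oracle(stat, 1.0, pairs, 1)
        }
        assert got == want


def test_form_clusters_empty_result_is_valid():
    assert form_clusters(np.zeros((4, 4)), 1.0, _chain_adjacency(4)) == []


def test_min_channels_per_timepoint_variant_not_needed_for_anywhere_rule():
    # a cluster that spans 3 channels only through time still counts
    stat = np.zeros((5, 6))
    stat[1, 0:3] = 3.0
    stat[2, 2:5] = 3.0
    stat[3, 4:6] = 3.0
    clusters = form_clusters(stat, 2.0, _chain_adjacency(5), min_channels=3)
    assert len(clusters) == 1
    assert set(clusters[0].channels) == {1, 2, 3}


# ------------------------------------------------------------- adjacency


def test_grid_adjacency_neighbor_counts():
    grid = toy_source_grid(shape=(4, 4, 4))
    adj = build_grid_adjacency(grid)
    counts = adj.neighbor_counts()
    ijk = grid.ijk
    interior = np.all((ijk > 0) & (ijk < 3), axis=1)
    corner = np.all((ijk == 0) | (ijk == 3), axis=1)
    assert np.all(counts[interior] == 26)
    assert np.all(counts[corner] == 7)


def test_sensor_adjacency_two_close_sensors():
    from chunklock.geometry import SensorLayout

    layout = SensorLayout(
        positions=np.array([[0, 0, 0.1], [0, 0.01, 0.1]]),
        orientations=np.array([[0, 0, 1.0], [0, 0, 1.0]]),
        names=["a", "b"],
    )
    adj = build_sensor_adjacency(layout, distance=0.02)
    assert len(adj.pairs) == 1
    assert adj.neighbor_counts().tolist() == [1, 1]


def test_sensor_adjacency_symmetric_irreflexive():
    adj = build_sensor_adjacency(toy_sensor_layout(20))
    assert np.all(adj.pairs[:, 0] < adj.pairs[:, 1])
    counts = adj.neighbor_counts()
    assert counts.min() >= 1


# ------------------------------------------------------------- inference


def _signal_data(rng, P=12, L=7, S=8, T=10, effect=0.0):
    data = rng.normal(size=(P, L, S, T))
    data[:, :, 2:5, 3:7] += effect * np.arange(1, L + 1)[None, :, None, None]
    return data


def test_permutation_p_floor():
    """+1 convention: p >= 1/(n_perm + 1)."""
    rng = np.random.default_rng(0)
    data = _signal_data(rng, effect=2.0)
    adj = _chain_adjacency(8)
    res = permutation_test(data, adj, n_perm=100, sided="two", rng=1)
    assert len(res.clusters) >= 1
    for c in res.clusters:
        assert c.p_value >= 1 / 101 - 1e-12


def test_permutation_detects_strong_effect_and_scale_invariance():
    rng = np.random.default_rng(1)
    data = _signal_data(rng, effect=1.5)
    adj = _chain_adjacency(8)
    res1 = permutation_test(data, adj, n_perm=200, sided="two", rng=5)
    res2 = permutation_test(2.0 * data, adj, n_perm=200, sided="two", rng=5)
    assert res1.significant()
    assert [c.p_value for c in res1.clusters] == [c.p_value for c in res2.clusters]
    assert np.allclose(res1.t_map, res2.t_map)


def test_permutation_invariant_to_participant_relabeling():
    rng = np.random.default_rng(2)
    data = _signal_data(rng, effect=1.0)
    adj = _chain_adjacency(8)
    res1 = permutation_test(data, adj, n_perm=150, sided="two", rng=9)
    perm = np.random.default_rng(3).permutation(data.shape[0])
    res2 = permutation_test(data[perm], adj, n_perm=150, sided="two", rng=9)
    assert [c.p_value for c in res1.clusters] == [c.p_value for c in res2.clusters]


def test_one_sided_mirror_on_sign_flip():
    rng = np.random.default_rng(4)
    data = _signal_data(rng, effect=1.5)
    adj = _chain_adjacency(8)
    pos = permutation_test(data, adj, n_perm=200, sided="pos", rng=11)
    neg = permutation_test(-data, adj, n_perm=200, sided="neg", rng=11)
    assert [c.p_value for c in pos.clusters] == [c.p_value for c in neg.clusters]
    assert [c.cluster_sum for c in pos.clusters] == [
        -c.cluster_sum for c in neg.clusters
    ]


def test_degenerate_constant_data_gives_no_clusters():
    data = np.ones((6, 7, 5, 4))
    res = permutation_test(data, _chain_adjacency(5), n_perm=100, rng=0)
    assert res.clusters == []


def test_small_n_perm_warns():
    rng = np.random.default_rng(5)
    data = rng.normal(size=(5, 7, 4, 3))
    with pytest.warns(UserWarning, match="small"):
        permutation_test(data, _chain_adjacency(4), n_perm=50, rng=0)
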