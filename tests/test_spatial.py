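"""Geometry on the periodic surface: densities, motion, shoving, aggregates."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from surfcol import (
    SimulationParams, local_sessile_density, move_planktonic,
    resolve_overlaps, aggregate_labels, detect_aggregates,
)
from surfcol._grid import count_neighbors
from surfcol.spatial import SHOVE_TOL

L = 1000.0


def brute_force_counts(points, sessile, R, L):
    """O(N^2) minimum-image neighbor counting (the reference oracle)."""
    points = np.atleast_2d(points)
    sessile = np.atleast_2d(sessile)
    out = np.zeros(len(points), dtype=int)
    for i, p in enumerate(points):
        d = np.abs(sessile - p)
        d = np.minimum(d, L - d)
        out[i] = int(np.sum(np.hypot(d[:, 0], d[:, 1]) <= R))
    return out


def brute_force_partition(pos, contact, L):
    """Union-find over all pairs (the aggregate-detection oracle)."""
    n = len(pos)
    parent = list(range(n))

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for i in range(n):
        for j in range(i + 1, n):
            d = np.abs(pos[i] - pos[j])
            d = np.minimum(d, L - d)
            if np.hypot(d[0], d[1]) <= contact:
                parent[find(i)] = find(j)
    return np.array([find(i) for i in range(n)])


class TestDensity:
    def test_self_count(self):
        pos = np.array([[500.0, 500.0]])
        assert local_sessile_density(pos[0], pos, 10.0, L) == 1

    def test_far_query_is_zero(self):
        pos = np.array([[100.0, 100.0]])
        assert local_sessile_density(np.array([900.0, 500.0]), pos, 10.0, L) == 0

    def test_periodic_wraparound(self):
        pos = np.array([[999.0, 500.0]])
        assert local_sessile_density(np.array([1.0, 500.0]), pos, 10.0, L) == 1

    @given(seed=st.integers(0, 10**6))
    @settings(max_examples=20, derandomize=True, deadline=None)
    def test_matches_brute_force(self, seed):
        """KD-tree counts equal the O(N^2) oracle on random configurations,
        including clustered ones."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(1, 120))
        pts = rng.uniform(0, L, (n, 2))
        if seed % 2:  # clustered near the wrap seam
            pts[: n // 2] = rng.normal(0, 15, (n // 2, 2)) % L
        q = rng.uniform(0, L, (40, 2))
        expected = brute_force_counts(q, pts, 10.0, L)
        assert np.array_equal(local_sessile_density(q, pts, 10.0, L), expected)
        assert np.array_equal(count_neighbors(pts, q, 10.0, L), expected)

    def test_grid_engine_matches_kdtree_on_dense_cluster(self):
        rng = np.random.default_rng(7)
        pts = (np.array([500.0, 500.0]) + rng.normal(0, 5, (400, 2))) % L
        q = (np.array([500.0, 500.0]) + rng.normal(0, 8, (100, 2))) % L
        assert np.array_equal(count_neighbors(pts, q, 10.0, L),
                              local_sessile_density(q, pts, 10.0, L))


class TestMotion:
    def test_zero_speed_walk_stays_put(self, rng):
        p = SimulationParams(V=0.0, motion_mode="bounded_walk")
        pos = rng.uniform(0, L, (20, 2))
        assert np.allclose(move_planktonic(pos, p, rng), pos)

    def test_walk_step_bounded_by_speed(self, rng):
        p = SimulationParams(V=0.001, motion_mode="bounded_walk")
        pos = rng.uniform(100, 900, (500, 2))
        out = move_planktonic(pos, p, rng)
        max_step = p.V * 3600 * p.dt
        assert np.all(np.hypot(*(out - pos).T) <= max_step + 1e-9)

    def test_well_mixed_positions_uniform(self, rng):
        p = SimulationParams()
        pos = np.full((10_000, 2), 500.0)
        out = move_planktonic(pos, p, rng)
        assert np.all((out >= 0) & (out < L))
        for axis in (0, 1):
            ks = stats.kstest(out[:, axis] / L, "uniform")
            assert ks.pvalue > 0.01


class TestShoving:
    def test_pair_pushed_apart_symmetrically(self):
        pos = np.array([[500.0, 500.0], [500.5, 500.0]])
        out = resolve_overlaps(pos, 1.0, L)
        d = np.hypot(*(out[1] - out[0]))
        assert d >= 1.0 * (1 - SHOVE_TOL)
        assert np.allclose(out.mean(axis=0), pos.mean(axis=0), atol=1e-9)

    def test_non_overlapping_fixed_point(self, rng):
        pos = rng.uniform(0, L, (50, 2))  # mean spacing ~140 um >> 1 um
        out = resolve_overlaps(pos, 1.0, L)
        assert np.allclose(out, pos)

    def test_isolated_cells_never_move(self, rng):
        pos = np.vstack([
            rng.uniform(0, 400, (30, 2)),
            600 + rng.uniform(0, 1.0, (10, 2)),  # one overlapping clump
        ])
        out = resolve_overlaps(pos, 1.0, L)
        assert np.allclose(out[:30], pos[:30])

    def test_dense_seed_point_relaxes_to_packing(self):
        pos = np.full((50, 2), 500.0)
        out = resolve_overlaps(pos, 1.0, L)
        c = brute_force_counts(out, out, 1.0 * (1 - SHOVE_TOL), L)
        assert np.all(c == 1)  # only self within the tolerance radius
        assert np.all((out >= 0) & (out < L))

    def test_relaxes_across_wrap_seam(self):
        pos = np.array([[0.2, 500.0], [999.9, 500.0]])  # 0.3 um apart
        out = resolve_overlaps(pos, 1.0, L)
        d = np.abs(out[0] - out[1])
        d = np.minimum(d, L - d)
        assert np.hypot(*d) >= 1.0 * (1 - SHOVE_TOL)


class TestAggregates:
    def test_chain_is_one_aggregate(self):
        pos = np.array([[500.0, 500.0], [501.1, 500.0], [502.2, 500.0]])
        labels = aggregate_labels(pos, 1.2, L)
        assert len(set(labels)) == 1

    def test_distant_cells_are_singletons(self):
        pos = np.array([[100.0, 100.0], [105.0, 100.0]])
        labels = aggregate_labels(pos, 1.2, L)
        assert len(set(labels)) == 2

    @given(seed=st.integers(0, 10**6))
    @settings(max_examples=10, derandomize=True, deadline=None)
    def test_matches_union_find_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 200))
        # clumpy configuration so non-trivial components appear
        centers = rng.uniform(0, L, (max(1, n // 10), 2))
        pos = (centers[rng.integers(0, len(centers), n)]
               + rng.normal(0, 2.0, (n, 2))) % L
        labels = aggregate_labels(pos, 1.2, L)
        oracle = brute_force_partition(pos, 1.2, L)
        # identical partitions: label pairs agree on same/different
        for arr in (labels, oracle):
            assert len(arr) == n
        same_a = labels[:, None] == labels[None, :]
        same_b = oracle[:, None] == oracle[None, :]
        assert np.array_equal(same_a, same_b)

    def test_records_partition_population(self, rng):
        n = 150
        pos = rng.uniform(0, L, (n, 2))
        ids = np.arange(n) + 1000
        lineages = rng.integers(0, 5, n)
        recs = detect_aggregates(ids, lineages, pos, 1.2, L)
        assert sum(r.size for r in recs) == n
        all_ids = set()
        for r in recs:
            assert sum(r.lineage_counts.values()) == r.size
            assert not (all_ids & r.member_ids)
            all_ids |= r.member_ids
        assert all_ids == set(ids.tolist())

    def test_empty_input(self):
        assert detect_aggregates([], [], np.zeros((0, 2)), 1.2, L) == []
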