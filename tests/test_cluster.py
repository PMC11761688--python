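"""DBSCAN clustering, cluster morphology, and NN density mapping."""

import numpy as np
import pytest

from paintkit import cluster as ck
from paintkit import sim

from oracles import (
    clusterings_equivalent,
    dbscan_bruteforce,
    hull_area_shoelace,
    neighbor_counts_bruteforce,
    nn_distances_bruteforce,
)


def _random_instance(rng, n):
    """Mixed-density instance: a few tight blobs plus uniform background."""
    k = rng.integers(1, 4)
    pts = [rng.uniform(0, 10, size=(rng.integers(3, 15), 2))]
    for _ in range(k):
        center = rng.uniform(1, 9, size=2)
        pts.append(center + rng.normal(0, 0.2, size=(rng.integers(5, 20), 2)))
    pts = np.vstack(pts)
    return pts[:n] if len(pts) > n else pts


class TestDBSCAN:
    def test_defaults(self):
        assert ck.DEFAULT_EPS == 0.3
        assert ck.DEFAULT_MIN_PTS == 5

    def test_two_well_separated_groups(self):
        rng = np.random.default_rng(1)
        a = rng.normal(0, 0.01, size=(6, 2))
        b = rng.normal(0, 0.01, size=(6, 2)) + 100.0
        labels = ck.dbscan(np.vstack([a, b]), eps=0.3, min_pts=5)
        assert set(labels) == {0, 1}
        assert np.all(labels[:6] == labels[0])
        assert np.all(labels[6:] == labels[6])

    def test_empty_input(self):
        assert len(ck.dbscan(np.empty((0, 2)))) == 0

    def test_invalid_parameters(self):
        with pytest.raises(ValueError):
            ck.dbscan(np.zeros((3, 2)), eps=0.0)
        with pytest.raises(ValueError):
            ck.dbscan(np.zeros((3, 2)), min_pts=0)

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_bruteforce_oracle(self, seed):
        rng = np.random.default_rng(seed)
        pts = _random_instance(rng, 100)
        eps = float(rng.uniform(0.2, 0.8))
        min_pts = int(rng.integers(2, 8))
        mine = ck.dbscan(pts, eps, min_pts)
        oracle = dbscan_bruteforce(pts, eps, min_pts)
        assert clusterings_equivalent(mine, oracle, pts, eps, min_pts)


class TestClusterMetrics:
    def test_circle_is_round(self):
        theta = np.linspace(0, 2 * np.pi, 100, endpoint=False)
        pts = np.column_stack([np.cos(theta), np.sin(theta)])
        res = ck.cluster_metrics(pts, np.zeros(100, dtype=int))
        row = res.per_cluster.iloc[0]
        assert row.axis_ratio == pytest.approx(1.0, abs=0.01)
        assert row.eccentricity == pytest.approx(0.0, abs=0.15)

    def test_collinear_degenerate(self):
        pts = np.column_stack([np.arange(5.0), np.arange(5.0)])
        res = ck.cluster_metrics(pts, np.zeros(5, dtype=int))
        row = res.per_cluster.iloc[0]
        assert row.area == 0.0
        assert row.axis_ratio == pytest.approx(0.0, abs=1e-6)

    def test_unit_square_hull_area(self):
        pts = np.array([[0.0, 0.0], [1.0, 0.0], [1.0, 1.0], [0.0, 1.0]])
        res = ck.cluster_metrics(pts, np.zeros(4, dtype=int))
        assert res.per_cluster.iloc[0].area == pytest.approx(1.0)

    def test_hull_area_matches_shoelace_oracle(self, rng):
        pts = rng.uniform(0, 100, size=(30, 2))
        res = ck.cluster_metrics(pts, np.zeros(30, dtype=int))
        assert res.per_cluster.iloc[0].area == pytest.approx(
            hull_area_shoelace(pts), rel=1e-9)

    def test_anisotropic_gaussian_axis_ratio(self):
        rng = np.random.default_rng(3)
        pts = rng.normal(0, 1, size=(500, 2)) * [100.0, 50.0]
        res = ck.cluster_metrics(pts, np.zeros(500, dtype=int))
        assert abs(res.per_cluster.iloc[0].axis_ratio - 0.5) < 0.15 * 0.5

    def test_rigid_motion_invariance(self, rng):
        pts = rng.normal(0, 1, size=(200, 2)) * [80.0, 30.0]
        labels = np.zeros(200, dtype=int)
        theta = 0.83
        rot = np.array([[np.cos(theta), -np.sin(theta)],
                        [np.sin(theta), np.cos(theta)]])
        moved = pts @ rot.T + [1234.5, -678.9]
        a = ck.cluster_metrics(pts, labels).per_cluster.iloc[0]
        b = ck.cluster_metrics(moved, labels).per_cluster.iloc[0]
        assert a.area == pytest.approx(b.area, rel=1e-9)
        assert a.axis_ratio == pytest.approx(b.axis_ratio, rel=1e-9)
        assert a.mean_nn_distance == pytest.approx(b.mean_nn_distance, rel=1e-9)

    def test_small_cluster_undefined_eccentricity(self):
        pts = np.array([[0.0, 0.0], [1.0, 1.0]])
        res = ck.cluster_metrics(pts, np.zeros(2, dtype=int))
        row = res.per_cluster.iloc[0]
        assert row.area == 0.0
        assert np.isnan(row.eccentricity)


class TestNNDistances:
    def test_two_points(self):
        d = ck.nn_distances(np.array([[0.0, 0.0], [30.0, 0.0]]))
        assert np.allclose(d, 30.0)

    def test_regular_grid(self):
        gx, gy = np.meshgrid(np.arange(5.0), np.arange(5.0))
        pts = np.column_stack([gx.ravel(), gy.ravel()]) * 7.0
        assert np.allclose(ck.nn_distances(pts), 7.0)

    def test_single_point_insufficient(self):
        with pytest.raises(ValueError):
            ck.nn_distances(np.array([[0.0, 0.0]]))

    def test_matches_bruteforce(self, rng):
        pts = rng.uniform(0, 100, size=(80, 2))
        assert np.allclose(ck.nn_distances(pts), nn_distances_bruteforce(pts))


class TestDensityMap:
    def test_pair_within_radius(self):
        # two-point cluster: mean NN distance equals their separation, so
        # each sees exactly one neighbor at radius_scale = 1
        pts = np.array([[0.0, 0.0], [1.0, 0.0]])
        dmap = ck.local_density_map(pts, np.zeros(2, dtype=int), radius_scale=1.0)
        assert np.allclose(dmap.neighbor_count, 1.0)

    def test_uniform_grid_equal_interior_density(self):
        gx, gy = np.meshgrid(np.arange(10.0), np.arange(10.0))
        pts = np.column_stack([gx.ravel(), gy.ravel()])
        labels = np.zeros(100, dtype=int)
        dmap = ck.local_density_map(pts, labels, radius_scale=1.0)
        interior = (gx.ravel() > 0) & (gx.ravel() < 9) & (gy.ravel() > 0) & (gy.ravel() < 9)
        counts = dmap.neighbor_count[interior]
        assert len(np.unique(counts)) == 1

    def test_noise_points_undefined(self):
        pts = np.array([[0.0, 0.0], [0.1, 0.0], [50.0, 50.0]])
        labels = np.array([0, 0, -1])
        dmap = ck.local_density_map(pts, labels)
        assert np.isnan(dmap.neighbor_count[2])
        assert np.isfinite(dmap.neighbor_count[0])

    def test_matches_bruteforce_counts(self, rng):
        pts = rng.normal(0, 1, size=(60, 2))
        labels = np.zeros(60, dtype=int)
        dmap = ck.local_density_map(pts, labels, radius_scale=2.0)
        radius = 2.0 * nn_distances_bruteforce(pts).mean()
        assert np.allclose(dmap.neighbor_count,
                           neighbor_counts_bruteforce(pts, radius))


class TestHighlight:
    def test_default_multiplier(self):
        assert ck.DEFAULT_HIGHLIGHT_K == 5.0

    def test_equidistant_all_true(self):
        gx, gy = np.meshgrid(np.arange(4.0), np.arange(4.0))
        pts = np.column_stack([gx.ravel(), gy.ravel()])
        labels = np.zeros(16, dtype=int)
        dmap = ck.local_density_map(pts, labels)
        mask = ck.highlight_threshold(dmap, k=5.0)
        assert mask.all()

    def test_outlier_excluded(self):
        # 20-point unit grid (NN = 1) plus one straggler 16 away: the
        # cluster mean NN is ~1.75, so the straggler exceeds 5x the mean
        gx, gy = np.meshgrid(np.arange(4.0), np.arange(5.0))
        grid = np.column_stack([gx.ravel(), gy.ravel()])
        pts = np.vstack([grid, [[0.0, 20.0]]])
        labels = np.zeros(len(pts), dtype=int)
        dmap = ck.local_density_map(pts, labels)
        mask = ck.highlight_threshold(dmap, k=5.0)
        assert not mask[-1]
        assert mask[:-1].all()


class TestRecoveryOnSimulatedScenes:
    def test_cluster_count_and_fraction(self):
        scene = sim.make_clutch_scene(200, 30, 50.0, (100000.0, 100000.0), seed=61)
        labels = ck.dbscan(scene.sites / 1000.0, eps=0.3, min_pts=5)
        res = ck.cluster_metrics(scene.sites, labels)
        assert abs(res.n_clusters - 200) <= 0.02 * 200
        assert res.fraction_clustered > 0.99

    def test_mean_hull_area_matches_footprint(self):
        scene = sim.make_clutch_scene(50, 100, 50.0, (100000.0, 100000.0), seed=62)
        labels = ck.dbscan(scene.sites / 1000.0, eps=0.3, min_pts=5)
        res = ck.cluster_metrics(scene.sites, labels)
        mean_area_um2 = res.per_cluster.area.mean() / 1e6
        # footprint oracle: mean hull area of n=100 draws from the same Gaussian
        rng = np.random.default_rng(63)
        oracle = np.mean([
            hull_area_shoelace(rng.normal(0, 50.0, size=(100, 2))) / 1e6
            for _ in range(50)
        ])
        assert 1e-3 < mean_area_um2 < 1e-1
        assert abs(mean_area_um2 - oracle) < 0.3 * oracle
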