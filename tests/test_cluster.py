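"""Cluster-statistic tests: linkage, min-3 rule, hulls, distances, histograms."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from immunogold import (
    ClusterParams,
    composition_histogram,
    hull_area,
    link_clusters,
    make_profile,
    plant_clusters,
)
from immunogold.compartments import CompartmentClass, Klass, Layer


def brute_force_components(xy, link):
    """O(n^2) union-find oracle for single-linkage components."""
    n = len(xy)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if np.hypot(*(xy[i] - xy[j])) <= link:
                parent[find(i)] = find(j)
    comps = {}
    for i in range(n):
        comps.setdefault(find(i), set()).add(i)
    return {frozenset(c) for c in comps.values()}


def brute_force_hull_area(points):
    """Shoelace area of the hull found by the all-subset extreme-point test."""
    pts = np.asarray(points, float)
    hull = []
    for i, p in enumerate(pts):
        # p is extreme iff it is not inside the hull of the others, i.e. not
        # a convex combination; test via all triangles
        inside = False
        for a, b, c in itertools.combinations(range(len(pts)), 3):
            if i in (a, b, c):
                continue
            if _in_triangle(p, pts[a], pts[b], pts[c]):
                inside = True
                break
        if not inside:
            hull.append(p)
    hull = np.array(hull)
    center = hull.mean(axis=0)
    order = np.argsort(np.arctan2(hull[:, 1] - center[1], hull[:, 0] - center[0]))
    hull = hull[order]
    x, y = hull[:, 0], hull[:, 1]
    return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


def _in_triangle(p, a, b, c):
    def cross(o, u, v):
        return (u[0] - o[0]) * (v[1] - o[1]) - (u[1] - o[1]) * (v[0] - o[0])

    d1, d2, d3 = cross(a, b, p), cross(b, c, p), cross(c, a, p)
    has_neg = (d1 < 0) or (d2 < 0) or (d3 < 0)
    has_pos = (d1 > 0) or (d2 > 0) or (d3 > 0)
    return not (has_neg and has_pos)


class TestLinkage:
    def test_chain_forms_one_cluster(self):
        xy = np.array([(0.0, 0.0), (30.0, 0.0), (60.0, 0.0)])
        clusters, scattered = link_clusters(xy, ClusterParams(50.0, 3))
        assert len(clusters) == 1
        assert clusters[0].size == 3
        assert len(scattered) == 0

    def test_pairs_discarded_by_min3_rule(self):
        xy = np.array([(0.0, 0.0), (10.0, 0.0)])
        clusters, scattered = link_clusters(xy, ClusterParams(50.0, 3))
        assert clusters == []
        assert len(scattered) == 2

    def test_empty_input(self):
        clusters, scattered = link_clusters(np.empty((0, 2)))
        assert clusters == [] and len(scattered) == 0

    def test_matches_brute_force_union_find(self):
        rng = np.random.default_rng(17)
        for n in (50, 200, 500):
            xy = rng.uniform(0, 1500, size=(n, 2))
            clusters, scattered = link_clusters(xy, ClusterParams(50.0, 3))
            got = {frozenset(c.member_indices) for c in clusters}
            got |= {frozenset({i}) for i in scattered}
            oracle = brute_force_components(xy, 50.0)
            # merge oracle singletons/pairs into the scattered representation
            oracle_clusters = {c for c in oracle if len(c) >= 3}
            oracle_scattered = {
                frozenset({i}) for c in oracle if len(c) < 3 for i in c
            }
            assert got == oracle_clusters | oracle_scattered

    def test_partition_conserves_particles(self):
        rng = np.random.default_rng(3)
        xy = rng.uniform(0, 800, size=(300, 2))
        clusters, scattered = link_clusters(xy)
        members = [i for c in clusters for i in c.member_indices] + list(scattered)
        assert sorted(members) == list(range(300))

    def test_order_independence(self):
        rng = np.random.default_rng(5)
        xy = rng.uniform(0, 500, size=(80, 2))
        perm = rng.permutation(80)
        a, _ = link_clusters(xy)
        b, _ = link_clusters(xy[perm])
        key_a = sorted(tuple(sorted(map(tuple, xy[list(c.member_indices)]))) for c in a)
        key_b = sorted(
            tuple(sorted(map(tuple, xy[perm][list(c.member_indices)]))) for c in b
        )
        assert key_a == key_b

    def test_planted_well_separated_recovery(self, rng):
        profile = make_profile(
            CompartmentClass(Layer.SR_PROX, Klass.OBLIQUE_DENDRITE),
            4.0,
            rng,
            profile_id="p0",
        )
        pts = plant_clusters([profile], 8, (3, 10), 0.3, 20.0, 300.0, rng)
        clusters, scattered = link_clusters(pts)
        assert len(clusters) == 8
        assert len(scattered) == 0
        # memberships recovered exactly
        got = {
            frozenset(pts.iloc[list(c.member_indices)]["cluster_id"]) for c in clusters
        }
        assert all(len(s) == 1 for s in got)


class TestHull:
    def test_square(self):
        pts = [(0.0, 0.0), (0.0, 100.0), (100.0, 0.0), (100.0, 100.0)]
        assert hull_area(np.array(pts)) == pytest.approx(10000.0)

    def test_collinear_zero(self):
        pts = [(0.0, 0.0), (10.0, 10.0), (20.0, 20.0)]
        assert hull_area(np.array(pts)) == 0.0

    def test_fewer_than_three_rejected(self):
        with pytest.raises(ValueError):
            hull_area(np.array([(0.0, 0.0), (1.0, 1.0)]))

    def test_matches_brute_force_hull(self):
        rng = np.random.default_rng(23)
        for _ in range(15):
            pts = rng.uniform(0, 300, size=(10, 2))
            assert hull_area(pts) == pytest.approx(
                brute_force_hull_area(pts), rel=1e-9
            )

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(
        scale=st.floats(0.1, 50.0),
        seed=st.integers(0, 1000),
    )
    def test_scale_covariance(self, scale, seed):
        # scaling coordinates by s scales hull areas by s^2
        pts = np.random.default_rng(seed).uniform(0, 100, size=(8, 2))
        assert hull_area(pts * scale) == pytest.approx(
            hull_area(pts) * scale**2, rel=1e-9
        )


class TestNearestDistance:
    def two_clusters(self, centers):
        xy = np.concatenate(
            [np.array([(0.0, 0.0), (10.0, 0.0), (0.0, 10.0)]) + c for c in centers]
        )
        clusters, _ = link_clusters(xy, ClusterParams(50.0, 3))
        return clusters

    def test_symmetric_pair(self):
        clusters = self.two_clusters([(0.0, 0.0), (300.0, 0.0)])
        d = [c.nearest_cluster_distance_nm for c in clusters]
        assert d[0] == pytest.approx(300.0, abs=1e-9)
        assert d[0] == d[1]

    def test_three_collinear(self):
        clusters = self.two_clusters([(0.0, 0.0), (100.0, 0.0), (250.0, 0.0)])
        mid = [c for c in clusters if abs(c.centroid_nm[0] - 103.33) < 1][0]
        assert mid.nearest_cluster_distance_nm == pytest.approx(100.0, abs=1e-9)

    def test_single_cluster_flagged(self):
        clusters = self.two_clusters([(0.0, 0.0)])
        assert clusters[0].nearest_cluster_distance_nm is None

    def test_matches_exhaustive_minimum(self):
        rng = np.random.default_rng(31)
        centers = rng.uniform(0, 5000, size=(20, 2))
        clusters = self.two_clusters(centers)
        cents = np.array([c.centroid_nm for c in clusters])
        d = np.hypot(
            cents[:, None, 0] - cents[None, :, 0],
            cents[:, None, 1] - cents[None, :, 1],
        )
        np.fill_diagonal(d, np.inf)
        for c, expect in zip(clusters, d.min(axis=1)):
            assert c.nearest_cluster_distance_nm == pytest.approx(float(expect))

    def test_scaling_distances_linear(self):
        a = self.two_clusters([(0.0, 0.0), (300.0, 0.0)])
        b = self.two_clusters([(0.0, 0.0), (600.0, 0.0)])
        assert b[0].nearest_cluster_distance_nm == pytest.approx(
            2 * a[0].nearest_cluster_distance_nm, rel=1e-6
        )


class TestComposition:
    def test_simple_histogram(self):
        h = composition_histogram([3, 3, 5], 140.0, 140.0)
        assert h["counts"] == {3: 2, 5: 1}
        assert h["total_clusters"] == 3
        assert h["size_range"] == (3, 5)
        assert h["percentages"][3] == pytest.approx(200 / 3)

    def test_empty(self):
        h = composition_histogram([], 140.0, 140.0)
        assert h["total_clusters"] == 0 and h["counts"] == {}

    def test_area_tolerance_enforced(self):
        with pytest.raises(ValueError, match="re-sample"):
            composition_histogram([3], 100.0, 140.0)

    def test_calibrated_recovery_totals(self, cal):
        # 12-month proximal sr oblique dendrites over 140 um^2:
        # 298 planted clusters in wild type, recovered exactly; the largest
        # cluster exceeds 20 particles at this condition
        from immunogold.pipeline import recover_cluster_composition

        r = recover_cluster_composition(cal, "sr_prox", "WT", 42)
        assert r["recovered_total"] == 298
        assert r["size_range"][0] == 3
        assert r["size_range"][1] >= 20
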