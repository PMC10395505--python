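"""Trait extraction: stem diameter, geodesics, leaf length and width."""

import networkx as nx
import numpy as np
import pytest

from shootseg.cloud import LEAF, STEM, LabeledPointCloud, ValidationError
from shootseg.synthetic import PlantSpec, generate_plant
from shootseg.traits import (
    extract_traits,
    geodesic_path_length,
    leaf_length,
    leaf_width,
    stem_diameter,
)


def _cylinder(radius=1.0, height=40.0, n_rings=40, ring=10, sigma=0.0, seed=0):
    # complete rings at each height: the centroid sits on the axis and the
    # cross-covariances vanish, so the fitted line is exactly the true axis
    theta = np.tile(np.arange(ring) * 2 * np.pi / ring, n_rings)
    z = np.repeat(np.linspace(0, height, n_rings), ring)
    pts = np.column_stack([radius * np.cos(theta), radius * np.sin(theta), z])
    if sigma:
        pts += np.random.default_rng(seed).normal(0, sigma, size=pts.shape)
    return pts


def _grid(length=40.0, width=20.0, step=0.5):
    # lexicographic order: ties along an edge resolve deterministically
    xs = np.arange(0, length + step / 2, step)
    ys = np.arange(-width / 2, width / 2 + step / 2, step)
    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    return np.column_stack([gx.ravel(), gy.ravel(), np.zeros(gx.size)])


class TestStemDiameter:
    def test_noise_free_cylinder_exact(self):
        assert stem_diameter(_cylinder(radius=1.0)) == pytest.approx(2.0, abs=1e-9)

    def test_two_parallel_rows(self):
        z = np.linspace(0, 10, 20)
        left = np.column_stack([np.full(20, -0.5), np.zeros(20), z])
        right = np.column_stack([np.full(20, 0.5), np.zeros(20), z])
        assert stem_diameter(np.vstack([left, right])) == pytest.approx(1.0, abs=1e-9)

    def test_jittered_cylinder_within_5pct_and_matches_direct_median(self):
        pts = _cylinder(radius=1.0, sigma=0.05, seed=3)
        d = stem_diameter(pts)
        assert d == pytest.approx(2.0, rel=0.05)
        # direct-geometry oracle on the lowest quartile
        z = pts[:, 2]
        low = pts[z <= z.min() + (z.max() - z.min()) / 4]
        c = low - low.mean(axis=0)
        w, v = np.linalg.eigh(c.T @ c)
        axis = v[:, np.argmax(w)]
        perp = c - np.outer(c @ axis, axis)
        assert d == pytest.approx(2 * np.median(np.linalg.norm(perp, axis=1)))

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValidationError):
            stem_diameter(np.zeros((20, 3)))  # zero z range
        with pytest.raises(ValidationError):
            stem_diameter(np.zeros((5, 3)))  # too few points

    def test_scales_linearly_and_rotation_invariant(self):
        pts = _cylinder(radius=1.5, sigma=0.02, seed=1)
        base = stem_diameter(pts)
        assert stem_diameter(pts * 2.0) == pytest.approx(2 * base, rel=1e-6)
        a = 0.7
        rot = np.array([[np.cos(a), -np.sin(a), 0], [np.sin(a), np.cos(a), 0], [0, 0, 1]])
        assert stem_diameter(pts @ rot.T) == pytest.approx(base, rel=1e-9)


class TestGeodesic:
    def test_collinear_chain(self):
        pts = np.column_stack([np.arange(31.0), np.zeros(31), np.zeros(31)])
        assert geodesic_path_length(pts, 0, 30) == pytest.approx(30.0)

    def test_two_points_euclidean(self):
        pts = np.array([[0.0, 0, 0], [3.0, 4.0, 0]])
        assert geodesic_path_length(pts, 0, 1) == pytest.approx(5.0)

    def test_semicircle_arc_not_chord(self):
        t = np.linspace(0, np.pi, 200)
        pts = np.column_stack([10 * np.cos(t), 10 * np.sin(t), np.zeros(200)])
        d = geodesic_path_length(pts, 0, 199)
        assert d == pytest.approx(10 * np.pi, rel=0.01)
        assert d > 25.0  # far from the 20 mm chord
        # brute-force shortest-path oracle on the same k-NN graph
        from scipy.spatial import cKDTree

        dist, idx = cKDTree(pts).query(pts, k=11)
        g = nx.Graph()
        for i in range(200):
            for j, w in zip(idx[i, 1:], dist[i, 1:]):
                g.add_edge(i, int(j), weight=float(w))
        assert d == pytest.approx(nx.dijkstra_path_length(g, 0, 199))

    def test_disconnected_falls_back_to_straight_line(self):
        a = np.zeros((12, 3)) + np.arange(12)[:, None] * [0.1, 0, 0]
        b = a + np.array([1000.0, 0, 0])
        pts = np.vstack([a, b])
        with pytest.warns(RuntimeWarning):
            d = geodesic_path_length(pts, 0, 23, k=3)
        assert d == pytest.approx(np.linalg.norm(pts[0] - pts[23]))

    def test_invalid_indices_rejected(self):
        with pytest.raises(ValidationError):
            geodesic_path_length(np.zeros((5, 3)), 0, 9)


class TestLeafLengthWidth:
    def test_flat_grid_dimensions(self):
        grid = _grid(40.0, 20.0, step=0.5)
        assert leaf_length(grid) == pytest.approx(40.0, rel=0.02)
        assert leaf_width(grid) == pytest.approx(20.0, rel=0.02)

    def test_straight_line_length(self):
        pts = np.column_stack([np.arange(31.0), np.zeros(31), np.zeros(31)])
        assert leaf_length(pts) == pytest.approx(30.0)

    def test_collinear_width_near_zero(self):
        pts = np.column_stack([np.arange(31.0), np.zeros(31), np.zeros(31)])
        assert leaf_width(pts) <= 1.0 + 1e-9  # within point spacing

    def test_curved_synthetic_leaf_recovers_ground_truth(self):
        cloud, traits = generate_plant(PlantSpec(n_leaves=1, noise_sigma=0.0, seed=21))
        pts = cloud.coords[cloud.instance == 1]
        _, gt_len, gt_wid = traits.leaves[0]
        assert leaf_length(pts) == pytest.approx(gt_len, rel=0.05)
        assert leaf_width(pts) == pytest.approx(gt_wid, rel=0.05)

    def test_length_at_least_width_on_elongated_leaves(self):
        cloud, _ = generate_plant(PlantSpec(n_leaves=2, noise_sigma=0.0, seed=4))
        for iid in (1, 2):
            pts = cloud.coords[cloud.instance == iid]
            assert leaf_length(pts) >= leaf_width(pts)

    def test_rotation_and_translation_invariance(self):
        cloud, _ = generate_plant(PlantSpec(n_leaves=1, noise_sigma=0.0, seed=2))
        pts = cloud.coords[cloud.instance == 1]
        a = 1.2
        rot = np.array([[np.cos(a), -np.sin(a), 0], [np.sin(a), np.cos(a), 0], [0, 0, 1]])
        moved = pts @ rot.T + np.array([5.0, -30.0, 12.0])
        assert leaf_length(moved) == pytest.approx(leaf_length(pts), rel=1e-6)
        assert leaf_width(moved) == pytest.approx(leaf_width(pts), rel=1e-6)


class TestExtractTraits:
    def test_cardinality(self, small_plant):
        cloud, _, _ = small_plant
        rec = extract_traits(cloud)
        assert rec.stem_diameter is not None
        assert len(rec.leaves) == 3
        assert all(l is not None and w is not None for _, l, w in rec.leaves)

    def test_speck_leaf_yields_missing_values(self, small_plant):
        cloud, _, _ = small_plant
        speck = LabeledPointCloud(
            coords=np.vstack([cloud.coords, np.zeros((5, 3)) + [50, 50, 50]]),
            semantic=np.concatenate([cloud.semantic, np.full(5, LEAF)]),
            instance=np.concatenate([cloud.instance, np.full(5, 9)]),
        )
        with pytest.warns(RuntimeWarning):
            rec = extract_traits(speck)
        by_id = {iid: (l, w) for iid, l, w in rec.leaves}
        assert by_id[9] == (None, None)
        assert all(by_id[i][0] is not None for i in (1, 2, 3))

    def test_no_stem_warns_and_continues(self):
        cloud, _ = generate_plant(PlantSpec(n_leaves=2, noise_sigma=0.0, seed=3))
        leaf_only = cloud.select(cloud.semantic == LEAF)
        with pytest.warns(RuntimeWarning):
            rec = extract_traits(leaf_only)
        assert rec.stem_diameter is None
        assert len(rec.leaves) == 2
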