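"""The centroid -> distance -> kernel -> range-scale -> L1 chain."""

import math

import numpy as np
import pytest
from hypothesis import assume, given, settings, strategies as st

from oracles import scalar_chain

import fatesimplex as fs
from fatesimplex.coords import (BarycentricCoordinates, CentroidMatrix,
                                DistanceMatrix, SimilarityMatrix)
from fatesimplex.io import DegenerateDataWarning, ValidationError


class TestCentroids:
    def test_singleton_cluster(self):
        m = fs.ExpressionMatrix(np.array([[1.0, 5.0], [2.0, 6.0]]),
                                ["g1", "g2"], ["c1", "c2"])
        ann = fs.CellAnnotation(["c1", "c2"], ["A", "B"])
        cen = fs.compute_centroids(m, ann, fs.SimplexSpec(["A", "B"]))
        np.testing.assert_array_equal(cen.values, [[1, 5], [2, 6]])

    def test_arithmetic_mean(self):
        m = fs.ExpressionMatrix(np.array([[0.0, 2.0, 7.0], [0.0, 4.0, 7.0]]),
                                ["g1", "g2"], ["c1", "c2", "c3"])
        ann = fs.CellAnnotation(["c1", "c2", "c3"], ["A", "A", "B"])
        cen = fs.compute_centroids(m, ann, fs.SimplexSpec(["A", "B"]))
        np.testing.assert_array_equal(cen.values[:, 0], [1, 2])

    def test_identical_cells_share_centroid(self, rng):
        k = 7
        vec = rng.random(5)
        x = np.tile(vec[:, None], (1, k + 1))
        ann = fs.CellAnnotation([f"c{i}" for i in range(k + 1)],
                                ["A"] * k + ["B"])
        m = fs.ExpressionMatrix(x, [f"g{i}" for i in range(5)], ann.barcodes)
        cen = fs.compute_centroids(m, ann, fs.SimplexSpec(["A", "B"]))
        np.testing.assert_allclose(cen.values[:, 0], vec)

    def test_empty_cluster_rejected(self):
        m = fs.ExpressionMatrix(np.ones((2, 2)), ["g1", "g2"], ["c1", "c2"])
        ann = fs.CellAnnotation(["c1", "c2"], ["A", "A"])
        with pytest.raises(ValidationError):
            fs.compute_centroids(m, ann, fs.SimplexSpec(["A", "B"]))


class TestDistances:
    def test_three_four_five(self):
        m = fs.ExpressionMatrix(np.array([[0.0], [0.0]]), ["g1", "g2"], ["c1"])
        cen = CentroidMatrix(np.array([[3.0], [4.0]]), ["A"])
        d = fs.compute_distances(m, cen)
        assert d.values[0, 0] == pytest.approx(5.0)

    def test_zero_at_own_centroid(self):
        m = fs.ExpressionMatrix(np.array([[2.0], [3.0]]), ["g1", "g2"], ["c1"])
        cen = CentroidMatrix(np.array([[2.0, 0.0], [3.0, 0.0]]), ["A", "B"])
        d = fs.compute_distances(m, cen)
        assert d.values[0, 0] == 0.0

    def test_matches_double_loop_oracle(self, rng):
        x = rng.random((6, 20))
        cen = rng.random((6, 3))
        m = fs.ExpressionMatrix(x, [f"g{i}" for i in range(6)],
                                [f"c{i}" for i in range(20)])
        d = fs.compute_distances(m, CentroidMatrix(cen, ["A", "B", "C"]))
        for c in range(20):
            for v in range(3):
                expect = math.sqrt(sum((x[i, c] - cen[i, v]) ** 2
                                       for i in range(6)))
                assert d.values[c, v] == pytest.approx(expect, abs=1e-10)

    def test_dimension_mismatch(self):
        m = fs.ExpressionMatrix(np.ones((2, 1)), ["g1", "g2"], ["c1"])
        with pytest.raises(ValidationError, match="features"):
            fs.compute_distances(m, CentroidMatrix(np.ones((3, 2)), ["A", "B"]))


class TestRowNormalize:
    def test_unit_sum(self):
        d = fs.row_normalize_distances(DistanceMatrix(np.array([[1.0, 1.0, 2.0]])))
        np.testing.assert_allclose(d.values, [[0.25, 0.25, 0.5]])

    def test_zero_entry_preserved(self):
        d = fs.row_normalize_distances(DistanceMatrix(np.array([[0.0, 5.0, 5.0]])))
        np.testing.assert_allclose(d.values, [[0.0, 0.5, 0.5]])

    def test_degenerate_centroids_rejected(self):
        with pytest.raises(ValidationError, match="coincide"):
            fs.row_normalize_distances(DistanceMatrix(np.zeros((1, 3))))

    @given(st.lists(st.lists(st.floats(0.001, 1000), min_size=3, max_size=3),
                    min_size=1, max_size=30))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_rows_sum_to_one(self, rows):
        d = fs.row_normalize_distances(DistanceMatrix(np.asarray(rows)))
        np.testing.assert_allclose(d.values.sum(axis=1), 1.0, atol=1e-9)


class TestGaussianSimilarity:
    def test_zero_distance_unit_similarity(self):
        s = fs.gaussian_similarity(DistanceMatrix(np.array([[0.0]])))
        assert s.values[0, 0] == 1.0

    def test_unit_bandwidth_point(self):
        s = fs.gaussian_similarity(DistanceMatrix(np.array([[0.08]])), sigma=0.08)
        assert s.values[0, 0] == pytest.approx(math.exp(-1), abs=1e-12)

    def test_invalid_sigma(self):
        with pytest.raises(ValidationError, match="sigma"):
            fs.gaussian_similarity(DistanceMatrix(np.zeros((1, 2))), sigma=0.0)

    @given(st.floats(0.0, 1.0), st.floats(0.0, 1.0))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_strictly_decreasing_in_distance(self, a, b):
        assume(abs(a - b) > 1e-9)
        s = fs.gaussian_similarity(DistanceMatrix(np.array([[a], [b]])))
        if a < b:
            assert s.values[0, 0] > s.values[1, 0]
        elif a > b:
            assert s.values[0, 0] < s.values[1, 0]


class TestRangeScale:
    def test_affine_map(self):
        s = fs.range_scale(SimilarityMatrix(np.array([[0.2], [0.5], [0.8]])))
        np.testing.assert_allclose(s.values.ravel(), [0, 0.5, 1])

    def test_constant_column_half(self):
        with pytest.warns(DegenerateDataWarning, match="constant"):
            s = fs.range_scale(SimilarityMatrix(np.array([[0.4], [0.4]])))
        np.testing.assert_array_equal(s.values.ravel(), [0.5, 0.5])

    def test_column_extremes(self, rng):
        s = fs.range_scale(SimilarityMatrix(rng.random((30, 4))))
        np.testing.assert_allclose(s.values.min(axis=0), 0.0, atol=1e-12)
        np.testing.assert_allclose(s.values.max(axis=0), 1.0, atol=1e-12)


class TestL1Normalize:
    def test_even_split(self):
        b = fs.l1_normalize(SimilarityMatrix(np.array([[1.0, 1.0]])))
        np.testing.assert_allclose(b.values, [[0.5, 0.5]])

    def test_single_support(self):
        b = fs.l1_normalize(SimilarityMatrix(np.array([[0.0, 0.0, 1.0]])))
        np.testing.assert_allclose(b.values, [[0, 0, 1]])

    def test_zero_row_uniform_with_warning(self):
        with pytest.warns(DegenerateDataWarning, match="uniform"):
            b = fs.l1_normalize(SimilarityMatrix(np.array([[0.0, 0.0, 0.0],
                                                           [0.2, 0.2, 0.6]])))
        np.testing.assert_allclose(b.values[0], [1 / 3] * 3)


class TestCartesianProjection:
    def test_vertex_rows_map_to_vertices(self):
        for n in (2, 3, 4):
            b = BarycentricCoordinates(np.eye(n), [f"t{i}" for i in range(n)])
            np.testing.assert_array_equal(fs.barycentric_to_cartesian(b),
                                          fs.simplex_vertices(n))

    def test_uniform_row_maps_to_centroid(self):
        b = BarycentricCoordinates(np.full((1, 3), 1 / 3), ["a", "b", "c"])
        np.testing.assert_allclose(fs.barycentric_to_cartesian(b),
                                   [[0.5, math.sqrt(3) / 6]], atol=1e-12)

    def test_points_inside_hull(self, rng):
        for n in (3, 4):
            raw = rng.random((50, n))
            b = BarycentricCoordinates(raw / raw.sum(1, keepdims=True),
                                       [f"t{i}" for i in range(n)])
            xy = fs.barycentric_to_cartesian(b)
            # invert the projection: recovered weights must be a valid convex
            # combination (the hull-membership certificate)
            v = fs.simplex_vertices(n)
            aug = np.vstack([v.T, np.ones(n)])
            for row in xy:
                w, *_ = np.linalg.lstsq(aug, np.append(row, 1.0), rcond=None)
                assert w.min() > -1e-9
                assert w.sum() == pytest.approx(1.0, abs=1e-9)

    def test_unnormalized_row_rejected(self):
        b = BarycentricCoordinates(np.array([[0.5, 0.5]]), ["a", "b"])
        b.values = np.array([[0.9, 0.5]])  # bypass the constructor check
        with pytest.raises(ValidationError, match="sum to 1"):
            fs.barycentric_to_cartesian(b)


def _pure_cluster_dataset(n_vertices=3, per_cluster=5, seed=5):
    """Clusters whose cells equal their centroid exactly (zero noise)."""
    rng = np.random.default_rng(seed)
    g = 12
    profiles = rng.random((n_vertices, g)) * 4 + 0.5
    cols, labels = [], []
    for i in range(n_vertices):
        for _ in range(per_cluster):
            cols.append(profiles[i])
            labels.append(f"T{i + 1}")
    x = np.column_stack(cols)
    barcodes = [f"c{i}" for i in range(x.shape[1])]
    m = fs.ExpressionMatrix(x, [f"g{i}" for i in range(g)], barcodes)
    return m, fs.CellAnnotation(barcodes, labels)


class TestComputeSimplex:
    def test_pure_clusters_argmax_own_vertex(self):
        m, ann = _pure_cluster_dataset()
        spec = fs.SimplexSpec(["T1", "T2", "T3"])
        res = fs.compute_simplex(m, ann, spec, method="pca", n_components=2,
                                 normalize=False)
        vals = res.coordinates.values
        for i, lab in enumerate(spec.terminal_labels):
            idx = ann.indices_of(lab)
            assert (vals[idx].argmax(axis=1) == i).all()

    def test_two_vertices_complement(self):
        m, ann = _pure_cluster_dataset(n_vertices=2)
        res = fs.compute_simplex(m, ann, fs.SimplexSpec(["T1", "T2"]),
                                 method="pca", n_components=1, normalize=False)
        vals = res.coordinates.values
        np.testing.assert_allclose(vals[:, 0] + vals[:, 1], 1.0, atol=1e-12)
        assert res.cartesian.shape == (m.n_cells, 1)
        np.testing.assert_allclose(res.cartesian[:, 0], vals[:, 1])

    def test_vertex_permutation_equivariance_exact(self, fixture_data):
        _, matrix, annotation, _, _ = fixture_data
        r1 = fs.compute_simplex(matrix, annotation,
                                fs.SimplexSpec(["T1", "T2", "T3"]))
        r2 = fs.compute_simplex(matrix, annotation,
                                fs.SimplexSpec(["T3", "T1", "T2"]))
        np.testing.assert_array_equal(r1.coordinates.values,
                                      r2.coordinates.values[:, [1, 2, 0]])
        lab1 = [r1.coordinates.terminal_labels[i]
                for i in r1.coordinates.values.argmax(axis=1)]
        lab2 = [r2.coordinates.terminal_labels[i]
                for i in r2.coordinates.values.argmax(axis=1)]
        assert lab1 == lab2

    def test_cell_order_equivariance(self, fixture_data):
        _, matrix, annotation, _, _ = fixture_data
        rng = np.random.default_rng(3)
        perm = rng.permutation(matrix.n_cells)
        m2 = matrix.subset_cells(perm)
        a2 = fs.CellAnnotation([annotation.barcodes[i] for i in perm],
                               [annotation.clusters[i] for i in perm])
        spec = fs.SimplexSpec(["T1", "T2", "T3"])
        r1 = fs.compute_simplex(matrix, annotation, spec)
        r2 = fs.compute_simplex(m2, a2, spec)
        np.testing.assert_array_equal(r1.coordinates.values[perm],
                                      r2.coordinates.values)

    def test_full_chain_matches_scalar_oracle(self, rng):
        cells = rng.random((10, 4)).tolist()
        centroids = rng.random((3, 4)).tolist()
        x = np.asarray(cells).T
        m = fs.ExpressionMatrix(x, [f"g{i}" for i in range(4)],
                                [f"c{i}" for i in range(10)])
        cen = CentroidMatrix(np.asarray(centroids).T, ["A", "B", "C"])
        d = fs.row_normalize_distances(fs.compute_distances(m, cen))
        b = fs.l1_normalize(fs.range_scale(fs.gaussian_similarity(d)))
        expect = scalar_chain(cells, centroids)
        np.testing.assert_allclose(b.values, expect, atol=1e-10)

    def test_similarity_monotone_in_distance(self):
        # decreasing one cell's distance to a vertex (others fixed) never
        # decreases its final coordinate for that vertex
        rng = np.random.default_rng(9)
        d0 = rng.random((12, 3)) + 0.1
        for delta in (0.01, 0.05):
            d1 = d0.copy()
            d1[0, 0] = max(d1[0, 0] - delta, 1e-6)

            def finish(d):
                dn = fs.row_normalize_distances(DistanceMatrix(d))
                return fs.l1_normalize(
                    fs.range_scale(fs.gaussian_similarity(dn))).values

            assert finish(d1)[0, 0] >= finish(d0)[0, 0] - 1e-12
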