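import itertools

import networkx as nx
import numpy as np
import pytest

from scnet import (
    DensityGrid,
    auc_over_densities,
    clustering_coefficient,
    eigenvector_centrality,
    in_out_degree,
    metric_curve,
    weighted_degree,
)
from scnet.errors import ConfigurationError, DisconnectedGraphError
from scnet.metrics import MetricCurve

from conftest import random_directed, random_symmetric


def brute_onnela(W):
    """Exhaustive triangle enumeration of the Onnela clustering coefficient."""
    W = W / W.max()
    n = W.shape[0]
    out = np.zeros(n)
    for i in range(n):
        nbrs = np.flatnonzero(W[i] > 0)
        k = len(nbrs)
        if k < 2:
            continue
        s = 0.0
        for j, h in itertools.combinations(nbrs, 2):
            s += (W[i, j] * W[i, h] * W[j, h]) ** (1 / 3)
        out[i] = 2 * s / (k * (k - 1))
    return out


class TestWeightedDegree:
    def test_unit_triangle(self):
        A = np.ones((3, 3)) - np.eye(3)
        np.testing.assert_allclose(weighted_degree(A), [2, 2, 2])

    def test_star(self):
        A = np.zeros((5, 5))
        A[0, 1:] = A[1:, 0] = 1.0
        np.testing.assert_allclose(weighted_degree(A), [4, 1, 1, 1, 1])

    def test_row_sum_oracle(self, rng):
        A = random_symmetric(rng, 8)
        np.testing.assert_allclose(weighted_degree(A), A.sum(axis=1))

    def test_asymmetric_input_rejected(self, rng):
        A = random_directed(rng, 5)
        with pytest.raises(ConfigurationError):
            weighted_degree(A)


class TestClustering:
    def test_binary_triangle(self):
        A = np.ones((3, 3)) - np.eye(3)
        np.testing.assert_allclose(clustering_coefficient(A), 1.0)

    def test_path_has_no_triangles(self):
        A = np.diag(np.ones(3), 1)
        A = A + A.T
        np.testing.assert_allclose(clustering_coefficient(A), 0.0)

    def test_matches_exhaustive_triangle_oracle(self, rng):
        for _ in range(10):
            A = random_symmetric(rng, 6, density=0.8)
            if A.max() == 0:
                continue
            np.testing.assert_allclose(
                clustering_coefficient(A), brute_onnela(A), atol=1e-12
            )

    def test_matches_networkx(self, rng):
        A = random_symmetric(rng, 8, density=0.9)
        G = nx.from_numpy_array(A)
        expect = np.array([nx.clustering(G, weight="weight")[i] for i in range(8)])
        np.testing.assert_allclose(clustering_coefficient(A), expect, atol=1e-12)


class TestEigenvectorCentrality:
    def test_complete_graph_uniform(self):
        A = np.ones((5, 5)) - np.eye(5)
        np.testing.assert_allclose(eigenvector_centrality(A), 1 / np.sqrt(5))

    def test_star_center_leaf_ratio(self):
        A = np.zeros((5, 5))
        A[0, 1:] = A[1:, 0] = 1.0
        v = eigenvector_centrality(A)
        assert v[0] / v[1] == pytest.approx(2.0, abs=1e-10)  # sqrt(k) for k = 4 leaves
        assert np.linalg.norm(v) == pytest.approx(1.0)

    def test_matches_dense_eig_and_networkx(self, rng):
        for _ in range(5):
            A = random_symmetric(rng, 10, density=0.6)
            if not (A.sum(axis=1) > 0).all():
                continue
            from scnet import is_fully_connected

            if not is_fully_connected(A):
                continue
            v = eigenvector_centrality(A)
            w, vecs = np.linalg.eigh(A)
            expect = np.abs(vecs[:, -1])
            np.testing.assert_allclose(v, expect, atol=1e-8)
            G = nx.from_numpy_array(A)
            nxv = nx.eigenvector_centrality_numpy(G, weight="weight")
            nxv = np.abs(np.array([nxv[i] for i in range(10)]))
            nxv = nxv / np.linalg.norm(nxv)
            np.testing.assert_allclose(v, nxv, atol=1e-8)

    def test_disconnected_raises_by_default(self):
        A = np.zeros((4, 4))
        A[0, 1] = A[1, 0] = 1.0
        A[2, 3] = A[3, 2] = 1.0
        with pytest.raises(DisconnectedGraphError):
            eigenvector_centrality(A)

    def test_disconnected_component_mode(self):
        A = np.zeros((5, 5))
        A[0, 1] = A[1, 0] = 1.0
        A[2, 3] = A[3, 2] = 1.0  # node 4 isolated
        v = eigenvector_centrality(A, on_disconnected="components")
        np.testing.assert_allclose(v[:4], 1 / np.sqrt(2))
        assert v[4] == 0.0


class TestInOutDegree:
    def test_single_edge(self):
        A = np.zeros((2, 2))
        A[0, 1] = 0.7
        ind, outd = in_out_degree(A)
        np.testing.assert_allclose(ind, [0.0, 0.7])
        np.testing.assert_allclose(outd, [0.7, 0.0])

    def test_transpose_swaps_outputs(self, rng):
        A = random_directed(rng, 6)
        ind, outd = in_out_degree(A)
        ind_t, outd_t = in_out_degree(A.T)
        np.testing.assert_allclose(ind, outd_t)
        np.testing.assert_allclose(outd, ind_t)

    def test_sum_oracle_and_conservation(self, rng):
        A = random_directed(rng, 7)
        ind, outd = in_out_degree(A)
        np.testing.assert_allclose(ind, A.sum(axis=0))
        np.testing.assert_allclose(outd, A.sum(axis=1))
        assert ind.sum() == pytest.approx(outd.sum())

    def test_nonzero_diagonal_rejected(self):
        A = np.eye(3)
        with pytest.raises(ConfigurationError):
            in_out_degree(A)


class TestAUC:
    def _curve(self, values, grid=None):
        values = np.atleast_2d(np.asarray(values, float))
        if grid is None:
            grid = DensityGrid(0.2, 0.2 + 0.01 * (values.shape[1] - 1), 0.01)
        return MetricCurve("degree", values, grid)

    def test_constant_curve(self):
        auc = auc_over_densities(self._curve(np.full((3, 41), 2.5)))
        np.testing.assert_allclose(auc.values, 41 * 2.5)

    def test_single_grid_point(self):
        auc = auc_over_densities(self._curve([[7.0]]))
        assert auc.values[0] == 7.0

    def test_linear_ramp(self):
        auc = auc_over_densities(self._curve([np.linspace(0, 1, 5)]))
        assert auc.values[0] == pytest.approx(2.5)

    def test_linearity_difference_of_aucs(self, rng):
        a = rng.standard_normal((6, 10))
        b = rng.standard_normal((6, 10))
        auc_a = auc_over_densities(self._curve(a)).values
        auc_b = auc_over_densities(self._curve(b)).values
        auc_diff = auc_over_densities(self._curve(a - b)).values
        # identical up to float summation order (mathematically exact)
        np.testing.assert_allclose(auc_diff, auc_a - auc_b, rtol=0, atol=1e-12)

    def test_degree_auc_monotone_in_grid_upper_bound(self, rng):
        from scnet.covariance import CovarianceGraph, density_sweep

        W = random_symmetric(rng, 12, density=1.0)
        g = CovarianceGraph(W, False, ("CT", "CT"), "G", 1.0)
        short = DensityGrid(0.2, 0.4, 0.05)
        long = DensityGrid(0.2, 0.6, 0.05)
        auc_s = auc_over_densities(
            metric_curve(density_sweep(g, short), "degree", short)
        ).values
        auc_l = auc_over_densities(
            metric_curve(density_sweep(g, long), "degree", long)
        ).values
        assert np.all(auc_l >= auc_s)
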