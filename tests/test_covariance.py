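import itertools

import numpy as np
import pytest

from scnet import (
    DensityGrid,
    MorphometricMatrix,
    cross_correlation_matrix,
    cross_property_covariance,
    density_sweep,
    is_fully_connected,
    structural_covariance,
    threshold_to_density,
)
from scnet.covariance import sorted_positive_edges
from scnet.errors import (
    AlignmentError,
    ConfigurationError,
    DensityInfeasibleError,
    ZeroVarianceRegionError,
)

from conftest import random_symmetric


def _mm(values, prop="CT", group="G", subjects=None):
    return MorphometricMatrix(np.asarray(values, float), group, prop, subject_ids=subjects or [])


def _brute_pearson(x, y):
    x = np.asarray(x, float) - np.mean(x)
    y = np.asarray(y, float) - np.mean(y)
    return float(x @ y / np.sqrt((x @ x) * (y @ y)))


class TestStructuralCovariance:
    def test_identical_columns_give_unit_weight(self):
        mm = _mm([[1, 1, 5], [2, 2, 1], [3, 3, 2]])
        g = structural_covariance(mm)
        assert g.weights[0, 1] == pytest.approx(1.0)
        assert not g.directed
        assert np.all(np.diag(g.weights) == 0.0)

    def test_small_worked_example(self):
        # columns (1,2,3) and (1,2,4): r = 3 / sqrt(2 * 14/3) = 0.9820
        mm = _mm([[1, 1], [2, 2], [3, 4]])
        g = structural_covariance(mm)
        assert g.weights[0, 1] == pytest.approx(0.982, abs=5e-4)
        assert g.weights[0, 1] == pytest.approx(_brute_pearson([1, 2, 3], [1, 2, 4]))

    def test_negative_edges_are_excluded(self):
        mm = _mm([[1, 3], [2, 2], [3, 1]])  # exactly anticorrelated
        g = structural_covariance(mm)
        assert g.weights[0, 1] == 0.0
        assert g.retained_fraction == 0.0

    def test_retained_fraction_counts_positive_pairs(self, rng):
        X = rng.standard_normal((30, 8))
        g = structural_covariance(_mm(X))
        iu = np.triu_indices(8, 1)
        R = np.corrcoef(X.T)
        assert g.retained_fraction == pytest.approx(np.mean(R[iu] > 0))

    def test_zero_variance_region_is_named(self):
        mm = _mm([[1, 5], [2, 5], [3, 5]])
        with pytest.raises(ZeroVarianceRegionError) as exc:
            structural_covariance(mm)
        assert "r0001" in str(exc.value)

    def test_subject_permutation_invariance(self, rng):
        X = rng.standard_normal((20, 6))
        g1 = structural_covariance(_mm(X))
        perm = rng.permutation(20)
        g2 = structural_covariance(_mm(X[perm]))
        np.testing.assert_allclose(g1.weights, g2.weights, atol=1e-12)
        assert g1.retained_fraction == g2.retained_fraction


class TestCrossPropertyCovariance:
    def test_self_pair_degenerate_case(self, rng):
        X = rng.standard_normal((15, 5))
        subj = [f"s{i}" for i in range(15)]
        m1 = _mm(X, "CT", subjects=subj)
        m2 = _mm(X.copy(), "MC", subjects=subj)
        raw = cross_correlation_matrix(m1, m2)
        np.testing.assert_allclose(raw, raw.T, atol=1e-12)
        np.testing.assert_allclose(np.diag(raw), 1.0)
        g = cross_property_covariance(m1, m2)
        assert np.all(np.diag(g.weights) == 0.0)
        assert g.directed

    def test_transpose_identity_before_zeroing(self, rng):
        subj = [f"s{i}" for i in range(12)]
        m1 = _mm(rng.standard_normal((12, 6)), "CT", subjects=subj)
        m2 = _mm(rng.standard_normal((12, 6)), "MC", subjects=subj)
        a = cross_correlation_matrix(m1, m2)
        b = cross_correlation_matrix(m2, m1)
        np.testing.assert_allclose(a, b.T, atol=1e-12)

    def test_brute_force_oracle_3x3(self, rng):
        subj = [f"s{i}" for i in range(4)]
        X1 = rng.standard_normal((4, 3))
        X2 = rng.standard_normal((4, 3))
        m1 = _mm(X1, "CT", subjects=subj)
        m2 = _mm(X2, "MC", subjects=subj)
        raw = cross_correlation_matrix(m1, m2)
        for i in range(3):
            for j in range(3):
                assert raw[i, j] == pytest.approx(
                    _brute_pearson(X1[:, i], X2[:, j]), abs=1e-12
                )

    def test_misaligned_subjects_raise(self, rng):
        m1 = _mm(rng.standard_normal((5, 3)), "CT", subjects=["a", "b", "c", "d", "e"])
        m2 = _mm(rng.standard_normal((5, 3)), "MC", subjects=["a", "b", "c", "e", "d"])
        with pytest.raises(AlignmentError):
            cross_property_covariance(m1, m2)


class TestThresholdToDensity:
    def _graph(self, W, directed=False):
        from scnet.covariance import CovarianceGraph

        return CovarianceGraph(
            weights=np.asarray(W, float),
            directed=directed,
            property_pair=("CT", "CT") if not directed else ("CT", "MC"),
            group="G",
            retained_fraction=1.0,
        )

    def test_top_k_selection(self):
        W = np.zeros((4, 4))
        vals = {(0, 1): 0.9, (0, 2): 0.8, (0, 3): 0.7, (1, 2): 0.6, (1, 3): 0.5, (2, 3): 0.4}
        for (i, j), v in vals.items():
            W[i, j] = W[j, i] = v
        A = threshold_to_density(self._graph(W), 0.5)
        assert (np.triu(A, 1) > 0).sum() == 3
        assert set(np.round(A[A > 0], 6)) == {0.9, 0.8, 0.7}

    def test_full_density_identity(self, rng):
        W = random_symmetric(rng, 6, density=1.0)
        A = threshold_to_density(self._graph(W), 1.0)
        np.testing.assert_allclose(A, W)

    def test_exact_edge_count(self, rng):
        for directed in (False, True):
            n = 9
            W = np.abs(rng.standard_normal((n, n)))
            if not directed:
                W = (W + W.T) / 2
            np.fill_diagonal(W, 0.0)
            g = self._graph(W, directed)
            for rho in (0.2, 0.35, 0.6):
                A = threshold_to_density(g, rho)
                count = (A > 0).sum() if directed else (np.triu(A, 1) > 0).sum()
                assert count == int(np.floor(rho * g.e_max + 0.5))

    def test_tie_determinism(self):
        W = np.zeros((5, 5))
        # many tied weights at the cut
        for i, j in itertools.combinations(range(5), 2):
            W[i, j] = W[j, i] = 0.5
        W[0, 1] = W[1, 0] = 0.9
        g = self._graph(W)
        A1 = threshold_to_density(g, 0.4)
        A2 = threshold_to_density(g, 0.4)
        np.testing.assert_array_equal(A1, A2)
        # deterministic tie-break: descending weight then ascending (row, col)
        i_idx, j_idx, w = sorted_positive_edges(W, directed=False)
        assert (i_idx[0], j_idx[0]) == (0, 1)
        kept = list(zip(i_idx[:4], j_idx[:4]))
        assert kept == [(0, 1), (0, 2), (0, 3), (0, 4)]

    def test_infeasible_density_names_maximum(self):
        W = np.zeros((4, 4))
        W[0, 1] = W[1, 0] = 0.5
        g = self._graph(W)
        with pytest.raises(DensityInfeasibleError) as exc:
            threshold_to_density(g, 0.9)
        assert exc.value.max_density == pytest.approx(1 / 6)

    def test_invalid_density(self):
        with pytest.raises(ConfigurationError):
            threshold_to_density(self._graph(np.zeros((3, 3))), 0.0)


class TestDensitySweep:
    def _graph(self, W, directed=False):
        from scnet.covariance import CovarianceGraph

        return CovarianceGraph(W, directed, ("CT", "CT"), "G", 1.0)

    def test_default_grid_has_41_points(self, rng):
        W = np.abs(np.corrcoef(rng.standard_normal((10, 40))))
        np.fill_diagonal(W, 0.0)
        sweep = density_sweep(self._graph(W), DensityGrid())
        assert len(sweep) == 41

    def test_nestedness_and_topk_oracle(self, rng):
        grid = DensityGrid(0.2, 0.6, 0.05)
        for _ in range(10):
            W = random_symmetric(rng, 20, density=1.0)
            g = self._graph(W)
            sweep = density_sweep(g, grid)
            prev = None
            for rho, A in zip(grid.rhos, sweep):
                edges = set(zip(*np.where(np.triu(A, 1) > 0)))
                k = int(np.floor(rho * g.e_max + 0.5))
                assert len(edges) == k
                # brute-force top-k by full sort
                iu = np.triu_indices(20, 1)
                order = np.argsort(-W[iu], kind="stable")
                expect_w = np.sort(W[iu][order[:k]])
                np.testing.assert_allclose(np.sort(A[iu][A[iu] > 0]), expect_w)
                if prev is not None:
                    assert prev <= edges
                prev = edges


class TestConnectivity:
    def test_path_graph_connected(self):
        A = np.diag(np.ones(4), 1)
        A = A + A.T
        assert is_fully_connected(A)

    def test_disjoint_triangles_disconnected(self):
        A = np.zeros((6, 6))
        for i, j in [(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5)]:
            A[i, j] = A[j, i] = 1.0
        assert not is_fully_connected(A)

    def test_matches_boolean_powering_oracle(self, rng):
        for _ in range(20):
            A = random_symmetric(rng, 10, density=0.2)
            B = (A > 0).astype(int) + np.eye(10, dtype=int)
            reach = np.linalg.matrix_power(B, 10) > 0
            assert is_fully_connected(A) == bool(reach.all())


class TestDensityGrid:
    def test_validation(self):
        with pytest.raises(ConfigurationError):
            DensityGrid(0.0, 0.6, 0.01)
        with pytest.raises(ConfigurationError):
            DensityGrid(0.2, 0.6, 0.07)  # step does not divide the range
        grid = DensityGrid(0.2, 0.6, 0.01)
        assert len(grid) == 41
        assert grid.rhos[0] == pytest.approx(0.2)
        assert grid.rhos[-1] == pytest.approx(0.6)
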