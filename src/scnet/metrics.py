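"""Per-region weighted graph metrics and their AUC-over-density reduction.

Same-property (symmetric) graphs are summarized per region by weighted
degree (sum of incident edge weights), the Onnela weighted clustering
coefficient (geometric mean of triangle weights, on weights rescaled by the
graph maximum), and eigenvector centrality (leading eigenvector of the
adjacency, nonnegative, unit Euclidean norm).  Directed cross-property
graphs are summarized by in-degree (column sums) and out-degree (row
sums).

Each metric is computed at every density of the sweep, and the curve is
reduced to its area under the curve (AUC) — here the plain sum of the
metric values over the grid points, which makes the AUC of a difference of
curves exactly the difference of the curves' AUCs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import eigh
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .covariance import DensityGrid
from .errors import ConfigurationError, DisconnectedGraphError

SAME_PROPERTY_METRICS = ("degree", "clustering", "eigencentrality")
CROSS_PROPERTY_METRICS = ("in_degree", "out_degree")


@dataclass
class MetricCurve:
    """Per-region values of one metric across the density grid."""

    metric: str
    values: np.ndarray  # regions x grid points
    grid: DensityGrid
    group: str = ""
    subcase: str = ""
    region_ids: list[str] | None = None


@dataclass
class AUCTable:
    """Per-region AUC of one metric curve."""

    values: np.ndarray  # regions
    metric: str
    group: str = ""
    subcase: str = ""
    grid: DensityGrid | None = None
    region_ids: list[str] | None = None


def _require_symmetric(A: np.ndarray) -> None:
    if not np.allclose(A, A.T, atol=1e-12):
        raise ConfigurationError(
            "adjacency must be symmetric; use in_out_degree for directed graphs"
        )


def weighted_degree(adjacency: np.ndarray) -> np.ndarray:
    """Sum of incident edge weights per node (symmetric graphs)."""
    A = np.asarray(adjacency, dtype=float)
    _require_symmetric(A)
    return A.sum(axis=1)


def _clustering_fast(A: np.ndarray, rescale: bool = True) -> np.ndarray:
    if A.max() <= 0.0:
        return np.zeros(A.shape[0])
    W = A / A.max() if rescale else A
    W13 = np.cbrt(W)
    cyc3 = ((W13 @ W13) * W13).sum(axis=1)  # diag(W13^3)
    k = (A > 0.0).sum(axis=1).astype(float)
    denom = k * (k - 1.0)
    out = np.zeros(A.shape[0])
    ok = denom > 0.0
    out[ok] = cyc3[ok] / denom[ok]
    return out


def clustering_coefficient(adjacency: np.ndarray, rescale: bool = True) -> np.ndarray:
    """Onnela weighted clustering coefficient.

    C_i = sum_{j,h} (w_ij w_ih w_jh)^(1/3) / (k_i (k_i - 1)) with k_i the
    number of neighbors; weights are first rescaled by the maximum weight of
    the graph.  Nodes with fewer than two neighbors get 0.
    """
    A = np.asarray(adjacency, dtype=float)
    _require_symmetric(A)
    return _clustering_fast(A, rescale=rescale)


def _leading_eigenvector(A: np.ndarray) -> np.ndarray:
    P = A.shape[0]
    if P == 1:
        return np.zeros(1) if A[0, 0] == 0.0 else np.ones(1)
    _, vec = eigh(A, subset_by_index=[P - 1, P - 1])
    v = vec[:, 0]
    if v.sum() < 0.0:
        v = -v
    # Perron vector of a connected nonnegative matrix; clip tiny negatives
    v = np.clip(v, 0.0, None)
    n = np.linalg.norm(v)
    return v / n if n > 0 else v


def eigenvector_centrality(
    adjacency: np.ndarray, on_disconnected: str = "raise"
) -> np.ndarray:
    """Leading-eigenvector centrality, nonnegative, unit Euclidean norm.

    For a connected graph the Perron-Frobenius theorem makes this unique.
    On a disconnected graph, ``on_disconnected="raise"`` errors (the
    centrality is not unique), while ``"components"`` computes the leading
    eigenvector within each connected component (unit norm per component,
    isolated nodes get 0) and concatenates — used for permuted graphs so
    that degenerate null realizations are not silently discarded.
    """
    A = np.asarray(adjacency, dtype=float)
    _require_symmetric(A)
    n_comp, labels = connected_components(csr_matrix(A > 0.0), directed=False)
    if n_comp == 1:
        return _leading_eigenvector(A)
    if on_disconnected == "raise":
        raise DisconnectedGraphError(
            f"graph has {n_comp} connected components; eigenvector centrality "
            "is not unique"
        )
    if on_disconnected != "components":
        raise ConfigurationError("on_disconnected must be 'raise' or 'components'")
    out = np.zeros(A.shape[0])
    for c in range(n_comp):
        idx = np.flatnonzero(labels == c)
        if idx.size == 1:
            continue
        out[idx] = _leading_eigenvector(A[np.ix_(idx, idx)])
    return out


def in_out_degree(adjacency: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(in-degree, out-degree) = (column sums, row sums) of a directed adjacency.

    In-degree at region j measures how strongly the second property there
    depends on the first property elsewhere; out-degree the converse.  The
    diagonal must be zero (self-loops are excluded by construction).
    """
    A = np.asarray(adjacency, dtype=float)
    if A.shape[0] != A.shape[1]:
        raise ConfigurationError("adjacency must be square")
    if np.any(np.diag(A) != 0.0):
        raise ConfigurationError("directed adjacency must have a zero diagonal")
    return A.sum(axis=0), A.sum(axis=1)


def metric_curve(
    adjacencies: list[np.ndarray],
    metric: str,
    grid: DensityGrid,
    on_disconnected: str = "raise",
    **meta,
) -> MetricCurve:
    """Evaluate one metric over a density sweep's adjacencies."""
    cols = []
    for A in adjacencies:
        if metric == "degree":
            cols.append(weighted_degree(A))
        elif metric == "clustering":
            cols.append(clustering_coefficient(A))
        elif metric == "eigencentrality":
            cols.append(eigenvector_centrality(A, on_disconnected=on_disconnected))
        elif metric == "in_degree":
            cols.append(in_out_degree(A)[0])
        elif metric == "out_degree":
            cols.append(in_out_degree(A)[1])
        else:
            raise ConfigurationError(f"unknown metric {metric!r}")
    return MetricCurve(metric=metric, values=np.column_stack(cols), grid=grid, **meta)


def auc_over_densities(curve: MetricCurve) -> AUCTable:
    """Reduce a metric curve to its per-region AUC: the sum over grid points.

    The sum (rather than a trapezoid) makes the reduction linear, so the
    AUC of a between-group difference curve equals the difference of the
    groups' AUCs exactly.
    """
    if curve.values.ndim != 2 or curve.values.shape[1] < 1:
        raise ConfigurationError("curve needs at least one grid point")
    return AUCTable(
        values=curve.values.sum(axis=1),
        metric=curve.metric,
        group=curve.group,
        subcase=curve.subcase,
        grid=curve.grid,
        region_ids=curve.region_ids,
    )
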