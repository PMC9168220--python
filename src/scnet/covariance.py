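"""Structural covariance graphs and density thresholding.

A same-property structural covariance graph has one node per region; the
edge weight between regions i and j is the Pearson correlation, across the
subjects of one group, of the (residualized) morphometric values in the two
regions.  Negative correlations are excluded (set to zero) so the weighted
graph-theoretical machinery applies, and the diagonal is zero.

A cross-property covariance graph correlates property m1 in region i with
property m2 in region j; the matrix is not symmetric, so the graph is
directed, with self-loops (the diagonal) removed before the negative-edge
exclusion.

Graphs are analyzed over a sweep of edge densities: at density rho the
round(rho * E_max) strongest positive edges are kept with their weights
(E_max = P(P-1)/2 undirected, P(P-1) directed).  Ties at the cut are broken
by descending weight then ascending (row, column) index, which makes the
sweep fully deterministic and its edge sets nested across densities.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .errors import (
    AlignmentError,
    ConfigurationError,
    DensityInfeasibleError,
    ZeroVarianceRegionError,
)
from .residualize import MorphometricMatrix


@dataclass(frozen=True)
class DensityGrid:
    """Evenly spaced density grid, 20%..60% in 1% steps by default."""

    rho_min: float = 0.20
    rho_max: float = 0.60
    step: float = 0.01

    def __post_init__(self):
        if not 0.0 < self.rho_min <= self.rho_max < 1.0:
            raise ConfigurationError("need 0 < rho_min <= rho_max < 1")
        if self.step <= 0:
            raise ConfigurationError("step must be positive")
        n = round((self.rho_max - self.rho_min) / self.step)
        if abs(self.rho_min + n * self.step - self.rho_max) > 1e-9:
            raise ConfigurationError("step must divide rho_max - rho_min")

    @property
    def rhos(self) -> np.ndarray:
        n = round((self.rho_max - self.rho_min) / self.step)
        return self.rho_min + self.step * np.arange(n + 1)

    def __len__(self) -> int:
        return len(self.rhos)


@dataclass
class CovarianceGraph:
    """A group-level weighted covariance graph (symmetric or directed)."""

    weights: np.ndarray
    directed: bool
    property_pair: tuple[str, str]
    group: str
    retained_fraction: float
    region_ids: list[str] = field(default_factory=list)

    @property
    def n_regions(self) -> int:
        return self.weights.shape[0]

    @property
    def e_max(self) -> int:
        P = self.n_regions
        return P * (P - 1) if self.directed else P * (P - 1) // 2


def _standardize_columns(mm: MorphometricMatrix) -> np.ndarray:
    """Z-score columns across subjects; name the region if variance is zero."""
    X = mm.values
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    bad = np.flatnonzero(sd == 0.0)
    if bad.size:
        raise ZeroVarianceRegionError(mm.region_ids[bad[0]])
    return (X - mu) / sd


def structural_covariance(mm: MorphometricMatrix) -> CovarianceGraph:
    """Same-property covariance graph: pairwise Pearson correlations.

    Negative edges are set to zero, the diagonal is zero, and
    ``retained_fraction`` records the share of unordered region pairs whose
    edge survived the negative-edge exclusion.
    """
    if mm.n_subjects < 3:
        raise ConfigurationError("need at least 3 subjects for covariance")
    Z = _standardize_columns(mm)
    W = (Z.T @ Z) / (mm.n_subjects - 1)
    W = np.clip((W + W.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(W, 0.0)
    iu = np.triu_indices(mm.n_regions, k=1)
    retained = float(np.mean(W[iu] > 0.0))
    W[W < 0.0] = 0.0
    return CovarianceGraph(
        weights=W,
        directed=False,
        property_pair=(mm.property, mm.property),
        group=mm.group,
        retained_fraction=retained,
        region_ids=list(mm.region_ids),
    )


def cross_correlation_matrix(m1: MorphometricMatrix, m2: MorphometricMatrix) -> np.ndarray:
    """Raw cross-property correlation matrix, before diagonal/negative zeroing.

    Entry (i, j) correlates property m1 in region i with property m2 in
    region j across the (aligned) subjects.  Satisfies the transpose
    identity cross(m1, m2) == cross(m2, m1).T exactly.
    """
    if m1.subject_ids != m2.subject_ids:
        raise AlignmentError(
            f"subject ids of {m1.property} and {m2.property} tables do not match"
        )
    if m1.n_regions != m2.n_regions:
        raise AlignmentError("cross-property tables must cover the same regions")
    if m1.n_subjects < 3:
        raise ConfigurationError("need at least 3 subjects for covariance")
    Z1 = _standardize_columns(m1)
    Z2 = _standardize_columns(m2)
    return np.clip((Z1.T @ Z2) / (m1.n_subjects - 1), -1.0, 1.0)


def cross_property_covariance(
    m1: MorphometricMatrix, m2: MorphometricMatrix
) -> CovarianceGraph:
    """Directed cross-property covariance graph over the cortical regions.

    Diagonal entries (self-pairs) are forced to zero to exclude self-loops,
    then negative edges are excluded.  ``retained_fraction`` counts ordered
    off-diagonal pairs with positive weight.
    """
    W = cross_correlation_matrix(m1, m2)
    np.fill_diagonal(W, 0.0)
    P = W.shape[0]
    off = ~np.eye(P, dtype=bool)
    retained = float(np.mean(W[off] > 0.0))
    W = W.copy()
    W[W < 0.0] = 0.0
    return CovarianceGraph(
        weights=W,
        directed=True,
        property_pair=(m1.property, m2.property),
        group=m1.group,
        retained_fraction=retained,
        region_ids=list(m1.region_ids),
    )


def sorted_positive_edges(
    weights: np.ndarray, directed: bool
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Positive off-diagonal edges sorted by (weight desc, row asc, col asc)."""
    P = weights.shape[0]
    if directed:
        i_idx, j_idx = np.where(~np.eye(P, dtype=bool))
    else:
        i_idx, j_idx = np.triu_indices(P, k=1)
    w = weights[i_idx, j_idx]
    pos = w > 0.0
    i_idx, j_idx, w = i_idx[pos], j_idx[pos], w[pos]
    order = np.lexsort((j_idx, i_idx, -w))
    return i_idx[order], j_idx[order], w[order]


def _edge_count(rho: float, e_max: int) -> int:
    # round-half-up keeps the count deterministic across platforms
    return int(np.floor(rho * e_max + 0.5))


def threshold_to_density(g: CovarianceGraph, rho: float) -> np.ndarray:
    """Weighted adjacency keeping the round(rho * E_max) strongest edges.

    Surviving edges keep their weights.  Raises
    :class:`DensityInfeasibleError` (naming the maximum feasible density)
    when the graph has fewer positive edges than requested — the reason a
    density sweep over correlation graphs cannot extend arbitrarily high.
    """
    if not 0.0 < rho <= 1.0:
        raise ConfigurationError("density must be in (0, 1]")
    i_idx, j_idx, w = sorted_positive_edges(g.weights, g.directed)
    k = _edge_count(rho, g.e_max)
    if k > w.size:
        raise DensityInfeasibleError(rho, w.size / g.e_max)
    A = np.zeros_like(g.weights)
    A[i_idx[:k], j_idx[:k]] = w[:k]
    if not g.directed:
        A[j_idx[:k], i_idx[:k]] = w[:k]
    return A


def density_sweep(g: CovarianceGraph, grid: DensityGrid) -> list[np.ndarray]:
    """One thresholded adjacency per grid density, with nested edge sets."""
    i_idx, j_idx, w = sorted_positive_edges(g.weights, g.directed)
    ks = [_edge_count(rho, g.e_max) for rho in grid.rhos]
    if ks and ks[-1] > w.size:
        raise DensityInfeasibleError(grid.rho_max, w.size / g.e_max)
    out = []
    A = np.zeros_like(g.weights)
    prev = 0
    for k in ks:
        sl = slice(prev, k)
        A[i_idx[sl], j_idx[sl]] = w[sl]
        if not g.directed:
            A[j_idx[sl], i_idx[sl]] = w[sl]
        prev = k
        out.append(A.copy())
    return out


def is_fully_connected(adjacency: np.ndarray, directed: bool = False) -> bool:
    """True iff one (weakly, for directed) connected component spans all nodes."""
    A = np.asarray(adjacency)
    if A.shape[0] != A.shape[1]:
        raise ConfigurationError("adjacency must be square")
    n, _ = connected_components(
        csr_matrix(A > 0.0), directed=directed, connection="weak"
    )
    return n == 1
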