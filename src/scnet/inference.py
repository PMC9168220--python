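"""Group contrasts of AUC metrics with permutation nulls and FDR control.

For each *subcase* — a (morphometric property, graph metric) combination
for same-property graphs, or a (property pair, in/out-degree) combination
for directed cross-property graphs; 15 subcases in the full analysis — the
observed statistic is the per-region difference in metric AUC between two
groups.  Its null distribution is built by randomly reshuffling subjects
across the two groups (preserving group sizes) and rerunning the entire
chain from the covariance computation onward.  Two-sided add-one
permutation p-values are corrected with the Benjamini-Hochberg step-up
procedure, by default pooling all regions and subcases of one contrast.

Permutations shuffle residualized rows; the confound regression is not
re-fitted per permutation (it is a preprocessing step performed on the
observed group labels).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .covariance import (
    DensityGrid,
    _edge_count,
    is_fully_connected,
    sorted_positive_edges,
)
from .errors import (
    ConfigurationError,
    DensityInfeasibleError,
    DisconnectedGraphError,
    ZeroVarianceRegionError,
)
from .metrics import (
    CROSS_PROPERTY_METRICS,
    SAME_PROPERTY_METRICS,
    _clustering_fast,
    _leading_eigenvector,
    eigenvector_centrality,
)

logger = logging.getLogger(__name__)

ALPHA1 = 0.01
ALPHA2 = 0.001


@dataclass(frozen=True)
class Subcase:
    """One (property or property pair, metric) analysis branch."""

    kind: str  # "same" | "cross"
    key: str | tuple[str, str]
    metric: str

    def __post_init__(self):
        if self.kind not in ("same", "cross"):
            raise ConfigurationError("subcase kind must be 'same' or 'cross'")
        if self.kind == "same" and self.metric not in SAME_PROPERTY_METRICS:
            raise ConfigurationError(f"{self.metric!r} is not a same-property metric")
        if self.kind == "cross":
            if self.metric not in CROSS_PROPERTY_METRICS:
                raise ConfigurationError(f"{self.metric!r} is not a cross-property metric")
            object.__setattr__(self, "key", tuple(self.key))

    @property
    def label(self) -> str:
        if self.kind == "same":
            return f"{self.key}.{self.metric}"
        return f"{self.key[0]}-{self.key[1]}.{self.metric}"

    @property
    def property_label(self) -> str:
        if self.kind == "same":
            return str(self.key)
        return f"{self.key[0]}->{self.key[1]}"


def _pair_list(cross: dict) -> list[tuple[str, str]]:
    """Ordered property pairs available in a cross-table dict."""
    props = [p for p in ("CT", "SA", "MC") if p in cross]
    return [(a, b) for i, a in enumerate(props) for b in props[i + 1 :]]


def enumerate_subcases(
    properties=("CT", "SA", "MC"),
    pairs=(("CT", "SA"), ("CT", "MC"), ("SA", "MC")),
    same_metrics=SAME_PROPERTY_METRICS,
    cross_metrics=CROSS_PROPERTY_METRICS,
) -> list[Subcase]:
    """The full subcase enumeration: 3x3 same-property + 3x2 cross-property."""
    out = [Subcase("same", p, m) for p in properties for m in same_metrics]
    out += [Subcase("cross", pair, m) for pair in pairs for m in cross_metrics]
    return out


@dataclass(frozen=True)
class ContrastSpec:
    """A two-group contrast with its permutation scheme."""

    name: str
    group_a: str
    group_b: str
    n_permutations: int = 8000
    shuffle_scheme: str = "unrestricted"  # or "paired_swap"
    seed: int = 0

    def __post_init__(self):
        if self.group_a == self.group_b:
            raise ConfigurationError("contrast groups must be distinct")
        if self.n_permutations < 1:
            raise ConfigurationError("need at least one permutation")
        if self.shuffle_scheme not in ("unrestricted", "paired_swap"):
            raise ConfigurationError("unknown shuffle scheme")


#: the two contrasts of the full analysis
DEFAULT_CONTRASTS = (
    ContrastSpec("HC_minus_ETpre", "HC", "ET_pre"),
    ContrastSpec("ETpost_minus_ETpre", "ET_post", "ET_pre"),
)


@dataclass
class GroupTables:
    """Residualized analysis inputs for one group.

    ``same`` maps each property to its subjects x regions residual matrix
    used for same-property graphs (cortical values plus the non-cortical
    volumes); ``cross`` maps each property to its cortical-only matrix used
    for cross-property graphs.
    """

    same: dict[str, np.ndarray]
    cross: dict[str, np.ndarray]
    same_region_ids: list[str] = field(default_factory=list)
    cross_region_ids: list[str] = field(default_factory=list)

    @property
    def n_subjects(self) -> int:
        for X in self.same.values():
            return X.shape[0]
        for X in self.cross.values():
            return X.shape[0]
        raise ConfigurationError("empty group tables")

    def subset(self, rows: np.ndarray) -> "GroupTables":
        return GroupTables(
            same={p: X[rows] for p, X in self.same.items()},
            cross={p: X[rows] for p, X in self.cross.items()},
            same_region_ids=self.same_region_ids,
            cross_region_ids=self.cross_region_ids,
        )


@dataclass
class ContrastResult:
    """Per-region AUC difference for one contrast and subcase."""

    subcase: Subcase
    contrast: str
    delta_auc: np.ndarray
    null_deltas: np.ndarray  # permutations x regions
    p: np.ndarray
    q: np.ndarray
    region_ids: list[str]
    n_permutations: int
    alpha1: float = ALPHA1
    alpha2: float = ALPHA2


class DensityEngine:
    """Computes metric AUCs over a density sweep, incrementally.

    The sweep's edge sets are nested, so the engine sorts the positive
    edges once and grows a single adjacency matrix across grid points,
    keeping degree totals incrementally and recomputing the heavier metrics
    (clustering, eigenvector centrality) per grid point.  Disconnected
    graphs (possible under permutation at low density) get per-component
    eigenvector centrality and are counted rather than discarded, which
    would bias the null; ``strict=True`` raises instead.
    """

    def __init__(self, grid: DensityGrid, strict: bool = False):
        self.grid = grid
        self.strict = strict
        self.disconnected_count = 0

    @staticmethod
    def _corr(X: np.ndarray) -> np.ndarray:
        mu = X.mean(axis=0)
        Z = X - mu
        sd = np.sqrt((Z * Z).sum(axis=0))
        bad = np.flatnonzero(sd == 0.0)
        if bad.size:
            raise ZeroVarianceRegionError(int(bad[0]))
        Z = Z / sd
        return Z.T @ Z

    def same_property_aucs(
        self, X: np.ndarray, metrics: tuple[str, ...]
    ) -> dict[str, np.ndarray]:
        """AUC per region of each requested metric on the same-property graph."""
        W = self._corr(X)
        W = (W + W.T) / 2.0
        np.fill_diagonal(W, 0.0)
        W[W < 0.0] = 0.0
        P = W.shape[0]
        e_max = P * (P - 1) // 2
        i_idx, j_idx, w = sorted_positive_edges(W, directed=False)
        ks = [_edge_count(rho, e_max) for rho in self.grid.rhos]
        if ks[-1] > w.size:
            raise DensityInfeasibleError(self.grid.rho_max, w.size / e_max)

        need_clust = "clustering" in metrics
        need_eig = "eigencentrality" in metrics
        aucs = {m: np.zeros(P) for m in metrics}
        A = np.zeros((P, P))
        deg = np.zeros(P)
        prev = 0
        connected = False
        for k in ks:
            for t in range(prev, k):
                i, j, wt = i_idx[t], j_idx[t], w[t]
                A[i, j] = wt
                A[j, i] = wt
                deg[i] += wt
                deg[j] += wt
            prev = k
            if "degree" in metrics:
                aucs["degree"] += deg
            if need_clust:
                aucs["clustering"] += _clustering_fast(A)
            if need_eig:
                if not connected:
                    connected = is_fully_connected(A)
                if connected:
                    aucs["eigencentrality"] += _leading_eigenvector(A)
                else:
                    if self.strict:
                        raise DisconnectedGraphError(
                            "graph disconnected within the density sweep (strict mode)"
                        )
                    self.disconnected_count += 1
                    aucs["eigencentrality"] += eigenvector_centrality(
                        A, on_disconnected="components"
                    )
        return aucs

    def cross_property_aucs(
        self, X1: np.ndarray, X2: np.ndarray, metrics: tuple[str, ...]
    ) -> dict[str, np.ndarray]:
        """AUC per region of in/out-degree on the directed cross-property graph."""
        Z1 = X1 - X1.mean(axis=0)
        Z2 = X2 - X2.mean(axis=0)
        sd1 = np.sqrt((Z1 * Z1).sum(axis=0))
        sd2 = np.sqrt((Z2 * Z2).sum(axis=0))
        for sd in (sd1, sd2):
            bad = np.flatnonzero(sd == 0.0)
            if bad.size:
                raise ZeroVarianceRegionError(int(bad[0]))
        W = (Z1 / sd1).T @ (Z2 / sd2)
        np.fill_diagonal(W, 0.0)
        W[W < 0.0] = 0.0
        P = W.shape[0]
        e_max = P * (P - 1)
        i_idx, j_idx, w = sorted_positive_edges(W, directed=True)
        ks = [_edge_count(rho, e_max) for rho in self.grid.rhos]
        if ks[-1] > w.size:
            raise DensityInfeasibleError(self.grid.rho_max, w.size / e_max)
        aucs = {m: np.zeros(P) for m in metrics}
        in_deg = np.zeros(P)
        out_deg = np.zeros(P)
        prev = 0
        for k in ks:
            sl = slice(prev, k)
            np.add.at(in_deg, j_idx[sl], w[sl])
            np.add.at(out_deg, i_idx[sl], w[sl])
            prev = k
            if "in_degree" in metrics:
                aucs["in_degree"] += in_deg
            if "out_degree" in metrics:
                aucs["out_degree"] += out_deg
        return aucs


def _families(subcases: list[Subcase]) -> dict[tuple, tuple[str, ...]]:
    """Group subcases sharing one graph so the sweep is computed once."""
    fam: dict[tuple, list[str]] = {}
    for sc in subcases:
        fam.setdefault((sc.kind, sc.key), []).append(sc.metric)
    return {k: tuple(v) for k, v in fam.items()}


def _group_aucs(
    engine: DensityEngine, tables: GroupTables, families: dict
) -> dict[tuple, dict[str, np.ndarray]]:
    out = {}
    for (kind, key), metrics in families.items():
        if kind == "same":
            out[(kind, key)] = engine.same_property_aucs(tables.same[key], metrics)
        else:
            m1, m2 = key
            out[(kind, key)] = engine.cross_property_aucs(
                tables.cross[m1], tables.cross[m2], metrics
            )
    return out


def observed_contrast(
    tables_a: GroupTables,
    tables_b: GroupTables,
    subcases: list[Subcase],
    grid: DensityGrid,
    strict: bool = False,
) -> dict[str, np.ndarray]:
    """Observed per-region delta AUC (group A minus group B) per subcase label."""
    engine = DensityEngine(grid, strict=strict)
    fams = _families(subcases)
    auc_a = _group_aucs(engine, tables_a, fams)
    auc_b = _group_aucs(engine, tables_b, fams)
    return {
        sc.label: auc_a[(sc.kind, sc.key)][sc.metric] - auc_b[(sc.kind, sc.key)][sc.metric]
        for sc in subcases
    }


def design_residualizer(pooled_design: np.ndarray):
    """Strict-mode transform: re-fit the confound regression per pseudo-group.

    ``pooled_design`` holds one row per pooled subject (intercept, age,
    gender, total gray-matter volume).  The returned callable residualizes a
    pseudo-group's raw rows on its own covariate rows, restoring exact
    exchangeability under the permutation null (the default mode instead
    permutes residuals fitted once on the observed groups).
    """
    D = np.asarray(pooled_design, dtype=float)

    def transform(t: GroupTables, idx: np.ndarray) -> GroupTables:
        X = D[idx]

        def res(V: np.ndarray) -> np.ndarray:
            beta, *_ = np.linalg.lstsq(X, V, rcond=None)
            return V - X @ beta

        return GroupTables(
            same={p: res(v) for p, v in t.same.items()},
            cross={p: res(v) for p, v in t.cross.items()},
            same_region_ids=t.same_region_ids,
            cross_region_ids=t.cross_region_ids,
        )

    return transform


def _pooled(tables_a: GroupTables, tables_b: GroupTables) -> GroupTables:
    return GroupTables(
        same={
            p: np.vstack([tables_a.same[p], tables_b.same[p]]) for p in tables_a.same
        },
        cross={
            p: np.vstack([tables_a.cross[p], tables_b.cross[p]]) for p in tables_a.cross
        },
        same_region_ids=tables_a.same_region_ids,
        cross_region_ids=tables_a.cross_region_ids,
    )


def _draw_assignment(
    rng: np.random.Generator, n_a: int, n_b: int, scheme: str
) -> tuple[np.ndarray, np.ndarray]:
    if scheme == "unrestricted":
        perm = rng.permutation(n_a + n_b)
        return perm[:n_a], perm[n_a:]
    # paired_swap: flip pre/post labels independently per pair
    if n_a != n_b:
        raise ConfigurationError("paired_swap requires equal group sizes")
    flips = rng.integers(0, 2, size=n_a).astype(bool)
    base = np.arange(n_a)
    idx_a = np.where(flips, base + n_a, base)
    idx_b = np.where(flips, base, base + n_a)
    return idx_a, idx_b


def permutation_null(
    tables_a: GroupTables,
    tables_b: GroupTables,
    spec: ContrastSpec,
    subcases: list[Subcase],
    grid: DensityGrid,
    assignments=None,
    max_retry: int = 10,
    transform=None,
) -> dict[str, np.ndarray]:
    """Null delta-AUC distributions by re-assigning subjects to pseudo-groups.

    Each permutation re-runs the full chain from the covariance computation
    onward on two pseudo-groups of the original sizes.  Permutations whose
    pseudo-group graphs cannot reach the top of the density grid (too few
    positive edges) are redrawn with a fresh assignment, up to ``max_retry``
    attempts each, so exactly ``n_permutations`` rows are produced; the
    retries are logged.  Passing explicit ``assignments`` (pairs of row
    index arrays into the pooled table) overrides the random scheme.
    """
    pooled = _pooled(tables_a, tables_b)
    n_a, n_b = tables_a.n_subjects, tables_b.n_subjects
    engine = DensityEngine(grid)
    fams = _families(subcases)
    rng = np.random.default_rng(spec.seed)
    n_perm = spec.n_permutations if assignments is None else len(assignments)
    null = {sc.label: np.empty((n_perm, len(_delta_len(tables_a, sc)))) for sc in subcases}
    n_infeasible = 0
    for it in range(n_perm):
        for attempt in range(max_retry):
            if assignments is not None:
                idx_a, idx_b = assignments[it]
            else:
                idx_a, idx_b = _draw_assignment(rng, n_a, n_b, spec.shuffle_scheme)
            try:
                idx_a = np.asarray(idx_a)
                idx_b = np.asarray(idx_b)
                pa = pooled.subset(idx_a)
                pb = pooled.subset(idx_b)
                if transform is not None:
                    pa = transform(pa, idx_a)
                    pb = transform(pb, idx_b)
                auc_a = _group_aucs(engine, pa, fams)
                auc_b = _group_aucs(engine, pb, fams)
                break
            except DensityInfeasibleError:
                n_infeasible += 1
                if assignments is not None or attempt == max_retry - 1:
                    raise
        for sc in subcases:
            null[sc.label][it] = (
                auc_a[(sc.kind, sc.key)][sc.metric] - auc_b[(sc.kind, sc.key)][sc.metric]
            )
    if n_infeasible:
        logger.warning("redrew %d density-infeasible permutations", n_infeasible)
    if engine.disconnected_count:
        logger.warning(
            "%d permuted graphs were disconnected at low density; eigenvector "
            "centrality was computed per component",
            engine.disconnected_count,
        )
    return null


def _delta_len(tables: GroupTables, sc: Subcase) -> np.ndarray:
    X = tables.same[sc.key] if sc.kind == "same" else tables.cross[sc.key[0]]
    return np.empty(X.shape[1])


def pvalues(delta_auc: np.ndarray, null_deltas: np.ndarray) -> np.ndarray:
    """Two-sided add-one permutation p-value per region.

    p = (1 + #{permutations with |null| >= |observed|}) / (n + 1); the
    add-one convention avoids exact zeros and is valid for any number of
    permutations.
    """
    null_deltas = np.atleast_2d(null_deltas)
    n = null_deltas.shape[0]
    exceed = (np.abs(null_deltas) >= np.abs(delta_auc)[None, :]).sum(axis=0)
    return (1.0 + exceed) / (n + 1.0)


def fdr_correct(p: np.ndarray, alpha: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values."""
    p = np.asarray(p, dtype=float)
    return multipletests(p, alpha=alpha, method="fdr_bh")[1]


def run_contrast(
    tables_a: GroupTables,
    tables_b: GroupTables,
    spec: ContrastSpec,
    grid: DensityGrid,
    subcases: list[Subcase] | None = None,
    fdr_scope: str = "pooled_across_subcases",
    transform=None,
) -> list[ContrastResult]:
    """Observed deltas, permutation null, p-values and FDR for one contrast.

    ``fdr_scope="pooled_across_subcases"`` adjusts all regions x subcases of
    the contrast jointly (the full analysis pools 9 x 87 + 6 x 68 = 1,191
    tests); ``"per_subcase"`` adjusts within each subcase separately.
    """
    if subcases is None:
        subcases = enumerate_subcases()
    if fdr_scope not in ("pooled_across_subcases", "per_subcase"):
        raise ConfigurationError("unknown FDR scope")
    obs_a, obs_b = tables_a, tables_b
    if transform is not None:
        n_a, n_b = tables_a.n_subjects, tables_b.n_subjects
        obs_a = transform(tables_a, np.arange(n_a))
        obs_b = transform(tables_b, np.arange(n_a, n_a + n_b))
    deltas = observed_contrast(obs_a, obs_b, subcases, grid)
    null = permutation_null(
        tables_a, tables_b, spec, subcases, grid, transform=transform
    )
    ps = {sc.label: pvalues(deltas[sc.label], null[sc.label]) for sc in subcases}
    if fdr_scope == "pooled_across_subcases":
        flat = np.concatenate([ps[sc.label] for sc in subcases])
        qflat = fdr_correct(flat)
        qs, pos = {}, 0
        for sc in subcases:
            k = len(ps[sc.label])
            qs[sc.label] = qflat[pos : pos + k]
            pos += k
    else:
        qs = {sc.label: fdr_correct(ps[sc.label]) for sc in subcases}
    results = []
    for sc in subcases:
        region_ids = (
            tables_a.same_region_ids if sc.kind == "same" else tables_a.cross_region_ids
        )
        if not region_ids:
            region_ids = [f"r{i:04d}" for i in range(len(deltas[sc.label]))]
        results.append(
            ContrastResult(
                subcase=sc,
                contrast=spec.name,
                delta_auc=deltas[sc.label],
                null_deltas=null[sc.label],
                p=ps[sc.label],
                q=qs[sc.label],
                region_ids=list(region_ids),
                n_permutations=spec.n_permutations,
            )
        )
    return results


def significance_tier(q: float, alpha1: float = ALPHA1, alpha2: float = ALPHA2) -> str:
    if q < alpha2:
        return "alpha2"
    if q < alpha1:
        return "alpha1"
    return "ns"


def significance_report(results: list[ContrastResult]) -> pd.DataFrame:
    """Long-format results table over every region, sorted by q.

    Columns: region, property (or directed pair), metric, contrast,
    delta_auc, p, q and the significance tier at the two alpha levels.
    """
    rows = []
    for res in results:
        for r, name in enumerate(res.region_ids):
            rows.append(
                {
                    "region": name,
                    "property": res.subcase.property_label,
                    "metric": res.subcase.metric,
                    "contrast": res.contrast,
                    "delta_auc": res.delta_auc[r],
                    "p": res.p[r],
                    "q": res.q[r],
                    "tier": significance_tier(res.q[r], res.alpha1, res.alpha2),
                }
            )
    df = pd.DataFrame(rows)
    return df.sort_values(
        ["q", "p", "contrast", "property", "metric", "region"], kind="mergesort"
    ).reset_index(drop=True)


def significant_view(report: pd.DataFrame, alpha: float = ALPHA1) -> pd.DataFrame:
    """The rows of the report with q below the given significance level."""
    return report[report["q"] < alpha].reset_index(drop=True)
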