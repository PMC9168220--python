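"""Synthetic morphometric cohort generator.

Emulates the data structure the covariance analysis assumes: three groups
(healthy controls, patients before intervention, the same patients one year
after), each described by regional cortical thickness (CT), surface area
(SA) and mean curvature (MC) over the cortical parcels plus regional volume
(VOL) over the non-cortical parcels.

The generative model is a latent-factor Gaussian model.  For subject ``s``
and region ``r`` of property ``m``::

    x[s, r] = mean_m + scale_m * ( L_m[r] . z_m[s]
                                   + confound_loadings_m[:, r] . c[s]
                                   + noise_sd * eps[s, r] )

where ``L_m`` is the property's regions x factors loading matrix, ``c[s]``
are standardized confounds (age, gender, total gray-matter volume) and
``eps`` is white Gaussian noise.  The factor vector ``z_m`` is itself a
unit-variance mixture of an own component and one shared component per
property pair::

    z_m = sqrt(g) * u_glob + w_own * u_m
          + sum over pairs (m, m') of sqrt(|gamma|) * u_{m,m'}

with ``u_glob`` a global component shared by every property including the
non-cortical volumes (emulating the brain-size/atrophy factor that couples
all morphometric measures in real data, and tying the non-cortical block
into the cortical graphs), ``g`` the ``global_coupling``, ``gamma`` the
pair's ``cross_property_coupling`` (its sign applied on the second
property's side) and ``w_own`` chosen so the total variance is one.  This
makes the population cross-property correlation of a region pair exactly
``g + gamma`` times its same-property correlation, so a coupling strong
enough for the directed graphs to support the full density sweep does not
inflate the properties' marginal covariance, and within-property graph
topology is controlled independently of the coupling weights.  Every assumption of
the downstream analysis — cross-regional correlation, cross-property
coupling, linear confound effects, paired pre/post subjects, plantable
group differences in covariance structure — is expressible as a loading
pattern, which is why the model is factor-based rather than drawing
directly from a covariance matrix.

Pre/post pairing: the latent factors of a patient's pre and post rows share
a common per-pair component so that corr(pre, post) equals
``pre_post_subject_correlation`` for every factor stream.

Planted effects multiply the common-mode component of the loadings of a
chosen region set in a chosen group only (see ``_apply_plant``): the
region's long-range coupling with the rest of the network is scaled, which
is the kind of covariance reorganization the graph contrasts detect.  A
same-property target applies the boost across every component of that
property (raising the regions' expected covariance-graph degree in that
group); a property-pair target applies it to the first property's loadings
only within that pair's shared component (raising their out-degree in the
pair's directed graph).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .atlas import RegionAtlas, homotopic_pairs, synthetic_atlas
from .errors import ConfigurationError
from .residualize import MorphometricMatrix

GROUPS = ("HC", "ET_pre", "ET_post")
CORTICAL_PROPERTIES = ("CT", "SA", "MC")
NONCORTICAL_PROPERTY = "VOL"
PROPERTIES = CORTICAL_PROPERTIES + (NONCORTICAL_PROPERTY,)
PROPERTY_PAIRS = (("CT", "SA"), ("CT", "MC"), ("SA", "MC"))

#: plausible regional means and fluctuation scales per property
#: (mm, mm^2, 1/mm, mm^3); correlations are scale-free so these are cosmetic
PROPERTY_MEANS = {"CT": 2.5, "SA": 2500.0, "MC": 0.13, "VOL": 4500.0}
PROPERTY_SCALES = {"CT": 0.15, "SA": 150.0, "MC": 0.012, "VOL": 400.0}

#: confound population parameters (age years, gender 0/1, total GM volume mm^3)
AGE_MEAN, AGE_SD, AGE_LO, AGE_HI = 70.0, 8.0, 45.0, 90.0
GMV_MEAN, GMV_SD = 600_000.0, 50_000.0


@dataclass(frozen=True)
class ConfoundBetas:
    """Linear confound effect sizes, in residual units per SD of covariate."""

    age: float = 0.0
    gender: float = 0.0
    gmv: float = 0.0

    def as_array(self) -> np.ndarray:
        return np.array([self.age, self.gender, self.gmv], dtype=float)


DEFAULT_CONFOUND_BETAS = ConfoundBetas(age=-0.3, gender=0.2, gmv=0.4)


@dataclass(frozen=True)
class PlantedEffect:
    """Multiply loadings of ``regions`` (indices into the target's frame) in one group.

    ``target`` is either a property name ("CT", "SA", "MC", "VOL") — the
    effect acts on that property's own factor loadings — or a property pair
    ("CT", "MC") — the effect acts on the first property's loadings on the
    pair's shared factor block (the out-degree side of the directed graph).
    """

    group: str
    target: str | tuple[str, str]
    regions: tuple[int, ...]
    multiplier: float

    def __post_init__(self):
        object.__setattr__(self, "regions", tuple(int(r) for r in self.regions))
        object.__setattr__(
            self,
            "target",
            self.target if isinstance(self.target, str) else tuple(self.target),
        )


@dataclass(frozen=True)
class CohortConfig:
    """Full parameterization of the synthetic cohort generator."""

    n_hc: int = 29
    n_et: int = 34
    n_cortical: int = 68
    n_noncortical: int = 19
    n_factors: int = 8
    loading_scale: float = 0.42
    loading_disp: float = 0.6
    loading_row_disp: float = 0.2
    # default coupling keeps cross-property graphs feasible over the whole
    # 20-60% density grid (enough positive-valued entries)
    cross_property_coupling: Mapping[tuple[str, str], float] = field(
        default_factory=lambda: {p: 0.1 for p in PROPERTY_PAIRS}
    )
    global_coupling: float = 0.75
    # the non-cortical volumes ride the global (brain-size-like) factor much
    # harder than the cortical surface measures do, which is what ties the
    # non-cortical block into the full-parcellation covariance graphs
    vol_global_coupling: float = 0.95
    # loading weight of the left/right homologous-pair factors; homotopic
    # covariance is a hallmark of real structural covariance
    homotopic_strength: float = 1.3
    # loading weight of the lobe-community factors; together with the
    # homotopic pairs this local structure is what keeps real covariance
    # graphs connected at the bottom of the density sweep
    cluster_strength: float = 0.7
    # stable subject-level anatomical idiosyncrasy: deviation from the group
    # factor structure that is a property of the subject's anatomy and hence
    # shared between the pre- and post-intervention scans of a patient
    subject_noise_sd: float = 0.8
    # scan/measurement noise, independent across sessions
    noise_sd: float = 0.3
    confound_betas: Mapping[str, ConfoundBetas] = field(
        default_factory=lambda: {p: DEFAULT_CONFOUND_BETAS for p in PROPERTIES}
    )
    confound_loading_disp: float = 0.3
    pre_post_subject_correlation: float = 0.9
    planted_effects: tuple[PlantedEffect, ...] = ()
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "planted_effects", tuple(self.planted_effects))
        self.validate()

    def validate(self) -> None:
        if self.n_hc < 2 or self.n_et < 2:
            raise ConfigurationError("group sizes must be >= 2")
        if self.n_cortical < 2 or self.n_noncortical < 0:
            raise ConfigurationError("need >= 2 cortical regions")
        if self.n_factors < 1:
            raise ConfigurationError("need >= 1 latent factor")
        if self.loading_scale < 0:
            raise ConfigurationError("loading_scale must be nonnegative")
        if not 0.0 <= self.loading_row_disp < 1.0:
            raise ConfigurationError("loading_row_disp must be in [0, 1)")
        if self.noise_sd <= 0:
            raise ConfigurationError("noise_sd must be positive")
        if self.subject_noise_sd < 0:
            raise ConfigurationError("subject_noise_sd must be nonnegative")
        if not 0.0 <= self.pre_post_subject_correlation <= 1.0:
            raise ConfigurationError("pre_post_subject_correlation must be in [0, 1]")
        for pair, gamma in self.cross_property_coupling.items():
            if not -1.0 <= gamma <= 1.0:
                raise ConfigurationError(f"coupling for {pair} must be in [-1, 1]")
        if not 0.0 <= self.global_coupling <= 1.0:
            raise ConfigurationError("global_coupling must be in [0, 1]")
        if not 0.0 <= self.vol_global_coupling <= 1.0:
            raise ConfigurationError("vol_global_coupling must be in [0, 1]")
        if self.homotopic_strength < 0:
            raise ConfigurationError("homotopic_strength must be nonnegative")
        if self.cluster_strength < 0:
            raise ConfigurationError("cluster_strength must be nonnegative")
        for prop in CORTICAL_PROPERTIES:
            total = self.global_coupling + sum(
                abs(g)
                for pair, g in self.cross_property_coupling.items()
                if prop in pair
            )
            if total > 1.0 + 1e-12:
                raise ConfigurationError(
                    f"global plus pair couplings involving {prop} sum to {total:.3f} "
                    "> 1; the factor mixture would need negative own variance"
                )
        for eff in self.planted_effects:
            if eff.group not in GROUPS:
                raise ConfigurationError(f"unknown planted group {eff.group!r}")
            n = self._target_size(eff.target)
            if any(not 0 <= r < n for r in eff.regions):
                raise ConfigurationError(
                    f"planted region index out of atlas bounds for target {eff.target!r}"
                )
            if eff.multiplier < 0:
                raise ConfigurationError("planted multiplier must be nonnegative")

    def _target_size(self, target) -> int:
        if target == NONCORTICAL_PROPERTY:
            return self.n_noncortical
        return self.n_cortical


@dataclass(frozen=True)
class ClinicalSummary:
    """Summary moments of one clinical score before/after intervention."""

    score_name: str
    mean_pre: float
    sd_pre: float
    n_pre: int
    mean_post: float
    sd_post: float
    n_post: int

    def __post_init__(self):
        if self.sd_pre <= 0 or self.sd_post <= 0:
            raise ConfigurationError("clinical score SDs must be positive")
        if self.n_pre < 2 or self.n_post < 2:
            raise ConfigurationError("clinical score ns must be >= 2")


#: summary moments typical of a drug-resistant ET cohort before / one year
#: after Vim thalamotomy (daily-living, head-tremor, quality-of-life and
#: treated-hand tremor scores), used as generator defaults
DEFAULT_CLINICAL_SUMMARIES = {
    "ADL": ClinicalSummary("ADL", 29.59, 11.39, 34, 6.03, 11.26, 34),
    "HEAD": ClinicalSummary("HEAD", 1.0, 0.85, 34, 0.56, 0.75, 33),
    "QUEST": ClinicalSummary("QUEST", 45.46, 16.4, 26, 23.16, 16.57, 25),
    "TSTH": ClinicalSummary("TSTH", 20.41, 5.53, 34, 6.26, 7.71, 34),
}


@dataclass
class Cohort:
    """Generated raw tables plus the subject table and atlas."""

    config: CohortConfig
    atlas: RegionAtlas
    subjects: pd.DataFrame
    tables: dict[tuple[str, str], MorphometricMatrix]

    def table(self, group: str, prop: str) -> MorphometricMatrix:
        return self.tables[(group, prop)]

    def covariates(self, group: str) -> pd.DataFrame:
        sub = self.subjects[self.subjects["group"] == group]
        return sub.set_index("subject_id")[["age", "gender", "total_gmv"]]


def _stream_keys(config: CohortConfig) -> list[str]:
    """Fixed, size-independent ordering of the random substreams.

    One global seed expands into named substreams so that e.g. enlarging a
    group or adding regions never perturbs draws in unrelated streams.
    """
    keys = []
    for prop in PROPERTIES:
        keys.append(f"load_{prop}")
        keys.append(f"confload_{prop}")
    for grp in ("HC", "ET_common", "ET_pre", "ET_post"):
        keys.append(f"globfactors_{grp}")
        keys.append(f"hglobfactors_{grp}")
        for prop in PROPERTIES:
            keys.append(f"factors_{grp}_{prop}")
            keys.append(f"hfactors_{grp}_{prop}")
        for m1, m2 in PROPERTY_PAIRS:
            keys.append(f"pairfactors_{grp}_{m1}_{m2}")
            keys.append(f"hpairfactors_{grp}_{m1}_{m2}")
    for grp in ("HC", "ET_pre"):
        keys.append(f"confounds_{grp}")
    for grp in GROUPS:
        for prop in PROPERTIES:
            keys.append(f"noise_{grp}_{prop}")
    for grp in ("HC", "ET"):
        for prop in PROPERTIES:
            keys.append(f"subjnoise_{grp}_{prop}")
    return keys


def _rngs(config: CohortConfig) -> dict[str, np.random.Generator]:
    keys = _stream_keys(config)
    children = np.random.SeedSequence(config.seed).spawn(len(keys))
    return {k: np.random.default_rng(c) for k, c in zip(keys, children)}


def _loadings(rng, n_regions: int, config: CohortConfig) -> np.ndarray:
    """(P, K) factor loadings with controlled row magnitudes.

    Row directions come from ``1 + loading_disp * N(0,1)`` draws — the
    common positive component makes cross-regional correlations
    predominantly positive, as observed for real morphometric covariance —
    and each row is then rescaled to a magnitude drawn uniformly within
    ``loading_row_disp`` of the nominal ``loading_scale`` norm.  Bounding
    row magnitudes away from zero keeps every region correlated with the
    rest of the brain, so covariance graphs stay connected at the bottom
    of the density sweep the way real ones do.
    """
    K = config.n_factors
    z = rng.standard_normal((n_regions, K))
    L = 1.0 + config.loading_disp * z
    norms = np.linalg.norm(L, axis=1, keepdims=True)
    norms[norms == 0.0] = 1.0
    target = config.loading_scale * math.sqrt(K * (1.0 + config.loading_disp**2))
    mag = target * rng.uniform(
        1.0 - config.loading_row_disp, 1.0 + config.loading_row_disp, size=(n_regions, 1)
    )
    return L / norms * mag


def _plant_multipliers(config: CohortConfig, group: str, target) -> np.ndarray:
    n = config._target_size(target)
    mult = np.ones(n)
    for eff in config.planted_effects:
        if eff.group == group and eff.target == target:
            mult[list(eff.regions)] *= eff.multiplier
    return mult


def _apply_plant(
    L: np.ndarray, S: np.ndarray, mult: np.ndarray, config: CohortConfig
) -> tuple[np.ndarray, np.ndarray]:
    """Boost planted regions' loadings on the shared covariance directions.

    The multiplier scales the common-mode component of a planted region's
    factor loadings (its projection on the all-ones direction every region
    shares).  This strengthens the region's coupling with the rest of the
    network — the covariance reorganization the graph contrasts are
    designed to detect — rather than merely rescaling the region, which
    Pearson correlation would normalize away.  The local structural
    loadings (homotopic pair, lobe community) are left untouched: the
    planted change is a gain in long-range coupling, not a louder local
    neighborhood.
    """
    if np.all(mult == 1.0):
        return L, S
    K = L.shape[1]
    u = np.ones(K) / math.sqrt(K)
    mag = np.linalg.norm(L, axis=1)
    L2 = L + np.outer((mult - 1.0) * mag, u)
    return L2, S


def _confound_values(rng, n: int, prefix: str, start: int = 1) -> pd.DataFrame:
    age = stats.truncnorm.rvs(
        (AGE_LO - AGE_MEAN) / AGE_SD,
        (AGE_HI - AGE_MEAN) / AGE_SD,
        loc=AGE_MEAN,
        scale=AGE_SD,
        size=n,
        random_state=rng,
    )
    gender = rng.integers(0, 2, size=n)
    gmv = rng.normal(GMV_MEAN, GMV_SD, size=n)
    ids = [f"{prefix}{i:03d}" for i in range(start, start + n)]
    return pd.DataFrame(
        {"subject_id": ids, "age": age, "gender": gender, "total_gmv": gmv}
    )


def _standardize_confounds(cov: pd.DataFrame) -> np.ndarray:
    """Population-standardized (n, 3) covariate matrix: age, gender, gmv."""
    age_z = (cov["age"].to_numpy() - AGE_MEAN) / AGE_SD
    gender_z = cov["gender"].to_numpy() - 0.5
    gmv_z = (cov["total_gmv"].to_numpy() - GMV_MEAN) / GMV_SD
    return np.column_stack([age_z, gender_z, gmv_z])


def _confound_loadings(rng, config: CohortConfig, prop: str, n_regions: int) -> np.ndarray:
    """(3, P) per-region confound effect profile around the property's betas."""
    betas = config.confound_betas.get(prop, ConfoundBetas()).as_array()
    jitter = 1.0 + config.confound_loading_disp * rng.standard_normal((3, n_regions))
    return betas[:, None] * jitter


def _glob_weight(config: CohortConfig, prop: str) -> float:
    g = (
        config.vol_global_coupling
        if prop == NONCORTICAL_PROPERTY
        else config.global_coupling
    )
    return math.sqrt(g)


def _own_weight(config: CohortConfig, prop: str) -> float:
    """Weight of the property's own factor component in the unit-variance mix."""
    total = _glob_weight(config, prop) ** 2 + sum(
        abs(g) for pair, g in config.cross_property_coupling.items() if prop in pair
    )
    if prop == NONCORTICAL_PROPERTY:
        total = _glob_weight(config, prop) ** 2
    return math.sqrt(max(0.0, 1.0 - total))


def _pair_weight(config: CohortConfig, pair: tuple[str, str], prop: str) -> float:
    """Weight of the pair's shared component; the sign rides on the second side."""
    gamma = config.cross_property_coupling.get(pair, 0.0)
    w = math.sqrt(abs(gamma))
    return w if prop == pair[0] else math.copysign(w, gamma)


def _paired_factors(rng_common, rng_pre, rng_post, shape, r):
    """Pre/post factor draws with corr r through a shared per-pair component."""
    common = rng_common.standard_normal(shape)
    pre = math.sqrt(r) * common + math.sqrt(1.0 - r) * rng_pre.standard_normal(shape)
    post = math.sqrt(r) * common + math.sqrt(1.0 - r) * rng_post.standard_normal(shape)
    return pre, post


def _region_clusters(
    atlas: RegionAtlas, min_size: int = 4, max_size: int = 6
) -> list[list[int]]:
    """Lobe-based region communities, split into sub-communities of 4-6.

    Small covariance communities mimic the local (sub-lobar) covariance
    structure of real morphometry; keeping them small leaves most of a
    density-thresholded graph's edge budget to long-range correlations,
    which is what holds the graph together as one component.  Lobes smaller
    than ``min_size`` are merged into the largest community of their
    (cortical / non-cortical) block.
    """
    blocks: dict[tuple[bool, str], list[int]] = {}
    for r in atlas:
        blocks.setdefault((r.cortical, r.lobe), []).append(r.region_id)
    out: list[list[int]] = []
    for cortical in (True, False):
        members = {k: sorted(v) for k, v in blocks.items() if k[0] == cortical}
        if not members:
            continue
        big = [v for v in members.values() if len(v) >= min_size]
        small = [i for v in members.values() if len(v) < min_size for i in v]
        if not big:
            big = [sorted(small)] if small else []
            small = []
        if small:
            j = int(np.argmax([len(v) for v in big]))
            big[j] = sorted(big[j] + small)
        for group in big:
            n_chunks = max(1, -(-len(group) // max_size))
            for chunk in np.array_split(np.array(group), n_chunks):
                out.append([int(i) for i in chunk])
    return sorted(out)


def _structure_loadings(
    config: CohortConfig, atlas: RegionAtlas
) -> tuple[dict[str, np.ndarray], int]:
    """Per-property (P_m, n_struct) structural loading matrices.

    Structural factors carry the local covariance features of real
    morphometry: one factor per left/right homologous region pair (loaded
    with ``homotopic_strength`` by both members) and one per lobe community
    (loaded with ``cluster_strength`` by its members).  Cortical properties
    share the cortical columns — so homotopic and lobar covariance also
    appear across properties — while the volume property uses the
    non-cortical columns.
    """
    pairs = homotopic_pairs(atlas)
    clusters = _region_clusters(atlas)
    n_struct = len(pairs) + len(clusters)
    nc = atlas.n_cortical
    S: dict[str, np.ndarray] = {}

    def build(row_of) -> np.ndarray:
        n_rows = len([r for r in atlas if row_of(r.region_id) is not None])
        M = np.zeros((n_rows, n_struct))
        for k, (i, j) in enumerate(pairs):
            for idx in (i, j):
                row = row_of(idx)
                if row is not None:
                    M[row, k] = config.homotopic_strength
        for k, cluster in enumerate(clusters):
            for idx in cluster:
                row = row_of(idx)
                if row is not None:
                    M[row, len(pairs) + k] = config.cluster_strength
        return M

    Sc = build(lambda i: i if i < nc else None)
    Sv = build(lambda i: i - nc if i >= nc else None)
    for prop in CORTICAL_PROPERTIES:
        S[prop] = Sc
    S[NONCORTICAL_PROPERTY] = Sv
    return S, n_struct


def generate_cohort(config: CohortConfig) -> Cohort:
    """Generate raw per-property tables for all three groups.

    Returns a :class:`Cohort` holding one ``MorphometricMatrix`` per
    (group, property), the subject table (group label, pairing id, age,
    gender, total gray-matter volume) and the region atlas.  Fully
    reproducible from ``config.seed``.
    """
    config.validate()
    rngs = _rngs(config)
    atlas = synthetic_atlas(config.n_cortical, config.n_noncortical)

    prop_regions = {p: atlas.cortical_names for p in CORTICAL_PROPERTIES}
    prop_regions[NONCORTICAL_PROPERTY] = atlas.noncortical_names
    prop_size = {p: len(ids) for p, ids in prop_regions.items()}

    own_load = {p: _loadings(rngs[f"load_{p}"], prop_size[p], config) for p in PROPERTIES}
    conf_load = {
        p: _confound_loadings(rngs[f"confload_{p}"], config, p, prop_size[p])
        for p in PROPERTIES
    }

    # confounds: HC independent; ET_post shares ET_pre's covariates (same
    # subjects one year later; the small age offset is irrelevant once
    # confounds are regressed out)
    sub_hc = _confound_values(rngs["confounds_HC"], config.n_hc, "HC")
    sub_hc.insert(1, "group", "HC")
    sub_hc.insert(2, "pair_id", "")
    sub_pre = _confound_values(rngs["confounds_ET_pre"], config.n_et, "ETpre")
    sub_pre.insert(1, "group", "ET_pre")
    sub_pre.insert(2, "pair_id", [f"P{i:03d}" for i in range(1, config.n_et + 1)])
    sub_post = sub_pre.copy()
    sub_post["subject_id"] = [f"ETpost{i:03d}" for i in range(1, config.n_et + 1)]
    sub_post["group"] = "ET_post"
    subjects = pd.concat([sub_hc, sub_pre, sub_post], ignore_index=True)

    sizes = {"HC": config.n_hc, "ET_pre": config.n_et, "ET_post": config.n_et}
    ids = {
        "HC": list(sub_hc["subject_id"]),
        "ET_pre": list(sub_pre["subject_id"]),
        "ET_post": list(sub_post["subject_id"]),
    }
    conf_z = {
        "HC": _standardize_confounds(sub_hc),
        "ET_pre": _standardize_confounds(sub_pre),
        "ET_post": _standardize_confounds(sub_post),
    }

    S_load, n_struct = _structure_loadings(config, atlas)
    r = config.pre_post_subject_correlation
    K = config.n_factors

    def draw(base: str, suffix: str, width: int) -> dict[str, np.ndarray]:
        """Per-group factor draws; pre/post share a common component."""
        key = lambda grp: f"{base}_{grp}{suffix}"  # noqa: E731
        out = {"HC": rngs[key("HC")].standard_normal((config.n_hc, width))}
        out["ET_pre"], out["ET_post"] = _paired_factors(
            rngs[key("ET_common")],
            rngs[key("ET_pre")],
            rngs[key("ET_post")],
            (config.n_et, width),
            r,
        )
        return out

    glob_z = draw("globfactors", "", K)
    glob_h = draw("hglobfactors", "", n_struct)
    own_z = {p: draw("factors", f"_{p}", K) for p in PROPERTIES}
    own_h = {p: draw("hfactors", f"_{p}", n_struct) for p in PROPERTIES}
    pair_z = {pr: draw("pairfactors", f"_{pr[0]}_{pr[1]}", K) for pr in PROPERTY_PAIRS}
    pair_h = {pr: draw("hpairfactors", f"_{pr[0]}_{pr[1]}", n_struct) for pr in PROPERTY_PAIRS}

    # stable anatomical idiosyncrasy: one draw per subject, shared verbatim
    # by a patient's pre and post rows
    subj_rngs = {
        (grp, prop): rngs[f"subjnoise_{grp}_{prop}"].standard_normal(
            (config.n_hc if grp == "HC" else config.n_et, prop_size[prop])
        )
        for grp in ("HC", "ET")
        for prop in PROPERTIES
    }

    tables: dict[tuple[str, str], MorphometricMatrix] = {}
    for grp in GROUPS:
        for prop in PROPERTIES:
            P = prop_size[prop]
            mult = _plant_multipliers(config, grp, prop)
            L, Hm = _apply_plant(own_load[prop], S_load[prop], mult, config)
            w_own = _own_weight(config, prop)
            w_glob = _glob_weight(config, prop)
            latent = own_z[prop][grp] @ (w_own * L).T + own_h[prop][grp] @ (w_own * Hm).T
            latent += glob_z[grp] @ (w_glob * L).T + glob_h[grp] @ (w_glob * Hm).T
            for pr in PROPERTY_PAIRS:
                if prop not in pr:
                    continue
                w = _pair_weight(config, pr, prop)
                Lp, Hp = L, Hm
                if prop == pr[0]:
                    pmult = _plant_multipliers(config, grp, pr)
                    Lp, Hp = _apply_plant(L, Hm, pmult, config)
                latent += pair_z[pr][grp] @ (w * Lp).T + pair_h[pr][grp] @ (w * Hp).T
            conf = conf_z[grp] @ conf_load[prop]
            noise = config.noise_sd * rngs[f"noise_{grp}_{prop}"].standard_normal(
                (sizes[grp], P)
            )
            subj_key = "HC" if grp == "HC" else "ET"
            subj = config.subject_noise_sd * subj_rngs[(subj_key, prop)]
            values = PROPERTY_MEANS[prop] + PROPERTY_SCALES[prop] * (
                latent + conf + subj + noise
            )
            tables[(grp, prop)] = MorphometricMatrix(
                values=values,
                group=grp,
                property=prop,
                subject_ids=list(ids[grp]),
                region_ids=list(prop_regions[prop]),
            )
    return Cohort(config=config, atlas=atlas, subjects=subjects, tables=tables)


def implied_correlation(config: CohortConfig, group: str, prop: str) -> np.ndarray:
    """Analytic cross-regional correlation matrix implied by the loadings.

    Accumulates covariance contributions from the property's own factor
    block, the shared pair blocks, the confound profile (with the exact
    variances of the standardized covariates) and the white noise, then
    normalizes to a correlation matrix.  Used to check moment convergence
    of the generator.
    """
    rngs = _rngs(config)
    atlas = synthetic_atlas(config.n_cortical, config.n_noncortical)
    S_load, _ = _structure_loadings(config, atlas)
    P = config.n_cortical if prop != NONCORTICAL_PROPERTY else config.n_noncortical
    mult = _plant_multipliers(config, group, prop)
    L, S = _apply_plant(
        _loadings(rngs[f"load_{prop}"], P, config), S_load[prop], mult, config
    )
    B = np.hstack([L, S])
    w_own = _own_weight(config, prop)
    cov = (w_own**2 + _glob_weight(config, prop) ** 2) * (B @ B.T)
    for m1, m2 in PROPERTY_PAIRS:
        if prop not in (m1, m2):
            continue
        w2 = abs(_pair_weight(config, (m1, m2), prop)) ** 2
        Bp = B
        if prop == m1:
            pmult = _plant_multipliers(config, group, (m1, m2))
            Lp, Sp = _apply_plant(L, S, pmult, config)
            Bp = np.hstack([Lp, Sp])
        cov += w2 * (Bp @ Bp.T)
    a, b = (AGE_LO - AGE_MEAN) / AGE_SD, (AGE_HI - AGE_MEAN) / AGE_SD
    conf_var = np.array([stats.truncnorm.var(a, b), 0.25, 1.0])
    B = _confound_loadings(rngs[f"confload_{prop}"], config, prop, P)
    cov += (B * conf_var[:, None]).T @ B
    cov += (config.noise_sd**2 + config.subject_noise_sd**2) * np.eye(P)
    d = np.sqrt(np.diag(cov))
    return cov / np.outer(d, d)


def generate_clinical_scores(
    summary: ClinicalSummary,
    pairing_correlation: float,
    seed: int,
    n_pairs: int | None = None,
) -> pd.DataFrame:
    """Draw per-subject pre/post clinical scores with the requested moments.

    Pre and post scores are bivariate Gaussian with the summary's means and
    SDs and the given within-pair correlation.  With correlation 1 and
    equal pre/post moments the post column is an exact copy of the pre one.
    """
    if not -1.0 <= pairing_correlation <= 1.0:
        raise ConfigurationError("pairing correlation must be in [-1, 1]")
    n = n_pairs if n_pairs is not None else min(summary.n_pre, summary.n_post)
    rng = np.random.default_rng(seed)
    z1 = rng.standard_normal(n)
    z2 = rng.standard_normal(n)
    rho = pairing_correlation
    pre = summary.mean_pre + summary.sd_pre * z1
    post = summary.mean_post + summary.sd_post * (
        rho * z1 + math.sqrt(1.0 - rho**2) * z2
    )
    return pd.DataFrame(
        {
            "subject_id": [f"P{i:03d}" for i in range(1, n + 1)],
            "score_name": summary.score_name,
            "pre": pre,
            "post": post,
        }
    )


def exchangeable_config(config: CohortConfig) -> CohortConfig:
    """The same configuration with all planted group differences removed."""
    return replace(config, planted_effects=())
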