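"""End-to-end pipeline: simulate/load -> residualize -> graphs -> AUC -> inference.

The pipeline wires the modules together for the full analysis: per-group
structural covariance graphs for each morphometric property (cortical
values plus non-cortical volumes), directed cross-property graphs over the
cortical regions, a density sweep with per-region metric AUCs, and
permutation contrasts with FDR control across all 15 subcases.  Every
source of randomness flows from the single configured seed, and a manifest
records enough to reproduce every output byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .atlas import RegionAtlas
from .cohort import (
    CORTICAL_PROPERTIES,
    GROUPS,
    NONCORTICAL_PROPERTY,
    PROPERTIES,
    Cohort,
    CohortConfig,
    ConfoundBetas,
    PlantedEffect,
    generate_cohort,
)
from .covariance import (
    DensityGrid,
    is_fully_connected,
    structural_covariance,
    threshold_to_density,
)
from .errors import ConfigurationError, DisconnectedGraphError
from .inference import (
    DEFAULT_CONTRASTS,
    ContrastSpec,
    DensityEngine,
    GroupTables,
    enumerate_subcases,
    run_contrast,
    significance_report,
    significant_view,
)
from .io import (
    ensure_dir,
    read_atlas,
    read_morphometry_table,
    read_subject_table,
    write_adjacency,
    write_atlas,
    write_morphometry_table,
    write_report,
    write_subject_table,
)
from .residualize import MorphometricMatrix, residualize

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Parameterization of a full pipeline run."""

    seed: int = 0
    out_dir: str = "scnet_out"
    cohort: CohortConfig | None = None
    data_dir: str | None = None
    grid: DensityGrid = field(default_factory=DensityGrid)
    n_permutations: int = 8000
    fdr_scope: str = "pooled_across_subcases"
    shuffle_scheme: str = "unrestricted"
    contrasts: tuple[str, ...] = ("HC_minus_ETpre", "ETpost_minus_ETpre")

    def __post_init__(self):
        if self.cohort is None and self.data_dir is None:
            self.cohort = CohortConfig(seed=self.seed)
        known = {c.name for c in DEFAULT_CONTRASTS}
        for name in self.contrasts:
            if name not in known:
                raise ConfigurationError(f"unknown contrast {name!r}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        kwargs: dict = {}
        for key in ("seed", "out_dir", "data_dir", "n_permutations", "fdr_scope", "shuffle_scheme"):
            if key in raw:
                kwargs[key] = raw[key]
        if "grid" in raw:
            kwargs["grid"] = DensityGrid(**raw["grid"])
        if "contrasts" in raw:
            kwargs["contrasts"] = tuple(raw["contrasts"])
        if "cohort" in raw:
            c = dict(raw["cohort"])
            if "planted_effects" in c:
                c["planted_effects"] = tuple(
                    PlantedEffect(
                        group=e["group"],
                        target=tuple(e["target"]) if isinstance(e["target"], list) else e["target"],
                        regions=tuple(e["regions"]),
                        multiplier=float(e["multiplier"]),
                    )
                    for e in c["planted_effects"]
                )
            if "confound_betas" in c:
                c["confound_betas"] = {
                    p: ConfoundBetas(**b) for p, b in c["confound_betas"].items()
                }
            if "cross_property_coupling" in c:
                c["cross_property_coupling"] = {
                    tuple(k.split("-")): float(v)
                    for k, v in c["cross_property_coupling"].items()
                }
            c.setdefault("seed", kwargs.get("seed", 0))
            kwargs["cohort"] = CohortConfig(**c)
        return cls(**kwargs)

    def to_jsonable(self) -> dict:
        d = {
            "seed": self.seed,
            "out_dir": self.out_dir,
            "data_dir": self.data_dir,
            "grid": asdict(self.grid),
            "n_permutations": self.n_permutations,
            "fdr_scope": self.fdr_scope,
            "shuffle_scheme": self.shuffle_scheme,
            "contrasts": list(self.contrasts),
        }
        if self.cohort is not None:
            c = asdict(self.cohort)
            c["cross_property_coupling"] = {
                "-".join(k): v for k, v in self.cohort.cross_property_coupling.items()
            }
            c["confound_betas"] = {
                p: asdict(b) for p, b in self.cohort.confound_betas.items()
            }
            d["cohort"] = c
        return d


def residualize_cohort(cohort: Cohort) -> dict[tuple[str, str], MorphometricMatrix]:
    """Residualize every (group, property) table within its own group."""
    out = {}
    for grp in GROUPS:
        cov = cohort.covariates(grp)
        for prop in PROPERTIES:
            if (grp, prop) in cohort.tables:
                out[(grp, prop)] = residualize(cohort.table(grp, prop), cov)
    return out


def build_group_tables(
    resid: dict[tuple[str, str], MorphometricMatrix], group: str
) -> GroupTables:
    """Assemble the analysis inputs for one group.

    Same-property matrices append the non-cortical volume columns to each
    cortical property (the full parcel set); cross-property matrices use
    the cortical columns only.
    """
    same: dict[str, np.ndarray] = {}
    cross: dict[str, np.ndarray] = {}
    vol = resid.get((group, NONCORTICAL_PROPERTY))
    same_ids: list[str] = []
    cross_ids: list[str] = []
    for prop in CORTICAL_PROPERTIES:
        mm = resid[(group, prop)]
        cross[prop] = mm.values
        cross_ids = list(mm.region_ids)
        if vol is not None and vol.n_regions > 0:
            same[prop] = np.hstack([mm.values, vol.values])
            same_ids = list(mm.region_ids) + list(vol.region_ids)
        else:
            same[prop] = mm.values
            same_ids = list(mm.region_ids)
    return GroupTables(
        same=same, cross=cross, same_region_ids=same_ids, cross_region_ids=cross_ids
    )


def load_cohort(data_dir) -> Cohort:
    """Load raw tables, subject table and atlas from a data directory.

    Expects ``atlas.tsv``, ``subjects.tsv`` and one ``{group}_{property}.tsv``
    morphometry table per group and property.
    """
    data_dir = Path(data_dir)
    atlas = read_atlas(data_dir / "atlas.tsv")
    subjects = read_subject_table(data_dir / "subjects.tsv")
    tables = {}
    for grp in GROUPS:
        for prop in PROPERTIES:
            path = data_dir / f"{grp}_{prop}.tsv"
            ids = (
                atlas.cortical_names
                if prop != NONCORTICAL_PROPERTY
                else atlas.noncortical_names
            )
            if not ids:
                continue
            tables[(grp, prop)] = read_morphometry_table(path, ids, grp, prop)
    return Cohort(config=None, atlas=atlas, subjects=subjects, tables=tables)


def write_cohort(cohort: Cohort, out_dir) -> None:
    out = ensure_dir(out_dir)
    write_atlas(cohort.atlas, out / "atlas.tsv")
    write_subject_table(cohort.subjects, out / "subjects.tsv")
    for (grp, prop), mm in cohort.tables.items():
        write_morphometry_table(mm, out / f"{grp}_{prop}.tsv")


def effective_grid(
    tables: dict[str, GroupTables],
    grid: DensityGrid,
    strict: bool = False,
    require_connected: bool = True,
) -> DensityGrid:
    """Choose the density range the observed graphs actually support.

    Mirrors how the range is chosen in practice: the lower bound is the
    smallest grid density at which every observed graph (same-property and
    cross-property, every group) is fully connected, and the upper bound
    the largest at which every graph still has enough positive edges.  The
    configured bounds are the starting point; they are tightened — never
    widened — when a cohort demands it, and any adjustment is logged.
    With ``strict=True`` a needed adjustment raises instead.
    """
    from .covariance import cross_property_covariance, sorted_positive_edges
    from .inference import _pair_list

    graphs = []
    for grp, t in tables.items():
        for prop, X in t.same.items():
            mm = MorphometricMatrix(X, grp, prop, region_ids=list(t.same_region_ids))
            graphs.append(structural_covariance(mm))
        for m1, m2 in _pair_list(t.cross):
            mm1 = MorphometricMatrix(t.cross[m1], grp, m1, region_ids=list(t.cross_region_ids))
            mm2 = MorphometricMatrix(t.cross[m2], grp, m2, region_ids=list(t.cross_region_ids))
            graphs.append(cross_property_covariance(mm1, mm2))

    rho_max = grid.rho_max
    for g in graphs:
        n_pos = len(sorted_positive_edges(g.weights, g.directed)[2])
        feasible = math.floor(n_pos / g.e_max / grid.step) * grid.step
        rho_max = min(rho_max, round(feasible, 10))
    rho_min = grid.rho_min
    if not require_connected:
        graphs = []
    for g in graphs:
        for rho in np.round(np.arange(rho_min, rho_max + grid.step / 2, grid.step), 10):
            if is_fully_connected(threshold_to_density(g, rho), g.directed):
                if rho > rho_min:
                    rho_min = float(rho)
                break
        else:
            raise DisconnectedGraphError(
                f"{g.group}/{'-'.join(g.property_pair)} graph is not fully "
                f"connected at any density up to {rho_max:.2f}"
            )
    if (rho_min, rho_max) != (grid.rho_min, grid.rho_max):
        msg = (
            f"density grid tightened to [{rho_min:.2f}, {rho_max:.2f}] "
            f"(configured [{grid.rho_min:.2f}, {grid.rho_max:.2f}]) to keep all "
            "observed graphs connected and density-feasible"
        )
        if strict:
            raise DisconnectedGraphError(msg)
        logger.warning(msg)
    if rho_min > rho_max:
        raise DisconnectedGraphError(
            "no density is simultaneously connected and feasible for all "
            "observed graphs"
        )
    return DensityGrid(rho_min, rho_max, grid.step)


def _contrast_seed(seed: int, name: str) -> int:
    digest = hashlib.sha256(f"{seed}:{name}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full analysis and write all artifacts to ``config.out_dir``.

    Returns a dict with the report DataFrame, the significant view, the
    per-contrast results and the manifest.  Idempotent: identical config
    and seed produce byte-identical outputs.
    """
    out = ensure_dir(config.out_dir)
    if config.data_dir is not None:
        cohort = load_cohort(config.data_dir)
    else:
        cohort = generate_cohort(config.cohort)
        write_cohort(cohort, out / "cohort")

    resid = residualize_cohort(cohort)
    resid_dir = ensure_dir(out / "residuals")
    for (grp, prop), mm in resid.items():
        write_morphometry_table(mm, resid_dir / f"{grp}_{prop}.tsv")

    tables = {grp: build_group_tables(resid, grp) for grp in GROUPS}
    grid = effective_grid(tables, config.grid)

    # per-group observed covariance graphs and retained-edge fractions
    graphs_dir = ensure_dir(out / "graphs")
    retained: dict[str, float] = {}
    for grp in GROUPS:
        for prop in CORTICAL_PROPERTIES:
            mm = MorphometricMatrix(
                tables[grp].same[prop],
                grp,
                prop,
                region_ids=list(tables[grp].same_region_ids),
            )
            g = structural_covariance(mm)
            retained[f"{grp}/{prop}"] = g.retained_fraction
            write_adjacency(g.weights, g.region_ids, graphs_dir / f"{grp}_{prop}_sc.tsv")
    with open(graphs_dir / "retained_fractions.json", "w") as fh:
        json.dump(retained, fh, indent=2, sort_keys=True)

    # observed per-group AUC tables for every subcase
    subcases = enumerate_subcases()
    engine = DensityEngine(grid)
    auc_rows = []
    fams: dict[tuple, list[str]] = {}
    for sc in subcases:
        fams.setdefault((sc.kind, sc.key), []).append(sc.metric)
    for grp in GROUPS:
        for (kind, key), mets in fams.items():
            if kind == "same":
                aucs = engine.same_property_aucs(tables[grp].same[key], tuple(mets))
                ids = tables[grp].same_region_ids
            else:
                m1, m2 = key
                aucs = engine.cross_property_aucs(
                    tables[grp].cross[m1], tables[grp].cross[m2], tuple(mets)
                )
                ids = tables[grp].cross_region_ids
            for met, vals in aucs.items():
                label = f"{key}.{met}" if kind == "same" else f"{key[0]}-{key[1]}.{met}"
                for r, name in enumerate(ids):
                    auc_rows.append(
                        {"region": name, "group": grp, "subcase": label, "auc": vals[r]}
                    )
    auc_df = pd.DataFrame(auc_rows)
    auc_df.to_csv(out / "auc_tables.tsv", sep="\t", index=False, float_format="%.12g")

    # contrasts
    all_results = []
    for cname in config.contrasts:
        base = next(c for c in DEFAULT_CONTRASTS if c.name == cname)
        spec = ContrastSpec(
            name=base.name,
            group_a=base.group_a,
            group_b=base.group_b,
            n_permutations=config.n_permutations,
            shuffle_scheme=config.shuffle_scheme,
            seed=_contrast_seed(config.seed, cname),
        )
        results = run_contrast(
            tables[spec.group_a],
            tables[spec.group_b],
            spec,
            grid,
            subcases=subcases,
            fdr_scope=config.fdr_scope,
        )
        all_results.extend(results)

    report = significance_report(all_results)
    write_report(report, out / "report.tsv")
    sig = significant_view(report)
    write_report(sig, out / "significant.tsv")

    config_json = json.dumps(config.to_jsonable(), sort_keys=True)
    manifest = {
        "scnet_version": __version__,
        "config": config.to_jsonable(),
        "config_sha256": hashlib.sha256(config_json.encode()).hexdigest(),
        "effective_grid": asdict(grid),
        "n_subcases": len(subcases),
        "retained_fractions": retained,
        "outputs": {},
        "versions": _library_versions(),
    }
    for f in sorted(out.rglob("*.tsv")):
        manifest["outputs"][str(f.relative_to(out))] = _sha256(f)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)

    return {
        "report": report,
        "significant": sig,
        "results": all_results,
        "manifest": manifest,
        "retained_fractions": retained,
        "out_dir": str(out),
    }


def _sha256(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def _library_versions() -> dict[str, str]:
    import scipy
    import statsmodels

    return {
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "pandas": pd.__version__,
        "statsmodels": statsmodels.__version__,
    }
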