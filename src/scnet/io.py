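"""Readers and writers for the pipeline's tabular text formats.

All interchange is tab-separated text with explicit headers, compatible
with regional stats tables exported from surface-reconstruction pipelines:
morphometry tables are subjects x regions (first column ``subject_id``),
the subject table carries group labels and confounds, adjacency matrices
are square tables with region names on both axes, and edge lists are
(source, target, weight) triples.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .atlas import RegionAtlas
from .errors import TableFormatError
from .residualize import MorphometricMatrix

FLOAT_FORMAT = "%.12g"


def write_morphometry_table(mm: MorphometricMatrix, path) -> None:
    mm.to_dataframe().to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)


def read_morphometry_table(
    path,
    region_ids: list[str] | RegionAtlas,
    group: str = "",
    property: str = "",
) -> MorphometricMatrix:
    """Read a subjects x regions table, aligning columns to the atlas order.

    ``region_ids`` is the expected region name list (or an atlas, whose full
    name list is used).  Column order in the file is irrelevant; missing or
    unknown region columns, duplicate subject ids and non-numeric cells are
    reported explicitly.
    """
    if isinstance(region_ids, RegionAtlas):
        region_ids = region_ids.names
    df = pd.read_csv(path, sep="\t")
    if df.columns[0] != "subject_id":
        raise TableFormatError(f"{path}: first column must be 'subject_id'")
    have = list(df.columns[1:])
    missing = [r for r in region_ids if r not in have]
    extra = [c for c in have if c not in region_ids]
    if missing or extra:
        parts = []
        if missing:
            parts.append(f"missing region column(s): {', '.join(missing)}")
        if extra:
            parts.append(f"unexpected column(s): {', '.join(extra)}")
        raise TableFormatError(f"{path}: " + "; ".join(parts))
    subjects = df["subject_id"].astype(str).tolist()
    if len(set(subjects)) != len(subjects):
        dupes = sorted({s for s in subjects if subjects.count(s) > 1})
        raise TableFormatError(f"{path}: duplicate subject id(s): {', '.join(dupes)}")
    block = df[region_ids]
    numeric = block.apply(pd.to_numeric, errors="coerce")
    if numeric.isna().to_numpy().any():
        r, c = np.argwhere(numeric.isna().to_numpy())[0]
        raise TableFormatError(
            f"{path}: non-numeric cell at row {r + 2}, column {region_ids[c]!r}"
        )
    return MorphometricMatrix(
        values=numeric.to_numpy(dtype=float),
        group=group,
        property=property,
        subject_ids=subjects,
        region_ids=list(region_ids),
    )


def write_subject_table(subjects: pd.DataFrame, path) -> None:
    subjects.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)


def read_subject_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", keep_default_na=False, dtype={"pair_id": str})
    required = {"subject_id", "group", "age", "gender", "total_gmv"}
    if not required.issubset(df.columns):
        raise TableFormatError(
            f"{path}: subject table must have columns {sorted(required)}"
        )
    return df


def write_atlas(atlas: RegionAtlas, path) -> None:
    atlas.to_dataframe().to_csv(path, sep="\t", index=False)


def read_atlas(path) -> RegionAtlas:
    return RegionAtlas.from_dataframe(pd.read_csv(path, sep="\t"))


def write_adjacency(A: np.ndarray, region_ids: list[str], path) -> None:
    df = pd.DataFrame(A, index=region_ids, columns=region_ids)
    df.to_csv(path, sep="\t", float_format=FLOAT_FORMAT, index_label="region")


def read_adjacency(path) -> tuple[np.ndarray, list[str]]:
    df = pd.read_csv(path, sep="\t", index_col="region")
    return df.to_numpy(dtype=float), list(df.columns)


def write_edge_list(
    A: np.ndarray, region_ids: list[str], path, directed: bool = False
) -> None:
    """Weighted edge list (source, target, weight); ordered pairs if directed."""
    if directed:
        i_idx, j_idx = np.where((A != 0) & ~np.eye(A.shape[0], dtype=bool))
    else:
        iu = np.triu_indices(A.shape[0], k=1)
        keep = A[iu] != 0
        i_idx, j_idx = iu[0][keep], iu[1][keep]
    df = pd.DataFrame(
        {
            "source": [region_ids[i] for i in i_idx],
            "target": [region_ids[j] for j in j_idx],
            "weight": A[i_idx, j_idx],
        }
    )
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)


def write_metric_curve(curve, path) -> None:
    """Long-format metric curve: (region, group, subcase, density, value)."""
    region_ids = curve.region_ids or [f"r{i:04d}" for i in range(curve.values.shape[0])]
    rows = []
    for gi, rho in enumerate(curve.grid.rhos):
        for ri, name in enumerate(region_ids):
            rows.append(
                {
                    "region": name,
                    "group": curve.group,
                    "subcase": curve.subcase,
                    "density": rho,
                    "value": curve.values[ri, gi],
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)


def write_auc_table(auc_values, region_ids, group, subcase, path) -> None:
    """Long-format AUC table: (region, group, subcase, auc)."""
    pd.DataFrame(
        {
            "region": region_ids,
            "group": group,
            "subcase": subcase,
            "auc": auc_values,
        }
    ).to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)


def write_report(report: pd.DataFrame, path) -> None:
    report.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
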