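"""Confound removal from regional morphometry.

Regional morphometric values carry linear effects of age, gender and total
gray-matter volume that would otherwise masquerade as cross-regional
covariance.  Before any covariance graph is built, each region's values are
replaced by ordinary-least-squares residuals on [intercept, age, gender,
total_gmv], fitted separately within each group.  Residuals then have zero
mean per region and are orthogonal to every covariate column.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import AlignmentError, ConfigurationError, DegenerateDesignError

COVARIATE_COLUMNS = ("age", "gender", "total_gmv")


@dataclass
class MorphometricMatrix:
    """One property's subjects x regions value table for one group."""

    values: np.ndarray
    group: str
    property: str
    subject_ids: list[str] = field(default_factory=list)
    region_ids: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ConfigurationError("values must be a 2-D subjects x regions array")
        if not self.subject_ids:
            self.subject_ids = [f"s{i:04d}" for i in range(self.values.shape[0])]
        if not self.region_ids:
            self.region_ids = [f"r{i:04d}" for i in range(self.values.shape[1])]
        if len(self.subject_ids) != self.values.shape[0]:
            raise ConfigurationError("subject_ids length must match row count")
        if len(self.region_ids) != self.values.shape[1]:
            raise ConfigurationError("region_ids length must match column count")
        if not np.isfinite(self.values).all():
            raise ConfigurationError("values must contain no missing/NaN entries")

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_regions(self) -> int:
        return self.values.shape[1]

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.region_ids)
        df.insert(0, "subject_id", self.subject_ids)
        return df


def _design_matrix(mm: MorphometricMatrix, covariates: pd.DataFrame) -> np.ndarray:
    """[1, age, gender, gmv] aligned to the matrix's subject rows."""
    cov = covariates
    if "subject_id" in cov.columns:
        cov = cov.set_index("subject_id")
    missing = [s for s in mm.subject_ids if s not in cov.index]
    if missing:
        raise AlignmentError(
            f"covariates missing for subject(s): {', '.join(map(str, missing[:5]))}"
        )
    cov = cov.loc[mm.subject_ids, list(COVARIATE_COLUMNS)]
    X = np.column_stack(
        [np.ones(mm.n_subjects)] + [cov[c].to_numpy(dtype=float) for c in COVARIATE_COLUMNS]
    )
    return X


def _check_design_rank(X: np.ndarray) -> None:
    names = ("intercept",) + COVARIATE_COLUMNS
    degenerate = [
        names[j] for j in range(1, X.shape[1]) if np.ptp(X[:, j]) == 0.0
    ]
    if degenerate:
        raise DegenerateDesignError(degenerate)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        # collinear but no single constant column; report non-intercept names
        raise DegenerateDesignError(
            names[1:], "degenerate confound design: covariate columns are collinear"
        )


def residualize(raw: MorphometricMatrix, covariates: pd.DataFrame) -> MorphometricMatrix:
    """OLS-residualize every region on [intercept, age, gender, total_gmv].

    The fit uses only the subjects of ``raw`` (i.e. one group): editing
    another group's rows can never change this group's residuals.
    Residualizing residuals returns them unchanged (idempotence).
    """
    X = _design_matrix(raw, covariates)
    if raw.n_subjects <= X.shape[1]:
        raise ConfigurationError(
            f"need more than {X.shape[1]} subjects to fit {X.shape[1]} coefficients"
        )
    _check_design_rank(X)
    beta, *_ = np.linalg.lstsq(X, raw.values, rcond=None)
    resid = raw.values - X @ beta
    return MorphometricMatrix(
        values=resid,
        group=raw.group,
        property=raw.property,
        subject_ids=list(raw.subject_ids),
        region_ids=list(raw.region_ids),
    )
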