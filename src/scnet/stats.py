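"""Summary-statistics helpers for clinical score tables."""

from __future__ import annotations

import math

import numpy as np
from scipy import stats as sps

from .errors import ConfigurationError


def two_sample_t_from_summary(
    mean1: float, sd1: float, n1: int, mean2: float, sd2: float, n2: int
) -> tuple[float, int, float]:
    """Pooled-variance two-sample t test from summary moments.

    Returns (t, df, two-sided p) with df = n1 + n2 - 2.  This is the
    classical equal-variance t statistic typically used to compare clinical
    scores between two groups when only means, SDs and group sizes are
    reported.
    """
    if sd1 <= 0 or sd2 <= 0:
        raise ConfigurationError("SDs must be positive")
    if n1 < 2 or n2 < 2:
        raise ConfigurationError("group sizes must be >= 2")
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / df
    se = math.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    t = (mean1 - mean2) / se
    p = 2.0 * sps.t.sf(abs(t), df)
    return float(t), int(df), float(p)


def sample_moments(x) -> tuple[float, float]:
    """(mean, SD with n-1 normalization) of a 1-D sample."""
    x = np.asarray(x, dtype=float)
    return float(x.mean()), float(x.std(ddof=1))
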