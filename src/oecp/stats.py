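"""Frequency-stability ANOVA and radius-vs-depth regression.

``anova_one_way`` tests whether extracted sensing distances differ across
measurement frequencies (the study's stability question); ``fit_linear``
quantifies the linear relationship between sensing radius and sensing depth
across test liquids.  Both are thin, validated fronts over scipy.stats;
p-values are taken from the F distribution with no multiple-testing
correction (stability is assessed per liquid and per metric).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as _st

from .errors import DegenerateVarianceError, DomainError


@dataclass(frozen=True)
class AnovaResult:
    """Classic one-way fixed-effects ANOVA outcome."""

    f_statistic: float
    p_value: float
    df_between: int
    df_within: int


@dataclass(frozen=True)
class RegressionFit:
    """Ordinary least squares fit of radius on depth."""

    slope: float
    intercept: float
    r_squared: float
    n: int


def anova_one_way(groups: Sequence[Sequence[float]]) -> AnovaResult:
    """Between/within mean-square F test across replicate groups.

    Requires at least two groups of at least two values each, and non-zero
    pooled within-group variance; identical data raise
    :class:`DegenerateVarianceError` (F would be 0/0).
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise DomainError(f"need >= 2 groups, got {len(arrays)}")
    for i, g in enumerate(arrays):
        if g.size < 2:
            raise DomainError(f"group {i} has {g.size} value(s); need >= 2")
    pooled = np.concatenate(arrays)
    ssw = sum(float(((g - g.mean()) ** 2).sum()) for g in arrays)
    if ssw == 0.0:
        if np.all(pooled == pooled[0]):
            raise DegenerateVarianceError("all observations identical; F undefined")
        raise DegenerateVarianceError("zero within-group variance; F unbounded")
    f_stat, p = _st.f_oneway(*arrays)
    k = len(arrays)
    n_total = pooled.size
    return AnovaResult(
        f_statistic=float(f_stat),
        p_value=float(p),
        df_between=k - 1,
        df_within=n_total - k,
    )


def fit_linear(depths: Sequence[float], radii: Sequence[float]) -> RegressionFit:
    """OLS of sensing radius on sensing depth; R^2 = Sxy^2 / (Sxx * Syy)."""
    x = np.asarray(depths, dtype=float)
    y = np.asarray(radii, dtype=float)
    if x.size != y.size:
        raise DomainError(f"length mismatch: {x.size} depths vs {y.size} radii")
    if x.size < 2:
        raise DomainError(f"need >= 2 points, got {x.size}")
    if np.all(x == x[0]):
        raise DegenerateVarianceError("depths are constant; slope undefined")
    res = _st.linregress(x, y)
    return RegressionFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        n=int(x.size),
    )
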