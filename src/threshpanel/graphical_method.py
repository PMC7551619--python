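"""Group threshold by the graphical (regression) method.

Individual discrimination outcomes are coded 0/1, an ordinary
least-squares line is fit against log10 concentration, and the group
threshold is the antilog of the concentration where the fitted line
crosses a chance-adjusted criterion — halfway between chance and perfect
performance, i.e. (1 + chance)/2, which for the triangle test (chance
1/3) is 2/3, the familiar "67% correct" criterion.  The estimate is
chance-adjusted by construction and does not depend on panel size.

Confidence bounds for the threshold come from inverse prediction: the
two concentrations where the pointwise (1 − α) confidence band for the
regression mean crosses the criterion.  Anosmic groups produce flat or
negative slopes; the fit is then returned with the threshold flagged
undefined rather than raising.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Collection

import numpy as np
import statsmodels.api as sm
from scipy import stats
from scipy.optimize import brentq

from threshpanel.core_data import DiscriminationDataset
from threshpanel.errors import DomainError, InsufficientDataError, UndefinedThresholdError

TRIANGLE_CHANCE = 1.0 / 3.0

#: Slopes smaller than this (proportion-correct per decade) are treated as
#: flat; any scientifically meaningful fit is orders of magnitude steeper.
_SLOPE_EPS = 1e-9


@dataclass(frozen=True)
class GraphicalFit:
    """OLS fit of 0/1 outcomes on log10 concentration, with inversion.

    ``threshold`` is ``None`` when the slope is non-positive (an anosmic
    group performs at chance across the ladder and the criterion is never
    reached).  ``flag`` carries a short diagnostic: empty for a clean
    in-range inversion, ``"undefined-slope"``, or ``"extrapolated"``
    when the crossing lies outside the tested concentration range.
    """

    slope: float
    intercept: float
    criterion: float
    threshold: float | None
    ci_lower: float | None
    ci_upper: float | None
    n_points: int
    confidence_level: float
    flag: str = ""


def criterion_for(chance: float) -> float:
    """Chance-adjusted performance criterion: halfway from chance to 1."""
    if not 0 < chance < 1:
        raise DomainError(f"chance must be in (0, 1), got {chance}")
    return (1.0 + chance) / 2.0


def invert_at(fit: GraphicalFit, criterion: float) -> float:
    """Concentration where the fitted line reaches ``criterion`` (ng/L)."""
    if fit.slope <= _SLOPE_EPS:
        raise UndefinedThresholdError(
            f"cannot invert a fit with slope {fit.slope:.4g}"
        )
    return 10 ** ((criterion - fit.intercept) / fit.slope)


def _band_crossing(x0, sign, slope, intercept, criterion, tcrit, s, n, xbar, sxx):
    """Inverse-prediction bound: where yhat(x) + sign*halfwidth(x) = criterion.

    Searches outward from the point estimate x0; returns None when the
    band never crosses the criterion within 12 log10 units (slope not
    separated from zero at this confidence level).
    """

    def f(x):
        half = tcrit * s * math.sqrt(1.0 / n + (x - xbar) ** 2 / sxx)
        return intercept + slope * x + sign * half - criterion

    direction = -1.0 if sign > 0 else 1.0  # upper band crosses below x0
    step, limit = 0.25, 12.0
    a = x0
    while abs(a - x0) < limit:
        b = a + direction * step
        if f(a) * f(b) <= 0:
            return brentq(f, min(a, b), max(a, b))
        a = b
    return None


def fit_graphical(
    data: DiscriminationDataset,
    include: Collection[str] | None = None,
    criterion: float | None = None,
    confidence_level: float = 0.95,
    chance: float = TRIANGLE_CHANCE,
) -> GraphicalFit:
    """Fit the 0/1-vs-log-concentration line and invert at the criterion.

    Parameters
    ----------
    data : DiscriminationDataset
        Triangle outcomes on an ascending ladder.
    include : collection of panelist ids, optional
        Restrict the fit to a subset (e.g. BET-classified responders).
    criterion : float, optional
        Proportion-correct criterion; default ``criterion_for(chance)``.
    confidence_level : float
        Level for the inverse-prediction bounds on the threshold.
    chance : float
        Guessing rate of the task (1/3 for the triangle test).
    """
    if criterion is None:
        criterion = criterion_for(chance)
    if not chance < criterion < 1:
        raise DomainError(
            f"criterion must lie in (chance, 1) = ({chance:.3g}, 1), got {criterion}"
        )

    records = data.records
    if include is not None:
        include = set(include)
        records = {pid: v for pid, v in records.items() if pid in include}
    if not records:
        raise InsufficientDataError("no panelists selected for the graphical fit")

    logc = np.log10(data.series.levels)
    x = np.concatenate([logc for _ in records])
    y = np.concatenate([np.asarray(v, dtype=float) for v in records.values()])
    if len(np.unique(x)) < 2:
        raise InsufficientDataError("need >=2 distinct concentration levels")

    res = sm.OLS(y, sm.add_constant(x)).fit()
    intercept, slope = float(res.params[0]), float(res.params[1])
    n = len(x)

    # slopes below arithmetic dust are flat lines, not usable fits
    if slope <= _SLOPE_EPS:
        warnings.warn(
            "non-positive slope: group performs at or below chance across "
            "the ladder; threshold undefined",
            stacklevel=2,
        )
        return GraphicalFit(
            slope, intercept, criterion, None, None, None, n,
            confidence_level, flag="undefined-slope",
        )

    log_thr = (criterion - intercept) / slope
    if abs(log_thr) > 300:  # crossing beyond float range: effectively never
        warnings.warn(
            "fitted line reaches the criterion only at an unphysical "
            "concentration; threshold undefined",
            stacklevel=2,
        )
        return GraphicalFit(
            slope, intercept, criterion, None, None, None, n,
            confidence_level, flag="criterion-unreachable",
        )
    threshold = 10 ** log_thr
    flag = ""
    if not data.series.levels[0] <= threshold <= data.series.levels[-1]:
        flag = "extrapolated"

    xbar = float(x.mean())
    sxx = float(((x - xbar) ** 2).sum())
    s = math.sqrt(res.mse_resid)
    tcrit = stats.t.ppf(1 - (1 - confidence_level) / 2, n - 2)
    lo = _band_crossing(log_thr, +1, slope, intercept, criterion, tcrit, s, n, xbar, sxx)
    hi = _band_crossing(log_thr, -1, slope, intercept, criterion, tcrit, s, n, xbar, sxx)

    return GraphicalFit(
        slope=slope,
        intercept=intercept,
        criterion=criterion,
        threshold=threshold,
        ci_lower=None if lo is None else 10 ** lo,
        ci_upper=None if hi is None else 10 ** hi,
        n_points=n,
        confidence_level=confidence_level,
        flag=flag,
    )
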