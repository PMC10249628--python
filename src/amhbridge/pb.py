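"""Passing-Bablok nonparametric method-comparison regression.

Estimates the linear relation ``y = a + b*x`` between two assays without
distributional assumptions on the measurement errors: the slope is a shifted
median of all pairwise slopes, and confidence intervals come from ranks of
the ordered slope collection. The shift ``K`` (the number of pairwise slopes
below -1) makes the estimator invariant under exchange of the two axes.

Pair handling follows the original procedure for the standard case of a
positive association:

* pairs with identical x and identical y are uninformative (0/0) and dropped;
* pairs with identical x but differing y contribute slopes of ``±inf`` with
  the sign of the y-difference, placed at the extremes of the sort order;
* slopes exactly equal to -1 are excluded from the collection.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import DegenerateDataError
from .pairs import PairedMeasurements

__all__ = ["PBFit", "pairwise_slopes", "fit_pb", "pb_predict"]


@dataclass(frozen=True)
class PBFit:
    """A fitted Passing-Bablok regression ``y = intercept + slope*x``.

    ``slope`` is unitless; ``intercept`` is in ng/mL. The difference flags
    are derived from the confidence intervals: a systematic difference means
    the intercept CI excludes 0, a proportional difference means the slope CI
    excludes 1.
    """

    slope: float
    intercept: float
    slope_ci: tuple[float, float]
    intercept_ci: tuple[float, float]
    n_samples: int
    n_slopes_used: int
    offset_k: int
    conf_level: float = 0.95
    assay_x: str = "assay_x"
    assay_y: str = "assay_y"

    @property
    def systematic_difference(self) -> bool:
        lo, hi = self.intercept_ci
        return not (lo <= 0.0 <= hi)

    @property
    def proportional_difference(self) -> bool:
        lo, hi = self.slope_ci
        return not (lo <= 1.0 <= hi)

    def to_dict(self) -> dict:
        return {
            "slope": self.slope,
            "intercept": self.intercept,
            "slope_ci": list(self.slope_ci),
            "intercept_ci": list(self.intercept_ci),
            "n_samples": self.n_samples,
            "n_slopes_used": self.n_slopes_used,
            "offset_k": self.offset_k,
            "conf_level": self.conf_level,
            "systematic_difference": self.systematic_difference,
            "proportional_difference": self.proportional_difference,
        }


def pairwise_slopes(data: PairedMeasurements) -> tuple[np.ndarray, int]:
    """All usable pairwise slopes, sorted ascending, plus the offset K.

    Returns
    -------
    slopes
        The C(n,2) candidate slopes after exclusions (see module docstring),
        sorted ascending with signed infinities at the extremes.
    K
        Count of slopes strictly below -1.
    """
    if data.n < 3:
        raise DegenerateDataError(f"need at least 3 paired samples, got {data.n}")
    x, y = data.x, data.y
    i, j = np.triu_indices(data.n, k=1)
    dx = x[j] - x[i]
    dy = y[j] - y[i]

    both_zero = (dx == 0) & (dy == 0)
    dx = dx[~both_zero]
    dy = dy[~both_zero]
    with np.errstate(divide="ignore"):
        slopes = np.where(dx == 0, np.sign(dy) * np.inf, dy / np.where(dx == 0, 1, dx))
    slopes = slopes[slopes != -1.0]
    if len(slopes) < 2:
        raise DegenerateDataError(
            "degenerate data: fewer than 2 usable pairwise slopes after exclusions"
        )
    slopes.sort()
    k = int(np.sum(slopes < -1.0))
    return slopes, k


def _shifted_order_stat(slopes: np.ndarray, rank: int, k: int) -> float:
    """1-based rank into the sorted slopes, shifted by K and clamped."""
    idx = min(max(rank - 1 + k, 0), len(slopes) - 1)
    return float(slopes[idx])


def _shifted_median(slopes: np.ndarray, k: int) -> float:
    n = len(slopes)
    if n % 2 == 1:
        return _shifted_order_stat(slopes, (n + 1) // 2, k)
    lo = _shifted_order_stat(slopes, n // 2, k)
    hi = _shifted_order_stat(slopes, n // 2 + 1, k)
    return 0.5 * (lo + hi)


def fit_pb(data: PairedMeasurements, conf_level: float = 0.95) -> PBFit:
    """Fit a Passing-Bablok regression with rank-based confidence intervals.

    The slope is the median of the sorted pairwise slopes with its index
    shifted by K; the intercept is the median of ``y - slope*x``. Slope CI
    ranks are ``M1 = round((N - C)/2)`` and ``M2 = N - M1 + 1`` with
    ``C = z * sqrt(n(n-1)(2n+5)/18)``, both shifted by K; intercept CI bounds
    re-use the slope CI bounds through ``median(y - b_bound * x)``.
    """
    if not 0.0 < conf_level < 1.0:
        raise ValueError(f"conf_level must be in (0, 1), got {conf_level}")
    slopes, k = pairwise_slopes(data)
    n = data.n
    n_slopes = len(slopes)

    b = _shifted_median(slopes, k)
    a = float(np.median(data.y - b * data.x))

    z = stats.norm.ppf(0.5 + conf_level / 2.0)
    c = z * math.sqrt(n * (n - 1) * (2 * n + 5) / 18.0)
    m1 = math.floor((n_slopes - c) / 2.0 + 0.5)  # round half-up
    m1 = min(max(m1, 1), n_slopes)
    m2 = n_slopes - m1 + 1
    b_lo = _shifted_order_stat(slopes, m1, k)
    b_hi = _shifted_order_stat(slopes, m2, k)
    if b_lo > b_hi:
        b_lo, b_hi = b_hi, b_lo

    a_bounds = sorted(
        (
            float(np.median(data.y - b_hi * data.x)),
            float(np.median(data.y - b_lo * data.x)),
        )
    )
    return PBFit(
        slope=b,
        intercept=a,
        slope_ci=(b_lo, b_hi),
        intercept_ci=(a_bounds[0], a_bounds[1]),
        n_samples=n,
        n_slopes_used=n_slopes,
        offset_k=k,
        conf_level=conf_level,
        assay_x=data.assay_x,
        assay_y=data.assay_y,
    )


def pb_predict(fit: PBFit, x) -> np.ndarray | float:
    """Map source-assay concentrations through ``intercept + slope*x``.

    Vectorised over arrays; no clamping to measuring ranges is applied here.
    """
    arr = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("x must be finite")
    out = fit.intercept + fit.slope * arr
    if np.isscalar(x) or arr.ndim == 0:
        return float(out)
    return out
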