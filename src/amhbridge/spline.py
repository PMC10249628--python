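"""Linear spline regression with AICc-guided knot selection.

A linear spline is a continuous piecewise-linear function: ordinary least
squares on the truncated-power basis ``{1, x, (x - k1)+, (x - k2)+, ...}``.
Each knot adds one coefficient, the change of slope at that knot. Candidate
knot subsets are compared by AICc; the winner converts one assay's scale to
another's where a single straight line (a "global" relation) does not hold
across the whole measuring range.

Beyond the observed x-range the terminal linear segments continue unchanged
(the basis is linear outside the knot span); predictions out there are
extrapolations and are flagged by the converter layer.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np

from .errors import DegenerateDataError
from .pairs import PairedMeasurements
from .pb import PBFit, pb_predict

__all__ = [
    "FitMetrics",
    "SplineFit",
    "ModelComparison",
    "compute_metrics",
    "fit_spline",
    "select_knots",
    "compare_models",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class FitMetrics:
    """Goodness-of-fit summary for a regression's predictions.

    AIC uses the full Gaussian log-likelihood with the residual variance
    counted as a parameter: ``AIC = n ln(2*pi) + n ln(SSE/n) + n + 2p`` with
    ``p = n_params + 1``, and ``AICc = AIC + 2p(p+1)/(n-p-1)``. RMSE is
    ``sqrt(SSE/n)`` in ng/mL.
    """

    r2: float
    adjusted_r2: float
    rmse: float
    aic: float
    aicc: float
    n: int
    n_params: int

    def to_dict(self) -> dict:
        return {
            "r2": self.r2,
            "adjusted_r2": self.adjusted_r2,
            "rmse": self.rmse,
            "aic": self.aic,
            "aicc": self.aicc,
            "n": self.n,
            "n_params": self.n_params,
        }


def compute_metrics(observed, predicted, n_params: int) -> FitMetrics:
    """r², adjusted r², RMSE, AIC and AICc for a set of predictions.

    ``n_params`` is the number of regression coefficients (2 for a straight
    line). When the observed values are constant (SST = 0), r² is undefined
    unless the predictions are exact, in which case r² = 1.
    """
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape or obs.ndim != 1:
        raise ValueError("observed and predicted must be 1-d arrays of equal length")
    n = len(obs)
    if n <= n_params:
        raise ValueError(f"need n > n_params, got n={n}, n_params={n_params}")
    resid = obs - pred
    sse = float(resid @ resid)
    sst = float(np.sum((obs - obs.mean()) ** 2))
    # An exact fit leaves only floating-point noise in SSE; its log-likelihood
    # is unbounded, so AIC/AICc are reported as -inf rather than a number
    # driven by rounding error.
    exact = sse <= 1e-12 * max(sst, 1e-12)
    if sst == 0.0:
        if not exact:
            raise ValueError("r2 undefined: observed values are constant (SST = 0)")
        r2 = 1.0
    else:
        r2 = 1.0 if exact else 1.0 - sse / sst
    adjusted_r2 = 1.0 - (1.0 - r2) * (n - 1) / (n - n_params)
    rmse = float(np.sqrt(sse / n))
    p = n_params + 1  # residual variance counted as a parameter
    if exact:
        aic = -np.inf
    else:
        aic = n * np.log(2 * np.pi) + n * np.log(sse / n) + n + 2 * p
    aicc = aic + 2 * p * (p + 1) / (n - p - 1) if n > p + 1 else np.inf
    return FitMetrics(
        r2=r2, adjusted_r2=adjusted_r2, rmse=rmse,
        aic=float(aic), aicc=float(aicc), n=n, n_params=n_params,
    )


def _design_matrix(x: np.ndarray, knots: tuple[float, ...]) -> np.ndarray:
    cols = [np.ones_like(x), x]
    cols.extend(np.maximum(x - k, 0.0) for k in knots)
    return np.column_stack(cols)


@dataclass(frozen=True)
class SplineFit:
    """A fitted linear spline: knots, coefficients and fit metrics.

    ``coefficients`` is ``(intercept, base slope, slope change at knot 1, ...)``
    so its length is always ``2 + len(knots)``.
    """

    knots: tuple[float, ...]
    coefficients: np.ndarray
    n_samples: int
    x_range: tuple[float, float]
    metrics: FitMetrics
    assay_x: str = "assay_x"
    assay_y: str = "assay_y"
    selection_trace: tuple = field(default=(), compare=False)

    def predict(self, x) -> np.ndarray | float:
        """Evaluate the spline; terminal segments extend beyond x_range."""
        arr = np.atleast_1d(np.asarray(x, dtype=float))
        out = _design_matrix(arr, self.knots) @ self.coefficients
        if np.isscalar(x) or np.asarray(x).ndim == 0:
            return float(out[0])
        return out

    def segment_slopes(self) -> np.ndarray:
        """Slope of each linear segment, left to right (len(knots)+1 values)."""
        return np.cumsum(self.coefficients[1:])

    def to_dict(self) -> dict:
        return {
            "knots": list(self.knots),
            "coefficients": [float(c) for c in self.coefficients],
            "metrics": self.metrics.to_dict(),
            "n": self.n_samples,
        }


def fit_spline(data: PairedMeasurements, knots) -> SplineFit:
    """Least-squares linear spline with the given interior knots.

    Knots must be strictly increasing and strictly inside the observed
    x-range; an empty knot sequence reduces to ordinary least squares on
    ``{1, x}``.
    """
    knots = tuple(float(k) for k in knots)
    if any(b <= a for a, b in zip(knots, knots[1:])):
        raise ValueError(f"knots must be strictly increasing, got {knots}")
    x, y = data.x, data.y
    xmin, xmax = float(x.min()), float(x.max())
    for k in knots:
        if not xmin < k < xmax:
            raise ValueError(
                f"knot {k} outside the open data range ({xmin}, {xmax})"
            )
    n_coef = 2 + len(knots)
    if data.n <= n_coef:
        raise DegenerateDataError(
            f"need more samples ({data.n}) than coefficients ({n_coef})"
        )
    design = _design_matrix(x, knots)
    coef, _, rank, _ = np.linalg.lstsq(design, y, rcond=None)
    if rank < n_coef:
        raise DegenerateDataError("degenerate design: basis columns are collinear")
    metrics = compute_metrics(y, design @ coef, n_params=n_coef)
    return SplineFit(
        knots=knots, coefficients=coef, n_samples=data.n,
        x_range=(xmin, xmax), metrics=metrics,
        assay_x=data.assay_x, assay_y=data.assay_y,
    )


def default_knot_grid(data: PairedMeasurements) -> list[float]:
    """Interior deciles of x plus the clinically anchored 1 and 9 ng/mL."""
    qs = np.quantile(data.x, np.arange(0.1, 1.0, 0.1))
    grid = set(float(q) for q in qs) | {1.0, 9.0}
    xmin, xmax = float(data.x.min()), float(data.x.max())
    return sorted(g for g in grid if xmin < g < xmax)


def select_knots(
    data: PairedMeasurements,
    candidate_knots=None,
    max_knots: int = 3,
) -> SplineFit:
    """Exhaustive AICc search over knot subsets of a candidate grid.

    Evaluates every subset of size 0..``max_knots`` of the grid (default:
    interior deciles of x plus {1, 9} ng/mL) and returns the fit with the
    smallest AICc; ties prefer fewer knots, then the smaller first knot. The
    search trace (knots, AICc per candidate) is logged and attached to the
    returned fit.
    """
    if candidate_knots is None:
        candidate_knots = default_knot_grid(data)
    grid = sorted(float(k) for k in candidate_knots)
    if not grid and max_knots > 0:
        raise ValueError("candidate knot grid is empty")

    trace = []
    best = None
    best_key = None
    for size in range(0, max_knots + 1):
        for subset in itertools.combinations(grid, size):
            try:
                fit = fit_spline(data, subset)
            except (DegenerateDataError, ValueError):
                continue
            trace.append((subset, fit.metrics.aicc))
            key = (fit.metrics.aicc, len(subset), subset)
            if best_key is None or key < best_key:
                best, best_key = fit, key
    if best is None:
        raise DegenerateDataError("degenerate design: no fittable knot subset")
    log.info(
        "knot selection over %d candidates: chose %s (AICc %.3f)",
        len(trace), best.knots, best.metrics.aicc,
    )
    return SplineFit(
        knots=best.knots, coefficients=best.coefficients,
        n_samples=best.n_samples, x_range=best.x_range, metrics=best.metrics,
        assay_x=best.assay_x, assay_y=best.assay_y,
        selection_trace=tuple(trace),
    )


_CRITERIA = ("rmse", "r2", "adjusted_r2", "aic", "aicc")
_HIGHER_IS_BETTER = {"r2", "adjusted_r2"}


@dataclass(frozen=True)
class ModelComparison:
    """Side-by-side fit metrics for a spline and a Passing-Bablok line."""

    spline_metrics: FitMetrics
    pb_metrics: FitMetrics
    winners: dict

    def render(self) -> str:
        names = {
            "rmse": "RMSE", "r2": "r2", "adjusted_r2": "adjusted r2",
            "aic": "AIC", "aicc": "AICc",
        }
        lines = [
            f"{'Criterion':<14}{'Spline':>12}{'Passing-Bablok':>18}{'Better':>10}"
        ]
        for c in _CRITERIA:
            s = getattr(self.spline_metrics, c)
            p = getattr(self.pb_metrics, c)
            lines.append(
                f"{names[c]:<14}{s:>12.3f}{p:>18.3f}{self.winners[c]:>10}"
            )
        return "\n".join(lines)


def compare_models(
    data: PairedMeasurements, pb: PBFit, spline: SplineFit
) -> ModelComparison:
    """Compare a spline fit and a PB fit on the data both were fitted to.

    PB metrics are computed from its predictions with 2 parameters (intercept
    and slope). The report names the better model per criterion: lower is
    better for RMSE/AIC/AICc, higher for r² and adjusted r².
    """
    if pb.n_samples != data.n or spline.n_samples != data.n:
        raise ValueError("both fits must come from the supplied data (n mismatch)")
    pb_metrics = compute_metrics(data.y, pb_predict(pb, data.x), n_params=2)
    winners = {}
    for c in _CRITERIA:
        s = getattr(spline.metrics, c)
        p = getattr(pb_metrics, c)
        if s == p or (
            np.isfinite(s) and np.isfinite(p)
            and np.isclose(s, p, rtol=1e-9, atol=1e-12)
        ):
            winners[c] = "tie"
        elif (s > p) == (c in _HIGHER_IS_BETTER):
            winners[c] = "spline"
        else:
            winners[c] = "pb"
    return ModelComparison(
        spline_metrics=spline.metrics, pb_metrics=pb_metrics, winners=winners
    )
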