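"""Synthetic paired-assay data with the study's stratified sampling design.

Source-assay concentrations are drawn from ten strata of 30 samples each,
spanning the low (<1 ng/mL), mid (1-3.5 ng/mL) and high (>3.5 ng/mL) AMH
ranges seen in a reproductive-medicine population; the open-ended top
stratum is filled log-uniformly. Target-assay values follow a known linear
or piecewise-linear relation with proportional Gaussian noise plus a small
additive floor, reproducing the variance heterogeneity that method
comparisons of immunoassays show on Bland-Altman plots.

Every generator takes a seed and is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import published
from .pairs import PairedMeasurements
from .qc import QCSeries

__all__ = [
    "LinearRelation",
    "PiecewiseLinearRelation",
    "SimulationConfig",
    "simulate_pairs",
    "simulate_qc",
]


@dataclass(frozen=True)
class LinearRelation:
    """True relation y = a + b*x."""

    intercept: float = 0.0
    slope: float = 1.0

    def __call__(self, x):
        return self.intercept + self.slope * np.asarray(x, dtype=float)

    def to_dict(self) -> dict:
        return {"kind": "linear", "intercept": self.intercept, "slope": self.slope}


@dataclass(frozen=True)
class PiecewiseLinearRelation:
    """Continuous piecewise-linear truth in truncated-power form.

    ``y = intercept + slope*x + sum_j delta_j * (x - knot_j)+`` where
    ``delta_j`` is the slope change at knot j.
    """

    intercept: float
    slope: float
    knots: tuple[float, ...]
    slope_changes: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.knots) != len(self.slope_changes):
            raise ValueError("one slope change per knot required")

    def __call__(self, x):
        x = np.asarray(x, dtype=float)
        y = self.intercept + self.slope * x
        for k, d in zip(self.knots, self.slope_changes):
            y = y + d * np.maximum(x - k, 0.0)
        return y

    def to_dict(self) -> dict:
        return {
            "kind": "piecewise_linear", "intercept": self.intercept,
            "slope": self.slope, "knots": list(self.knots),
            "slope_changes": list(self.slope_changes),
        }


def _default_strata() -> tuple[tuple[float, float, int], ...]:
    return tuple(published.SAMPLING_STRATA)


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for a simulated paired-assay comparison.

    Defaults mirror the cross-calibration study design: 10 concentration
    strata of 30 samples each (300 total), proportional noise of CV 5% with
    a 0.02 ng/mL additive floor, an identity true relation, and the
    open-ended top stratum truncated at 24 ng/mL (the widest of the three
    platforms' measuring ranges).
    """

    strata: tuple = field(default_factory=_default_strata)
    relation: LinearRelation | PiecewiseLinearRelation = field(
        default_factory=LinearRelation
    )
    cv_pct: float = 5.0
    floor_sd: float = 0.02
    top_max: float = 24.0
    seed: int | None = None
    assay_x: str = "assay_x"
    assay_y: str = "assay_y"

    def __post_init__(self) -> None:
        if self.cv_pct < 0:
            raise ValueError("noise CV must be non-negative")
        if self.floor_sd < 0:
            raise ValueError("additive noise floor must be non-negative")
        for lo, hi, n in self.strata:
            if lo >= hi:
                raise ValueError(f"impossible stratum: low {lo} >= high {hi}")
            if n < 1:
                raise ValueError("each stratum needs at least one sample")


def simulate_pairs(config: SimulationConfig) -> tuple[PairedMeasurements, dict]:
    """Draw a paired dataset plus a truth record for recovery tests.

    x is uniform within each bounded stratum and log-uniform in the
    open-ended top stratum (up to ``config.top_max``); then
    ``y = f(x) * (1 + eps_prop) + eps_add`` with independent Gaussian noise
    terms. The truth record retains the generating relation and noise
    parameters.
    """
    rng = np.random.default_rng(config.seed)
    xs = []
    for lo, hi, n in config.strata:
        if np.isinf(hi):
            hi_eff = config.top_max
            xs.append(np.exp(rng.uniform(np.log(lo), np.log(hi_eff), size=n)))
        else:
            xs.append(rng.uniform(lo, hi, size=n))
    x = np.concatenate(xs)
    f_true = np.asarray(config.relation(x), dtype=float)
    y = f_true * (1.0 + rng.normal(0.0, config.cv_pct / 100.0, size=len(x)))
    y = y + rng.normal(0.0, config.floor_sd, size=len(x))
    data = PairedMeasurements(
        x=x, y=y, assay_x=config.assay_x, assay_y=config.assay_y
    )
    truth = {
        "relation": config.relation.to_dict(),
        "cv_pct": config.cv_pct,
        "floor_sd": config.floor_sd,
        "seed": config.seed,
        "n": len(x),
    }
    return data, truth


def simulate_qc(
    target: float,
    cv_pct: float,
    days: int = 5,
    reps_per_day: int = 4,
    seed: int | None = None,
    control_id: str = "control",
) -> QCSeries:
    """Gaussian QC replicates around a target, in the 5-day x 4-rep layout."""
    if target <= 0:
        raise ValueError("target must be positive")
    if cv_pct < 0:
        raise ValueError("noise CV must be non-negative")
    rng = np.random.default_rng(seed)
    n = days * reps_per_day
    values = target * (1.0 + rng.normal(0.0, cv_pct / 100.0, size=n))
    day_idx = np.repeat(np.arange(1, days + 1), reps_per_day)
    rep_idx = np.tile(np.arange(1, reps_per_day + 1), days)
    return QCSeries(
        control_id=control_id, target=target,
        days=day_idx, replicates=rep_idx, values=values,
    )
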