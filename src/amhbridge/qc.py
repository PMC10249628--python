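"""Precision and trueness evaluation of quality-control replicates.

Follows the user-verification style of CLSI EP15-A3 (each control measured
in replicate across days) but summarises with a single pooled SD, since
that is what the kit inserts and routine QC reports use. Acceptance limits
default to total error within ±25%, bias within ±12% and CV at most 8%.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["QCSeries", "QCEvaluation", "QCLimits", "evaluate_qc", "read_qc_csv"]


@dataclass(frozen=True)
class QCLimits:
    """Acceptance limits in percent: |TE| <= te, |bias| <= bias, CV <= cv."""

    te: float = 25.0
    bias: float = 12.0
    cv: float = 8.0


@dataclass(frozen=True)
class QCSeries:
    """Replicate measurements of one control with an assigned target (ng/mL)."""

    control_id: str
    target: float
    days: np.ndarray
    replicates: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        for name in ("days", "replicates", "values"):
            object.__setattr__(self, name, np.asarray(getattr(self, name)))
        if len(self.values) < 2:
            raise ValueError("a QC series needs at least 2 measurements")
        if not len(self.days) == len(self.replicates) == len(self.values):
            raise ValueError("days, replicates and values must have equal length")
        if not self.target > 0:
            raise ValueError(f"target must be positive, got {self.target}")

    @property
    def n(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class QCEvaluation:
    """Summary statistics and pass/fail flags for one control series.

    ``total_error_pct = |bias_pct| + 1.96 * cv_pct`` (Westgard form).
    """

    control_id: str
    target: float
    mean: float
    sd: float
    cv_pct: float
    bias_pct: float
    total_error_pct: float
    limits: QCLimits
    pass_cv: bool
    pass_bias: bool
    pass_te: bool

    @property
    def pass_all(self) -> bool:
        return self.pass_cv and self.pass_bias and self.pass_te


def evaluate_qc(series: QCSeries, limits: QCLimits | None = None) -> QCEvaluation:
    """CV, bias and total error for a control series, flagged against limits.

    The SD pools all replicates with the n-1 denominator (total SD, no
    within/between-day decomposition).
    """
    limits = limits or QCLimits()
    mean = float(series.values.mean())
    if mean <= 0:
        raise ValueError(f"invalid series: mean must be positive, got {mean}")
    sd = float(series.values.std(ddof=1))
    cv = 100.0 * sd / mean
    bias = 100.0 * (mean - series.target) / series.target
    te = abs(bias) + 1.96 * cv
    return QCEvaluation(
        control_id=series.control_id,
        target=series.target,
        mean=mean,
        sd=sd,
        cv_pct=cv,
        bias_pct=bias,
        total_error_pct=te,
        limits=limits,
        pass_cv=cv <= limits.cv,
        pass_bias=abs(bias) <= limits.bias,
        pass_te=te <= limits.te,
    )


def read_qc_csv(path) -> list[QCSeries]:
    """Read ``control_id,day,replicate,value,target`` rows into series."""
    frame = pd.read_csv(path)
    required = {"control_id", "day", "replicate", "value", "target"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"QC CSV missing columns: {sorted(missing)}")
    out = []
    for cid, grp in frame.groupby("control_id", sort=False):
        targets = grp["target"].unique()
        if len(targets) != 1:
            raise ValueError(f"control {cid!r} has multiple target values")
        out.append(
            QCSeries(
                control_id=str(cid),
                target=float(targets[0]),
                days=grp["day"].to_numpy(),
                replicates=grp["replicate"].to_numpy(),
                values=grp["value"].to_numpy(dtype=float),
            )
        )
    return out
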