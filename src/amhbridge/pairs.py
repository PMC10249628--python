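"""Paired measurements of the same samples on two immunoassay platforms.

The central container for method-comparison work: ``n`` serum samples, each
measured on a source assay (``x``) and a target assay (``y``), both in ng/mL.
CSV round-trips use the dialect ``sample_id,<assay_x>,<assay_y>`` with a
header row naming the two assays.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["PairedMeasurements", "read_pairs_csv"]


@dataclass(frozen=True)
class PairedMeasurements:
    """Concentrations of the same samples on two named assays (ng/mL).

    Parameters
    ----------
    x, y
        Measured concentrations on the source and target assay respectively.
    sample_ids
        Opaque per-sample labels; generated as ``s1..sn`` when omitted.
    assay_x, assay_y
        Names of the two platforms (e.g. ``"kangrun"``, ``"roche"``).

    Negative concentrations are physically implausible but can arise from
    blank subtraction near the detection limit, so they trigger a warning
    rather than an error.
    """

    x: np.ndarray
    y: np.ndarray
    assay_x: str = "assay_x"
    assay_y: str = "assay_y"
    sample_ids: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        x = np.asarray(self.x, dtype=float)
        y = np.asarray(self.y, dtype=float)
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)
        if x.ndim != 1 or y.ndim != 1:
            raise ValueError("x and y must be one-dimensional")
        if len(x) != len(y):
            raise ValueError(f"length mismatch: {len(x)} x values vs {len(y)} y values")
        if len(x) == 0:
            raise ValueError("at least one paired measurement is required")
        if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
            raise ValueError("all measurements must be finite")
        ids = self.sample_ids
        if ids is None:
            ids = np.array([f"s{i + 1}" for i in range(len(x))])
        else:
            ids = np.asarray(ids)
            if len(ids) != len(x):
                raise ValueError("sample_ids length does not match measurements")
        object.__setattr__(self, "sample_ids", ids)
        if np.any(x < 0) or np.any(y < 0):
            warnings.warn(
                "negative concentrations present; expected for values near the "
                "detection limit only",
                UserWarning,
                stacklevel=3,
            )

    @property
    def n(self) -> int:
        return len(self.x)

    def swapped(self) -> "PairedMeasurements":
        """Exchange the roles of the two assays (y becomes the regressor)."""
        return PairedMeasurements(
            x=self.y, y=self.x, assay_x=self.assay_y, assay_y=self.assay_x,
            sample_ids=self.sample_ids,
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"sample_id": self.sample_ids, self.assay_x: self.x, self.assay_y: self.y}
        )

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def read_pairs_csv(path) -> PairedMeasurements:
    """Read a ``sample_id,<assay_x>,<assay_y>`` CSV into a container.

    The second and third header fields name the assays.
    """
    frame = pd.read_csv(path)
    if frame.shape[1] < 3:
        raise ValueError(
            "expected at least three columns: sample_id,<assay_x>,<assay_y>"
        )
    id_col, x_col, y_col = frame.columns[:3]
    return PairedMeasurements(
        x=frame[x_col].to_numpy(dtype=float),
        y=frame[y_col].to_numpy(dtype=float),
        assay_x=str(x_col),
        assay_y=str(y_col),
        sample_ids=frame[id_col].to_numpy(),
    )
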