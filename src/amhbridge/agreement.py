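"""Agreement diagnostics between two assays: Bland-Altman and mountain plots.

Differences are always taken as second-named assay minus first-named assay
(``y - x``). The Bland-Altman limits of agreement are mean difference
± 1.96 SD; the mountain plot is the folded empirical CDF of the differences,
which peaks at the median and is symmetric about 0 when the assays agree.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .pairs import PairedMeasurements

__all__ = [
    "BlandAltmanResult",
    "MountainCurve",
    "AgreementReport",
    "bland_altman",
    "mountain",
    "agreement_report",
    "plot_bland_altman",
    "plot_mountain",
]


@dataclass(frozen=True)
class BlandAltmanResult:
    """Bland-Altman statistics for differences ``assay_y - assay_x`` (ng/mL)."""

    assay_x: str
    assay_y: str
    means: np.ndarray
    diffs: np.ndarray
    mean_diff: float
    sd_diff: float
    loa_low: float
    loa_high: float
    ci_mean_diff: tuple[float, float]
    pct_outside: float

    @property
    def n(self) -> int:
        return len(self.diffs)

    def to_frame(self) -> pd.DataFrame:
        """Per-sample means and differences, ready for CSV export."""
        return pd.DataFrame({"mean": self.means, "diff": self.diffs})


@dataclass(frozen=True)
class MountainCurve:
    """Folded empirical percentiles over sorted differences.

    ``folded_percentiles[i] = min(p_i, 100 - p_i)`` with
    ``p_i = 100 * i / (n + 1)``; values lie in (0, 50] and peak at the median.
    """

    sorted_diffs: np.ndarray
    folded_percentiles: np.ndarray


def bland_altman(data: PairedMeasurements, conf_level: float = 0.95) -> BlandAltmanResult:
    """Limits of agreement between two assays.

    The SD of differences uses the n-1 denominator; the CI of the mean
    difference uses the t distribution with n-1 degrees of freedom.
    ``pct_outside`` is the percentage of samples strictly outside the LoA.
    """
    if data.n < 3:
        raise ValueError(f"need at least 3 samples, got {data.n}")
    diffs = data.y - data.x
    means = 0.5 * (data.x + data.y)
    mean_diff = float(diffs.mean())
    sd_diff = float(diffs.std(ddof=1))
    loa_low = mean_diff - 1.96 * sd_diff
    loa_high = mean_diff + 1.96 * sd_diff
    tval = stats.t.ppf(0.5 + conf_level / 2.0, df=data.n - 1)
    half = tval * sd_diff / np.sqrt(data.n)
    outside = (diffs < loa_low) | (diffs > loa_high)
    return BlandAltmanResult(
        assay_x=data.assay_x,
        assay_y=data.assay_y,
        means=means,
        diffs=diffs,
        mean_diff=mean_diff,
        sd_diff=sd_diff,
        loa_low=loa_low,
        loa_high=loa_high,
        ci_mean_diff=(mean_diff - half, mean_diff + half),
        pct_outside=float(100.0 * outside.mean()),
    )


def mountain(data: PairedMeasurements) -> MountainCurve:
    """Folded empirical-CDF curve of the per-sample differences."""
    if data.n < 2:
        raise ValueError(f"need at least 2 samples, got {data.n}")
    diffs = np.sort(data.y - data.x)
    ranks = np.arange(1, data.n + 1)
    p = 100.0 * ranks / (data.n + 1)
    return MountainCurve(sorted_diffs=diffs, folded_percentiles=np.minimum(p, 100.0 - p))


@dataclass(frozen=True)
class AgreementReport:
    """Verdict plus plot-ready tables from both diagnostics."""

    ba: BlandAltmanResult
    mtn: MountainCurve
    verdict: str
    inside_threshold: float

    def render(self) -> str:
        b = self.ba
        lines = [
            f"Agreement: {b.assay_y} minus {b.assay_x} (n={b.n})",
            f"  mean difference : {b.mean_diff:.4f} ng/mL "
            f"(95% CI {b.ci_mean_diff[0]:.4f} to {b.ci_mean_diff[1]:.4f})",
            f"  SD of difference: {b.sd_diff:.4f} ng/mL",
            f"  limits of agreement: {b.loa_low:.4f} to {b.loa_high:.4f} ng/mL",
            f"  outside LoA     : {b.pct_outside:.1f}% "
            f"(threshold: >= {self.inside_threshold:.0f}% inside)",
            f"  verdict         : {self.verdict}",
        ]
        return "\n".join(lines)


def agreement_report(
    ba: BlandAltmanResult, mtn: MountainCurve, inside_threshold: float = 95.0
) -> AgreementReport:
    """Consistency verdict from the two diagnostics.

    The assays are called "consistent" iff at least ``inside_threshold``
    percent of samples fall inside the limits of agreement and the 95% CI of
    the mean difference contains 0; otherwise "not consistent".
    """
    inside_ok = (100.0 - ba.pct_outside) >= inside_threshold
    lo, hi = ba.ci_mean_diff
    unbiased = lo <= 0.0 <= hi
    verdict = "consistent" if (inside_ok and unbiased) else "not consistent"
    return AgreementReport(ba=ba, mtn=mtn, verdict=verdict, inside_threshold=inside_threshold)


def plot_bland_altman(ba: BlandAltmanResult, path=None, ax=None):
    """Render the Bland-Altman scatter with mean-difference and LoA lines."""
    import matplotlib
    if path is not None:
        matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    ax.scatter(ba.means, ba.diffs, s=12, alpha=0.6)
    ax.axhline(0.0, color="grey")
    ax.axhline(ba.mean_diff, color="red")
    for b in ba.ci_mean_diff:
        ax.axhline(b, color="red", linestyle=":")
    for b in (ba.loa_low, ba.loa_high):
        ax.axhline(b, color="grey", linestyle="--")
    ax.set_xlabel(f"mean of {ba.assay_x} and {ba.assay_y} (ng/mL)")
    ax.set_ylabel(f"{ba.assay_y} - {ba.assay_x} (ng/mL)")
    if path is not None:
        ax.figure.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(ax.figure)
    return ax


def plot_mountain(mtn: MountainCurve, path=None, ax=None):
    """Render the folded-CDF mountain curve."""
    import matplotlib
    if path is not None:
        matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    ax.plot(mtn.sorted_diffs, mtn.folded_percentiles, marker=".", lw=1)
    ax.axvline(0.0, color="grey", linestyle="--")
    ax.set_xlabel("difference (ng/mL)")
    ax.set_ylabel("folded percentile (%)")
    if path is not None:
        ax.figure.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(ax.figure)
    return ax
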