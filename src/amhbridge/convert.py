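"""Conversion engine: the PB-vs-spline decision rule and the formula registry.

The decision rule: fit Passing-Bablok first; if the 95% CI of its intercept
contains 0 (no systematic difference) the PB line itself is the conversion,
otherwise a linear spline is fitted, because an offset that a single line
cannot absorb usually signals a relation that changes across the measuring
range. The registry ships the six published PB conversion formulas between
the Roche, Beckman and Kangrun AMH platforms; the published spline
conversions appear as placeholders (their coefficients were never printed)
that refuse to convert until refit.

Computation keeps full precision; ``round2`` applies the half-up 2-decimal
display rounding used for reported concentrations.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from . import published
from .errors import FormulaNotFittedError, NoFormulaError
from .pairs import PairedMeasurements
from .pb import PBFit, fit_pb
from .spline import SplineFit, select_knots

__all__ = [
    "AssaySpec",
    "ConversionFormula",
    "builtin_assays",
    "decide_method",
    "build_conversion",
    "convert",
    "convert_batch",
    "registry",
    "round2",
]

SCHEMA_VERSION = "1"


def round2(value: float) -> float:
    """Half-up rounding to 2 decimals, for display (e.g. -0.034 -> -0.03)."""
    return float(Decimal(repr(float(value))).quantize(Decimal("0.01"), ROUND_HALF_UP))


@dataclass(frozen=True)
class AssaySpec:
    """An assay platform and its linear measuring range (ng/mL)."""

    name: str
    measuring_range: tuple[float, float]

    def __post_init__(self) -> None:
        lo, hi = self.measuring_range
        if not lo < hi:
            raise ValueError(f"measuring range must satisfy low < high, got {lo}, {hi}")

    def in_range(self, value: float) -> bool:
        lo, hi = self.measuring_range
        return lo <= value <= hi


def builtin_assays() -> dict[str, AssaySpec]:
    """The three platforms with their published measuring ranges."""
    return {
        name: AssaySpec(name=name, measuring_range=rng)
        for name, rng in published.MEASURING_RANGES.items()
    }


@dataclass(frozen=True)
class ConversionFormula:
    """A registered source-to-target mapping, PB line or linear spline.

    PB formulas carry ``intercept``/``slope`` (optionally with their CIs);
    spline formulas carry ``spline_fit``. A spline entry whose coefficients
    were never supplied (``spline_fit is None`` with only ``knots`` known)
    cannot convert and raises :class:`FormulaNotFittedError`.
    """

    source: AssaySpec
    target: AssaySpec
    method: str  # "pb" | "spline"
    intercept: float | None = None
    slope: float | None = None
    intercept_ci: tuple[float, float] | None = None
    slope_ci: tuple[float, float] | None = None
    spline_fit: SplineFit | None = None
    knots: tuple[float, ...] | None = None
    provenance: str = ""
    decision: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        if self.method == "pb":
            if self.intercept is None or self.slope is None:
                raise ValueError("a PB formula requires intercept and slope")
        elif self.method != "spline":
            raise ValueError(f"method must be 'pb' or 'spline', got {self.method!r}")

    @property
    def fitted(self) -> bool:
        return self.method == "pb" or self.spline_fit is not None

    def predict(self, x):
        if self.method == "pb":
            return self.intercept + self.slope * np.asarray(x, dtype=float)
        if self.spline_fit is None:
            raise FormulaNotFittedError(
                f"{self.source.name} -> {self.target.name}: spline coefficients "
                "unavailable - refit required (fit on paired data or supply "
                "coefficients)"
            )
        return self.spline_fit.predict(x)

    def to_dict(self) -> dict:
        d = {
            "schema_version": SCHEMA_VERSION,
            "source": {"name": self.source.name, "range": list(self.source.measuring_range)},
            "target": {"name": self.target.name, "range": list(self.target.measuring_range)},
            "method": self.method,
            "provenance": self.provenance,
        }
        if self.method == "pb":
            d["intercept"] = self.intercept
            d["slope"] = self.slope
            if self.intercept_ci:
                d["intercept_ci"] = list(self.intercept_ci)
            if self.slope_ci:
                d["slope_ci"] = list(self.slope_ci)
        else:
            d["knots"] = list(self.knots) if self.knots else None
            d["spline"] = self.spline_fit.to_dict() if self.spline_fit else None
        if self.decision:
            d["decision"] = self.decision
        return d

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), **kw)


def decide_method(pb: PBFit) -> str:
    """'pb' iff the intercept CI contains 0 (closed interval), else 'spline'.

    No systematic offset means one straight line can serve across the whole
    range; an offset signals a locally varying relation better captured by a
    spline. A CI bound exactly at 0 counts as containing 0.
    """
    lo, hi = pb.intercept_ci
    return "pb" if lo <= 0.0 <= hi else "spline"


def build_conversion(
    data: PairedMeasurements,
    knot_grid=None,
    conf_level: float = 0.95,
    max_knots: int = 3,
) -> ConversionFormula:
    """Fit PB, apply the decision rule, and fall through to a spline if needed.

    The returned formula carries the full decision trace: the PB estimates
    with CIs always, plus the knot-selection outcome when a spline was
    chosen.
    """
    pb = fit_pb(data, conf_level=conf_level)
    method = decide_method(pb)
    decision = {
        "pb": pb.to_dict(),
        "rule": "intercept CI contains 0 -> pb, else spline",
        "method": method,
    }
    source = AssaySpec(data.assay_x, (float(data.x.min()), float(data.x.max())))
    target = AssaySpec(data.assay_y, (float(data.y.min()), float(data.y.max())))
    known = builtin_assays()
    source = known.get(data.assay_x, source)
    target = known.get(data.assay_y, target)
    if method == "pb":
        return ConversionFormula(
            source=source, target=target, method="pb",
            intercept=pb.intercept, slope=pb.slope,
            intercept_ci=pb.intercept_ci, slope_ci=pb.slope_ci,
            provenance=f"fitted on {data.n} paired samples", decision=decision,
        )
    sfit = select_knots(data, candidate_knots=knot_grid, max_knots=max_knots)
    decision["spline_knots"] = list(sfit.knots)
    decision["spline_aicc"] = sfit.metrics.aicc
    return ConversionFormula(
        source=source, target=target, method="spline",
        spline_fit=sfit, knots=sfit.knots,
        provenance=f"fitted on {data.n} paired samples", decision=decision,
    )


def convert(
    formula: ConversionFormula, value, clamp: bool = False
) -> tuple[np.ndarray | float, list[str]]:
    """Apply a conversion formula to one value or a batch.

    Returns the full-precision result plus a list of warnings: input outside
    the source measuring range, or output outside the target range. With
    ``clamp=True`` out-of-range outputs are truncated to the target range;
    by default negative or out-of-range results are reported as-is.
    """
    arr = np.atleast_1d(np.asarray(value, dtype=float))
    if not np.all(np.isfinite(arr)):
        raise ValueError("values to convert must be finite")
    warnings: list[str] = []
    s_lo, s_hi = formula.source.measuring_range
    n_out = int(np.sum((arr < s_lo) | (arr > s_hi)))
    if n_out:
        warnings.append(
            f"{n_out} input value(s) outside the {formula.source.name} "
            f"measuring range {s_lo}-{s_hi} ng/mL"
        )
    out = np.atleast_1d(np.asarray(formula.predict(arr), dtype=float))
    t_lo, t_hi = formula.target.measuring_range
    n_out = int(np.sum((out < t_lo) | (out > t_hi)))
    if n_out:
        warnings.append(
            f"{n_out} converted value(s) outside the {formula.target.name} "
            f"measuring range {t_lo}-{t_hi} ng/mL"
        )
        if clamp:
            out = np.clip(out, t_lo, t_hi)
    if np.isscalar(value) or np.asarray(value).ndim == 0:
        return float(out[0]), warnings
    return out, warnings


def convert_batch(
    formula: ConversionFormula,
    frame: pd.DataFrame,
    value_column: str = "value",
    clamp: bool = False,
) -> tuple[pd.DataFrame, int]:
    """Row-wise conversion of a table; ids are preserved.

    Rows whose value cannot be parsed as a finite number are skipped and
    counted. The output gains a full-precision ``converted`` column, a 2-dp
    ``converted_2dp`` display column and a ``warnings`` column.
    """
    if value_column not in frame.columns:
        raise ValueError(f"no {value_column!r} column in input")
    values = pd.to_numeric(frame[value_column], errors="coerce")
    ok = values.notna() & np.isfinite(values.to_numpy(dtype=float, na_value=np.nan))
    n_skipped = int((~ok).sum())
    out = frame.loc[ok].copy()
    if len(out):
        converted, warns = convert(
            formula, out[value_column].to_numpy(dtype=float), clamp=clamp
        )
        out["converted"] = converted
        out["converted_2dp"] = [round2(v) for v in np.atleast_1d(converted)]
        out["warnings"] = "; ".join(warns)
    else:
        out["converted"] = []
        out["converted_2dp"] = []
        out["warnings"] = []
    return out, n_skipped


class Registry:
    """Built-in conversion formulas between the three AMH platforms."""

    def __init__(self) -> None:
        assays = builtin_assays()
        self._formulas: dict[tuple[str, str, str], ConversionFormula] = {}
        prov = "published three-platform AMH cross-calibration (300 sera)"
        for (src, tgt), coef in published.PB_COEFFICIENTS.items():
            self._formulas[(src, tgt, "pb")] = ConversionFormula(
                source=assays[src], target=assays[tgt], method="pb",
                intercept=coef["intercept"], slope=coef["slope"],
                intercept_ci=coef["intercept_ci"], slope_ci=coef["slope_ci"],
                provenance=prov,
            )
            # Spline conversions were published for the four pairs with a
            # systematic offset, but without coefficients: placeholders only.
            pb_fit_ci = coef["intercept_ci"]
            if not pb_fit_ci[0] <= 0.0 <= pb_fit_ci[1]:
                self._formulas[(src, tgt, "spline")] = ConversionFormula(
                    source=assays[src], target=assays[tgt], method="spline",
                    knots=published.SPLINE_KNOTS.get((src, tgt)),
                    provenance=prov + "; coefficients unavailable - refit required",
                )
        for name, spec in assays.items():
            self._formulas[(name, name, "pb")] = ConversionFormula(
                source=spec, target=spec, method="pb",
                intercept=0.0, slope=1.0, provenance="identity",
            )

    def get(self, source: str, target: str, method: str = "pb") -> ConversionFormula:
        key = (source.lower(), target.lower(), method)
        try:
            return self._formulas[key]
        except KeyError:
            avail = ", ".join(
                f"{s}->{t} ({m})" for s, t, m in sorted(self._formulas)
            )
            raise NoFormulaError(
                f"no formula for {source}->{target} ({method}); available: {avail}"
            ) from None

    def pairs(self) -> list[tuple[str, str, str]]:
        return sorted(self._formulas)


def registry() -> Registry:
    """The built-in set of published conversion formulas."""
    return Registry()
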