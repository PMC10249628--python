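"""Exception types shared across the package."""


class DegenerateDataError(ValueError):
    """Raised when data cannot support a fit (too few usable pairs, singular design)."""


class NoFormulaError(LookupError):
    """Raised when the registry holds no formula for a requested assay pair."""


class FormulaNotFittedError(RuntimeError):
    """Raised when a conversion formula lacks fitted coefficients.

    The published spline conversions ship without printed coefficients; such
    registry entries carry knots/provenance only and must be refit on paired
    data before they can convert values.
    """
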