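"""Published reference values from the three-platform AMH comparison study.

These constants reproduce the printed results of the cross-calibration study
of the Roche Elecsys, Beckman Access and Kangrun AMH immunoassays on 300
shared sera: measuring ranges, the six Passing-Bablok conversion
coefficients with their 95% confidence intervals, the spline knots reported
for the Roche-to-Beckman conversion, the quality-control summaries, the
stratified sampling design, and the original values of the worked example
samples. All concentrations are ng/mL.
"""

from __future__ import annotations

MEASURING_RANGES: dict[str, tuple[float, float]] = {
    "roche": (0.02, 24.0),
    "beckman": (0.01, 23.0),
    "kangrun": (0.06, 18.0),
}

# (source, target) -> intercept, intercept 95% CI, slope, slope 95% CI
PB_COEFFICIENTS: dict[tuple[str, str], dict] = {
    ("kangrun", "beckman"): {
        "intercept": -0.1027, "intercept_ci": (-0.1264, -0.0786),
        "slope": 1.1386, "slope_ci": (1.1194, 1.1607),
    },
    ("kangrun", "roche"): {
        "intercept": 0.0108, "intercept_ci": (-0.0035, 0.0303),
        "slope": 0.8683, "slope_ci": (0.85, 0.8844),
    },
    ("beckman", "roche"): {
        "intercept": 0.0868, "intercept_ci": (0.07, 0.1129),
        "slope": 0.7632, "slope_ci": (0.7429, 0.7789),
    },
    ("roche", "beckman"): {
        "intercept": -0.1138, "intercept_ci": (-0.1515, -0.0899),
        "slope": 1.3103, "slope_ci": (1.2840, 1.3462),
    },
    ("roche", "kangrun"): {
        "intercept": -0.0124, "intercept_ci": (-0.0356, 0.00393),
        "slope": 1.1517, "slope_ci": (1.1307, 1.1765),
    },
    ("beckman", "kangrun"): {
        "intercept": 0.0902, "intercept_ci": (0.0702, 0.1089),
        "slope": 0.8783, "slope_ci": (0.8615, 0.8933),
    },
}

# Spline knots were printed only for the Roche-to-Beckman conversion; the
# spline coefficients themselves were not published for any pair.
SPLINE_KNOTS: dict[tuple[str, str], tuple[float, ...]] = {
    ("roche", "beckman"): (1.0, 9.0),
}

# QC summaries: per control, the assigned target and the summary statistics
# printed from the 5-day x 4-replicate verification runs.
QC_SUMMARIES: list[dict] = [
    {"assay": "roche", "control": "Control 1", "target": 1.22,
     "mean": 1.17, "sd": 0.02, "cv_pct": 1.49, "bias_pct": -4.18},
    {"assay": "roche", "control": "Control 2", "target": 5.92,
     "mean": 5.89, "sd": 0.10, "cv_pct": 1.78, "bias_pct": -0.45},
    {"assay": "beckman", "control": "Control 1", "target": 1.01,
     "mean": 0.95, "sd": 0.04, "cv_pct": 4.51, "bias_pct": -6.24},
    {"assay": "beckman", "control": "Control 2", "target": 5.13,
     "mean": 5.02, "sd": 0.23, "cv_pct": 4.51, "bias_pct": -2.19},
    {"assay": "beckman", "control": "Control 3", "target": 15.2,
     "mean": 14.37, "sd": 0.34, "cv_pct": 2.38, "bias_pct": -5.44},
    {"assay": "kangrun", "control": "Control 1", "target": 2.39,
     "mean": 2.37, "sd": 0.09, "cv_pct": 3.67, "bias_pct": -0.92},
    {"assay": "kangrun", "control": "Control 2", "target": 5.8,
     "mean": 5.76, "sd": 0.21, "cv_pct": 3.59, "bias_pct": -0.69},
]

# Stratified sampling design of the 300 study sera: (low, high, n) in ng/mL;
# the top stratum is open-ended (high = inf).
SAMPLING_STRATA: list[tuple[float, float, int]] = [
    (0.02, 0.2, 30),
    (0.2, 0.4, 30),
    (0.4, 0.6, 30),
    (0.6, 0.8, 30),
    (0.8, 1.0, 30),
    (1.0, 1.5, 30),
    (1.5, 2.5, 30),
    (2.5, 3.5, 30),
    (3.5, 15.5, 30),
    (15.5, float("inf"), 30),
]

# Original measured values of the worked-example samples (ng/mL), as printed
# alongside the PB conversions. Two batches of six samples each.
WORKED_SAMPLES_A: list[dict] = [
    {"sample": 1, "beckman": 0.08, "roche": 0.08, "kangrun": 0.06},
    {"sample": 2, "beckman": 0.43, "roche": 0.39, "kangrun": 0.46},
    {"sample": 3, "beckman": 1.21, "roche": 1.04, "kangrun": 1.08},
    {"sample": 4, "beckman": 3.02, "roche": 2.23, "kangrun": 2.38},
    {"sample": 5, "beckman": 10.21, "roche": 6.90, "kangrun": 10.35},
    {"sample": 6, "beckman": 23.70, "roche": 18.50, "kangrun": 18.12},
]

WORKED_SAMPLES_B: list[dict] = [
    {"sample": 1, "beckman": 0.08, "roche": 0.05, "kangrun": 0.08},
    {"sample": 2, "beckman": 0.39, "roche": 0.38, "kangrun": 0.36},
    {"sample": 3, "beckman": 1.21, "roche": 1.04, "kangrun": 1.08},
    {"sample": 4, "beckman": 2.67, "roche": 2.33, "kangrun": 2.52},
    {"sample": 5, "beckman": 11.47, "roche": 7.21, "kangrun": 9.43},
    {"sample": 6, "beckman": 22.50, "roche": 16.00, "kangrun": 17.64},
]
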