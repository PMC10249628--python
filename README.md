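# amhbridge

Cross-platform conversion of anti-Müllerian hormone (AMH) measurements.

Serum AMH is the workhorse marker of ovarian reserve, but the automated
immunoassays that measure it — Roche Elecsys, Beckman Access, Kangrun —
disagree enough that a value from one platform cannot be read against
reference ranges or online tools built on another. `amhbridge` is for
laboratorians and reproductive-medicine researchers who need to translate
results between platforms, or to build and validate such translations for
their own assay pairs.

## What it does

- **Passing–Bablok regression** (`fit_pb`): the nonparametric
  method-comparison fit $y = a + bx$ whose slope is the shifted median of
  all pairwise slopes, with rank-based 95% CIs and systematic/proportional
  difference flags.
- **Linear spline regression** (`fit_spline`, `select_knots`): continuous
  piecewise-linear least squares on the basis $\{1, x, (x-k)_+\}$, with
  AICc-guided knot selection, for assay pairs whose relation changes across
  the concentration range.
- **The decision rule** (`build_conversion`): fit PB first; if the 95% CI
  of the intercept contains 0, the PB line is the conversion; otherwise a
  systematic difference exists and the spline is used.
- **Agreement diagnostics** (`bland_altman`, `mountain`): limits of
  agreement and folded-CDF mountain curves, with a consistency verdict.
- **QC evaluation** (`evaluate_qc`): CV / bias / total error of control
  replicates against 8% / 12% / 25% acceptance limits.
- **A conversion registry** (`registry`): the six published PB formulas
  between the three platforms, with measuring-range warnings, batch CSV
  conversion, and a thin `amhbridge` CLI.
- **Synthetic data** (`simulate_pairs`, `simulate_qc`): seeded generators
  reproducing the stratified 10 × 30 sampling design with proportional
  noise, used throughout the tests for parameter-recovery checks.

## Worked example

Convert Kangrun results onto the Roche scale with the built-in published
formula:

```bash
$ python examples/convert_values.py
formula: roche = 0.0108 + 0.8683 * kangrun
sample 1: kangrun   0.06 -> roche   0.06
sample 2: kangrun   0.46 -> roche   0.41
sample 3: kangrun   1.08 -> roche   0.95
sample 4: kangrun   2.38 -> roche   2.08
sample 5: kangrun  10.35 -> roche   9.00
sample 6: kangrun  18.12 -> roche  15.74  [1 input value(s) outside the kangrun measuring range 0.06-18.0 ng/mL]
```

Each line applies `roche = 0.0108 + 0.8683 × kangrun` (all ng/mL) and
rounds half-up to two decimals for display; the last sample exceeds the
Kangrun measuring range (0.06–18 ng/mL), so the result carries a warning.
The same conversion from the shell:

```bash
$ amhbridge convert --from kangrun --to roche --value 10.35
9.00
```

Fitting a conversion from your own paired data (CSV with columns
`sample_id,<assay_x>,<assay_y>`):

```bash
amhbridge fit --input pairs.csv --output formula.json
```

which prints the PB fit, the decision (PB or spline), and the selected
knots when a spline was needed. The other `examples/` scripts walk through
agreement diagnostics, QC evaluation, spline-vs-PB model comparison and
simulation; each prints a short, annotated result.

## Layout

- `src/amhbridge/` — the library (`pb`, `spline`, `agreement`, `qc`,
  `convert`, `simulate`, `published`, `cli`)
- `examples/` — one short narrative script per capability
- `tests/` — pytest suite with brute-force oracles and property tests
- `docs/methods.md` — models, numerical choices, limitations
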