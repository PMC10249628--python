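# Methods

`amhbridge` converts anti-Müllerian hormone (AMH) concentrations between
immunoassay platforms (Roche Elecsys, Beckman Access, Kangrun) and provides
the method-comparison statistics needed to build and judge such
conversions. This note records the models, the numerical choices, and what
the synthetic-data tests do and do not establish.

## Passing–Bablok regression

For paired measurements $(x_i, y_i)$ of the same sera on two platforms, the
conversion line $y = a + bx$ is estimated nonparametrically. All
$\binom{n}{2}$ pairwise slopes $S_{ij} = (y_j - y_i)/(x_j - x_i)$ are
formed, with three exclusions: pairs identical in both coordinates (0/0)
are dropped; pairs tied in $x$ only contribute $\pm\infty$ with the sign of
the $y$-difference, placed at the ends of the sort order; slopes exactly
$-1$ are removed. With $K$ the count of slopes below $-1$, the slope
estimate is the median of the sorted slopes with its index shifted by $K$
(even counts average the two central shifted order statistics). The shift
makes the estimator invariant under exchange of the axes: refitting with
the assays swapped returns $1/b$ and reciprocal CI bounds, which the suite
checks.

The slope CI uses the ranks $M_1 = \operatorname{round}((N - C)/2)$,
$M_2 = N - M_1 + 1$, with $C = z_{1-\alpha/2}\sqrt{n(n-1)(2n+5)/18}$,
shifted by $K$ and clamped to $[1, N]$; rounding is half-up. The intercept
is $\operatorname{median}(y_i - b x_i)$ and its CI bounds reuse the slope
CI bounds through the same median. A systematic difference is declared when
the intercept CI excludes 0; a proportional difference when the slope CI
excludes 1. No distributional or linearity checks are performed; those are
the caller's concern.

### Known limitation: CI coverage under proportional noise

The rank-based CI attains its nominal level under the classical
errors-in-both-variables model with homoscedastic errors (the suite
verifies ~95% slope coverage there). Immunoassay noise is predominantly
proportional, and across the three-decade AMH working range this
heteroscedasticity makes the intervals anti-conservative: on the stratified
synthetic design with CV 5% noise the 95% slope CI covers the true slope in
only ~85% of replicates. The acceptance suite asserts the nominal-coverage
expectation and therefore records this shortfall as a failure by design;
the slope *point* estimate remains accurate (within ±0.03 of truth in
>99% of replicates). Users who need honest interval coverage under strong
heteroscedasticity should bootstrap; that is outside the present scope.

## Linear spline regression and knot selection

When a systematic difference exists, a single line tends to fit the low
concentrations poorly — the inter-assay relation is "local". The conversion
is then a continuous piecewise-linear function: ordinary least squares on
the truncated-power basis $\{1, x, (x-k_1)_+, \dots\}$. Continuity at the
knots is the intended degree of smoothness; a linear spline with continuous
first derivatives would collapse to a single line. Beyond the observed
x-range the terminal segments continue linearly and the converter flags
such inputs as out of range.

Knot sets are chosen by exhaustive search over subsets (size 0–3 by
default) of a candidate grid — by default the interior deciles of $x$ plus
the clinically anchored 1 and 9 ng/mL — minimising AICc, with ties broken
toward fewer knots and then the smaller first knot. This replaces the
manual "inspect the scatter and adjust" refinement a human analyst would
do with a reproducible procedure. AICc selection is mildly greedy: on
straight-line data with noise it still admits a spurious knot in roughly
10% of replicates, and when a true knot exists it often keeps a cheap extra
knot alongside it. The tests therefore assert that the *true* knot is
contained in the selected set, not that the set is minimal.

## Fit metrics

$r^2 = 1 - SSE/SST$; adjusted $r^2 = 1 - (1-r^2)(n-1)/(n-p)$ with $p$ the
number of regression coefficients; $RMSE = \sqrt{SSE/n}$ (ng/mL). AIC uses
the full Gaussian log-likelihood with the residual variance counted as a
parameter: $AIC = n\ln 2\pi + n\ln(SSE/n) + n + 2(p+1)$ and
$AICc = AIC + 2(p+1)(p+2)/(n-p-2)$. Statistical packages differ in whether
they keep the constant terms and count $\sigma^2$; this convention is used
consistently, so model comparisons are internally valid (the suite
cross-checks it against statsmodels' OLS, whose AIC is exactly 2 smaller).
Fits whose SSE is at floating-point-noise level ($SSE \le 10^{-12}\,SST$)
are treated as exact: their AIC is $-\infty$ and parsimony tie-breaking
decides among them — without this, knot selection on noiseless data would
be driven by rounding error.

Passing–Bablok fits are compared with splines by computing the same
metrics from PB predictions with $p = 2$.

## Agreement diagnostics

Differences are second-named minus first-named assay. Bland–Altman limits
of agreement are $\bar d \pm 1.96\,s_d$ ($s_d$ with the $n-1$
denominator); the mean difference gets a $t$-based 95% CI. The mountain
curve folds the empirical CDF of the differences at 50% using the
$p_i = 100\,i/(n+1)$ percentile convention. The packaged verdict calls two
assays "consistent" iff at least 95% of samples (configurable) fall inside
the LoA and the mean-difference CI contains 0 — an operational reading of
the usual prose criterion. Under i.i.d. normal differences ~5% of points
fall outside the LoA, which the suite checks at n = 10 000.

## QC evaluation

Controls measured four times daily for five days are summarised by a single
pooled SD (the within/between-day structure is retained in the data type
but not decomposed, matching how kit inserts report precision):
$CV = 100\,s/\bar x$, $bias = 100(\bar x - T)/T$ against the assigned
target $T$, and total error $|bias| + 1.96\,CV$ (Westgard form). Default
acceptance limits: CV ≤ 8%, |bias| ≤ 12%, TE ≤ 25%.

## The decision procedure and the registry

`build_conversion` fits PB first; if the intercept CI contains 0 (closed
interval — a bound exactly at 0 counts, conservatively favouring the
simpler model) the PB line is the conversion, otherwise the AICc-selected
spline is. The registry ships the six published PB formulas between the
three platforms, with measuring ranges Roche 0.02–24, Beckman 0.01–23,
Kangrun 0.06–18 ng/mL. The published spline conversions were reported
without coefficients (only the 1 and 9 ng/mL knots for Roche→Beckman), so
their registry entries are explicit placeholders that refuse to convert
until refit on paired data — silently substituting the PB line would
misrepresent the published method. Display rounding is half-up at two
decimals, which reproduces all arithmetically consistent printed example
conversions; computation keeps full precision, negative outputs near the
detection limit are reported (with a range warning) rather than suppressed,
and clamping to the target range is opt-in.

## Synthetic data

The generator emulates the study design: ten concentration strata
(<0.2 up to ≥15.5 ng/mL) of 30 samples each, uniform within bounded strata
and log-uniform in the open-ended top stratum up to 24 ng/mL (the widest
platform range). The target-assay value is
$y = f(x)(1+\varepsilon_p) + \varepsilon_a$ with Gaussian proportional
noise (default CV 5%) and a 0.02 ng/mL additive floor — values chosen to
match the precision the platforms demonstrate in QC and to produce the
variance heterogeneity visible in real Bland–Altman plots. QC replicates
are Gaussian around the target at a stated CV in the 5-day × 4-replicate
layout. All draws are seeded and bit-reproducible.

What the generator does not emulate: measurement error on the source axis
(the generating $x$ is treated as the source assay's reading), antibody
cross-reactivity, matrix effects, dilution-step error above the measuring
range, or non-Gaussian outliers. Passing tests on this generator therefore
demonstrate estimator correctness and calibration under a clean version of
the study's sampling design, not robustness to every artefact of real sera.

## Problem sizes used in the test suite

Stochastic checks use 200 replicates of the 300-sample design for PB
recovery and coverage, 100 replicates for knot-selection behaviour, and
n = 10 000 for the LoA calibration check — sizes at which the Monte-Carlo
error is comfortably below the asserted margins while the whole suite runs
in well under a minute of simulation time.
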