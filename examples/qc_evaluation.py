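"""Precision and trueness check of a control, EP15-style.

Simulates one quality-control serum (target 2.39 ng/mL) measured four times
a day for five days with a true CV of 3.7%, then evaluates CV, bias and
total error against the 8% / 12% / 25% acceptance limits.
"""

from amhbridge import evaluate_qc, simulate_qc

series = simulate_qc(target=2.39, cv_pct=3.7, seed=5, control_id="control-1")
ev = evaluate_qc(series)
print(f"{ev.control_id}: n={series.n} replicates over 5 days")
print(f"  mean {ev.mean:.3f} ng/mL vs target {ev.target:.2f} ng/mL")
print(f"  CV   {ev.cv_pct:.2f}%  (limit {ev.limits.cv}%)  -> {'pass' if ev.pass_cv else 'FAIL'}")
print(f"  bias {ev.bias_pct:+.2f}% (limit +-{ev.limits.bias}%) -> {'pass' if ev.pass_bias else 'FAIL'}")
print(f"  TE   {ev.total_error_pct:.2f}% (limit {ev.limits.te}%)  -> {'pass' if ev.pass_te else 'FAIL'}")
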