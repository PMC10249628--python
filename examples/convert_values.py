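"""Convert AMH values between platforms with the built-in published formulas.

Takes the six worked-example sera measured on the Kangrun platform and maps
them onto the Roche Elecsys scale with the published Passing-Bablok formula
(roche = 0.0108 + 0.8683 * kangrun). The printed numbers are ng/mL at the
2-decimal display rounding; values outside a platform's measuring range are
flagged rather than suppressed.
"""

from amhbridge import convert, registry, round2
from amhbridge.published import WORKED_SAMPLES_A

formula = registry().get("kangrun", "roche")
print(f"formula: {formula.target.name} = {formula.intercept} + {formula.slope} * {formula.source.name}")
for row in WORKED_SAMPLES_A:
    value, warnings = convert(formula, row["kangrun"])
    note = f"  [{'; '.join(warnings)}]" if warnings else ""
    print(f"sample {row['sample']}: kangrun {row['kangrun']:6.2f} -> roche {round2(value):6.2f}{note}")
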