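"""Evaluate the five response-curve families at the combined-taxa parameters.

Prints detection probability against the number of humans recorded the same
day at a camera.  The Arps curve with d = 0.784 drops steeply over the
first one-to-three people and then flattens — the signature of discounting —
while exponential decay with the same sensitivity collapses far too fast.
"""

import numpy as np

from fearcurve import CurveParams, ModelForm, eval_curve, encounter_interval

params = CurveParams(y0=0.724, sensitivity=5.00, discount=0.784)
x = np.array([0, 1, 2, 3, 5, 10, 20], dtype=float)

print("humans/day:", "  ".join(f"{int(v):>6d}" for v in x))
for form in ModelForm:
    y = eval_curve(form, x, params)
    print(f"{form.value:>11s}:", "  ".join(f"{v:6.3f}" for v in y))

print()
print("Detection starts at y0 = 0.724 when nobody visits; the discounting")
print("forms (hyperbolic, harmonic, arps) keep a detectable tail at high")
print("disturbance where the exponential model has already hit zero.")
print()
print("Encounter arithmetic: 1 visitor/day is one disturbance per "
      f"{encounter_interval(1):.0f} min (24 h), 2/day per {encounter_interval(2):.0f} min;")
print(f"going from 20 to 21 visitors only moves the interval from "
      f"{encounter_interval(20):.1f} to {encounter_interval(21):.1f} min — "
      "why the first few people matter most.")
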