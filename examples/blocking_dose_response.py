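"""Dose-effect curve of stable-iodine thyroid blocking and its ED50.

Sweeps stable-iodine doses for a week-24 pregnancy (700 kBq I-131 given
simultaneously), once with only the competition at the NIS carrier and
once with the Wolff-Chaikoff uptake block enabled, then summarises each
curve with a Hill fit.  A coarse 13-point grid keeps the demo quick; the
analysis default is 25 points.
"""

import numpy as np

from thyroblock import dose_response, fit_hill

WEEK = 24
doses = np.logspace(-1, 3, 13)

for wc, label in ((False, "competition only"), (True, "with Wolff-Chaikoff")):
    pts = dose_response(WEEK, doses_mg=doses, wc_enabled=wc)
    fit = fit_hill(pts)
    print(f"{label}:")
    for p in pts[4:10]:
        print(f"  {p.stable_dose_mg:8.2f} mg -> efficacy {p.efficacy:.4f}")
    print(f"  Hill fit: ED50 = {fit.ed50_mg:.4g} mg, b = {fit.b:.3g}\n")

print("ED50 is the stable-iodine dose halving the thyroid dose.  The")
print("Wolff-Chaikoff switch shifts it from ~150 mg down to ~1.5 mg and")
print("steepens the curve (larger Hill coefficient).")
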