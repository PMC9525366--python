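"""Onset of the Wolff-Chaikoff uptake block across pregnancy.

After 100 mg of stable iodine the maternal gland saturates (content
increase of 350 ug) within minutes; the fetal gland saturates later
because the iodide must first cross the placenta and build up in the
fetal circulation.  The onset shortens over gestation as the carrier
capacities grow.
"""

from thyroblock import SUPPORTED_WEEKS, onset_time

print("week   maternal onset (min)   fetal onset (min)")
for week in SUPPORTED_WEEKS:
    t = onset_time(week, stable_dose_mg=100.0, horizon_d=5.0)
    fetal = "-" if t["fetal"] is None else f"{t['fetal']:.1f}"
    print(f"{week:4d}   {t['maternal']:20.2f}   {fetal:>17}")
print()
print("Fetal values depend on the assumed fetal saturation content")
print("(adult gland iodine concentration scaled to the fetal gland weight).")
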