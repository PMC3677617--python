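"""Worm-like-chain basics and cantilever calibration.

Evaluates the Marko-Siggia force law for a typical unfolded polypeptide,
inverts it, and calibrates a cantilever from its thermal deflection
variance via the equipartition theorem.
"""

import numpy as np

import rejmech as rm

params = rm.WLCParams(persistence_length_p=0.4, contour_length_Lc=100.0,
                      temperature_T=298.0)

print("WLC force-extension (p = 0.4 nm, Lc = 100 nm, T = 298 K):")
for frac in (0.25, 0.5, 0.75, 0.9, 0.95):
    f = rm.wlc_force(frac * 100.0, params)
    print(f"  x = {frac * 100:5.1f} nm  ->  F = {f:8.2f} pN")
print("The force diverges as the extension approaches the contour length —")
print("that steep rise is what makes per-peak contour lengths fittable.")

f = 150.0
x = rm.invert_wlc(f, params)
print(f"\nInverse: F = {f} pN is reached at x = {x:.2f} nm "
      f"({100 * x / 100.0:.1f}% of Lc)")

var = 0.08229  # nm^2 thermal deflection variance
k = rm.spring_constant_equipartition(var, temperature=298.0)
print(f"\nEquipartition calibration: <dx^2> = {var} nm^2  ->  "
      f"k = {k:.1f} pN/nm")
print("Every recorded force in a pull is deflection x this spring constant.")
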