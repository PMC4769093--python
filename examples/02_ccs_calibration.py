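"""Fit a travelling-wave CCS calibration and estimate an unknown's CCS.

Synthetic calibrants are generated exactly on a power law (reduced CCS
= 400 * corrected-drift^0.55), the fit recovers the law, and the forward
estimate on a fresh ion round-trips through the exact inverse.
"""

import math

from oligoscreen import Calibrant, estimate_ccs, fit_calibration, invert_ccs
from oligoscreen.calibration import N2_MASS

A_TRUE, B_TRUE, EDC = 400.0, 0.55, 1.41

calibrants = []
for i in range(8):
    mass, charge = 3000.0 + 1500.0 * i, 1 + i % 3
    t_prime = 2.0 + 0.8 * i
    omega_prime = A_TRUE * t_prime**B_TRUE
    ccs = omega_prime * charge * math.sqrt(1.0 / mass + 1.0 / N2_MASS)
    t_d = t_prime + EDC * math.sqrt(mass / charge) / 1000.0
    calibrants.append(Calibrant(f"cal{i}", mass, charge, ccs, t_d))

cal = fit_calibration(calibrants, edc_delay=EDC)
print(f"fitted power law: A = {cal.A:.6f}, B = {cal.B:.6f}, r^2 = {cal.r_squared:.6f}")

# estimate the CCS of an amyloid-beta dimer 4+ ion arriving at 7.0 ms
mass, z, t_d = 2 * 4329.86 + 4 * 1.007276, 4, 7.0
ccs = estimate_ccs(t_d, mass / z, z, mass, cal)
print(f"dimer 4+ at {t_d} ms -> CCS {ccs:.1f} A^2")
print(f"inverse check: {invert_ccs(ccs, z, mass, cal):.6f} ms (should be {t_d})")
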