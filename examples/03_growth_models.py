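"""Compare isotropic, linear and spherical oligomer growth models.

Simulates an apo spectrum whose drift times encode linear (fibril-like)
growth, estimates each oligomer's CCS from the lowest observed charge
state, and lets AICc pick the growth law back out.
"""

from oligoscreen import CcsSeries, assign_spectrum, estimate_ccs, fit_growth, simulate_apo
from oligoscreen.growth import selected_model
from oligoscreen.synth import abeta40_scenario, default_calibration

scenario = abeta40_scenario(seed=0, noise_cv=0.0)
calibration = default_calibration()

result = assign_spectrum(simulate_apo(scenario), scenario.peptide, calibration=calibration)

# lowest charge state per oligomer order (least Coulombically distorted)
lowest = {}
for a in result.assignments:
    if a.n not in lowest or a.z < lowest[a.n].z:
        lowest[a.n] = a

points = []
for n, a in sorted(lowest.items()):
    mass = n * scenario.peptide.monomer_mass + a.z * 1.007276
    ccs = estimate_ccs(a.peak.drift_time, a.peak.mz, a.z, mass, calibration)
    points.append((n, ccs, a.z))
    print(f"n={n}  z={a.z}  CCS = {ccs:7.1f} A^2")

fits = fit_growth(CcsSeries(points), scenario.peptide.monomer_mass)
print("\nmodel comparison (lower AICc wins):")
for f in fits:
    mark = " <- selected" if f.selected else ""
    print(f"  {f.model:10s} rss={f.rss:10.3e} aicc={f.aicc:8.2f}{mark}")
best = selected_model(fits)
print(f"\nselected: {best.model} {best.params}")
# Linear growth from the trimer up is the signature of extended,
# protofibril-like assembly rather than compact globular oligomers.
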