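# Methods

## Species arithmetic and assignment

All mass arithmetic uses *average* masses: the target peptides are ~4 kDa
and their oligomers appear as unresolved isotope envelopes, so centroid
positions track the average mass. A positive-mode species [nP + lL + zH]ᶻ⁺
sits at m/z = (n·M + l·M_L + z·m_H)/z with m_H = 1.007276 Da (no
electron-mass correction; it is ~0.1 ppm, far below the matching tolerance).
Monoisotopic masses can be passed through the same functions unchanged.

Assignment enumerates the full candidate grid — oligomer orders 1..n_max,
the peptide's charge range, ligand adduct counts 0..l_max, plus ligand
self-multimers 1..j_max (recorded as n = 0, l = j; searched at charge 1 by
default, since drug-like small molecules rarely carry more) — inside a ppm
window. The default tolerance is 50 ppm: average-mass centroiding on a Q-ToF
does not support better, and the synthetic grid spacing is orders of
magnitude coarser, so the window is not a sensitive knob. Peaks below 0.5%
of the base peak are ignored as noise.

m/z is invariant under common integer scaling of (n, z, l), so degenerate
candidate sets are routine (dimer⁴⁺ = trimer⁶⁺ = monomer²⁺ ...). They are
resolved by drift time: each candidate's CCS is predicted from a growth
prior, pushed through the inverse calibration to a predicted arrival time,
and the nearest candidate to the observed drift wins; exact ties break
toward smaller n (parsimony). The default prior is the isotropic law
anchored at the spherical monomer CCS (density 0.44 Da/Å³) — parameter-free,
and within ~10% of a linear-growth truth over n ≤ 6, which is ample because
the decision only needs the *ordering* of candidate drifts, and the
degenerate candidates' reduced cross sections Ω′ = Ω/(z√(1/m+1/m_gas))
differ by tens of percent. Ligand adducts scale a species' CCS by the ⅔
power of its mass ratio (volume without shape change); ligand multimers use
the spherical CCS of their own mass.

## Travelling-wave CCS calibration

The standard corrected-drift / reduced-CCS protocol: correct each drift for
the mobility-independent transit t_d′ = t_d − EDC·√(m/z)/1000 (EDC default
1.41 in instrument-native units — instrument-specific, always overridable);
reduce literature CCS values for charge and reduced mass against the drift
gas (N₂, 28.0134 Da); fit ln Ω′ = ln A + B·ln t_d′ by ordinary least squares
(scipy linregress). One global fit serves all charge states, as is standard
when calibrating with denatured proteins and peptides jointly. The exponent
is sanity-checked to (0, 2). `invert_ccs` is the exact algebraic inverse and
is what the synthetic generator uses to plant drift times, which is why
estimate∘invert round-trips to numerical precision.

## Growth models

Isotropic growth σ_n = σ₁·n^⅔ (one parameter), linear growth σ_n = a·n + k
with a the per-monomer cross-section increment and k the fibril-cap term
(two parameters), and the parameter-free spherical model: volume n·M/ρ at
ρ = 0.44 Da/Å³, CCS = projected area πr². A ρ-fitted spherical variant
(one parameter) is available.

Fits are least squares on **relative** residuals (weights 1/CCS). Calibrated
CCS values carry multiplicative, roughly constant-CV error, so relative
weighting is the matched estimator; it also keeps the monomer point — which
carries most of the curve-shape information — from being drowned by the
absolute scale of the larger oligomers. On noiseless data the weighted and
unweighted parameter estimates coincide; `weighting="absolute"` restores the
unweighted fit. Model selection is by AICc computed from the (weighted) RSS,
with parameter counts 1/2/0 (isotropic/linear/spherical); with fewer than
four points the correction term is undefined for the linear model and the
comparison degrades gracefully to "not selectable" (infinite AICc). An exact
fit floors the RSS at 1e-300 before the log. Conventionally the CCS of the
lowest observed charge state represents each oligomer (least Coulombic
distortion), as in `examples/03_growth_models.py`.

## Binding-mode classifier

Adduct stoichiometry is read off the monomer charge states (the species
adduct counts are annotated on experimentally; peptide oligomers are not
observed to carry ligand). Profiles are intensity-normalised per charge
state and pooled by intensity weight. Decision cascade:

1. **colloidal** if ligand self-multimers span ≥ 2 orders and sum to > 2% of
   the base peak — self-association contaminates any stoichiometry readout,
   so this check precedes the distribution fits;
2. **negative** if the bound fraction (peptide ion current with l ≥ 1 over
   total peptide current) is below 5% — deliberately low, because
   hydrophobic contacts survive the gas phase only partially and genuine
   binders can show weak adduction; the threshold is configurable;
3. otherwise **specific** vs **non-specific** by comparing the RSS of the
   best binomial fit (grid over integer site counts N with the closed-form
   moment estimate p̂ = mean(l)/N per N) against the best
   truncated-renormalised Poisson fit (rate by bounded 1-D minimisation
   started at the profile mean). RSS on normalised profiles is used rather
   than a likelihood ratio because the ion-current-to-count mapping is
   unknown; the margin (Poisson RSS − binomial RSS) is reported so callers
   can impose their own cutoff.

Binomial(N, c/N) converges to Poisson(c), so the margin necessarily shrinks
as N grows at fixed mean occupancy; the test suite asserts this trend at
N ∈ {2, 5, 10, 20}. Depletion metrics (largest observed oligomer order and
oligomer intensity fraction, holo vs apo) are always computed when an apo
reference is available: a "positive" inhibitor verdict is the specific mode,
with depletion reported as corroborating evidence rather than a gate.
Profiles with all intensity at l = 0 return degenerate fits rather than
errors.

## Synthetic generator

The generator is the package's ground-truth oracle, not a fixture. The
default scenario emulates a freshly diluted amyloid-β(1-40) oligomer
mixture: monomer through hexamer with geometrically decaying abundance
(ratio 0.45 — monomer-dominated, higher orders at a few percent, matching a
spectrum acquired within minutes of dilution); native-like charge states
rising with oligomer order (monomer 3+/4+, dimer 4+/5+, ... hexamer 8+),
which plants the dimer⁴⁺/trimer⁶⁺ degeneracy; linear growth truth a = 250 Å²
per monomer over a k = 380 Å² cap (monomer ≈ 630 Å², in the range measured
for 4 kDa amyloid peptides); and a synthetic calibration A = 400, B = 0.55
yielding drift times of 3–8 ms. The hIAPP scenario reuses the structure with
the hIAPP average mass (3903.33 Da) and a proportionally smaller growth law.

Intensity noise is multiplicative lognormal parameterised by CV, with the
mean fixed at 1 so noise does not bias total ion current; the default screen
condition is CV = 0.05. The generator is deterministic per seed, and plate
wells derive their seeds as SHA-256(seed:compound_id) mod 2³¹. Binding
signatures conserve ion current: binomial and truncated-Poisson adduct
weights sum to 1 per charge state. Colloidal spectra add a singly charged
jL multimer series (orders 2–5, geometric decay 0.7, amplitude 25% of the
base peak) and a peptide+jL series with the same decay; the decay and
amplitude are configurable since real colloids vary widely. The focused
plate plants 20 compounds with drug-like masses (228–394 Da): two specific
binders (N = 2 sites, p = 0.3, full depletion above the trimer), one
colloidal, two non-specific (λ = 1), fifteen negative.

What the generator does *not* emulate: isotope structure, peak width and
overlap, detector saturation, chemical background, drift-time noise, or
charge-state-dependent CCS shifts. Passing tests therefore demonstrate that
the analysis chain is correct and self-consistent under planted truth —
assignment inverts the generator exactly at zero noise — not that real
spectra of this quality will classify as cleanly; on instrument data the
practical limits are centroiding quality and the colloid/bind thresholds.

## Numerical choices and degenerate inputs

Peak-list I/O is plain CSV (columns mz, drift_time, intensity) written at
full float precision; malformed rows are counted and reported, not fatal.
Corrected drift times ≤ 0 raise a calibration-domain error (the recorded
drift is shorter than the mobility-independent transit). Calibration needs
≥ 3 calibrants with distinct corrected drifts; growth fitting needs ≥ 3
points; model selection with an exactly zero RSS is handled by the RSS
floor. A degenerate peak with multiple candidates but no calibration is
returned unassigned with a degeneracy flag rather than guessed. Screens
record per-compound failures and continue.

## Problem sizes

Default test and reproduction runs use the 10-peak apo spectrum (6 oligomer
orders), 20-compound plates, 8 calibrants, 100 replicates for the
growth-selection and classifier recovery rates, and n = 1..6 CCS series —
sizes chosen to mirror the focused-screen setting while keeping any run in
seconds.
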