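"""Synthetic ESI-IMS-MS spectrum generator with planted ground truth.

Generates centroided peak lists that emulate a native ion-mobility mass
spectrum of an aggregating peptide: a charge-state envelope per oligomer
order, drift times consistent with a chosen growth model routed through the
travelling-wave calibration, and the four ligand-binding signatures the
classifier distinguishes:

* **specific** — per charge state, intensity across l = 0..N adducts follows
  Binomial(N, p) (saturable occupancy of N equivalent sites); optionally
  combined with depletion of higher-order oligomers, the spectral signature
  of an aggregation inhibitor;
* **non_specific** — intensity across l = 0..l_max follows a truncated,
  renormalised Poisson(lambda) (random adduction during droplet desolvation);
* **colloidal** — ligand self-multimer peaks jL plus a slowly decaying
  peptide+jL series (the small molecule aggregates and sequesters peptide);
* **negative** — the spectrum is identical to the apo peptide alone.

Intensity noise is multiplicative lognormal parameterised by a coefficient
of variation, applied per peak; the generator is deterministic for a fixed
seed.  Adduct redistribution conserves ion current: with zero noise the
intensities over l for a charge state sum to that charge state's apo
intensity.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from oligoscreen.calibration import CcsCalibration, invert_ccs
from oligoscreen.growth import (
    predict_isotropic,
    predict_linear,
    predict_spherical,
)
from oligoscreen.spectrum import (
    PROTON_MASS,
    LigandSpec,
    Peak,
    PeptideSpec,
    species_mz,
    multimer_mz,
)

#: Average mass of the 40-residue amyloid-beta peptide, Da.
ABETA40_MASS = 4329.86

#: Average mass of human islet amyloid polypeptide (37 residues, amidated,
#: one disulfide), Da.
HIAPP_MASS = 3903.33


def default_calibration() -> CcsCalibration:
    """Synthetic travelling-wave calibration used by the generator.

    A=400, B=0.55 with the default EDC delay and N2 drift gas gives drift
    times of a few ms for 4 kDa peptide ions, in the range of a real
    travelling-wave separation.
    """
    return CcsCalibration(A=400.0, B=0.55, r_squared=1.0)


@dataclass
class OligomerScenario:
    """Ground truth for an apo (peptide-only) spectrum.

    ``abundance_by_n`` maps oligomer order to relative abundance (sums to 1);
    ``charge_envelope`` maps oligomer order to per-charge weights (each
    summing to 1).  ``growth_model`` and ``growth_params`` define the true
    CCS-vs-n law used to synthesise drift times through ``calibration``.
    """

    peptide: PeptideSpec
    abundance_by_n: dict[int, float]
    charge_envelope: dict[int, dict[int, float]]
    growth_model: str = "linear"
    growth_params: dict[str, float] = field(default_factory=lambda: {"a": 250.0, "k": 380.0})
    noise_cv: float = 0.0
    seed: int = 0
    calibration: CcsCalibration = field(default_factory=default_calibration)

    def __post_init__(self) -> None:
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        total = sum(self.abundance_by_n.values())
        if any(a < 0 for a in self.abundance_by_n.values()):
            raise ValueError("abundances must be >= 0")
        if abs(total - 1.0) > 1e-6:
            raise ValueError(f"abundances must sum to 1, got {total}")
        for n in self.abundance_by_n:
            if n < 1 or n > self.peptide.n_max:
                raise ValueError(f"abundance references n={n} outside 1..n_max")
        for n in self.abundance_by_n:
            if n not in self.charge_envelope:
                raise ValueError(f"no charge envelope for oligomer order {n}")

    def true_ccs(self, n: int) -> float:
        """CCS of the bare n-mer under the scenario's growth truth."""
        if self.growth_model == "isotropic":
            return float(predict_isotropic(n, self.growth_params["sigma_monomer"]))
        if self.growth_model == "linear":
            return float(predict_linear(n, self.growth_params["a"], self.growth_params["k"]))
        if self.growth_model == "spherical":
            return float(
                predict_spherical(
                    n, self.peptide.monomer_mass, self.growth_params.get("rho", 0.44)
                )
            )
        raise ValueError(f"unknown growth model {self.growth_model!r}")


@dataclass
class BindingScenario:
    """Ground truth for a compound's binding mode.

    Only the parameters of the declared mode are consulted.  For specific
    binding, ``depletion_factor`` multiplies the abundance of oligomers with
    order above ``depletion_cutoff`` (0 removes them entirely — the
    higher-order-oligomer depletion an inhibitor produces).
    """

    mode: str
    binomial_sites: int = 2
    occupancy: float = 0.3
    poisson_rate: float = 1.0
    colloid_multimer_range: tuple[int, int] = (2, 5)
    colloid_decay: float = 0.7
    colloid_amplitude: float = 0.25
    depletion_factor: float = 1.0
    depletion_cutoff: int = 3

    def __post_init__(self) -> None:
        if self.mode not in ("specific", "non_specific", "colloidal", "negative"):
            raise ValueError(f"unknown binding mode {self.mode!r}")
        if self.mode == "specific":
            if self.binomial_sites < 1:
                raise ValueError("specific mode needs binomial_sites >= 1")
            if not 0 <= self.occupancy <= 1:
                raise ValueError("occupancy must lie in [0, 1]")
        if self.mode == "non_specific" and not self.poisson_rate > 0:
            raise ValueError("non_specific mode needs poisson_rate > 0")
        if not 0 <= self.depletion_factor <= 1:
            raise ValueError("depletion_factor must lie in [0, 1]")


def _ligand_scaled_ccs(ccs_bare: float, n: int, l: int, M: float, ML: float) -> float:
    # Ligand adducts add volume, not shape change: scale CCS by the 2/3 power
    # of the mass ratio, the same convexity as the spherical model.
    if l == 0:
        return ccs_bare
    return ccs_bare * ((n * M + l * ML) / (n * M)) ** (2.0 / 3.0)


def _noise_factors(rng: np.random.Generator, cv: float, size: int) -> np.ndarray:
    if cv == 0:
        return np.ones(size)
    sigma = np.sqrt(np.log1p(cv**2))
    # mean-1 lognormal so noise does not bias total ion current
    return rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=size)


def _species_drift(
    scenario: OligomerScenario,
    n: int,
    z: int,
    l: int = 0,
    ligand: LigandSpec | None = None,
) -> float:
    M = scenario.peptide.monomer_mass
    ML = ligand.ligand_mass if ligand is not None else 0.0
    ccs = _ligand_scaled_ccs(scenario.true_ccs(n), n, l, M, ML)
    mass = n * M + l * ML + z * PROTON_MASS
    return invert_ccs(ccs, z, mass, scenario.calibration)


def simulate_apo(scenario: OligomerScenario) -> list[Peak]:
    """Simulate the apo (peptide-only) spectrum: one peak per (n, z) pair."""
    rng = np.random.default_rng(scenario.seed)
    entries: list[tuple[int, int, float]] = []
    for n in sorted(scenario.abundance_by_n):
        abundance = scenario.abundance_by_n[n]
        for z in sorted(scenario.charge_envelope[n]):
            weight = scenario.charge_envelope[n][z]
            entries.append((n, z, abundance * weight))
    noise = _noise_factors(rng, scenario.noise_cv, len(entries))
    peaks = [
        Peak(
            mz=species_mz(n, z, 0, scenario.peptide),
            drift_time=_species_drift(scenario, n, z),
            intensity=base * f,
        )
        for (n, z, base), f in zip(entries, noise)
    ]
    peaks.sort(key=lambda p: p.mz)
    return peaks


def _adduct_weights(binding: BindingScenario, l_max: int) -> np.ndarray:
    """Per-adduct-count intensity weights (sum to 1) for the declared mode."""
    if binding.mode == "specific":
        N = binding.binomial_sites
        ls = np.arange(N + 1)
        return stats.binom.pmf(ls, N, binding.occupancy)
    if binding.mode == "non_specific":
        ls = np.arange(l_max + 1)
        pmf = stats.poisson.pmf(ls, binding.poisson_rate)
        return pmf / pmf.sum()  # truncated and renormalised
    raise ValueError(f"no adduct weights for mode {binding.mode!r}")


def simulate_holo(
    scenario: OligomerScenario,
    binding: BindingScenario,
    ligand: LigandSpec,
) -> list[Peak]:
    """Simulate a peptide-plus-compound spectrum for one binding mode.

    Ligand adducts are planted on the monomer charge states, the species on
    which adduct counts are read out experimentally (higher oligomers of the
    target peptide are not observed to bind); colloidal mode adds a ligand
    self-multimer series and a peptide+jL series on top of the apo spectrum.
    """
    if binding.mode == "negative":
        return simulate_apo(scenario)

    rng = np.random.default_rng(scenario.seed)
    M = scenario.peptide.monomer_mass

    abundance = dict(scenario.abundance_by_n)
    if binding.mode == "specific" and binding.depletion_factor < 1.0:
        abundance = {
            n: (a * binding.depletion_factor if n > binding.depletion_cutoff else a)
            for n, a in abundance.items()
        }

    entries: list[tuple[int, int, int, float]] = []  # (n, z, l, base intensity)
    for n in sorted(abundance):
        for z in sorted(scenario.charge_envelope[n]):
            base = abundance[n] * scenario.charge_envelope[n][z]
            if base == 0:
                continue
            if n == 1 and binding.mode in ("specific", "non_specific"):
                weights = _adduct_weights(binding, ligand.l_max)
                for l, w in enumerate(weights):
                    entries.append((n, z, l, base * float(w)))
            else:
                entries.append((n, z, 0, base))

    peaks: list[Peak] = []
    noise = _noise_factors(rng, scenario.noise_cv, len(entries))
    for (n, z, l, base), f in zip(entries, noise):
        peaks.append(
            Peak(
                mz=species_mz(n, z, l, scenario.peptide, ligand),
                drift_time=_species_drift(scenario, n, z, l, ligand),
                intensity=base * f,
            )
        )

    if binding.mode == "colloidal":
        base_peak = max(p.intensity for p in peaks)
        j_lo, j_hi = binding.colloid_multimer_range
        colloid_entries: list[tuple[float, float, float]] = []  # (mz, drift, base)
        # ligand-only multimer series jL (singly charged)
        for j in range(j_lo, j_hi + 1):
            amp = binding.colloid_amplitude * base_peak * binding.colloid_decay ** (j - j_lo)
            mass = j * ligand.ligand_mass + PROTON_MASS
            ccs = float(predict_spherical(1, mass))
            drift = invert_ccs(ccs, 1, mass, scenario.calibration)
            colloid_entries.append((multimer_mz(j, 1, ligand), drift, amp))
        # peptide + jL series on the monomer charge states
        for z in sorted(scenario.charge_envelope.get(1, {})):
            base = abundance.get(1, 0.0) * scenario.charge_envelope[1][z]
            for j in range(1, j_hi + 1):
                amp = binding.colloid_amplitude * base * binding.colloid_decay ** (j - 1)
                colloid_entries.append(
                    (
                        species_mz(1, z, j, scenario.peptide, ligand),
                        _species_drift(scenario, 1, z, j, ligand),
                        amp,
                    )
                )
        cnoise = _noise_factors(rng, scenario.noise_cv, len(colloid_entries))
        for (mz, drift, base), f in zip(colloid_entries, cnoise):
            peaks.append(Peak(mz=mz, drift_time=drift, intensity=base * f))

    peaks.sort(key=lambda p: p.mz)
    return peaks


def compound_seed(plate_seed: int, compound_id: str) -> int:
    """Deterministic per-compound seed: SHA-256 of "<seed>:<compound_id>"."""
    digest = hashlib.sha256(f"{plate_seed}:{compound_id}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def simulate_screen(
    plate: Sequence[tuple[LigandSpec, BindingScenario]],
    scenario: OligomerScenario,
) -> dict[str, list[Peak]]:
    """Simulate one peak list per plate compound with derived per-well seeds."""
    ids = [lig.compound_id for lig, _ in plate]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate compound_id in plate")
    out: dict[str, list[Peak]] = {}
    for lig, binding in plate:
        well_scenario = replace(scenario, seed=compound_seed(scenario.seed, lig.compound_id))
        out[lig.compound_id] = simulate_holo(well_scenario, binding, lig)
    return out


#: Binding mode of each compound of the focused 20-compound screen against
#: the amyloid-beta(1-40) target: two specific inhibitors (3 and 16), one
#: colloidal aggregator (9), two non-specific binders (15 and 17), the rest
#: negative.
AB40_SCREEN_MODES: dict[str, str] = {
    str(i): "negative" for i in range(1, 21)
} | {"3": "specific", "16": "specific", "9": "colloidal", "15": "non_specific", "17": "non_specific"}

#: The same compounds screened against human IAPP: identical verdicts except
#: compound 3 (non-specific instead of specific) and compound 9 (negative
#: instead of colloidal) — 18 of 20 in agreement.
HIAPP_SCREEN_MODES: dict[str, str] = AB40_SCREEN_MODES | {"3": "non_specific", "9": "negative"}

#: Average masses (Da) of the 20 screened compounds, drug-like 230-400 Da.
_COMPOUND_MASSES = [
    232.28, 246.31, 228.25, 258.27, 270.28, 284.31, 296.32, 310.35, 340.42,
    252.31, 264.32, 278.35, 290.36, 304.39, 318.41, 393.82, 332.44, 346.46,
    358.47, 372.50,
]


def _binding_for_mode(mode: str, compound_id: str) -> BindingScenario:
    if mode == "specific":
        # inhibitors: saturable 2-site binding plus depletion of oligomers
        # above trimer, so only dimers and trimers survive alongside monomer
        return BindingScenario(
            "specific", binomial_sites=2, occupancy=0.3,
            depletion_factor=0.0, depletion_cutoff=3,
        )
    if mode == "non_specific":
        return BindingScenario("non_specific", poisson_rate=1.0)
    if mode == "colloidal":
        return BindingScenario("colloidal")
    return BindingScenario("negative")


def focused_plate(
    modes: Mapping[str, str] | None = None,
) -> list[tuple[LigandSpec, BindingScenario]]:
    """The focused 20-compound screen as generator input.

    ``modes`` maps compound id ("1".."20") to its planted binding mode;
    defaults to the amyloid-beta(1-40) verdicts (:data:`AB40_SCREEN_MODES`).
    """
    if modes is None:
        modes = AB40_SCREEN_MODES
    plate = []
    for i, mass in enumerate(_COMPOUND_MASSES, start=1):
        cid = str(i)
        plate.append((LigandSpec(cid, mass), _binding_for_mode(modes[cid], cid)))
    return plate


def abeta40_scenario(seed: int = 0, noise_cv: float = 0.0) -> OligomerScenario:
    """Default scenario emulating a fresh amyloid-beta(1-40) oligomer mixture.

    Monomer through hexamer with geometrically decaying abundance (the
    monomer dominates a spectrum acquired minutes after dilution), native-like
    charge states climbing with oligomer order (monomer predominantly 3+/4+),
    including the m/z-degenerate dimer 4+ / trimer 6+ pair, and linear
    (fibril-like) growth truth with 250 A^2 added per monomer over a 380 A^2
    cap.
    """
    peptide = PeptideSpec("Abeta40", ABETA40_MASS, charge_range=(2, 8), n_max=6)
    decay = 0.45
    raw = {n: decay ** (n - 1) for n in range(1, 7)}
    total = sum(raw.values())
    abundance = {n: v / total for n, v in raw.items()}
    envelope = {
        1: {3: 0.6, 4: 0.4},
        2: {4: 0.5, 5: 0.5},
        3: {5: 0.5, 6: 0.5},
        4: {6: 0.6, 7: 0.4},
        5: {7: 1.0},
        6: {8: 1.0},
    }
    return OligomerScenario(
        peptide=peptide,
        abundance_by_n=abundance,
        charge_envelope=envelope,
        growth_model="linear",
        growth_params={"a": 250.0, "k": 380.0},
        noise_cv=noise_cv,
        seed=seed,
    )


def hiapp_scenario(seed: int = 0, noise_cv: float = 0.0) -> OligomerScenario:
    """Scenario emulating a human IAPP oligomer mixture.

    Same envelope structure as the amyloid-beta default with the hIAPP
    monomer mass and a proportionally smaller linear growth law.
    """
    base = abeta40_scenario(seed=seed, noise_cv=noise_cv)
    peptide = PeptideSpec("hIAPP", HIAPP_MASS, charge_range=(2, 8), n_max=6)
    return replace(
        base,
        peptide=peptide,
        growth_params={"a": 230.0, "k": 350.0},
    )
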