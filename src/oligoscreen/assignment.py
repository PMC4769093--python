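"""Species assignment: label peaks with oligomer order, charge and ligand count.

Every peak above an intensity floor is matched against the grid of candidate
species within a ppm tolerance:

* peptide oligomers with adducts, [n·P + l·L + z·H]^z+ for n = 1..n_max,
  z in the peptide's charge range, l = 0..l_max;
* ligand self-multimers [j·L + z·H]^z+ for j = 1..j_max (recorded with
  n = 0, l = j).

Because m/z is invariant under common scaling of (n, z, l), distinct species
can land on the same peak (the classic dimer 4+ vs trimer 6+ overlap).  Such
degeneracies are resolved by ion mobility: each candidate's drift time is
predicted from a growth-model CCS prior pushed through the travelling-wave
calibration, and the candidate nearest the observed drift time wins, with
ties broken toward the smaller oligomer (parsimony).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd

from oligoscreen.calibration import CcsCalibration, invert_ccs
from oligoscreen.growth import GrowthFit, predict, predict_spherical
from oligoscreen.spectrum import (
    PROTON_MASS,
    LigandSpec,
    Peak,
    PeptideSpec,
    multimer_mz,
    species_mz,
)

OLIGOMER = "oligomer"
LIGAND_MULTIMER = "ligand_multimer"
UNASSIGNED = "unassigned"


@dataclass(frozen=True)
class AssignmentConfig:
    """Matching parameters.

    ``tolerance_ppm`` — half-width of the m/z match window (50 ppm default,
    loose enough for average-mass arithmetic on a Q-ToF).
    ``min_rel_intensity`` — peaks below this fraction of the base peak are
    ignored as noise.  ``multimer_charges`` — charge states searched for
    ligand self-multimers (small molecules are typically singly charged).
    """

    tolerance_ppm: float = 50.0
    drift_consistency_weight: float = 1.0
    min_rel_intensity: float = 0.005
    multimer_charges: tuple[int, ...] = (1,)

    def __post_init__(self) -> None:
        if not self.tolerance_ppm > 0:
            raise ValueError("tolerance_ppm must be positive")


@dataclass(frozen=True)
class Candidate:
    """One (n, z, l) hypothesis for a peak; n = 0 marks a ligand multimer
    with l the multimer order."""

    n: int
    z: int
    l: int
    species_class: str
    mass_error_ppm: float


@dataclass
class SpeciesAssignment:
    """A peak labelled with its species, or flagged unassigned.

    ``degenerate`` is set when several candidates matched but no calibration
    was available to discriminate them.
    """

    peak: Peak
    n: int | None = None
    z: int | None = None
    l: int | None = None
    species_class: str = UNASSIGNED
    mass_error_ppm: float | None = None
    degenerate: bool = False


@dataclass
class AssignmentResult:
    """Assignments for one spectrum plus the oligomer abundance table."""

    assignments: list[SpeciesAssignment]
    oligomer_abundance: pd.DataFrame
    n_ignored: int = 0

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "mz": a.peak.mz,
                "drift_time": a.peak.drift_time,
                "intensity": a.peak.intensity,
                "n": a.n,
                "z": a.z,
                "l": a.l,
                "species_class": a.species_class,
                "mass_error_ppm": a.mass_error_ppm,
            }
            for a in self.assignments
        ]
        return pd.DataFrame(rows)


def _ppm(observed: float, theoretical: float) -> float:
    return (observed - theoretical) / theoretical * 1e6


def enumerate_candidates(
    peak: Peak,
    peptide: PeptideSpec,
    ligand: LigandSpec | None,
    config: AssignmentConfig = AssignmentConfig(),
) -> list[Candidate]:
    """All species hypotheses within the ppm tolerance of a peak's m/z."""
    out: list[Candidate] = []
    l_max = ligand.l_max if ligand is not None else 0
    for n in range(1, peptide.n_max + 1):
        for z in peptide.charges:
            for l in range(l_max + 1):
                theo = species_mz(n, z, l, peptide, ligand)
                err = _ppm(peak.mz, theo)
                if abs(err) <= config.tolerance_ppm:
                    out.append(Candidate(n, z, l, OLIGOMER, err))
    if ligand is not None:
        for j in range(1, ligand.j_max + 1):
            for z in config.multimer_charges:
                theo = multimer_mz(j, z, ligand)
                err = _ppm(peak.mz, theo)
                if abs(err) <= config.tolerance_ppm:
                    out.append(Candidate(0, z, j, LIGAND_MULTIMER, err))
    return out


def _prior_ccs(
    cand: Candidate,
    peptide: PeptideSpec,
    ligand: LigandSpec | None,
    growth_prior: GrowthFit | None,
) -> float:
    """Expected CCS of a candidate species under the growth prior.

    Without an explicit prior, the isotropic law anchored at the spherical
    monomer CCS (density 0.44 Da/A^3) is used — a parameter-free default that
    preserves the ordering the drift comparison needs.  Ligand adducts scale
    the bare CCS by the 2/3 power of the mass ratio; ligand multimers use the
    spherical CCS of their own mass.
    """
    ML = ligand.ligand_mass if ligand is not None else 0.0
    if cand.species_class == LIGAND_MULTIMER:
        return float(predict_spherical(1, cand.l * ML + cand.z * PROTON_MASS))
    if growth_prior is not None:
        bare = float(predict(growth_prior, cand.n, peptide.monomer_mass))
    else:
        sigma1 = float(predict_spherical(1, peptide.monomer_mass))
        bare = sigma1 * cand.n ** (2.0 / 3.0)
    if cand.l == 0:
        return bare
    nM = cand.n * peptide.monomer_mass
    return bare * ((nM + cand.l * ML) / nM) ** (2.0 / 3.0)


def resolve_degeneracy(
    candidates: Sequence[Candidate],
    peak: Peak,
    peptide: PeptideSpec,
    ligand: LigandSpec | None = None,
    calibration: CcsCalibration | None = None,
    growth_prior: GrowthFit | None = None,
) -> SpeciesAssignment:
    """Pick one candidate for a peak, using drift time when needed.

    A single candidate is accepted outright.  With several candidates and a
    calibration, the candidate whose predicted drift time is nearest the
    observed one is chosen (ties toward smaller n).  With several candidates
    and no calibration the peak stays unassigned with the degeneracy flag.
    """
    if not candidates:
        return SpeciesAssignment(peak=peak)
    if len(candidates) == 1:
        c = candidates[0]
        return SpeciesAssignment(peak, c.n, c.z, c.l, c.species_class, c.mass_error_ppm)
    if calibration is None:
        return SpeciesAssignment(peak=peak, degenerate=True)

    ML = ligand.ligand_mass if ligand is not None else 0.0

    def score(c: Candidate) -> tuple[float, int, int]:
        ccs = _prior_ccs(c, peptide, ligand, growth_prior)
        mass = c.n * peptide.monomer_mass + c.l * ML + c.z * PROTON_MASS
        predicted = invert_ccs(ccs, c.z, mass, calibration)
        return (abs(predicted - peak.drift_time), c.n, c.l)

    best = min(candidates, key=score)
    return SpeciesAssignment(
        peak, best.n, best.z, best.l, best.species_class, best.mass_error_ppm
    )


def assign_spectrum(
    peaks: Sequence[Peak],
    peptide: PeptideSpec,
    ligand: LigandSpec | None = None,
    config: AssignmentConfig = AssignmentConfig(),
    calibration: CcsCalibration | None = None,
    growth_prior: GrowthFit | None = None,
) -> AssignmentResult:
    """Assign every peak above the intensity floor and tabulate oligomers.

    Returns the assignments plus a relative oligomer abundance table
    (summed assigned intensity per oligomer order, normalised to 1).
    Assignment is order-independent: peaks are processed in m/z order.
    """
    if not peaks:
        raise ValueError("peak list is empty")
    base = max(p.intensity for p in peaks)
    floor = config.min_rel_intensity * base
    kept = sorted((p for p in peaks if p.intensity >= floor), key=lambda p: p.mz)
    n_ignored = len(peaks) - len(kept)
    if not kept:
        warnings.warn("all peaks below the relative-intensity floor")
        return AssignmentResult([], _abundance_table([]), n_ignored)

    assignments = [
        resolve_degeneracy(
            enumerate_candidates(p, peptide, ligand, config),
            p,
            peptide,
            ligand,
            calibration,
            growth_prior,
        )
        for p in kept
    ]
    return AssignmentResult(assignments, _abundance_table(assignments), n_ignored)


def _abundance_table(assignments: list[SpeciesAssignment]) -> pd.DataFrame:
    rows = [
        (a.n, a.peak.intensity)
        for a in assignments
        if a.species_class == OLIGOMER
    ]
    if not rows:
        return pd.DataFrame(columns=["n", "intensity", "fraction"]).set_index("n")
    df = pd.DataFrame(rows, columns=["n", "intensity"]).groupby("n").sum()
    df["fraction"] = df["intensity"] / df["intensity"].sum()
    return df
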