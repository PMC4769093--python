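"""Binding-mode classification from ligand-adduct stoichiometry.

A screened compound is sorted into one of four modes from the topology of
its holo spectrum relative to the apo reference:

* **colloidal** — a ligand self-multimer series (jL peaks over at least two
  multimer orders carrying appreciable summed intensity) betrays
  self-association of the small molecule;
* **negative** — essentially no peptide-bound ligand: the spectrum is the
  peptide's own;
* **specific** — bound-peak intensities across the adduct count l follow a
  binomial distribution, the signature of saturable occupancy of a fixed
  number of sites;
* **non_specific** — the adduct-count distribution is Poisson, the signature
  of random adduction during ionisation.

The specific / non-specific call compares residual sums of squares of the
best binomial and the best truncated-Poisson fit to the normalised
stoichiometry profile.  RSS on normalised profiles (rather than a
likelihood-ratio test) is deliberately agnostic about the unknown mapping
from ion current to counts; the margin between the two fits is reported so
a caller can impose its own cutoff.  Adduct counts are read off the monomer
charge states, the species adduct labels are annotated on experimentally.

Oligomer-depletion metrics (highest observed order and the intensity
fraction in oligomers, holo vs apo) are always computed when an apo
reference is supplied: depletion of higher-order oligomers alongside
specific binding is the hallmark of a true aggregation inhibitor.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
from scipy import optimize, stats

from oligoscreen.assignment import (
    LIGAND_MULTIMER,
    OLIGOMER,
    AssignmentResult,
    SpeciesAssignment,
)

MODES = ("specific", "non_specific", "colloidal", "negative")


@dataclass(frozen=True)
class ClassifierConfig:
    """Decision thresholds for the four-way cascade.

    ``colloid_threshold`` — minimum summed ligand-multimer intensity, as a
    fraction of the base peak, to call colloidal (with at least
    ``min_multimer_orders`` distinct multimer orders observed).
    ``bind_threshold`` — bound intensity fraction below which a compound is
    negative; deliberately low (5%) because hydrophobic contacts are partly
    lost in the gas phase, so genuine binders can show weak adduction.
    """

    colloid_threshold: float = 0.02
    min_multimer_orders: int = 2
    bind_threshold: float = 0.05
    l_max: int = 5
    monomer_only: bool = True


class BinomialFit(NamedTuple):
    n_sites: int
    p: float
    rss: float
    degenerate: bool = False


class PoissonFit(NamedTuple):
    rate: float
    rss: float
    degenerate: bool = False


@dataclass
class StoichiometryProfile:
    """Normalised adduct-count intensity profiles.

    ``per_charge`` maps charge state to a length-(l_max+1) array summing to
    1; ``pooled`` is the intensity-weighted mean over charge states,
    renormalised.
    """

    per_charge: dict[int, np.ndarray]
    pooled: np.ndarray


@dataclass
class BindingVerdict:
    """One compound's classification with its supporting statistics."""

    mode: str
    binomial_fit: BinomialFit | None = None
    poisson_fit: PoissonFit | None = None
    bound_fraction: float = 0.0
    colloid_orders: int = 0
    colloid_intensity: float = 0.0
    margin: float | None = None
    depletion: dict[str, float] | None = None


def build_profile(
    assignments: AssignmentResult | list[SpeciesAssignment],
    l_max: int = 5,
    monomer_only: bool = True,
) -> StoichiometryProfile:
    """Normalised intensity-vs-adduct-count profile per charge state.

    By default only monomer (n=1) peptide assignments contribute, matching
    how adduct counts are annotated on spectra.
    """
    items = assignments.assignments if isinstance(assignments, AssignmentResult) else assignments
    peptide = [
        a
        for a in items
        if a.species_class == OLIGOMER and (not monomer_only or a.n == 1)
    ]
    if not peptide:
        raise ValueError("no assigned peptide peaks to build a profile from")
    per_charge: dict[int, np.ndarray] = {}
    for a in peptide:
        vec = per_charge.setdefault(a.z, np.zeros(l_max + 1))
        if a.l <= l_max:
            vec[a.l] += a.peak.intensity
    weights = {z: v.sum() for z, v in per_charge.items()}
    pooled = np.zeros(l_max + 1)
    for z, v in per_charge.items():
        pooled += v
        per_charge[z] = v / v.sum() if v.sum() > 0 else v
    pooled = pooled / pooled.sum()
    return StoichiometryProfile(per_charge=per_charge, pooled=pooled)


def fit_binomial(profile: StoichiometryProfile | np.ndarray) -> BinomialFit:
    """Best binomial fit to the pooled profile.

    Grid search over the integer site count N; for each N the occupancy is
    the moment/ML estimate ``p = mean(l) / N``; the (N, p) pair with the
    lowest residual sum of squares wins.
    """
    p_vec = profile.pooled if isinstance(profile, StoichiometryProfile) else np.asarray(profile)
    ls = np.arange(len(p_vec))
    mean_l = float(ls @ p_vec)
    if mean_l == 0:
        return BinomialFit(0, 0.0, 0.0, degenerate=True)
    best: BinomialFit | None = None
    for N in range(1, len(p_vec)):
        p_hat = min(mean_l / N, 1.0)
        pmf = stats.binom.pmf(ls, N, p_hat)
        rss = float(np.sum((p_vec - pmf) ** 2))
        if best is None or rss < best.rss:
            best = BinomialFit(N, p_hat, rss)
    return best


def _truncated_poisson_pmf(ls: np.ndarray, rate: float) -> np.ndarray:
    pmf = stats.poisson.pmf(ls, rate)
    return pmf / pmf.sum()


def fit_poisson(profile: StoichiometryProfile | np.ndarray) -> PoissonFit:
    """Best truncated-and-renormalised Poisson fit to the pooled profile.

    The rate is found by one-dimensional minimisation of the RSS, started
    from the profile mean (the untruncated MLE).
    """
    p_vec = profile.pooled if isinstance(profile, StoichiometryProfile) else np.asarray(profile)
    ls = np.arange(len(p_vec))
    mean_l = float(ls @ p_vec)
    if mean_l == 0:
        return PoissonFit(0.0, 0.0, degenerate=True)

    def rss(lam: float) -> float:
        return float(np.sum((p_vec - _truncated_poisson_pmf(ls, lam)) ** 2))

    res = optimize.minimize_scalar(
        rss, bounds=(1e-9, max(4.0 * mean_l, len(p_vec))), method="bounded",
        options={"xatol": 1e-10},
    )
    return PoissonFit(float(res.x), float(res.fun))


def _depletion_metrics(
    holo: AssignmentResult, apo: AssignmentResult | None
) -> dict[str, float] | None:
    if apo is None:
        warnings.warn("no apo reference: depletion metrics omitted")
        return None

    def summarise(result: AssignmentResult) -> tuple[int, float]:
        tab = result.oligomer_abundance
        if tab.empty:
            return 0, 0.0
        max_n = int(tab.index.max())
        frac = float(tab.loc[tab.index >= 2, "intensity"].sum() / tab["intensity"].sum())
        return max_n, frac

    holo_max, holo_frac = summarise(holo)
    apo_max, apo_frac = summarise(apo)
    return {
        "max_order_holo": holo_max,
        "max_order_apo": apo_max,
        "oligomer_fraction_holo": holo_frac,
        "oligomer_fraction_apo": apo_frac,
    }


def classify(
    assignments_holo: AssignmentResult,
    assignments_apo: AssignmentResult | None = None,
    config: ClassifierConfig = ClassifierConfig(),
) -> BindingVerdict:
    """Four-way binding-mode decision for one compound.

    Cascade: (1) colloidal when a ligand self-multimer series is present;
    (2) negative when the bound intensity fraction is below the binding
    threshold; (3) otherwise specific vs non-specific by comparing the
    binomial and Poisson fits to the stoichiometry profile.
    """
    if not assignments_holo.assignments:
        raise ValueError("holo assignment set is empty")
    items = assignments_holo.assignments
    base = max(a.peak.intensity for a in items)

    multimers = [a for a in items if a.species_class == LIGAND_MULTIMER]
    colloid_orders = len({a.l for a in multimers})
    colloid_intensity = sum(a.peak.intensity for a in multimers)

    peptide = [a for a in items if a.species_class == OLIGOMER]
    total_peptide = sum(a.peak.intensity for a in peptide)
    bound = sum(a.peak.intensity for a in peptide if a.l and a.l > 0)
    bound_fraction = bound / total_peptide if total_peptide > 0 else 0.0

    depletion = _depletion_metrics(assignments_holo, assignments_apo)

    verdict = BindingVerdict(
        mode="negative",
        bound_fraction=bound_fraction,
        colloid_orders=colloid_orders,
        colloid_intensity=colloid_intensity,
        depletion=depletion,
    )

    if (
        colloid_orders >= config.min_multimer_orders
        and colloid_intensity > config.colloid_threshold * base
    ):
        verdict.mode = "colloidal"
        return verdict

    if bound_fraction < config.bind_threshold:
        verdict.mode = "negative"
        return verdict

    profile = build_profile(assignments_holo, config.l_max, config.monomer_only)
    bfit = fit_binomial(profile)
    pfit = fit_poisson(profile)
    verdict.binomial_fit = bfit
    verdict.poisson_fit = pfit
    verdict.margin = pfit.rss - bfit.rss
    verdict.mode = "specific" if bfit.rss < pfit.rss else "non_specific"
    return verdict
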