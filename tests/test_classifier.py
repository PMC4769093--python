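"""Stoichiometry profiles, binomial/Poisson fits and the mode cascade."""

import numpy as np
import pytest
from scipy import stats

from oligoscreen import (
    AssignmentConfig,
    BindingScenario,
    ClassifierConfig,
    LigandSpec,
    assign_spectrum,
    build_profile,
    classify,
    fit_binomial,
    fit_poisson,
    simulate_apo,
    simulate_holo,
)
from oligoscreen.assignment import SpeciesAssignment, AssignmentResult, OLIGOMER
from oligoscreen.spectrum import Peak
from oligoscreen.synth import abeta40_scenario, default_calibration


def truncated_poisson(rate, l_max):
    pmf = stats.poisson.pmf(np.arange(l_max + 1), rate)
    return pmf / pmf.sum()


def fake_assignment(z, l, intensity):
    return SpeciesAssignment(Peak(1000.0 + l, 1.0, intensity), 1, z, l, OLIGOMER, 0.0)


class TestBuildProfile:
    def test_single_unbound_peak(self):
        prof = build_profile([fake_assignment(3, 0, 2.0)], l_max=3)
        assert prof.pooled == pytest.approx([1.0, 0.0, 0.0, 0.0])

    def test_binomial_profile_from_generator(self, calibration):
        sc = abeta40_scenario(seed=0, noise_cv=0.0)
        ligand = LigandSpec("c", 228.25)
        binding = BindingScenario("specific", binomial_sites=2, occupancy=0.5)
        res = assign_spectrum(
            simulate_holo(sc, binding, ligand), sc.peptide, ligand, calibration=calibration
        )
        prof = build_profile(res, l_max=2)
        assert prof.pooled == pytest.approx([0.25, 0.5, 0.25], abs=1e-9)
        for vec in prof.per_charge.values():
            assert vec == pytest.approx([0.25, 0.5, 0.25], abs=1e-9)

    def test_profiles_sum_to_one(self):
        assignments = [fake_assignment(3, l, 0.3 + l) for l in range(4)]
        assignments += [fake_assignment(4, l, 1.0 + l) for l in range(3)]
        prof = build_profile(assignments, l_max=5)
        assert prof.pooled.sum() == pytest.approx(1.0, abs=1e-9)
        for vec in prof.per_charge.values():
            assert vec.sum() == pytest.approx(1.0, abs=1e-9)

    def test_no_peptide_peaks_rejected(self):
        with pytest.raises(ValueError):
            build_profile([], l_max=3)


class TestFitBinomial:
    def test_self_fit_three_sites(self):
        profile = stats.binom.pmf(np.arange(4), 3, 0.3)
        fit = fit_binomial(profile)
        assert fit.n_sites == 3
        assert fit.p == pytest.approx(0.3, abs=1e-9)
        assert fit.rss < 1e-18

    def test_self_fit_single_site(self):
        fit = fit_binomial(np.array([0.4, 0.6]))
        assert (fit.n_sites, fit.p) == (1, pytest.approx(0.6))

    def test_poisson_data_fits_poisson_better(self):
        profile = truncated_poisson(0.8, 5)
        assert fit_binomial(profile).rss > fit_poisson(profile).rss

    def test_all_mass_at_zero_degenerate(self):
        fit = fit_binomial(np.array([1.0, 0.0, 0.0]))
        assert fit.degenerate


class TestFitPoisson:
    def test_self_fit(self):
        fit = fit_poisson(truncated_poisson(1.0, 4))
        assert fit.rate == pytest.approx(1.0, abs=1e-6)
        assert fit.rss < 1e-12

    def test_all_mass_at_zero_degenerate(self):
        fit = fit_poisson(np.array([1.0, 0.0, 0.0, 0.0, 0.0]))
        assert fit.degenerate
        assert fit.rate == 0.0

    def test_binomial_data_fits_binomial_better(self):
        profile = stats.binom.pmf(np.arange(6), 2, 0.9)
        assert fit_poisson(profile).rss > fit_binomial(profile).rss


class TestClassify:
    @pytest.fixture
    def pipeline(self, calibration):
        def run(mode_scenario, seed=3, noise_cv=0.0, ligand_mass=228.25):
            sc = abeta40_scenario(seed=seed, noise_cv=noise_cv)
            ligand = LigandSpec("c", ligand_mass)
            apo = assign_spectrum(simulate_apo(sc), sc.peptide, None, calibration=calibration)
            holo = assign_spectrum(
                simulate_holo(sc, mode_scenario, ligand), sc.peptide, ligand,
                calibration=calibration,
            )
            return classify(holo, apo, ClassifierConfig())

        return run

    def test_negative_recovered(self, pipeline):
        assert pipeline(BindingScenario("negative")).mode == "negative"

    def test_specific_recovered_with_depletion(self, pipeline):
        verdict = pipeline(
            BindingScenario("specific", binomial_sites=2, occupancy=0.3, depletion_factor=0.0)
        )
        assert verdict.mode == "specific"
        assert verdict.depletion["max_order_holo"] < verdict.depletion["max_order_apo"]
        assert (
            verdict.depletion["oligomer_fraction_holo"]
            < verdict.depletion["oligomer_fraction_apo"]
        )

    def test_non_specific_recovered(self, pipeline):
        assert pipeline(BindingScenario("non_specific", poisson_rate=1.0)).mode == "non_specific"

    def test_colloidal_recovered(self, pipeline):
        verdict = pipeline(BindingScenario("colloidal"))
        assert verdict.mode == "colloidal"
        assert verdict.colloid_orders >= 2

    def test_missing_apo_reference_warns_but_classifies(self, pipeline, calibration):
        sc = abeta40_scenario(seed=3, noise_cv=0.0)
        ligand = LigandSpec("c", 228.25)
        holo = assign_spectrum(
            simulate_holo(sc, BindingScenario("non_specific"), ligand),
            sc.peptide, ligand, calibration=calibration,
        )
        with pytest.warns(UserWarning, match="apo"):
            verdict = classify(holo, None, ClassifierConfig())
        assert verdict.mode == "non_specific"
        assert verdict.depletion is None

    def test_bound_fraction_scale_invariant(self, calibration):
        sc = abeta40_scenario(seed=1, noise_cv=0.0)
        ligand = LigandSpec("c", 228.25)
        peaks = simulate_holo(sc, BindingScenario("non_specific"), ligand)
        apo = assign_spectrum(simulate_apo(sc), sc.peptide, None, calibration=calibration)
        res1 = assign_spectrum(peaks, sc.peptide, ligand, calibration=calibration)
        scaled = [Peak(p.mz, p.drift_time, 37.5 * p.intensity) for p in peaks]
        res2 = assign_spectrum(scaled, sc.peptide, ligand, calibration=calibration)
        v1, v2 = classify(res1, apo), classify(res2, apo)
        assert v1.bound_fraction == pytest.approx(v2.bound_fraction, rel=1e-12)

    def test_margin_shrinks_toward_poisson_limit(self):
        """Binomial(N, c/N) approaches Poisson(c); the decision margin decays."""
        margins = []
        for N in (2, 5, 10, 20):
            profile = stats.binom.pmf(np.arange(9), N, 1.0 / N)
            profile = profile / profile.sum()
            margins.append(abs(fit_poisson(profile).rss - fit_binomial(profile).rss))
        assert margins == sorted(margins, reverse=True)
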