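"""Structural model: allometry, dose conversions, ODE solution, exposures."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import solve_ivp

import cefetox as cx
from cefetox.pk import (AllometricBetas, InvalidInputError, PKParameters,
                        predict_concentrations)
from conftest import random_pk_parameters

BETAS = AllometricBetas()


class TestAllometry:
    def test_identity_at_reference_weight(self, final_params):
        out = cx.scale_by_weight(final_params, BETAS, BETAS.ref_weight)
        assert out == final_params

    def test_power_law_on_kel(self, final_params):
        out = cx.scale_by_weight(final_params, BETAS, 2 * BETAS.ref_weight)
        assert out.kel == pytest.approx(0.14 * 2 ** 0.75, rel=1e-12)
        assert out.kel == pytest.approx(0.23546, rel=1e-4)

    def test_linear_scaling_on_central_volume(self, final_params):
        out = cx.scale_by_weight(final_params, BETAS, 0.564)
        assert out.V_central == pytest.approx(0.24, rel=1e-12)
        # brain parameters are weight-independent
        assert out.V_cortex == final_params.V_cortex
        assert out.k21 == final_params.k21

    def test_non_positive_weight_rejected(self, final_params):
        with pytest.raises(InvalidInputError):
            cx.scale_by_weight(final_params, BETAS, 0.0)


class TestDoseConversion:
    def test_maximum_human_daily_dose_to_rat(self):
        """2 g q8h in a 70-kg patient is 85.7 mg/kg/day; the BSA factor 6.2
        gives the rat starting dose of 531 mg/kg/day."""
        human = 3 * 2000 / 70
        assert round(human) == 86
        assert round(cx.hed_to_rat_dose(human)) == 531

    def test_zero_and_round_trip(self):
        assert cx.hed_to_rat_dose(0.0) == 0.0
        assert cx.rat_to_hed_dose(531.4) == pytest.approx(85.71, abs=0.01)
        assert cx.rat_to_hed_dose(cx.hed_to_rat_dose(85.714)) == pytest.approx(85.714)

    def test_negative_dose_rejected(self):
        with pytest.raises(InvalidInputError):
            cx.hed_to_rat_dose(-1.0)


class TestSolveProfile:
    def test_zero_dose_gives_zero_everywhere(self, final_params):
        reg = cx.Regimen((cx.DoseEvent(0.0, 0.0, 0.0),), weight=0.282)
        prof = cx.solve_profile(final_params, reg, np.linspace(0, 24, 100))
        for m in ("plasma", "cortex", "hippocampus"):
            assert np.all(prof.concentrations[m] == 0)

    def test_one_compartment_closed_form(self, final_params, single_dose_regimen):
        """With both brain transfer constants zero the model collapses to
        C(t) = (D/V)·exp(-kel·t)."""
        p = PKParameters(kel=0.14, k12=1e-300, k21=0.17, k13=1e-300, k31=0.15,
                         V_central=0.12, V_cortex=0.0039, V_hippocampus=0.00039)
        grid = np.linspace(0, 24, 241)
        prof = cx.solve_profile(p, single_dose_regimen, grid)
        expected = (449.2 / 0.12) * np.exp(-0.14 * grid)
        expected[0] = 0.0  # pre-dose convention at t = 0
        assert prof.concentrations["plasma"][1:] == pytest.approx(
            expected[1:], rel=1e-10)
        assert expected[1] == pytest.approx(3743.3 * np.exp(-0.14 * 0.1), rel=1e-4)

    @pytest.mark.parametrize("seed", range(6))
    def test_mass_balance_any_regimen(self, seed):
        rng = np.random.default_rng(seed)
        p = random_pk_parameters(rng)
        events = []
        t = 0.0
        for _ in range(rng.integers(1, 4)):
            events.append(cx.DoseEvent(t, rng.uniform(10, 500),
                                       rng.choice([0.0, 5 / 60, 0.5])))
            t += rng.uniform(4, 24)
        reg = cx.Regimen(tuple(events), weight=0.282)
        grid = np.linspace(0, t + 24, 200)
        prof = cx.solve_profile(p, reg, grid)
        assert prof.mass_balance_error() <= 1e-8

    def test_superposition_doubling(self, final_params, single_dose_regimen):
        grid = np.linspace(0, 24, 100)
        prof1 = cx.solve_profile(final_params, single_dose_regimen, grid)
        reg2 = cx.Regimen((cx.DoseEvent(0.0, 2 * 449.2, 0.0),), weight=0.282)
        prof2 = cx.solve_profile(final_params, reg2, grid)
        for m in ("plasma", "cortex", "hippocampus"):
            assert prof2.concentrations[m] == pytest.approx(
                2 * prof1.concentrations[m], rel=1e-12)

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_stiff_ode_integrator(self, seed):
        """The piecewise matrix-exponential solution agrees with an
        independent numerical integration of the ODE system."""
        rng = np.random.default_rng(100 + seed)
        p = random_pk_parameters(rng)
        dur = 5 / 60
        reg = cx.Regimen((cx.DoseEvent(0.0, 350.0, dur),), weight=0.282)
        grid = np.linspace(0, 24, 25)
        prof = cx.solve_profile(p, reg, grid)

        def rhs(t, A):
            r = 350.0 / dur if t < dur else 0.0
            return [-(p.kel + p.k12 + p.k13) * A[0] + p.k21 * A[1]
                    + p.k31 * A[2] + r,
                    p.k12 * A[0] - p.k21 * A[1],
                    p.k13 * A[0] - p.k31 * A[2]]

        sol = solve_ivp(rhs, (0, 24), [0, 0, 0], t_eval=grid, method="LSODA",
                        rtol=1e-10, atol=1e-12, max_step=dur / 2)
        scale = np.abs(sol.y.T).max()
        assert np.allclose(prof.amounts[:, :3], sol.y.T, rtol=1e-6,
                           atol=1e-6 * scale)

    def test_fast_path_matches_reference_solver(self, final_params):
        reg = cx.Regimen.daily(1250.0, 0.29, n_days=3)
        grid = np.linspace(0.0, 72.0, 289)
        prof = cx.solve_profile(final_params, reg, grid)
        times = np.array([0.25, 2.0, 26.0, 50.0, 71.0])
        for code, m in enumerate(("plasma", "cortex", "hippocampus")):
            fast = predict_concentrations(final_params, reg, times,
                                          np.full(len(times), code))
            ref = np.interp(times, grid, prof.concentrations[m])
            assert fast == pytest.approx(ref, rel=1e-6)

    def test_central_cmax_at_infusion_end_and_brain_tmax_later(self, final_params):
        reg = cx.Regimen((cx.DoseEvent(0.0, 449.2, 0.5),), weight=0.282)
        prof = cx.solve_profile(final_params, reg, np.arange(0, 24.05, 0.05))
        m = cx.exposure_metrics(prof, cmax_grid_step=0.05)
        assert m.tmax["plasma"] == pytest.approx(0.5, abs=0.051)
        assert m.tmax["cortex"] >= m.tmax["plasma"]
        assert m.tmax["hippocampus"] >= m.tmax["plasma"]

    def test_invalid_grids_rejected(self, final_params, single_dose_regimen):
        with pytest.raises(InvalidInputError):
            cx.solve_profile(final_params, single_dose_regimen, np.array([1.0, 0.5]))
        with pytest.raises(InvalidInputError):
            reg = cx.Regimen((cx.DoseEvent(30.0, 10.0, 0.0),), weight=0.282)
            cx.solve_profile(final_params, reg, np.linspace(0, 24, 10))


class TestProperties:
    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000), amount=st.floats(1.0, 2000.0),
           duration=st.sampled_from([0.0, 2 / 60, 0.5, 2.0]))
    def test_mass_balance_and_positivity(self, seed, amount, duration):
        p = random_pk_parameters(np.random.default_rng(seed))
        reg = cx.Regimen((cx.DoseEvent(0.0, amount, duration),), weight=0.282)
        prof = cx.solve_profile(p, reg, np.linspace(0, 24, 49))
        assert prof.mass_balance_error() <= 1e-8
        for m in ("plasma", "cortex", "hippocampus"):
            assert np.all(prof.concentrations[m] >= 0)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(dose=st.floats(0.0, 1e4))
    def test_dose_conversion_round_trip(self, dose):
        assert cx.rat_to_hed_dose(cx.hed_to_rat_dose(dose)) == \
            pytest.approx(dose, rel=1e-12, abs=1e-12)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000), weight=st.floats(0.1, 1.0))
    def test_allometric_scaling_monotone_and_invertible(self, seed, weight):
        p = random_pk_parameters(np.random.default_rng(seed))
        scaled = cx.scale_by_weight(p, BETAS, weight)
        back = cx.scale_by_weight(scaled, AllometricBetas(ref_weight=weight),
                                  BETAS.ref_weight)
        assert back.kel == pytest.approx(p.kel, rel=1e-12)
        assert back.V_central == pytest.approx(p.V_central, rel=1e-12)


class TestExposureMetrics:
    def _constant_profile(self, value=10.0):
        grid = np.linspace(0, 24, 100)
        conc = {m: np.full(100, value) for m in ("plasma", "cortex", "hippocampus")}
        return cx.ConcentrationProfile(times=grid, amounts=np.zeros((100, 4)),
                                       concentrations=conc,
                                       infused=np.zeros(100))

    def test_constant_profile(self):
        m = cx.exposure_metrics(self._constant_profile())
        assert m.auc_0_24["plasma"] == pytest.approx(240.0)
        assert m.cmax_0_24["plasma"] == pytest.approx(10.0)

    def test_bolus_auc_against_analytic_integral(self, single_dose_regimen):
        p = PKParameters(kel=0.14, k12=1e-300, k21=0.17, k13=1e-300, k31=0.15,
                         V_central=0.12, V_cortex=0.0039, V_hippocampus=0.00039)
        grid = np.arange(0, 24.05, 0.1)
        prof = cx.solve_profile(p, single_dose_regimen, grid)
        m = cx.exposure_metrics(prof)
        analytic = (449.2 / (0.14 * 0.12)) * (1 - np.exp(-0.14 * 24))
        assert m.auc_0_24["plasma"] == pytest.approx(analytic, rel=5e-3)

    def test_grid_refinement_tightens_auc(self, final_params, single_dose_regimen):
        """Halving the trapezoid step changes the AUC by less than the
        coarse-step error bound (second-order convergence)."""
        grid = np.arange(0, 24.0025, 0.0025)
        prof = cx.solve_profile(final_params, single_dose_regimen, grid)
        exact = cx.exposure_metrics(prof, auc_grid_step=0.0025).auc_0_24["plasma"]
        coarse = cx.exposure_metrics(prof, auc_grid_step=0.2).auc_0_24["plasma"]
        fine = cx.exposure_metrics(prof, auc_grid_step=0.1).auc_0_24["plasma"]
        assert abs(fine - exact) < abs(coarse - exact)
        assert abs(fine - coarse) < 2 * abs(coarse - exact) + 1e-9

    def test_short_profile_rejected(self):
        prof = self._constant_profile()
        prof.times = np.linspace(0, 12, 100)
        with pytest.raises(InvalidInputError):
            cx.exposure_metrics(prof)
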