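"""Outlier screen, SAEM fitting, empirical Bayes, criteria, diagnostics."""

import numpy as np
import pytest

import cefetox as cx
from cefetox.data import Dataset, Subject
from cefetox.estimation import empirical_bayes, information_criteria
from cefetox.pk import DoseEvent, PKParameters, Regimen
from cefetox.population import (ConfigurationError, ErrorModel, Observation,
                                PopulationModel)
from cefetox.saem import SAEMState


def _plasma_dataset(strata_values):
    """One subject per value, all dosed at 0 and sampled at the same nominal
    time, so they share a single outlier stratum."""
    subjects = []
    for i, v in enumerate(strata_values):
        reg = Regimen((DoseEvent(0.0, 100.0, 0.0),), weight=0.28)
        obs = [Observation(f"S{i}", 1.0, "plasma", float(v))]
        subjects.append(Subject(f"S{i}", 0.28, reg, obs))
    return Dataset(subjects)


class TestExcludeOutliers:
    def test_clean_data_unchanged(self):
        ds = _plasma_dataset([10, 11, 9, 10, 10.5])
        out, report = cx.exclude_outliers(ds, 3.0)
        assert out.n_observations() == 5
        assert report.empty

    def test_toy_stratum_gross_outlier_removed(self):
        ds = _plasma_dataset([10, 11, 9, 10, 60])
        out, report = cx.exclude_outliers(ds, 3.0)
        assert out.n_observations() == 4
        assert list(report["DV"]) == [60.0]
        assert 60.0 not in [o.value for s in out.subjects for o in s.observations]

    def test_study_sized_screen_retains_127_of_129(self):
        """A 129-plasma-record dataset with two injected extreme values keeps
        127 records, mirroring the study's exclusion count."""
        # homogeneous design (one arm, one sacrifice day) and low
        # between-subject variability, so only the injected errors trip the
        # 3-SD screen
        pop = cx.healthy_population()
        pop.omega = {k: 0.05 for k in pop.omega}
        design = cx.StudyDesign(n_rats=44, sacrifice_schedule=((1, 2.0),))
        cohort = cx.generate_cohort(design=design, pop=pop, seed=2024)
        subjects = []
        n_plasma = 0
        for s in cohort.dataset.subjects:
            obs = []
            for o in s.observations:
                if o.matrix == "plasma":
                    if n_plasma >= 129:
                        continue
                    n_plasma += 1
                obs.append(o)
            subjects.append(Subject(s.subject_id, s.weight, s.regimen, obs,
                                    s.stage, s.event_time, s.sacrifice_time))
        assert n_plasma == 129
        ds = Dataset(subjects)
        # corrupt two quantified plasma records with gross assay errors
        corrupted = 0
        for s in ds.subjects:
            for j, o in enumerate(s.observations):
                if corrupted < 2 and o.matrix == "plasma" and not o.blq:
                    s.observations[j] = Observation(o.subject_id, o.time, o.matrix,
                                                    o.value * 100, loq=o.loq)
                    corrupted += 1
                    break
            if corrupted == 2:
                break
        out, report = cx.exclude_outliers(ds, 3.0)
        assert len(report) == 2
        assert out.n_observations("plasma") == 127


class TestInformationCriteria:
    def test_formulas(self):
        crit = information_criteria(100.0, 3, 50)
        assert crit["AIC"] == pytest.approx(106.0)
        assert crit["BIC"] == pytest.approx(100 + 3 * np.log(50), abs=1e-6)
        zero = information_criteria(42.0, 0, 10)
        assert zero["AIC"] == zero["BIC"] == 42.0

    def test_bic_penalizes_superfluous_parameter(self):
        """On data generated from a one-mean model, the candidate with a
        useless extra regressor has the higher BIC in most replicates."""
        rng = np.random.default_rng(12)
        wins = 0
        n = 40
        for _ in range(50):
            y = rng.normal(1.0, 1.0, n)
            x = rng.normal(size=n)  # pure noise regressor
            rss1 = np.sum((y - y.mean()) ** 2)
            beta = np.polyfit(x, y, 1)
            rss2 = np.sum((y - np.polyval(beta, x)) ** 2)
            m2ll1 = n * np.log(rss1 / n)
            m2ll2 = n * np.log(rss2 / n)
            bic1 = information_criteria(m2ll1, 2, n)["BIC"]
            bic2 = information_criteria(m2ll2, 3, n)["BIC"]
            wins += bic2 > bic1
        assert wins >= 40


def _rich_dataset(pop, n_subjects, rng, noise_sd=1e-3):
    """Dense noise-free sampling of all three matrices; omega = 0 truth."""
    subjects = []
    times = np.arange(0.5, 24.5, 2.0)
    for i in range(n_subjects):
        w = float(rng.uniform(0.25, 0.32))
        reg = Regimen((DoseEvent(0.0, 1250 * w, 5 / 60),), weight=w)
        params = cx.scale_by_weight(pop.theta, pop.betas, w)
        grid = np.arange(0.0, 24.05, 0.1)
        prof = cx.solve_profile(params, reg, grid)
        obs = []
        for m in ("plasma", "cortex", "hippocampus"):
            conc = np.interp(times, grid, prof.concentrations[m])
            obs += [Observation(f"D{i}", float(t), m, float(c))
                    for t, c in zip(times, conc)]
        subjects.append(Subject(f"D{i}", w, reg, obs))
    return Dataset(subjects)


class TestFitPopulation:
    def test_self_consistency_noise_free_limit(self):
        """Rich noise-free data simulated without between-subject variability:
        the fit (tiny fixed error, small omegas) recovers the structural
        parameters within 1%."""
        truth = cx.final_model_population()
        rng = np.random.default_rng(21)
        ds = _rich_dataset(truth, 6, rng)
        theta0 = PKParameters(kel=0.2, k12=0.00013, k21=0.25, k13=0.000015,
                              k31=0.25, V_central=0.15, V_cortex=0.003,
                              V_hippocampus=0.0005)
        spec = PopulationModel(
            theta=theta0,
            omega={p: 0.05 for p in ("kel", "k21", "k31", "V_central",
                                     "V_cortex", "V_hippocampus")},
            error={m: ErrorModel(1e-3, 1e-4)
                   for m in ("plasma", "cortex", "hippocampus")})
        cfg = cx.SAEMConfig(seed=31, n_explore=120, n_smooth=80, chains=1,
                            estimate_correlation=False,
                            error_forms={m: "fixed" for m in
                                         ("plasma", "cortex", "hippocampus")})
        fit = cx.fit_population(ds, spec, cfg)
        for name in ("kel", "k21", "k31", "V_central", "V_cortex",
                     "V_hippocampus"):
            est = getattr(fit.model.theta, name)
            true = getattr(truth.theta, name)
            assert est == pytest.approx(true, rel=0.01), name

    def test_fixed_mask_holds_parameters(self, small_fit, generic_spec):
        fit, _ = small_fit
        assert fit.model.theta.k12 == generic_spec.theta.k12
        assert fit.model.theta.k13 == generic_spec.theta.k13

    def test_same_seed_bit_reproducible(self, small_cohort, generic_spec):
        ds, _ = cx.exclude_outliers(small_cohort.dataset)
        cfg = cx.SAEMConfig(seed=5, n_explore=20, n_smooth=10, chains=1)
        f1 = cx.fit_population(ds, generic_spec, cfg)
        f2 = cx.fit_population(ds, generic_spec, cfg)
        assert f1.model.theta == f2.model.theta
        assert f1.minus2ll == f2.minus2ll
        assert f1.model.omega == f2.model.omega

    def test_all_fixed_is_configuration_error(self, small_cohort, generic_spec):
        ds = small_cohort.dataset
        bad = PopulationModel(theta=generic_spec.theta, omega={},
                              fixed_mask=tuple(
                                  ("kel", "k12", "k21", "k13", "k31",
                                   "V_central", "V_cortex", "V_hippocampus")))
        with pytest.raises(ConfigurationError):
            cx.fit_population(ds, bad, cx.SAEMConfig(seed=1, n_explore=2,
                                                     n_smooth=2, chains=1))

    def test_aic_bic_consistency(self, small_fit):
        fit, _ = small_fit
        assert fit.aic == pytest.approx(fit.minus2ll + 2 * fit.k_free)
        assert fit.bic == pytest.approx(
            fit.minus2ll + fit.k_free * np.log(fit.n_subjects))

    def test_recovery_bias_across_replicates(self, generic_spec):
        """Median relative bias of kel, V_central, k21, k31 over five
        replicates of the 18-rat study design stays within 15%."""
        bias = {k: [] for k in ("kel", "V_central", "k21", "k31")}
        truth = cx.final_model_population().theta
        for rep in range(5):
            co = cx.generate_cohort(design=cx.StudyDesign(n_rats=18),
                                    seed=300 + rep)
            ds, _ = cx.exclude_outliers(co.dataset)
            cfg = cx.SAEMConfig(seed=400 + rep, n_explore=300, n_smooth=200,
                                chains=3)
            fit = cx.fit_population(ds, generic_spec, cfg)
            for k in bias:
                est = getattr(fit.model.theta, k)
                bias[k].append((est - getattr(truth, k)) / getattr(truth, k))
        for k, v in bias.items():
            assert abs(np.median(v)) <= 0.15, (k, v)

    def test_truth_beats_perturbed_parameters(self, small_cohort):
        """The likelihood at the generating parameters exceeds the likelihood
        at 2x-perturbed parameters in nearly all trials."""
        ds, _ = cx.exclude_outliers(small_cohort.dataset)
        truth = cx.final_model_population()
        spec = PopulationModel(theta=truth.theta, omega=dict(truth.omega),
                               re_correlation=truth.re_correlation,
                               error=dict(truth.error))
        cfg = cx.SAEMConfig(seed=55, n_explore=1, n_smooth=1, chains=1,
                            n_importance=150)
        st = SAEMState(ds, spec, cfg)
        ll_truth = -0.5 * st.marginal_minus2ll()
        rng = np.random.default_rng(66)
        wins = 0
        trials = 8
        for _ in range(trials):
            factors = np.where(rng.random(8) < 0.5, 2.0, 0.5)
            pert = PKParameters.from_array(truth.theta.as_array() * factors)
            spec_p = PopulationModel(theta=pert, omega=dict(truth.omega),
                                     re_correlation=truth.re_correlation,
                                     error=dict(truth.error))
            st_p = SAEMState(ds, spec_p, cfg)
            wins += ll_truth > -0.5 * st_p.marginal_minus2ll()
        assert wins >= int(0.95 * trials)


class TestEmpiricalBayes:
    def test_tight_prior_shrinks_to_population(self, small_cohort):
        ds, _ = cx.exclude_outliers(small_cohort.dataset)
        pop = cx.final_model_population()
        spec = PopulationModel(theta=pop.theta,
                               omega={k: 1e-4 for k in pop.omega},
                               error=dict(pop.error))
        st = SAEMState(ds, spec, cx.SAEMConfig(seed=2, chains=1))
        mode, ok = st.eb_mode(0)
        assert ok
        assert np.allclose(mode, 0.0, atol=1e-3)

    def test_dense_data_recovers_individual_parameters(self, small_cohort):
        """A subject with dense near-noise-free sampling gets EB parameters
        within 1% of its simulated truth."""
        truth_pop = cx.final_model_population()
        rng = np.random.default_rng(8)
        ind = cx.sample_individual(truth_pop, 0.282, rng, subject_id="X")
        ind_params = ind.params
        reg = Regimen((DoseEvent(0.0, 449.2, 5 / 60),), weight=0.282)
        grid = np.arange(0.0, 24.05, 0.1)
        prof = cx.solve_profile(ind_params, reg, grid)
        times = np.arange(0.5, 24.0, 1.0)
        obs = []
        for m in ("plasma", "cortex", "hippocampus"):
            conc = np.interp(times, grid, prof.concentrations[m])
            obs += [Observation("X", float(t), m, float(c))
                    for t, c in zip(times, conc)]
        ds = Dataset([Subject("X", 0.282, reg, obs)])
        spec = PopulationModel(theta=truth_pop.theta,
                               omega=dict(truth_pop.omega),
                               re_correlation=truth_pop.re_correlation,
                               error={m: ErrorModel(1e-3, 1e-3)
                                      for m in ("plasma", "cortex",
                                                "hippocampus")})
        st = SAEMState(ds, spec, cx.SAEMConfig(seed=3, chains=1))
        mode, ok = st.eb_mode(0)
        assert ok
        est = PKParameters.from_array(st._params_for(0, mode))
        for name in ("kel", "k21", "k31", "V_central", "V_cortex",
                     "V_hippocampus"):
            assert getattr(est, name) == pytest.approx(
                getattr(ind_params, name), rel=0.01), name

    def test_no_observations_shrinks_to_population(self, small_fit):
        fit, _ = small_fit
        reg = Regimen((DoseEvent(0.0, 350.0, 5 / 60),), weight=0.282)
        ghost = Subject("GHOST", 0.282, reg, [])
        ip, profile = empirical_bayes(fit, ghost)
        expected = cx.scale_by_weight(fit.model.theta, fit.model.betas, 0.282)
        assert ip.params == expected
        assert profile.times[0] == 0.0 and profile.times[-1] >= 24.0


class TestDiagnostics:
    def test_pwres_distribution_and_r2(self, small_fit):
        """Under a model fitted to its own data, PWRES are roughly standard
        and the per-matrix observed-vs-predicted R² is a valid proportion."""
        fit, ds = small_fit
        rep = cx.gof_diagnostics(fit, ds)
        summary = rep.pwres_summary()
        assert summary["n"] >= 200
        assert abs(summary["mean"]) <= 0.25
        assert 0.6 <= summary["sd"] <= 1.4
        for m, r2 in rep.r_squared.items():
            assert r2 is None or 0.0 <= r2 <= 1.0
        assert rep.r_squared["plasma"] > 0.5

    def test_constant_observations_report_missing_r2(self, small_cohort,
                                                     generic_spec):
        ds, _ = cx.exclude_outliers(small_cohort.dataset)
        flat = []
        for s in ds.subjects[:6]:
            obs = [Observation(s.subject_id, o.time, o.matrix,
                               25.0 if o.matrix == "cortex" else o.value,
                               blq=o.blq, loq=o.loq)
                   for o in s.observations]
            flat.append(Subject(s.subject_id, s.weight, s.regimen, obs,
                                s.stage, s.event_time, s.sacrifice_time))
        ds_flat = Dataset(flat)
        cfg = cx.SAEMConfig(seed=9, n_explore=10, n_smooth=5, chains=1)
        fit = cx.fit_population(ds_flat, generic_spec, cfg)
        rep = cx.gof_diagnostics(fit, ds_flat)
        assert rep.r_squared["cortex"] is None
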