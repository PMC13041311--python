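import numpy as np
import pytest

import cefetox as cx
from cefetox.pk import PKParameters
from cefetox.population import ErrorModel, PopulationModel


@pytest.fixture(scope="session")
def final_params() -> PKParameters:
    return cx.final_model_population().theta


@pytest.fixture(scope="session")
def single_dose_regimen() -> cx.Regimen:
    """One 1,593 mg/kg bolus for a median-weight rat (449.2 mg)."""
    return cx.Regimen((cx.DoseEvent(0.0, 449.2, 0.0),), weight=0.282)


@pytest.fixture(scope="session")
def generic_spec() -> PopulationModel:
    """Estimation starting values deliberately displaced from the generating
    model, so fits do real work."""
    theta0 = PKParameters(kel=0.3, k12=0.00013, k21=0.3, k13=0.000015, k31=0.3,
                          V_central=0.2, V_cortex=0.002, V_hippocampus=0.0008)
    return PopulationModel(
        theta=theta0,
        omega={"kel": 0.3, "V_central": 0.3, "V_cortex": 0.3,
               "V_hippocampus": 0.3, "k21": 0.3, "k31": 0.3},
        re_correlation=0.0,
        error={m: ErrorModel(1.0, 0.3) for m in ("plasma", "cortex", "hippocampus")})


@pytest.fixture(scope="session")
def small_cohort() -> cx.SyntheticCohort:
    """40 virtual rats under the study design, fixed seed."""
    return cx.generate_cohort(design=cx.StudyDesign(n_rats=40), seed=2024)


@pytest.fixture(scope="session")
def small_fit(small_cohort, generic_spec):
    """A short SAEM fit of the 40-rat cohort, shared across test modules."""
    ds, _ = cx.exclude_outliers(small_cohort.dataset)
    cfg = cx.SAEMConfig(seed=77, n_explore=100, n_smooth=60, chains=2)
    return cx.fit_population(ds, generic_spec, cfg), ds


def random_pk_parameters(rng: np.random.Generator) -> PKParameters:
    """Physiologically plausible random parameter draws for property tests."""
    return PKParameters(
        kel=rng.uniform(0.05, 1.5), k12=rng.uniform(1e-5, 0.1),
        k21=rng.uniform(0.05, 0.5), k13=rng.uniform(1e-6, 0.05),
        k31=rng.uniform(0.05, 0.5), V_central=rng.uniform(0.05, 0.3),
        V_cortex=rng.uniform(5e-4, 1e-2), V_hippocampus=rng.uniform(1e-4, 1e-3))
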