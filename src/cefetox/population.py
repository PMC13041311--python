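"""Population layer: between-subject variability, residual error and censoring.

Individual parameters are lognormal around covariate-scaled population
medians:  ``log p_i = log p_pop + beta·log(W_i/W_ref) + eta_i`` with
``eta ~ N(0, Omega)``.  Omega is diagonal except for a single off-diagonal
correlation between the elimination-rate and hippocampal-volume random
effects, the one correlation retained in the final model.

Residual error is combined additive + proportional per matrix,
``SD(pred) = sqrt(a² + (b·pred)²)``.  Concentrations below the assay limit
of quantification (LOQ) enter the likelihood as interval-censored on
``(0, LOQ]`` — the M3-style treatment, with the positivity constraint —
rather than being discarded or imputed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.stats import norm

from .pk import (MATRICES, PARAM_NAMES, AllometricBetas, InvalidInputError,
                 PKParameters, scale_by_weight)

#: structural parameters carrying a random effect in the default (final) model
DEFAULT_RANDOM_EFFECTS = ("kel", "k21", "k31", "V_central", "V_cortex", "V_hippocampus")


class ConfigurationError(ValueError):
    """Raised when a model specification is internally inconsistent."""


@dataclass(frozen=True)
class ErrorModel:
    """Combined residual error: SD(pred) = sqrt(a² + (b·pred)²)."""

    a: float = 0.5   # additive SD, mg/L
    b: float = 0.15  # proportional SD (CV)

    def __post_init__(self) -> None:
        if self.a < 0 or self.b < 0 or self.a + self.b <= 0:
            raise ConfigurationError(f"need a, b >= 0 and a + b > 0, got {self}")

    def sd(self, predicted):
        return np.sqrt(self.a ** 2 + (self.b * np.asarray(predicted)) ** 2)


@dataclass
class PopulationModel:
    """Full population specification for simulation and estimation.

    ``omega`` maps parameter name -> SD of its log-scale random effect
    (parameters absent from the map have no random effect);
    ``re_correlation`` is the single retained off-diagonal, between the kel
    and V_hippocampus random effects.  ``fixed_mask`` names parameters whose
    population value is held fixed during estimation (k12 and k13 in the
    final model, whose transfer into brain is too slow to estimate from
    terminal-only brain samples).
    """

    theta: PKParameters
    betas: AllometricBetas = field(default_factory=AllometricBetas)
    omega: dict[str, float] = field(default_factory=dict)
    re_correlation: float = 0.0  # corr(eta_kel, eta_V_hippocampus)
    error: dict[str, ErrorModel] = field(
        default_factory=lambda: {m: ErrorModel() for m in MATRICES})
    loq: dict[str, float] = field(default_factory=lambda: {m: 0.5 for m in MATRICES})
    fixed_mask: tuple[str, ...] = ("k12", "k13")

    def __post_init__(self) -> None:
        for name, sd in self.omega.items():
            if name not in PARAM_NAMES:
                raise ConfigurationError(f"unknown parameter {name!r} in omega")
            if sd < 0:
                raise ConfigurationError(f"omega[{name!r}] must be >= 0")
        if not -1.0 < self.re_correlation < 1.0:
            raise ConfigurationError("re_correlation must lie in (-1, 1)")
        for m, l in self.loq.items():
            if l <= 0:
                raise ConfigurationError(f"loq[{m!r}] must be > 0")

    @property
    def random_effect_names(self) -> tuple[str, ...]:
        return tuple(n for n in PARAM_NAMES if self.omega.get(n, 0.0) > 0)

    def omega_matrix(self) -> np.ndarray:
        """Covariance of the random-effect vector, in random_effect_names order."""
        names = self.random_effect_names
        sds = np.array([self.omega[n] for n in names])
        cov = np.diag(sds ** 2)
        if self.re_correlation != 0.0 and "kel" in names and "V_hippocampus" in names:
            i, j = names.index("kel"), names.index("V_hippocampus")
            cov[i, j] = cov[j, i] = self.re_correlation * sds[i] * sds[j]
        try:
            np.linalg.cholesky(cov + 1e-300 * np.eye(len(cov)))
        except np.linalg.LinAlgError as exc:
            raise ConfigurationError("random-effect covariance not positive definite") from exc
        return cov


@dataclass
class IndividualParameters:
    """One subject's realized parameters and the random effects behind them."""

    subject_id: str
    params: PKParameters
    eta: dict[str, float]


@dataclass(frozen=True)
class Observation:
    """A concentration record; BLQ records carry the censoring bound, not a value."""

    subject_id: str
    time: float
    matrix: str
    value: float | None
    blq: bool = False
    loq: float = 0.5

    def __post_init__(self) -> None:
        if self.matrix not in MATRICES:
            raise InvalidInputError(f"unknown matrix {self.matrix!r}")
        if not self.blq and (self.value is None or self.value <= 0):
            raise InvalidInputError("non-censored observation must have a positive value")


def individual_params(pop: PopulationModel, weight: float,
                      eta: dict[str, float]) -> PKParameters:
    """Apply covariate scaling then the lognormal random effects."""
    scaled = scale_by_weight(pop.theta, pop.betas, weight)
    updates = {n: getattr(scaled, n) * math.exp(e) for n, e in eta.items()}
    return replace(scaled, **updates)


def sample_individual(pop: PopulationModel, weight: float,
                      rng: np.random.Generator,
                      subject_id: str = "1") -> IndividualParameters:
    """Draw one subject: eta ~ MVN(0, Omega); params = scaled medians × exp(eta)."""
    if weight <= 0:
        raise InvalidInputError(f"weight must be > 0, got {weight!r}")
    names = pop.random_effect_names
    eta_vec = rng.multivariate_normal(np.zeros(len(names)), pop.omega_matrix(),
                                      method="cholesky") if names else np.empty(0)
    eta = dict(zip(names, map(float, eta_vec)))
    return IndividualParameters(subject_id, individual_params(pop, weight, eta), eta)


def observation_loglik(obs: Observation, predicted: float, error: ErrorModel) -> float:
    """Log-likelihood of one record given its model prediction.

    Quantified records contribute a Gaussian density with combined-error SD;
    BLQ records contribute log P(Y in (0, LOQ]) for Y ~ N(predicted, SD²),
    the interval-censored (M3 with positivity) contribution.
    """
    if predicted < 0:
        raise InvalidInputError("predicted concentration must be >= 0")
    sd = float(error.sd(predicted))
    if sd <= 0:
        raise ConfigurationError("residual SD is zero; error model degenerate")
    if not obs.blq:
        z = (obs.value - predicted) / sd
        return -0.5 * z * z - math.log(sd) - 0.5 * math.log(2 * math.pi)
    hi = norm.logcdf((obs.loq - predicted) / sd)
    lo = norm.logcdf((0.0 - predicted) / sd)
    # log(e^hi - e^lo), stable for hi >= lo
    with np.errstate(divide="ignore"):
        return float(hi + np.log1p(-np.exp(lo - hi)))


def simulate_observations(profile, design_times: dict[str, np.ndarray],
                          error: dict[str, ErrorModel], loq: dict[str, float],
                          rng: np.random.Generator,
                          subject_id: str = "1") -> list[Observation]:
    """Sample noisy observations at the design times for each matrix.

    Values drawn below the LOQ (or non-positive) are flagged BLQ with the
    value suppressed, mirroring how an assay reports them.
    """
    out: list[Observation] = []
    for m, times in design_times.items():
        times = np.atleast_1d(np.asarray(times, dtype=float))
        if times.size == 0:
            continue
        if times.min() < profile.times[0] or times.max() > profile.times[-1]:
            raise InvalidInputError(f"design time outside profile span for {m!r}")
        pred = np.interp(times, profile.times, profile.concentrations[m])
        sd = error[m].sd(pred)
        vals = pred + sd * rng.standard_normal(len(times))
        for t, v in zip(times, vals):
            if v < loq[m]:
                out.append(Observation(subject_id, float(t), m, None, blq=True, loq=loq[m]))
            else:
                out.append(Observation(subject_id, float(t), m, float(v), loq=loq[m]))
    return out


def final_model_population() -> PopulationModel:
    """The final fitted population model (AKI-state rats).

    Medians: kel 0.14 h⁻¹, V_central 0.12 L, V_cortex 0.0039 L,
    V_hippocampus 0.00039 L, k12 0.00013 h⁻¹ (fixed), k21 0.17 h⁻¹,
    k13 0.000015 h⁻¹ (fixed), k31 0.15 h⁻¹; allometric betas 0.75 (kel) and
    1 (V_central) on weight normalised to 0.282 kg; corr(eta_kel,
    eta_V_hippocampus) = 0.92.  Between-subject SDs and residual-error
    magnitudes are package defaults (see docs/methods.md); the medians,
    betas and correlation are the reported final-model values.
    """
    theta = PKParameters(kel=0.14, k12=0.00013, k21=0.17, k13=0.000015, k31=0.15,
                         V_central=0.12, V_cortex=0.0039, V_hippocampus=0.00039)
    omega = {"kel": 0.40, "V_central": 0.10, "V_cortex": 0.25,
             "V_hippocampus": 0.25, "k21": 0.25, "k31": 0.25}
    return PopulationModel(theta=theta, omega=omega, re_correlation=0.92)


def healthy_population() -> PopulationModel:
    """Same model with healthy-kidney elimination (kel 1.4 h⁻¹).

    Folic-acid AKI prolongs the cefepime half-life ~10-fold; the study-state
    (AKI) kel of 0.14 h⁻¹ is recovered by applying the generator's AKI kel
    multiplier of 0.1 to this model.
    """
    pop = final_model_population()
    pop.theta = replace(pop.theta, kel=1.4)
    return pop
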