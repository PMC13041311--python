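"""Virtual AKI-rat cohorts with the study's design and statistical structure.

The generator emulates the animal experiment end to end: body weights drawn
around 282 ± 17 g; i.v. cefepime either 1,593 mg/kg once (rats sacrificed on
day 1) or 1,250 mg/kg daily (rats sacrificed on day 3 or 5); folic-acid AKI
represented as a constant multiplier (default 0.1) on each rat's elimination
rate constant, matching the ~10-fold half-life prolongation; plasma sampled
at 0, 15, 30 and 120 min after each dose up to sacrifice; a single terminal
cortex and hippocampus sample per rat at its serial-sacrifice time (30 or
120 min on day 1, 120 min on day 3 or 5); seizure outcomes drawn from a
logistic exposure-toxicity model on the noise-free exposure, with the
time-to-seizure uniform on 1-4 h after the first dose.

Everything is reproducible from a single seed, and the ground truth
(individual parameters, true exposures, outcome probabilities) travels with
the cohort so estimation and exposure-response analyses can be validated
against it.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field, replace

import numpy as np

from . import pk
from .data import Dataset, Subject
from .pk import DoseEvent, ExposureMetrics, InvalidInputError, Regimen
from .population import (ConfigurationError, IndividualParameters,
                         PopulationModel, healthy_population,
                         sample_individual, simulate_observations)


@dataclass(frozen=True)
class DoseArm:
    """One dosing arm: mg/kg per dose, number of daily doses, infusion duration."""

    dose_mg_per_kg: float
    n_days: int
    infusion_duration: float = 5 / 60  # h
    label: str = ""


@dataclass
class StudyDesign:
    """Cohort design: who gets what, when they are sampled, when they die.

    ``sacrifice_schedule`` lists (day, hours-after-that-day's-dose) slots;
    rats are spread over the slots round-robin.  Day-1 slots receive the
    single high-dose arm (1,593 mg/kg once), later slots the daily arm
    (1,250 mg/kg/day), mirroring the serial-sacrifice layout.
    """

    n_rats: int = 18
    weight_mean: float = 0.282  # kg
    weight_sd: float = 0.017
    weight_truncation_sd: float = 3.0
    single_dose_arm: DoseArm = field(default_factory=lambda: DoseArm(1593.0, 1, label="1593x1"))
    daily_dose_arm: DoseArm = field(default_factory=lambda: DoseArm(1250.0, 5, label="1250qd"))
    plasma_offsets: tuple[float, ...] = (0.0, 0.25, 0.5, 2.0)  # h post-dose
    sacrifice_schedule: tuple[tuple[int, float], ...] = (
        (1, 0.5), (1, 2.0), (3, 2.0), (5, 2.0))
    aki_kel_multiplier: float = 0.1
    #: optional linear renal-recovery hook: the kel multiplier rises by this
    #: amount per study day (capped at 1), emulating the spontaneous return
    #: of renal function over days; 0 = constant AKI (default)
    kel_recovery_per_day: float = 0.0
    loq: float = 0.5  # mg/L

    def __post_init__(self) -> None:
        if self.n_rats < 1:
            raise ConfigurationError("n_rats must be >= 1")
        if not 0 < self.aki_kel_multiplier <= 1:
            raise ConfigurationError("aki_kel_multiplier must lie in (0, 1]")
        if any(o < 0 or o >= 24 for o in self.plasma_offsets):
            raise ConfigurationError("plasma offsets must lie within the dosing day")
        if any(d < 1 or h < 0 for d, h in self.sacrifice_schedule):
            raise ConfigurationError("sacrifice before first dose")
        if self.kel_recovery_per_day < 0:
            raise ConfigurationError("kel_recovery_per_day must be >= 0")


@dataclass
class OutcomeModel:
    """Logistic exposure-toxicity model generating Racine stages.

    P(seizure, i.e. stage > 1) = logistic(slope·(x − tc50)) where x is the
    driving exposure metric (default hippocampal Cmax, the strongest
    association).  Seizing rats draw a stage uniformly from ``stage_choices``
    and an event time uniform on ``event_window`` after the first dose;
    non-seizing rats draw stage 0 or 1 and are censored at sacrifice.
    """

    metric: str = "cmax"              # "auc" or "cmax"
    matrix: str = "hippocampus"
    tc50: float = 48.2                # mg/L, hippocampal Cmax scale
    slope: float = 3.0 / 48.2         # per exposure unit
    stage_choices: tuple[int, ...] = (2, 3, 4, 5, 6)
    event_window: tuple[float, float] = (1.0, 4.0)  # h post first dose

    def __post_init__(self) -> None:
        if self.tc50 <= 0 or self.slope <= 0:
            raise ConfigurationError("tc50 and slope must be positive")
        if not 0 <= self.event_window[0] < self.event_window[1]:
            raise ConfigurationError("invalid event window")

    def probability(self, exposure: float) -> float:
        return float(1.0 / (1.0 + np.exp(-self.slope * (exposure - self.tc50))))

    def exposure_of(self, metrics: ExposureMetrics) -> float:
        d = metrics.auc_0_24 if self.metric == "auc" else metrics.cmax_0_24
        return d[self.matrix]


@dataclass
class SyntheticCohort:
    """A generated dataset plus the ground truth that produced it."""

    dataset: Dataset
    true_params: dict[str, IndividualParameters]
    true_exposures: dict[str, ExposureMetrics]
    true_probabilities: dict[str, float]
    generating_population: PopulationModel
    design: StudyDesign
    outcome: OutcomeModel
    seed: int

    def ground_truth_json(self) -> str:
        cfg = {"design": dataclasses.asdict(self.design),
               "outcome": dataclasses.asdict(self.outcome)}
        blob = json.dumps(cfg, sort_keys=True)
        gt = {
            "seed": self.seed,
            "generator_config": cfg,
            "config_hash": hashlib.sha256(blob.encode()).hexdigest()[:16],
            "subjects": {
                sid: {
                    "params": dataclasses.asdict(ip.params),
                    "eta": ip.eta,
                    "exposure": dataclasses.asdict(self.true_exposures[sid]),
                    "p_seizure": self.true_probabilities[sid],
                } for sid, ip in self.true_params.items()},
        }
        return json.dumps(gt, indent=1, sort_keys=True)


def escalation_plan(base_rat_dose: float, multipliers) -> list[int]:
    """Dose-escalation ladder: base rat dose × each multiplier, whole mg/kg.

    The study escalated from the allometrically scaled maximum human daily
    dose (531 mg/kg/day in the rat) through 3× (1,593; the maximum tolerated
    dose) to 4× (2,124, lethal).
    """
    if base_rat_dose <= 0:
        raise InvalidInputError("base dose must be positive")
    out = []
    for m in multipliers:
        if m <= 0:
            raise InvalidInputError(f"non-positive multiplier {m!r}")
        out.append(round(base_rat_dose * m))
    return out


def assign_outcome(exposure: float, outcome: OutcomeModel,
                   rng: np.random.Generator,
                   sacrifice_time: float) -> tuple[int, bool, float, bool]:
    """Draw (stage, seizure indicator, event-or-censor time, event flag).

    Seizing rats keep the drawn onset time (1-4 h post-dose by default);
    the cohort generator moves their sacrifice to seizure onset when the
    scheduled slot would fall earlier, mirroring sacrifice "at the onset of
    seizure or at predetermined time points".  Non-seizing rats are censored
    at sacrifice.
    """
    p = outcome.probability(exposure)
    seized = bool(rng.random() < p)
    if seized:
        stage = int(rng.choice(outcome.stage_choices))
        t = float(rng.uniform(*outcome.event_window))
        return stage, True, t, True
    stage = int(rng.choice([0, 1]))
    return stage, False, float(sacrifice_time), False


def solve_with_recovery(healthy_params, regimen: Regimen, grid: np.ndarray,
                        multiplier0: float, rate_per_day: float):
    """Profile with a day-wise elimination rate during renal recovery.

    Day d uses kel = healthy kel × min(1, multiplier0 + rate_per_day·d);
    each 24-h window is solved exactly and the compartment amounts are
    carried into the next window, so the only approximation is the daily
    (rather than continuous) update of the recovery multiplier.
    """
    grid = np.asarray(grid, dtype=float)
    if grid[0] != 0.0:
        raise InvalidInputError("recovery profiles must start at t = 0")
    n_days = max(1, int(np.ceil(grid[-1] / 24.0 - 1e-12)))
    amounts = np.zeros((len(grid), 4))
    state = np.zeros(4)
    for d in range(n_days):
        lo = 24.0 * d
        hi = min(24.0 * (d + 1), float(grid[-1]))
        m = min(1.0, multiplier0 + rate_per_day * d)
        p_d = replace(healthy_params, kel=healthy_params.kel * m)
        events = tuple(DoseEvent(e.start_time - lo, e.amount, e.duration)
                       for e in regimen.events if lo <= e.start_time < hi)
        sel = (grid > lo) & (grid <= hi)
        pts = grid[sel] - lo
        local_grid = np.unique(np.concatenate([[0.0], pts, [hi - lo]]))
        prof = pk.solve_profile(p_d, Regimen(events, regimen.weight),
                                local_grid, initial_amounts=state)
        idx = np.searchsorted(local_grid, pts)
        amounts[sel] = prof.amounts[idx]
        state = prof.amounts[-1]
    conc = {
        "plasma": amounts[:, 0] / healthy_params.V_central,
        "cortex": amounts[:, 1] / healthy_params.V_cortex,
        "hippocampus": amounts[:, 2] / healthy_params.V_hippocampus,
    }
    infused = pk._cumulative_infused(regimen.events, grid)
    return pk.ConcentrationProfile(times=grid, amounts=amounts,
                                   concentrations=conc, infused=infused,
                                   params=healthy_params)


def _truncated_normal(mean, sd, n_sd, rng, size):
    out = np.empty(size)
    filled = 0
    while filled < size:
        draw = rng.normal(mean, sd, size=size - filled)
        keep = draw[np.abs(draw - mean) <= n_sd * sd]
        out[filled:filled + len(keep)] = keep
        filled += len(keep)
    return out


def generate_cohort(design: StudyDesign | None = None,
                    pop: PopulationModel | None = None,
                    outcome: OutcomeModel | None = None,
                    seed: int = 0) -> SyntheticCohort:
    """Simulate a full virtual cohort under the study design.

    ``pop`` describes the pre-AKI (healthy-kidney) population; each rat's kel
    is multiplied by ``design.aki_kel_multiplier`` after the random effects,
    so with the defaults the effective population kel is the study-state
    0.14 h⁻¹.  Observations carry residual noise and BLQ flags; the returned
    cohort also records each rat's true parameters, noise-free exposures and
    outcome probability.
    """
    design = design or StudyDesign()
    pop = pop or healthy_population()
    outcome = outcome or OutcomeModel()
    root = np.random.default_rng(seed)
    rngs = root.spawn(4)  # weights, etas, noise, outcomes

    weights = _truncated_normal(design.weight_mean, design.weight_sd,
                                design.weight_truncation_sd, rngs[0], design.n_rats)

    slots = [design.sacrifice_schedule[i % len(design.sacrifice_schedule)]
             for i in range(design.n_rats)]

    subjects, true_params, true_exp, true_p = [], {}, {}, {}
    for i, (w, (sac_day, sac_offset)) in enumerate(zip(weights, slots)):
        sid = f"R{i + 1:03d}"
        arm = design.single_dose_arm if sac_day == 1 else design.daily_dose_arm
        n_days = min(arm.n_days, sac_day)
        regimen = Regimen(
            tuple(DoseEvent(24.0 * d, arm.dose_mg_per_kg * w, arm.infusion_duration)
                  for d in range(n_days)), weight=w)
        scheduled_sacrifice = 24.0 * (sac_day - 1) + sac_offset

        indiv = sample_individual(pop, w, rngs[1], subject_id=sid)
        healthy_params = indiv.params
        indiv.params = replace(indiv.params,
                               kel=indiv.params.kel * design.aki_kel_multiplier)
        true_params[sid] = indiv

        if design.kel_recovery_per_day > 0:
            def solve(grid, _hp=healthy_params, _reg=regimen):
                return solve_with_recovery(_hp, _reg, grid,
                                           design.aki_kel_multiplier,
                                           design.kel_recovery_per_day)
        else:
            def solve(grid, _p=indiv.params, _reg=regimen):
                return pk.solve_profile(_p, _reg, grid)

        exposure_grid = np.arange(0.0, max(24.0, scheduled_sacrifice) + 0.05, 0.1)
        metrics = pk.exposure_metrics(solve(exposure_grid))
        true_exp[sid] = metrics

        exposure = outcome.exposure_of(metrics)
        true_p[sid] = outcome.probability(exposure)
        stage, seized, t_event, _is_event = assign_outcome(
            exposure, outcome, rngs[3], scheduled_sacrifice)
        # rats seizing after their scheduled slot are sacrificed at onset
        sacrifice_time = max(scheduled_sacrifice, t_event) if seized \
            else scheduled_sacrifice

        horizon = max(sacrifice_time, 24.0)
        grid = np.unique(np.concatenate([
            np.arange(0.0, horizon + 0.05, 0.1), [sacrifice_time, horizon]]))
        profile = solve(grid)

        plasma_times = sorted(
            24.0 * d + off
            for d in range(n_days) for off in design.plasma_offsets
            if 24.0 * d + off <= sacrifice_time)
        obs = simulate_observations(
            profile,
            {"plasma": np.array(plasma_times),
             "cortex": np.array([sacrifice_time]),
             "hippocampus": np.array([sacrifice_time])},
            pop.error, {m: design.loq for m in pop.error}, rngs[2], subject_id=sid)

        subjects.append(Subject(sid, float(w), regimen, obs, stage,
                                event_time=t_event if seized else None,
                                sacrifice_time=sacrifice_time))

    dataset = Dataset(subjects, metadata={"generator_seed": seed,
                                          "aki_kel_multiplier": design.aki_kel_multiplier})
    return SyntheticCohort(dataset, true_params, true_exp, true_p,
                           pop, design, outcome, seed)
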