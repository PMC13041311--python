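"""Structural pharmacokinetic model: plasma, cerebral cortex and hippocampus.

The structural model is a linear three-compartment system.  Drug is infused
into a central (plasma) compartment, distributes reversibly into two small
brain compartments (cerebral cortex via ``k12``/``k21``, hippocampus via
``k13``/``k31``) and is eliminated from the central compartment at first-order
rate ``kel``::

    dA_central/dt     = -(kel + k12 + k13)·A_central + k21·A_cortex + k31·A_hippocampus + R(t)
    dA_cortex/dt      = k12·A_central - k21·A_cortex
    dA_hippocampus/dt = k13·A_central - k31·A_hippocampus

with concentrations ``C_x = A_x / V_x`` in each compartment.  ``R(t)`` is the
piecewise-constant infusion rate.  Amounts are in mg, volumes in L,
concentrations in mg/L and times in h; brain µg/g is treated as numerically
equal to mg/L (tissue density 1 g/mL).

Because the system is linear with piecewise-constant input it is solved
exactly, segment by segment, with a matrix exponential (no truncation error
beyond floating point).  ``kel`` and ``V_central`` scale allometrically with
body weight; the brain rate constants and volumes do not.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace

import numpy as np
from scipy.linalg import expm

MATRICES = ("plasma", "cortex", "hippocampus")

#: FDA body-surface-area conversion factor between human and rat mg/kg doses.
HED_RAT_FACTOR = 6.2

PARAM_NAMES = ("kel", "k12", "k21", "k13", "k31",
               "V_central", "V_cortex", "V_hippocampus")


class InvalidInputError(ValueError):
    """Raised when an argument violates a documented precondition."""


@dataclass(frozen=True)
class PKParameters:
    """Structural rate constants (1/h) and apparent volumes (L)."""

    kel: float
    k12: float
    k21: float
    k13: float
    k31: float
    V_central: float
    V_cortex: float
    V_hippocampus: float

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not np.isfinite(v) or v <= 0:
                raise InvalidInputError(
                    f"PKParameters.{f.name} must be strictly positive and finite, got {v!r}"
                )

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in PARAM_NAMES], dtype=float)

    @classmethod
    def from_array(cls, arr: np.ndarray) -> "PKParameters":
        return cls(**dict(zip(PARAM_NAMES, map(float, arr))))

    def volume(self, matrix: str) -> float:
        return {"plasma": self.V_central,
                "cortex": self.V_cortex,
                "hippocampus": self.V_hippocampus}[matrix]


@dataclass(frozen=True)
class AllometricBetas:
    """Power-law weight exponents for kel and V_central.

    Individual parameters follow ``p_i = p_pop * (W_i / ref_weight)**beta``
    with beta 0.75 on the elimination rate constant and 1 on the central
    volume (the conventional allometric exponents for clearance-like and
    volume-like parameters).
    """

    beta_kel: float = 0.75
    beta_V_central: float = 1.0
    ref_weight: float = 0.282  # kg, median study rat

    def __post_init__(self) -> None:
        if not (np.isfinite(self.ref_weight) and self.ref_weight > 0):
            raise InvalidInputError(f"ref_weight must be > 0, got {self.ref_weight!r}")


@dataclass(frozen=True)
class DoseEvent:
    """One i.v. administration: constant-rate infusion (``duration`` h, 0 = bolus)."""

    start_time: float  # h
    amount: float      # mg
    duration: float = 0.0  # h

    def __post_init__(self) -> None:
        if self.start_time < 0 or self.amount < 0 or self.duration < 0:
            raise InvalidInputError(f"invalid dose event {self}")

    @property
    def end_time(self) -> float:
        return self.start_time + self.duration


@dataclass(frozen=True)
class Regimen:
    """An ordered sequence of dose events for one subject of given weight (kg)."""

    events: tuple[DoseEvent, ...]
    weight: float

    def __post_init__(self) -> None:
        if self.weight <= 0 or not np.isfinite(self.weight):
            raise InvalidInputError(f"weight must be > 0, got {self.weight!r}")
        starts = [e.start_time for e in self.events]
        if any(b < a for a, b in zip(starts, starts[1:])):
            raise InvalidInputError("dose events must be sorted by start_time")

    @classmethod
    def daily(cls, dose_mg_per_kg: float, weight: float, n_days: int,
              duration: float = 5 / 60) -> "Regimen":
        """Once-daily dosing of ``dose_mg_per_kg`` for ``n_days`` days."""
        amount = dose_mg_per_kg * weight
        events = tuple(DoseEvent(24.0 * d, amount, duration) for d in range(n_days))
        return cls(events, weight)


@dataclass
class ConcentrationProfile:
    """Amounts and concentrations on a time grid.

    ``amounts`` has one row per grid point and columns (central, cortex,
    hippocampus, eliminated); ``concentrations`` maps each matrix to
    ``A_compartment / V_compartment``.  ``infused`` is the cumulative amount
    administered up to each grid time, so mass balance can be checked as
    ``amounts.sum(axis=1) == infused``.
    """

    times: np.ndarray
    amounts: np.ndarray
    concentrations: dict[str, np.ndarray]
    infused: np.ndarray
    params: PKParameters = field(repr=False, default=None)

    def mass_balance_error(self) -> float:
        """Largest relative mass-balance violation over the grid."""
        total = self.amounts.sum(axis=1)
        scale = np.maximum(self.infused, 1e-300)
        return float(np.max(np.abs(total - self.infused) / scale, initial=0.0))

    def to_frame(self, subject_id: str = ""):
        """Tidy long-format table: subject, time, matrix, concentration."""
        import pandas as pd
        frames = [pd.DataFrame({"subject": subject_id, "time": self.times,
                                "matrix": m, "concentration": c})
                  for m, c in self.concentrations.items()]
        return pd.concat(frames, ignore_index=True)


@dataclass(frozen=True)
class ExposureMetrics:
    """AUC₀₋₂₄ (mg·h/L), Cmax₀₋₂₄ (mg/L) and tmax (h) per matrix."""

    auc_0_24: dict[str, float]
    cmax_0_24: dict[str, float]
    tmax: dict[str, float]


def scale_by_weight(pop: PKParameters, betas: AllometricBetas, weight: float) -> PKParameters:
    """Allometric covariate model: scale kel and V_central by body weight.

    ``kel_i = kel_pop·(W/W_ref)^0.75`` and ``V_central,i = V_pop·(W/W_ref)^1``;
    the brain transfer constants and volumes are weight-independent.
    """
    if not (np.isfinite(weight) and weight > 0):
        raise InvalidInputError(f"weight must be > 0, got {weight!r}")
    ratio = weight / betas.ref_weight
    return replace(
        pop,
        kel=pop.kel * ratio ** betas.beta_kel,
        V_central=pop.V_central * ratio ** betas.beta_V_central,
    )


def hed_to_rat_dose(human_dose: float) -> float:
    """Convert a human mg/kg/day dose to the rat equivalent (×6.2, BSA scaling)."""
    if human_dose < 0:
        raise InvalidInputError(f"dose must be non-negative, got {human_dose!r}")
    return human_dose * HED_RAT_FACTOR


def rat_to_hed_dose(rat_dose: float) -> float:
    """Inverse of :func:`hed_to_rat_dose`."""
    if rat_dose < 0:
        raise InvalidInputError(f"dose must be non-negative, got {rat_dose!r}")
    return rat_dose / HED_RAT_FACTOR


def _rate_matrix(p: PKParameters) -> np.ndarray:
    """4-state rate matrix over (central, cortex, hippocampus, eliminated)."""
    return np.array([
        [-(p.kel + p.k12 + p.k13), p.k21, p.k31, 0.0],
        [p.k12, -p.k21, 0.0, 0.0],
        [p.k13, 0.0, -p.k31, 0.0],
        [p.kel, 0.0, 0.0, 0.0],
    ])


def _breakpoints(events: tuple[DoseEvent, ...], t_end: float) -> tuple[np.ndarray, np.ndarray]:
    """Segment boundaries and the constant infusion rate within each segment."""
    cuts = {0.0, t_end}
    for e in events:
        cuts.add(e.start_time)
        cuts.add(min(e.end_time, t_end) if e.duration > 0 else e.start_time)
    bounds = np.array(sorted(t for t in cuts if t <= t_end))
    rates = np.zeros(len(bounds) - 1)
    mid = (bounds[:-1] + bounds[1:]) / 2
    for e in events:
        if e.duration > 0:
            rates += np.where((mid >= e.start_time) & (mid < e.end_time),
                              e.amount / e.duration, 0.0)
    return bounds, rates


def _cumulative_infused(events, times: np.ndarray) -> np.ndarray:
    out = np.zeros_like(times, dtype=float)
    for e in events:
        if e.duration > 0:
            frac = np.clip((times - e.start_time) / e.duration, 0.0, 1.0)
        else:
            frac = (times >= e.start_time).astype(float)
        out += e.amount * frac
    return out


def solve_profile(params: PKParameters, regimen: Regimen, grid: np.ndarray,
                  initial_amounts: np.ndarray | None = None) -> ConcentrationProfile:
    """Solve the three-compartment system exactly on ``grid``.

    Uses a piecewise matrix-exponential propagator on the augmented linear
    system (states plus constant input), which is exact for piecewise-constant
    infusion rates.  Bolus doses are applied as instantaneous jumps of the
    central amount.  The grid must start at or after 0, be strictly
    increasing, and cover every dose event.

    ``initial_amounts`` (central, cortex, hippocampus, eliminated), default
    all zero, lets callers chain segments solved with different parameters —
    e.g. a day-by-day elimination rate during renal recovery.  Grid times are
    then relative to the segment start, and the reported cumulative input
    includes the initial amounts so mass balance still closes.
    """
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 1 or len(grid) < 2 or np.any(np.diff(grid) <= 0):
        raise InvalidInputError("grid must be a strictly increasing 1-D array")
    if grid[0] < 0:
        raise InvalidInputError("grid must not start before time 0")
    t_end = grid[-1]
    for e in regimen.events:
        if e.start_time > t_end:
            raise InvalidInputError(
                f"dose event at t={e.start_time} lies outside the grid (end {t_end})")

    K = _rate_matrix(params)
    bounds, rates = _breakpoints(regimen.events, t_end)
    boluses = [(e.start_time, e.amount) for e in regimen.events if e.duration == 0]

    out = np.zeros((len(grid), 4))
    state = np.zeros(4) if initial_amounts is None \
        else np.asarray(initial_amounts, dtype=float).copy()
    carried = float(state.sum())
    # augmented system: d/dt [A; u] = [[K, r_vec],[0,0]] [A; u], u ≡ 1
    for lo, hi, rate in zip(bounds[:-1], bounds[1:], rates):
        for t0, amt in boluses:
            if t0 == lo:
                state[0] += amt
        targets = grid[(grid > lo) & (grid <= hi)]
        M = np.zeros((5, 5))
        M[:4, :4] = K
        M[0, 4] = rate
        for t in targets:
            prop = expm(M * (t - lo))
            aug = prop @ np.append(state, 1.0)
            out[np.searchsorted(grid, t)] = aug[:4]
        prop = expm(M * (hi - lo))
        state = (prop @ np.append(state, 1.0))[:4]
    if grid[0] == 0.0:
        a0 = np.zeros(4) if initial_amounts is None \
            else np.asarray(initial_amounts, dtype=float).copy()
        for t0, amt in boluses:
            if t0 == 0.0:
                a0[0] += amt
        out[0] = a0

    conc = {
        "plasma": out[:, 0] / params.V_central,
        "cortex": out[:, 1] / params.V_cortex,
        "hippocampus": out[:, 2] / params.V_hippocampus,
    }
    infused = _cumulative_infused(regimen.events, grid) + carried
    return ConcentrationProfile(times=grid, amounts=out, concentrations=conc,
                                infused=infused, params=params)


def predict_concentrations(params: PKParameters, regimen: Regimen,
                           times: np.ndarray, matrices: np.ndarray) -> np.ndarray:
    """Model-predicted concentration at each (time, matrix) pair.

    Fast path used by the estimation machinery: the 3×3 amount system is
    eigendecomposed once (real eigenvalues for this mamillary structure) and
    evaluated analytically segment by segment, which is orders of magnitude
    faster than the generic propagator for repeated calls.  ``matrices`` holds
    integer codes (0 plasma, 1 cortex, 2 hippocampus).
    """
    times = np.asarray(times, dtype=float)
    matrices = np.asarray(matrices)
    t_end = float(times.max(initial=0.0))
    K = _rate_matrix(params)[:3, :3]
    lam, V = np.linalg.eig(K)
    lam, V = np.real(lam), np.real(V)
    Vinv = np.linalg.inv(V)

    bounds, rates = _breakpoints(regimen.events, t_end)
    boluses = [(e.start_time, e.amount) for e in regimen.events if e.duration == 0]

    amounts = np.zeros((len(times), 3))
    state = np.zeros(3)
    for lo, hi, rate in zip(bounds[:-1], bounds[1:], rates):
        for t0, amt in boluses:
            if t0 == lo:
                state[0] += amt
        if rate != 0.0:
            part = np.linalg.solve(K, -np.array([rate, 0.0, 0.0]))
        else:
            part = np.zeros(3)
        c0 = Vinv @ (state - part)
        mask = (times > lo) & (times <= hi)
        if mask.any():
            dt = times[mask] - lo
            amounts[mask] = (V @ (c0[:, None] * np.exp(np.outer(lam, dt)))).T + part
        state = V @ (c0 * np.exp(lam * (hi - lo))) + part
    for t0, amt in boluses:
        if t0 == t_end:
            state[0] += amt
    if np.any(times == 0.0):
        a0 = np.zeros(3)
        for t0, amt in boluses:
            if t0 == 0.0:
                a0[0] += amt
        amounts[times == 0.0] = a0

    vols = np.array([params.V_central, params.V_cortex, params.V_hippocampus])
    return amounts[np.arange(len(times)), matrices] / vols[matrices]


def exposure_metrics(profile: ConcentrationProfile, auc_grid_step: float = 0.1,
                     cmax_grid_step: float = 0.1, window: float = 24.0) -> ExposureMetrics:
    """AUC₀₋₂₄ (linear trapezoid), Cmax₀₋₂₄ and tmax per matrix on 0.1-h grids.

    Both metrics are evaluated on fixed fine grids (default 0.1 h = 6-min
    intervals) by linear interpolation of the profile, so they depend only on
    the requested resolution, not on the solver grid.
    """
    if auc_grid_step <= 0 or cmax_grid_step <= 0:
        raise InvalidInputError("grid steps must be positive")
    if profile.times[0] > 0 or profile.times[-1] < window:
        raise InvalidInputError(f"profile must cover [0, {window}] h")
    auc, cmax, tmax = {}, {}, {}
    for m in MATRICES:
        ga = np.arange(0.0, window + auc_grid_step / 2, auc_grid_step)
        ca = np.interp(ga, profile.times, profile.concentrations[m])
        auc[m] = float(np.trapezoid(ca, ga))
        gc = np.arange(0.0, window + cmax_grid_step / 2, cmax_grid_step)
        cc = np.interp(gc, profile.times, profile.concentrations[m])
        i = int(np.argmax(cc))
        cmax[m] = float(cc[i])
        tmax[m] = float(gc[i])
    return ExposureMetrics(auc_0_24=auc, cmax_0_24=cmax, tmax=tmax)
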