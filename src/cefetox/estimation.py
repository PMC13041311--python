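"""Population fitting, empirical-Bayes profiles, model comparison, diagnostics.

`fit_population` runs SAEM on an event dataset; `empirical_bayes` turns the
fit into per-animal MAP parameter estimates and posterior concentration
profiles on a 0.1-h grid (the profiles from which the exposure metrics are
computed); `exclude_outliers` applies the pre-modelling z-score screen;
`information_criteria` and `gof_diagnostics` support the model-selection
ladder and goodness-of-fit review.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import pk
from .data import Dataset, Subject
from .pk import PARAM_NAMES, PKParameters
from .population import (ConfigurationError, ErrorModel, IndividualParameters,
                         PopulationModel)
from .saem import SAEMConfig, SAEMState

__all__ = ["SAEMConfig", "FitResult", "DiagnosticsReport", "exclude_outliers",
           "fit_population", "empirical_bayes", "information_criteria",
           "gof_diagnostics"]


@dataclass
class FitResult:
    """Everything the SAEM run produced."""

    model: PopulationModel                      # estimated population model
    rse_percent: dict[str, float] | None
    minus2ll: float
    aic: float
    bic: float
    k_free: int
    n_subjects: int
    bic_convention: str
    trace: pd.DataFrame
    eb_params: dict[str, IndividualParameters]
    converged: bool
    warnings: list[str] = field(default_factory=list)
    _state: "SAEMState" = field(default=None, repr=False)
    _dataset: Dataset = field(default=None, repr=False)


@dataclass
class DiagnosticsReport:
    """Observed-vs-predicted and population-weighted residual tables."""

    obs_vs_pred: pd.DataFrame      # ID, TIME, MATRIX, DV, EB_PRED, POP_PRED, PWRES
    r_squared: dict[str, float | None]

    def pwres_summary(self) -> dict[str, float]:
        pw = self.obs_vs_pred["PWRES"].dropna()
        return {"mean": float(pw.mean()), "sd": float(pw.std(ddof=1)),
                "n": int(len(pw))}


def exclude_outliers(dataset: Dataset, z_threshold: float = 3.0
                     ) -> tuple[Dataset, pd.DataFrame]:
    """Drop plasma records more than ``z_threshold`` SDs from their stratum mean.

    Strata are (matrix, nominal post-dose sampling time); only quantified
    plasma records are screened (brain samples are one-per-rat and BLQ
    records carry no value).  Each record is compared against the mean and SD
    of the *other* records in its stratum (leave-one-out), so a gross outlier
    cannot mask itself by inflating the stratum SD.  Returns the filtered
    dataset and a report of removals (strata with fewer than three other
    records, or zero spread, are skipped).
    """
    records = []
    for s in dataset.subjects:
        dose_times = np.array([e.start_time for e in s.regimen.events])
        for o in s.observations:
            prior = dose_times[dose_times <= o.time]
            offset = o.time - (prior.max() if len(prior) else 0.0)
            records.append((s.subject_id, o, round(offset, 6)))

    values: dict[float, list[float]] = {}
    for _, o, off in records:
        if o.matrix == "plasma" and not o.blq:
            values.setdefault(off, []).append(o.value)

    removed = []
    keep: dict[str, list] = {s.subject_id: [] for s in dataset.subjects}
    for sid, o, off in records:
        drop = False
        if o.matrix == "plasma" and not o.blq:
            vals = np.array(values.get(off, []))
            # leave this record out of its own reference distribution
            i = int(np.nonzero(vals == o.value)[0][0])
            peers = np.delete(vals, i)
            if len(peers) >= 3 and peers.std(ddof=1) > 0:
                z = (o.value - peers.mean()) / peers.std(ddof=1)
                if abs(z) > z_threshold:
                    drop = True
                    removed.append({"ID": sid, "TIME": o.time, "MATRIX": o.matrix,
                                    "DV": o.value, "nominal_offset": off,
                                    "z_score": float(z)})
        if not drop:
            keep[sid].append(o)

    subjects = [Subject(s.subject_id, s.weight, s.regimen, keep[s.subject_id],
                        s.stage, s.event_time, s.sacrifice_time)
                for s in dataset.subjects]
    meta = dict(dataset.metadata)
    meta["outlier_exclusion"] = {"z_threshold": z_threshold,
                                 "stratification": "matrix x nominal post-dose time",
                                 "n_removed": len(removed)}
    report = pd.DataFrame(removed, columns=["ID", "TIME", "MATRIX", "DV",
                                            "nominal_offset", "z_score"])
    return Dataset(subjects, meta), report


def information_criteria(minus2ll: float, k: int, n: int) -> dict[str, float]:
    """AIC = -2LL + 2k; BIC = -2LL + k·ln(n) with n = number of subjects."""
    if n < 1 or k < 0:
        raise ConfigurationError("need n >= 1 and k >= 0")
    return {"AIC": minus2ll + 2 * k, "BIC": minus2ll + k * math.log(n)}


def _rse_from_scores(state: SAEMState, rng_seed: int) -> dict[str, float]:
    """Score-based standard errors for the population medians.

    Per-subject scores of the importance-sampled log-likelihood with respect
    to each log-median (central differences with common random numbers);
    the Fisher information is approximated by the sum of score outer
    products.  On the log scale the SE is directly the RSE of the median.
    """
    h = 0.02
    ns = state.config.n_importance_rse
    idx = state.re_idx
    p = len(idx)
    scores = np.zeros((state.n, p))
    rng = np.random.default_rng(rng_seed)
    om = state.omega_matrix()
    om_inv = np.linalg.inv(om)
    _, logdet = np.linalg.slogdet(om)

    for i in range(state.n):
        mode, _ = state.eb_mode(i, n_starts=1, rng=rng)
        cov = state._laplace_cov(i, mode)
        L = np.linalg.cholesky(cov + 1e-10 * np.eye(state.q))
        draws = mode + rng.standard_normal((ns, state.q)) @ L.T
        delta = draws - mode
        prior = -0.5 * np.einsum("bq,qk,bk->b", draws, om_inv, draws)
        logq = -0.5 * np.sum(delta * np.linalg.solve(cov, delta.T).T, axis=1)

        def is_ll(mu_shift):
            state.mu_full[idx] += mu_shift
            try:
                logw = state.subject_loglik_batch(i, draws) + prior - logq
                m = logw.max()
                return m + math.log(np.mean(np.exp(logw - m)))
            finally:
                state.mu_full[idx] -= mu_shift

        for j in range(p):
            e = np.zeros(p)
            e[j] = h
            scores[i, j] = (is_ll(e) - is_ll(-e)) / (2 * h)

    info = scores.T @ scores
    try:
        cov_theta = np.linalg.inv(info)
        se = np.sqrt(np.clip(np.diag(cov_theta), 0, None))
    except np.linalg.LinAlgError:
        se = np.full(p, np.nan)
    return {name: float(100 * se[j]) for j, name in enumerate(state.re_names)}


def fit_population(dataset: Dataset, spec: PopulationModel,
                   config: SAEMConfig) -> FitResult:
    """SAEM fit of the population model to an event dataset.

    ``spec`` supplies the initial values, which parameters are held fixed
    (``fixed_mask``; k12/k13 by default, since terminal-only brain sampling
    cannot inform them) and the initial between-subject SDs.  BLQ records
    contribute interval-censored likelihood throughout.  The -2LL at the
    final estimates is computed by importance sampling; AIC/BIC use
    n = number of subjects.  Deterministic for a given seed.
    """
    warn_list: list[str] = []
    state = SAEMState(dataset, spec, config)
    converged = True
    try:
        state.run()
    except (np.linalg.LinAlgError, FloatingPointError) as exc:  # pragma: no cover
        converged = False
        warn_list.append(f"SAEM did not complete: {exc!r}")

    theta_arr = np.exp(state.mu_full)
    for name in spec.fixed_mask:  # fixed parameters round-trip exactly
        theta_arr[PARAM_NAMES.index(name)] = getattr(spec.theta, name)
    theta = PKParameters.from_array(theta_arr)
    omega = {name: float(sd) for name, sd in zip(state.re_names, state.omega_sd)}
    mats = ("plasma", "cortex", "hippocampus")
    error = {m: ErrorModel(a=max(float(state.err_a[i]), 0.0),
                           b=max(float(state.err_b[i]), 0.0))
             for i, m in enumerate(mats)}
    model = PopulationModel(theta=theta, betas=spec.betas, omega=omega,
                            re_correlation=float(state.corr), error=error,
                            loq=dict(spec.loq), fixed_mask=spec.fixed_mask)

    minus2ll = state.marginal_minus2ll()
    k = state.n_free_parameters()
    crit = information_criteria(minus2ll, k, state.n)

    rse = None
    if config.compute_rse:
        rse = _rse_from_scores(state, config.seed + 2)

    eb_rng = np.random.default_rng(config.seed + 3)
    eb_params: dict[str, IndividualParameters] = {}
    for i, subj in enumerate(dataset.subjects):
        mode, ok = state.eb_mode(i, rng=eb_rng)
        if not ok:
            warn_list.append(f"EB optimisation failed for {subj.subject_id}; "
                             "population parameters substituted")
            mode = np.zeros(state.q)
        params = PKParameters.from_array(state._params_for(i, mode))
        eta = dict(zip(state.re_names, map(float, mode)))
        eb_params[subj.subject_id] = IndividualParameters(subj.subject_id, params, eta)

    return FitResult(model=model, rse_percent=rse, minus2ll=float(minus2ll),
                     aic=float(crit["AIC"]), bic=float(crit["BIC"]), k_free=k,
                     n_subjects=state.n, bic_convention="n = subjects",
                     trace=pd.DataFrame(state.trace_rows), eb_params=eb_params,
                     converged=converged, warnings=warn_list,
                     _state=state, _dataset=dataset)


def empirical_bayes(fit: FitResult, subject_id: "str | Subject",
                    grid_step: float = 0.1
                    ) -> tuple[IndividualParameters, "pk.ConcentrationProfile"]:
    """MAP individual parameters and the posterior concentration profile.

    The profile is evaluated on a ``grid_step``-spaced grid (default 0.1 h)
    from time 0 to the end of the subject's last dosing day (at least 24 h).
    A ``Subject`` with no observations may be passed directly; it shrinks
    fully to the covariate-scaled population prediction (eta = 0).
    """
    if isinstance(subject_id, Subject):
        subj = subject_id
        if subj.observations and subj.subject_id in fit.eb_params:
            ip = fit.eb_params[subj.subject_id]
        else:
            from .population import individual_params
            params = individual_params(fit.model, subj.weight, {})
            ip = IndividualParameters(subj.subject_id, params, {})
    else:
        subj = fit._dataset.subject(subject_id)
        ip = fit.eb_params[subject_id]
    last = max((e.start_time for e in subj.regimen.events), default=0.0)
    horizon = max(24.0, last + 24.0)
    grid = np.arange(0.0, horizon + grid_step / 2, grid_step)
    profile = pk.solve_profile(ip.params, subj.regimen, grid)
    return ip, profile


def gof_diagnostics(fit: FitResult, dataset: Dataset, n_pop_draws: int = 200
                    ) -> DiagnosticsReport:
    """Observed-vs-predicted pairs, per-matrix R² and PWRES.

    PWRES = (obs - population prediction)/population SD, with the population
    mean and SD obtained by Monte-Carlo over the fitted random-effect
    distribution plus the residual-error variance.  R² compares observed and
    EB-predicted concentrations per matrix; a matrix with no spread in the
    observations reports R² as missing.
    """
    state = fit._state
    rng = np.random.default_rng(state.config.seed + 4)
    chol = np.linalg.cholesky(state.omega_matrix() + 1e-12 * np.eye(state.q))
    rows = []
    for i, subj in enumerate(dataset.subjects):
        eb = fit.eb_params[subj.subject_id]
        eta_eb = np.array([eb.eta[n] for n in state.re_names])
        f_eb = state.predict_subject_batch(i, eta_eb[None, :])[0]
        etas = rng.standard_normal((n_pop_draws, state.q)) @ chol.T
        sims = state.predict_subject_batch(i, etas)
        pop_mean = sims.mean(axis=0)
        mats = state.groups[state.subject_group[i]].mats
        a, b = state.err_a[mats], state.err_b[mats]
        resid_var = a ** 2 + b ** 2 * (sims ** 2).mean(axis=0)
        pop_sd = np.sqrt(sims.var(axis=0) + resid_var)
        for j, o in enumerate(subj.observations):
            pw = ((o.value - pop_mean[j]) / pop_sd[j]
                  if (not o.blq and pop_sd[j] > 0) else np.nan)
            rows.append({"ID": subj.subject_id, "TIME": o.time, "MATRIX": o.matrix,
                         "DV": o.value if not o.blq else np.nan, "BLQ": int(o.blq),
                         "EB_PRED": f_eb[j], "POP_PRED": pop_mean[j],
                         "PWRES": pw})
    df = pd.DataFrame(rows)
    r2 = {}
    for m in ("plasma", "cortex", "hippocampus"):
        sub = df[(df["MATRIX"] == m) & (df["BLQ"] == 0)]
        if len(sub) < 2 or sub["DV"].std(ddof=0) == 0:
            r2[m] = None
            continue
        r = np.corrcoef(sub["DV"], sub["EB_PRED"])[0, 1]
        r2[m] = float(r ** 2)
    return DiagnosticsReport(obs_vs_pred=df, r_squared=r2)
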