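"""Stochastic-approximation EM engine for the nonlinear mixed-effects model.

Latent variables are the per-subject log-parameter vectors
``phi_i = mu + c_i + eta_i`` (``c_i`` the known allometric covariate offset,
``eta_i ~ N(0, Omega)``).  Each iteration runs a few Metropolis-Hastings
transitions per subject and chain — one independent proposal from the prior,
one prior-shaped joint random walk and one componentwise random-walk sweep,
with step sizes adapted toward a target acceptance rate during the
exploratory phase — then updates the sufficient statistics with the
stochastic-approximation step size (1 during exploration, 1/(k - K1) during
smoothing) and solves the M-step: closed form for mu and Omega, a small
numeric minimisation for the combined residual-error parameters.  BLQ
records contribute the interval-censored likelihood in every MH acceptance
ratio and are imputed from the truncated Gaussian when accumulating residual
statistics.

The conditional model (three-compartment profile at the observation times)
is evaluated through a batched eigendecomposition: subjects sharing a design
group — identical dose times and sampling times — are stacked so one numpy
call serves the whole group, with a per-subject matrix-exponential fallback
for degenerate spectra.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import expm
from scipy.optimize import minimize
from scipy.special import gammaln, log_ndtr, ndtr, ndtri

from .pk import PARAM_NAMES, AllometricBetas, _breakpoints
from .population import ConfigurationError

LOG2PI = math.log(2 * math.pi)
_MAT_CODE = {"plasma": 0, "cortex": 1, "hippocampus": 2}


@dataclass
class SAEMConfig:
    """Tuning of the SAEM run; the seed is mandatory for reproducibility."""

    seed: int
    n_explore: int = 300
    n_smooth: int = 200
    chains: int = 5
    estimate_correlation: bool = True
    error_forms: dict = field(default_factory=lambda: {
        "plasma": "combined", "cortex": "combined", "hippocampus": "combined"})
    rw_target: float = 0.35
    n_importance: int = 300        # samples per subject for the -2LL estimate
    n_importance_rse: int = 100
    compute_rse: bool = False
    anneal_factor: float = 0.95    # max per-iteration shrink of variances (exploratory)


class DesignGroup:
    """Subjects sharing dose times, infusion windows and observation times.

    Holds the shared segment structure once and the per-subject data as
    stacked arrays, so the conditional model and likelihood evaluate for the
    whole group (or for many parameter draws of one subject) in a handful of
    vectorized numpy calls.
    """

    def __init__(self, key, subjects, betas: AllometricBetas):
        self.key = key
        self.sids = [s.subject_id for s in subjects]
        g = len(subjects)
        obs0 = subjects[0].observations
        self.times = np.array([o.time for o in obs0])
        self.mats = np.array([_MAT_CODE[o.matrix] for o in obs0])
        self.n_obs = len(obs0)

        self.y = np.full((g, self.n_obs), np.nan)
        self.blq = np.zeros((g, self.n_obs), dtype=bool)
        self.loq = np.zeros((g, self.n_obs))
        self.cov_offsets = np.zeros((g, len(PARAM_NAMES)))
        i_kel = PARAM_NAMES.index("kel")
        i_vc = PARAM_NAMES.index("V_central")
        for i, s in enumerate(subjects):
            for j, o in enumerate(s.observations):
                self.blq[i, j] = o.blq
                self.loq[i, j] = o.loq
                if not o.blq:
                    self.y[i, j] = o.value
            lw = math.log(s.weight / betas.ref_weight)
            self.cov_offsets[i, i_kel] = betas.beta_kel * lw
            self.cov_offsets[i, i_vc] = betas.beta_V_central * lw

        events0 = subjects[0].regimen.events
        t_end = max(float(self.times.max(initial=0.0)),
                    max((e.end_time for e in events0), default=0.0))
        self.bounds, rates0 = _breakpoints(events0, t_end)
        self.n_seg = len(self.bounds) - 1
        self.rates = np.zeros((g, self.n_seg))
        self.bolus_times = [e.start_time for e in events0 if e.duration == 0]
        self.bolus_amounts = np.zeros((g, len(self.bolus_times)))
        for i, s in enumerate(subjects):
            _, r = _breakpoints(s.regimen.events, t_end)
            self.rates[i] = r
            self.bolus_amounts[i] = [e.amount for e in s.regimen.events
                                     if e.duration == 0]
        self.seg_idx, self.seg_dt = [], []
        for lo, hi in zip(self.bounds[:-1], self.bounds[1:]):
            idx = np.nonzero((self.times > lo) & (self.times <= hi))[0]
            self.seg_idx.append(idx)
            self.seg_dt.append(self.times[idx] - lo)
        self.zero_idx = np.nonzero(self.times == 0.0)[0]

    @staticmethod
    def signature(subject):
        obs = tuple((round(o.time, 9), o.matrix) for o in subject.observations)
        doses = tuple((round(e.start_time, 9), round(e.duration, 9))
                      for e in subject.regimen.events)
        return (obs, doses)

    # -- batched model evaluation ------------------------------------------
    def predict(self, P: np.ndarray, rates: np.ndarray | None = None,
                bolus_amounts: np.ndarray | None = None) -> np.ndarray:
        """Concentrations (B, n_obs) for stacked natural parameters P (B, 8)."""
        rates = self.rates if rates is None else rates
        bolus_amounts = self.bolus_amounts if bolus_amounts is None else bolus_amounts
        B = P.shape[0]
        kel, k12, k21, k13, k31 = (P[:, i] for i in range(5))
        K = np.zeros((B, 3, 3))
        K[:, 0, 0] = -(kel + k12 + k13)
        K[:, 0, 1] = k21
        K[:, 0, 2] = k31
        K[:, 1, 0] = k12
        K[:, 1, 1] = -k21
        K[:, 2, 0] = k13
        K[:, 2, 2] = -k31
        with np.errstate(all="ignore"):
            lam, V = np.linalg.eig(K)
            lam, V = np.real(lam), np.real(V)
            try:
                Vinv = np.linalg.inv(V)
            except np.linalg.LinAlgError:
                return self._predict_fallback(P, K, rates, bolus_amounts)
        conc = np.empty((B, self.n_obs))
        state = np.zeros((B, 3))
        rng3 = np.arange(3)
        for s in range(self.n_seg):
            lo, hi = self.bounds[s], self.bounds[s + 1]
            for bi, t0 in enumerate(self.bolus_times):
                if t0 == lo:
                    state[:, 0] += bolus_amounts[:, bi]
            r = rates[:, s]
            if np.any(r != 0.0):
                rhs = np.zeros((B, 3, 1))
                rhs[:, 0, 0] = -r
                try:
                    part = np.linalg.solve(K, rhs)[:, :, 0]
                except np.linalg.LinAlgError:
                    return self._predict_fallback(P, K, rates, bolus_amounts)
            else:
                part = np.zeros((B, 3))
            c0 = np.einsum("bij,bj->bi", Vinv, state - part)
            idx = self.seg_idx[s]
            if len(idx):
                E = np.exp(lam[:, :, None] * self.seg_dt[s][None, None, :])
                amt = np.einsum("bij,bjt->bit", V, c0[:, :, None] * E) \
                    + part[:, :, None]
                m = self.mats[idx]
                conc[:, idx] = amt[:, m, np.arange(len(idx))] / P[:, 5 + m]
            state = np.einsum("bij,bj->bi", V, c0 * np.exp(lam * (hi - lo))) + part
        if len(self.zero_idx):
            conc[:, self.zero_idx] = 0.0
        conc = np.maximum(conc, 0.0)
        bad = ~np.isfinite(conc).all(axis=1)
        if bad.any():
            conc[bad] = self._predict_fallback(P[bad], K[bad], rates[bad],
                                               bolus_amounts[bad])
        return conc

    def _predict_fallback(self, P, K, rates, bolus_amounts) -> np.ndarray:
        """Per-row augmented matrix exponential; exact for any spectrum."""
        B = P.shape[0]
        conc = np.zeros((B, self.n_obs))
        for b in range(B):
            state = np.zeros(3)
            amounts = np.zeros((self.n_obs, 3))
            for s in range(self.n_seg):
                lo, hi = self.bounds[s], self.bounds[s + 1]
                for bi, t0 in enumerate(self.bolus_times):
                    if t0 == lo:
                        state[0] += bolus_amounts[b, bi]
                M = np.zeros((4, 4))
                M[:3, :3] = K[b]
                M[0, 3] = rates[b, s]
                for j, dt in zip(self.seg_idx[s], self.seg_dt[s]):
                    amounts[j] = (expm(M * dt) @ np.append(state, 1.0))[:3]
                state = (expm(M * (hi - lo)) @ np.append(state, 1.0))[:3]
            amounts[self.zero_idx] = 0.0
            conc[b] = amounts[np.arange(self.n_obs), self.mats] / P[b, 5 + self.mats]
        return np.maximum(np.nan_to_num(conc, nan=0.0, posinf=0.0), 0.0)

    def loglik(self, f: np.ndarray, err_a: np.ndarray, err_b: np.ndarray,
               y=None, blq=None, loq=None) -> np.ndarray:
        """Observed-data log-likelihood per row of f (B, n_obs)."""
        y = self.y if y is None else y
        blq = self.blq if blq is None else blq
        loq = self.loq if loq is None else loq
        a, b = err_a[self.mats], err_b[self.mats]
        sd = np.sqrt(a * a + (b * f) ** 2)
        with np.errstate(all="ignore"):
            z = (np.nan_to_num(y) - f) / sd
            gauss = -0.5 * z * z - np.log(sd) - 0.5 * LOG2PI
            hi = log_ndtr((loq - f) / sd)
            lo = log_ndtr(-f / sd)
            cens = hi + np.log1p(-np.exp(np.minimum(lo - hi, -1e-12)))
            terms = np.where(blq, cens, gauss)
        out = terms.sum(axis=1)
        return np.where(np.isfinite(out), out, -np.inf)


def _build_omega(sds, corr, corr_pair):
    om = np.diag(np.asarray(sds, dtype=float) ** 2)
    if corr_pair is not None and corr != 0.0:
        i, j = corr_pair
        om[i, j] = om[j, i] = corr * sds[i] * sds[j]
    return om


def _error_mstep(form, f2_bar, r2_bar, a0, b0):
    """Minimise the complete-data -2LL profile in (a, b) for one matrix."""
    if len(f2_bar) == 0:
        return a0, b0
    if form == "additive":
        return float(np.sqrt(np.mean(r2_bar))), 0.0
    if form == "proportional":
        return 0.0, float(np.sqrt(np.mean(r2_bar / np.maximum(f2_bar, 1e-12))))

    def nll(x):
        a2, b2 = np.exp(2 * x)
        v = a2 + b2 * f2_bar
        return float(np.sum(np.log(v) + r2_bar / v))

    x0 = np.log(np.maximum([a0, b0], 1e-6))
    res = minimize(nll, x0, method="Nelder-Mead",
                   options={"xatol": 1e-4, "fatol": 1e-8, "maxiter": 200})
    a, b = np.exp(res.x)
    return float(a), float(b)


class SAEMState:
    """Mutable state of a SAEM run over one dataset."""

    def __init__(self, dataset, spec, config: SAEMConfig):
        self.config = config
        self.rng = np.random.default_rng(config.seed)
        self.n = len(dataset.subjects)
        if self.n == 0:
            raise ConfigurationError("empty dataset")
        if any(len(s.observations) == 0 for s in dataset.subjects):
            raise ConfigurationError("every subject needs at least one observation")

        self.free = [p for p in PARAM_NAMES if p not in spec.fixed_mask]
        if not self.free:
            raise ConfigurationError("all parameters fixed: nothing to estimate")
        for p in self.free:
            if spec.omega.get(p, 0.0) <= 0:
                raise ConfigurationError(
                    f"estimated parameter {p!r} needs a positive initial omega")
        self.re_names = tuple(self.free)       # estimated <=> carries a random effect
        self.re_idx = np.array([PARAM_NAMES.index(p) for p in self.re_names])
        self.q = len(self.re_names)
        if ("kel" in self.re_names and "V_hippocampus" in self.re_names
                and config.estimate_correlation):
            self.corr_pair = (self.re_names.index("kel"),
                              self.re_names.index("V_hippocampus"))
        else:
            self.corr_pair = None

        # group subjects by design signature, preserving a global subject order
        sig_map: dict = {}
        for i, s in enumerate(dataset.subjects):
            sig_map.setdefault(DesignGroup.signature(s), []).append(i)
        self.groups: list[DesignGroup] = []
        self.group_rows: list[np.ndarray] = []   # global subject index per group row
        for sig, idxs in sig_map.items():
            self.groups.append(DesignGroup(sig, [dataset.subjects[i] for i in idxs],
                                           spec.betas))
            self.group_rows.append(np.array(idxs))
        self.subject_group = np.empty(self.n, dtype=int)
        self.subject_row = np.empty(self.n, dtype=int)
        for gi, rows in enumerate(self.group_rows):
            for r, i in enumerate(rows):
                self.subject_group[i] = gi
                self.subject_row[i] = r
        self.cov_offsets = np.zeros((self.n, len(PARAM_NAMES)))
        for gi, rows in enumerate(self.group_rows):
            self.cov_offsets[rows] = self.groups[gi].cov_offsets
        self.n_obs_per_subject = np.array(
            [self.groups[self.subject_group[i]].n_obs for i in range(self.n)])

        self.mu_full = np.log(spec.theta.as_array())   # 8-vector, fixed comps frozen
        self.omega_sd = np.array([spec.omega[p] for p in self.re_names])
        self.corr = spec.re_correlation if self.corr_pair is not None else 0.0
        mats = ("plasma", "cortex", "hippocampus")
        self.err_a = np.array([spec.error[m].a for m in mats])
        self.err_b = np.array([spec.error[m].b for m in mats])
        self.err_forms = [config.error_forms.get(m, "combined") for m in mats]

        nc = config.chains
        self.eta = np.zeros((nc, self.n, self.q))
        self.ll = np.full((nc, self.n), -np.inf)
        self.F = [np.zeros((nc, g.n_obs * len(rows))).reshape(nc, len(rows), g.n_obs)
                  for g, rows in zip(self.groups, self.group_rows)]
        for c in range(nc):
            self._refresh_chain(c)
        self.rw_scale = np.full(self.n, 0.4)
        self.cw_scale = np.full((self.n, self.q), 0.4)

        # stochastic-approximation statistics
        self.T1 = np.zeros(self.q)
        self.T2 = np.zeros((self.q, self.q))
        self.F2 = [np.zeros((len(rows), g.n_obs))
                   for g, rows in zip(self.groups, self.group_rows)]
        self.R2 = [np.zeros((len(rows), g.n_obs))
                   for g, rows in zip(self.groups, self.group_rows)]
        self.trace_rows = []

    # -- parameter plumbing -------------------------------------------------
    def _params_matrix(self, eta: np.ndarray, rows: np.ndarray) -> np.ndarray:
        """Natural parameters (len(rows), 8) for eta (len(rows), q)."""
        logp = self.mu_full[None, :] + self.cov_offsets[rows]
        logp = logp.copy()
        logp[:, self.re_idx] += eta
        return np.exp(np.clip(logp, -60.0, 60.0))

    def _params_for(self, i: int, eta_vec: np.ndarray) -> np.ndarray:
        return self._params_matrix(eta_vec[None, :], np.array([i]))[0]

    def omega_matrix(self) -> np.ndarray:
        return _build_omega(self.omega_sd, self.corr, self.corr_pair)

    def _eval_all(self, eta: np.ndarray) -> tuple[np.ndarray, list[np.ndarray]]:
        """Log-likelihood (n,) and per-group predictions for eta (n, q)."""
        ll = np.empty(self.n)
        fs = []
        for g, rows in zip(self.groups, self.group_rows):
            P = self._params_matrix(eta[rows], rows)
            f = g.predict(P)
            fs.append(f)
            ll[rows] = g.loglik(f, self.err_a, self.err_b)
        return ll, fs

    def _refresh_chain(self, c: int, repredict: bool = True) -> None:
        """Re-sync cached likelihoods.  After the M-step phi is unchanged (the
        stored etas are shifted), so only the error parameters moved and the
        cached predictions can be reused."""
        if repredict:
            ll, fs = self._eval_all(self.eta[c])
            self.ll[c] = ll
            for gi, f in enumerate(fs):
                self.F[gi][c] = f
        else:
            for gi, (g, rows) in enumerate(zip(self.groups, self.group_rows)):
                self.ll[c][rows] = g.loglik(self.F[gi][c], self.err_a, self.err_b)

    def subject_loglik(self, i: int, eta_vec: np.ndarray) -> tuple[float, np.ndarray]:
        g = self.groups[self.subject_group[i]]
        r = self.subject_row[i]
        P = self._params_for(i, eta_vec)[None, :]
        f = g.predict(P, rates=g.rates[r:r + 1], bolus_amounts=g.bolus_amounts[r:r + 1])
        ll = g.loglik(f, self.err_a, self.err_b, y=g.y[r:r + 1],
                      blq=g.blq[r:r + 1], loq=g.loq[r:r + 1])
        return float(ll[0]), f[0]

    def predict_subject_batch(self, i: int, etas: np.ndarray) -> np.ndarray:
        """Predicted concentrations (B, n_obs) for many eta draws of subject i."""
        B = etas.shape[0]
        g = self.groups[self.subject_group[i]]
        r = self.subject_row[i]
        logp = self.mu_full[None, :] + self.cov_offsets[i][None, :]
        logp = np.repeat(logp, B, axis=0)
        logp[:, self.re_idx] += etas
        P = np.exp(np.clip(logp, -60.0, 60.0))
        return g.predict(P, rates=np.repeat(g.rates[r:r + 1], B, axis=0),
                         bolus_amounts=np.repeat(g.bolus_amounts[r:r + 1], B, axis=0))

    def subject_loglik_batch(self, i: int, etas: np.ndarray) -> np.ndarray:
        """Log-likelihoods for many eta draws (B, q) of one subject."""
        g = self.groups[self.subject_group[i]]
        r = self.subject_row[i]
        f = self.predict_subject_batch(i, etas)
        return g.loglik(f, self.err_a, self.err_b, y=g.y[r:r + 1],
                        blq=g.blq[r:r + 1], loq=g.loq[r:r + 1])

    # -- MCMC ---------------------------------------------------------------
    def _accept(self, c, accept, eta_new, ll_new, fs_new) -> None:
        self.eta[c][accept] = eta_new[accept]
        self.ll[c][accept] = ll_new[accept]
        for gi, rows in enumerate(self.group_rows):
            sel = accept[rows]
            if sel.any():
                self.F[gi][c][sel] = fs_new[gi][sel]

    def _mh_sweep(self, chol, om_inv, adapt: bool) -> None:
        nc = self.config.chains
        acc_rw = np.zeros(self.n)
        acc_cw = np.zeros((self.n, self.q))
        for c in range(nc):
            # kernel 1: independent proposal from the prior (prior cancels)
            prop = self.rng.standard_normal((self.n, self.q)) @ chol.T
            ll_new, fs_new = self._eval_all(prop)
            accept = np.log(self.rng.random(self.n)) < ll_new - self.ll[c]
            self._accept(c, accept, prop, ll_new, fs_new)

            # kernel 2: prior-shaped joint random walk
            step = self.rw_scale[:, None] * (self.rng.standard_normal((self.n, self.q))
                                             @ chol.T)
            prop = self.eta[c] + step
            ll_new, fs_new = self._eval_all(prop)
            dprior = -0.5 * (np.einsum("nq,qk,nk->n", prop, om_inv, prop)
                             - np.einsum("nq,qk,nk->n", self.eta[c], om_inv,
                                         self.eta[c]))
            accept = np.log(self.rng.random(self.n)) < ll_new - self.ll[c] + dprior
            acc_rw += accept
            self._accept(c, accept, prop, ll_new, fs_new)

            # kernel 3: componentwise random walk
            for j in range(self.q):
                prop = self.eta[c].copy()
                prop[:, j] += (self.cw_scale[:, j] * self.omega_sd[j]
                               * self.rng.standard_normal(self.n))
                ll_new, fs_new = self._eval_all(prop)
                dprior = -0.5 * (np.einsum("nq,qk,nk->n", prop, om_inv, prop)
                                 - np.einsum("nq,qk,nk->n", self.eta[c], om_inv,
                                             self.eta[c]))
                accept = np.log(self.rng.random(self.n)) < ll_new - self.ll[c] + dprior
                acc_cw[:, j] += accept
                self._accept(c, accept, prop, ll_new, fs_new)
        if adapt:
            tgt = self.config.rw_target
            self.rw_scale *= np.exp(0.25 * (acc_rw / nc - tgt))
            np.clip(self.rw_scale, 1e-3, 10.0, out=self.rw_scale)
            self.cw_scale *= np.exp(0.25 * (acc_cw / nc - tgt))
            np.clip(self.cw_scale, 1e-3, 10.0, out=self.cw_scale)

    def _latent_residual_stats(self, gamma: float) -> None:
        """SA-update per-observation chain-averaged f² and squared residuals,
        imputing BLQ values from the truncated Gaussian."""
        nc = self.config.chains
        for gi, g in enumerate(self.groups):
            f = self.F[gi]                      # (nc, rows, n_obs)
            a, b = self.err_a[g.mats], self.err_b[g.mats]
            sd = np.sqrt(a * a + (b * f) ** 2)
            y = np.broadcast_to(g.y, f.shape).copy()
            m = np.broadcast_to(g.blq, f.shape)
            if m.any():
                fm, sdm = f[m], sd[m]
                loqm = np.broadcast_to(g.loq, f.shape)[m]
                ulo = ndtr(-fm / sdm)
                uhi = ndtr((loqm - fm) / sdm)
                u = ulo + (uhi - ulo) * self.rng.random(m.sum())
                y[m] = fm + sdm * ndtri(np.clip(u, 1e-12, 1 - 1e-12))
            f2 = (f * f).mean(axis=0)
            r2 = ((y - f) ** 2).mean(axis=0)
            self.F2[gi] += gamma * (f2 - self.F2[gi])
            self.R2[gi] += gamma * (r2 - self.R2[gi])

    # -- one SAEM iteration -------------------------------------------------
    def iterate(self, k: int) -> None:
        cfg = self.config
        explore = k < cfg.n_explore
        gamma = 1.0 if explore else 1.0 / (k - cfg.n_explore + 1)

        om = self.omega_matrix()
        chol = np.linalg.cholesky(om + 1e-12 * np.eye(self.q))
        om_inv = np.linalg.inv(om)
        self._mh_sweep(chol, om_inv, adapt=explore)

        mu_re = self.mu_full[self.re_idx]
        phi_c = self.eta.mean(axis=0) + mu_re          # (n, q) chain-averaged
        s1 = phi_c.mean(axis=0)
        s2 = np.zeros((self.q, self.q))
        for c in range(cfg.chains):
            pc = self.eta[c] + mu_re
            s2 += pc.T @ pc / (self.n * cfg.chains)
        self.T1 += gamma * (s1 - self.T1)
        self.T2 += gamma * (s2 - self.T2)
        self._latent_residual_stats(gamma)

        # M-step: mu and Omega in closed form
        mu_new = self.mu_full.copy()
        mu_new[self.re_idx] = self.T1
        omega_full = self.T2 - np.outer(self.T1, self.T1)
        var = np.clip(np.diag(omega_full), 1e-8, None)
        if explore:  # annealing: variances shrink at most 5% per iteration
            var = np.maximum(var, cfg.anneal_factor * self.omega_sd ** 2)
        sd_new = np.sqrt(var)
        if self.corr_pair is not None:
            i, j = self.corr_pair
            denom = math.sqrt(omega_full[i, i] * omega_full[j, j])
            corr_new = float(np.clip(omega_full[i, j] / max(denom, 1e-12),
                                     -0.98, 0.98))
        else:
            corr_new = 0.0

        a_new, b_new = self.err_a.copy(), self.err_b.copy()
        for m in range(3):
            if self.err_forms[m] == "fixed":
                continue
            f2 = np.concatenate([F2[:, g.mats == m].ravel()
                                 for g, F2 in zip(self.groups, self.F2)])
            r2 = np.concatenate([R2[:, g.mats == m].ravel()
                                 for g, R2 in zip(self.groups, self.R2)])
            if len(f2):
                a, b = _error_mstep(self.err_forms[m], f2, r2,
                                    self.err_a[m], self.err_b[m])
                if explore:
                    # trust region: early residuals reflect the bad initial
                    # guess, so bound the per-iteration move of the error
                    # parameters in both directions
                    lo, hi = cfg.anneal_factor, 1.0 / cfg.anneal_factor
                    a = float(np.clip(a, lo * self.err_a[m], hi * self.err_a[m]))
                    b = float(np.clip(b, lo * self.err_b[m], hi * self.err_b[m]))
                a_new[m], b_new[m] = a, b

        # shift stored etas so phi is continuous across the mu update
        dmu = mu_new[self.re_idx] - self.mu_full[self.re_idx]
        self.eta -= dmu[None, None, :]
        self.mu_full = mu_new
        self.omega_sd = sd_new
        self.corr = corr_new
        self.err_a, self.err_b = a_new, b_new
        for c in range(self.config.chains):
            self._refresh_chain(c, repredict=False)

        row = {"iteration": k, "phase": "explore" if explore else "smooth"}
        for p, v in zip(PARAM_NAMES, np.exp(self.mu_full)):
            row[p] = v
        for p, s in zip(self.re_names, self.omega_sd):
            row[f"omega_{p}"] = s
        row["corr_kel_V_hippocampus"] = self.corr
        for m, name in enumerate(("plasma", "cortex", "hippocampus")):
            row[f"a_{name}"] = self.err_a[m]
            row[f"b_{name}"] = self.err_b[m]
        self.trace_rows.append(row)

    def run(self) -> None:
        for k in range(self.config.n_explore + self.config.n_smooth):
            self.iterate(k)

    # -- empirical Bayes and marginal likelihood ----------------------------
    def _neg_post_stencil(self, i, x, om_inv, h=1e-3):
        """Value, gradient and Hessian of the negative log posterior at x,
        from one batched central-difference stencil."""
        q = self.q
        eye = np.eye(q)
        pts = [x]
        for a in range(q):
            pts += [x + h * eye[a], x - h * eye[a]]
        cross = [(a, b) for a in range(q) for b in range(a + 1, q)]
        pts += [x + h * (eye[a] + eye[b]) for a, b in cross]
        pts = np.array(pts)
        ll = self.subject_loglik_batch(i, pts)
        vals = -(ll - 0.5 * np.einsum("bq,qk,bk->b", pts, om_inv, pts))
        f0 = vals[0]
        fp = vals[1:2 * q + 1:2]
        fm = vals[2:2 * q + 1:2]
        grad = (fp - fm) / (2 * h)
        H = np.zeros((q, q))
        for a in range(q):
            H[a, a] = (fp[a] - 2 * f0 + fm[a]) / h ** 2
        for (a, b), v in zip(cross, vals[2 * q + 1:]):
            H[a, b] = H[b, a] = (v - fp[a] - fp[b] + f0) / h ** 2
        return f0, grad, H

    def _newton_map(self, i, x0, om_inv, max_iter=25, tol=1e-6):
        """Damped-Newton minimisation of the negative log posterior."""
        x = np.asarray(x0, dtype=float)
        f0, grad, H = self._neg_post_stencil(i, x, om_inv)
        if not np.isfinite(f0):
            return x, np.inf, False
        for _ in range(max_iter):
            if not np.all(np.isfinite(grad)) or not np.all(np.isfinite(H)):
                return x, f0, np.isfinite(f0)
            w, U = np.linalg.eigh((H + H.T) / 2)
            w = np.clip(w, 1e-6, None)
            step = -U @ ((U.T @ grad) / w)
            nrm = np.linalg.norm(step)
            if nrm > 5.0:  # trust region: eta moves of >5 log units are noise
                step *= 5.0 / nrm
            cands = np.clip(x + np.outer([1.0, 0.5, 0.25, 0.1, 0.02], step),
                            -15.0, 15.0)
            ll = self.subject_loglik_batch(i, cands)
            vals = -(ll - 0.5 * np.einsum("bq,qk,bk->b", cands, om_inv, cands))
            j = int(np.argmin(vals))
            if not np.isfinite(vals[j]) or vals[j] >= f0 - tol:
                return x, f0, True
            x, f0 = cands[j], vals[j]
            _, grad, H = self._neg_post_stencil(i, x, om_inv)
        return x, f0, True

    def eb_mode(self, i: int, n_starts: int = 3,
                rng: np.random.Generator | None = None) -> tuple[np.ndarray, bool]:
        """MAP of eta for subject i under the current population estimates.

        Multi-start damped Newton: the chain state, eta = 0, and ``n_starts``
        prior draws; the best posterior wins."""
        rng = rng or self.rng
        om = self.omega_matrix()
        om_inv = np.linalg.inv(om)
        chol = np.linalg.cholesky(om + 1e-12 * np.eye(self.q))
        warm = self.eta[:, i, :].mean(axis=0)
        starts = [warm, np.zeros(self.q)] + [chol @ rng.standard_normal(self.q)
                                             for _ in range(n_starts)]
        best, best_val, ok = np.zeros(self.q), np.inf, False
        for x0 in starts:
            x, val, success = self._newton_map(i, x0, om_inv)
            if success and val < best_val:
                best, best_val, ok = x, val, True
        return best, ok

    def _laplace_cov(self, i: int, mode: np.ndarray) -> np.ndarray:
        """Inverse Hessian of the negative log posterior, by batched central
        differences, eigenvalue-floored to stay positive definite."""
        om_inv = np.linalg.inv(self.omega_matrix())
        h = 1e-3
        q = self.q
        pts = [mode]
        eye = np.eye(q)
        for a in range(q):
            pts += [mode + h * eye[a], mode - h * eye[a]]
        for a in range(q):
            for b in range(a + 1, q):
                pts.append(mode + h * (eye[a] + eye[b]))
        pts = np.array(pts)
        ll = self.subject_loglik_batch(i, pts)
        vals = -(ll - 0.5 * np.einsum("bq,qk,bk->b", pts, om_inv, pts))
        f0 = vals[0]
        fp = vals[1:2 * q + 1:2]
        fm = vals[2:2 * q + 1:2]
        H = np.zeros((q, q))
        pos = 2 * q + 1
        for a in range(q):
            H[a, a] = (fp[a] - 2 * f0 + fm[a]) / h ** 2
        for a in range(q):
            for b in range(a + 1, q):
                H[a, b] = H[b, a] = (vals[pos] - fp[a] - fp[b] + f0) / h ** 2
                pos += 1
        w, U = np.linalg.eigh((H + H.T) / 2)
        w = np.clip(w, 1e-6, None)
        return U @ np.diag(1.0 / w) @ U.T

    def marginal_minus2ll(self, n_samples: int | None = None,
                          df: float = 4.0) -> float:
        """-2 log-likelihood by importance sampling with a t proposal centred
        at each subject's EB mode with Laplace covariance."""
        ns = n_samples or self.config.n_importance
        rng = np.random.default_rng(self.config.seed + 1)
        om = self.omega_matrix()
        om_inv = np.linalg.inv(om)
        _, logdet = np.linalg.slogdet(om)
        total = 0.0
        for i in range(self.n):
            mode, _ = self.eb_mode(i, n_starts=0, rng=rng)
            cov = self._laplace_cov(i, mode)
            L = np.linalg.cholesky(cov + 1e-10 * np.eye(self.q))
            zs = rng.standard_normal((ns, self.q))
            g = rng.chisquare(df, ns) / df
            etas = mode + (zs / np.sqrt(g)[:, None]) @ L.T
            _, logdet_c = np.linalg.slogdet(cov)
            delta = etas - mode
            sol = np.linalg.solve(cov, delta.T).T
            quad = np.sum(delta * sol, axis=1)
            logq = (gammaln((df + self.q) / 2) - gammaln(df / 2)
                    - 0.5 * self.q * np.log(df * np.pi) - 0.5 * logdet_c
                    - 0.5 * (df + self.q) * np.log1p(quad / df))
            ll = self.subject_loglik_batch(i, etas)
            prior = (-0.5 * np.einsum("bq,qk,bk->b", etas, om_inv, etas)
                     - 0.5 * logdet - 0.5 * self.q * LOG2PI)
            w = ll + prior - logq
            m = np.max(w)
            total += m + math.log(np.mean(np.exp(w - m)))
        return -2.0 * total

    def n_free_parameters(self) -> int:
        k = self.q                 # population medians
        k += self.q                # omega SDs
        if self.corr_pair is not None:
            k += 1
        for m in range(3):
            present = any((g.mats == m).any() for g in self.groups)
            if present:
                k += {"combined": 2, "additive": 1, "proportional": 1,
                      "fixed": 0}[self.err_forms[m]]
        return k
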