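"""End-to-end analysis pipeline with file-based stage handoff.

Stages mirror the study workflow: simulate (or load) the cohort, screen
outliers, fit the population model, derive empirical-Bayes exposures,
run the logistic TC₅₀ / rank-sum / Kaplan-Meier toxicodynamic analyses, and
assemble a run report.  Each stage reads its inputs from and writes its
outputs to the run directory, so stages can be re-run individually; a full
run under a fixed seed is byte-reproducible (timings are kept out of the
hashed outputs, in ``timings.log``).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, pk
from .data import Dataset, ValidationError, read_dataset, write_dataset
from .estimation import (SAEMConfig, exclude_outliers, fit_population,
                         gof_diagnostics)
from .pk import PKParameters
from .population import ErrorModel, PopulationModel, healthy_population
from .response import (ExposureRecord, exposure_summary, exposure_table,
                       fit_logistic_tc50, km_estimate, rank_sum_test)
from .simulate import DoseArm, OutcomeModel, StudyDesign, generate_cohort

_MATS = ("plasma", "cortex", "hippocampus")

#: deliberately generic starting values for estimation — displaced from the
#: final-model medians so the fit has real work to do; k12/k13 are the fixed
#: final-model constants (not estimable from terminal-only brain sampling)
DEFAULT_INITIAL = {
    "kel": 0.3, "k12": 0.00013, "k21": 0.3, "k13": 0.000015, "k31": 0.3,
    "V_central": 0.2, "V_cortex": 0.002, "V_hippocampus": 0.0008,
}
DEFAULT_INITIAL_OMEGA = {"kel": 0.3, "k21": 0.3, "k31": 0.3, "V_central": 0.3,
                         "V_cortex": 0.3, "V_hippocampus": 0.3}


@dataclass
class PipelineConfig:
    seed: int
    output_dir: str = "cefetox_run"
    dataset_path: str | None = None       # load instead of simulating
    design: dict = field(default_factory=dict)
    outcome: dict = field(default_factory=dict)
    population: dict = field(default_factory=dict)   # generator overrides
    estimation: dict = field(default_factory=dict)
    exposure: dict = field(default_factory=lambda: {"auc_grid_step": 0.1,
                                                    "cmax_grid_step": 0.1})
    km_cutoff: float | None = None        # default: fitted plasma AUC TC50
    outlier_z: float = 3.0
    plots: bool = False

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config key(s): {sorted(unknown)}")
        if "seed" not in raw:
            raise ValidationError("config must set an integer 'seed'")
        if "estimation" not in raw:
            raise ValidationError("config must contain an 'estimation' block "
                                  "(may be empty only explicitly: 'estimation: {}')")
        cfg = cls(**raw)
        for step in cfg.exposure.values():
            if step <= 0:
                raise ValidationError("exposure grid steps must be > 0")
        return cfg

    def config_hash(self) -> str:
        """Hash of the scientific configuration (paths excluded, so the same
        analysis in two directories reports the same hash)."""
        payload = dataclasses.asdict(self)
        payload.pop("output_dir")
        blob = json.dumps(payload, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class RunReport:
    version: str
    config_hash: str
    seed: int
    manifest: list[str]
    warnings: list[str]
    stage_timings: dict[str, float]


def _design_from(cfg: PipelineConfig) -> StudyDesign:
    d = dict(cfg.design)
    for key in ("single_dose_arm", "daily_dose_arm"):
        if key in d:
            d[key] = DoseArm(**d[key])
    for key in ("plasma_offsets", "sacrifice_schedule"):
        if key in d:
            d[key] = tuple(tuple(x) if isinstance(x, list) else x for x in d[key])
    return StudyDesign(**d)


def _population_from(cfg: PipelineConfig) -> PopulationModel:
    pop = healthy_population()
    over = dict(cfg.population)
    if "theta" in over:
        pop.theta = PKParameters(**{**dataclasses.asdict(pop.theta), **over["theta"]})
    if "omega" in over:
        pop.omega.update(over["omega"])
    if "re_correlation" in over:
        pop.re_correlation = over["re_correlation"]
    if "error" in over:
        for m, ab in over["error"].items():
            pop.error[m] = ErrorModel(**ab)
    return pop


def _spec_from(cfg: PipelineConfig) -> tuple[PopulationModel, SAEMConfig]:
    est = dict(cfg.estimation)
    initial = {**DEFAULT_INITIAL, **est.pop("initial", {})}
    omega0 = {**DEFAULT_INITIAL_OMEGA, **est.pop("initial_omega", {})}
    fixed = tuple(est.pop("fixed_mask", ("k12", "k13")))
    spec = PopulationModel(theta=PKParameters(**initial), omega=omega0,
                           re_correlation=0.0,
                           error={m: ErrorModel(1.0, 0.3) for m in _MATS},
                           fixed_mask=fixed)
    saem = SAEMConfig(seed=cfg.seed + 1, **est)
    return spec, saem


class PipelineRun:
    """Stateful driver: each stage persists its outputs under ``out``."""

    def __init__(self, cfg: PipelineConfig):
        self.cfg = cfg
        self.out = Path(cfg.output_dir)
        self.out.mkdir(parents=True, exist_ok=True)
        self.timings: dict[str, float] = {}
        self.warnings: list[str] = []
        self._fit = None
        self._dataset = None

    def _track(self, name):
        run = self

        class _T:
            def __enter__(self):
                self.t0 = time.perf_counter()

            def __exit__(self, *exc):
                run.timings[name] = time.perf_counter() - self.t0

        return _T()

    # -- stages ------------------------------------------------------------
    def simulate(self) -> Dataset:
        with self._track("simulate"):
            if self.cfg.dataset_path:
                ds = read_dataset(self.cfg.dataset_path)
            else:
                cohort = generate_cohort(design=_design_from(self.cfg),
                                         pop=_population_from(self.cfg),
                                         outcome=OutcomeModel(**self.cfg.outcome),
                                         seed=self.cfg.seed)
                ds = cohort.dataset
                (self.out / "ground_truth.json").write_text(
                    cohort.ground_truth_json())
            write_dataset(ds, self.out / "dataset.csv")
        return ds

    def screen(self) -> Dataset:
        with self._track("exclude_outliers"):
            ds = read_dataset(self.out / "dataset.csv")
            ds, report = exclude_outliers(ds, self.cfg.outlier_z)
            report.to_csv(self.out / "outliers.csv", index=False)
            write_dataset(ds, self.out / "dataset_filtered.csv")
            self._dataset = ds
        return ds

    def fit(self) -> None:
        with self._track("fit"):
            ds = self._dataset or read_dataset(self.out / "dataset_filtered.csv")
            spec, saem = _spec_from(self.cfg)
            fit = fit_population(ds, spec, saem)
            self._fit, self._dataset = fit, ds
            self.warnings.extend(fit.warnings)
            fit.trace.to_csv(self.out / "fit_trace.csv", index=False)
            summary = {
                "theta": dataclasses.asdict(fit.model.theta),
                "omega": fit.model.omega,
                "re_correlation": fit.model.re_correlation,
                "error": {m: dataclasses.asdict(e)
                          for m, e in fit.model.error.items()},
                "rse_percent": fit.rse_percent,
                "minus2LL": fit.minus2ll, "AIC": fit.aic, "BIC": fit.bic,
                "k_free": fit.k_free, "n_subjects": fit.n_subjects,
                "bic_convention": fit.bic_convention,
                "converged": fit.converged,
                "eb_params": {sid: dataclasses.asdict(ip.params)
                              for sid, ip in fit.eb_params.items()},
                "eb_eta": {sid: ip.eta for sid, ip in fit.eb_params.items()},
            }
            (self.out / "fit.json").write_text(
                json.dumps(summary, indent=1, sort_keys=True))
            diag = gof_diagnostics(fit, ds)
            diag.obs_vs_pred.to_csv(self.out / "diagnostics.csv", index=False)
            (self.out / "gof_r2.json").write_text(json.dumps(
                diag.r_squared, indent=1, sort_keys=True))

    def _exposure_records(self) -> list[ExposureRecord]:
        ds = self._dataset or read_dataset(self.out / "dataset_filtered.csv")
        fitd = json.loads((self.out / "fit.json").read_text())
        records = []
        for subj in ds.subjects:
            if subj.stage is None or subj.subject_id not in fitd["eb_params"]:
                continue
            params = PKParameters(**fitd["eb_params"][subj.subject_id])
            last = max((e.start_time for e in subj.regimen.events), default=0.0)
            grid = np.arange(0.0, max(24.0, last + 24.0) + 0.05, 0.1)
            profile = pk.solve_profile(params, subj.regimen, grid)
            metrics = pk.exposure_metrics(
                profile, self.cfg.exposure["auc_grid_step"],
                self.cfg.exposure["cmax_grid_step"])
            event = subj.stage > 1
            t = subj.event_time if (event and subj.event_time is not None) \
                else (subj.sacrifice_time or 24.0)
            records.append(ExposureRecord(subj.subject_id, metrics, subj.stage,
                                          float(t), event))
        return records

    def exposures(self) -> None:
        with self._track("exposures"):
            records = self._exposure_records()
            rows = []
            for r in records:
                row = {"ID": r.subject_id, "STAGE": r.stage,
                       "SEIZURE": int(r.indicator), "TIME": r.time,
                       "EVENT": int(r.event)}
                for m in _MATS:
                    row[f"AUC_{m}"] = r.metrics.auc_0_24[m]
                    row[f"CMAX_{m}"] = r.metrics.cmax_0_24[m]
                rows.append(row)
            pd.DataFrame(rows).to_csv(self.out / "exposure_table.csv", index=False)
            exposure_summary(records).to_csv(self.out / "exposure_summary.csv",
                                             index=False)
            comp = []
            for metric in ("auc", "cmax"):
                for m in _MATS:
                    g0 = [r.exposure(metric, m) for r in records if not r.indicator]
                    g1 = [r.exposure(metric, m) for r in records if r.indicator]
                    if g0 and g1:
                        res = rank_sum_test(g0, g1)
                        comp.append({"metric": metric, "matrix": m, **res})
            pd.DataFrame(comp).to_csv(self.out / "ranksum.csv", index=False)

    def tc50(self) -> None:
        with self._track("tc50"):
            records = self._exposure_records()
            y = [int(r.indicator) for r in records]
            out = {}
            for metric in ("auc", "cmax"):
                for m in _MATS:
                    x = [r.exposure(metric, m) for r in records]
                    try:
                        lf = fit_logistic_tc50(x, y)
                    except Exception as exc:
                        self.warnings.append(f"tc50 {metric}/{m}: {exc}")
                        continue
                    out[f"{metric}_{m}"] = {
                        "tc50": lf.tc50, "intercept": lf.intercept,
                        "slope": lf.slope, "se_tc50": lf.se_tc50,
                        "converged": lf.converged, "separation": lf.separation,
                        "tc50_bounds": lf.tc50_bounds, "n": lf.n}
            (self.out / "tc50.json").write_text(
                json.dumps(out, indent=1, sort_keys=True))

    def km(self) -> None:
        with self._track("km"):
            records = self._exposure_records()
            cutoff = self.cfg.km_cutoff
            if cutoff is None:
                tc = json.loads((self.out / "tc50.json").read_text())
                cutoff = tc.get("auc_plasma", {}).get("tc50")
            if cutoff is None or not np.isfinite(cutoff):
                self.warnings.append("no usable plasma AUC cut-off; KM skipped")
                return
            curves = km_estimate(records, cutoff)
            frames = [c.as_frame() for c in curves.values()]
            df = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
                columns=["time", "survival", "at_risk", "group"])
            df.insert(0, "cutoff", cutoff)
            df.to_csv(self.out / "km_curves.csv", index=False)

    def report(self) -> RunReport:
        with self._track("report"):
            if self.cfg.plots:
                from .plots import render_all
                render_all(self.out)
        manifest = sorted(p.name for p in self.out.iterdir()
                          if p.name not in ("run_report.json", "timings.log"))
        rep = RunReport(version=__version__, config_hash=self.cfg.config_hash(),
                        seed=self.cfg.seed, manifest=manifest,
                        warnings=self.warnings, stage_timings=dict(self.timings))
        payload = dataclasses.asdict(rep)
        del payload["stage_timings"]          # kept out for byte-reproducibility
        (self.out / "run_report.json").write_text(
            json.dumps(payload, indent=1, sort_keys=True))
        (self.out / "timings.log").write_text(
            "".join(f"{k}\t{v:.3f}s\n" for k, v in self.timings.items()))
        return rep


def run_pipeline(cfg: PipelineConfig) -> RunReport:
    """simulate → screen → fit → exposures → TC50 → KM → report."""
    run = PipelineRun(cfg)
    run.simulate()
    run.screen()
    run.fit()
    run.exposures()
    run.tc50()
    run.km()
    return run.report()
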