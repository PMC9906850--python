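"""End-to-end orchestration: simulate -> preprocess -> indices -> DHGLM ->
repeatability -> home range -> survival -> model comparison.

A run is fully described by a RunConfig (YAML-serializable); every
artifact directory receives a consolidated ``report.json`` carrying the
config dump, its hash, the global seed and the package version, so a
run is reproducible from the report alone plus the inputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, dhglm, homerange, indices, modelsel, preprocess, repeatability, simulate, survival


@dataclass
class RunConfig:
    """Every stage parameter, defaulting to the study's printed values."""

    outdir: str = "results/run"
    seed: int = 0
    # simulation
    n_individuals: int = 20
    nights_per_individual: int = 40
    fix_interval_s: float = 8.0
    # preprocessing
    std_max_m: float = 50.0
    speed_max_ms: float = 15.0
    night_start_hour: int = 17
    night_end_hour: int = 6
    utc_offset_h: int = 2
    min_fixes_per_night: int = 1000
    min_nights_per_period: int = 25
    # indices
    stop_radius_m: float = 20.0
    stop_min_duration_s: float = 60.0
    # dhglm
    dhglm_chains: int = 2
    dhglm_iterations: int = 2000
    dhglm_min_nights: int = 5
    # repeatability
    n_boot: int = 200
    # home range
    hr_subsample_s: float = 600.0
    hr_level: float = 0.95
    hr_min_points: int = 30
    density_radius_m: float = 1700.0
    # stage toggles
    stages: tuple[str, ...] = (
        "simulate", "preprocess", "indices", "dhglm", "repeatability",
        "homerange", "survival", "models",
    )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["stages"] = list(d["stages"])
        return d

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if "stages" in data:
            data["stages"] = tuple(data["stages"])
        return cls(**data)


def _write_table(df: pd.DataFrame, path: Path) -> None:
    if path.suffix == ".parquet":
        df.to_parquet(path, index=False)
    else:
        df.to_csv(path, index=False)


class MissingArtifact(RuntimeError):
    pass


def run_all(config: RunConfig) -> dict:
    """Execute the enabled stages in dependency order; return the report."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "config": config.to_dict(),
        "config_hash": config.config_hash,
        "seed": config.seed,
        "package_version": __version__,
        "stages": {},
    }
    state: dict = {}
    stages = config.stages
    order = [
        "simulate", "preprocess", "indices", "dhglm", "repeatability",
        "homerange", "survival", "models",
    ]
    deps = {
        "preprocess": ["simulate"],
        "indices": ["preprocess"],
        "dhglm": ["indices"],
        "repeatability": ["dhglm"],
        "homerange": ["indices"],
        "survival": ["dhglm"],
        "models": ["homerange", "survival"],
    }
    for stage in order:
        if stage not in stages:
            continue
        for dep in deps.get(stage, []):
            if dep not in report["stages"]:
                raise MissingArtifact(
                    f"stage '{stage}' requires stage '{dep}' which did not run"
                )
        runner = globals()[f"_stage_{stage}"]
        runner(config, state, out, report)
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=1, default=str)
    return report


def _stage_simulate(config, state, out, report):
    sim = simulate.SimConfig(
        n_individuals=config.n_individuals,
        nights_per_individual=config.nights_per_individual,
        fix_interval_s=config.fix_interval_s,
        night_start_hour=config.night_start_hour,
        night_end_hour=config.night_end_hour,
        utc_offset_h=config.utc_offset_h,
        seed=config.seed,
    )
    meta, truth = simulate.simulate_cohort(sim)
    fixes, truth = simulate.simulate_tracks(sim, truth)
    occupancy = simulate.simulate_occupancy(sim, truth)
    paths = simulate.write_cohort(out / "raw", fixes, meta, truth, occupancy)
    state.update(sim=sim, meta=meta, truth=truth, fixes=fixes, occupancy=occupancy)
    report["stages"]["simulate"] = {
        "paths": paths,
        "n_individuals": len(meta),
        "n_fixes": len(fixes),
        "truncated_fraction": truth.truncated_fraction,
    }


def _stage_preprocess(config, state, out, report):
    raw = state["fixes"][["tag_id", "time_utc_ms", "x_m", "y_m", "std_m"]]
    nights, rep = preprocess.preprocess(
        raw,
        state["meta"],
        std_max=config.std_max_m,
        speed_max=config.speed_max_ms,
        utc_offset_h=config.utc_offset_h,
        start_hour=config.night_start_hour,
        end_hour=config.night_end_hour,
        min_fixes=config.min_fixes_per_night,
        min_nights=config.min_nights_per_period,
    )
    state["nights"] = nights
    qc = out / "qc.json"
    with open(qc, "w") as fh:
        json.dump(rep.to_dict(), fh, indent=1)
    report["stages"]["preprocess"] = {"qc": str(qc), **rep.to_dict()}


def _stage_indices(config, state, out, report):
    table, summary, labeled = indices.build_index_table(
        state["nights"],
        stop_radius=config.stop_radius_m,
        stop_min_duration=config.stop_min_duration_s,
        keep_stop_labels=True,
    )
    state["index_table"] = table
    state["index_summary"] = summary
    state["labeled_fixes"] = labeled
    _write_table(table, out / "indices.csv")
    _write_table(summary, out / "indices_summary.csv")
    report["stages"]["indices"] = {
        "n_nights": len(table),
        "mean_max_disp_km": float(table["max_disp_km"].mean()) if len(table) else None,
        "mean_total_dist_km": float(table["total_dist_km"].mean()) if len(table) else None,
    }


def _stage_dhglm(config, state, out, report):
    # small cohorts can make the full design collinear; drop terms until
    # the model is identifiable
    fit = None
    for mean_effects in (
        ("age_class", "sex", "period"),
        ("age_class", "sex"),
        ("age_class",),
        (),
    ):
        spec = dhglm.DHGLMSpec(
            mean_effects=mean_effects,
            chains=config.dhglm_chains,
            iterations=config.dhglm_iterations,
            seed=config.seed,
            min_nights=config.dhglm_min_nights,
        )
        try:
            fit = dhglm.fit_dhglm(state["index_table"], spec)
            break
        except ValueError as exc:
            if "singular" not in str(exc):
                raise
            warnings.warn(f"DHGLM design singular with {mean_effects}; reducing")
    if fit is None:
        raise RuntimeError("DHGLM could not be fit with any fixed-effect set")
    riiv = dhglm.extract_riiv(fit)
    state["dhglm_fit"] = fit
    state["riiv"] = riiv
    _write_table(riiv, out / "riiv.csv")
    try:
        riiv_period = dhglm.riiv_by_period(state["index_table"], spec)
    except Exception as exc:
        warnings.warn(f"period-wise rIIV skipped: {exc}")
        riiv_period = pd.DataFrame(columns=riiv.columns)
    state["riiv_period"] = riiv_period
    _write_table(riiv_period, out / "riiv_period.csv")
    report["stages"]["dhglm"] = {
        "converged": fit.converged,
        "diagnostics": fit.diagnostics.to_dict(orient="records"),
        "mean_effects": list(fit.mean_columns),
        "disp_effects": list(fit.disp_columns),
        "riiv_range_km": [float(riiv["riiv_km"].min()), float(riiv["riiv_km"].max())],
    }


def _stage_repeatability(config, state, out, report):
    est = repeatability.estimate_repeatability(
        state["index_table"].rename(columns={"max_disp_km": "value"}),
        n_boot=config.n_boot,
        seed=config.seed,
    )
    res = {
        "trait": "max_disp_km",
        "rp": est.rp,
        "rp_ci": list(est.rp_ci),
        "cvi": est.cvi,
        "cvi_ci": list(est.cvi_ci),
        "n_individuals": est.n_individuals,
        "n_obs": est.n_obs,
        "n_boot": est.n_boot,
    }
    rp_period = state.get("riiv_period")
    if rp_period is not None and rp_period["scope"].nunique() >= 2:
        try:
            cons = repeatability.riiv_consistency(
                rp_period, n_boot=config.n_boot, seed=config.seed
            )
            res["riiv_consistency_rp"] = cons.rp
            res["riiv_consistency_ci"] = list(cons.rp_ci)
        except ValueError as exc:
            res["riiv_consistency_error"] = str(exc)
    with open(out / "repeatability.json", "w") as fh:
        json.dump(res, fh, indent=1)
    state["repeatability"] = res
    report["stages"]["repeatability"] = res


def _stage_homerange(config, state, out, report):
    hr = homerange.estimate_home_ranges(
        state["labeled_fixes"],
        subsample_interval_s=config.hr_subsample_s,
        level=config.hr_level,
        min_points=config.hr_min_points,
    )
    if len(hr) and "occupancy" in state:
        dens = homerange.density_index(hr, state["occupancy"], config.density_radius_m)
        hr = hr.merge(dens, on=["individual", "period", "period_year"], how="left")
    state["homerange"] = hr
    _write_table(hr, out / "homerange.csv")
    report["stages"]["homerange"] = {
        "n_cells": len(hr),
        "median_area_km2": float(hr["area_km2"].median()) if len(hr) else None,
    }


def _stage_survival(config, state, out, report):
    truth = state["truth"]
    table = survival.build_survival_table(
        truth.individuals,
        truth.survival,
        index_summary=state["index_summary"],
        riiv=state["riiv"],
    )
    state["survival_table"] = table
    _write_table(table, out / "survival.csv")
    res = {"n_records": len(table), "n_events": int(table["event"].sum())}
    covs = ["riiv_km", "mean_max_disp_km", "sex", "age_group", "track_days"]
    usable = [c for c in covs if table[c].nunique() > 1]
    if table["event"].sum() >= 1 and usable:
        fit = survival.fit_cox(table, usable)
        hr_table = survival.hazard_ratio_table(fit)
        _write_table(hr_table, out / "cox.csv")
        state["cox"] = fit
        res["hazard_ratios"] = dict(zip(hr_table["covariate"], hr_table["hr"]))
        res["converged"] = fit.converged
    report["stages"]["survival"] = res


def _stage_models(config, state, out, report):
    hr = state.get("homerange")
    res = {}
    if hr is None or len(hr) < 8:
        res["skipped"] = "too few home-range cells for model comparison"
        report["stages"]["models"] = res
        return
    merged = hr.merge(
        state["index_summary"], on=["individual", "period", "period_year"], how="inner"
    ).merge(
        state["riiv"][["individual", "riiv_km"]], on="individual", how="inner"
    )
    merged["log_hr"] = np.log(merged["area_km2"])
    numeric = [c for c in ["mean_max_disp_km", "riiv_km", "n_nights"]
               if merged[c].nunique() > 1]
    if not numeric:
        res["skipped"] = "no varying numeric predictors"
        report["stages"]["models"] = res
        return
    merged, _ = modelsel.standardize(merged, numeric)
    core = [c for c in ["mean_max_disp_km", "riiv_km", "n_nights", "period"]
            if merged[c].nunique() > 1]
    models = modelsel.enumerate_and_rank(merged, "log_hr", core)
    table = modelsel.models_table(models)
    _write_table(table, out / "models.csv")
    avg = modelsel.model_average(models)
    _write_table(avg, out / "models_avg.csv")
    state["models"] = models
    res["n_models"] = len(models)
    res["top_formula"] = models[0].formula
    report["stages"]["models"] = res
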