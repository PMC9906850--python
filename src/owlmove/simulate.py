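"""Synthetic tracking cohorts with known ground truth.

The generator emulates the statistical structure of a nocturnal
central-place forager tracked by a regional reverse-GPS array: each
individual performs nightly out-and-back trips from its nest, the
nightly maximal displacement follows an individual-specific Gaussian
whose mean (behavioral type, ``u_i``) and log residual SD
(predictability, ``v_i``) are drawn from a correlated bivariate normal,
localization noise and accuracy/speed artifacts are superimposed, and
survival times depend on the individual's true rIIV.

Ground-truth parameters and artifact labels are kept alongside the
"raw" outputs so every downstream stage has a recovery oracle.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from datetime import date, datetime, timedelta, timezone
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

KM = 1000.0  # meters per kilometre

# Default generative parameters follow the study population they emulate:
# cohort mean nightly max-displacement 2.45 km, among-individual SD chosen
# so that CVi ~ 0.36 and Rp ~ 0.23, adult residual SD 1.23 km vs juvenile
# 2.25 km, ~30% mortality over up to two tracked years with higher hazard
# for predictable (low-rIIV) individuals.


@dataclass
class SimConfig:
    """Configuration of the synthetic cohort generator.

    Distances are km unless suffixed ``_m``; rates are per day.
    """

    n_individuals: int = 74
    nights_per_individual: int | Sequence[int] = 115
    fix_interval_s: float = 8.0
    night_start_hour: int = 17
    night_end_hour: int = 6
    utc_offset_h: int = 2

    # mean submodel (km)
    mu: float = 2.45
    beta_age: float = 0.5       # juvenile offset
    beta_sex: float = 0.3       # male offset
    # dispersion submodel (log-km)
    lambda0: float = float(np.log(1.23))
    lambda_age: float = float(np.log(2.25 / 1.23))
    # individual random effects
    tau_u: float = 0.887
    tau_v: float = 0.5
    rho: float = 0.3

    displacement_floor_km: float = 0.05
    noise_sd_m: float = 5.0
    flight_speed_ms: float = 8.0
    stop_bout_s: float = 300.0
    stop_every_m: float = 600.0

    artifact_rate_std: float = 0.005
    artifact_rate_speed: float = 0.002

    hazard_baseline: float = 1.0 / 200.0    # per day
    gamma_riiv: float = -0.5                # per km of true rIIV
    gamma_age: float = 0.3                  # juvenile offset
    censor_day: float = 600.0

    study_start: date = date(2020, 1, 1)
    juvenile_fraction: float = 0.55
    transition_fraction: float = 0.07       # juveniles that turn adult mid-study
    region_half_width_m: float = 5000.0

    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_individuals < 1:
            raise ValueError("n_individuals must be positive")
        if self.fix_interval_s <= 0:
            raise ValueError("fix_interval_s must be positive")
        for name in ("tau_u", "tau_v", "noise_sd_m"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if abs(self.rho) > 1:
            raise ValueError("|rho| must be <= 1 (invalid covariance)")
        for name in ("artifact_rate_std", "artifact_rate_speed"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.hazard_baseline <= 0:
            raise ValueError("hazard_baseline must be positive")

    def nights_for(self, i: int) -> int:
        if isinstance(self.nights_per_individual, (int, np.integer)):
            return int(self.nights_per_individual)
        return int(self.nights_per_individual[i])

    @property
    def night_duration_s(self) -> float:
        hours = (self.night_end_hour - self.night_start_hour) % 24
        return hours * 3600.0


@dataclass
class TrueParams:
    """Ground truth of a simulated cohort."""

    individuals: pd.DataFrame       # u_i, v_i, riiv_true, sex, hatch_date, nest x/y
    nights: pd.DataFrame | None = None       # per-night true draws
    survival: pd.DataFrame | None = None     # duration_days, event
    truncated_fraction: float = 0.0


def _rng(config: SimConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([config.seed % (2**31), stream])


def simulate_cohort(config: SimConfig) -> tuple[pd.DataFrame, TrueParams]:
    """Draw a cohort: metadata table plus ground-truth individual effects.

    (u_i, v_i) are bivariate normal with SDs ``tau_u``, ``tau_v`` and
    correlation ``rho``.  Age classes come from hatch dates; a configured
    fraction of juveniles crosses the one-year transition mid-study.
    """
    rng = _rng(config, 0)
    n = config.n_individuals

    # explicit Cholesky of the 2x2 covariance so tau = 0 degenerates cleanly
    z = rng.standard_normal((n, 2))
    u = config.tau_u * z[:, 0]
    v = config.tau_v * (config.rho * z[:, 0] + np.sqrt(1 - config.rho**2) * z[:, 1])

    sex = np.where(rng.random(n) < 0.5, "F", "M")
    is_juv = rng.random(n) < config.juvenile_fraction
    transitions = is_juv & (rng.random(n) < config.transition_fraction / max(config.juvenile_fraction, 1e-9))

    start0 = config.study_start
    track_start = np.array(
        [start0 + timedelta(days=int(d)) for d in rng.integers(0, 365, size=n)]
    )
    hatch = []
    for i in range(n):
        if not is_juv[i]:
            # adult at tagging: hatched 2-5 years before tracking start
            hatch.append(track_start[i] - timedelta(days=int(rng.integers(730, 1825))))
        elif transitions[i]:
            # first birthday falls inside the tracked window
            mid = max(10, config.nights_for(i) // 2)
            hatch.append(track_start[i] - timedelta(days=365 - int(mid)))
        else:
            hatch.append(track_start[i] - timedelta(days=int(rng.integers(70, 200))))

    nest = rng.uniform(-config.region_half_width_m, config.region_half_width_m, size=(n, 2))

    ids = [f"owl{i:03d}" for i in range(n)]
    meta = pd.DataFrame(
        {
            "individual": ids,
            "tag_id": [9720000 + i for i in range(n)],
            "sex": sex,
            "hatch_date": hatch,
            "track_start": track_start,
            "nest_x_m": nest[:, 0],
            "nest_y_m": nest[:, 1],
            "n_nights": [config.nights_for(i) for i in range(n)],
        }
    )

    juv_at_start = np.array(
        [(track_start[i] - hatch[i]).days < 365 for i in range(n)]
    )
    riiv_true = np.exp(config.lambda0 + config.lambda_age * juv_at_start + v)
    truth = meta.assign(
        u=u, v=v, juvenile_at_start=juv_at_start, riiv_true_km=riiv_true
    )
    return meta, TrueParams(individuals=truth)


def _age_is_juvenile(hatch: date, night: date) -> bool:
    return (night - hatch).days < 365


def simulate_night_indices(
    config: SimConfig, true_params: TrueParams
) -> pd.DataFrame:
    """Draw per-night true max-displacement values (fast generative path).

    d_ij ~ Normal(mu + beta_age*juv + beta_sex*male + u_i, sigma_ij) with
    sigma_ij = exp(lambda0 + lambda_age*juv + v_i), resampled below the
    configured floor so draws stay positive.  The truncated fraction is
    recorded on the returned TrueParams.
    """
    rng = _rng(config, 1)
    ind = true_params.individuals
    rows = []
    n_trunc = 0
    n_total = 0
    for i, rec in enumerate(ind.itertuples(index=False)):
        n_nights = config.nights_for(i)
        nights = [rec.track_start + timedelta(days=d) for d in range(n_nights)]
        juv = np.array([_age_is_juvenile(rec.hatch_date, nt) for nt in nights])
        male = rec.sex == "M"
        mean = config.mu + config.beta_age * juv + config.beta_sex * male + rec.u
        sd = np.exp(config.lambda0 + config.lambda_age * juv + rec.v)
        d = rng.normal(mean, sd)
        n_total += n_nights
        bad = d < config.displacement_floor_km
        while bad.any():
            n_trunc += int(bad.sum())
            d[bad] = rng.normal(mean[bad] if np.ndim(mean) else mean, sd[bad] if np.ndim(sd) else sd)
            bad = d < config.displacement_floor_km
        rows.append(
            pd.DataFrame(
                {
                    "individual": rec.individual,
                    "night_date": nights,
                    "age_class": np.where(juv, "juvenile", "adult"),
                    "sex": rec.sex,
                    "d_true_km": d,
                    "sigma_true_km": sd,
                }
            )
        )
    out = pd.concat(rows, ignore_index=True)
    true_params.nights = out
    true_params.truncated_fraction = n_trunc / max(n_total, 1)
    return out


def simulate_night_track(
    individual: pd.Series | dict,
    night_date: date,
    target_displacement_km: float,
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Build one night's fix sequence: out-and-back trip from the nest.

    The owl flies an out-leg (constant speed, interleaved perching bouts)
    to a far point at exactly ``target_displacement_km`` from the nest,
    perches there, returns, and perches at the nest for the rest of the
    night.  Isotropic Gaussian localization noise ``noise_sd_m`` is added.
    """
    if target_displacement_km <= 0:
        raise ValueError("target displacement must be positive")
    if rng is None:
        rng = _rng(config, 2)
    T = config.night_duration_s
    dt = config.fix_interval_s
    n_fix = int(T / dt)
    if n_fix < 2:
        raise ValueError("night window shorter than two fix intervals")

    nest = np.array([individual["nest_x_m"], individual["nest_y_m"]], float)
    bearing = rng.uniform(0, 2 * np.pi)
    direction = np.array([np.cos(bearing), np.sin(bearing)])
    far = nest + direction * target_displacement_km * KM

    speed = config.flight_speed_ms
    out_dist = target_displacement_km * KM
    # waypoints along the out leg, a stop bout roughly every stop_every_m
    n_stops_out = max(0, int(out_dist // config.stop_every_m) - 1)
    travel_time = 2 * out_dist / speed
    stop_time_budget = T - travel_time
    if stop_time_budget < 2 * config.stop_bout_s:
        # night barely long enough: fly straight out and back, no perching
        n_stops_out = 0

    segs: list[tuple[float, np.ndarray, np.ndarray]] = []  # (duration, p0, p1)

    def add_move(p0: np.ndarray, p1: np.ndarray) -> None:
        d = float(np.hypot(*(p1 - p0)))
        if d > 0:
            segs.append((d / speed, p0, p1))

    def add_stop(p: np.ndarray, duration: float) -> None:
        if duration > 0:
            segs.append((duration, p, p))

    pos = nest
    for k in range(1, n_stops_out + 1):
        wp = nest + direction * out_dist * k / (n_stops_out + 1)
        add_move(pos, wp)
        add_stop(wp, config.stop_bout_s)
        pos = wp
    add_move(pos, far)
    used = sum(s[0] for s in segs)
    # perch at the far point, then return and perch at the nest
    far_stop = max(config.stop_bout_s, dt * 2)
    add_stop(far, far_stop)
    add_move(far, nest)
    used = sum(s[0] for s in segs)
    add_stop(nest, max(T - used, dt))

    bounds = np.cumsum([0.0] + [s[0] for s in segs])
    pts = np.array([s[1] for s in segs] + [segs[-1][2]])
    t_fix = np.arange(n_fix) * dt
    x = np.interp(t_fix, bounds, pts[:, 0])
    y = np.interp(t_fix, bounds, pts[:, 1])

    x_noisy = x + rng.normal(0, config.noise_sd_m, n_fix)
    y_noisy = y + rng.normal(0, config.noise_sd_m, n_fix)

    night_start_local = datetime.combine(night_date, datetime.min.time()) + timedelta(
        hours=config.night_start_hour
    )
    start_utc = night_start_local - timedelta(hours=config.utc_offset_h)
    t_ms = (
        int(start_utc.replace(tzinfo=timezone.utc).timestamp() * 1000)
        + (t_fix * 1000).astype(np.int64)
    )
    return pd.DataFrame(
        {
            "tag_id": individual.get("tag_id", 0) if hasattr(individual, "get") else individual["tag_id"],
            "time_utc_ms": t_ms,
            "x_m": x_noisy,
            "y_m": y_noisy,
            "std_m": np.abs(rng.normal(5.0, 2.0, n_fix)),
            "x_true_m": x,
            "y_true_m": y,
            "artifact_std": False,
            "artifact_speed": False,
        }
    )


def inject_artifacts(
    track: pd.DataFrame, config: SimConfig, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Mark random fixes as accuracy or speed artifacts (ground truth kept).

    High-STD fixes get std drawn above the 50 m filter threshold; speed
    spikes displace a fix far enough that its incoming step speed exceeds
    15 m/s.  Labels are stored in ``artifact_std`` / ``artifact_speed``.
    """
    if rng is None:
        rng = _rng(config, 3)
    out = track.copy()
    n = len(out)
    u = rng.random(n)
    std_mask = u < config.artifact_rate_std
    speed_mask = (u >= config.artifact_rate_std) & (
        u < config.artifact_rate_std + config.artifact_rate_speed
    )
    speed_mask[0] = False  # first fix has no incoming segment

    out.loc[std_mask, "std_m"] = 51.0 + rng.exponential(60.0, int(std_mask.sum()))
    out.loc[std_mask, "artifact_std"] = True

    idx = np.flatnonzero(speed_mask.to_numpy() if hasattr(speed_mask, "to_numpy") else speed_mask)
    if len(idx):
        dt = np.diff(out["time_utc_ms"].to_numpy()) / 1000.0
        theta = rng.uniform(0, 2 * np.pi, len(idx))
        # displacement guaranteeing incoming speed > 15 m/s with margin
        mag = 20.0 * dt[idx - 1] + 300.0
        out.loc[out.index[idx], "x_m"] += mag * np.cos(theta)
        out.loc[out.index[idx], "y_m"] += mag * np.sin(theta)
        out.loc[out.index[idx], "artifact_speed"] = True
    return out


def simulate_tracks(
    config: SimConfig, true_params: pd.DataFrame | TrueParams | None = None
) -> tuple[pd.DataFrame, TrueParams]:
    """Full trajectory path: cohort -> night draws -> noisy tracks with artifacts.

    Returns the concatenated fix table (with ground-truth columns) and the
    TrueParams carrying cohort, night draws, and survival outcomes.
    """
    if true_params is None:
        _, true_params = simulate_cohort(config)
    if true_params.nights is None:
        simulate_night_indices(config, true_params)
    rng = _rng(config, 4)
    ind = true_params.individuals.set_index("individual")
    frames = []
    for rec in true_params.nights.itertuples(index=False):
        row = ind.loc[rec.individual]
        track = simulate_night_track(
            {
                "tag_id": row["tag_id"],
                "nest_x_m": row["nest_x_m"],
                "nest_y_m": row["nest_y_m"],
            },
            rec.night_date,
            rec.d_true_km,
            config,
            rng,
        )
        track = inject_artifacts(track, config, rng)
        track.insert(0, "individual", rec.individual)
        frames.append(track)
    fixes = pd.concat(frames, ignore_index=True)
    simulate_survival(true_params, config)
    return fixes, true_params


def simulate_survival(
    true_params: TrueParams, config: SimConfig, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Exponential event times with log-hazard linear in true rIIV and age.

    rate_i = baseline * exp(gamma_riiv * rIIV_i + gamma_age * juvenile_i);
    administrative censoring at ``censor_day``.
    """
    if config.hazard_baseline <= 0:
        raise ValueError("hazard_baseline must be positive")
    if rng is None:
        rng = _rng(config, 5)
    ind = true_params.individuals
    juv = ind["juvenile_at_start"].to_numpy().astype(float)
    rate = config.hazard_baseline * np.exp(
        config.gamma_riiv * ind["riiv_true_km"].to_numpy() + config.gamma_age * juv
    )
    t_event = rng.exponential(1.0 / rate)
    # administrative censoring and end of tracking, whichever first
    track_end = ind["n_nights"].to_numpy().astype(float)
    horizon = np.minimum(config.censor_day, track_end)
    duration = np.minimum(t_event, horizon)
    event = (t_event <= horizon).astype(int)
    if config.censor_day <= 0:
        duration = np.zeros_like(duration)
        event = np.zeros_like(event)
    surv = pd.DataFrame(
        {
            "individual": ind["individual"],
            "duration_days": duration,
            "event": event,
        }
    )
    true_params.survival = surv
    return surv


def simulate_occupancy(
    config: SimConfig, true_params: TrueParams, n_extra_boxes: int = 40
) -> pd.DataFrame:
    """Nest-box occupancy table: each nest plus extra boxes, with years."""
    rng = _rng(config, 6)
    ind = true_params.individuals
    years = sorted({d.year for d in ind["track_start"]} | {config.study_start.year})
    rows = []
    for rec in ind.itertuples(index=False):
        for yr in years:
            if rng.random() < 0.7:
                rows.append((rec.nest_x_m, rec.nest_y_m, yr))
    extra = rng.uniform(
        -config.region_half_width_m, config.region_half_width_m, size=(n_extra_boxes, 2)
    )
    for bx, by in extra:
        for yr in years:
            if rng.random() < 0.5:
                rows.append((bx, by, yr))
    return pd.DataFrame(rows, columns=["box_x_m", "box_y_m", "year"])


def write_cohort(
    outdir: str | Path,
    fixes: pd.DataFrame,
    meta: pd.DataFrame,
    true_params: TrueParams,
    occupancy: pd.DataFrame | None = None,
) -> dict[str, str]:
    """Write raw-format CSVs plus a ground-truth JSON.

    The fix CSV carries only the "observable" columns; artifact labels and
    true coordinates stay in the ground-truth file.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}

    raw = fixes[["tag_id", "time_utc_ms", "x_m", "y_m", "std_m"]]
    paths["fixes"] = str(outdir / "fixes.csv")
    raw.to_csv(paths["fixes"], index=False)

    paths["meta"] = str(outdir / "meta.csv")
    meta.to_csv(paths["meta"], index=False)

    if occupancy is not None:
        paths["occupancy"] = str(outdir / "occupancy.csv")
        occupancy.to_csv(paths["occupancy"], index=False)

    truth = {
        "individuals": true_params.individuals.assign(
            hatch_date=true_params.individuals["hatch_date"].astype(str),
            track_start=true_params.individuals["track_start"].astype(str),
        ).to_dict(orient="list"),
        "truncated_fraction": true_params.truncated_fraction,
    }
    if true_params.survival is not None:
        truth["survival"] = true_params.survival.to_dict(orient="list")
    if "artifact_std" in fixes:
        truth["n_artifact_std"] = int(fixes["artifact_std"].sum())
        truth["n_artifact_speed"] = int(fixes["artifact_speed"].sum())
    paths["truth"] = str(outdir / "truth.json")
    with open(paths["truth"], "w") as fh:
        json.dump(truth, fh, indent=1, default=str)
    return paths
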