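"""Raw-fix quality control, night segmentation, and inclusion rules.

Filters follow standard regional-telemetry practice: drop fixes whose
system accuracy estimate exceeds 50 m, then forward-sweep a speed filter
that removes any fix implying a step speed above 15 m/s relative to the
last retained fix.  The remaining fixes are cut into nights (17:00 local
through 06:00 the next morning), nights are labeled with a four-month
period (Feb-May, Jun-Sep, Oct-Jan), and individual-period cells with too
few qualifying nights are excluded.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date, datetime, time, timedelta, timezone

import numpy as np
import pandas as pd

REQUIRED_COLUMNS = ("tag_id", "time_utc_ms", "x_m", "y_m", "std_m")


class SchemaError(ValueError):
    pass


@dataclass
class InclusionReport:
    """Bookkeeping of every row/night/cell removed, stage by stage."""

    n_input_fixes: int = 0
    removed_std: int = 0
    removed_speed: int = 0
    removed_daytime: int = 0
    nights_input: int = 0
    nights_excluded_window: int = 0
    nights_below_min_fixes: int = 0
    cells_below_min_nights: int = 0
    nights_in_dropped_cells: int = 0
    nights_output: int = 0
    n_output_fixes: int = 0

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def read_fixes(path) -> pd.DataFrame:
    """Read a fix CSV, type, sort per tag, and drop duplicate timestamps."""
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"fix table missing required column(s): {', '.join(missing)}")
    if len(df) == 0:
        return df
    bad_time = pd.to_numeric(df["time_utc_ms"], errors="coerce").isna()
    if bad_time.any():
        raise ValueError(
            f"unparseable time_utc_ms in rows: {list(df.index[bad_time])[:10]}"
        )
    df["time_utc_ms"] = df["time_utc_ms"].astype(np.int64)
    for c in ("x_m", "y_m", "std_m"):
        df[c] = df[c].astype(float)
    df = (
        df.sort_values(["tag_id", "time_utc_ms"], kind="mergesort")
        .drop_duplicates(subset=["tag_id", "time_utc_ms"], keep="first")
        .reset_index(drop=True)
    )
    return df


def _speed_sweep(t_s: np.ndarray, x: np.ndarray, y: np.ndarray, vmax: float) -> np.ndarray:
    """Forward sweep: keep a fix iff its speed from the last retained fix <= vmax."""
    n = len(t_s)
    keep = np.ones(n, dtype=bool)
    if n < 2:
        return keep
    # fast path: no violations against the immediate predecessor
    dt = np.diff(t_s)
    dist = np.hypot(np.diff(x), np.diff(y))
    with np.errstate(divide="ignore"):
        v = np.where(dt > 0, dist / np.where(dt > 0, dt, 1.0), np.inf)
    if not (v > vmax).any():
        return keep
    last = 0
    for i in range(1, n):
        dti = t_s[i] - t_s[last]
        if dti <= 0:
            keep[i] = False
            continue
        sp = np.hypot(x[i] - x[last], y[i] - y[last]) / dti
        if sp > vmax:
            keep[i] = False
        else:
            last = i
    return keep


def filter_fixes(
    fixes: pd.DataFrame, std_max: float = 50.0, speed_max: float = 15.0
) -> tuple[pd.DataFrame, dict]:
    """Accuracy filter (std > std_max dropped) then forward-sweep speed filter.

    Returns the retained subset and per-stage removal counts.  Idempotent:
    reapplying to its own output removes nothing.
    """
    n0 = len(fixes)
    kept = fixes[fixes["std_m"] <= std_max]
    n_std = n0 - len(kept)

    parts = []
    for _, grp in kept.groupby("tag_id", sort=False):
        t = grp["time_utc_ms"].to_numpy() / 1000.0
        mask = _speed_sweep(t, grp["x_m"].to_numpy(), grp["y_m"].to_numpy(), speed_max)
        parts.append(grp[mask])
    out = pd.concat(parts) if parts else kept
    out = out.reset_index(drop=True)
    counts = {"removed_std": n_std, "removed_speed": (n0 - n_std) - len(out)}
    return out, counts


def night_of_fix(
    t_utc_ms: np.ndarray, utc_offset_h: float = 2, start_hour: int = 17, end_hour: int = 6
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized: (is_night, evening date ordinal) for each fix.

    A night runs [start_hour:00:00, end_hour:00:00) local and is labeled
    by the evening's calendar date.
    """
    local_s = t_utc_ms / 1000.0 + utc_offset_h * 3600.0
    day = np.floor(local_s / 86400.0).astype(np.int64)
    sec_of_day = local_s - day * 86400.0
    hour = sec_of_day / 3600.0
    evening = hour >= start_hour
    morning = hour < end_hour
    is_night = evening | morning
    night_day = np.where(evening, day, day - 1)
    return is_night, night_day


def segment_nights(
    fixes: pd.DataFrame,
    utc_offset_h: float = 2,
    start_hour: int = 17,
    end_hour: int = 6,
) -> tuple[pd.DataFrame, int]:
    """Drop daytime fixes and label the rest with their night's evening date."""
    t = fixes["time_utc_ms"].to_numpy()
    is_night, night_day = night_of_fix(t, utc_offset_h, start_hour, end_hour)
    out = fixes[is_night].copy()
    epoch = date(1970, 1, 1)
    out["night_date"] = [epoch + timedelta(days=int(d)) for d in night_day[is_night]]
    return out.reset_index(drop=True), int((~is_night).sum())


def assign_period(d: date) -> tuple[str, int]:
    """Four-month period of a night plus its keying year.

    Feb-May -> P1, Jun-Sep -> P2, Oct-Jan -> P3; a January night belongs
    to the preceding autumn's P3 (keyed by its October year).
    """
    m = d.month
    if 2 <= m <= 5:
        return "P1", d.year
    if 6 <= m <= 9:
        return "P2", d.year
    return ("P3", d.year - 1) if m == 1 else ("P3", d.year)


def assign_age_class(
    hatch_date: date | None, night: date, fallback_class: str | None = None
) -> str:
    """Juvenile before the first birthday, adult from it on."""
    if hatch_date is None or (isinstance(hatch_date, float) and np.isnan(hatch_date)):
        if fallback_class is None:
            raise ValueError("unknown age: no hatch date and no age class")
        return fallback_class
    return "juvenile" if (night - hatch_date).days < 365 else "adult"


def attach_metadata(
    night_fixes: pd.DataFrame, meta: pd.DataFrame
) -> pd.DataFrame:
    """Map tags to individuals and attach sex, age class, and period labels."""
    m = meta.set_index("tag_id")
    out = night_fixes.copy()
    out["individual"] = out["tag_id"].map(m["individual"])
    out["sex"] = out["tag_id"].map(m["sex"])
    hatch = m["hatch_date"]
    if hatch.dtype == object and len(hatch) and isinstance(hatch.iloc[0], str):
        hatch = pd.to_datetime(hatch).dt.date
    hatch_by_tag = hatch.to_dict()
    keys = out[["tag_id", "night_date"]].drop_duplicates()
    rows = []
    for tag, nd in keys.itertuples(index=False):
        per, yr = assign_period(nd)
        rows.append(
            {
                "tag_id": tag,
                "night_date": nd,
                "period": per,
                "period_year": yr,
                "age_class": assign_age_class(hatch_by_tag.get(tag), nd),
            }
        )
    labels = pd.DataFrame(rows)
    return out.merge(labels, on=["tag_id", "night_date"], how="left")


def apply_inclusion_rules(
    night_fixes: pd.DataFrame,
    min_fixes: int = 1000,
    min_nights: int = 25,
    exclusion_windows: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, InclusionReport]:
    """Night- and cell-level inclusion rules.

    Order: nights inside an individual's exclusion window are dropped
    first, then nights with <= ``min_fixes`` fixes (strictly more than
    1000 required), then individual-period cells with < ``min_nights``
    qualifying nights.
    """
    rep = InclusionReport(n_input_fixes=len(night_fixes))
    df = night_fixes
    nights0 = df.groupby(["individual", "night_date"], sort=False).ngroups
    rep.nights_input = nights0

    if exclusion_windows is not None and len(exclusion_windows):
        drop = pd.Series(False, index=df.index)
        for rec in exclusion_windows.itertuples(index=False):
            drop |= (
                (df["individual"] == rec.individual)
                & (df["night_date"] >= rec.start)
                & (df["night_date"] <= rec.end)
            )
        before = df.groupby(["individual", "night_date"], sort=False).ngroups
        df = df[~drop]
        rep.nights_excluded_window = before - df.groupby(
            ["individual", "night_date"], sort=False
        ).ngroups

    sizes = df.groupby(["individual", "night_date"], sort=False)["time_utc_ms"].transform("size")
    big = sizes > min_fixes
    before = df.groupby(["individual", "night_date"], sort=False).ngroups
    df = df[big]
    rep.nights_below_min_fixes = before - df.groupby(
        ["individual", "night_date"], sort=False
    ).ngroups

    nights = df[["individual", "night_date", "period", "period_year"]].drop_duplicates()
    cell_sizes = nights.groupby(["individual", "period", "period_year"]).size()
    bad_cells = cell_sizes[cell_sizes < min_nights]
    rep.cells_below_min_nights = len(bad_cells)
    if len(bad_cells):
        key = df.set_index(["individual", "period", "period_year"]).index
        mask = ~key.isin(bad_cells.index)
        before = df.groupby(["individual", "night_date"], sort=False).ngroups
        df = df[np.asarray(mask)]
        rep.nights_in_dropped_cells = before - df.groupby(
            ["individual", "night_date"], sort=False
        ).ngroups

    df = df.reset_index(drop=True)
    rep.nights_output = df.groupby(["individual", "night_date"], sort=False).ngroups if len(df) else 0
    rep.n_output_fixes = len(df)
    return df, rep


def preprocess(
    fixes: pd.DataFrame,
    meta: pd.DataFrame,
    std_max: float = 50.0,
    speed_max: float = 15.0,
    utc_offset_h: float = 2,
    start_hour: int = 17,
    end_hour: int = 6,
    min_fixes: int = 1000,
    min_nights: int = 25,
    exclusion_windows: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, InclusionReport]:
    """Full preprocessing chain from raw fixes to the retained night dataset."""
    filt, counts = filter_fixes(fixes, std_max=std_max, speed_max=speed_max)
    nights, n_day = segment_nights(filt, utc_offset_h, start_hour, end_hour)
    nights = attach_metadata(nights, meta)
    out, rep = apply_inclusion_rules(nights, min_fixes, min_nights, exclusion_windows)
    rep.n_input_fixes = len(fixes)
    rep.removed_std = counts["removed_std"]
    rep.removed_speed = counts["removed_speed"]
    rep.removed_daytime = n_day
    return out, rep
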