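"""Nightly movement indices: move/stop segmentation, max-displacement,
move-only total distance.

Stops are detected with a running-centroid rule: a maximal run of
consecutive fixes that all stay within ``stop_radius`` of the run's
running centroid, lasting at least ``stop_min_duration``, is a stop;
everything else is movement.  Max-displacement is the bee-line distance
from the night's first fix to its farthest fix.  Total distance sums
step lengths whose both endpoints are in move segments, so localization
jitter accumulated while perching does not inflate it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

KM = 1000.0


@dataclass
class Segment:
    mode: str          # "move" | "stop"
    start: int         # first fix index (inclusive)
    end: int           # last fix index (inclusive)
    duration_s: float
    centroid: tuple[float, float]
    radius_m: float | None = None


def segment_moves_stops(
    t_s: np.ndarray,
    x: np.ndarray,
    y: np.ndarray,
    stop_radius: float = 20.0,
    stop_min_duration: float = 60.0,
) -> list[Segment]:
    """Partition a night's fixes into alternating move/stop segments."""
    n = len(t_s)
    if n == 0:
        return []
    if n == 1:
        return [Segment("stop", 0, 0, 0.0, (float(x[0]), float(y[0])), 0.0)]

    labels = np.zeros(n, dtype=bool)  # True = stop
    i = 0
    while i < n:
        cx, cy = x[i], y[i]
        j = i + 1
        count = 1
        while j < n:
            if np.hypot(x[j] - cx, y[j] - cy) <= stop_radius:
                count += 1
                cx += (x[j] - cx) / count
                cy += (y[j] - cy) / count
                j += 1
            else:
                break
        if t_s[j - 1] - t_s[i] >= stop_min_duration:
            labels[i:j] = True
            i = j
        else:
            i += 1
    segments: list[Segment] = []
    start = 0
    for k in range(1, n + 1):
        if k == n or labels[k] != labels[start]:
            mode = "stop" if labels[start] else "move"
            xs, ys = x[start:k], y[start:k]
            cx, cy = float(xs.mean()), float(ys.mean())
            seg = Segment(
                mode,
                start,
                k - 1,
                float(t_s[k - 1] - t_s[start]),
                (cx, cy),
                float(np.hypot(xs - cx, ys - cy).max()) if mode == "stop" else None,
            )
            segments.append(seg)
            start = k
    return segments


def stop_labels(segments: list[Segment], n: int) -> np.ndarray:
    lab = np.zeros(n, dtype=bool)
    for s in segments:
        if s.mode == "stop":
            lab[s.start : s.end + 1] = True
    return lab


def max_displacement(x: np.ndarray, y: np.ndarray) -> float:
    """Bee-line distance (km) from the first fix to the farthest fix."""
    if len(x) == 0:
        raise ValueError("empty track")
    return float(np.hypot(x - x[0], y - y[0]).max()) / KM


def total_distance(
    x: np.ndarray, y: np.ndarray, is_stop: np.ndarray
) -> float:
    """Sum of step lengths (km) where both endpoints are move-labeled."""
    if len(x) < 2:
        return 0.0
    move = ~is_stop
    both = move[:-1] & move[1:]
    steps = np.hypot(np.diff(x), np.diff(y))
    return float(steps[both].sum()) / KM


def night_indices(
    t_s: np.ndarray,
    x: np.ndarray,
    y: np.ndarray,
    stop_radius: float = 20.0,
    stop_min_duration: float = 60.0,
) -> dict:
    segs = segment_moves_stops(t_s, x, y, stop_radius, stop_min_duration)
    lab = stop_labels(segs, len(t_s))
    return {
        "max_disp_km": max_displacement(x, y),
        "total_dist_km": total_distance(x, y, lab),
        "n_fixes": len(t_s),
        "n_stop_fixes": int(lab.sum()),
        "stop_labels": lab,
        "segments": segs,
    }


def build_index_table(
    dataset: pd.DataFrame,
    stop_radius: float = 20.0,
    stop_min_duration: float = 60.0,
    keep_stop_labels: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """One index row per retained individual-night, plus cell summaries.

    ``dataset`` is the preprocessed fix table (individual, night_date,
    period, time_utc_ms, x_m, y_m, ...).  When ``keep_stop_labels`` the
    returned night table is accompanied by a per-fix stop flag written
    back onto a copy of the dataset (used by the home-range stage).
    """
    rows = []
    flags = np.zeros(len(dataset), dtype=bool) if keep_stop_labels else None
    if len(dataset):
        dataset = dataset.sort_values(
            ["individual", "night_date", "time_utc_ms"], kind="mergesort"
        ).reset_index(drop=True)
        for (ind, nd), grp in dataset.groupby(["individual", "night_date"], sort=False):
            t = grp["time_utc_ms"].to_numpy() / 1000.0
            res = night_indices(
                t,
                grp["x_m"].to_numpy(),
                grp["y_m"].to_numpy(),
                stop_radius,
                stop_min_duration,
            )
            if flags is not None:
                flags[grp.index[0] : grp.index[-1] + 1] = res["stop_labels"]
            first = grp.iloc[0]
            rows.append(
                {
                    "individual": ind,
                    "night_date": nd,
                    "period": first.get("period"),
                    "period_year": first.get("period_year"),
                    "age_class": first.get("age_class"),
                    "sex": first.get("sex"),
                    "max_disp_km": res["max_disp_km"],
                    "total_dist_km": res["total_dist_km"],
                    "n_fixes": res["n_fixes"],
                    "n_stop_fixes": res["n_stop_fixes"],
                }
            )
    cols = [
        "individual", "night_date", "period", "period_year", "age_class",
        "sex", "max_disp_km", "total_dist_km", "n_fixes", "n_stop_fixes",
    ]
    table = pd.DataFrame(rows, columns=cols)
    if len(table):
        summary = (
            table.groupby(["individual", "period", "period_year"], dropna=False)
            .agg(
                n_nights=("night_date", "size"),
                mean_max_disp_km=("max_disp_km", "mean"),
                mean_total_dist_km=("total_dist_km", "mean"),
                age_class=("age_class", "first"),
                sex=("sex", "first"),
            )
            .reset_index()
        )
    else:
        summary = pd.DataFrame(
            columns=["individual", "period", "period_year", "n_nights",
                     "mean_max_disp_km", "mean_total_dist_km", "age_class", "sex"]
        )
    if keep_stop_labels:
        ds = dataset.copy()
        ds["is_stop"] = flags
        return table, summary, ds
    return table, summary
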