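"""Per-trajectory summaries and quality filtering.

Each trajectory is collapsed to one row aggregating its movement (net and
gross displacement, step-length statistics, mean speed, turning-angle
statistics) and its morphology (mean, median, SD and IQR of each descriptor
over the trajectory's detections — averaging over the trajectory mitigates
per-frame segmentation shape errors).

The quality filter removes artefacts such as slowly drifting debris by
requiring a minimum net displacement, duration, detection rate and median
step length.  Default thresholds are 50 μm, 0.2 s, 80% and 2 μm; e.g. a
trajectory spanning 10 frames must be detected on at least 8 of them.
Boundary semantics are fixed: net displacement, duration and detection rate
are inclusive (``>=``), the median step length is strict (``> 2 μm``).
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .morphology import MORPHOLOGY_DESCRIPTORS

#: summary statistics computed per morphology descriptor
_MORPH_STATS = ("mean", "median", "sd", "iqr")


def min_detections_for_rate(span_frames: int, rate: float = 0.8) -> int:
    """Minimum detections for a trajectory spanning ``span_frames`` frames
    to reach a detection rate of ``rate`` (e.g. 10 frames at 80% → 8)."""
    if span_frames < 1:
        raise ValueError(f"span_frames must be >= 1, got {span_frames}")
    return int(math.ceil(rate * span_frames - 1e-9))


def _iqr(v: np.ndarray) -> float:
    return float(np.percentile(v, 75) - np.percentile(v, 25))


def _summarize_one(group: pd.DataFrame, fps: float, scale: float) -> dict:
    frames = group["frame"].to_numpy()
    x = group["x"].to_numpy(dtype=float)
    y = group["y"].to_numpy(dtype=float)
    n = len(group)
    first, last = int(frames.min()), int(frames.max())
    span = last - first + 1
    duration = (last - first) / fps
    steps = group["step_length"].to_numpy(dtype=float)
    steps = steps[~np.isnan(steps)]
    turns = group["turning_angle"].to_numpy(dtype=float)
    turns = turns[~np.isnan(turns)]
    net = float(np.hypot(x[-1] - x[0], y[-1] - y[0])) * scale
    gross = float(np.nansum(group["step_length"].to_numpy(dtype=float)))
    rec = {
        "id": group["id"].iloc[0],
        "video": group["video"].iloc[0],
        "traj_id": group["traj_id"].iloc[0],
        "n_detections": n,
        "first_frame": first,
        "last_frame": last,
        "duration": duration,
        "detection_rate": n / span,
        "net_displacement": net,
        "gross_displacement": gross,
        "median_step": float(np.median(steps)) if len(steps) else np.nan,
        "mean_step": float(np.mean(steps)) if len(steps) else np.nan,
        "sd_step": float(np.std(steps, ddof=1)) if len(steps) > 1 else np.nan,
        "mean_speed": gross / duration if duration > 0 else np.nan,
        "mean_turning": float(np.mean(turns)) if len(turns) else np.nan,
        "sd_turning": float(np.std(turns, ddof=1)) if len(turns) > 1 else np.nan,
    }
    for col in MORPHOLOGY_DESCRIPTORS:
        if col not in group.columns:
            continue
        v = group[col].to_numpy(dtype=float)
        v = v[~np.isnan(v)]
        rec[f"{col}_mean"] = float(np.mean(v)) if len(v) else np.nan
        rec[f"{col}_median"] = float(np.median(v)) if len(v) else np.nan
        rec[f"{col}_sd"] = float(np.std(v, ddof=1)) if len(v) > 1 else np.nan
        rec[f"{col}_iqr"] = _iqr(v) if len(v) else np.nan
    return rec


def summarize_trajectories(
    traj_table: pd.DataFrame, fps: float, scale: float
) -> pd.DataFrame:
    """One summary row per trajectory id.

    Variability columns use the sample standard deviation (NaN when fewer
    than two values contribute); the interquartile range is emitted
    alongside for the morphology descriptors.  An empty input yields an
    empty output.
    """
    if traj_table.empty:
        return pd.DataFrame(
            columns=[
                "id", "video", "traj_id", "n_detections", "first_frame",
                "last_frame", "duration", "detection_rate", "net_displacement",
                "gross_displacement", "median_step", "mean_step", "sd_step",
                "mean_speed", "mean_turning", "sd_turning",
            ]
            + [f"{c}_{s}" for c in MORPHOLOGY_DESCRIPTORS for s in _MORPH_STATS]
        )
    rows = [
        _summarize_one(group, fps, scale)
        for _, group in traj_table.groupby(["video", "traj_id"], sort=True)
    ]
    return pd.DataFrame(rows).reset_index(drop=True)


def filter_data(
    summaries: pd.DataFrame,
    min_net: float = 50.0,
    min_duration: float = 0.2,
    min_detection_rate: float = 0.8,
    min_median_step: float = 2.0,
) -> pd.DataFrame:
    """Keep trajectories that satisfy all four quality thresholds.

    net_displacement >= min_net (μm), duration >= min_duration (s),
    detection_rate >= min_detection_rate, median_step > min_median_step
    (μm; strict).  A NaN median step (single-detection trajectory) fails
    the strict comparison and is removed unless ``min_median_step`` is
    negative and NaNs cannot occur.
    """
    for name, v in (
        ("min_net", min_net),
        ("min_duration", min_duration),
        ("min_detection_rate", min_detection_rate),
    ):
        if v < 0:
            raise ValueError(f"{name} must be >= 0, got {v}")
    if summaries.empty:
        return summaries.copy()
    step_ok = summaries["median_step"] > min_median_step
    if min_median_step < 0:
        # a negative threshold disables the step criterion entirely, so
        # single-detection trajectories (NaN median) are kept too
        step_ok = step_ok | summaries["median_step"].isna()
    keep = (
        (summaries["net_displacement"] >= min_net)
        & (summaries["duration"] >= min_duration)
        & (summaries["detection_rate"] >= min_detection_rate)
        & step_ok.fillna(False)
    )
    return summaries.loc[keep].reset_index(drop=True)
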