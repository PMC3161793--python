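"""Behavioral feature extraction from raw trials.

Movement onset/end are detected on the pointer trajectory with a
1.5 deg/s speed cutoff (centered finite differences after a light
3-sample moving-average smooth).  Decision time is the latency between
stimulus presentation and movement onset; movement time the
onset-to-end interval.  Localizations are normalized per subject by
subtracting the mean of that subject's unisensory responses (pooled
over both tasks), which removes the sensorimotor bias since the design
positions average to zero.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .synthetic_data import Trajectory

__all__ = [
    "OnsetNotFound",
    "V_THRESHOLD",
    "detect_movement_onset",
    "detect_movement_end",
    "extract_features",
    "normalize_localizations",
    "summarize_conditions",
]

V_THRESHOLD = 1.5  # deg/s


class OnsetNotFound(ValueError):
    """No trajectory sample crosses the velocity threshold."""


def _speed(traj: Trajectory) -> np.ndarray:
    pos = traj.positions
    if pos.size < 3:
        raise ValueError("trajectory needs at least 3 samples")
    dt = float(np.mean(np.diff(traj.times)))
    if dt <= 0:
        raise ValueError("non-increasing time grid")
    kernel = np.ones(3) / 3.0
    smooth = np.convolve(pos, kernel, mode="same")
    smooth[0], smooth[-1] = pos[0], pos[-1]
    return np.abs(np.gradient(smooth, dt))


def detect_movement_onset(traj: Trajectory, v_thresh: float = V_THRESHOLD) -> float:
    """Time of the first sample whose smoothed speed exceeds ``v_thresh``."""
    speed = _speed(traj)
    above = np.nonzero(speed > v_thresh)[0]
    if above.size == 0:
        raise OnsetNotFound(f"speed never exceeds {v_thresh} deg/s")
    return float(traj.times[above[0]])


def detect_movement_end(traj: Trajectory, v_thresh: float = V_THRESHOLD,
                        hold_window: float = 0.2) -> float:
    """First time after peak speed at which speed falls and stays below
    ``v_thresh`` for ``hold_window`` seconds."""
    speed = _speed(traj)
    if (speed > v_thresh).sum() == 0:
        raise OnsetNotFound(f"speed never exceeds {v_thresh} deg/s")
    dt = float(np.mean(np.diff(traj.times)))
    peak = int(np.argmax(speed))
    win = max(int(round(hold_window / dt)), 1)
    below = speed <= v_thresh
    for i in range(peak, speed.size):
        if below[i] and below[i:min(i + win, speed.size)].all():
            return float(traj.times[i])
    raise OnsetNotFound("speed never settles below threshold after the peak")


def extract_features(traj: Trajectory, stimulus_time: float = 0.0,
                     v_thresh: float = V_THRESHOLD):
    """(decision_time, movement_time, endpoint) from one trajectory.

    Endpoint is the median position over the post-movement hold phase.
    """
    onset = detect_movement_onset(traj, v_thresh)
    end = detect_movement_end(traj, v_thresh)
    hold = traj.positions[traj.times >= end]
    endpoint = float(np.median(hold)) if hold.size else float(traj.positions[-1])
    return onset - stimulus_time, end - onset, endpoint


def normalize_localizations(table: pd.DataFrame) -> pd.DataFrame:
    """Add ``response_norm``: raw response minus the subject's unisensory mean.

    The unisensory mean pools both tasks (the sensorimotor bias is a
    property of the subject, not of the task).  Raises if any subject
    lacks unisensory trials.
    """
    out = table.copy()
    uni = out[out["mode"] == 0]
    missing = set(out["subject"].unique()) - set(uni["subject"].unique())
    if missing:
        raise ValueError(f"subjects without unisensory trials: {sorted(missing)}")
    offsets = uni.groupby("subject")["response_raw"].mean()
    out["response_norm"] = (
        out["response_raw"] - out["subject"].map(offsets).to_numpy())
    return out


def summarize_conditions(table: pd.DataFrame) -> pd.DataFrame:
    """Per-condition summary: mean/SD of normalized localization and
    decision time for each (task, mode, xp, offset) cell.

    Two dispersion summaries are reported per cell: the pooled SD over
    all trials and the across-subject average of per-subject SDs.
    """
    df = table.copy()
    df["offset"] = df["xs"] - df["xp"]
    keys = ["task", "mode", "xp", "offset"]
    df["offset"] = df["offset"].fillna(np.inf)  # sentinel marker for grouping

    def per_cell(g):
        by_subj = g.groupby("subject")
        return pd.Series({
            "n": len(g),
            "response_mean": g["response_norm"].mean(),
            "response_sd": g["response_norm"].std(ddof=1),
            "response_sd_subject_avg": by_subj["response_norm"].std(ddof=1).mean(),
            "time_mean": g["decision_time"].mean(),
            "time_sd": g["decision_time"].std(ddof=1),
            "time_sd_subject_avg": by_subj["decision_time"].std(ddof=1).mean(),
        })

    summary = (df.groupby(keys, dropna=False)
                 .apply(per_cell, include_groups=False)
                 .reset_index())
    summary["offset"] = summary["offset"].replace(np.inf, np.nan)
    return summary
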