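"""Movement features: path length, target-proximity ratio, force direction,
normalized decision readouts, and last-100-ms intertrial variability.

The decision readouts map each 1-ms sample to a score in (0, 1) that is 0.5
at the neutral point between the two choice targets:

* free movement -> distance share d_long / (d_long + d_short), the logistic
  of the log proximity ratio (values > 0.5 mean the hand is closer to the
  short target);
* hold -> logistic((theta - 90 deg) / s) of the force direction theta, with
  gain s = 7.5 deg by default (a quarter of the 30-deg target separation);
  forces aimed above the 90-deg boundary push toward the short target.

Both are two-option softmax transforms: monotone, bounded, and neutral at
0.5, which is the contract downstream decoding relies on.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .core_io import Geometry, Trajectory, euclidean_distance

__all__ = [
    "path_length", "proximity_ratio", "force_direction", "normalize_readout",
    "intertrial_sd", "readout_matrix",
]

#: logistic gain (degrees) for the force-direction readout
FORCE_GAIN_DEG = 7.5


def path_length(traj: Trajectory, window: tuple[float, float] | None = None) -> float:
    """Summed Euclidean segment length (cm) of the trajectory inside ``window``.

    ``window`` is (t_from, t_to) in ms relative to tone onset; ``None`` uses
    the whole trajectory.  An empty window returns 0 with a warning.
    """
    tj = traj if window is None else traj.window(*window)
    if len(tj) == 0:
        warnings.warn("path_length: empty window")
        return 0.0
    return float(np.hypot(np.diff(tj.x), np.diff(tj.y)).sum())


def proximity_ratio(point, geometry: Geometry, orientation: str = "long_over_short") -> float:
    """Target-distance ratio at ``point``; > 1 means closer to the short target.

    Returns d_long / d_short (so the figure convention ">1 <=> closer to
    short" holds); pass orientation="short_over_long" to flip.  A point at a
    target center returns +/- inf.
    """
    d_short = euclidean_distance(point, geometry.short_target_xy)
    d_long = euclidean_distance(point, geometry.long_target_xy)
    if orientation == "long_over_short":
        num, den = d_long, d_short
    elif orientation == "short_over_long":
        num, den = d_short, d_long
    else:
        raise ValueError(f"unknown orientation {orientation!r}")
    if den == 0.0:
        return np.inf
    return num / den


def force_direction(fx, fy):
    """Four-quadrant angle (degrees in (-180, 180]) of the force vector(s).

    The zero vector has no direction and maps to NaN.
    """
    fx = np.asarray(fx, float)
    fy = np.asarray(fy, float)
    ang = np.degrees(np.arctan2(fy, fx))
    ang = np.where((fx == 0) & (fy == 0), np.nan, ang)
    if ang.ndim == 0:
        return float(ang)
    return ang


def normalize_readout(value, kind: str, geometry: Geometry | None = None,
                      gain_deg: float = FORCE_GAIN_DEG):
    """Two-option softmax readout in (0, 1), neutral value mapping to 0.5.

    kind "ratio": input is the proximity ratio d_long/d_short; returned score
    is d_long/(d_long+d_short) = ratio/(1+ratio).  kind "force": input is the
    force angle in degrees; returned score is logistic((theta - neutral)/gain)
    with neutral = 90 deg for the default geometry.  NaN propagates.
    """
    v = np.asarray(value, float)
    if kind == "ratio":
        out = v / (1.0 + v)
        out = np.where(np.isinf(v), 1.0, out)
    elif kind == "force":
        neutral = 90.0 if geometry is None else geometry.neutral_angle_deg
        out = 1.0 / (1.0 + np.exp(-(v - neutral) / gain_deg))
    else:
        raise ValueError(f"unknown readout kind {kind!r}")
    if out.ndim == 0:
        return float(out)
    return out


def intertrial_sd(trajectories: list[Trajectory], trials: pd.DataFrame,
                  last_ms: int = 100, combine: str = "mean") -> pd.DataFrame:
    """Per-duration intertrial positional SD over the final ``last_ms`` of each trial.

    For every 1-ms time point in the window leading up to target arrival
    (time-locked to each trial's final sample), the SD of x and of y across
    trials is computed, then averaged over the window and over the two
    coordinates (``combine="mean"``; ``"rss"`` uses the root sum of squares).
    Durations with a single trial yield NaN with a warning.
    """
    key_dur = {(r.subject_id, r.block, r.trial): r.duration_ms
               for r in trials.itertuples(index=False)}
    by_dur: dict[float, list[np.ndarray]] = {}
    for tj in trajectories:
        dur = key_dur.get(tj.trial_key)
        if dur is None:
            continue
        if len(tj) < last_ms:
            continue
        seg = np.column_stack([tj.x[-last_ms:], tj.y[-last_ms:]])
        by_dur.setdefault(dur, []).append(seg)
    rows = []
    for dur in sorted(by_dur):
        stack = np.stack(by_dur[dur])          # (n_trials, last_ms, 2)
        if stack.shape[0] < 2:
            warnings.warn(f"intertrial_sd: single trial for duration {dur}")
            rows.append({"duration_ms": dur, "intertrial_sd_cm": np.nan,
                         "n_trials": stack.shape[0]})
            continue
        sd = stack.std(axis=0, ddof=1)         # (last_ms, 2) per-ms, per-coord
        if combine == "mean":
            val = sd.mean()
        elif combine == "rss":
            val = np.sqrt((sd**2).sum(axis=1)).mean() / np.sqrt(2)
        else:
            raise ValueError(f"unknown combine {combine!r}")
        rows.append({"duration_ms": dur, "intertrial_sd_cm": float(val),
                     "n_trials": stack.shape[0]})
    return pd.DataFrame(rows)


def trial_readout_series(traj: Trajectory, condition: str, geometry: Geometry,
                         gain_deg: float = FORCE_GAIN_DEG) -> np.ndarray:
    """Normalized readout at every tone-phase sample of one trial."""
    tone = traj.phase_window("tone") if "tone" in traj.phase else traj.phase_window("encoding")
    if condition == "free":
        d_short = np.hypot(tone.x - geometry.short_target_xy[0],
                           tone.y - geometry.short_target_xy[1])
        d_long = np.hypot(tone.x - geometry.long_target_xy[0],
                          tone.y - geometry.long_target_xy[1])
        with np.errstate(divide="ignore"):
            ratio = np.where(d_short > 0, d_long / d_short, np.inf)
        return normalize_readout(ratio, "ratio")
    ang = force_direction(tone.fx, tone.fy)
    return normalize_readout(np.asarray(ang, float), "force", geometry, gain_deg)


def readout_matrix(trajectories: list[Trajectory], trials: pd.DataFrame,
                   geometry: Geometry, window_ms: int = 1000, step_ms: int = 1,
                   align: str = "offset") -> tuple[pd.DataFrame, np.ndarray, np.ndarray]:
    """Trial x time matrix of normalized readouts aligned to tone offset.

    Columns sample the last ``window_ms`` of the tone every ``step_ms``;
    column times are negative offsets (t = -1 is 1 ms before offset).  With
    align="onset" the first ``window_ms`` after tone onset is used instead
    (the pre-onset variant passes the warm-up phase through the same path).
    Trials whose tone is shorter than the window are excluded and counted.

    Returns (retained trial rows, times_ms, matrix).
    """
    # sample indices within the window, chosen so the last column is always
    # the final sample (1 ms before offset for align="offset")
    idx = np.arange(window_ms - 1, -1, -step_ms)[::-1]
    times = idx - window_ms if align == "offset" else idx
    rows, mats, n_skip = [], [], 0
    traj_by_key = {tj.trial_key: tj for tj in trajectories}
    for rec in trials.itertuples(index=False):
        key = (rec.subject_id, rec.block, rec.trial)
        tj = traj_by_key.get(key)
        if tj is None:
            n_skip += 1
            continue
        series = trial_readout_series(tj, rec.condition, geometry)
        if len(series) < window_ms:
            n_skip += 1
            continue
        base = series[len(series) - window_ms:] if align == "offset" else series[:window_ms]
        mats.append(base[idx])
        rows.append(rec._asdict() if hasattr(rec, "_asdict") else dict(rec))
    if n_skip:
        warnings.warn(f"readout_matrix: {n_skip} trial(s) excluded "
                      f"(no trajectory or tone shorter than window)")
    mat = np.asarray(mats) if mats else np.empty((0, len(times)))
    return pd.DataFrame(rows), times, mat
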