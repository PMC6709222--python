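"""Temporal-reproduction scoring and encoding/reproduction path similarity.

The reproduced duration of a trial is the time between movement start and
movement stop in the reproduction phase (5 cm/s threshold crossings, with a
200-ms stationary tail required before a stop counts, so micro-pauses do
not split the movement).  Central tendency (the Vierordt effect) is
quantified by the OLS slope of reproduced on presented duration: slope 1 is
veridical, slope 0 is total regression to the mean.  Variability is the
per-duration CV (sample SD / mean of reproduced durations), flat across
durations under scalar timing.

Path similarity between the encoding and reproduction movements uses the
discrete Frechet distance: the minimum over monotone couplings of two point
sequences of the maximum coupled pair distance (the shortest leash that
lets two walkers traverse both paths without backtracking), computed by the
Eiter-Mannila dynamic program.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.stats import linregress

from .change_of_mind import speed_profile
from .core_io import Trajectory
from .observer import SimulatedDataset

__all__ = ["reproduced_duration", "central_tendency_slope", "reproduction_cv",
           "discrete_frechet", "path_similarity", "resample_arclength"]

STOP_TAIL_MS = 200


def reproduced_duration(traj: Trajectory, v_thresh: float = 5.0) -> float:
    """Movement stop minus movement start (ms) within the reproduction phase.

    Start is the first sample with speed above ``v_thresh``; stop is the
    start of the final sub-threshold period lasting at least 200 ms.
    Returns NaN (with a warning) if the hand never moves.
    """
    rep = traj.phase_window("reproduction")
    if len(rep) == 0:
        warnings.warn("reproduced_duration: no reproduction phase")
        return np.nan
    speed = speed_profile(rep)
    moving = speed > v_thresh
    if not moving.any():
        warnings.warn("reproduced_duration: speed never exceeded threshold")
        return np.nan
    i_start = int(np.argmax(moving))
    t_start = rep.t_ms[i_start]
    # stop = start of the final sub-threshold run lasting >= STOP_TAIL_MS
    # (shorter pauses are micro-pauses and do not end the movement)
    stop_idx = int(np.nonzero(moving)[0][-1]) + 1
    for (a, b) in reversed(_subthreshold_runs(moving)):
        if b - a >= STOP_TAIL_MS and a > i_start:
            stop_idx = a
            break
    return float(rep.t_ms[min(stop_idx, len(rep) - 1)] - t_start)


def _subthreshold_runs(moving: np.ndarray) -> list[tuple[int, int]]:
    """[start, end) index pairs of consecutive still samples."""
    still = ~moving
    edges = np.diff(still.astype(int))
    starts = list(np.nonzero(edges == 1)[0] + 1)
    ends = list(np.nonzero(edges == -1)[0] + 1)
    if still[0]:
        starts = [0] + starts
    if still[-1]:
        ends = ends + [len(still)]
    return list(zip(starts, ends))


def central_tendency_slope(presented_ms, reproduced_ms) -> tuple[float, float]:
    """OLS slope and intercept of reproduced on presented duration."""
    x = np.asarray(presented_ms, float)
    y = np.asarray(reproduced_ms, float)
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if len(np.unique(x)) < 2:
        raise ValueError("need at least 2 distinct presented durations")
    res = linregress(x, y)
    return float(res.slope), float(res.intercept)


def reproduction_cv(trials: pd.DataFrame, per_duration: bool = True):
    """Sample CV (SD / mean) of reproduced durations, per tested interval.

    Returns a DataFrame (duration_ms, cv, n) when ``per_duration`` else a
    single pooled CV.  Durations with fewer than 2 valid reproductions, or
    non-positive mean, yield NaN.
    """
    df = trials.dropna(subset=["reproduced_ms"])
    if not per_duration:
        v = df["reproduced_ms"].to_numpy(float)
        return float(v.std(ddof=1) / v.mean()) if len(v) > 1 and v.mean() > 0 else np.nan
    rows = []
    for dur, g in df.groupby("duration_ms", sort=True):
        v = g["reproduced_ms"].to_numpy(float)
        if len(v) < 2 or v.mean() <= 0:
            cv = np.nan
        else:
            cv = v.std(ddof=1) / v.mean()
        rows.append({"duration_ms": dur, "cv": cv, "n": len(v)})
    return pd.DataFrame(rows)


def discrete_frechet(P, Q) -> float:
    """Discrete Frechet distance between two polylines (Eiter-Mannila DP).

    dF = min over monotone couplings (start at the first points, end at the
    last, advance by one in either or both sequences) of the maximum coupled
    pairwise distance.  Symmetric; zero iff the curves admit a coupling of
    coincident points.
    """
    P = np.atleast_2d(np.asarray(P, float))
    Q = np.atleast_2d(np.asarray(Q, float))
    if len(P) == 0 or len(Q) == 0:
        raise ValueError("polylines must be non-empty")
    d = np.hypot(P[:, None, 0] - Q[None, :, 0], P[:, None, 1] - Q[None, :, 1])
    n, m = d.shape
    ca = np.empty((n, m))
    ca[0, 0] = d[0, 0]
    for j in range(1, m):
        ca[0, j] = max(ca[0, j - 1], d[0, j])
    for i in range(1, n):
        ca[i, 0] = max(ca[i - 1, 0], d[i, 0])
        row_prev = ca[i - 1]
        row = ca[i]
        for j in range(1, m):
            row[j] = max(min(row_prev[j], row_prev[j - 1], row[j - 1]), d[i, j])
    return float(ca[-1, -1])


def resample_arclength(xy: np.ndarray, n_points: int = 100) -> np.ndarray:
    """Resample a polyline to ``n_points`` equally spaced in arc length."""
    xy = np.asarray(xy, float)
    seg = np.hypot(*np.diff(xy, axis=0).T)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    if s[-1] == 0.0:
        return np.repeat(xy[:1], n_points, axis=0)
    si = np.linspace(0.0, s[-1], n_points)
    return np.column_stack([np.interp(si, s, xy[:, 0]), np.interp(si, s, xy[:, 1])])


def path_similarity(dataset: SimulatedDataset | tuple, n_points: int = 100) -> pd.DataFrame:
    """Per-trial discrete Frechet distance between encoding and reproduction paths.

    Only free-encoding trials have an encoding movement; both phases are
    resampled to a common ``n_points`` arc-length grid so trials of
    different durations are comparable.  Trials missing either phase are
    skipped with a warning.  Returns one row per scored trial
    (subject_id, duration_ms, frechet_cm).
    """
    if isinstance(dataset, SimulatedDataset):
        trials, trajs = dataset.trials, dataset.trajectories
    else:
        trials, trajs = dataset
    by_key = {tj.trial_key: tj for tj in trajs}
    rows, n_skip = [], 0
    free = trials[trials["condition"] == "free"]
    for rec in free.itertuples(index=False):
        tj = by_key.get((rec.subject_id, rec.block, rec.trial))
        if tj is None:
            n_skip += 1
            continue
        enc = tj.phase_window("encoding")
        rep = tj.phase_window("reproduction")
        if len(enc) == 0 or len(rep) == 0:
            n_skip += 1
            continue
        p = resample_arclength(enc.positions(), n_points)
        q = resample_arclength(rep.positions(), n_points)
        rows.append({"subject_id": rec.subject_id, "duration_ms": rec.duration_ms,
                     "frechet_cm": discrete_frechet(p, q)})
    if n_skip:
        warnings.warn(f"path_similarity: {n_skip} trial(s) skipped (missing phase)")
    return pd.DataFrame(rows)
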