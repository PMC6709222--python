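"""Change-of-mind detection from response-reach trajectories.

A change of mind (COM) is a response reach that first heads toward one
choice target and then redirects to the other.  Detection uses the angle
theta between two vectors: V1 from movement initiation (first sample after
tone offset where hand speed exceeds 5 cm/s) to the point of maximum speed,
and V2 from that point to the chosen target.  Straight ballistic reaches
give theta near 0; redirected reaches give large theta.  Trials with
theta > 40 deg (default criterion) are flagged as COM, and the direction is
labeled by the final choice: a COM ending at the long target is
short_to_long, and vice versa.

Speed is computed from central differences of position after a 5-ms median
prefilter, so single-sample position spikes do not create spurious
velocity maxima; ties in maximum speed break to the earliest sample.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import median_filter

from .core_io import Geometry, Trajectory

__all__ = ["ComEvent", "speed_profile", "movement_onset", "com_angle",
           "detect_com", "com_rates"]

THETA_CRIT_DEG = 40.0
V_THRESH_CM_S = 5.0


class NoMovementError(RuntimeError):
    """Hand speed never exceeded the onset threshold."""


@dataclass
class ComEvent:
    trial_key: tuple
    theta_deg: float
    is_com: bool
    direction: str          # short_to_long | long_to_short | none
    t_init_ms: float
    t_vmax_ms: float
    audit_flag: str = ""    # nonempty when the angle was undefined


def speed_profile(traj: Trajectory, median_ms: int = 5) -> np.ndarray:
    """Hand speed (cm/s) per sample: median-prefiltered central differences."""
    if len(traj) < 3:
        return np.zeros(len(traj))
    x = median_filter(traj.x, size=median_ms, mode="nearest")
    y = median_filter(traj.y, size=median_ms, mode="nearest")
    vx = np.gradient(x) * 1000.0   # cm/ms -> cm/s
    vy = np.gradient(y) * 1000.0
    return np.hypot(vx, vy)


def movement_onset(traj: Trajectory, v_thresh: float = V_THRESH_CM_S,
                   search_from: float | None = None) -> int:
    """Time (ms) of the first sample at/after ``search_from`` with speed > v_thresh.

    ``search_from`` defaults to the start of the response phase (tone offset).
    Raises ``NoMovementError`` if the threshold is never exceeded.
    """
    speed = speed_profile(traj)
    if search_from is None:
        resp = np.nonzero(traj.phase == "response")[0]
        search_from = traj.t_ms[resp[0]] if len(resp) else traj.t_ms[0]
    mask = (traj.t_ms >= search_from) & (speed > v_thresh)
    hits = np.nonzero(mask)[0]
    if len(hits) == 0:
        raise NoMovementError(f"speed never exceeded {v_thresh} cm/s after t={search_from}")
    return int(traj.t_ms[hits[0]])


def com_angle(traj: Trajectory, chosen_target, v_thresh: float = V_THRESH_CM_S
              ) -> tuple[float, int, int]:
    """Angle theta (deg, in [0, 180]) between the init->vmax and vmax->target vectors.

    Returns (theta_deg, t_init_ms, t_vmax_ms); theta is NaN when either
    vector has zero length.  The max-speed sample is the global maximum over
    the response portion at/after movement initiation, earliest on ties.
    """
    t_init = movement_onset(traj, v_thresh)
    speed = speed_profile(traj)
    after = traj.t_ms >= t_init
    resp = after & np.isin(traj.phase, ["response", "reproduction"])
    if not resp.any():
        resp = after
    idx_pool = np.nonzero(resp)[0]
    i_vmax = idx_pool[np.argmax(speed[idx_pool])]   # argmax -> earliest on ties
    i_init = int(np.nonzero(traj.t_ms == t_init)[0][0])
    p_init = np.array([traj.x[i_init], traj.y[i_init]])
    p_vmax = np.array([traj.x[i_vmax], traj.y[i_vmax]])
    v1 = p_vmax - p_init
    v2 = np.asarray(chosen_target, float) - p_vmax
    n1, n2 = np.linalg.norm(v1), np.linalg.norm(v2)
    if n1 == 0 or n2 == 0:
        return (np.nan, t_init, int(traj.t_ms[i_vmax]))
    c = np.clip(np.dot(v1, v2) / (n1 * n2), -1.0, 1.0)
    return (float(np.degrees(np.arccos(c))), t_init, int(traj.t_ms[i_vmax]))


def detect_com(traj: Trajectory, geometry: Geometry, choice: str,
               theta_crit: float = THETA_CRIT_DEG,
               v_thresh: float = V_THRESH_CM_S) -> ComEvent:
    """Classify one trial as change-of-mind or not via the two-vector angle."""
    target = geometry.target(choice)
    theta, t_init, t_vmax = com_angle(traj, target, v_thresh)
    if np.isnan(theta):
        return ComEvent(traj.trial_key, theta, False, "none", t_init, t_vmax,
                        audit_flag="zero-length vector")
    is_com = theta > theta_crit
    if is_com:
        direction = "short_to_long" if choice == "long" else "long_to_short"
    else:
        direction = "none"
    return ComEvent(traj.trial_key, theta, is_com, direction, t_init, t_vmax)


def com_rates(events: list[ComEvent], trials: pd.DataFrame) -> pd.DataFrame:
    """Per-duration proportions of COM trials in each direction.

    Denominators are the number of trials at each duration; proportions
    times denominators therefore sum to the number of detected COM events.
    """
    key_dur = {(r.subject_id, r.block, r.trial): r.duration_ms
               for r in trials.itertuples(index=False)}
    counts: dict[float, dict[str, float]] = {}
    for dur in sorted(set(key_dur.values())):
        counts[dur] = {"n": 0, "short_to_long": 0, "long_to_short": 0}
    for ev in events:
        dur = key_dur.get(tuple(ev.trial_key))
        if dur is None:
            continue
        counts[dur]["n"] += 1
        if ev.is_com:
            counts[dur][ev.direction] += 1
    rows = []
    for dur, c in counts.items():
        n = max(c["n"], 1)
        rows.append({"duration_ms": dur, "n_trials": c["n"],
                     "p_short_to_long": c["short_to_long"] / n,
                     "p_long_to_short": c["long_to_short"] / n})
    return pd.DataFrame(rows)
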