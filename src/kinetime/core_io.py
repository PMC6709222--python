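"""Domain types and table I/O for bisection / reproduction reaching experiments.

Coordinate conventions
----------------------
All positions are in centimetres in a frame whose origin is the trial's
start location, with +y pointing away from the body and angles measured in
degrees counterclockwise from the +x axis.  In the default rig geometry the
"short" and "long" choice targets sit on a 10 cm circle around the start at
105 deg and 75 deg respectively, so the perpendicular bisector of the two
targets is the 90 deg direction.  Time is in milliseconds; trajectories are
sampled at 1000 Hz (1-ms spacing).

Two plain-text table formats are defined:

* trial table:
  ``subject_id,experiment,block,trial,duration_ms,condition,start_x,start_y,choice,rt_ms,reproduced_ms``
* trajectory table (long format):
  ``subject_id,block,trial,t_ms,x,y,fx,fy,phase``

Both are comma-separated UTF-8 CSV with a mandatory header row and empty
fields for missing values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

EXPERIMENTS = ("bisection_free", "bisection_hold", "bisection_hold_twostart", "reproduction")
CHOICES = ("short", "long", "none")
PHASES = ("warmup", "tone", "response", "encoding", "reproduction")

TRIAL_COLUMNS = [
    "subject_id", "experiment", "block", "trial", "duration_ms", "condition",
    "start_x", "start_y", "choice", "rt_ms", "reproduced_ms",
]
TRAJ_COLUMNS = ["subject_id", "block", "trial", "t_ms", "x", "y", "fx", "fy", "phase"]


class FormatError(ValueError):
    """A table violates the documented file format (e.g. missing column)."""


class IntegrityError(ValueError):
    """A table parses but violates a data invariant (duplicates, gaps...)."""


def euclidean_distance(p: Sequence[float], q: Sequence[float]) -> float:
    """Euclidean distance between two 2-D points in cm.

    Raises ``ValueError`` on non-finite coordinates.
    """
    px, py = float(p[0]), float(p[1])
    qx, qy = float(q[0]), float(q[1])
    if not all(map(math.isfinite, (px, py, qx, qy))):
        raise ValueError("non-finite coordinates in euclidean_distance")
    return math.hypot(px - qx, py - qy)


def _polar(radius_cm: float, angle_deg: float) -> tuple[float, float]:
    a = math.radians(angle_deg)
    return (radius_cm * math.cos(a), radius_cm * math.sin(a))


@dataclass(frozen=True)
class Geometry:
    """Rig geometry: start location and the two choice targets.

    Defaults place both targets on a 10 cm circle around the start, the
    short target at 105 deg and the long target at 75 deg (counterclockwise
    from +x), each 0.5 cm in diameter.  The 90 deg direction is then the
    neutral boundary between the two targets.
    """

    start_xy: tuple[float, float] = (0.0, 0.0)
    short_angle_deg: float = 105.0
    long_angle_deg: float = 75.0
    radius_cm: float = 10.0
    target_radius: float = 0.25
    short_target_xy: tuple[float, float] = field(default=None)  # type: ignore[assignment]
    long_target_xy: tuple[float, float] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.short_target_xy is None:
            object.__setattr__(
                self, "short_target_xy",
                tuple(np.add(self.start_xy, _polar(self.radius_cm, self.short_angle_deg))))
        if self.long_target_xy is None:
            object.__setattr__(
                self, "long_target_xy",
                tuple(np.add(self.start_xy, _polar(self.radius_cm, self.long_angle_deg))))
        if self.short_target_xy == self.long_target_xy:
            raise ValueError("short and long targets must be distinct")

    @property
    def neutral_angle_deg(self) -> float:
        """Angle of the perpendicular bisector between the targets (90 deg by default)."""
        return 0.5 * (self.short_angle_deg + self.long_angle_deg)

    def target(self, choice: str) -> tuple[float, float]:
        if choice == "short":
            return self.short_target_xy
        if choice == "long":
            return self.long_target_xy
        raise ValueError(f"no target for choice {choice!r}")


@dataclass
class TrialRecord:
    """One behavioral trial of any of the four experiment variants."""

    subject_id: str
    experiment: str
    block: int
    trial: int
    duration_ms: float
    condition: str
    start_xy: tuple[float, float]
    choice: str
    rt_ms: float | None = None
    reproduced_ms: float | None = None

    def __post_init__(self) -> None:
        if self.experiment not in EXPERIMENTS:
            raise ValueError(f"unknown experiment {self.experiment!r}")
        if self.choice not in CHOICES:
            raise ValueError(f"unknown choice {self.choice!r}")
        if not self.duration_ms > 0:
            raise ValueError("duration_ms must be positive")
        if self.choice == "none" and self.experiment != "reproduction":
            raise ValueError('choice "none" is only valid for reproduction trials')
        if self.rt_ms is not None and self.rt_ms < 0:
            raise ValueError("rt_ms must be nonnegative")

    @property
    def key(self) -> tuple[str, int, int]:
        return (self.subject_id, self.block, self.trial)


@dataclass
class Trajectory:
    """1000-Hz 2-D hand position + force time series for one trial.

    ``t_ms`` is relative to tone onset; spacing is exactly 1 ms.
    """

    trial_key: tuple[str, int, int]
    t_ms: np.ndarray
    x: np.ndarray
    y: np.ndarray
    fx: np.ndarray
    fy: np.ndarray
    phase: np.ndarray  # array of str labels from PHASES

    def __post_init__(self) -> None:
        n = len(self.t_ms)
        for name in ("x", "y", "fx", "fy", "phase"):
            if len(getattr(self, name)) != n:
                raise ValueError("trajectory arrays must have equal length")
        dt = np.diff(self.t_ms)
        if n > 1 and not np.all(dt == 1):
            raise IntegrityError("trajectory samples must be 1 ms apart and strictly increasing")
        bad = set(np.unique(self.phase)) - set(PHASES)
        if bad:
            raise FormatError(f"unknown phase labels: {sorted(bad)}")
        if not (np.all(np.isfinite(self.x)) and np.all(np.isfinite(self.y))):
            raise IntegrityError("non-finite position samples")

    def __len__(self) -> int:
        return len(self.t_ms)

    def window(self, t_from: float, t_to: float) -> "Trajectory":
        """Sub-trajectory with t_from <= t_ms <= t_to."""
        m = (self.t_ms >= t_from) & (self.t_ms <= t_to)
        return Trajectory(self.trial_key, self.t_ms[m], self.x[m], self.y[m],
                          self.fx[m], self.fy[m], self.phase[m])

    def phase_window(self, phase: str) -> "Trajectory":
        m = self.phase == phase
        return Trajectory(self.trial_key, self.t_ms[m], self.x[m], self.y[m],
                          self.fx[m], self.fy[m], self.phase[m])

    def positions(self) -> np.ndarray:
        return np.column_stack([self.x, self.y])


# ---------------------------------------------------------------------------
# trial table I/O

def trials_to_frame(trials: Iterable[TrialRecord]) -> pd.DataFrame:
    rows = []
    for tr in trials:
        rows.append({
            "subject_id": tr.subject_id, "experiment": tr.experiment,
            "block": tr.block, "trial": tr.trial, "duration_ms": tr.duration_ms,
            "condition": tr.condition, "start_x": tr.start_xy[0], "start_y": tr.start_xy[1],
            "choice": tr.choice,
            "rt_ms": np.nan if tr.rt_ms is None else tr.rt_ms,
            "reproduced_ms": np.nan if tr.reproduced_ms is None else tr.reproduced_ms,
        })
    return pd.DataFrame(rows, columns=TRIAL_COLUMNS)


def frame_to_trials(df: pd.DataFrame) -> list[TrialRecord]:
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"trial table missing mandatory column(s): {missing}")
    keys = list(zip(df["subject_id"], df["block"], df["trial"]))
    if len(set(keys)) != len(keys):
        raise IntegrityError("duplicate (subject, block, trial) key in trial table")
    out = []
    for row in df.itertuples(index=False):
        rt = None if pd.isna(row.rt_ms) else float(row.rt_ms)
        rep = None if pd.isna(row.reproduced_ms) else float(row.reproduced_ms)
        out.append(TrialRecord(
            subject_id=str(row.subject_id), experiment=str(row.experiment),
            block=int(row.block), trial=int(row.trial),
            duration_ms=float(row.duration_ms), condition=str(row.condition),
            start_xy=(float(row.start_x), float(row.start_y)),
            choice=str(row.choice), rt_ms=rt, reproduced_ms=rep))
    return out


def write_trial_table(trials: Iterable[TrialRecord], path) -> None:
    trials_to_frame(trials).to_csv(path, index=False)


def read_trial_table(path) -> list[TrialRecord]:
    """Read a trial table CSV; unparseable rows raise rather than being skipped."""
    df = pd.read_csv(path)
    return frame_to_trials(df)


# ---------------------------------------------------------------------------
# trajectory table I/O

def trajectories_to_frame(trajs: Iterable[Trajectory]) -> pd.DataFrame:
    frames = []
    for tj in trajs:
        sid, block, trial = tj.trial_key
        frames.append(pd.DataFrame({
            "subject_id": sid, "block": block, "trial": trial,
            "t_ms": tj.t_ms, "x": tj.x, "y": tj.y,
            "fx": tj.fx, "fy": tj.fy, "phase": tj.phase,
        }))
    if not frames:
        return pd.DataFrame(columns=TRAJ_COLUMNS)
    return pd.concat(frames, ignore_index=True)[TRAJ_COLUMNS]


def write_trajectories(trajs: Iterable[Trajectory], path) -> None:
    trajectories_to_frame(trajs).to_csv(path, index=False)


def frame_to_trajectories(df: pd.DataFrame) -> list[Trajectory]:
    missing = [c for c in TRAJ_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"trajectory table missing mandatory column(s): {missing}")
    bad = set(df["phase"].unique()) - set(PHASES)
    if bad:
        raise FormatError(f"unknown phase labels: {sorted(bad)}")
    out = []
    for (sid, block, trial), g in df.groupby(["subject_id", "block", "trial"], sort=True):
        g = g.sort_values("t_ms")
        t = g["t_ms"].to_numpy()
        if len(t) > 1 and not np.all(np.diff(t) == 1):
            raise IntegrityError(
                f"trial ({sid},{block},{trial}): t_ms not strictly increasing at 1-ms spacing")
        out.append(Trajectory(
            (str(sid), int(block), int(trial)), t.astype(np.int64),
            g["x"].to_numpy(float), g["y"].to_numpy(float),
            g["fx"].to_numpy(float), g["fy"].to_numpy(float),
            g["phase"].to_numpy(object)))
    return out


def read_trajectories(path) -> list[Trajectory]:
    """Read a long-format trajectory CSV, grouped per trial and sorted by t_ms."""
    return frame_to_trajectories(pd.read_csv(path))
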