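"""Generative scalar-timing observer and 1000-Hz trajectory simulator.

The observer carries a log-normal internal clock: a tone of physical
duration d is encoded as d_hat = d * exp(sigma_log * z), z ~ N(0, 1), so the
probability of judging d "long" relative to the criterion bp is

    P(long) = lapse/2 + (1 - lapse) * Phi(ln(d / bp) / sigma_log),

the standard scalar-timing (constant log-SD) choice law.  The same clock
noise z drives the movement strategy during the tone, so the hand's position
(free movement) and force direction (hold) carry single-trial information
about the upcoming choice -- the regularity the decoding analyses exploit.

Response reaches are minimum-jerk (smooth, ballistic, a unique mid-reach
speed maximum); with probability ``com_prob`` the reach first heads most of
the way to the non-chosen target before redirecting, producing a
change-of-mind trajectory whose two-vector angle exceeds 40 deg by
construction.  Hold-condition trials keep the hand exactly at the start
until tone offset while the force channel ramps 0 -> 2 N toward the
currently favored target with von-Mises angular noise.

Reproduction trials draw the reproduced duration from a log-domain
central-tendency model,

    ln r = (1 - w) * ln d_hat + w * ln prior + sigma_rep * z',

with the shrinkage weight w larger, and the reproduction noise smaller, in
the free-movement encoding condition.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

from .core_io import Geometry, Trajectory
from .design import DesignSpec

__all__ = ["ObserverParams", "SimulatedDataset", "simulate_choice",
           "simulate_bisection_trial", "simulate_reproduction_trial",
           "simulate_experiment", "simulate_choices_table"]

WARMUP_MS = 2000
RT_FLOOR_MS = 150.0


@dataclass
class ObserverParams:
    """Tunable parameters of the generative observer (defaults = study conditions)."""

    bp_ms: float = 2000.0          # subjective criterion (geometric mean of 1-4 s set)
    sigma_log: float = 0.3         # SD of internal log-duration noise
    lapse: float = 0.01            # probability of a stimulus-independent guess
    strategy: str = "ideal"        # free-movement template: ideal|arc|middle|updown|circular|random
    move_speed: float = 20.0       # mean response-reach speed, cm/s
    pos_noise_sd: float = 0.05     # smoothed positional noise during free movement, cm
    force_angle_kappa: float = 8.0 # von-Mises concentration of force-direction noise
    com_prob: float = 0.034        # probability of an injected change of mind
    rt_base_ms: float = 450.0      # decision-latency intercept
    rt_slope: float = 200.0        # latency drop per log-unit of |evidence|
    w_free: float = 0.4            # central-tendency weight, free-movement encoding
    w_hold: float = 0.1            # central-tendency weight, hold encoding
    rep_noise_free: float = 0.15   # log-SD of reproduction noise, free encoding
    rep_noise_hold: float = 0.25   # log-SD of reproduction noise, hold encoding
    prior_mean_ms: float = 2000.0  # centre of the duration prior
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma_log < 0:
            raise ValueError("sigma_log must be >= 0")
        if not 0 <= self.lapse <= 0.1:
            raise ValueError("lapse must lie in [0, 0.1]")
        if not 0 <= self.com_prob <= 0.5:
            raise ValueError("com_prob must lie in [0, 0.5]")


@dataclass
class SimulatedDataset:
    trials: pd.DataFrame
    trajectories: list[Trajectory]
    truth: pd.DataFrame
    geometry: Geometry

    def __post_init__(self) -> None:
        if self.trajectories and len(self.trajectories) != len(self.trials):
            raise ValueError("every trial must have exactly one trajectory")


# ---------------------------------------------------------------------------
# choice model

def simulate_choice(duration_ms: float, params: ObserverParams,
                    rng: np.random.Generator) -> tuple[str, float]:
    """Draw one bisection choice; returns (choice, internal_estimate_ms)."""
    if duration_ms <= 0:
        raise ValueError("duration must be positive")
    z = rng.standard_normal()
    d_hat = duration_ms * np.exp(params.sigma_log * z)
    if params.lapse > 0 and rng.random() < params.lapse:
        choice = "long" if rng.random() < 0.5 else "short"
    else:
        choice = "long" if d_hat > params.bp_ms else "short"
    return choice, float(d_hat)


def _decision_rt(d_hat: float, params: ObserverParams) -> float:
    ev = abs(np.log(d_hat / params.bp_ms))
    return max(params.rt_base_ms - params.rt_slope * ev, RT_FLOOR_MS)


# ---------------------------------------------------------------------------
# path primitives

def min_jerk(p0, p1, dur_ms: int) -> np.ndarray:
    """Minimum-jerk straight-line path from p0 to p1 over dur_ms 1-ms samples."""
    s = np.linspace(0.0, 1.0, max(int(dur_ms), 2))
    prof = 10 * s**3 - 15 * s**4 + 6 * s**5
    return np.asarray(p0, float) + np.outer(prof, np.subtract(p1, p0))


def _strategy_path(duration_ms: int, clock_rate: float, params: ObserverParams,
                   geom: Geometry, start, rng: np.random.Generator) -> np.ndarray:
    """Planned hand path during warm-up + tone for a free-movement trial.

    Returns positions for t = -WARMUP..duration-1.  The templates are
    parametric caricatures of the strategy classes seen in free-moving
    subjects; the "ideal"/"arc" template tracks subjective elapsed time
    t * clock_rate along the arc from the short to the long target.
    """
    r_arc = geom.radius_cm * 0.85
    cx, cy = geom.start_xy
    t_tone = np.arange(duration_ms)
    subj = t_tone * clock_rate
    if params.strategy in ("ideal", "arc"):
        frac = np.clip(subj / (2.0 * params.bp_ms), 0.0, 1.0)
        ang = np.radians(geom.short_angle_deg
                         - (geom.short_angle_deg - geom.long_angle_deg) * frac)
        tone_xy = np.column_stack([cx + r_arc * np.cos(ang), cy + r_arc * np.sin(ang)])
    elif params.strategy == "middle":
        mid = np.radians(geom.neutral_angle_deg)
        base = np.array([cx + 0.7 * r_arc * np.cos(mid), cy + 0.7 * r_arc * np.sin(mid)])
        wob = 0.4 * np.column_stack([np.sin(2 * np.pi * subj / 1500.0),
                                     np.cos(2 * np.pi * subj / 1900.0)])
        tone_xy = base + wob
    elif params.strategy == "updown":
        mid = np.radians(geom.neutral_angle_deg)
        r = 0.5 * r_arc + 0.25 * r_arc * np.sin(2 * np.pi * subj / 2000.0)
        tone_xy = np.column_stack([cx + r * np.cos(mid), cy + r * np.sin(mid)])
    elif params.strategy == "circular":
        th = 2 * np.pi * subj / 2500.0
        tone_xy = np.column_stack([cx + 3.0 * np.sin(th),
                                   cy + 5.0 + 3.0 * (1 - np.cos(th)) - 3.0])
    elif params.strategy == "random":
        steps = rng.standard_normal((duration_ms, 2)) * 0.15
        walk = gaussian_filter1d(np.cumsum(steps, axis=0), 80.0, axis=0)
        tone_xy = np.array([cx, cy + 5.0]) + walk
    else:
        raise ValueError(f"unknown strategy {params.strategy!r}")
    warm = min_jerk((cx, cy), tone_xy[0], WARMUP_MS)
    path = np.vstack([warm, tone_xy])
    if params.pos_noise_sd > 0:
        noise = gaussian_filter1d(rng.standard_normal(path.shape), 50.0, axis=0)
        noise *= params.pos_noise_sd / max(noise.std(), 1e-12)
        path = path + noise
    return path


def _response_reach(p_from, choice: str, d_hat: float, params: ObserverParams,
                    geom: Geometry, rng: np.random.Generator,
                    inject_com: bool) -> tuple[np.ndarray, float, bool]:
    """Reach segment (positions at 1 ms) from tone offset to target arrival.

    Returns (positions, rt_ms, com_injected).  rt = decision latency
    (stationary) + movement time at ``move_speed``; a change of mind first
    travels 80-95% of the way to the other target at elevated speed, then
    redirects, guaranteeing the two-vector angle criterion.
    """
    target = np.asarray(geom.target(choice), float)
    delay = int(round(_decision_rt(d_hat, params)))
    hold = np.repeat([np.asarray(p_from, float)], delay, axis=0)
    if not inject_com:
        dist = np.linalg.norm(target - p_from)
        dur = max(int(round(dist / params.move_speed * 1000.0)), 60)
        reach = min_jerk(p_from, target, dur)
        return np.vstack([hold, reach]), float(delay + dur), False
    other = np.asarray(geom.target("short" if choice == "long" else "long"), float)
    frac = rng.uniform(0.80, 0.95)
    detour = np.asarray(p_from) + frac * (other - p_from)
    d1 = np.linalg.norm(detour - p_from)
    d2 = np.linalg.norm(target - detour)
    # first leg fast, correction slower: keeps the global speed maximum in
    # the wrong-target leg so V1 points at the non-chosen target
    t1 = max(int(round(d1 / (1.8 * params.move_speed) * 1000.0)), 60)
    t2 = max(int(round(d2 / (0.8 * params.move_speed) * 1000.0)), 60)
    seg1 = min_jerk(p_from, detour, t1)
    seg2 = min_jerk(detour, target, t2)
    reach = np.vstack([seg1, seg2[1:]])
    return np.vstack([hold, reach]), float(delay + len(reach)), True


# ---------------------------------------------------------------------------
# per-trial simulators

def simulate_bisection_trial(duration_ms: float, condition: str,
                             params: ObserverParams, rng: np.random.Generator,
                             geom: Geometry | None = None,
                             start_xy: tuple[float, float] | None = None,
                             trial_key=("s0", 0, 0)) -> dict:
    """Simulate one bisection trial; returns a dict with trial fields,
    the Trajectory, and ground-truth labels."""
    geom = geom or Geometry()
    start = start_xy if start_xy is not None else geom.start_xy
    duration = int(round(duration_ms))
    z = rng.standard_normal()
    clock_rate = float(np.exp(params.sigma_log * z))
    d_hat = duration_ms * clock_rate
    if params.lapse > 0 and rng.random() < params.lapse:
        choice = "long" if rng.random() < 0.5 else "short"
    else:
        choice = "long" if d_hat > params.bp_ms else "short"
    inject = rng.random() < params.com_prob

    n_pre = WARMUP_MS + duration
    if condition == "hold":
        pre_xy = np.repeat([np.asarray(start, float)], n_pre, axis=0)
        # force points at the currently favored target: short until the
        # internal clock crosses the criterion, then long (300-ms blend)
        t = np.arange(duration)
        cross = params.bp_ms / clock_rate
        blend = 1.0 / (1.0 + np.exp(-(t - cross) / 75.0))
        ang = np.radians(geom.short_angle_deg
                         - (geom.short_angle_deg - geom.long_angle_deg) * blend)
        if params.force_angle_kappa > 0:
            jit = rng.vonmises(0.0, params.force_angle_kappa, size=duration)
            ang = ang + gaussian_filter1d(jit, 20.0) * np.sqrt(40.0)
        mag = 2.0 * np.clip(t / max(duration - 1, 1), 0.02, 1.0)
        f_tone = np.column_stack([mag * np.cos(ang), mag * np.sin(ang)])
        force_pre = np.vstack([np.zeros((WARMUP_MS, 2)), f_tone])
    elif condition == "free":
        pre_xy = _strategy_path(duration, clock_rate, params, geom, start, rng)
        force_pre = np.zeros((n_pre, 2))
    else:
        raise ValueError(f"unknown condition {condition!r}")

    resp_xy, rt_ms, com_injected = _response_reach(
        pre_xy[-1], choice, d_hat, params, geom, rng, inject)
    xy = np.vstack([pre_xy, resp_xy])
    force = np.vstack([force_pre, np.zeros((len(resp_xy), 2))])
    t_ms = np.arange(-WARMUP_MS, len(xy) - WARMUP_MS)
    phase = np.empty(len(xy), dtype=object)
    phase[:WARMUP_MS] = "warmup"
    phase[WARMUP_MS:n_pre] = "tone"
    phase[n_pre:] = "response"
    traj = Trajectory(trial_key, t_ms, xy[:, 0], xy[:, 1],
                      force[:, 0], force[:, 1], phase)
    if rt_ms > 5000:
        raise RuntimeError("response reach failed to arrive within 5 s")
    return {
        "duration_ms": duration_ms, "condition": condition, "choice": choice,
        "rt_ms": rt_ms, "trajectory": traj, "d_hat_ms": d_hat,
        "com_injected": com_injected,
        "com_direction": ("short_to_long" if choice == "long" else "long_to_short")
                         if com_injected else "none",
    }


def _reproduction_movement(start, reproduced_ms: int, rng: np.random.Generator,
                           go_delay_ms: int = 300, tail_ms: int = 300,
                           peak_speed: float = 10.0) -> np.ndarray:
    """Reproduction-phase positions: still, meandering movement of the
    reproduced duration (sharp 4-ms speed ramps so threshold crossings
    bracket it tightly), then still."""
    ramp = 4
    n_move = max(int(reproduced_ms), 2 * ramp + 2)
    env = np.full(n_move, peak_speed)
    r = 0.5 * (1 - np.cos(np.linspace(0, np.pi, ramp)))
    env[:ramp] *= r
    env[-ramp:] *= r[::-1]
    heading = gaussian_filter1d(np.cumsum(rng.standard_normal(n_move) * 0.01), 100.0)
    heading = heading + rng.uniform(0, 2 * np.pi)
    v = np.column_stack([env * np.cos(heading), env * np.sin(heading)]) / 1000.0
    move = np.asarray(start, float) + np.cumsum(v, axis=0)
    still0 = np.repeat([np.asarray(start, float)], go_delay_ms, axis=0)
    still1 = np.repeat([move[-1]], tail_ms, axis=0)
    return np.vstack([still0, move, still1])


def simulate_reproduction_trial(duration_ms: float, condition: str,
                                params: ObserverParams, rng: np.random.Generator,
                                geom: Geometry | None = None,
                                start_xy=(0.0, 0.0), repro_start_xy=(0.0, 5.0),
                                trial_key=("s0", 0, 0)) -> dict:
    """Simulate one reproduction trial (encoding phase + reproduction phase)."""
    geom = geom or Geometry()
    duration = int(round(duration_ms))
    z = rng.standard_normal()
    clock_rate = float(np.exp(params.sigma_log * z))
    d_hat = duration_ms * clock_rate
    w = params.w_free if condition == "free" else params.w_hold
    sig = params.rep_noise_free if condition == "free" else params.rep_noise_hold
    ln_r = (1 - w) * np.log(d_hat) + w * np.log(params.prior_mean_ms) \
        + sig * rng.standard_normal()
    reproduced = float(np.exp(ln_r))

    if condition == "free":
        enc_xy = _strategy_path(duration, clock_rate, params, geom, start_xy, rng)[WARMUP_MS:]
        enc_xy = enc_xy - enc_xy[0] + np.asarray(start_xy, float)
    else:
        enc_xy = np.repeat([np.asarray(start_xy, float)], duration, axis=0)
    rep_xy = _reproduction_movement(repro_start_xy, int(round(reproduced)), rng)
    xy = np.vstack([enc_xy, rep_xy])
    t_ms = np.arange(len(xy))
    phase = np.empty(len(xy), dtype=object)
    phase[:duration] = "encoding"
    phase[duration:] = "reproduction"
    traj = Trajectory(trial_key, t_ms, xy[:, 0], xy[:, 1],
                      np.zeros(len(xy)), np.zeros(len(xy)), phase)
    return {
        "duration_ms": duration_ms, "condition": condition, "choice": "none",
        "reproduced_ms": reproduced, "trajectory": traj, "d_hat_ms": d_hat,
        "com_injected": False, "com_direction": "none",
    }


# ---------------------------------------------------------------------------
# experiment-level simulation

def _experiment_label(design: DesignSpec) -> str:
    return design.experiment


def simulate_experiment(design: DesignSpec, params: ObserverParams | list[ObserverParams],
                        subjects: int | None = None, geometry: Geometry | None = None,
                        trajectories: bool = True) -> SimulatedDataset:
    """Run the per-trial simulators over a DesignSpec for one or more subjects.

    ``params`` may be a single ObserverParams (shared, per-subject streams
    derived from its seed) or a list with one entry per subject.  With
    ``trajectories=False`` only the behavioral table and truth labels are
    produced (identical draws for the choice/reproduction model), which is
    the fast path for group-level power runs.
    """
    geom = geometry or Geometry()
    if isinstance(params, ObserverParams):
        n_sub = subjects or 1
        plist = [replace(params) for _ in range(n_sub)]
        seeds = np.random.SeedSequence(params.seed).spawn(n_sub)
    else:
        plist = list(params)
        seeds = [np.random.SeedSequence(p.seed) for p in plist]
    is_repro = design.experiment == "reproduction"
    rows, trajs, truths = [], [], []
    for si, (p, ss) in enumerate(zip(plist, seeds)):
        rng = np.random.default_rng(ss)
        sid = f"s{si:02d}"
        for rec in design.trials.itertuples(index=False):
            key = (sid, int(rec.block), int(rec.trial))
            start = (float(rec.start_x), float(rec.start_y))
            if is_repro:
                if trajectories:
                    res = simulate_reproduction_trial(
                        rec.duration_ms, rec.condition, p, rng, geom,
                        start_xy=start,
                        repro_start_xy=(float(rec.repro_start_x), float(rec.repro_start_y)),
                        trial_key=key)
                else:
                    res = _fast_reproduction(rec.duration_ms, rec.condition, p, rng)
            else:
                if trajectories:
                    res = simulate_bisection_trial(
                        rec.duration_ms, rec.condition, p, rng, geom,
                        start_xy=start, trial_key=key)
                else:
                    res = _fast_bisection(rec.duration_ms, rec.condition, p, rng,
                                          geom, start)
            rows.append({
                "subject_id": sid, "experiment": design.experiment,
                "block": int(rec.block), "trial": int(rec.trial),
                "duration_ms": rec.duration_ms, "condition": rec.condition,
                "start_x": start[0], "start_y": start[1],
                "choice": res["choice"], "rt_ms": res.get("rt_ms", np.nan),
                "reproduced_ms": res.get("reproduced_ms", np.nan),
            })
            truths.append({
                "subject_id": sid, "block": int(rec.block), "trial": int(rec.trial),
                "d_hat_ms": res["d_hat_ms"], "com_injected": res["com_injected"],
                "com_direction": res["com_direction"],
            })
            if trajectories:
                trajs.append(res["trajectory"])
    return SimulatedDataset(pd.DataFrame(rows), trajs, pd.DataFrame(truths), geom)


def _fast_bisection(duration_ms, condition, p: ObserverParams,
                    rng: np.random.Generator, geom: Geometry, start) -> dict:
    z = rng.standard_normal()
    d_hat = duration_ms * np.exp(p.sigma_log * z)
    if p.lapse > 0 and rng.random() < p.lapse:
        choice = "long" if rng.random() < 0.5 else "short"
    else:
        choice = "long" if d_hat > p.bp_ms else "short"
    dist = np.linalg.norm(np.subtract(geom.target(choice), start))
    rt = _decision_rt(d_hat, p) + dist / p.move_speed * 1000.0
    return {"choice": choice, "rt_ms": rt, "d_hat_ms": d_hat,
            "com_injected": False, "com_direction": "none"}


def _fast_reproduction(duration_ms, condition, p: ObserverParams,
                       rng: np.random.Generator) -> dict:
    z = rng.standard_normal()
    d_hat = duration_ms * np.exp(p.sigma_log * z)
    w = p.w_free if condition == "free" else p.w_hold
    sig = p.rep_noise_free if condition == "free" else p.rep_noise_hold
    rep = np.exp((1 - w) * np.log(d_hat) + w * np.log(p.prior_mean_ms)
                 + sig * rng.standard_normal())
    return {"choice": "none", "reproduced_ms": float(rep), "d_hat_ms": d_hat,
            "com_injected": False, "com_direction": "none"}


def simulate_choices_table(design: DesignSpec, params: ObserverParams,
                           subjects: int, geometry: Geometry | None = None) -> pd.DataFrame:
    """Behavioral table only (no trajectories) for ``subjects`` observers."""
    return simulate_experiment(design, params, subjects=subjects,
                               geometry=geometry, trajectories=False).trials
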