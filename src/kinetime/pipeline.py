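"""End-to-end orchestration: simulate -> fit -> compare, per experiment.

Each ``run_*`` function simulates the corresponding experiment with the
generative observer, applies the same analysis chain a real dataset would
get (per-subject psychometric fits, CV comparison, reproduction scoring),
and returns a machine-readable report dict plus a RunManifest.  Group-level
claims are framed as power/calibration properties of the pipeline on
synthetic data.

Group CV comparisons need only the behavioral choice table, so those runs
use the simulator's fast path (no 1000-Hz trajectories); trajectory
simulation is switched on wherever a kinematic quantity (change-of-mind
removal, Frechet similarity) enters the analysis.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import change_of_mind as com
from . import psychometrics as psy
from . import reproduction as rep
from . import stats as st
from .design import bisection_design, reproduction_block_design, twostart_design
from .observer import ObserverParams, simulate_experiment

__all__ = ["RunManifest", "run_experiment1_vs_2", "run_experiment3",
           "run_experiment4", "subject_cvs"]


@dataclass
class RunManifest:
    config: dict
    seeds: dict
    stages: dict = field(default_factory=dict)

    @property
    def config_hash(self) -> str:
        blob = json.dumps(self.config, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def subject_cvs(trials: pd.DataFrame) -> pd.DataFrame:
    """Per-subject psychometric CV (and BP) from a bisection choice table."""
    rows = []
    for sid, g in trials.groupby("subject_id"):
        agg = g.assign(is_long=(g["choice"] == "long").astype(int)) \
            .groupby("duration_ms")["is_long"].agg(["sum", "count"])
        fit = psy.fit_psychometric(agg.index.to_numpy(), agg["sum"].to_numpy(),
                                   agg["count"].to_numpy())
        rows.append({"subject_id": sid, "bp_ms": fit.bp_ms, "dl_ms": fit.dl_ms,
                     "cv": fit.cv, "converged": fit.converged})
    return pd.DataFrame(rows)


def run_experiment1_vs_2(n_free: int = 20, n_hold: int = 20,
                         sigma_free: float = 0.20, sigma_hold: float = 0.30,
                         n_blocks: int = 8, seed: int = 0,
                         com_removal: bool = False,
                         n_perm: int = 10_000) -> dict:
    """Free-movement vs hold group comparison of psychometric CV (and BP).

    Simulates both groups, fits per-subject psychometric functions, and runs
    Mann-Whitney tests with permutation confirmation.  With lower free-group
    clock noise the pipeline should detect the lower free-group CV.
    ``com_removal=True`` additionally simulates trajectories, removes
    detected change-of-mind trials, and re-runs the CV comparison.
    """
    ss = np.random.SeedSequence(seed).spawn(4)
    design_free = bisection_design(n_blocks=n_blocks, seed=int(ss[0].generate_state(1)[0] % 2**31),
                                   experiment="bisection_free")
    design_hold = bisection_design(n_blocks=n_blocks, seed=int(ss[1].generate_state(1)[0] % 2**31),
                                   experiment="bisection_hold", condition="hold")
    p_free = ObserverParams(sigma_log=sigma_free, seed=int(ss[2].generate_state(1)[0] % 2**31))
    p_hold = ObserverParams(sigma_log=sigma_hold, seed=int(ss[3].generate_state(1)[0] % 2**31))
    need_traj = com_removal
    ds_free = simulate_experiment(design_free, p_free, subjects=n_free,
                                  trajectories=need_traj)
    ds_hold = simulate_experiment(design_hold, p_hold, subjects=n_hold,
                                  trajectories=need_traj)
    cv_free = subject_cvs(ds_free.trials)
    cv_hold = subject_cvs(ds_hold.trials)
    test_cv = st.mann_whitney_u(cv_free["cv"].dropna(), cv_hold["cv"].dropna(),
                                n_perm=n_perm, seed=seed)
    test_bp = st.mann_whitney_u(cv_free["bp_ms"].dropna(), cv_hold["bp_ms"].dropna(),
                                n_perm=n_perm, seed=seed + 1)
    report = {
        "cv_free_median": float(cv_free["cv"].median()),
        "cv_hold_median": float(cv_hold["cv"].median()),
        "cv_test": test_cv, "bp_test": test_bp,
        "cv_significant": test_cv.p_perm < 0.05,
        "direction_free_lower": cv_free["cv"].median() < cv_hold["cv"].median(),
    }
    if com_removal:
        geom = ds_free.geometry
        kept_frames = []
        n_removed = 0
        for ds in (ds_free, ds_hold):
            events = [com.detect_com(tj, geom,
                                     ds.trials.iloc[i]["choice"])
                      for i, tj in enumerate(ds.trajectories)]
            flags = np.array([ev.is_com for ev in events])
            n_removed += int(flags.sum())
            kept_frames.append(ds.trials[~flags])
        cv_free2 = subject_cvs(kept_frames[0])
        cv_hold2 = subject_cvs(kept_frames[1])
        test2 = st.mann_whitney_u(cv_free2["cv"].dropna(), cv_hold2["cv"].dropna(),
                                  n_perm=n_perm, seed=seed + 2)
        report["com_removed_n"] = n_removed
        report["cv_test_com_removed"] = test2
        report["cv_significant_com_removed"] = test2.p_perm < 0.05
    manifest = RunManifest(
        config={"n_free": n_free, "n_hold": n_hold, "sigma_free": sigma_free,
                "sigma_hold": sigma_hold, "n_blocks": n_blocks,
                "com_removal": com_removal},
        seeds={"master": seed},
        stages={"simulate": "ok", "fit": "ok", "compare": "ok"})
    report["manifest"] = manifest
    return report


def run_experiment3(n_subjects: int = 14, sigma_log: float = 0.3,
                    close_cm: float = 7.8, far_cm: float = 10.0,
                    n_blocks_per_distance: int = 8, seed: int = 0,
                    n_perm: int = 10_000) -> dict:
    """Within-subject two-start-distance comparison: CV (expected null) and RT.

    The observer's clock noise does not depend on start distance, so the CV
    comparison is a null; reach time scales with distance, so close-start
    RTs are faster than far-start RTs.
    """
    design = twostart_design(close_cm, far_cm,
                             n_blocks_per_distance=n_blocks_per_distance, seed=seed)
    params = ObserverParams(sigma_log=sigma_log, seed=seed + 1)
    ds = simulate_experiment(design, params, subjects=n_subjects, trajectories=False)
    trials = ds.trials.merge(
        design.trials[["block", "trial", "start_distance"]].drop_duplicates(),
        on=["block", "trial"], how="left")
    rows = []
    for (sid, dist), g in trials.groupby(["subject_id", "start_distance"]):
        agg = g.assign(is_long=(g["choice"] == "long").astype(int)) \
            .groupby("duration_ms")["is_long"].agg(["sum", "count"])
        fit = psy.fit_psychometric(agg.index.to_numpy(), agg["sum"].to_numpy(),
                                   agg["count"].to_numpy())
        rows.append({"subject_id": sid, "start_distance": dist, "cv": fit.cv,
                     "mean_rt_ms": g["rt_ms"].mean()})
    per = pd.DataFrame(rows).pivot(index="subject_id", columns="start_distance")
    test_cv = st.wilcoxon_signed_rank(per[("cv", "close")], per[("cv", "far")],
                                      n_perm=n_perm, seed=seed)
    test_rt = st.wilcoxon_signed_rank(per[("mean_rt_ms", "close")],
                                      per[("mean_rt_ms", "far")],
                                      n_perm=n_perm, seed=seed + 1)
    return {
        "cv_test": test_cv, "rt_test": test_rt,
        "cv_significant": test_cv.p_perm < 0.05,
        "rt_close_faster": bool(per[("mean_rt_ms", "close")].mean()
                                < per[("mean_rt_ms", "far")].mean()),
        "manifest": RunManifest(
            config={"n_subjects": n_subjects, "close_cm": close_cm, "far_cm": far_cm},
            seeds={"master": seed}, stages={"simulate": "ok", "compare": "ok"}),
    }


def run_experiment4(n_subjects: int = 10, seed: int = 0,
                    params: ObserverParams | None = None,
                    frechet_trials_per_subject: int = 0,
                    n_perm: int = 10_000) -> dict:
    """Within-subject reproduction comparison: central-tendency slope and CV.

    Free-movement encoding carries a larger central-tendency weight and
    smaller reproduction noise than hold, so the expected pattern is a
    shallower free slope and a lower free CV.  Slopes/CVs are computed from
    the reproduced durations; optionally ``frechet_trials_per_subject``
    free trials per subject are simulated with trajectories and scored with
    the discrete Frechet distance (one-sample Wilcoxon vs 0).
    """
    base = params or ObserverParams()
    design = reproduction_block_design(seed=seed)
    plist = [replace(base, seed=seed + 100 + i) for i in range(n_subjects)]
    ds = simulate_experiment(design, plist, trajectories=False)
    rows = []
    for (sid, cond), g in ds.trials.groupby(["subject_id", "condition"]):
        slope, intercept = rep.central_tendency_slope(g["duration_ms"], g["reproduced_ms"])
        cv = rep.reproduction_cv(g, per_duration=True)["cv"].mean()
        rows.append({"subject_id": sid, "condition": cond, "slope": slope, "cv": cv})
    per = pd.DataFrame(rows).pivot(index="subject_id", columns="condition")
    test_slope = st.wilcoxon_signed_rank(per[("slope", "free")], per[("slope", "hold")],
                                         n_perm=n_perm, seed=seed)
    test_cv = st.wilcoxon_signed_rank(per[("cv", "free")], per[("cv", "hold")],
                                      n_perm=n_perm, seed=seed + 1)
    report = {
        "slope_free_mean": float(per[("slope", "free")].mean()),
        "slope_hold_mean": float(per[("slope", "hold")].mean()),
        "cv_free_mean": float(per[("cv", "free")].mean()),
        "cv_hold_mean": float(per[("cv", "hold")].mean()),
        "slope_test": test_slope, "cv_test": test_cv,
        "slope_free_shallower": bool(per[("slope", "free")].mean()
                                     < per[("slope", "hold")].mean()),
        "cv_free_lower": bool(per[("cv", "free")].mean() < per[("cv", "hold")].mean()),
    }
    if frechet_trials_per_subject > 0:
        small = reproduction_block_design(n_testing_blocks=2, reps_per_block=3,
                                          seed=seed + 7)
        small.trials = small.trials[small.trials["condition"] == "free"] \
            .head(frechet_trials_per_subject).reset_index(drop=True)
        ds_f = simulate_experiment(small, base, subjects=min(n_subjects, 5),
                                   trajectories=True)
        sim = rep.path_similarity(ds_f)
        subj_means = sim.groupby("subject_id")["frechet_cm"].mean()
        report["frechet_mean_cm"] = float(subj_means.mean())
        report["frechet_test_vs_zero"] = st.wilcoxon_signed_rank(
            sim["frechet_cm"].to_numpy(), n_perm=min(n_perm, 2000), seed=seed + 3)
    report["manifest"] = RunManifest(
        config={"n_subjects": n_subjects,
                "frechet_trials_per_subject": frechet_trials_per_subject},
        seeds={"master": seed}, stages={"simulate": "ok", "compare": "ok"})
    return report
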