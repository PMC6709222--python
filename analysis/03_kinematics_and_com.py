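#!/usr/bin/env python
"""Movement features and change-of-mind detection on trajectory-level data.

Simulates two free-movement and two hold subjects with full 1000-Hz
trajectories, then computes the movement readouts: per-duration tone-phase
path length (free), last-100-ms intertrial positional SD, and the
two-vector change-of-mind classification (theta > 40 deg) with per-duration
direction rates.

Writes: results/path_length_by_duration.csv, results/intertrial_sd.csv,
        results/com_events.csv, results/com_rates.csv
"""

import pathlib

import pandas as pd

from kinetime.change_of_mind import com_rates, detect_com
from kinetime.design import bisection_design
from kinetime.kinematics import intertrial_sd, path_length
from kinetime.observer import ObserverParams, simulate_experiment

OUT = pathlib.Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)
SEED = 515


def main():
    datasets = {}
    for cond, sigma in (("free", 0.20), ("hold", 0.30)):
        spec = bisection_design(n_blocks=2, seed=SEED,
                                experiment=f"bisection_{cond}", condition=cond)
        datasets[cond] = simulate_experiment(
            spec, ObserverParams(sigma_log=sigma, seed=SEED + hash(cond) % 1000),
            subjects=2, trajectories=True)

    ds = datasets["free"]
    rows = []
    for rec, tj in zip(ds.trials.itertuples(index=False), ds.trajectories):
        rows.append({"duration_ms": rec.duration_ms, "choice": rec.choice,
                     "path_length_cm": path_length(tj, (0, rec.duration_ms - 1))})
    pl = pd.DataFrame(rows).groupby(["duration_ms", "choice"]).mean().reset_index()
    pl.to_csv(OUT / "path_length_by_duration.csv", index=False)
    mid = pl["duration_ms"].sub(2000).abs() < 1.0
    long_2s = pl[mid & (pl["choice"] == "long")]["path_length_cm"]
    short_2s = pl[mid & (pl["choice"] == "short")]["path_length_cm"]
    if len(long_2s) and len(short_2s):
        print(f"2-s trials: mean tone path length {float(long_2s.iloc[0]):.2f} cm "
              f"(chose long) vs {float(short_2s.iloc[0]):.2f} cm (chose short)")

    sd_frames = []
    for cond, d in datasets.items():
        s = intertrial_sd(d.trajectories, d.trials)
        s.insert(0, "condition", cond)
        sd_frames.append(s)
    pd.concat(sd_frames, ignore_index=True).to_csv(OUT / "intertrial_sd.csv", index=False)

    events, trials_all = [], []
    for cond, d in datasets.items():
        for rec, tj in zip(d.trials.itertuples(index=False), d.trajectories):
            events.append(detect_com(tj, d.geometry, rec.choice))
        trials_all.append(d.trials)
    trials_all = pd.concat(trials_all, ignore_index=True)
    ev_df = pd.DataFrame([{"subject_id": e.trial_key[0], "block": e.trial_key[1],
                           "trial": e.trial_key[2], "theta_deg": e.theta_deg,
                           "is_com": e.is_com, "direction": e.direction}
                          for e in events])
    ev_df.to_csv(OUT / "com_events.csv", index=False)
    rates = com_rates(events, trials_all)
    rates.to_csv(OUT / "com_rates.csv", index=False)
    print(f"change-of-mind rate: {ev_df['is_com'].mean():.3f} "
          f"({ev_df['is_com'].sum()} of {len(ev_df)} trials)")


if __name__ == "__main__":
    main()
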