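#!/usr/bin/env python
"""Fit per-subject psychometric functions to the simulated bisection groups.

For every subject the proportion of "long" choices per duration is fit with
a cumulative Gumbel on log duration; BP, DL and CV are extracted, with
bias-corrected parametric-bootstrap intervals (1999 replicates) for the
first subject of each group as a demonstration.  Chronometric (RT by
duration) summaries are also written.

Reads:  results/trials_free.csv, results/trials_hold.csv   (run 01 first)
Writes: results/psychometric_fits.csv, results/chronometric.csv
"""

import pathlib

import pandas as pd

from kinetime import psychometrics as psy
from kinetime.pipeline import subject_cvs

OUT = pathlib.Path(__file__).resolve().parents[1] / "results"


def main():
    frames = []
    chrono = []
    for group in ("free", "hold"):
        trials = pd.read_csv(OUT / f"trials_{group}.csv")
        fits = subject_cvs(trials)
        fits.insert(0, "group", group)
        frames.append(fits)
        ch = psy.chronometric(trials)
        ch.insert(0, "group", group)
        chrono.append(ch)

        # bootstrap interval demo on the first subject
        g = trials[trials["subject_id"] == trials["subject_id"].iloc[0]]
        agg = g.assign(is_long=(g["choice"] == "long").astype(int)) \
            .groupby("duration_ms")["is_long"].agg(["sum", "count"])
        fit = psy.bootstrap_ci(agg.index.to_numpy(), agg["sum"].to_numpy(),
                               agg["count"].to_numpy(), n_boot=1999, seed=11)
        lo, hi = fit.ci["bp_ms"]
        print(f"{group}: subject 0 BP {fit.bp_ms:.0f} ms "
              f"[95% CI {lo:.0f}, {hi:.0f}], CV {fit.cv:.3f}")

    fits = pd.concat(frames, ignore_index=True)
    fits.to_csv(OUT / "psychometric_fits.csv", index=False)
    pd.concat(chrono, ignore_index=True).to_csv(OUT / "chronometric.csv", index=False)
    med = fits.groupby("group")["cv"].median()
    print(f"median CV: free {med['free']:.3f} vs hold {med['hold']:.3f} "
          f"(lower CV = more precise timing)")


if __name__ == "__main__":
    main()
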