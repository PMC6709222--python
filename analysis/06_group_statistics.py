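#!/usr/bin/env python
"""Group-level nonparametric comparisons over the full simulated pipelines.

Runs the three end-to-end experiment pipelines (free vs hold CV, two-start
within-subject comparison, reproduction slope/CV comparison), each with
Mann-Whitney or Wilcoxon tests confirmed by 10,000-permutation p-values,
and writes a machine-readable summary.

Writes: results/group_stats.json
"""

import json
import pathlib

from kinetime import pipeline

OUT = pathlib.Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)
SEED = 7


def test_to_dict(t):
    return {"statistic": t.statistic, "p_value": t.p_value, "p_perm": t.p_perm,
            "n_perm": t.n_perm, "effect_size": t.effect_size, "exact": t.exact}


def main():
    summary = {}

    r12 = pipeline.run_experiment1_vs_2(seed=SEED)
    summary["exp1_vs_2"] = {
        "cv_free_median": r12["cv_free_median"],
        "cv_hold_median": r12["cv_hold_median"],
        "cv_test": test_to_dict(r12["cv_test"]),
        "bp_test": test_to_dict(r12["bp_test"]),
    }
    print(f"Exp 1 vs 2: CV free {r12['cv_free_median']:.3f} < hold "
          f"{r12['cv_hold_median']:.3f}; U={r12['cv_test'].statistic:.0f}, "
          f"p_perm={r12['cv_test'].p_perm:.4f}, d={r12['cv_test'].effect_size:.2f}; "
          f"BP difference p_perm={r12['bp_test'].p_perm:.3f}")

    r3 = pipeline.run_experiment3(seed=SEED)
    summary["exp3"] = {"cv_test": test_to_dict(r3["cv_test"]),
                       "rt_test": test_to_dict(r3["rt_test"])}
    print(f"Exp 3 (7.8 vs 10 cm starts): CV p_perm={r3['cv_test'].p_perm:.3f} "
          f"(expected null); RT p_perm={r3['rt_test'].p_perm:.4f}, "
          f"close faster: {r3['rt_close_faster']}")

    r4 = pipeline.run_experiment4(seed=SEED, frechet_trials_per_subject=4)
    summary["exp4"] = {
        "slope_free_mean": r4["slope_free_mean"],
        "slope_hold_mean": r4["slope_hold_mean"],
        "cv_free_mean": r4["cv_free_mean"], "cv_hold_mean": r4["cv_hold_mean"],
        "slope_test": test_to_dict(r4["slope_test"]),
        "cv_test": test_to_dict(r4["cv_test"]),
        "frechet_mean_cm": r4.get("frechet_mean_cm"),
    }
    print(f"Exp 4: slope free {r4['slope_free_mean']:.2f} < hold "
          f"{r4['slope_hold_mean']:.2f} (p_perm={r4['slope_test'].p_perm:.4f}); "
          f"CV free {r4['cv_free_mean']:.3f} < hold {r4['cv_hold_mean']:.3f} "
          f"(p_perm={r4['cv_test'].p_perm:.4f})")

    with open(OUT / "group_stats.json", "w") as fh:
        json.dump(summary, fh, indent=2)
    print(f"summary written to {OUT / 'group_stats.json'}")


if __name__ == "__main__":
    main()
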