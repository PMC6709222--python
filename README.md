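# kinetime

Analysis machinery for motor-timing psychophysics: does moving freely while
timing an interval make temporal judgments more precise? The package
implements, as a tested Python library plus a set of analysis drivers, the
full chain used to answer that question with a robotic-manipulandum
bisection task — psychometric fitting, reach-kinematic decision readouts,
change-of-mind detection, time-resolved choice decoding, and
temporal-reproduction scoring — together with a generative scalar-timing
observer that produces ground-truth-labeled synthetic experiments, so every
estimator is validated end to end without any experimental data download.

It is intended for researchers in timing/psychophysics and motor control
who want a reproducible reference implementation of these analyses, or a
simulation harness to power-test variants of the paradigm.

## The models at the core

**Psychometrics.** The probability of judging duration *d* "long" is fit
with a cumulative Gumbel on log duration,

    ψ(d) = γ + (1 − γ − λ) · [1 − exp(−exp((ln d − α)/β))],

which for γ = λ = 0 is a binomial cloglog regression on ln *d*. From the
fit: bisection point BP = ψ⁻¹(0.5), difference limen
DL = (ψ⁻¹(0.75) − ψ⁻¹(0.25))/2, coefficient of variation CV = DL/BP
(lower CV = more precise timing), with bias-corrected parametric-bootstrap
CIs (1999 replicates).

**Decision readouts and decoding.** During the tone, hand position (free
movement) or force direction (hold) is mapped to a softmax score in (0,1),
neutral at 0.5, and at every time step of the last 1000 ms before tone
offset a mixed-effects logistic model

    Y ~ 1 + D + M + (1|S)    (binomial, logit link, Laplace ML)

tests whether the movement readout M predicts the upcoming choice Y,
Bonferroni-corrected over time steps (α = 0.05/1000 = 5 × 10⁻⁵ at 1-ms
resolution).

**Changes of mind.** A response reach is flagged as a change of mind when
the angle θ between the onset→peak-speed vector and the
peak-speed→chosen-target vector exceeds 40°.

**Reproduction.** Reproduced durations (movement start→stop), the
central-tendency (Vierordt) slope of reproduced on presented duration,
per-duration CVs, and encoding↔reproduction path similarity by the
discrete Fréchet distance (Eiter–Mannila dynamic program).

The synthetic observer ties these together: a log-normal internal clock
(scalar timing) drives both the choice and the movement on each trial, so
simulated datasets contain exactly the regularities the analyses target,
with known ground truth.

## Worked example

```python
import numpy as np
from kinetime import design, psychometrics as psy
from kinetime.observer import ObserverParams, simulate_experiment
from kinetime.pipeline import run_experiment1_vs_2

# simulate one free-movement subject: 8 counterbalanced blocks of 49 trials
spec = design.bisection_design(seed=0)
ds = simulate_experiment(spec, ObserverParams(sigma_log=0.2, seed=1),
                         subjects=1, trajectories=False)
agg = (ds.trials.assign(is_long=lambda t: (t.choice == "long").astype(int))
       .groupby("duration_ms")["is_long"].agg(["sum", "count"]))
fit = psy.bootstrap_ci(agg.index.to_numpy(), agg["sum"].to_numpy(),
                       agg["count"].to_numpy(), seed=2)
print(f"BP {fit.bp_ms:.0f} ms, CV {fit.cv:.3f}, "
      f"BP 95% CI [{fit.ci['bp_ms'][0]:.0f}, {fit.ci['bp_ms'][1]:.0f}]")

# full two-group comparison (20 free vs 20 hold subjects)
rep = run_experiment1_vs_2(seed=7)
print(f"median CV free {rep['cv_free_median']:.3f} vs "
      f"hold {rep['cv_hold_median']:.3f}, "
      f"Mann-Whitney U={rep['cv_test'].statistic:.0f}, "
      f"p_perm={rep['cv_test'].p_perm:.4f}")
```

Output:

```
BP 2092 ms, CV 0.143, BP 95% CI [1997, 2184]
median CV free 0.163 vs hold 0.221, Mann-Whitney U=4, p_perm=0.0001
```

The subject's fitted bisection point sits near the 2000-ms midpoint of the
1–4 s set and the CI reflects 56 trials/duration; in the group comparison
the free-movement group (lower clock noise) shows the lower CV, and the
permutation-confirmed Mann–Whitney test detects it.

The numbered scripts under `analysis/` walk the same chain step by step
(01 simulate → 02 psychometrics → 03 kinematics & changes of mind →
04 decoding → 05 reproduction → 06 group statistics), each printing what it
found and writing tables under `results/`.

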