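# Methods

`kinetime` implements the analysis machinery for experiments asking whether
free hand movement during interval timing improves temporal precision,
exercised end-to-end on a synthetic generative observer so that every
analysis path can be validated against known ground truth.

## Task and geometry

The modeled task is temporal bisection with a robotic manipulandum: a tone
of one of seven durations plays, and the subject classifies it as "short"
or "long" by reaching to one of two targets. Both targets sit on a 10-cm
circle around the start location, at 105° (short) and 75° (long)
counterclockwise from +x, 0.5 cm in diameter; the perpendicular bisector of
the targets is the 90° direction, which is the neutral boundary for all
force-direction readouts. The bisection stimulus set is seven durations
log-spaced from 1000 to 4000 ms (middle element exactly 2000 ms); the
reproduction experiment uses seven linearly spaced durations (1000–4000 ms,
500-ms steps). Hand position and force are sampled at 1000 Hz.

The source descriptions of the rig are internally inconsistent (targets
"14 cm apart" vs. equidistant at 10 cm and 105°/75°, which implies a
5.18-cm chord). The package adopts the 105°/75° × 10 cm construction as the
default because the force-readout convention (90° boundary) depends on it;
the target placement is fully configurable through `core_io.Geometry`.

## Trial sequencing

First-order counterbalancing — every ordered pair of consecutive durations,
including repeats, equally frequent — is constructed as a randomized
Eulerian circuit on the complete directed graph with self-loops over the 7
durations: 49 transitions per block, 8 blocks, 392 trials, 56 per duration.
All blocks start at a common seed-chosen node so that each block is
cyclically balanced on its own *and* the concatenation read cyclically
contains every ordered pair exactly `n_blocks` times. This is verified
exhaustively in tests for all set sizes up to 7 and up to 3 blocks.

## The generative observer

The synthetic observer follows scalar timing: a tone of duration `d` is
encoded as `d_hat = d · exp(σ·z)`, `z ~ N(0,1)`, with constant log-SD σ
(default 0.3), and judged long when `d_hat` exceeds the criterion `bp`
(default 2000 ms, the geometric mean of the set), so

    P(long) = lapse/2 + (1 − lapse) · Φ(ln(d/bp) / σ).

The same trial's clock noise `z` drives the movement: in the free condition
the hand tracks subjective elapsed time along the arc between the targets
(plus smoothed positional noise, default SD 0.05 cm), and in the hold
condition the force vector points at the currently favored target (switching
from short to long when subjective time crosses the criterion) with
von-Mises angular noise (κ = 8) and a linear 0→2 N magnitude ramp. Because
choice and movement share one latent variable, single-trial readouts carry
decodable choice information that grows toward tone offset — the regularity
the decoding analyses are designed to detect. Five additional strategy
templates (arc, middle, updown, circular, random) provide qualitative
movement heterogeneity.

Response reaches are minimum-jerk: smooth, ballistic, with a unique
mid-reach speed maximum, which the change-of-mind detector requires.
Reaction time is `max(rt_base − rt_slope·|ln(d_hat/bp)|, 150 ms)` (faster
for clearly categorized intervals) plus movement time at `move_speed`
(default 20 cm/s), so reach time scales with start–target distance — the
mechanism behind the two-start-distance RT effect. With probability
`com_prob` (default 0.034) the reach first travels 80–95% of the way to the
non-chosen target at elevated speed before redirecting, which places the
global speed maximum inside the wrong-target leg and guarantees a
two-vector angle above the 40° criterion.

Reproduction trials draw the reproduced duration from a log-domain
central-tendency model, `ln r = (1−w)·ln d_hat + w·ln prior + σ_rep·z'`.
The free-movement encoding condition gets a larger shrinkage weight
(w = 0.4 vs 0.1) and smaller reproduction noise (0.15 vs 0.25 log-SD),
producing the expected pattern of a shallower free slope together with a
lower free CV. The reproduction movement itself is a meandering path with a
10 cm/s speed envelope and sharp 4-ms ramps, so 5-cm/s threshold crossings
bracket the intended duration within a few ms.

What the generator deliberately does **not** emulate: biomechanical arm
dynamics, learning or drift across blocks, manual curation of ambiguous
trials, and any quantitative movement model of real subjects (none is
published). Passing tests therefore validate the *analysis machinery* —
that each estimator recovers what the generator put in — not claims about
real subjects' movements.

## Psychometric fitting

Choice data are fit with a cumulative Gumbel CDF on natural-log duration,
`ψ(d) = γ + (1−γ−λ)·G(ln d; α, β)`, `G(x) = 1 − exp(−exp((x−α)/β))`. With
the default `lapse_mode="fixed0"` (γ = λ = 0) this is exactly a binomial
regression with a complementary log-log link on ln d; the package's
Newton/IRLS implementation agrees with an independent GLM to ~1e-7
(relative) and is vectorized over response vectors so the 1999-replicate
parametric bootstrap refits in milliseconds. The log abscissa makes BP and
DL scale equivariant and CV scale invariant. Thresholds use the
asymptote-corrected probability scale. The optional `estimate` mode bounds
both asymptotes at 0.05 and uses multi-start Nelder–Mead (ties broken by
likelihood, then smaller β).

Reported quantities: BP = ψ⁻¹(0.5), DL = (ψ⁻¹(0.75) − ψ⁻¹(0.25))/2,
CV = DL/BP. Intervals are bias-corrected (BC, not BCa) percentile intervals
from a parametric bootstrap (binomial counts resampled from the fitted
curve, 1999 replicates, deterministic given a seed).

Numerical note: when data are generated from the *Gumbel* law itself,
refitting recovers BP with ~1.6% median error and 94–96% CI coverage at 56
trials/duration. When data come from the log-normal observer instead
(model mismatch: a symmetric-in-log psychometric fit by an asymmetric
Gumbel), the fitted BP is systematically ≈5.8% above the generative
criterion (asymptotically 2115 ms for bp = 2000, σ = 0.3). This bias is a
property of the curve-family choice, affects both conditions equally, and
cancels in the between-group comparisons the pipeline runs.

## Movement readouts

- **Path length**: summed sample-to-sample Euclidean distance in a window.
- **Proximity ratio**: `d_long/d_short`, so values > 1 mean the hand is
  closer to the short target (the figure-facing convention; the printed
  methods text says "short/long" but the results semantics force this
  orientation — a flag flips it).
- **Force direction**: four-quadrant `atan2` angle of (fx, fy), degrees.
- **Normalized readouts** ("softmax"): both map to (0,1) with the neutral
  value at 0.5 exactly. Ratio kind: the distance share
  `d_long/(d_long+d_short)` (a logistic of the log ratio — no free gain).
  Force kind: `logistic((θ − 90°)/s)` with s = 7.5°, a quarter of the 30°
  target separation. The tested contract is monotonicity and the neutral
  point, not the gain, because the original transform's gain is not
  recoverable from the text.
- **Intertrial SD**: per-duration SD of x and y across trials at each of
  the final 100 ms (time-locked to target arrival), averaged over time and
  coordinates (arithmetic mean; root-sum-square available by option).

## Change-of-mind detection

Speed is computed from central differences of position after a 5-ms median
prefilter (suppresses single-sample spikes); ties in maximum speed break to
the earliest sample. Movement onset is the first post-offset sample above
5 cm/s. θ is the angle between V1 (onset → max-speed point) and V2
(max-speed point → chosen target); θ > 40° flags a change of mind, with
direction labeled from the final choice (a COM ending at long is
short→long). θ is invariant to rotation, translation, and uniform time
rescaling of the scene. Against simulator ground truth at default geometry
the detector's sensitivity and specificity are both ≥ 0.95 (measured at
1.00 at the defaults).

## Time-resolved decoding

At each time step in the last 1000 ms of the tone (aligned so t = −1 ms is
the final pre-offset sample) the model `Y ~ 1 + D + M + (1|S)` is fit —
binomial response, logit link, per-subject random intercept — by maximum
likelihood under the Laplace approximation. The fitter is native: penalized
IRLS jointly solves the fixed effects and subject modes at fixed
random-effect SD through a Schur-complement solve, Brent's method profiles
the SD, and a final L-BFGS polish maximizes the full Laplace objective
(which the PIRLS step alone ignores through the log-determinant term). On
reference datasets the coefficient agrees with lme4's `glmer` (Laplace,
nAGQ = 1) to four decimals and the Wald SE to < 1%; with zero random-effect
variance it reduces to a plain logistic regression. Wald covariance is the
inverse Schur-complement Fisher information at the optimum, conditional on
the estimated variance, as in standard GLMM software.

Quasi-separation (runaway standardized slope or non-finite SE) is flagged
and the timepoint's p set to NaN — never counted as significant. Bonferroni
correction is applied over the number of fitted steps: 1-ms steps over the
1000-ms window give the adjusted α = 0.05/1000 = 5e-5; desk-scale runs
default to 10-ms steps with correction over the actual 100 tests. The
"earliest decodable time" is the length of the maximal contiguous
significant run ending at offset; isolated significant points are reported
separately but not counted. Variants: `middle_only` (2000-ms trials only,
D dropped) and `pre_onset` (onset-aligned window).

## Reproduction scoring

Reproduced duration = movement stop − movement start in the reproduction
phase (5 cm/s crossings); a stop requires a ≥ 200-ms stationary tail so
micro-pauses do not split the movement. Central tendency is the OLS slope
of reproduced on presented duration; CV is the per-duration sample SD/mean.
Path similarity uses the discrete Fréchet distance (Eiter–Mannila dynamic
program, verified against exhaustive coupling enumeration for all polyline
pairs with ≤ 6 vertices); for trial-level comparability both phases are
resampled to a common 100-point arc-length grid before the distance is
taken (the core operation itself does not resample). Distances are
reported in cm.

## Nonparametric statistics

Mann–Whitney U (midrank ties, asymptotic p with tie correction), Wilcoxon
signed rank (zero differences dropped), Spearman ρ, and Cohen's d (pooled
SD unpaired; SD of differences paired). Every test also reports a
permutation p-value: exact enumeration whenever the permutation space has
≤ 1e5 elements (all group labelings, all sign patterns, all orderings),
otherwise Monte Carlo with the add-one rule, 10,000 permutations by
default, deterministic given a seed. Two-sided p-values use deviation of
the statistic from its null center. Mixed-model ANOVAs and partial
eta-squared are out of scope by design and left to general-purpose
statistics packages.

## Pipelines and problem sizes

`pipeline.run_experiment1_vs_2 / 3 / 4` chain simulation → fitting →
comparison with one seed and return machine-readable reports plus a
manifest (config hash, seeds, stage status); identical config + seeds
reproduce identical outputs. Group-level CV comparisons depend only on the
choice table, so power/calibration runs use the simulator's fast path
(choices and RTs without 1000-Hz trajectories); trajectory simulation is
switched on where a kinematic quantity enters (change-of-mind removal,
Fréchet scoring). Default desk-scale sizes, chosen so the full validation
battery runs in minutes on one core: 20 subjects/group × 392 trials for
group comparisons; 2000 trajectory-level trials for detector operating
characteristics; decoding at 10-ms steps with 16 subjects × 40 trials per
calibration replicate, 100 null replicates and 30 ordering replicates; 200
psychometric-recovery datasets with 1999-replicate bootstraps each.

## Known limitations

- The Gumbel/log-normal BP bias above (~6%) means absolute BP estimates
  under model mismatch inherit the curve-family convention; comparisons
  across conditions are unaffected.
- The decoding Wald p-values rely on asymptotic normality; at the 5e-5
  Bonferroni threshold the realized family-wise error at desk-scale sample
  sizes is consistent with, but measured only to binomial precision around,
  the nominal 5%.
- Only a single change of mind per trial is modeled and detected (the
  binary criterion); multiple reversals would be collapsed into one θ.
- The per-trial reproduction movement model is a convenience construction;
  its Fréchet distances validate the scoring machinery, not any claim about
  how closely real subjects retrace their encoding movements.
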