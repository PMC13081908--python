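# Methods

This note documents the models, defaults and numerical choices behind
foragekit, and what the synthetic cohort does and does not emulate.

## Task schedules

The four schedules are implemented as pure step functions over a small
mutable environment state.

* **Bandit p_hi:p_lo.** One side ("high") rewards a poke with probability
  `p_hi`, the other with `p_lo`; the study variants are 100:0 and 80:20.
  Any outcome poke that does not deliver a pellet starts a 10 s timeout.
  After every 20th pellet the high side flips, immediately on the 20th
  pellet and before the next poke (no stated delay in the schedule).
* **FR1.** Left pokes always deliver; right pokes have no programmed
  consequence and no timeout.
* **Resetting PR1.** Pellet *n* costs *n* left pokes; 30 minutes without a
  left poke resets the requirement to 1. The reset is evaluated *lazily* at
  the next left poke rather than by a clock thread, which reproduces the
  rule exactly while keeping the simulator single-threaded; the run's
  breakpoint is emitted retroactively.

Across all tasks a pellet must be retrieved before another can be earned.
Pokes made while the well is loaded or during a timeout are **blocked**:
they are logged (they count toward total pokes and poke-based accuracy) but
carry no outcome and are excluded from trial sequences. Blocked pokes do
not re-arm an active timeout; whether the hardware re-arms is unknown, and
the no-re-arm choice is the conservative one.

## WSLS agent

Choice follows lapse-then-rule: with probability λ a uniform random choice;
otherwise stay with probability *w* after a win, switch with probability
*l* after a loss. Applying the lapse gate first yields the closed forms
`P(stay|win) = (1−λ)w + λ/2` and `P(stay|loss) = (1−λ)(1−l) + λ/2`, which
the estimator tests use as oracles; the alternative order (rule first,
lapse on top) is observationally equivalent here but has no clean closed
form. The first trial, and any trial without outcome history, is uniform
random. A "loss" is any outcome poke that did not deliver a pellet,
including unrewarded pokes on the high-probability side of the 80:20
variant and unrewarded right pokes in FR1 (FR1 win-stay therefore treats
every poke as a trial with win ⇔ pellet; without this, FR1 stay metrics
would be undefined).

Study-scale settings: *l* = 0.5, λ = 0.25, *w* swept over [0.5, 1.0] in
steps of 0.05, 100 agents × 300 trials per reward pair (100:0 … 60:40).
`fit_lapse` recovers λ from observed (win-stay, accuracy) points by grid
search on the mean squared distance to the simulated sweep curve; the
original fitting objective behind λ = 0.25 is unspecified, so this
objective is an explicit artifact choice.

## Trial parsing and metrics

A log is scanned once into per-poke records carrying the blocked flag, the
win/loss outcome (a poke "wins" if a pellet event follows it before the
next poke), the active side at poke time, the latency from the previous
event ("poke time") and the pellet→retrieval latency ("retrieval time").
Poke time is not defined by the device documentation (beam-break duration
versus inter-poke latency); here it is the pre-poke latency, which the
synthetic generator controls through its inter-event gap distribution.

* **Accuracy** is the fraction of *all* pokes (blocked included) on the
  active/high-probability side.
* **Win-stay / lose-stay** are transition frequencies over consecutive
  outcome trials; the last trial of a session has no successor and never
  enters a denominator, and a condition with no transitions reports
  missing (NaN), not zero.
* **Sessions are summarised by medians** for retrieval and poke times —
  home-cage records contain hours-long pauses that would dominate a mean.
* **PR1 runs** are reconstructed from ≥30-minute gaps between non-blocked
  left pokes; the k-th pellet's price is the count of such pokes since the
  previous pellet, the run's breakpoint is its highest rewarded ratio, and
  the demand table counts pellets per price across runs (prices beyond the
  largest attained ratio are censoring, not zero demand).
* **Exclusions**: a mouse is dropped if any session day earned fewer than
  75 pellets or if any scheduled task/day is missing. Day boundaries
  follow the per-day session files produced at ingest.

## Choice-history regression

The default design codes lag k (k = 1..5) as +1 for a rewarded left
choice, −1 for a rewarded right choice and 0 for an unrewarded choice at
t−k; a dual coding with separate rewarded/unrewarded histories is
available behind a flag. The fit is a logistic MLE with intercept and an
L2 ridge of 10⁻³ on the slopes (absolute scale; it moves a well-conditioned
10⁴-trial fit by ≲10⁻³, verified against an unpenalized fit, while keeping
near-separated data — pure exploiters — finite). Standard errors come from
the inverse observed information at the optimum. Coefficients beyond ±10
are flagged as separation-dominated. Group summaries are means ± SE of
per-mouse odds ratios.

## Demand model

Consumption is fit on the log₁₀ scale by nonlinear least squares
(`scipy.optimize.curve_fit`, initialised at Q₀ = max Q, k = 1,
a = 1/(Q₀·C̄), all parameters bounded positive). The reported **α** is the
price at which the *fitted* curve crosses Q₀/2 — solved as
`α = −ln(1 − log₁₀2 / k)/(aQ₀)` — not the native exponential-demand rate
`a`, matching the operational definition used for this kind of data.
**β** is dQn/d(log₁₀C) at α, with Qn = Q/Q₀; the log-price scale matches
standard demand plots, and the scale choice is configurable in analysis
code built on `beta_at_alpha`. A curve is flagged *inelastic* when the
fitted curve never halves (k ≤ log₁₀2) or when observed consumption never
falls to half its own maximum in the observed price range (flat or rising
demand, where Q₀ and `a` are unidentifiable); α is then reported at the
maximum observed price. Fits need ≥4 distinct prices with nonzero
consumption; zero-consumption prices are dropped as censoring.

## Phenotyping

Seven session metrics (pellets, pokes, accuracy, win-stay, lose-stay,
median retrieval time, median poke time) from the deterministic bandit
(averaged over its 3 days) and FR1 form a mice × 14 table. PCA runs on
z-scored columns with a deterministic sign convention (each component's
largest-|loading| entry is positive). The sex classifier is a logistic
regression on a feature subset — default {accuracy, win-stay, pokes,
retrieval time} × both tasks; the six-feature alternative {retrieval time,
win-stay, accuracy} × both tasks is selectable — evaluated by seeded
stratified 5-fold cross-validation with within-fold standardisation, so no
held-out mouse touches its own scaler or fit. The scheme is recorded in
the report because reported accuracies are meaningless without it.

## Power

Empirical power at per-group size N draws N subjects per group *without*
replacement within each of 1000 resamples (a subsample of the observed
animals; a bootstrap is available by flag) and runs a pooled-variance
unpaired two-tailed t-test at α = 0.05 (Welch by flag). No multiplicity
correction is applied inside the loop, since the loop tests a single
metric. The analytic curve is the noncentral-t power at equal group sizes
(statsmodels `TTestIndPower`), with Cohen's d in the pooled-SD form.
`required_n` returns the smallest grid N from which the curve stays at or
above the target, which is robust to Monte-Carlo wiggle near the crossing.
Note that subsampling a finite cohort without replacement understates
between-experiment variability as N approaches the cohort size, so the
empirical curve is anti-conservative at the top of the grid; this is
inherent to the resampling design, not a defect of the estimator.

## Synthetic cohort

The generator's defaults are the study conditions: 62 female / 74 male
mice; schedule bandit 100:0 × 3 days, FR1 × 1, bandit 80:20 × 2, PR1 × 2.
Per-mouse parameters, drawn once per cohort:

| parameter | distribution | default |
|---|---|---|
| win-stay *w* | truncated normal on [0.5, 1] | M: 0.82 ± 0.072, F: 0.771 ± 0.086 |
| lose-shift *l* | truncated normal on [0, 1] | 0.5 ± 0.05 (both sexes) |
| lapse λ | truncated normal on [0, 1] | 0.25 ± 0.05 |
| retrieval time | log-normal, per-mouse median | F median 5 s, male ×0.8, σ 0.6 |
| poke gap | log-normal, per-mouse median | 90 s, σ 0.9 |
| daily pellet budget | truncated normal [110, 240] | task- and sex-specific means 165–187 |
| PR1 median quit ratio | truncated normal [6, 20] | 9 ± 1.5 |

The per-sex win-stay spreads are read as between-mouse SDs (as SEMs they
would be impossibly large), and the per-mouse spreads of *l* and λ are
invented small values (their real between-animal variability is
unreported). Bandit and FR1 sessions run the WSLS agent through the real
schedules until the day's pellet budget is met, which places daily intake
in the realistic ~120–190 pellets/day band; event times come from the
log-normal timing model, so no blocked pokes occur in generated logs.

PR1 behaviour cannot come from a two-choice stay/shift rule, so PR1 days
use a bout model whose only job is to exercise run/breakpoint/demand
analysis with known ground truth: each run works to a drawn quit ratio
(log-normal around the mouse's median), then pauses (log-normal, σ 0.5);
pauses longer than 30 minutes end the run. The per-mouse pause median
scales with its quit ratio (85 min at quit ratio 9), so daily intake stays
homeostatically stable (~120–135 pellets/day) whether a mouse makes many
short runs or few long ones — mirroring the tight intake spread alongside
variable breakpoints seen in real cohorts. Occasional right pokes (rate
~0.2) give PR1 accuracy near 80%.

**What the generator does not emulate**, hence what passing tests cannot
show about real data: circadian structure (events are spread through the
day without a light/dark rhythm); learning (agent parameters are constant
within and across days, so there is no acquisition curve after reversals
beyond the WSLS dynamics); correlated pellet budgets across tasks (budgets
are drawn independently per task, so cross-task intake correlations are
near zero even though strategy and timing metrics do correlate); satiety
and meal patterning; and the study's higher run counts arise here from the
pause model rather than measured inter-bout dynamics (the generator
produces ~27 runs over 2 PR1 days versus ~18 reported, with matching
breakpoints and intake — intake and breakpoint realism were prioritised
over run count when the three could not be matched simultaneously with a
two-parameter pause model).

## Reproducibility and problem sizes

All randomness flows from numpy `Generator`s. A single run seed fans out
through `SeedSequence` spawning (per mouse, per session) and per-stage
seeds derived by hashing the stage name, so rerunning one stage never
perturbs another's stream; identical seeds give byte-identical CSV
outputs. The test suite checks estimator consistency at 100 agents × 300
trials, the end-to-end study at the full 62/74 cohort over the 3-day
bandit phase across 15 fixed seeds, demand recovery over 100 noisy
replicates, and power calibration over N = 4..60 at 1000 resamples —
sizes chosen so the whole suite completes in about a minute while leaving
Monte-Carlo error well below the tolerances asserted. Empirical-vs-analytic
power agreement is asserted as the stated ±0.03 band on the true curves
plus the binomial sampling margin of a 1000-resample estimate, since the
point estimates themselves fluctuate by up to ±0.05.

## Known limitations

* The native-FED3 CSV adapter covers the common column layout; firmware
  variants may need a custom column map.
* The pipeline's estimated *w* inverts the stay-after-win closed form at
  the fixed study lapse (0.25); mice whose true lapse differs absorb the
  difference into ŵ.
* Demand α is extrapolated when the half-maximum lies below the smallest
  observed price; such fits carry the inelastic flag instead of a
  meaningless α.
* The empirical power curve inherits the anti-conservatism of
  finite-cohort subsampling at large N, as noted above.
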