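# Methods

## Task model

A trial hides a target circle (radius `r_target`, default 100 px) at a
location drawn uniformly under the constraint that the initial reinforcement
circle (radius `r_init`, default 400 px, concentric with the target) lies
entirely on the 1920×1080 screen; the feasible region for the center is
therefore `[400, 1520] × [400, 680]`. Clicks are evaluated against the
reinforcement radius *in force before the click* — the contraction triggered
by a reinforced click applies only from the next click on, matching a
schedule defined as the radius "after the n-th reinforcement". Both circles
are closed disks (`distance ≤ radius`); the boundary is a measure-zero set,
but scripted tests need a fixed convention. Clicks inside the target are
also reinforced and also increment the contraction count. The count is
clamped at `n_max`, so the window plateaus at `r_target`. A trial ends at
the first run of `consec_stop` (10) consecutive target clicks, else at
`max_clicks` (50).

The shaping family is

    r(n) = r_init − (r_init − r_target) · (1 − e^{bn}) / (1 − e^{b·n_max}).

It is singular at b = 0; `|b| < 1e−8` dispatches to the closed linear form
`r_init − n(r_init − r_target)/n_max`, which is its Taylor limit (numerically
the two agree to < 1e−3 px at b = 1e−9). The three experimental arms are
presets b = −0.3 (concave up), b ≈ 0 (linear), b = +0.3 (concave down);
endpoints r(0) = r_init and r(n_max) = r_target hold for every b. Concavity
classification uses second finite differences over n = 0..n_max, which agree
with the sign of b analytically (r'' ∝ −b²e^{bn}/(e^{b·n_max} − 1)).

## Synthetic participants

No behavioral model of the human participants exists, so the cohort is an
invented parametric stand-in with the minimal mechanism that makes
reinforcement history causally matter: a **win-stay/shift** searcher. It
clicks uniformly until first reinforced; thereafter it samples an isotropic
Gaussian around the last reinforced location, multiplying its spread by
`shrink` (< 1) after each reinforcement and by `grow` (> 1, capped at
`spread_cap`) after each miss. Off-screen draws are rejected and redrawn
(clamping would pile probability on the edges). With probability `lapse` a
click is replaced by a uniform one. Under this mechanism a front-loaded
(concave-up) contraction forces the search anchor close to the target early
— each reinforcement certifies the anchor is within the current window —
while a back-loaded (concave-down) contraction hands out easy reinforcements
whose anchors can sit far from the target, leaving the agent stranded when
the window finally collapses.

Cohort heterogeneity: each participant's `sigma_exploit` is perturbed
log-normally and `lapse` logit-normally with SD `skill_sd` on the
transformed scale, fixed across that participant's 45 trials. This induces
the between-participant variance component the mixed model estimates.

**Calibration.** The outcome ordering (mean AA concave_up > linear >
concave_down; mean clicks reversed) is emergent, so defaults were fixed by a
one-time seeded grid search over (`sigma_exploit`, `shrink`, `grow`,
`lapse`) at reduced cohort size, scored by whether both orderings hold and
by the smaller adjacent AA gap (`autoshape.calibrate`, rerunnable via
`autoshape calibrate`). The frozen defaults are `sigma_exploit = 140 px`,
`shrink = 0.65`, `grow = 1.2`, `lapse = 0.01`, `skill_sd = 0.35`,
`spread_cap = 400 px`; they sit in a region of the grid where both orderings
hold at every seed tried, and reproduce them at full cohort scale
(54 × 45 trials).

What the generator does *not* emulate: systematic (e.g. raster-scan) human
search strategies, learning or fatigue across trials, breaks, motor noise in
pixel quantization, or the empirical magnitudes of the human outcomes.
Passing tests therefore certify the machinery — the task rules, metrics and
inference — and the *direction* of shaping effects, not human effect sizes: simulated
arm gaps are wide and click counts high relative to what practiced humans
would plausibly produce, and only signs and orderings are asserted anywhere.

## Outcomes

**Target flags.** Each trial yields a length-50 binary vector: observed
in-target flags, with slots after an early stop imputed as 1 (the
participant had demonstrably located the target; counting the hypothetical
remaining clicks as hits keeps trajectories comparable across trial
lengths). **Total clicks** counts actual clicks only, so the two outcomes are
inversely related but not redundant.

**Trajectory and AA.** Flags are averaged over a participant's trials of one
arm, loess-smoothed, and integrated by the trapezoid rule over unit-spaced
click indices (maximum AA = 49 for 50 clicks; a Riemann-sum alternative with
maximum 50 sits behind `integration_rule="riemann"`). Loess details are
conventional for the smoother family: local polynomial degree 2 (degree is
configurable), tricube weights, span 0.4 interpreted as the nearest-neighbor
window fraction (`ceil(0.4·50) = 20` points), no robustness iterations;
fitted values are clamped to [0, 1] because local polynomials overshoot
probabilities. Degenerate windows (fewer distinct abscissae than the
polynomial order needs) fall back to a global polynomial fit. The
implementation is verified against an independent per-index weighted
least-squares oracle to 1e−6.

## Inference

**AA model.** `aa ~ function` with a participant random intercept, fit by
REML (statsmodels `MixedLM`), referent = linear. Wald 95% intervals
(normal approximation) for fixed effects; the concave_down-vs-concave_up
contrast comes from the coefficient covariance, so it equals the coefficient
difference exactly. Fits whose random-intercept variance collapses (or that
raise convergence warnings) are flagged `singular`, never silently dropped.

**Variance partition.** Two decompositions are reported side by side
because a residual-free two-way summary of "between-subject" vs "shaping
function" variance is ambiguous between them: (a) the classical VPC
σ²_between / (σ²_between + σ²_residual), and (b) a three-way split of
fixed-effect variance (variance of the fixed-effect predictor), σ²_between
and σ²_residual over their sum, plus the between/fixed pair renormalized to
sum to one. Output labels carry the definition; the ambiguity is surfaced,
not resolved.

**Clicks model.** Per-trial counts are overdispersed (across-participant
heterogeneity makes variance exceed the mean), so the final model is a
negative-binomial regression with log link (statsmodels discrete NB, MLE
dispersion), referent = linear; exponentiated coefficients are IRRs. A
companion Poisson GLM supplies the Pearson dispersion (Σ squared Pearson
residuals / residual df) as the overdispersion diagnostic — the estimator is
a design choice, as "dispersion parameter" alone does not pin one down. A
crossed-random-effects NB GLMM (participant × trial) was considered and not
implemented: targets are independently placed per trial, so trial-level
random effects are negligible by construction and the plain GLM is the
parsimonious final model.

**Diagnostics.** Q-Q pairs use (i − 0.5)/n plotting positions against
standardized residuals; the density summary is a Gaussian KDE on a 128-point
grid. Constant residuals produce a flagged degenerate output.

## Reproducibility and problem sizes

A master seed feeds a `SeedSequence` tree: one child for cohort
heterogeneity, one per participant, and one per trial (placement + agent
noise), so cohorts replay byte-identically and participants are independent.
The click log is a CSV with a fixed column contract, booleans as 0/1 and
full-precision floats; reading re-validates every record invariant
(reinforced ⇔ distance ≤ radius, target ⇒ reinforced, non-increasing radius)
and names the first offending row.

Test problem sizes are chosen to exercise the full default cohort once
(54 participants × 45 trials) and to run recovery simulations at 200
replicates for interval-coverage checks (binomial error band 0.90–0.995
around the nominal 0.95); most unit tests use reduced cohorts (12 × 18
trials) since the properties under test are scale-free.

## Known limitations

- The agent family is a modeling convenience; its parameters were calibrated
  to orderings, not fit to data (no human click logs are available), so
  absolute AA/click magnitudes are not comparable to human values.
- The linear mixed model and NB GLM assume the trial order is exchangeable;
  the simulator has no drift across trials, so this holds by construction
  but would need checking on real data.
- Loess degree and the meaning of its bandwidth are conventions; both are
  configurable and the defaults are documented above.
- `n_reinforcements_after` is not part of the CSV log contract and is not
  recoverable on load (it is re-derivable from flags and the schedule).
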