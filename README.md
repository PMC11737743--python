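# autoshape

Simulation and analysis of **automatic behavior shaping**: reinforcing
successive approximations of a target behavior while an algorithm — not a
human trainer — tightens the reinforcement criterion over time.

The concrete task is a hidden-target click game. A target circle of radius
100 px is hidden at a random location on a 1920×1080 screen, surrounded by a
concentric *reinforcement circle* that starts at 400 px. Clicks inside the
reinforcement circle are reinforced, and each reinforcement contracts the
circle toward the target according to a one-parameter shaping function

    r(n) = r_init − (r_init − r_target) · (1 − e^{bn}) / (1 − e^{b·n_max})

where *n* counts reinforcements, with r_init = 400 px, r_target = 100 px and
n_max = 10, so r(0) = 400 and r(10) = 100 for every contraction rate *b*.
Negative *b* gives a **concave-up** schedule (rapid early tightening),
positive *b* a **concave-down** one (slow early tightening), and the b → 0
Taylor limit is the **linear** schedule r(n) = −30n + 400. A trial ends after
10 consecutive clicks in the target or 50 clicks, whichever comes first.

The package provides, as a library with a thin CLI on top:

- `autoshape.shaping` — the shaping-function family, presets b ∈ {−0.3, 0, 0.3};
- `autoshape.engine` — the trial/session state machine (placement, click
  evaluation under the pre-contraction radius, early stop, CSV click log);
- `autoshape.agents` — synthetic participants. The default is a
  win-stay/shift searcher whose success depends causally on reinforcement
  history, with log-normal between-participant heterogeneity, so simulated
  cohorts have the structure the analysis assumes;
- `autoshape.metrics` — the outcomes: per-trial **total clicks** and the
  **accumulation area (AA)**, the trapezoidal area under the loess-smoothed
  (span 0.4) probability-of-target trajectory, with post-early-stop clicks
  imputed as target clicks;
- `autoshape.stats` — a random-intercept Gaussian mixed model for AA with a
  variance partition, and a negative-binomial regression for total clicks
  with IRRs, a Poisson-dispersion diagnostic, contrasts and Q-Q exports;
- `autoshape.pipeline` / `autoshape.cli` — simulate → analyze → report,
  deterministic given a master seed.

## Worked example

Twelve synthetic participants, six trials per shaping arm
(`python examples/03_cohort_pipeline.py`):

```
        group  aa_mean  aa_sd  clicks_mean  clicks_sd
all_functions   19.387  8.703       39.472     11.326
   concave_up   28.339  4.350       32.458      9.765
       linear   18.928  5.242       40.681     10.587
 concave_down   10.895  5.318       45.278      9.772

                comparison  estimate_aa  ci_low_aa  ci_high_aa   irr  irr_ci_low  irr_ci_high
      linear vs concave_up        9.411      6.252      12.570 0.798       0.728        0.875
    linear vs concave_down       -8.034    -11.193      -4.875 1.113       1.018        1.217
concave_down vs concave_up       17.445     14.286      20.604 0.717       0.654        0.785
```

Mean AA is ordered concave_up > linear > concave_down and mean total clicks
the other way: front-loaded tightening forces the searcher to localize the
target early, so the target behavior is acquired fastest. The mixed-model
coefficient for `linear vs concave_down` is negative (concave-down shaping
lowers AA relative to linear) and the corresponding IRR is above 1
(concave-down trials need more clicks); both signs flip for concave-up. The
Poisson Pearson dispersion on the same counts is 2.60 ≫ 1, which is why the
count model is negative-binomial rather than Poisson.

Other examples: `01_shaping_functions.py` (radius tables and concavity),
`02_single_trial.py` (one agent's click-by-click search trace),
`04_parameter_recovery.py` (both models recover known generative parameters
with ~95% interval coverage).

The same pipeline is scriptable from a shell:

```sh
autoshape simulate --seed 1 --out log.csv
autoshape report --log log.csv
autoshape trajectories --log log.csv --out curves.csv --plot curves.png
```

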