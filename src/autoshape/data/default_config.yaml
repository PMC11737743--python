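agent:
  fixed_point:
  - 0.0
  - 0.0
  grow: 1.2
  kind: win_stay_shift
  lapse: 0.01
  shrink: 0.65
  sigma_exploit: 140.0
  skill_sd: 0.35
  spread_cap: 400.0
consec_stop: 10
integration_rule: trapezoid
loess_degree: 2
max_clicks: 50
n_participants: 54
presets:
  concave_down:
    b: 0.3
    n_max: 10
    r_init: 400.0
    r_target: 100.0
  concave_up:
    b: -0.3
    n_max: 10
    r_init: 400.0
    r_target: 100.0
  linear:
    b: 0.0
    n_max: 10
    r_init: 400.0
    r_target: 100.0
screen:
  height: 1080.0
  width: 1920.0
seed: 1
span: 0.4
trials_per_function: 15
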