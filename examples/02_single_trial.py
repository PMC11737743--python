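"""Run one trial with a win-stay/shift agent and trace its search.

Prints each click's distance to the hidden target, the window radius in
force, and the reinforcement flags: you can watch the window contract and
the agent's clicks home in until ten consecutive target clicks stop the
trial.
"""

import numpy as np

from autoshape import ScreenGeometry, TrialConfig, run_trial
from autoshape.agents import AgentParams, make_agent
from autoshape.shaping import preset

cfg = TrialConfig(screen=ScreenGeometry(), shaping=preset("concave_up"))
agent = make_agent(AgentParams())
trial = run_trial(agent, cfg, np.random.default_rng(4))

print(f"target center: ({trial.center[0]:.0f}, {trial.center[1]:.0f})")
print("click  distance  window  reinforced  in_target")
for c in trial.clicks:
    print(
        f"{c.click_index:>5d}  {c.distance:8.1f}  {c.radius_in_force:6.1f}"
        f"  {str(c.reinforced):>10}  {str(c.in_target):>9}"
    )
print(f"total clicks: {trial.total_clicks}, ended early: {trial.ended_early}")
# distance should trend toward zero as reinforcements re-anchor the search
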