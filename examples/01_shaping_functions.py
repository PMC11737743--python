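"""Evaluate the three shaping schedules and classify their concavity.

The reinforcement window starts at 400 px and contracts to the 100 px
target over 10 reinforcements; the contraction rate b controls whether the
tightening is front-loaded (b < 0, concave up), even (b ~ 0, linear), or
back-loaded (b > 0, concave down).
"""

from autoshape import classify_concavity, default_presets, radius

presets = default_presets()
print("n   " + "".join(f"{lab:>14}" for lab in presets))
for n in range(11):
    row = "".join(f"{radius(spec, n):14.2f}" for spec in presets.values())
    print(f"{n:<4d}{row}")

for lab, spec in presets.items():
    print(f"b = {spec.b:+.1f}  ->  {classify_concavity(spec)}")

# Each column starts at 400 px and ends at 100 px; the concave-up arm has
# already given up most of its slack by n = 3, while the concave-down arm
# keeps a wide window until the final contractions.
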