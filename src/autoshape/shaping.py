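"""Shaping-function family for the contracting reinforcement window.

In an automatic behavior-shaping task the reinforcement criterion tightens as
the learner succeeds: here, a reinforcement circle of radius ``r(n)`` contracts
toward a fixed target circle after each reinforcement.  The family is

    r(n) = r_init - (r_init - r_target) * (1 - exp(b * n)) / (1 - exp(b * n_max))

for contraction rate ``b != 0``, with the linear schedule

    r(n) = r_init - n * (r_init - r_target) / n_max

as its ``b -> 0`` limit.  Negative ``b`` gives a concave-up schedule (rapid
early narrowing), positive ``b`` a concave-down one (slow early narrowing).
After ``n_max`` reinforcements the radius stays at ``r_target``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

__all__ = [
    "LINEAR_B_THRESHOLD",
    "FUNCTION_LABELS",
    "ShapingSpec",
    "radius",
    "linear_limit",
    "classify_concavity",
    "preset",
    "default_presets",
]

#: |b| below this dispatches to the closed linear form; the exponential form
#: is 0/0 at b = 0.
LINEAR_B_THRESHOLD = 1e-8

#: Canonical arm labels, ordered by contraction rate b.
FUNCTION_LABELS = ("concave_up", "linear", "concave_down")


@dataclass(frozen=True)
class ShapingSpec:
    """Parameters of one shaping schedule.

    Parameters
    ----------
    b:
        Contraction rate.  ``b < 0`` tightens fast early (concave up),
        ``b > 0`` tightens slowly early (concave down), ``|b| ~ 0`` is linear.
    r_init:
        Initial reinforcement-circle radius in px.
    r_target:
        Target-circle radius in px; the window never contracts below it.
    n_max:
        Number of reinforcements after which the window equals the target.
    """

    b: float
    r_init: float = 400.0
    r_target: float = 100.0
    n_max: int = 10
    label: str = field(init=False)

    def __post_init__(self) -> None:
        if not self.r_init > self.r_target > 0:
            raise ValueError(
                f"require r_init > r_target > 0, got {self.r_init}, {self.r_target}"
            )
        if self.n_max < 1:
            raise ValueError(f"n_max must be >= 1, got {self.n_max}")
        if abs(self.b) < LINEAR_B_THRESHOLD:
            lab = "linear"
        elif self.b < 0:
            lab = "concave_up"
        else:
            lab = "concave_down"
        object.__setattr__(self, "label", lab)


def radius(spec: ShapingSpec, n: int) -> float:
    """Reinforcement-circle radius after the n-th reinforcement.

    ``n`` is clamped at ``spec.n_max``: once the window has contracted to the
    target it is held constant for the remainder of the trial.

    Raises
    ------
    ValueError
        If ``n`` is negative.
    """
    n = int(n)
    if n < 0:
        raise ValueError(f"reinforcement count must be non-negative, got {n}")
    n = min(n, spec.n_max)
    if abs(spec.b) < LINEAR_B_THRESHOLD:
        return linear_limit(n, spec)
    span = spec.r_init - spec.r_target
    frac = (1.0 - math.exp(spec.b * n)) / (1.0 - math.exp(spec.b * spec.n_max))
    r = spec.r_init - span * frac
    # guard tiny float excursions outside the analytic range
    return min(max(r, spec.r_target), spec.r_init)


def linear_limit(n: int, spec: ShapingSpec | None = None) -> float:
    """Linear shaping schedule, the Taylor limit of the family at b = 0.

    With the default geometry this is ``r(n) = -30 n + 400``.
    """
    if spec is None:
        spec = ShapingSpec(0.0)
    n = int(n)
    if not 0 <= n <= spec.n_max:
        raise ValueError(f"n must lie in [0, {spec.n_max}], got {n}")
    return spec.r_init - n * (spec.r_init - spec.r_target) / spec.n_max


def classify_concavity(spec: ShapingSpec, tol: float = 1e-6) -> str:
    """Classify a schedule by the second finite differences of its radii.

    Returns ``"concave_up"`` when all second differences over ``n = 0..n_max``
    are positive, ``"concave_down"`` when all negative, ``"linear"`` when all
    within ``tol`` of zero.  Agrees with the sign of ``b`` by construction.
    """
    rs = [radius(spec, n) for n in range(spec.n_max + 1)]
    d2 = [rs[i + 1] - 2 * rs[i] + rs[i - 1] for i in range(1, len(rs) - 1)]
    if all(abs(v) <= tol for v in d2):
        return "linear"
    if all(v > 0 for v in d2):
        return "concave_up"
    if all(v < 0 for v in d2):
        return "concave_down"
    raise ValueError("schedule has mixed concavity; not a member of the family")


_PRESET_B = {"concave_up": -0.3, "linear": 0.0, "concave_down": 0.3}


def preset(label: str, **overrides) -> ShapingSpec:
    """One of the three named experimental arms (b in {-0.3, 0, 0.3})."""
    try:
        b = _PRESET_B[label]
    except KeyError:
        raise KeyError(
            f"unknown preset {label!r}; choose from {sorted(_PRESET_B)}"
        ) from None
    return ShapingSpec(b=b, **overrides)


def default_presets() -> dict[str, ShapingSpec]:
    """The three experimental arms keyed by label."""
    return {lab: preset(lab) for lab in FUNCTION_LABELS}
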