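"""Synthetic participants for the hidden-target click task.

The experiment's subjects are human; the cohort here is a parametric stand-in
with exactly the structure the downstream analysis assumes: search behavior
that is causally sensitive to reinforcement history (so different contraction
schedules produce different outcomes) and between-participant heterogeneity
(so a between-subject variance component exists to estimate).

The workhorse is a win-stay/shift searcher: it explores uniformly until its
first reinforcement, then re-centers an isotropic Gaussian on the last
reinforced location, shrinking its spread multiplicatively after each
reinforcement and growing it (capped) after each miss.  An occasional "lapse"
replaces the draw with a uniform click.  Degenerate agents (uniform random,
fixed point, target-center oracle) exist for tests and boundary anchors.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "AgentParams",
    "Participant",
    "RandomAgent",
    "OracleAgent",
    "FixedPointAgent",
    "WinStayShiftAgent",
    "make_agent",
    "make_cohort",
]

AGENT_KINDS = ("random", "oracle", "fixed_point", "win_stay_shift")


@dataclass(frozen=True)
class AgentParams:
    """Cohort-level agent parameters.

    sigma_exploit is the initial local-search spread in px; shrink/grow are
    the multiplicative spread updates on reinforcement / non-reinforcement
    (grow capped at spread_cap); lapse is the per-click probability of an
    off-policy uniform click; skill_sd perturbs sigma_exploit (log-normally)
    and lapse (logit-normally) per participant, fixed across that
    participant's trials.

    Defaults are the frozen one-time calibration shipped with the package
    (see ``autoshape.calibrate``).
    """

    kind: str = "win_stay_shift"
    sigma_exploit: float = 140.0
    shrink: float = 0.65
    grow: float = 1.2
    lapse: float = 0.01
    skill_sd: float = 0.35
    spread_cap: float = 400.0
    fixed_point: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if self.kind not in AGENT_KINDS:
            raise ValueError(f"unknown agent kind {self.kind!r}")
        if not 0 < self.shrink < 1 < self.grow:
            raise ValueError("require 0 < shrink < 1 < grow")
        if not 0 <= self.lapse < 1:
            raise ValueError("lapse must lie in [0, 1)")
        if self.sigma_exploit <= 0:
            raise ValueError("sigma_exploit must be positive")


class RandomAgent:
    """Clicks uniformly over the screen, ignoring all feedback."""

    def next_click(self, last_feedback, screen, rng):
        return (
            float(rng.uniform(0.0, screen.width)),
            float(rng.uniform(0.0, screen.height)),
        )


class OracleAgent:
    """Test-only agent that is handed the target center and always clicks it."""

    def __init__(self) -> None:
        self._center: tuple[float, float] | None = None

    def begin_trial(self, center) -> None:
        self._center = center

    def next_click(self, last_feedback, screen, rng):
        if self._center is None:
            raise RuntimeError("oracle agent was not given the target center")
        return self._center


class FixedPointAgent:
    """Always clicks the same point."""

    def __init__(self, point: tuple[float, float]) -> None:
        self.point = (float(point[0]), float(point[1]))

    def next_click(self, last_feedback, screen, rng):
        return self.point


class WinStayShiftAgent:
    """Reinforcement-driven local searcher (win-stay/shift).

    Before the first reinforcement: uniform exploration.  After a reinforced
    click: anchor on that click, sample a Gaussian around the anchor with the
    current spread, then spread <- spread * shrink.  After a miss: keep the
    anchor, spread <- min(spread * grow, spread_cap), sample around it.
    Off-screen draws are rejected and redrawn rather than clamped, so no
    probability mass piles up on the edges.  A lapse click is uniform and
    leaves the search state untouched.
    """

    def __init__(
        self,
        sigma_exploit: float,
        shrink: float,
        grow: float,
        lapse: float,
        spread_cap: float = 400.0,
    ) -> None:
        self.sigma0 = float(sigma_exploit)
        self.shrink = float(shrink)
        self.grow = float(grow)
        self.lapse = float(lapse)
        self.cap = float(spread_cap)
        self.anchor: tuple[float, float] | None = None
        self.spread = self.sigma0
        self._last_click: tuple[float, float] | None = None

    def _uniform(self, screen, rng):
        return (
            float(rng.uniform(0.0, screen.width)),
            float(rng.uniform(0.0, screen.height)),
        )

    def _gaussian(self, screen, rng):
        # rejection sampling keeps the click on screen without edge pile-up
        ax, ay = self.anchor
        for _ in range(1000):
            x = ax + self.spread * rng.standard_normal()
            y = ay + self.spread * rng.standard_normal()
            if 0 <= x <= screen.width and 0 <= y <= screen.height:
                return (float(x), float(y))
        return (float(min(max(ax, 0.0), screen.width)), float(min(max(ay, 0.0), screen.height)))

    def next_click(self, last_feedback, screen, rng):
        if last_feedback == "reinforced":
            self.anchor = self._last_click
            shrink_after = True
        else:
            shrink_after = False
            if last_feedback == "not_reinforced" and self.anchor is not None:
                self.spread = min(self.spread * self.grow, self.cap)
        if self.anchor is None:
            click = self._uniform(screen, rng)
        elif self.lapse > 0 and rng.uniform() < self.lapse:
            click = self._uniform(screen, rng)
        else:
            click = self._gaussian(screen, rng)
        if shrink_after:
            self.spread = max(self.spread * self.shrink, 1e-9)
        self._last_click = click
        return click


@dataclass(frozen=True)
class Participant:
    """One synthetic subject: concrete parameters fixed across all trials.

    ``make_agent`` returns a fresh agent per trial, so there is no memory of
    earlier targets."""

    participant_id: str
    params: AgentParams

    def make_agent(self):
        return make_agent(self.params)


def make_agent(params: AgentParams):
    if params.kind == "random":
        return RandomAgent()
    if params.kind == "oracle":
        return OracleAgent()
    if params.kind == "fixed_point":
        return FixedPointAgent(params.fixed_point)
    return WinStayShiftAgent(
        sigma_exploit=params.sigma_exploit,
        shrink=params.shrink,
        grow=params.grow,
        lapse=params.lapse,
        spread_cap=params.spread_cap,
    )


def _logit(p: float) -> float:
    return math.log(p / (1.0 - p))


def _expit(z: float) -> float:
    return 1.0 / (1.0 + math.exp(-z))


def make_cohort(
    params: AgentParams,
    n_participants: int,
    rng: np.random.Generator,
) -> list[Participant]:
    """Draw a cohort with between-participant heterogeneity.

    Each participant's sigma_exploit is perturbed log-normally and their lapse
    logit-normally, both with standard deviation ``skill_sd`` on the
    transformed scale; a lapse of exactly 0 stays 0.  With ``skill_sd = 0``
    every participant is identical.  Perturbed values are fixed for all of
    that participant's trials, which is what induces a nonzero
    between-subject variance component in the outcomes.
    """
    if n_participants < 1:
        raise ValueError("n_participants must be >= 1")
    cohort: list[Participant] = []
    for i in range(n_participants):
        pid = f"p{i + 1:03d}"
        if params.kind == "win_stay_shift" and params.skill_sd > 0:
            sigma = params.sigma_exploit * math.exp(
                params.skill_sd * rng.standard_normal()
            )
            if params.lapse > 0:
                lapse = _expit(_logit(params.lapse) + params.skill_sd * rng.standard_normal())
            else:
                lapse = 0.0
            p = replace(params, sigma_exploit=sigma, lapse=lapse)
        else:
            p = params
        cohort.append(Participant(participant_id=pid, params=p))
    return cohort
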