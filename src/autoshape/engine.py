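"""Trial and session state machine for the hidden-target click task.

A trial hides a target circle (radius ``r_target``) at a uniformly random
location such that the initial reinforcement circle fits on screen.  The agent
clicks; a click is reinforced when it lands inside the reinforcement circle in
force, and each reinforcement contracts that circle per the shaping schedule.
A trial ends after ``consec_stop`` consecutive clicks inside the target circle
(early stop) or after ``max_clicks`` clicks, whichever comes first.

Both circles are closed disks: "within" means distance <= radius.  The click
that triggers a contraction is judged under the pre-contraction radius; the
new radius applies from the next click.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .shaping import ShapingSpec, radius

__all__ = [
    "ScreenGeometry",
    "TrialConfig",
    "ClickRecord",
    "TrialResult",
    "TrialState",
    "place_target",
    "evaluate_click",
    "run_trial",
    "run_session",
    "trial_to_frame",
    "LOG_COLUMNS",
]

#: Click-log column contract between the simulate and analyze stages.
LOG_COLUMNS = [
    "participant_id",
    "trial_index",
    "function_label",
    "click_index",
    "x",
    "y",
    "distance",
    "radius_in_force",
    "reinforced",
    "in_target",
    "ended_early",
]


@dataclass(frozen=True)
class ScreenGeometry:
    """Screen size in px (default 1920 x 1080)."""

    width: float = 1920.0
    height: float = 1080.0


@dataclass(frozen=True)
class TrialConfig:
    screen: ScreenGeometry
    shaping: ShapingSpec
    max_clicks: int = 50
    consec_stop: int = 10

    def __post_init__(self) -> None:
        if not 1 <= self.consec_stop <= self.max_clicks:
            raise ValueError("require 1 <= consec_stop <= max_clicks")
        r0 = self.shaping.r_init
        if self.screen.width < 2 * r0 or self.screen.height < 2 * r0:
            raise ValueError(
                "screen cannot contain the initial reinforcement circle: "
                f"{self.screen.width}x{self.screen.height} vs radius {r0}"
            )


@dataclass(frozen=True)
class ClickRecord:
    """One click event, judged under the radius in force before the click."""

    participant_id: str
    trial_index: int
    function_label: str
    click_index: int
    x: float
    y: float
    distance: float
    radius_in_force: float
    reinforced: bool
    in_target: bool
    n_reinforcements_after: int


@dataclass
class TrialResult:
    center: tuple[float, float]
    clicks: list[ClickRecord]
    ended_early: bool

    @property
    def total_clicks(self) -> int:
        return len(self.clicks)


@dataclass
class TrialState:
    """Mutable per-trial state threaded through :func:`evaluate_click`."""

    config: TrialConfig
    center: tuple[float, float]
    participant_id: str = "p0"
    trial_index: int = 1
    n_reinforcements: int = 0
    consec_in_target: int = 0
    clicks: list[ClickRecord] = field(default_factory=list)

    @property
    def radius_in_force(self) -> float:
        return radius(self.config.shaping, self.n_reinforcements)


def place_target(config: TrialConfig, rng: np.random.Generator) -> tuple[float, float]:
    """Draw the shared circle center uniformly, keeping the initial
    reinforcement circle entirely on screen."""
    r0 = config.shaping.r_init
    w, h = config.screen.width, config.screen.height
    if w < 2 * r0 or h < 2 * r0:
        raise ValueError("infeasible geometry: reinforcement circle exceeds screen")
    x = rng.uniform(r0, w - r0)
    y = rng.uniform(r0, h - r0)
    return (float(x), float(y))


def evaluate_click(state: TrialState, x: float, y: float) -> ClickRecord:
    """Score one click against the current window and update the state.

    Flags use the pre-click radius; a reinforced click increments the
    contraction count (clamped at ``n_max``), so the contracted radius
    applies from the next click onward.
    """
    scr = state.config.screen
    if not (0 <= x <= scr.width and 0 <= y <= scr.height):
        raise ValueError(f"click ({x}, {y}) is off screen")
    cx, cy = state.center
    dist = float(np.hypot(x - cx, y - cy))
    r_now = state.radius_in_force
    reinforced = dist <= r_now
    in_target = dist <= state.config.shaping.r_target
    if reinforced and state.n_reinforcements < state.config.shaping.n_max:
        state.n_reinforcements += 1
    state.consec_in_target = state.consec_in_target + 1 if in_target else 0
    rec = ClickRecord(
        participant_id=state.participant_id,
        trial_index=state.trial_index,
        function_label=state.config.shaping.label,
        click_index=len(state.clicks) + 1,
        x=float(x),
        y=float(y),
        distance=dist,
        radius_in_force=r_now,
        reinforced=reinforced,
        in_target=in_target,
        n_reinforcements_after=state.n_reinforcements,
    )
    state.clicks.append(rec)
    return rec


def run_trial(
    agent,
    config: TrialConfig,
    rng: np.random.Generator,
    *,
    center: tuple[float, float] | None = None,
    participant_id: str = "p0",
    trial_index: int = 1,
) -> TrialResult:
    """Run one trial to completion.

    The agent is queried click by click and told, before each click, whether
    its previous click was reinforced (``"none"`` before the first).  An agent
    exposing ``begin_trial`` is handed the target center first (used only by
    the oracle agent in tests and anchors).
    """
    if center is None:
        center = place_target(config, rng)
    state = TrialState(
        config=config,
        center=center,
        participant_id=participant_id,
        trial_index=trial_index,
    )
    if hasattr(agent, "begin_trial"):
        agent.begin_trial(center)
    feedback = "none"
    while len(state.clicks) < config.max_clicks:
        x, y = agent.next_click(feedback, config.screen, rng)
        rec = evaluate_click(state, x, y)
        feedback = "reinforced" if rec.reinforced else "not_reinforced"
        if state.consec_in_target >= config.consec_stop:
            break
    ended_early = state.consec_in_target >= config.consec_stop
    return TrialResult(center=center, clicks=state.clicks, ended_early=ended_early)


def trial_to_frame(result: TrialResult) -> pd.DataFrame:
    """Flatten one trial into click-log rows (see :data:`LOG_COLUMNS`)."""
    rows = [
        {
            "participant_id": c.participant_id,
            "trial_index": c.trial_index,
            "function_label": c.function_label,
            "click_index": c.click_index,
            "x": c.x,
            "y": c.y,
            "distance": c.distance,
            "radius_in_force": c.radius_in_force,
            "reinforced": int(c.reinforced),
            "in_target": int(c.in_target),
            "ended_early": int(result.ended_early),
        }
        for c in result.clicks
    ]
    return pd.DataFrame(rows, columns=LOG_COLUMNS)


def run_session(
    participants,
    presets: dict[str, ShapingSpec],
    screen: ScreenGeometry,
    trials_per_function: int,
    seed,
    *,
    max_clicks: int = 50,
    consec_stop: int = 10,
) -> pd.DataFrame:
    """Simulate a cohort session and return the concatenated click log.

    Each participant receives ``trials_per_function`` trials of every shaping
    arm, shuffled with a participant-specific stream; targets are placed
    independently per trial and each trial gets a freshly instantiated agent,
    so nothing carries over between trials except the participant's own
    parameters.

    ``seed`` may be an int or a :class:`numpy.random.SeedSequence`; a master
    seed spawns per-participant streams (trial order, placement, agent noise)
    so cohorts replay exactly and participants are independent.
    """
    if trials_per_function < 1:
        raise ValueError("trials_per_function must be >= 1")
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    labels = sorted(presets)
    schedule_base = [lab for lab in labels for _ in range(trials_per_function)]
    frames: list[pd.DataFrame] = []
    part_seeds = ss.spawn(len(participants))
    for participant, pseed in zip(participants, part_seeds):
        shuffle_ss, trials_ss = pseed.spawn(2)
        order = list(schedule_base)
        np.random.default_rng(shuffle_ss).shuffle(order)
        trial_seeds = trials_ss.spawn(len(order))
        for t_idx, (lab, tseed) in enumerate(zip(order, trial_seeds), start=1):
            cfg = TrialConfig(
                screen=screen,
                shaping=presets[lab],
                max_clicks=max_clicks,
                consec_stop=consec_stop,
            )
            rng = np.random.default_rng(tseed)
            agent = participant.make_agent()
            result = run_trial(
                agent,
                cfg,
                rng,
                participant_id=participant.participant_id,
                trial_index=t_idx,
            )
            frames.append(trial_to_frame(result))
    return pd.concat(frames, ignore_index=True)
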