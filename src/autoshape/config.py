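"""Session configuration: experimental constants, agent parameters, seeds.

Defaults encode the experimental setup: a 1920 x 1080 screen, target radius
100 px, initial reinforcement radius 400 px contracting over 10
reinforcements, contraction rates b in {-0.3, 0, 0.3}, 54 participants with
15 trials per shaping arm (45 trials each), 50 clicks per trial with early
stop after 10 consecutive target clicks, loess span 0.4 and trapezoidal AA.
"""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import yaml

from .agents import AgentParams
from .engine import ScreenGeometry
from .shaping import FUNCTION_LABELS, ShapingSpec

__all__ = ["SessionConfig", "default_config", "load_config", "save_config"]


@dataclass(frozen=True)
class SessionConfig:
    screen: ScreenGeometry = field(default_factory=ScreenGeometry)
    presets: dict = field(
        default_factory=lambda: {
            "concave_up": ShapingSpec(-0.3),
            "linear": ShapingSpec(0.0),
            "concave_down": ShapingSpec(0.3),
        }
    )
    n_participants: int = 54
    trials_per_function: int = 15
    max_clicks: int = 50
    consec_stop: int = 10
    agent: AgentParams = field(default_factory=AgentParams)
    span: float = 0.4
    loess_degree: int = 2
    integration_rule: str = "trapezoid"
    seed: int = 1

    def digest(self) -> str:
        """Stable sha256 of the canonical YAML form, for provenance logs."""
        return hashlib.sha256(
            yaml.safe_dump(_to_plain(self), sort_keys=True).encode()
        ).hexdigest()[:16]


def default_config(**overrides) -> SessionConfig:
    return replace(SessionConfig(), **overrides) if overrides else SessionConfig()


def _to_plain(cfg: SessionConfig) -> dict:
    d = {
        "screen": {"width": cfg.screen.width, "height": cfg.screen.height},
        "presets": {
            lab: {
                "b": s.b,
                "r_init": s.r_init,
                "r_target": s.r_target,
                "n_max": s.n_max,
            }
            for lab, s in cfg.presets.items()
        },
        "n_participants": cfg.n_participants,
        "trials_per_function": cfg.trials_per_function,
        "max_clicks": cfg.max_clicks,
        "consec_stop": cfg.consec_stop,
        "agent": {k: (list(v) if isinstance(v, tuple) else v) for k, v in asdict(cfg.agent).items()},
        "span": cfg.span,
        "loess_degree": cfg.loess_degree,
        "integration_rule": cfg.integration_rule,
        "seed": cfg.seed,
    }
    return d


def save_config(cfg: SessionConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(_to_plain(cfg), sort_keys=True))


def load_config(path: str | Path) -> SessionConfig:
    """Read a YAML session config; omitted keys take the defaults above."""
    data = yaml.safe_load(Path(path).read_text()) or {}
    kwargs = {}
    if "screen" in data:
        kwargs["screen"] = ScreenGeometry(**data["screen"])
    if "presets" in data:
        kwargs["presets"] = {
            lab: ShapingSpec(**params) for lab, params in data["presets"].items()
        }
    if "agent" in data:
        a = dict(data["agent"])
        if "fixed_point" in a:
            a["fixed_point"] = tuple(a["fixed_point"])
        kwargs["agent"] = AgentParams(**a)
    for key in (
        "n_participants",
        "trials_per_function",
        "max_clicks",
        "consec_stop",
        "span",
        "loess_degree",
        "integration_rule",
        "seed",
    ):
        if key in data:
            kwargs[key] = data[key]
    cfg = SessionConfig(**kwargs)
    missing = set(FUNCTION_LABELS) - set(cfg.presets)
    if missing:
        raise ValueError(f"config presets missing arm(s): {sorted(missing)}")
    return cfg
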