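"""Outcome metrics: accumulation area (AA) and total clicks.

The learning outcome of a shaping arm is summarized by the *target behavior
trajectory*: the empirical probability, at each click index 1..50, that the
click landed in the target circle, averaged over a participant's trials of
that arm.  Trials that stopped early (10 consecutive target clicks) have
their remaining click slots imputed as target clicks before averaging.  The
averaged trajectory is loess-smoothed (span 0.4) and integrated by the
trapezoidal rule over unit-spaced click indices, giving the accumulation area
(AA); higher AA means the target behavior was acquired faster.  Total clicks
per trial counts actual clicks only (imputed slots excluded) and is the
per-trial count outcome; AA and total clicks are inversely related.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .engine import TrialResult

__all__ = [
    "target_flags",
    "flags_from_columns",
    "trajectory",
    "smooth_loess",
    "accumulation_area",
    "total_clicks",
    "aa_table",
    "clicks_table",
    "trajectory_table",
]


def flags_from_columns(
    in_target: np.ndarray, ended_early: bool, max_clicks: int
) -> np.ndarray:
    """Binary target-flag vector of length ``max_clicks`` with early-stop
    imputation: slots past the last actual click are scored 1 when the trial
    ended early (they can only exist in that case)."""
    obs = np.asarray(in_target, dtype=float)
    n = obs.size
    if n > max_clicks:
        raise ValueError(f"trial has {n} clicks but max_clicks={max_clicks}")
    if n < max_clicks and not ended_early:
        raise ValueError("short trial without the early-stop flag")
    flags = np.ones(max_clicks, dtype=float) if ended_early else np.zeros(max_clicks)
    flags[:n] = obs
    if ended_early:
        flags[n:] = 1.0
    return flags


def target_flags(trial: TrialResult, max_clicks: int = 50) -> np.ndarray:
    """Target flags for one trial, imputing post-early-stop slots as hits."""
    obs = np.array([c.in_target for c in trial.clicks], dtype=float)
    return flags_from_columns(obs, trial.ended_early, max_clicks)


def trajectory(flag_vectors, max_clicks: int = 50) -> np.ndarray:
    """Element-wise mean of per-trial target-flag vectors.

    Accepts an iterable of flag vectors (or TrialResults)."""
    mats = []
    for fv in flag_vectors:
        if isinstance(fv, TrialResult):
            fv = target_flags(fv, max_clicks)
        mats.append(np.asarray(fv, dtype=float))
    if not mats:
        raise ValueError("trajectory requires at least one trial")
    return np.mean(mats, axis=0)


def smooth_loess(
    raw: np.ndarray,
    span: float = 0.4,
    degree: int = 2,
    clamp: tuple[float, float] | None = (0.0, 1.0),
) -> np.ndarray:
    """Loess smoothing over click index.

    Locally weighted polynomial regression: at each index, the nearest
    ``ceil(span * n)`` points are fit with a degree-``degree`` polynomial
    under tricube weights, and the fitted value at that index is returned.
    ``span`` is the fraction of points in each nearest-neighbor window.
    Fitted values are clamped to ``clamp`` (probabilities can be overshot by
    local polynomials); pass ``clamp=None`` to disable.

    Windows too degenerate for the local fit (fewer distinct abscissae than
    ``degree + 1``) fall back to a global polynomial fit.
    """
    y = np.asarray(raw, dtype=float)
    n = y.size
    if not 0 < span <= 1:
        raise ValueError("span must lie in (0, 1]")
    if n < 2:
        raise ValueError("need at least two points to smooth")
    x = np.arange(n, dtype=float)
    k = max(int(math.ceil(span * n)), degree + 2)
    k = min(k, n)
    if k <= degree + 1:
        # global fallback: too few points for a local fit anywhere
        coeffs = np.polyfit(x, y, min(degree, n - 1))
        out = np.polyval(coeffs, x)
    else:
        out = np.empty(n)
        for i in range(n):
            d = np.abs(x - x[i])
            idx = np.argsort(d, kind="stable")[:k]
            dw = d[idx]
            dmax = dw.max()
            if dmax == 0:
                out[i] = y[idx].mean()
                continue
            w = (1.0 - (dw / dmax) ** 3) ** 3
            w[w < 0] = 0.0
            out[i] = _wls_fit_at(x[idx] - x[i], y[idx], w, degree)
    if clamp is not None:
        out = np.clip(out, clamp[0], clamp[1])
    return out


def _wls_fit_at(dx: np.ndarray, yw: np.ndarray, w: np.ndarray, degree: int) -> float:
    # weighted polynomial fit centered at the evaluation point; the fitted
    # value there is the intercept
    pos = w > 0
    if np.unique(dx[pos]).size <= degree:
        deg = max(np.unique(dx[pos]).size - 1, 0)
    else:
        deg = degree
    X = np.vander(dx, deg + 1, increasing=True)
    sw = np.sqrt(w)
    beta, *_ = np.linalg.lstsq(X * sw[:, None], yw * sw, rcond=None)
    return float(beta[0])


def accumulation_area(values: np.ndarray, rule: str = "trapezoid") -> float:
    """Area under a trajectory over unit-spaced click indices.

    The default trapezoid rule integrates over the 49 unit intervals of a
    50-click trajectory (max AA = 49 for an all-target trajectory); the
    ``"riemann"`` alternative sums the values (max 50).
    """
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("need at least two points to integrate")
    if rule == "trapezoid":
        return float(np.trapezoid(v))
    if rule == "riemann":
        return float(v.sum())
    raise ValueError(f"unknown integration rule {rule!r}")


def total_clicks(trial: TrialResult) -> int:
    """Number of actual clicks in a trial; imputed slots are never counted."""
    return trial.total_clicks


def _iter_trials(log: pd.DataFrame):
    for (pid, t_idx), g in log.groupby(["participant_id", "trial_index"], sort=True):
        g = g.sort_values("click_index")
        yield pid, t_idx, g


def clicks_table(log: pd.DataFrame) -> pd.DataFrame:
    """Per-trial total clicks: one row per participant x trial."""
    rows = []
    for pid, t_idx, g in _iter_trials(log):
        rows.append(
            {
                "participant_id": pid,
                "trial_index": int(t_idx),
                "function_label": g["function_label"].iloc[0],
                "total_clicks": int(len(g)),
            }
        )
    return pd.DataFrame(rows)


def aa_table(
    log: pd.DataFrame,
    max_clicks: int = 50,
    span: float = 0.4,
    degree: int = 2,
    rule: str = "trapezoid",
) -> pd.DataFrame:
    """Per participant x shaping arm AA: one row per (participant, label)."""
    curves = trajectory_table(log, max_clicks=max_clicks, span=span, degree=degree)
    rows = []
    for (pid, lab), g in curves.groupby(["participant_id", "function_label"], sort=True):
        g = g.sort_values("click_index")
        rows.append(
            {
                "participant_id": pid,
                "function_label": lab,
                "aa": accumulation_area(g["smoothed"].to_numpy(), rule=rule),
            }
        )
    return pd.DataFrame(rows)


def trajectory_table(
    log: pd.DataFrame,
    max_clicks: int = 50,
    span: float = 0.4,
    degree: int = 2,
) -> pd.DataFrame:
    """Raw and smoothed trajectories, long format: one row per
    (participant, label, click index)."""
    per_trial: dict[tuple[str, str], list[np.ndarray]] = {}
    for pid, _t, g in _iter_trials(log):
        lab = g["function_label"].iloc[0]
        flags = flags_from_columns(
            g["in_target"].to_numpy(), bool(g["ended_early"].iloc[0]), max_clicks
        )
        per_trial.setdefault((pid, lab), []).append(flags)
    rows = []
    for (pid, lab), vecs in sorted(per_trial.items()):
        raw = trajectory(vecs, max_clicks)
        smoothed = smooth_loess(raw, span=span, degree=degree)
        for i in range(max_clicks):
            rows.append(
                {
                    "participant_id": pid,
                    "function_label": lab,
                    "click_index": i + 1,
                    "raw": raw[i],
                    "smoothed": smoothed[i],
                }
            )
    return pd.DataFrame(rows)
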