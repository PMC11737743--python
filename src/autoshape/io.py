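"""Click-log I/O: the CSV contract between the simulate and analyze stages.

One row per click with a header; columns exactly
participant_id, trial_index, function_label, click_index, x, y, distance,
radius_in_force, reinforced, in_target, ended_early (a trial-level flag
repeated per row).  Booleans are stored as 0/1; floats with full round-trip
precision, so write -> read is lossless.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .engine import LOG_COLUMNS, TrialResult, ClickRecord

__all__ = ["write_click_log", "read_click_log", "log_to_trials", "ClickLogError"]


class ClickLogError(ValueError):
    """Raised when a click log violates the schema or a record invariant."""


def write_click_log(log: pd.DataFrame, path: str | Path) -> None:
    missing = [c for c in LOG_COLUMNS if c not in log.columns]
    if missing:
        raise ClickLogError(f"log is missing column(s): {missing}")
    log[LOG_COLUMNS].to_csv(path, index=False)


def read_click_log(path: str | Path, r_target: float = 100.0) -> pd.DataFrame:
    """Load and validate a click log.

    Validation re-checks the record invariants row by row: reinforced is
    equivalent to distance <= radius_in_force, a target click implies a
    reinforced one, in_target is equivalent to distance <= r_target, and the
    radius in force never increases within a trial.  The first offending row
    is named in the error.
    """
    df = pd.read_csv(path)
    if list(df.columns) != LOG_COLUMNS:
        raise ClickLogError(
            f"schema mismatch: expected columns {LOG_COLUMNS}, got {list(df.columns)}"
        )
    _validate(df, r_target)
    return df


def _validate(df: pd.DataFrame, r_target: float) -> None:
    dist = df["distance"].to_numpy(float)
    r = df["radius_in_force"].to_numpy(float)
    reinforced = df["reinforced"].to_numpy().astype(bool)
    in_target = df["in_target"].to_numpy().astype(bool)
    bad = np.nonzero(reinforced != (dist <= r))[0]
    if bad.size:
        raise ClickLogError(
            f"row {bad[0]}: reinforced flag inconsistent with distance/radius"
        )
    bad = np.nonzero(in_target & ~reinforced)[0]
    if bad.size:
        raise ClickLogError(f"row {bad[0]}: in_target without reinforced")
    bad = np.nonzero(in_target != (dist <= r_target))[0]
    if bad.size:
        raise ClickLogError(
            f"row {bad[0]}: in_target flag inconsistent with distance and "
            f"r_target={r_target}"
        )
    for (pid, t), g in df.groupby(["participant_id", "trial_index"], sort=False):
        rr = g.sort_values("click_index")["radius_in_force"].to_numpy(float)
        if np.any(np.diff(rr) > 1e-9):
            raise ClickLogError(
                f"participant {pid} trial {t}: radius_in_force increases"
            )


def log_to_trials(df: pd.DataFrame) -> list[TrialResult]:
    """Reconstruct TrialResult objects from a click log.

    The target center is not part of the log schema, so reconstructed trials
    carry a NaN center; all metrics operate on flags and counts only.
    """
    trials = []
    for (pid, t_idx), g in df.groupby(["participant_id", "trial_index"], sort=True):
        g = g.sort_values("click_index")
        clicks = [
            ClickRecord(
                participant_id=str(pid),
                trial_index=int(t_idx),
                function_label=row.function_label,
                click_index=int(row.click_index),
                x=float(row.x),
                y=float(row.y),
                distance=float(row.distance),
                radius_in_force=float(row.radius_in_force),
                reinforced=bool(row.reinforced),
                in_target=bool(row.in_target),
                n_reinforcements_after=-1,  # not recoverable from the log
            )
            for row in g.itertuples()
        ]
        trials.append(
            TrialResult(
                center=(float("nan"), float("nan")),
                clicks=clicks,
                ended_early=bool(g["ended_early"].iloc[0]),
            )
        )
    return trials
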