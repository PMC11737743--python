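"""simulate -> analyze -> report, as plain functions.

Each stage consumes and produces DataFrames, so the pipeline composes in
memory or through the CSV click-log contract.  Identical config + seed gives
byte-identical logs and tables.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import metrics, stats
from .agents import make_cohort
from .config import SessionConfig
from .engine import run_session

__all__ = ["simulate", "analyze", "report", "AnalysisResult"]

log = logging.getLogger("autoshape")


def simulate(cfg: SessionConfig) -> pd.DataFrame:
    """Simulate the configured cohort and return the click log.

    The master seed spawns one stream for cohort heterogeneity and one per
    participant for trial order, target placement and agent noise.
    """
    log.info("simulate: config digest %s, seed %s", cfg.digest(), cfg.seed)
    ss = np.random.SeedSequence(cfg.seed)
    cohort_ss, session_ss = ss.spawn(2)
    cohort = make_cohort(cfg.agent, cfg.n_participants, np.random.default_rng(cohort_ss))
    return run_session(
        cohort,
        cfg.presets,
        cfg.screen,
        cfg.trials_per_function,
        session_ss,
        max_clicks=cfg.max_clicks,
        consec_stop=cfg.consec_stop,
    )


@dataclass
class AnalysisResult:
    aa_table: pd.DataFrame
    clicks_table: pd.DataFrame
    aa_fit: stats.ModelFit
    clicks_fit: stats.ModelFit
    variance_partition: dict[str, float]


def analyze(click_log: pd.DataFrame, cfg: SessionConfig) -> AnalysisResult:
    """Compute both outcome tables and fit both outcome models."""
    aa = metrics.aa_table(
        click_log,
        max_clicks=cfg.max_clicks,
        span=cfg.span,
        degree=cfg.loess_degree,
        rule=cfg.integration_rule,
    )
    clicks = metrics.clicks_table(click_log)
    aa_fit = stats.fit_aa_model(aa)
    clicks_fit = stats.fit_clicks_model(clicks)
    return AnalysisResult(
        aa_table=aa,
        clicks_table=clicks,
        aa_fit=aa_fit,
        clicks_fit=clicks_fit,
        variance_partition=stats.variance_partition(aa_fit),
    )


def report(result: AnalysisResult) -> dict[str, pd.DataFrame]:
    """Descriptive and model-summary tables (CSV-ready DataFrames)."""
    desc = stats.descriptives(result.aa_table, result.clicks_table)
    aa_rows = pd.concat(
        [result.aa_fit.coefficients, result.aa_fit.contrasts], ignore_index=True
    )
    clicks_rows = pd.concat(
        [result.clicks_fit.coefficients, result.clicks_fit.contrasts],
        ignore_index=True,
    )
    model = aa_rows.merge(
        clicks_rows, on="comparison", suffixes=("_aa", "_clicks")
    )
    vp = pd.DataFrame([result.variance_partition])
    return {"descriptives": desc, "model_summary": model, "variance_partition": vp}


def format_report(tables: dict[str, pd.DataFrame]) -> str:
    """Aligned-text rendering of the report tables."""
    parts = []
    for name, df in tables.items():
        parts.append(name)
        parts.append("-" * len(name))
        parts.append(df.to_string(index=False, float_format=lambda v: f"{v:.3f}"))
        parts.append("")
    return "\n".join(parts)
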