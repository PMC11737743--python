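"""Inference layer: mixed model for AA, negative-binomial model for clicks.

AA is analyzed with a random-intercept Gaussian linear mixed model,
``AA ~ shaping function`` with a participant random intercept (REML), the
linear arm as referent.  Its variance components support two partitions of
the total outcome variance; a residual-free two-way summary (between-subject
share vs shaping-function share summing to one) is ambiguous between them,
so both are reported:

* ``vpc_between`` — the classical variance partition coefficient,
  between-participant variance / (between + residual);
* a three-way split of fixed-effect, between-participant and residual
  variance, each as a share of their sum, plus ``share_between_of_explained``
  / ``share_fixed_of_explained`` which renormalize the between and
  fixed-effect components to sum to one (the reading consistent with a
  residual-free two-way summary).

Total clicks per trial is an overdispersed count: a Poisson fit's Pearson
dispersion (sum of squared Pearson residuals over residual df) diagnoses the
overdispersion, and the final model is a negative-binomial regression with a
log link, whose exponentiated coefficients are incidence rate ratios (IRR).
All intervals are 95% Wald.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.tools.sm_exceptions import ConvergenceWarning

from .shaping import FUNCTION_LABELS

__all__ = [
    "ModelFit",
    "Diagnostics",
    "fit_aa_model",
    "variance_partition",
    "fit_clicks_model",
    "residual_diagnostics",
    "descriptives",
]

_Z95 = scipy.stats.norm.ppf(0.975)


@dataclass
class ModelFit:
    """Fitted-coefficient container for either outcome model.

    ``coefficients`` and ``contrasts`` are DataFrames with one row per
    comparison and columns estimate / ci_low / ci_high (plus irr columns for
    the count model).  ``variance_components`` is populated for the mixed
    model only, ``dispersion`` (Poisson Pearson dispersion) for the count
    model only.
    """

    outcome: str
    referent: str
    coefficients: pd.DataFrame
    contrasts: pd.DataFrame
    residuals: np.ndarray
    fittedvalues: np.ndarray
    variance_components: dict[str, float] | None = None
    dispersion: float | None = None
    singular: bool = False
    result: Any = field(default=None, repr=False)


def _check_levels(df: pd.DataFrame) -> None:
    present = set(df["function_label"].unique())
    missing = set(FUNCTION_LABELS) - present
    if missing:
        raise ValueError(
            f"function level(s) missing from data: {sorted(missing)}; "
            f"present: {sorted(present)}"
        )


def _wald_row(name: str, est: float, se: float) -> dict[str, float]:
    return {
        "comparison": name,
        "estimate": est,
        "ci_low": est - _Z95 * se,
        "ci_high": est + _Z95 * se,
    }


def _term_for(label: str, referent: str) -> str:
    return f"C(function_label, Treatment('{referent}'))[T.{label}]"


def fit_aa_model(aa_table: pd.DataFrame, referent: str = "linear") -> ModelFit:
    """Random-intercept Gaussian mixed model of AA on shaping function.

    Fits ``aa ~ function`` with a participant random intercept by REML and
    reports Wald intervals for the two non-referent arms plus the
    concave-up-vs-concave-down contrast formed from the coefficient
    covariance.  A fit whose random-intercept variance collapses toward zero
    (or that fails to converge) is flagged ``singular`` rather than dropped.
    """
    _check_levels(aa_table)
    if aa_table["participant_id"].nunique() < 2:
        raise ValueError("mixed model requires at least 2 participants")
    formula = f"aa ~ C(function_label, Treatment('{referent}'))"
    model = smf.mixedlm(formula, aa_table, groups=aa_table["participant_id"])
    singular = False
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        res = model.fit(reml=True)
        if any(issubclass(w.category, ConvergenceWarning) for w in caught):
            singular = True
    sigma_b2 = float(res.cov_re.iloc[0, 0])
    sigma_e2 = float(res.scale)
    if sigma_b2 < 1e-8 * max(sigma_e2, 1e-12):
        singular = True

    others = [lab for lab in FUNCTION_LABELS if lab != referent]
    rows, contrast_rows = [], []
    for lab in others:
        term = _term_for(lab, referent)
        rows.append(_wald_row(f"{referent} vs {lab}", float(res.params[term]), float(res.bse[term])))
    # contrast between the two non-referent arms via the coefficient
    # covariance; the lower-mean arm leads the name, matching the referent-
    # first convention of the per-arm rows
    a, b = others[::-1]
    ta, tb = _term_for(a, referent), _term_for(b, referent)
    cov = res.cov_params()
    est = float(res.params[tb] - res.params[ta])
    se = float(np.sqrt(cov.loc[ta, ta] + cov.loc[tb, tb] - 2 * cov.loc[ta, tb]))
    contrast_rows.append(_wald_row(f"{a} vs {b}", est, se))

    fixed = np.asarray(model.exog @ res.fe_params, dtype=float)
    var_fixed = float(np.var(fixed))
    return ModelFit(
        outcome="aa",
        referent=referent,
        coefficients=pd.DataFrame(rows),
        contrasts=pd.DataFrame(contrast_rows),
        residuals=np.asarray(res.resid, dtype=float),
        fittedvalues=np.asarray(res.fittedvalues, dtype=float),
        variance_components={
            "between_participant": sigma_b2,
            "residual": sigma_e2,
            "fixed_effect": var_fixed,
        },
        singular=singular,
        result=res,
    )


def variance_partition(fit: ModelFit) -> dict[str, float]:
    """Partition the AA variance among its model components.

    Returns both readings described in the module docstring; the
    ``*_of_explained`` pair renormalizes the between-participant and
    fixed-effect components so they alone sum to one.
    """
    vc = fit.variance_components
    if vc is None:
        raise ValueError("variance partition requires a fitted mixed model")
    b, e, f = vc["between_participant"], vc["residual"], vc["fixed_effect"]
    total = b + e + f
    explained = b + f
    return {
        "vpc_between": b / (b + e) if b + e > 0 else 0.0,
        "share_between": b / total if total > 0 else 0.0,
        "share_fixed": f / total if total > 0 else 0.0,
        "share_residual": e / total if total > 0 else 0.0,
        "share_between_of_explained": b / explained if explained > 0 else 0.0,
        "share_fixed_of_explained": f / explained if explained > 0 else 0.0,
    }


def fit_clicks_model(clicks_table: pd.DataFrame, referent: str = "linear") -> ModelFit:
    """Negative-binomial regression of per-trial total clicks on function.

    Log link, linear arm as referent; the NB dispersion is estimated by
    maximum likelihood.  Exponentiated coefficients are IRRs with Wald
    intervals.  A companion Poisson fit supplies the Pearson dispersion that
    motivates the NB model (values far above 1 indicate overdispersion).
    """
    _check_levels(clicks_table)
    counts = clicks_table["total_clicks"]
    arr = counts.to_numpy()
    if np.any(arr < 0) or not np.allclose(arr, np.round(arr)):
        raise ValueError("total_clicks must be non-negative integers")
    formula = f"total_clicks ~ C(function_label, Treatment('{referent}'))"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        nb = smf.negativebinomial(formula, clicks_table).fit(disp=0, maxiter=200)
        poisson = smf.glm(
            formula, clicks_table, family=sm.families.Poisson()
        ).fit()
    dispersion = float(poisson.pearson_chi2 / poisson.df_resid)

    others = [lab for lab in FUNCTION_LABELS if lab != referent]
    rows = []
    for lab in others:
        term = _term_for(lab, referent)
        row = _wald_row(f"{referent} vs {lab}", float(nb.params[term]), float(nb.bse[term]))
        rows.append(_with_irr(row))
    a, b = others[::-1]
    ta, tb = _term_for(a, referent), _term_for(b, referent)
    cov = nb.cov_params()
    est = float(nb.params[tb] - nb.params[ta])
    se = float(np.sqrt(cov.loc[ta, ta] + cov.loc[tb, tb] - 2 * cov.loc[ta, tb]))
    contrast = _with_irr(_wald_row(f"{a} vs {b}", est, se))

    mu = np.asarray(nb.predict(clicks_table), dtype=float)
    return ModelFit(
        outcome="total_clicks",
        referent=referent,
        coefficients=pd.DataFrame(rows),
        contrasts=pd.DataFrame([contrast]),
        residuals=np.asarray(counts - mu, dtype=float),
        fittedvalues=mu,
        dispersion=dispersion,
        singular=not bool(nb.mle_retvals.get("converged", True)),
        result=nb,
    )


def _with_irr(row: dict[str, float]) -> dict[str, float]:
    row = dict(row)
    row["irr"] = float(np.exp(row["estimate"]))
    row["irr_ci_low"] = float(np.exp(row["ci_low"]))
    row["irr_ci_high"] = float(np.exp(row["ci_high"]))
    return row


@dataclass
class Diagnostics:
    """Q-Q quantile pairs and a residual density summary for export."""

    qq: pd.DataFrame  # columns: theoretical, observed (standardized)
    density: pd.DataFrame  # columns: x, density
    degenerate: bool


def residual_diagnostics(fit: ModelFit, gridsize: int = 128) -> Diagnostics:
    """Normal Q-Q pairs and kernel-density summary of model residuals.

    Residuals are standardized; theoretical quantiles use the (i - 0.5)/n
    plotting positions.  Constant residuals yield a flagged degenerate
    output (identity Q-Q against zeros, a point-mass density)."""
    r = np.asarray(fit.residuals, dtype=float)
    n = r.size
    sd = r.std(ddof=1) if n > 1 else 0.0
    probs = (np.arange(1, n + 1) - 0.5) / n
    theo = scipy.stats.norm.ppf(probs)
    if sd == 0 or not np.isfinite(sd):
        qq = pd.DataFrame({"theoretical": theo, "observed": np.zeros(n)})
        density = pd.DataFrame({"x": [float(r.mean())], "density": [np.inf]})
        return Diagnostics(qq=qq, density=density, degenerate=True)
    z = np.sort((r - r.mean()) / sd)
    qq = pd.DataFrame({"theoretical": theo, "observed": z})
    kde = scipy.stats.gaussian_kde(r)
    xs = np.linspace(r.min() - 2 * sd, r.max() + 2 * sd, gridsize)
    density = pd.DataFrame({"x": xs, "density": kde(xs)})
    return Diagnostics(qq=qq, density=density, degenerate=False)


def descriptives(aa: pd.DataFrame, clicks: pd.DataFrame) -> pd.DataFrame:
    """Mean and SD of AA and total clicks per shaping arm and pooled."""
    rows = []

    def _row(name, aa_vals, click_vals):
        return {
            "group": name,
            "aa_mean": float(np.mean(aa_vals)),
            "aa_sd": float(np.std(aa_vals, ddof=1)),
            "clicks_mean": float(np.mean(click_vals)),
            "clicks_sd": float(np.std(click_vals, ddof=1)),
        }

    rows.append(_row("all_functions", aa["aa"], clicks["total_clicks"]))
    for lab in FUNCTION_LABELS:
        rows.append(
            _row(
                lab,
                aa.loc[aa["function_label"] == lab, "aa"],
                clicks.loc[clicks["function_label"] == lab, "total_clicks"],
            )
        )
    return pd.DataFrame(rows)
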