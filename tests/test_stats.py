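import numpy as np
import pandas as pd
import pytest

from autoshape.shaping import FUNCTION_LABELS
from autoshape.stats import (
    ModelFit,
    descriptives,
    fit_aa_model,
    fit_clicks_model,
    residual_diagnostics,
    variance_partition,
)


def simulate_aa_table(
    rng,
    n_participants=54,
    intercept=31.45,
    delta_down=-2.3,
    delta_up=2.3,
    sigma_b=3.0,
    sigma_e=2.0,
):
    """Draw an AA table from the exact generative model the LMM assumes."""
    deltas = {"linear": 0.0, "concave_down": delta_down, "concave_up": delta_up}
    rows = []
    for i in range(n_participants):
        u = sigma_b * rng.standard_normal()
        for lab in FUNCTION_LABELS:
            rows.append(
                {
                    "participant_id": f"p{i:03d}",
                    "function_label": lab,
                    "aa": intercept + deltas[lab] + u + sigma_e * rng.standard_normal(),
                }
            )
    return pd.DataFrame(rows)


def simulate_clicks_table(rng, n_per_group=810, mu=25.0, irr_down=1.1, irr_up=0.9, alpha=0.1):
    """NB counts with known rate ratios (gamma-Poisson mixture)."""
    rows = []
    mus = {"linear": mu, "concave_down": mu * irr_down, "concave_up": mu * irr_up}
    for lab in FUNCTION_LABELS:
        lam = rng.gamma(1 / alpha, alpha * mus[lab], size=n_per_group)
        counts = rng.poisson(lam)
        for j, c in enumerate(counts):
            rows.append(
                {
                    "participant_id": f"p{j % 54:03d}",
                    "trial_index": j,
                    "function_label": lab,
                    "total_clicks": int(c),
                }
            )
    return pd.DataFrame(rows)


class TestAAModel:
    def test_null_data_gives_null_coefficients(self):
        rng = np.random.default_rng(0)
        df = simulate_aa_table(rng, delta_down=0.0, delta_up=0.0, sigma_b=0.0)
        fit = fit_aa_model(df)
        assert np.all(np.abs(fit.coefficients["estimate"]) < 1.0)
        # generative between-subject variance is zero; the REML estimate
        # should be small relative to the residual variance of 4
        assert fit.variance_components["between_participant"] < 1.0

    def test_recovers_known_fixed_effects(self):
        rng = np.random.default_rng(1)
        df = simulate_aa_table(rng)
        fit = fit_aa_model(df)
        coef = fit.coefficients.set_index("comparison")["estimate"]
        assert coef["linear vs concave_down"] == pytest.approx(-2.3, abs=1.0)
        assert coef["linear vs concave_up"] == pytest.approx(2.3, abs=1.0)

    def test_contrast_equals_coefficient_difference(self):
        rng = np.random.default_rng(2)
        fit = fit_aa_model(simulate_aa_table(rng))
        coef = fit.coefficients.set_index("comparison")["estimate"]
        expected = coef["linear vs concave_up"] - coef["linear vs concave_down"]
        got = fit.contrasts["estimate"].iloc[0]
        assert got == pytest.approx(expected, abs=1e-10)

    def test_referent_invariance_of_pairwise_contrasts(self):
        """Changing the referent permutes coefficients but leaves every
        pairwise arm difference unchanged."""
        rng = np.random.default_rng(3)
        df = simulate_aa_table(rng)

        def pairwise(fit):
            diffs = {}
            for _, row in pd.concat([fit.coefficients, fit.contrasts]).iterrows():
                a, b = row["comparison"].split(" vs ")
                diffs[frozenset((a, b))] = abs(row["estimate"])
            return diffs

        d1 = pairwise(fit_aa_model(df, referent="linear"))
        d2 = pairwise(fit_aa_model(df, referent="concave_down"))
        for key in d1.keys() & d2.keys():
            assert d1[key] == pytest.approx(d2[key], abs=1e-6)

    def test_missing_level_rejected(self):
        rng = np.random.default_rng(4)
        df = simulate_aa_table(rng)
        with pytest.raises(ValueError, match="missing"):
            fit_aa_model(df[df["function_label"] != "linear"])

    def test_intervals_contain_estimates(self):
        fit = fit_aa_model(simulate_aa_table(np.random.default_rng(5)))
        for frame in (fit.coefficients, fit.contrasts):
            assert (frame["ci_low"] <= frame["estimate"]).all()
            assert (frame["estimate"] <= frame["ci_high"]).all()


class TestVariancePartition:
    def test_zero_random_variance_gives_zero_vpc(self):
        """A fit whose random-intercept variance is exactly zero partitions
        no variance to the between-subject component; an estimated fit on
        sigma_b = 0 data stays close to that."""
        rng = np.random.default_rng(6)
        fit = fit_aa_model(simulate_aa_table(rng, sigma_b=0.0))
        exact = ModelFit(
            outcome="aa",
            referent="linear",
            coefficients=fit.coefficients,
            contrasts=fit.contrasts,
            residuals=fit.residuals,
            fittedvalues=fit.fittedvalues,
            variance_components={
                "between_participant": 0.0,
                "residual": 4.0,
                "fixed_effect": 3.5,
            },
        )
        assert variance_partition(exact)["vpc_between"] == 0.0
        assert variance_partition(fit)["vpc_between"] < 0.2

    def test_equal_variances_give_half(self):
        """With sigma_b = sigma_e and null fixed effects the classical VPC
        is ~0.5."""
        rng = np.random.default_rng(7)
        df = simulate_aa_table(
            rng, n_participants=200, delta_down=0, delta_up=0, sigma_b=2.0, sigma_e=2.0
        )
        vp = variance_partition(fit_aa_model(df))
        assert vp["vpc_between"] == pytest.approx(0.5, abs=0.08)

    def test_shares_sum_to_one(self):
        vp = variance_partition(fit_aa_model(simulate_aa_table(np.random.default_rng(8))))
        total = vp["share_between"] + vp["share_fixed"] + vp["share_residual"]
        assert total == pytest.approx(1.0, abs=1e-9)
        both = vp["share_between_of_explained"] + vp["share_fixed_of_explained"]
        assert both == pytest.approx(1.0, abs=1e-9)
        assert all(0 <= v <= 1 for v in vp.values())


class TestClicksModel:
    def test_identical_groups_give_unit_irr(self):
        rng = np.random.default_rng(9)
        df = simulate_clicks_table(rng, irr_down=1.0, irr_up=1.0)
        fit = fit_clicks_model(df)
        assert np.all(np.abs(fit.coefficients["irr"] - 1.0) < 0.08)

    def test_recovers_known_rate_ratios(self):
        rng = np.random.default_rng(10)
        fit = fit_clicks_model(simulate_clicks_table(rng))
        irr = fit.coefficients.set_index("comparison")["irr"]
        assert irr["linear vs concave_down"] == pytest.approx(1.1, abs=0.06)
        assert irr["linear vs concave_up"] == pytest.approx(0.9, abs=0.06)

    def test_irr_is_exponentiated_coefficient(self):
        fit = fit_clicks_model(simulate_clicks_table(np.random.default_rng(11)))
        assert np.allclose(
            fit.coefficients["irr"], np.exp(fit.coefficients["estimate"])
        )

    def test_poisson_dispersion_near_one_for_equidispersed_counts(self):
        rng = np.random.default_rng(12)
        rows = []
        for lab in FUNCTION_LABELS:
            for j, c in enumerate(rng.poisson(25.0, size=600)):
                rows.append(
                    {"participant_id": "x", "trial_index": j, "function_label": lab,
                     "total_clicks": int(c)}
                )
        fit = fit_clicks_model(pd.DataFrame(rows))
        assert fit.dispersion == pytest.approx(1.0, abs=0.15)

    def test_overdispersed_counts_flagged_by_dispersion(self):
        fit = fit_clicks_model(simulate_clicks_table(np.random.default_rng(13), alpha=0.3))
        assert fit.dispersion > 3.0

    def test_non_integer_counts_rejected(self):
        df = simulate_clicks_table(np.random.default_rng(14), n_per_group=30)
        df["total_clicks"] = df["total_clicks"].astype(float)
        df.loc[0, "total_clicks"] = 12.5
        with pytest.raises(ValueError):
            fit_clicks_model(df)


class TestDiagnostics:
    def test_normal_residuals_track_identity(self):
        rng = np.random.default_rng(15)
        fit = fit_aa_model(simulate_aa_table(rng))
        diag = residual_diagnostics(fit)
        assert len(diag.qq) == len(fit.residuals)
        # interior quantiles hug the identity line at n = 162
        inner = diag.qq.iloc[10:-10]
        assert np.max(np.abs(inner["theoretical"] - inner["observed"])) < 0.6
        assert not diag.degenerate

    def test_constant_residuals_flagged_degenerate(self):
        rng = np.random.default_rng(16)
        fit = fit_aa_model(simulate_aa_table(rng))
        fit.residuals = np.zeros_like(fit.residuals)
        assert residual_diagnostics(fit).degenerate


class TestDescriptives:
    def test_four_rows_and_pooled_consistency(self, small_log):
        from autoshape import metrics

        aa = metrics.aa_table(small_log)
        ck = metrics.clicks_table(small_log)
        desc = descriptives(aa, ck)
        assert list(desc["group"]) == ["all_functions", *FUNCTION_LABELS]
        pooled = desc.loc[desc["group"] == "all_functions", "aa_mean"].iloc[0]
        assert pooled == pytest.approx(aa["aa"].mean())
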