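"""Synthetic-control estimator: counterfactual, gaps, effects, balance."""

import numpy as np
import pandas as pd
import pytest

from synthctrl import (
    DgpConfig,
    PoorFitWarning,
    SyntheticControl,
    adjust_donor_level,
    balance_table,
    fit_synthetic_control,
    generate_panel,
    make_study_fixture,
    relative_effect,
    summarize_effect,
)

from conftest import build_panel


def duplicate_treated_panel():
    """Treated unit 'A' duplicates donor 'B' in outcomes and covariates."""
    series = [50.0, 47.0, 44.0, 40.0, 39.0]
    return build_panel(
        outcomes={
            "A": series,
            "B": series,
            "C": [60.0, 58.0, 56.0, 54.0, 52.0],
            "D": [40.0, 39.0, 38.0, 37.0, 36.0],
        },
        covariates={
            "gdp": {
                "A": [5.0] * 5, "B": [5.0] * 5, "C": [9.0] * 5, "D": [1.0] * 5,
            }
        },
        policy_year=2013,
    )


class TestFit:
    def test_duplicated_donor_gives_zero_gap(self):
        fit = fit_synthetic_control(duplicate_treated_panel(), v_mode="equal")
        np.testing.assert_allclose(fit.gap_series_.to_numpy(), 0.0, atol=1e-8)
        assert fit.pre_mspe_ == pytest.approx(0.0, abs=1e-12)

    def test_noiseless_convex_hull_pre_gaps_vanish(self):
        panel, _ = generate_panel(
            DgpConfig(seed=3, noise_sd=0.0, covariate_noise=0.0,
                      treated_in_hull=True, tau=-7.7)
        )
        fit = fit_synthetic_control(panel, v_mode="equal")
        pre_gaps = fit.gap_series_.loc[panel.pre_years].to_numpy()
        assert np.abs(pre_gaps).max() < 1e-6

    def test_study_scale_fit_satisfies_constraints(self, outpatient_panel):
        panel, _ = outpatient_panel
        fit = SyntheticControl(v_mode="auto", random_state=7).fit(panel)
        w = fit.weights_.to_numpy()
        assert (w >= -1e-8).all()
        assert w.sum() == pytest.approx(1.0, abs=1e-8)
        v = fit.importance_.to_numpy()
        assert (v >= 0).all()
        assert v.sum() == pytest.approx(1.0, abs=1e-10)
        # gap identity and pre-MSPE definition
        recon = fit.observed_path_ - fit.synthetic_path_
        pd.testing.assert_series_equal(
            fit.gap_series_, recon, check_names=False
        )
        assert fit.pre_mspe_ == pytest.approx(
            float((fit.gap_series_.loc[panel.pre_years] ** 2).mean())
        )

    def test_affine_equivariance_of_counterfactual(self, outpatient_panel):
        """Adding c to every outcome shifts the synthetic path by c only."""
        panel, _ = outpatient_panel
        c = 7.0
        shifted = build_shifted(panel, c)
        f0 = SyntheticControl(v_mode="equal").fit(panel)
        f1 = SyntheticControl(v_mode="equal").fit(shifted)
        np.testing.assert_allclose(
            f1.synthetic_path_.to_numpy(),
            f0.synthetic_path_.to_numpy() + c,
            atol=1e-6,
        )
        np.testing.assert_allclose(
            f1.gap_series_.to_numpy(), f0.gap_series_.to_numpy(), atol=1e-6
        )

    def test_poor_fit_warns_for_offset_treated_unit(self):
        panel, _ = make_study_fixture("inpatient-like", seed=0)
        with pytest.warns(PoorFitWarning):
            fit_synthetic_control(panel, v_mode="equal")

    def test_adjustment_restores_constructibility(self):
        panel, _ = make_study_fixture("inpatient-like", seed=0)
        adjusted = adjust_donor_level(panel, 10.0)
        fit = fit_synthetic_control(adjusted, v_mode="equal")
        assert fit.pre_mspe_ < 1.0

    def test_unfitted_access_raises(self):
        with pytest.raises(RuntimeError, match="not fitted"):
            SyntheticControl().predict()


def build_shifted(panel, c):
    from synthctrl import PanelDataset

    return PanelDataset(
        outcomes=panel.outcomes + c,
        covariates=panel.covariates,
        treated_unit=panel.treated_unit,
        policy_year=panel.policy_year,
    )


class TestEffectSummary:
    def test_printed_inpatient_identity(self):
        """Mean gap 3.2 on a 2012 level of 34.8 is a 9.2% relative effect."""
        assert round(relative_effect(3.2, 34.8), 1) == 9.2

    def test_simple_arithmetic(self):
        panel = build_panel(
            outcomes={
                "A": [41.0, 40.0, 38.0, 36.0, 34.0],
                "B": [41.0, 40.0, 40.0, 40.0, 40.0],
                "C": [41.0, 40.0, 40.0, 40.0, 40.0],
            },
            policy_year=2012,
        )
        fit = fit_synthetic_control(panel, v_mode="equal")
        # gaps are (-2, -4, -6) against the flat synthetic at 40; baseline 40
        summ = summarize_effect(fit)
        assert summ.mean_post_gap == pytest.approx(-4.0, abs=1e-8)
        assert summ.relative_effect == pytest.approx(10.0, abs=1e-6)
        assert summ.baseline_year == 2011

    def test_zero_gaps_give_zero_effect(self):
        fit = fit_synthetic_control(duplicate_treated_panel(), v_mode="equal")
        summ = fit.effect_summary()
        assert summ.mean_post_gap == pytest.approx(0.0, abs=1e-8)
        assert summ.relative_effect == pytest.approx(0.0, abs=1e-8)

    def test_zero_baseline_rejected(self):
        assert pytest.raises(ZeroDivisionError, relative_effect, 3.2, 0.0)

    def test_baseline_must_be_pre_policy(self, outpatient_panel):
        panel, _ = outpatient_panel
        fit = fit_synthetic_control(panel, v_mode="equal")
        with pytest.raises(ValueError, match="pre-policy"):
            fit.effect_summary(baseline_year=2014)


class TestBalanceTable:
    def test_duplicated_donor_columns_identical(self):
        fit = fit_synthetic_control(duplicate_treated_panel(), v_mode="equal")
        table = fit.balance_table()
        np.testing.assert_allclose(
            table["treated"].to_numpy(), table["synthetic"].to_numpy(),
            atol=1e-6,
        )

    def test_equal_weights_equal_donor_mean(self):
        """With uniform W the synthetic column is the unweighted donor mean."""
        panel, _ = make_study_fixture("null", seed=9)
        fit = SyntheticControl(v_mode="equal").fit(panel)
        J = panel.n_donors
        fit.weights_ = pd.Series(np.full(J, 1.0 / J), index=panel.donors)
        table = fit.balance_table()
        np.testing.assert_allclose(
            table["synthetic"].to_numpy(), table["donor_mean"].to_numpy(),
            atol=1e-9,
        )

    def test_synthetic_column_is_weighted_mean(self, outpatient_panel):
        panel, _ = outpatient_panel
        fit = SyntheticControl(v_mode="equal").fit(panel)
        table = fit.balance_table()
        w = fit.weights_
        # independent weighted mean of raw pre-policy covariate values
        pre = panel.pre_years
        for cov in panel.covariate_names:
            means = panel.covariates[cov].loc[panel.donors, pre].mean(axis=1)
            expect = float((means * w).sum())
            assert table.loc[cov, "synthetic"] == pytest.approx(expect)
        # and the outcome row
        ymeans = panel.outcomes.loc[panel.donors, pre].mean(axis=1)
        assert table.loc["outcome (pre-policy mean)", "synthetic"] == (
            pytest.approx(float((ymeans * w).sum()))
        )

    def test_balance_table_wrapper_checks_panel(self, outpatient_panel):
        panel, _ = outpatient_panel
        fit = SyntheticControl(v_mode="equal").fit(panel)
        other, _ = make_study_fixture("null", seed=1)
        with pytest.raises(ValueError, match="not produced"):
            balance_table(other, fit)
        assert balance_table(panel, fit) is not None
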