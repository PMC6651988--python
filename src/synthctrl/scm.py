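"""Synthetic-control estimator.

Builds a weighted convex combination of donor units whose pre-policy outcomes
and covariates match the treated unit; its post-policy trajectory is the
counterfactual.  The year-by-year gap (observed minus synthetic) estimates
the policy effect.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .optim import DonorWeights, ImportanceWeights, optimize_importance, solve_weights
from .panel import PanelDataset
from .predictors import PredictorMatrices, PredictorSpec, build_predictor_matrices

__all__ = [
    "SyntheticControl",
    "EffectSummary",
    "PoorFitWarning",
    "fit_synthetic_control",
    "summarize_effect",
    "balance_table",
    "relative_effect",
]


class PoorFitWarning(UserWarning):
    """Pre-policy fit is poor; the counterfactual may be unreliable."""


@dataclass
class EffectSummary:
    """Post-policy effect of the intervention on the treated unit.

    ``mean_post_gap`` is the signed mean gap (observed minus synthetic) over
    post-policy years, in percentage points; ``relative_effect`` expresses its
    magnitude as a percentage of the treated unit's outcome in a pre-policy
    baseline year (by default the last pre-policy year).
    """

    mean_post_gap: float
    baseline_year: int
    baseline_level: float
    n_post_years: int

    @property
    def mean_abs_effect(self) -> float:
        return abs(self.mean_post_gap)

    @property
    def relative_effect(self) -> float:
        return self.mean_abs_effect / self.baseline_level * 100.0

    def to_dict(self, display: bool = False) -> dict:
        d = {
            "mean_post_gap": self.mean_post_gap,
            "mean_abs_effect": self.mean_abs_effect,
            "baseline_year": self.baseline_year,
            "baseline_level": self.baseline_level,
            "relative_effect": self.relative_effect,
            "n_post_years": self.n_post_years,
        }
        if display:
            for key in ("mean_post_gap", "mean_abs_effect", "baseline_level",
                        "relative_effect"):
                d[key] = round(d[key], 1)
        return d


def relative_effect(mean_abs_effect: float, baseline_level: float) -> float:
    """Effect magnitude as a percentage of a baseline outcome level."""
    if baseline_level == 0:
        raise ZeroDivisionError("relative effect undefined for zero baseline level")
    return abs(mean_abs_effect) / baseline_level * 100.0


class SyntheticControl(BaseEstimator):
    """Synthetic-control estimator for a one-treated-unit annual panel.

    Parameters
    ----------
    covariates : "all" or sequence of str
        Covariates entering the match as pre-policy means.
    outcome_lags : "all" or sequence of int
        Pre-policy years whose outcomes enter as special predictors.
    v_mode : {"auto", "equal"} or array-like
        How predictor-importance weights V are chosen: ``"auto"`` runs the
        nested optimization minimizing pre-policy outcome MSPE, ``"equal"``
        uses uniform importance, an array fixes V explicitly.
    standardize : bool
        Standardize predictor rows across units before matching (recommended:
        the distance is scale-sensitive and predictors mix persons, currency
        and percentages).
    n_restarts : int
        Random multistarts for the nested V optimization.
    poor_fit_mspe : float
        Warn (never fail) when the pre-policy MSPE exceeds this threshold,
        signalling that no convex combination of donors tracks the treated
        unit — e.g. a treated unit at a persistently different level.
    random_state : int or None
        Seed for the V-optimization restarts; recorded on the fit.

    Attributes
    ----------
    weights_ : pd.Series            donor weights W (simplex)
    importance_ : pd.Series         predictor importance V (simplex)
    synthetic_path_ : pd.Series     synthetic outcome for every year
    gap_series_ : pd.Series         observed treated outcome minus synthetic
    pre_mspe_ : float               mean squared gap over pre-policy years
    objective_ : float              achieved matching objective
    """

    def __init__(
        self,
        covariates="all",
        outcome_lags="all",
        v_mode="auto",
        standardize: bool = True,
        n_restarts: int = 3,
        poor_fit_mspe: float = 25.0,
        random_state: int | None = None,
    ):
        self.covariates = covariates
        self.outcome_lags = outcome_lags
        self.v_mode = v_mode
        self.standardize = standardize
        self.n_restarts = n_restarts
        self.poor_fit_mspe = poor_fit_mspe
        self.random_state = random_state

    # ------------------------------------------------------------------
    def fit(self, panel: PanelDataset, y=None) -> "SyntheticControl":
        """Fit the synthetic control to a validated panel."""
        if not isinstance(panel, PanelDataset):
            raise TypeError("fit expects a PanelDataset")
        spec = PredictorSpec(
            covariates=(
                "all" if self.covariates == "all" else tuple(self.covariates)
            ),
            outcome_lags=(
                "all" if self.outcome_lags == "all" else tuple(self.outcome_lags)
            ),
        )
        pm = build_predictor_matrices(panel, spec, standardize=self.standardize)

        if isinstance(self.v_mode, str):
            if self.v_mode == "auto":
                v = optimize_importance(
                    pm,
                    panel,
                    n_restarts=self.n_restarts,
                    random_state=self.random_state,
                )
            elif self.v_mode == "equal":
                v = ImportanceWeights.equal(pm.row_names)
            else:
                raise ValueError(f"unknown v_mode {self.v_mode!r}")
        else:
            arr = np.asarray(self.v_mode, dtype=float)
            arr = arr / arr.sum()
            v = ImportanceWeights(pd.Series(arr, index=pm.row_names, name="v"))

        dw = solve_weights(pm, v)

        years = panel.years
        Y0 = panel.outcomes.loc[panel.donors, years].to_numpy(dtype=float)
        w = dw.w.to_numpy()
        synthetic = pd.Series(w @ Y0, index=panel.outcomes.columns, name="synthetic")
        observed = panel.outcomes.loc[panel.treated_unit]
        gaps = (observed - synthetic).rename("gap")
        pre_mspe = float(np.mean(gaps.loc[panel.pre_years].to_numpy() ** 2))

        self.panel_ = panel
        self.spec_ = spec
        self.predictors_ = pm
        self.weights_ = dw.w
        self.donor_weights_ = dw
        self.importance_ = v.v
        self.v_mspe_ = v.achieved_mspe
        self.objective_ = dw.objective
        self.synthetic_path_ = synthetic
        self.observed_path_ = observed.rename("observed")
        self.gap_series_ = gaps
        self.pre_mspe_ = pre_mspe
        self.seed_ = self.random_state

        if pre_mspe > self.poor_fit_mspe:
            warnings.warn(
                f"pre-policy MSPE {pre_mspe:.2f} exceeds {self.poor_fit_mspe}: "
                "a synthetic control may not be constructible from this donor "
                "pool (consider a donor-level adjustment)",
                PoorFitWarning,
                stacklevel=2,
            )
        return self

    # ------------------------------------------------------------------
    def predict(self, years=None) -> pd.Series:
        """Synthetic (counterfactual) outcome path; all fitted years by default."""
        self._check_fitted()
        if years is None:
            return self.synthetic_path_.copy()
        return self.synthetic_path_.loc[[int(y) for y in years]]

    def effect_summary(self, baseline_year: int | None = None) -> EffectSummary:
        """Mean post-policy gap and its size relative to a baseline year."""
        self._check_fitted()
        panel = self.panel_
        if baseline_year is None:
            baseline_year = panel.policy_year - 1
        if baseline_year not in panel.pre_years:
            raise ValueError(
                f"baseline year {baseline_year} not in pre-policy period"
            )
        baseline_level = float(
            panel.outcomes.loc[panel.treated_unit, baseline_year]
        )
        if baseline_level == 0:
            raise ZeroDivisionError(
                "relative effect undefined: baseline outcome level is zero"
            )
        post = panel.post_years
        mean_gap = float(self.gap_series_.loc[post].mean())
        return EffectSummary(
            mean_post_gap=mean_gap,
            baseline_year=int(baseline_year),
            baseline_level=baseline_level,
            n_post_years=len(post),
        )

    def balance_table(self) -> pd.DataFrame:
        """Raw-scale predictor balance: treated vs synthetic vs donor mean.

        One row per predictor plus a pre-policy outcome mean row; columns are
        the treated unit's value, the W-weighted donor value, and the
        unweighted donor-pool mean.
        """
        self._check_fitted()
        pm = self.predictors_
        w = self.weights_.to_numpy()
        rows = {
            "treated": pm.raw_X1,
            "synthetic": pm.raw_X0 @ w,
            "donor_mean": pm.raw_X0.mean(axis=1),
        }
        table = pd.DataFrame(rows, index=pm.row_names)
        panel = self.panel_
        pre = panel.pre_years
        y1 = panel.outcomes.loc[panel.treated_unit, pre].to_numpy(dtype=float)
        Y0 = panel.outcomes.loc[panel.donors, pre].to_numpy(dtype=float)
        table.loc["outcome (pre-policy mean)"] = [
            float(y1.mean()),
            float(w @ Y0.mean(axis=1)),
            float(Y0.mean()),
        ]
        return table

    def _check_fitted(self) -> None:
        if not hasattr(self, "weights_"):
            raise RuntimeError("estimator is not fitted; call fit(panel) first")


# ----------------------------------------------------------------------
# thin functional wrappers
# ----------------------------------------------------------------------

def fit_synthetic_control(panel: PanelDataset, **params) -> SyntheticControl:
    """Fit a :class:`SyntheticControl` with the given parameters."""
    return SyntheticControl(**params).fit(panel)


def summarize_effect(
    fit: SyntheticControl, baseline_year: int | None = None
) -> EffectSummary:
    return fit.effect_summary(baseline_year)


def balance_table(panel: PanelDataset, fit: SyntheticControl) -> pd.DataFrame:
    if fit.panel_ is not panel and not fit.panel_.equals(panel):
        raise ValueError("fit was not produced from this panel")
    return fit.balance_table()
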