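"""Difference-in-differences cross-validation regression.

OLS on unit-year rows of

    Y_it = gamma + b1*Treat_i + b2*Post_t + b3*Treat_i*Post_t + b X_it + e_it

with the interaction coefficient b3 as the treatment effect.  Covariates
enter as raw yearly values.  The model carries no unit or year fixed effects
beyond the two dummies (optional two-way fixed effects behind a flag).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.base import BaseEstimator

from .panel import PanelDataset

__all__ = ["DifferenceInDifferences", "DidResult", "fit_did", "build_did_design"]

_INTERACTION = "treat_post"


def build_did_design(
    panel: PanelDataset, covariates="all"
) -> pd.DataFrame:
    """Long unit-year design frame with dummies, interaction and covariates."""
    cov_names = panel.covariate_names if covariates == "all" else list(covariates)
    missing = [c for c in cov_names if c not in panel.covariate_names]
    if missing:
        raise ValueError(f"covariates not in panel: {missing}")
    rows = []
    for unit in panel.unit_ids:
        for year in panel.years:
            row = {
                "unit": unit,
                "year": year,
                "y": float(panel.outcomes.loc[unit, year]),
                "treat": 1.0 if unit == panel.treated_unit else 0.0,
                "post": 1.0 if year >= panel.policy_year else 0.0,
            }
            for c in cov_names:
                row[c] = float(panel.covariates[c].loc[unit, year])
            rows.append(row)
    df = pd.DataFrame(rows)
    df[_INTERACTION] = df["treat"] * df["post"]
    return df


def _rank_check(X: pd.DataFrame) -> None:
    """Raise naming an offending column if the design is rank deficient."""
    arr = X.to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(arr)
    if rank == X.shape[1]:
        return
    for col in X.columns:
        reduced = X.drop(columns=[col]).to_numpy(dtype=float)
        if np.linalg.matrix_rank(reduced) == rank:
            raise np.linalg.LinAlgError(
                f"design matrix is rank deficient: column {col!r} is "
                "collinear or constant within groups"
            )
    raise np.linalg.LinAlgError("design matrix is rank deficient")


@dataclass
class DidResult:
    beta3: float
    ci95: tuple[float, float]
    p_value: float
    params: pd.Series
    bse: pd.Series
    se_mode: str
    resid_summary: dict
    nobs: int
    ols_result: object

    def to_dict(self) -> dict:
        return {
            "beta3": self.beta3,
            "ci95": list(self.ci95),
            "p_value": self.p_value,
            "se_mode": self.se_mode,
            "nobs": self.nobs,
            "coefficients": {
                name: {"estimate": float(self.params[name]), "se": float(self.bse[name])}
                for name in self.params.index
            },
            "residuals": self.resid_summary,
        }


class DifferenceInDifferences(BaseEstimator):
    """Two-dummy DiD regression with covariates on a policy panel.

    Parameters
    ----------
    covariates : "all" or sequence of str
        Covariates entering as raw yearly values; "all" uses every covariate
        in the panel.
    se_mode : {"classical", "cluster"}
        Classical OLS standard errors (default, matching the single-error-term
        model) or cluster-robust by unit.
    two_way_fe : bool
        Add unit and year fixed effects (non-default extension; the base
        model carries only the Treat/Post dummies).

    Attributes
    ----------
    beta3_ : float                  interaction coefficient (treatment effect)
    ci95_ : (float, float)          95% confidence interval for beta3
    p_value_ : float
    params_, bse_ : pd.Series       full coefficient table
    result_ : DidResult
    """

    def __init__(self, covariates="all", se_mode: str = "classical",
                 two_way_fe: bool = False):
        self.covariates = covariates
        self.se_mode = se_mode
        self.two_way_fe = two_way_fe

    def fit(self, panel: PanelDataset, y=None) -> "DifferenceInDifferences":
        if self.se_mode not in ("classical", "cluster"):
            raise ValueError(f"unknown se_mode {self.se_mode!r}")
        df = build_did_design(panel, self.covariates)
        cov_names = [
            c for c in df.columns
            if c not in ("unit", "year", "y", "treat", "post", _INTERACTION)
        ]
        cols = ["treat", "post", _INTERACTION] + cov_names
        X = df[cols].copy()
        if self.two_way_fe:
            unit_d = pd.get_dummies(df["unit"], prefix="unit", drop_first=True,
                                    dtype=float)
            year_d = pd.get_dummies(df["year"], prefix="year", drop_first=True,
                                    dtype=float)
            # unit FE absorb treat, year FE absorb post; keep the interaction
            X = pd.concat([X.drop(columns=["treat", "post"]), unit_d, year_d],
                          axis=1)
        X = sm.add_constant(X, prepend=True, has_constant="add")
        _rank_check(X)

        model = sm.OLS(df["y"].to_numpy(), X)
        if self.se_mode == "cluster":
            res = model.fit(cov_type="cluster",
                            cov_kwds={"groups": df["unit"].to_numpy()})
        else:
            res = model.fit()

        ci = res.conf_int(alpha=0.05)
        beta3 = float(res.params[_INTERACTION])
        resid = np.asarray(res.resid, dtype=float)
        self.design_ = df
        self.params_ = res.params
        self.bse_ = res.bse
        self.beta3_ = beta3
        self.ci95_ = (float(ci.loc[_INTERACTION, 0]), float(ci.loc[_INTERACTION, 1]))
        self.p_value_ = float(res.pvalues[_INTERACTION])
        self.result_ = DidResult(
            beta3=beta3,
            ci95=self.ci95_,
            p_value=self.p_value_,
            params=res.params,
            bse=res.bse,
            se_mode=self.se_mode,
            resid_summary={
                "mean": float(resid.mean()),
                "sd": float(resid.std(ddof=1)),
                "min": float(resid.min()),
                "max": float(resid.max()),
            },
            nobs=int(res.nobs),
            ols_result=res,
        )
        return self


def fit_did(
    panel: PanelDataset, covariates="all", se_mode: str = "classical", **kwargs
) -> DidResult:
    """Fit the DiD regression; thin wrapper over the estimator class."""
    est = DifferenceInDifferences(
        covariates=covariates, se_mode=se_mode, **kwargs
    ).fit(panel)
    return est.result_
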