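"""In-space placebo permutation inference for the synthetic-control effect.

Treatment is iteratively reassigned to each donor; the estimator is refit
with the identical specification and the treated unit's effect is judged
against the resulting permutation distribution.  Donors whose pre-policy
MSPE exceeds a multiple of the treated unit's (default 5x) are excluded as
lacking fit before the pseudo p-value is computed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, clone

from .panel import PanelDataset
from .scm import SyntheticControl

__all__ = [
    "PlaceboUnit",
    "PlaceboResult",
    "PlaceboTest",
    "run_placebo",
    "mspe_filter",
    "pseudo_p_value",
]


def mspe_filter(ratios: Mapping[str, float], threshold: float) -> set[str]:
    """Labels whose pre-policy MSPE ratio is strictly greater than threshold."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    return {u for u, r in ratios.items() if r > threshold}


def pseudo_p_value(
    treated_effect: float, placebo_effects: Mapping[str, float]
) -> tuple[float, list[str]]:
    """Proportion of placebo effects at least as extreme as the treated one.

    Extremeness is compared in absolute value; returns the pseudo p-value and
    the labels attaining it.  Denominator = number of placebo units supplied
    (the treated unit is not self-counted).
    """
    if not placebo_effects:
        raise ValueError("no placebo effects to compare against")
    thr = abs(treated_effect)
    extreme = sorted(u for u, e in placebo_effects.items() if abs(e) >= thr)
    return len(extreme) / len(placebo_effects), extreme


@dataclass
class PlaceboUnit:
    """One placebo run: unit treated as if it had received the policy."""

    gap_series: pd.Series
    pre_mspe: float
    mean_post_gap: float
    failed: bool = False
    reason: str | None = None


@dataclass
class PlaceboResult:
    per_unit: dict[str, PlaceboUnit]
    treated_unit: str
    treated_pre_mspe: float
    treated_effect: float
    mspe_ratios: pd.Series
    ratio_threshold: float
    excluded_units: list[str]
    failed_units: list[str]
    retained_units: list[str]
    pseudo_p: float
    extreme_units: list[str]
    effect_statistic: str = "mean_post_gap"
    meta: dict = field(default_factory=dict)

    def effects_frame(self) -> pd.DataFrame:
        """Plotting-ready table of placebo mean effects with exclusion flags."""
        rows = []
        for unit, pu in self.per_unit.items():
            rows.append(
                {
                    "unit": unit,
                    "mean_post_gap": pu.mean_post_gap,
                    "pre_mspe": pu.pre_mspe,
                    "mspe_ratio": self.mspe_ratios.get(unit, np.nan),
                    "excluded": unit in self.excluded_units,
                    "failed": unit in self.failed_units,
                    "extreme": unit in self.extreme_units,
                }
            )
        rows.append(
            {
                "unit": self.treated_unit,
                "mean_post_gap": self.treated_effect,
                "pre_mspe": self.treated_pre_mspe,
                "mspe_ratio": 1.0,
                "excluded": False,
                "failed": False,
                "extreme": True,
            }
        )
        return pd.DataFrame(rows).set_index("unit")

    def gaps_long(self) -> pd.DataFrame:
        """Long table (unit, year, gap) of every non-failed placebo gap path."""
        frames = []
        for unit, pu in self.per_unit.items():
            if pu.failed:
                continue
            df = pu.gap_series.rename("gap").reset_index()
            df.insert(0, "unit", unit)
            frames.append(df)
        return pd.concat(frames, ignore_index=True)


class PlaceboTest(BaseEstimator):
    """Placebo permutation test around a synthetic-control fit.

    Parameters
    ----------
    estimator : SyntheticControl or None
        Template estimator cloned for the treated fit and every placebo fit;
        default ``SyntheticControl()``.
    ratio_threshold : float
        Exclude placebo units whose pre-policy MSPE is strictly more than
        this multiple of the treated unit's (default 5).
    include_treated_in_pools : bool
        If True, the genuinely treated unit is allowed in placebo donor
        pools; by default it is excluded so the real treatment cannot
        contaminate placebo counterfactuals.
    effect_statistic : {"mean_post_gap", "mspe_ratio"}
        Statistic used for the extremeness comparison; the default compares
        |mean post-policy gap|, the alternative compares post/pre MSPE ratios.
    """

    def __init__(
        self,
        estimator: SyntheticControl | None = None,
        ratio_threshold: float = 5.0,
        include_treated_in_pools: bool = False,
        effect_statistic: str = "mean_post_gap",
    ):
        self.estimator = estimator
        self.ratio_threshold = ratio_threshold
        self.include_treated_in_pools = include_treated_in_pools
        self.effect_statistic = effect_statistic

    def fit(self, panel: PanelDataset, y=None) -> "PlaceboTest":
        if panel.n_donors < 3:
            raise ValueError(
                "placebo test needs J >= 3 donors so every placebo run keeps "
                ">= 2 donors"
            )
        if self.effect_statistic not in ("mean_post_gap", "mspe_ratio"):
            raise ValueError(f"unknown effect statistic {self.effect_statistic!r}")
        template = (
            self.estimator if self.estimator is not None else SyntheticControl()
        )

        treated_fit = clone(template).fit(panel)
        post = panel.post_years
        treated_pre_mspe = treated_fit.pre_mspe_
        treated_effect = float(treated_fit.gap_series_.loc[post].mean())

        per_unit: dict[str, PlaceboUnit] = {}
        for unit in panel.donors:
            pool = [u for u in panel.donors if u != unit]
            if self.include_treated_in_pools:
                pool = [panel.treated_unit] + pool
            sub = panel.subset(units=[unit] + pool, treated_unit=unit)
            try:
                f = clone(template).fit(sub)
            except Exception as exc:  # convergence failure: flag, never drop
                per_unit[unit] = PlaceboUnit(
                    gap_series=pd.Series(dtype=float),
                    pre_mspe=np.nan,
                    mean_post_gap=np.nan,
                    failed=True,
                    reason=f"{type(exc).__name__}: {exc}",
                )
                continue
            per_unit[unit] = PlaceboUnit(
                gap_series=f.gap_series_,
                pre_mspe=f.pre_mspe_,
                mean_post_gap=float(f.gap_series_.loc[post].mean()),
            )

        failed = sorted(u for u, pu in per_unit.items() if pu.failed)
        ok = {u: pu for u, pu in per_unit.items() if not pu.failed}
        if treated_pre_mspe > 0:
            ratios = {u: pu.pre_mspe / treated_pre_mspe for u, pu in ok.items()}
        else:
            ratios = {
                u: (np.inf if pu.pre_mspe > 0 else 1.0) for u, pu in ok.items()
            }
        excluded = sorted(mspe_filter(ratios, self.ratio_threshold))
        retained = sorted(u for u in ok if u not in excluded)
        if not retained:
            raise RuntimeError(
                "every placebo unit was excluded by the MSPE filter; "
                "pseudo p-value undefined"
            )

        if self.effect_statistic == "mean_post_gap":
            stat = {u: ok[u].mean_post_gap for u in retained}
            treated_stat = treated_effect
        else:
            treated_post_mspe = float(
                np.mean(treated_fit.gap_series_.loc[post].to_numpy() ** 2)
            )
            treated_stat = treated_post_mspe / max(treated_pre_mspe, 1e-12)
            stat = {
                u: float(np.mean(ok[u].gap_series.loc[post].to_numpy() ** 2))
                / max(ok[u].pre_mspe, 1e-12)
                for u in retained
            }
        pseudo_p, extreme = pseudo_p_value(treated_stat, stat)

        self.treated_fit_ = treated_fit
        self.result_ = PlaceboResult(
            per_unit=per_unit,
            treated_unit=panel.treated_unit,
            treated_pre_mspe=treated_pre_mspe,
            treated_effect=treated_effect,
            mspe_ratios=pd.Series(ratios, name="mspe_ratio").sort_index(),
            ratio_threshold=self.ratio_threshold,
            excluded_units=excluded,
            failed_units=failed,
            retained_units=retained,
            pseudo_p=pseudo_p,
            extreme_units=extreme,
            effect_statistic=self.effect_statistic,
            meta={"include_treated_in_pools": self.include_treated_in_pools},
        )
        self.pseudo_p_ = pseudo_p
        self.excluded_units_ = excluded
        self.retained_units_ = retained
        self.extreme_units_ = extreme
        return self


def run_placebo(
    panel: PanelDataset,
    ratio_threshold: float = 5.0,
    include_treated_in_pools: bool = False,
    effect_statistic: str = "mean_post_gap",
    **scm_params,
) -> PlaceboResult:
    """Run the full placebo experiment; thin wrapper over :class:`PlaceboTest`."""
    est = SyntheticControl(**scm_params) if scm_params else None
    test = PlaceboTest(
        estimator=est,
        ratio_threshold=ratio_threshold,
        include_treated_in_pools=include_treated_in_pools,
        effect_statistic=effect_statistic,
    ).fit(panel)
    return test.result_
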