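"""Predictor construction for synthetic-control matching.

Each covariate contributes one row equal to its pre-policy mean per unit; each
outcome lag (a chosen pre-policy year) contributes one row equal to that
year's outcome per unit.  Rows are standardized across the J+1 units before
optimization so that predictors measured in persons, currency and percentage
points enter the matching distance on a comparable scale; the standardization
is recorded so balance tables can be reported on the raw scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .panel import PanelDataset

__all__ = ["PredictorSpec", "PredictorMatrices", "build_predictor_matrices"]


@dataclass(frozen=True)
class PredictorSpec:
    """Which predictors enter the matching problem.

    ``covariates``: covariate names aggregated as pre-policy means, or
    ``"all"`` for every covariate in the panel.  ``outcome_lags``: pre-policy
    years whose outcome values enter as special predictors, or ``"all"`` for
    every pre-policy year.
    """

    covariates: tuple[str, ...] | str = "all"
    outcome_lags: tuple[int, ...] | str = "all"

    def resolve(self, panel: PanelDataset) -> tuple[list[str], list[int]]:
        covs = (
            panel.covariate_names
            if self.covariates == "all"
            else list(self.covariates)
        )
        lags = (
            panel.pre_years
            if self.outcome_lags == "all"
            else sorted(int(y) for y in self.outcome_lags)
        )
        missing = [c for c in covs if c not in panel.covariate_names]
        if missing:
            raise ValueError(f"covariates not in panel: {missing}")
        bad = [y for y in lags if y not in panel.pre_years]
        if bad:
            raise ValueError(f"outcome lags outside pre-policy period: {bad}")
        if not covs and not lags:
            raise ValueError("predictor spec selects no predictors")
        return covs, lags


@dataclass
class PredictorMatrices:
    """The k-vector X1 (treated) and k x J matrix X0 (donors).

    ``X1``/``X0`` are on the standardized scale used by the optimizer;
    ``raw_X1``/``raw_X0`` keep the original units for balance reporting.
    """

    X1: np.ndarray
    X0: np.ndarray
    row_names: list[str]
    donor_ids: list[str]
    raw_X1: np.ndarray
    raw_X0: np.ndarray
    center: np.ndarray
    scale: np.ndarray
    spec: PredictorSpec = field(default_factory=PredictorSpec)

    @property
    def k(self) -> int:
        return len(self.row_names)

    @property
    def n_donors(self) -> int:
        return self.X0.shape[1]


def build_predictor_matrices(
    panel: PanelDataset,
    spec: PredictorSpec | None = None,
    standardize: bool = True,
) -> PredictorMatrices:
    """Assemble X1 and X0 from a panel according to ``spec``."""
    spec = spec or PredictorSpec()
    covs, lags = spec.resolve(panel)
    pre = panel.pre_years
    units = [panel.treated_unit] + panel.donors

    rows: list[np.ndarray] = []
    names: list[str] = []
    for c in covs:
        block = panel.covariates[c].loc[units, pre]
        means = block.mean(axis=1, skipna=True)
        if means.isna().any():
            unit = means.index[means.isna()][0]
            raise ValueError(
                f"covariate {c!r} has no pre-policy observations for unit {unit!r}"
            )
        rows.append(means.to_numpy(dtype=float))
        names.append(c)
    for y in lags:
        rows.append(panel.outcomes.loc[units, y].to_numpy(dtype=float))
        names.append(f"outcome[{y}]")

    raw = np.vstack(rows)  # k x (J+1), treated first
    if standardize:
        center = raw.mean(axis=1)
        scale = raw.std(axis=1)
        scale = np.where(scale > 0, scale, 1.0)
    else:
        center = np.zeros(raw.shape[0])
        scale = np.ones(raw.shape[0])
    std = (raw - center[:, None]) / scale[:, None]

    return PredictorMatrices(
        X1=std[:, 0].copy(),
        X0=std[:, 1:].copy(),
        row_names=names,
        donor_ids=panel.donors,
        raw_X1=raw[:, 0].copy(),
        raw_X0=raw[:, 1:].copy(),
        center=center,
        scale=scale,
        spec=spec,
    )
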