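"""Panel data container, CSV readers/writers, and the donor-pool level adjustment.

The unit of analysis is an annual city-level panel: one treated unit, a donor
pool of untreated units, an outcome measured in percentage points (0-100), and
a set of named covariates.  The treated unit receives the policy from
``policy_year`` onward; years before it form the pre-policy period used for
matching.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PanelDataset",
    "AdjustmentWarning",
    "load_panel",
    "write_panel",
    "adjust_donor_level",
]


class AdjustmentWarning(UserWarning):
    """A donor-level adjustment pushed an outcome outside [0, 100]."""


def _as_year_index(years: Iterable) -> pd.Index:
    return pd.Index([int(y) for y in years], name="year")


@dataclass
class PanelDataset:
    """Units x years outcome and covariate panel with treatment annotations.

    Parameters
    ----------
    outcomes : DataFrame
        Units (rows) by years (columns) outcome matrix, percentage points.
    covariates : mapping of str -> DataFrame
        One units-by-years matrix per named covariate.  Missing cells are
        permitted in covariates (the predictor builder averages over what is
        observed); outcomes must be complete.
    treated_unit : str
        Label of the single treated unit.
    policy_year : int
        First post-policy year; years before it are the pre-policy period.
    meta : dict
        Provenance metadata (adjustment record, source path, ...).
    """

    outcomes: pd.DataFrame
    covariates: dict[str, pd.DataFrame]
    treated_unit: str
    policy_year: int
    meta: dict = field(default_factory=dict)
    # Unadjusted base outcomes + cumulative adjustment state.  Donor outcomes
    # are always rematerialized as base * mult - add, so composing an
    # adjustment with its inverse restores the original values bit-exactly.
    _base_outcomes: pd.DataFrame | None = field(default=None, repr=False)
    _adjust_add: float = field(default=0.0, repr=False)
    _adjust_mult: float = field(default=1.0, repr=False)

    def __post_init__(self) -> None:
        self.outcomes = self.outcomes.copy()
        self.outcomes.columns = _as_year_index(self.outcomes.columns)
        self.outcomes.index = self.outcomes.index.astype(str)
        self.covariates = {
            str(name): df.copy() for name, df in self.covariates.items()
        }
        for name, df in self.covariates.items():
            df.columns = _as_year_index(df.columns)
            df.index = df.index.astype(str)
        self.policy_year = int(self.policy_year)
        self.treated_unit = str(self.treated_unit)
        if self._base_outcomes is None:
            self._base_outcomes = self.outcomes.copy()
        self.validate()

    # ------------------------------------------------------------------
    # derived views
    # ------------------------------------------------------------------
    @property
    def unit_ids(self) -> list[str]:
        return list(self.outcomes.index)

    @property
    def years(self) -> list[int]:
        return [int(y) for y in self.outcomes.columns]

    @property
    def donors(self) -> list[str]:
        return [u for u in self.unit_ids if u != self.treated_unit]

    @property
    def n_donors(self) -> int:
        return len(self.donors)

    @property
    def pre_years(self) -> list[int]:
        return [y for y in self.years if y < self.policy_year]

    @property
    def post_years(self) -> list[int]:
        return [y for y in self.years if y >= self.policy_year]

    @property
    def covariate_names(self) -> list[str]:
        return list(self.covariates)

    # ------------------------------------------------------------------
    # validation
    # ------------------------------------------------------------------
    def validate(self) -> None:
        units = self.unit_ids
        if len(set(units)) != len(units):
            dupes = sorted({u for u in units if units.count(u) > 1})
            raise ValueError(f"duplicate unit labels: {dupes}")
        if self.treated_unit not in units:
            raise ValueError(
                f"treated unit {self.treated_unit!r} not present in panel"
            )
        years = self.years
        if any(b <= a for a, b in zip(years, years[1:])):
            raise ValueError(f"years must be strictly increasing, got {years}")
        gaps = [
            (a, b) for a, b in zip(years, years[1:]) if b != a + 1
        ]
        if gaps:
            a, b = gaps[0]
            raise ValueError(f"year gap between {a} and {b}: panel must be contiguous")
        if len(self.pre_years) < 2:
            raise ValueError(
                f"need >=2 pre-policy years before {self.policy_year}, "
                f"got {self.pre_years}"
            )
        if len(self.post_years) < 1:
            raise ValueError(
                f"need >=1 post-policy year from {self.policy_year}, got none"
            )
        if self.n_donors < 2:
            raise ValueError(f"need J >= 2 donors, got {self.n_donors}")
        vals = self.outcomes.to_numpy(dtype=float)
        if np.isnan(vals).any():
            bad = self.outcomes.isna()
            unit = bad.any(axis=1).idxmax()
            raise ValueError(f"missing outcome values (e.g. unit {unit!r})")
        adjusted = self._adjust_add != 0.0 or self._adjust_mult != 1.0
        out_of_range = (vals < 0).any() or (vals > 100).any()
        if out_of_range:
            if adjusted:
                # adjustment may legitimately push donors out of range; the
                # adjusting operation has already warned and flagged it
                self.meta.setdefault("outcome_out_of_range", True)
            else:
                raise ValueError("outcomes must lie within [0, 100]")
        for name, df in self.covariates.items():
            if list(df.index) != units or [int(y) for y in df.columns] != years:
                raise ValueError(
                    f"covariate {name!r} not aligned with outcome panel"
                )

    # ------------------------------------------------------------------
    # manipulation
    # ------------------------------------------------------------------
    def subset(
        self,
        units: Sequence[str] | None = None,
        treated_unit: str | None = None,
        years: Sequence[int] | None = None,
    ) -> "PanelDataset":
        """Return a new panel restricted to ``units``/``years``.

        ``treated_unit`` reassigns treatment status (used by placebo runs).
        """
        units = list(units) if units is not None else self.unit_ids
        years = [int(y) for y in years] if years is not None else self.years
        treated = treated_unit if treated_unit is not None else self.treated_unit
        missing = [u for u in units if u not in self.unit_ids]
        if missing:
            raise KeyError(f"units not in panel: {missing}")
        # The subset's materialized outcomes become its own adjustment base:
        # treatment status may be reassigned (placebo runs), which changes
        # which rows future adjustments apply to.
        return PanelDataset(
            outcomes=self.outcomes.loc[units, years],
            covariates={n: df.loc[units, years] for n, df in self.covariates.items()},
            treated_unit=treated,
            policy_year=self.policy_year,
            meta=dict(self.meta),
        )

    def equals(self, other: "PanelDataset") -> bool:
        """Value equality of outcomes, covariates and annotations."""
        return (
            self.treated_unit == other.treated_unit
            and self.policy_year == other.policy_year
            and self.outcomes.equals(other.outcomes)
            and set(self.covariates) == set(other.covariates)
            and all(
                self.covariates[n].equals(other.covariates[n])
                for n in self.covariates
            )
        )


def adjust_donor_level(
    panel: PanelDataset, offset: float, mode: str = "additive"
) -> PanelDataset:
    """Shift every donor's outcome series by a fixed amount.

    This implements the comparability adjustment used when the treated unit
    sits at a persistently different outcome level than every donor: with
    ``mode="additive"`` (default) each donor outcome becomes ``Y - offset``
    percentage points in every year; ``mode="multiplicative"`` rescales donor
    outcomes by ``1 - offset/100``.  The treated unit and all covariates are
    untouched.  The adjustment is recorded in ``meta["adjustment"]`` so
    downstream reports can state it.

    Adjusting by ``offset`` and then by ``-offset`` restores the panel
    bit-exactly (donor outcomes are rematerialized from the stored unadjusted
    base, not re-subtracted).
    """
    if not np.isfinite(offset):
        raise ValueError("offset must be finite")
    if mode not in ("additive", "multiplicative"):
        raise ValueError(f"unknown adjustment mode {mode!r}")

    add = panel._adjust_add
    mult = panel._adjust_mult
    if mode == "additive":
        add = add + float(offset)
    else:
        mult = mult * (1.0 - float(offset) / 100.0)

    base = panel._base_outcomes
    donors = [u for u in base.index if u != panel.treated_unit]
    new_outcomes = base.copy()
    if add == 0.0 and mult == 1.0:
        pass  # bit-exact restore of the unadjusted panel
    else:
        new_outcomes.loc[donors] = base.loc[donors] * mult - add

    donor_vals = new_outcomes.loc[donors].to_numpy(dtype=float)
    flagged = bool((donor_vals < 0).any() or (donor_vals > 100).any())
    if flagged:
        warnings.warn(
            f"donor-level adjustment (cumulative add={add}, mult={mult}) pushed "
            "donor outcomes outside [0, 100]",
            AdjustmentWarning,
            stacklevel=2,
        )

    meta = dict(panel.meta)
    meta["adjustment"] = {
        "mode": mode,
        "last_offset": float(offset),
        "cumulative_additive": add,
        "cumulative_multiplicative": mult,
    }
    meta["outcome_out_of_range"] = flagged
    return PanelDataset(
        outcomes=new_outcomes,
        covariates=panel.covariates,
        treated_unit=panel.treated_unit,
        policy_year=panel.policy_year,
        meta=meta,
        _base_outcomes=base,
        _adjust_add=add,
        _adjust_mult=mult,
    )


# ----------------------------------------------------------------------
# CSV interchange
# ----------------------------------------------------------------------

_LONG_COLS = ("unit", "year", "variable", "value")


def load_panel(
    path: str | Path,
    layout: str = "long",
    *,
    treated_unit: str,
    policy_year: int,
    outcome: str = "outcome",
    covariates: Sequence[str] | None = None,
    schema: Mapping[str, str] | None = None,
) -> PanelDataset:
    """Read a panel from CSV.

    ``layout="long"`` expects melted columns ``unit,year,variable,value``;
    ``layout="wide"`` expects one row per unit-year with ``unit,year`` plus one
    column per variable.  ``outcome`` names the outcome variable; every other
    variable becomes a covariate unless ``covariates`` restricts the set.
    ``schema`` optionally remaps the structural column names, e.g.
    ``{"unit": "city", "year": "yr"}``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    colmap = {c: c for c in _LONG_COLS}
    if schema:
        colmap.update(schema)

    df = pd.read_csv(path, float_precision="round_trip")
    df = df.rename(columns={v: k for k, v in colmap.items()})

    if layout == "long":
        needed = set(_LONG_COLS)
        if not needed.issubset(df.columns):
            raise ValueError(
                f"long layout needs columns {sorted(needed)}, got {list(df.columns)}"
            )
        dupes = df.duplicated(subset=["unit", "year", "variable"])
        if dupes.any():
            row = df[dupes].iloc[0]
            raise ValueError(
                f"duplicate row for unit={row['unit']!r} year={row['year']} "
                f"variable={row['variable']!r}"
            )
        wide = df.pivot(index=["unit", "year"], columns="variable", values="value")
        wide = wide.reset_index()
    elif layout == "wide":
        if not {"unit", "year"}.issubset(df.columns):
            raise ValueError("wide layout needs 'unit' and 'year' columns")
        dupes = df.duplicated(subset=["unit", "year"])
        if dupes.any():
            row = df[dupes].iloc[0]
            raise ValueError(
                f"duplicate row for unit={row['unit']!r} year={row['year']}"
            )
        wide = df
    else:
        raise ValueError(f"unknown layout {layout!r}")

    if outcome not in wide.columns:
        raise ValueError(f"outcome column {outcome!r} not found")
    variables = [c for c in wide.columns if c not in ("unit", "year")]
    cov_names = (
        [c for c in variables if c != outcome]
        if covariates is None
        else list(covariates)
    )
    missing = [c for c in cov_names if c not in wide.columns]
    if missing:
        raise ValueError(f"covariate columns not found: {missing}")

    wide = wide.copy()
    wide["unit"] = wide["unit"].astype(str)
    wide["year"] = wide["year"].astype(int)

    def pivot(var: str) -> pd.DataFrame:
        return wide.pivot(index="unit", columns="year", values=var).sort_index()

    outcomes = pivot(outcome)
    covs = {c: pivot(c) for c in cov_names}
    # keep treated unit first for readability, donors in sorted order
    treated_unit = str(treated_unit)
    if treated_unit in outcomes.index:
        order = [treated_unit] + [u for u in outcomes.index if u != treated_unit]
        outcomes = outcomes.loc[order]
        covs = {c: df.loc[order] for c, df in covs.items()}
    return PanelDataset(
        outcomes=outcomes,
        covariates=covs,
        treated_unit=treated_unit,
        policy_year=policy_year,
        meta={"source": str(path), "outcome_name": outcome},
    )


def write_panel(
    panel: PanelDataset, path: str | Path, meta_path: str | Path | None = None
) -> Path:
    """Write the canonical long CSV plus a JSON metadata sidecar.

    Floats are written with Python's shortest round-tripping repr, so a
    load -> write -> load cycle reproduces values bit-exactly.
    """
    path = Path(path)
    outcome_name = panel.meta.get("outcome_name", "outcome")
    frames = []
    for var, df in [(outcome_name, panel.outcomes)] + [
        (n, panel.covariates[n]) for n in sorted(panel.covariates)
    ]:
        long = df.stack().rename("value").reset_index()
        long.columns = ["unit", "year", "value"]
        long.insert(2, "variable", var)
        frames.append(long)
    out = pd.concat(frames, ignore_index=True)
    out = out.sort_values(["variable", "unit", "year"], kind="mergesort")
    with open(path, "w", newline="\n") as fh:
        fh.write("unit,year,variable,value\n")
        for row in out.itertuples(index=False):
            fh.write(f"{row.unit},{int(row.year)},{row.variable},{float(row.value)!r}\n")

    meta_path = Path(meta_path) if meta_path else path.with_suffix(".meta.json")
    sidecar = {
        "treated_unit": panel.treated_unit,
        "policy_year": panel.policy_year,
        "outcome_name": outcome_name,
        "meta": {k: v for k, v in panel.meta.items() if k != "source"},
    }
    with open(meta_path, "w", newline="\n") as fh:
        json.dump(sidecar, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return path
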