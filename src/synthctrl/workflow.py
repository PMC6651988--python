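"""End-to-end study orchestration: adjust -> fit -> placebo -> DiD -> report.

One config drives the whole analysis; every stage is also callable on its
own through the library API.  Outputs are deterministic under a fixed seed
(byte-identical report bundles on rerun).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .did import DifferenceInDifferences
from .panel import PanelDataset, adjust_donor_level, load_panel
from .placebo import PlaceboTest
from .scm import SyntheticControl
from .simulate import make_study_fixture

__all__ = ["RunConfig", "run_study", "REPORT_SCHEMA_VERSION"]

REPORT_SCHEMA_VERSION = "1"
log = logging.getLogger("synthctrl")


@dataclass
class RunConfig:
    """Configuration for a full study run.

    Exactly one of ``panel_path`` (CSV on disk) or ``scenario`` (generator
    scenario name) selects the input panel.
    """

    panel_path: str | None = None
    scenario: str | None = None
    layout: str = "long"
    outcome: str = "outcome"
    treated_unit: str | None = None
    policy_year: int | None = None
    covariates: list[str] | str = "all"
    outcome_lags: list[int] | str = "all"
    v_mode: str = "auto"
    adjust_offset: float = 0.0
    adjust_mode: str = "additive"
    ratio_threshold: float = 5.0
    include_treated_in_pools: bool = False
    did_covariates: list[str] | str = "all"
    se_mode: str = "classical"
    baseline_year: int | None = None
    seed: int = 0
    out_dir: str | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _load_input(config: RunConfig) -> PanelDataset:
    if (config.panel_path is None) == (config.scenario is None):
        raise ValueError("exactly one of panel_path or scenario must be set")
    if config.scenario is not None:
        panel, _ = make_study_fixture(config.scenario, seed=config.seed)
        return panel
    if config.treated_unit is None or config.policy_year is None:
        raise ValueError("panel_path input needs treated_unit and policy_year")
    return load_panel(
        config.panel_path,
        layout=config.layout,
        treated_unit=config.treated_unit,
        policy_year=config.policy_year,
        outcome=config.outcome,
    )


def _json_dump(obj, path: Path) -> None:
    with open(path, "w", newline="\n") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def _csv_dump(df, path: Path, index: bool = True) -> None:
    with open(path, "w", newline="\n") as fh:
        fh.write(df.to_csv(index=index, lineterminator="\n"))


def run_study(config: RunConfig, out_dir: str | Path | None = None) -> dict:
    """Execute the full pipeline and return (and optionally write) the report.

    Stages: donor-level adjustment (if requested) -> synthetic-control fit ->
    effect summary and balance table -> placebo permutation test -> DiD
    cross-validation.  A stage failure aborts with the stage name; anything
    already written is flagged incomplete in the manifest.
    """
    out = Path(out_dir or config.out_dir) if (out_dir or config.out_dir) else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    stage = "load"
    try:
        panel = _load_input(config)

        stage = "adjust"
        adjustment = None
        if config.adjust_offset != 0.0:
            panel = adjust_donor_level(
                panel, config.adjust_offset, mode=config.adjust_mode
            )
            adjustment = panel.meta["adjustment"]
            log.info("applied donor adjustment: %s", adjustment)

        stage = "fit"
        scm = SyntheticControl(
            covariates=(
                "all" if config.covariates == "all" else tuple(config.covariates)
            ),
            outcome_lags=(
                "all" if config.outcome_lags == "all"
                else tuple(config.outcome_lags)
            ),
            v_mode=config.v_mode,
            random_state=config.seed,
        ).fit(panel)

        stage = "summarize"
        effect = scm.effect_summary(config.baseline_year)
        balance = scm.balance_table()
        gaps = scm.observed_path_.to_frame().join(scm.synthetic_path_)
        gaps["gap"] = scm.gap_series_

        stage = "placebo"
        placebo = PlaceboTest(
            estimator=SyntheticControl(
                covariates=scm.covariates,
                outcome_lags=scm.outcome_lags,
                v_mode=config.v_mode,
                random_state=config.seed,
            ),
            ratio_threshold=config.ratio_threshold,
            include_treated_in_pools=config.include_treated_in_pools,
        ).fit(panel)
        pr = placebo.result_

        stage = "did"
        did = DifferenceInDifferences(
            covariates=(
                "all" if config.did_covariates == "all"
                else list(config.did_covariates)
            ),
            se_mode=config.se_mode,
        ).fit(panel)

        stage = "report"
        report = {
            "schema_version": REPORT_SCHEMA_VERSION,
            "version": __version__,
            "seed": config.seed,
            "config": config.to_dict(),
            "adjustment": adjustment,
            "effect": effect.to_dict(),
            "effect_display": effect.to_dict(display=True),
            "weights": {u: float(w) for u, w in scm.weights_.items()},
            "importance": {m: float(v) for m, v in scm.importance_.items()},
            "objective": scm.objective_,
            "pre_mspe": scm.pre_mspe_,
            "balance": {
                row: {col: float(balance.loc[row, col]) for col in balance.columns}
                for row in balance.index
            },
            "placebo": {
                "pseudo_p": pr.pseudo_p,
                "ratio_threshold": pr.ratio_threshold,
                "retained": pr.retained_units,
                "excluded": pr.excluded_units,
                "failed": pr.failed_units,
                "extreme_units": pr.extreme_units,
                "treated_effect": pr.treated_effect,
                "effect_statistic": pr.effect_statistic,
            },
            "did": did.result_.to_dict(),
        }
    except Exception as exc:
        if out is not None:
            _json_dump(
                {"incomplete": True, "failed_stage": stage, "error": str(exc)},
                out / "manifest.json",
            )
        raise RuntimeError(f"study failed at stage {stage!r}: {exc}") from exc

    if out is not None:
        _json_dump(report, out / "report.json")
        _csv_dump(scm.weights_.rename("weight").to_frame(), out / "weights.csv")
        _csv_dump(gaps, out / "gaps.csv")
        _csv_dump(balance, out / "balance.csv")
        _csv_dump(pr.gaps_long(), out / "placebo_gaps.csv", index=False)
        _csv_dump(pr.effects_frame(), out / "placebo_effects.csv")
        _json_dump(
            {
                "schema_version": REPORT_SCHEMA_VERSION,
                "version": __version__,
                "seed": config.seed,
                "config": config.to_dict(),
                "incomplete": False,
            },
            out / "manifest.json",
        )
    return report
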