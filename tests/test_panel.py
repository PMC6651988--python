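"""Panel container, CSV interchange, validation, donor-level adjustment."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from synthctrl import (
    AdjustmentWarning,
    adjust_donor_level,
    load_panel,
    make_study_fixture,
    write_panel,
)

from conftest import build_panel


def _write_long_csv(path, rows):
    with open(path, "w") as fh:
        fh.write("unit,year,variable,value\n")
        for r in rows:
            fh.write(",".join(map(str, r)) + "\n")


class TestLoadPanel:
    def test_long_csv_study_shape(self, tmp_path):
        """13 units x 8 years with 6 covariates: J=12 donors, 5 pre, 3 post."""
        panel, _ = make_study_fixture("outpatient-like", seed=0)
        path = tmp_path / "panel.csv"
        write_panel(panel, path)
        loaded = load_panel(
            path, layout="long", treated_unit="treated", policy_year=2013,
            outcome="drug_share",
        )
        assert loaded.n_donors == 12
        assert loaded.pre_years == [2008, 2009, 2010, 2011, 2012]
        assert loaded.post_years == [2013, 2014, 2015]
        assert len(loaded.covariate_names) == 6

    def test_wide_csv_without_covariates(self, tmp_path):
        path = tmp_path / "wide.csv"
        with open(path, "w") as fh:
            fh.write("unit,year,outcome\n")
            for u in ("A", "B", "C"):
                for i, y in enumerate(range(2010, 2014)):
                    fh.write(f"{u},{y},{40 + i}\n")
        panel = load_panel(
            path, layout="wide", treated_unit="A", policy_year=2012
        )
        assert panel.covariate_names == []
        assert panel.n_donors == 2

    def test_duplicate_unit_year_is_an_error(self, tmp_path):
        path = tmp_path / "dup.csv"
        rows = [
            ("A", y, "outcome", 40) for y in range(2010, 2014)
        ] + [
            ("B", y, "outcome", 41) for y in range(2010, 2014)
        ] + [
            ("C", y, "outcome", 42) for y in range(2010, 2014)
        ] + [("A", 2011, "outcome", 99)]
        _write_long_csv(path, rows)
        with pytest.raises(ValueError, match="duplicate"):
            load_panel(path, treated_unit="A", policy_year=2012)

    def test_absent_treated_unit_is_an_error(self, tmp_path):
        path = tmp_path / "p.csv"
        rows = [(u, y, "outcome", 40) for u in "ABC" for y in range(2010, 2014)]
        _write_long_csv(path, rows)
        with pytest.raises(ValueError, match="Zhenjiang"):
            load_panel(path, treated_unit="Zhenjiang", policy_year=2012)

    def test_year_gap_is_named_in_error(self, tmp_path):
        path = tmp_path / "gap.csv"
        rows = [
            (u, y, "outcome", 40)
            for u in "ABC"
            for y in (2010, 2011, 2013, 2014)
        ]
        _write_long_csv(path, rows)
        with pytest.raises(ValueError, match="2011.*2013"):
            load_panel(path, treated_unit="A", policy_year=2013)

    def test_roundtrip_is_bit_exact(self, tmp_path):
        panel, _ = make_study_fixture("null", seed=5)
        p1 = tmp_path / "a.csv"
        write_panel(panel, p1)
        loaded = load_panel(
            p1, treated_unit="treated", policy_year=2013, outcome="drug_share"
        )
        p2 = tmp_path / "b.csv"
        write_panel(loaded, p2)
        assert p1.read_bytes() == p2.read_bytes()
        assert loaded.equals(panel)


class TestValidation:
    def test_out_of_range_outcome_rejected(self):
        with pytest.raises(ValueError, match=r"\[0, 100\]"):
            build_panel({"A": [50, 50, 101, 50], "B": [1] * 4, "C": [2] * 4})

    def test_missing_outcome_rejected(self):
        with pytest.raises(ValueError, match="missing outcome"):
            build_panel({"A": [50, 50, np.nan, 50], "B": [1] * 4, "C": [2] * 4})

    def test_single_donor_rejected(self):
        with pytest.raises(ValueError, match="J >= 2"):
            build_panel({"A": [1, 2, 3, 4], "B": [2, 3, 4, 5]})

    def test_too_few_pre_years_rejected(self):
        with pytest.raises(ValueError, match="pre-policy"):
            build_panel(
                {"A": [1, 2, 3, 4], "B": [1] * 4, "C": [2] * 4},
                policy_year=2011,
            )


class TestAdjustDonorLevel:
    def test_zero_offset_is_identity(self, tiny_panel):
        adjusted = adjust_donor_level(tiny_panel, 0.0)
        assert adjusted.equals(tiny_panel)

    def test_definition_on_single_series(self):
        panel = build_panel(
            {"A": [45, 44, 43, 42], "B": [50, 40, 45, 44], "C": [48, 47, 46, 45]}
        )
        adj = adjust_donor_level(panel, 10.0)
        assert adj.outcomes.loc["B"].tolist() == [40.0, 30.0, 35.0, 34.0]
        # treated unit untouched
        assert adj.outcomes.loc["A"].equals(panel.outcomes.loc["A"])
        # covariates untouched by construction (none here)

    def test_aligns_donor_mean_with_treated(self):
        """Donors averaging 47.5 shifted by 10 land at the treated 37.5."""
        panel = build_panel(
            {"A": [37.5] * 4, "B": [45.0] * 4, "C": [50.0] * 4}
        )
        adj = adjust_donor_level(panel, 10.0)
        donor_mean = adj.outcomes.loc[["B", "C"]].to_numpy().mean()
        assert donor_mean == pytest.approx(37.5)
        assert adj.outcomes.loc["A"].to_numpy().mean() == 37.5

    @given(
        offset=st.floats(min_value=-30, max_value=30, allow_nan=False),
        seed=st.integers(0, 50),
    )
    def test_additive_adjustment_is_exactly_invertible(self, offset, seed):
        panel, _ = make_study_fixture("null", seed=seed)
        restored = adjust_donor_level(adjust_donor_level(panel, offset), -offset)
        assert restored.outcomes.equals(panel.outcomes)

    def test_commutes_with_year_subsetting(self, tiny_panel):
        years = [2010, 2011, 2012]
        a = adjust_donor_level(tiny_panel, 5.0).subset(years=years)
        b = adjust_donor_level(tiny_panel.subset(years=years), 5.0)
        assert a.outcomes.equals(b.outcomes)

    def test_out_of_range_warns_and_flags(self):
        panel = build_panel(
            {"A": [40] * 4, "B": [5, 6, 7, 8], "C": [50] * 4}
        )
        with pytest.warns(AdjustmentWarning):
            adj = adjust_donor_level(panel, 10.0)
        assert adj.meta["outcome_out_of_range"] is True
        assert (adj.outcomes.loc["B"] < 0).all()

    def test_adjustment_recorded_in_provenance(self, tiny_panel):
        adj = adjust_donor_level(tiny_panel, 10.0)
        rec = adj.meta["adjustment"]
        assert rec["mode"] == "additive"
        assert rec["cumulative_additive"] == 10.0

    def test_multiplicative_mode(self, tiny_panel):
        adj = adjust_donor_level(tiny_panel, 10.0, mode="multiplicative")
        expected = tiny_panel.outcomes.loc["B"] * 0.9
        assert adj.outcomes.loc["B"].equals(expected)
        assert adj.outcomes.loc["A"].equals(tiny_panel.outcomes.loc["A"])


class TestSubset:
    def test_reassign_treated(self, tiny_panel):
        sub = tiny_panel.subset(units=["B", "A", "C"], treated_unit="B")
        assert sub.treated_unit == "B"
        assert sub.donors == ["A", "C"]

    def test_unknown_unit_raises(self, tiny_panel):
        with pytest.raises(KeyError):
            tiny_panel.subset(units=["A", "Z"])
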