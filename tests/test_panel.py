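"""Panel containers, I/O round trips, standardization and descriptives."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import obesity_elasticity as oe
from obesity_elasticity.panel import (
    DegenerateCovariateError,
    PanelValidationError,
    PartialCoverageWarning,
    SchemaError,
)


class TestPanelIO:
    def test_round_trip_is_lossless(self, tiny_dataset, tmp_path):
        path = tmp_path / "panel.csv"
        tiny_dataset.panel.write_csv(path)
        back = oe.read_panel(path)
        pd.testing.assert_frame_equal(back.data, tiny_dataset.panel.data, check_exact=True)

    def test_schema_renaming(self, small_panel_frame, tmp_path):
        renamed = small_panel_frame.rename(columns={"prevalence_pct": "obesity", "gdppc": "income"})
        path = tmp_path / "odd.csv"
        renamed.to_csv(path, index=False)
        panel = oe.read_panel(
            path,
            schema={
                "country": "country",
                "year": "year",
                "stratum": "stratum",
                "prevalence_pct": "obesity",
                "gdppc": "income",
            },
        )
        assert panel.countries == ["AAA", "BBB", "CCC"]

    def test_missing_column_is_schema_error(self, small_panel_frame, tmp_path):
        path = tmp_path / "broken.csv"
        small_panel_frame.drop(columns=["gdppc"]).to_csv(path, index=False)
        with pytest.raises(SchemaError, match="gdppc"):
            oe.read_panel(path)

    def test_nonpositive_prevalence_row_rejected_with_reason(self, small_panel_frame):
        bad = small_panel_frame.copy()
        bad.loc[0, "prevalence_pct"] = 0.0
        panel = oe.CountryYearPanel.from_frame(bad)
        assert len(panel.rejected) == 1
        assert panel.rejected["reason"].iloc[0] == "non-positive prevalence"
        assert len(panel.data) == len(bad) - 1

    def test_duplicate_keys_raise_listing_offenders(self, small_panel_frame):
        dup = pd.concat([small_panel_frame, small_panel_frame.iloc[[0]]])
        with pytest.raises(PanelValidationError, match="AAA"):
            oe.CountryYearPanel.from_frame(dup)

    def test_too_few_years_rejected(self, small_panel_frame):
        short = small_panel_frame[
            ~((small_panel_frame.country == "AAA") & (small_panel_frame.year > 2001))
        ]
        panel = oe.CountryYearPanel.from_frame(short)
        assert "AAA" not in panel.countries
        assert (panel.rejected["reason"] == "fewer than 3 years in stratum").all()


class TestStandardize:
    def _table(self, values: dict, dummies: set = frozenset()):
        df = pd.DataFrame(values, index=[f"C{i}" for i in range(len(next(iter(values.values()))))])
        dims = pd.Series(
            [oe.panel.DIMENSIONS[i % 5] for i in range(len(values))], index=list(values)
        )
        return oe.ModeratorTable(
            values=df,
            dimensions=dims,
            is_dummy=pd.Series([v in dummies for v in values], index=list(values)),
        )

    def test_three_point_example(self):
        tab = self._table({c: [1.0, 2.0, 3.0] for c in "abcde"})
        out = oe.standardize_moderators(tab)
        np.testing.assert_allclose(out.values["a"], [-1.0, 0.0, 1.0], atol=1e-12)

    def test_dummy_passes_through(self):
        tab = self._table({"a": [1.0, 2.0, 3.0, 4.0], "b": [0, 1, 1, 0], "c": [1, 2, 4, 8.0],
                           "d": [0.1, 0.2, 0.3, 0.5], "e": [3, 1, 4, 1.0]}, dummies={"b"})
        out = oe.standardize_moderators(tab)
        assert out.values["b"].tolist() == [0, 1, 1, 0]

    def test_mean_zero_sd_one_and_idempotence(self, tiny_dataset):
        table = tiny_dataset.moderators
        out = oe.standardize_moderators(table)
        for var in out.variables:
            if out.is_dummy[var]:
                continue
            col = out.values[var].to_numpy()
            assert abs(col.mean()) < 1e-10
            assert abs(col.std(ddof=1) - 1) < 1e-10
        again = oe.standardize_moderators(out)
        pd.testing.assert_frame_equal(again.values, out.values, atol=1e-10, rtol=0)

    def test_zero_variance_raises_naming_covariate(self):
        tab = self._table({"flat": [2.0, 2.0, 2.0], "b": [1, 2, 3.0], "c": [1, 3, 2.0],
                           "d": [0, 1, 2.0], "e": [5, 1, 3.0]})
        with pytest.raises(DegenerateCovariateError, match="flat"):
            oe.standardize_moderators(tab)

    def test_moderator_round_trip(self, tiny_dataset, tmp_path):
        path = tmp_path / "mods.csv"
        tiny_dataset.moderators.write_csv(path)
        back = oe.ModeratorTable.read_csv(path)
        pd.testing.assert_frame_equal(
            back.values, tiny_dataset.moderators.values, check_exact=True, check_names=False
        )
        assert back.dimensions.tolist() == tiny_dataset.moderators.dimensions.tolist()


class TestCAGR:
    @pytest.mark.parametrize(
        "start,end,n,expected",
        [
            (5.41, 17.51, 39, 3.06),  # 1975→2014 overall prevalence
            (10.0, 10.0, 5, 0.0),
            (100.0, 121.0, 2, 10.0),
        ],
    )
    def test_known_values(self, start, end, n, expected):
        assert round(oe.compute_cagr(start, end, n), 2) == expected

    @pytest.mark.parametrize("start,end,n", [(-1, 5, 3), (5, 0, 3), (5, 5, 0)])
    def test_domain_errors(self, start, end, n):
        with pytest.raises(ValueError):
            oe.compute_cagr(start, end, n)

    @given(
        a=st.floats(0.1, 50),
        b=st.floats(0.1, 50),
        k=st.floats(0.01, 100),
        n=st.integers(1, 60),
    )
    def test_scale_invariance(self, a, b, k, n):
        assert oe.compute_cagr(a, b, n) == pytest.approx(
            oe.compute_cagr(k * a, k * b, n), rel=1e-9, abs=1e-9
        )


class TestGroupSummary:
    def _setup(self):
        years = (2000, 2001, 2002, 2003)
        frame = pd.DataFrame(
            [("AAA", y, "overall", 10.0, 1000.0) for y in years]
            + [("BBB", y, "overall", 20.0, 9000.0) for y in years]
            + [("CCC", y, "overall", 30.0, 20000.0) for y in years]
        , columns=["country", "year", "stratum", "prevalence_pct", "gdppc"])
        panel = oe.CountryYearPanel.from_frame(frame)
        groups = oe.CountryGroupTable(
            pd.DataFrame(
                {"income_group": ["low", "low", "high"], "region": ["r1", "r1", "r2"]},
                index=["AAA", "BBB", "CCC"],
            )
        )
        return panel, groups

    def test_two_country_mean(self):
        panel, groups = self._setup()
        out = oe.group_summary(panel, groups, 2001)
        low = out[out.group == "low"].iloc[0]
        assert low.mean_prevalence == 15.0
        assert low.n_countries == 2

    def test_single_country_group_sd_flagged(self):
        panel, groups = self._setup()
        out = oe.group_summary(panel, groups, 2001)
        high = out[out.group == "high"].iloc[0]
        assert high.n_countries == 1 and np.isnan(high.sd_prevalence)

    def test_partial_coverage_warns(self):
        panel, groups = self._setup()
        trimmed = oe.CountryYearPanel.from_frame(
            pd.concat(
                [
                    panel.data[panel.data.country != "CCC"],
                    panel.data[(panel.data.country == "CCC") & (panel.data.year != 2001)],
                ]
            )
        )
        with pytest.warns(PartialCoverageWarning, match="CCC"):
            oe.group_summary(trimmed, groups, 2001)

    def test_group_means_track_generator_structure(self, tiny_dataset):
        """Income groups built from baseline GDPPC quartiles behave sanely."""
        out = oe.group_summary(tiny_dataset.panel, tiny_dataset.groups, 1975)
        assert set(out.group) <= set(oe.panel.INCOME_GROUPS)
        assert (out.n_countries > 0).all()
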