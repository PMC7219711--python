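"""Forecast compounding, ramps, aggregation and the scenario table."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import obesity_elasticity as oe
from obesity_elasticity.forecast import (
    ForecastScenario,
    aggregate_forecast,
    apply_ramp,
    project_country,
)


class TestRamp:
    @pytest.mark.parametrize(
        "d,K,idx,expected",
        [
            (0.2, 6, 5, 0.8),  # final-year factor is exactly 1−d
            (0.1, 6, 2, 0.95),  # midpoint of the linear ramp
        ],
    )
    def test_linear_values(self, d, K, idx, expected):
        assert apply_ramp(d, K)[idx] == pytest.approx(expected)

    def test_zero_decline_all_ones(self):
        assert (apply_ramp(0.0, 6) == 1.0).all()

    def test_step_mode(self):
        assert (apply_ramp(0.2, 4, "step") == 0.8).all()

    @given(d=st.floats(0, 0.99, exclude_max=True), K=st.integers(1, 40))
    def test_endpoint_and_monotone(self, d, K):
        s = apply_ramp(d, K)
        assert s[-1] == pytest.approx(1 - d)
        assert (np.diff(s) <= 1e-12).all()


class TestProjection:
    def test_unit_elasticity_tracks_income_growth(self):
        traj, clamped = project_country(10.0, [1.0], np.full(5, 2.0))
        np.testing.assert_allclose(traj[0], 10.0 * 1.02 ** np.arange(1, 6))
        assert clamped == 0

    def test_zero_elasticity_flat(self):
        traj, _ = project_country(10.0, [0.0], np.full(8, 3.0))
        assert (traj == 10.0).all()

    def test_compounding_closed_form(self):
        traj, _ = project_country(10.0, [1.5], np.full(10, 2.0))
        assert traj[0, -1] == pytest.approx(13.4392, abs=5e-5)

    def test_growth_domain_error(self):
        with pytest.raises(ValueError, match="−100"):
            project_country(10.0, [1.0], np.array([-100.0]))

    def test_clamp_counter(self):
        traj, clamped = project_country(50.0, [30.0], np.full(5, 10.0))
        assert clamped > 0 and traj.max() <= 100.0

    def test_bridge_years_pure_compounding(self):
        """Scenario factors of 1 over bridge years reproduce raw compounding."""
        g = np.array([1.0, 2.0, 3.0])
        traj, _ = project_country(20.0, [1.2], g, scenario_factors=np.ones(3))
        expect = 20.0 * np.cumprod(1 + 1.2 * g / 100)
        np.testing.assert_allclose(traj[0], expect)


class TestAggregation:
    def _result(self, trajs, start):
        years = np.array([2019, 2020, 2021])
        return aggregate_forecast(
            trajs, years, start, ForecastScenario("full_window", (1975, 2014)),
            horizon_mask=np.array([True, True, True]),
        )

    def test_single_country_identity(self):
        traj, _ = project_country(10.0, [1.0, 1.0], np.full(3, 2.0))
        res = self._result({"AAA": traj}, {"AAA": 10.0})
        np.testing.assert_allclose(res.aggregate["mean"], traj[0])

    def test_two_constant_countries_average(self):
        t1, _ = project_country(10.0, [0.0], np.full(3, 2.0))
        t2, _ = project_country(20.0, [0.0], np.full(3, 2.0))
        res = self._result({"AAA": t1, "BBB": t2}, {"AAA": 10.0, "BBB": 20.0})
        assert (res.aggregate["mean"] == 15.0).all()
        assert res.avg_annual_growth_pct == pytest.approx(0.0)

    def test_point_mass_draws_zero_band_width(self):
        traj, _ = project_country(10.0, np.full(100, 1.3), np.full(3, 2.0))
        res = self._result({"AAA": traj}, {"AAA": 10.0})
        np.testing.assert_allclose(res.aggregate["lower"], res.aggregate["upper"])

    def test_band_ordering(self):
        rng = np.random.default_rng(0)
        traj, _ = project_country(10.0, rng.normal(1.2, 0.3, 500), np.full(3, 2.0))
        res = self._result({"AAA": traj}, {"AAA": 10.0})
        assert (res.aggregate["lower"] <= res.aggregate["mean"]).all()
        assert (res.aggregate["mean"] <= res.aggregate["upper"]).all()

    def test_mismatched_grids_error(self):
        t1, _ = project_country(10.0, [1.0], np.full(3, 2.0))
        t2, _ = project_country(10.0, [1.0], np.full(4, 2.0))
        with pytest.raises(ValueError, match="mismatched"):
            self._result({"AAA": t1, "BBB": t2}, {"AAA": 10.0, "BBB": 10.0})


@pytest.fixture(scope="module")
def scenario_run(tiny_dataset):
    table, results = oe.run_scenarios(
        tiny_dataset.panel,
        tiny_dataset.moderators,
        tiny_dataset.projections,
        stratum="overall",
        n_draws=300,
        seed=4,
        mcmc=oe.MCMCConfig(n_iter=800, burn_in=300, thin=1, seed=4),
    )
    return table, results


class TestScenarios:
    def test_five_scenarios_in_presentation_order(self, scenario_run):
        table, _ = scenario_run
        assert table["scenario"].tolist() == [
            "full_window",
            "recent_15y",
            "recent_10y",
            "drop_10pct",
            "drop_20pct",
        ]

    def test_growth_monotone_in_decline(self, scenario_run):
        table, _ = scenario_run
        g = table.set_index("scenario")["avg_annual_growth_pct"]
        assert g["drop_20pct"] < g["drop_10pct"] < g["recent_10y"]

    def test_no_clamping_on_default_synthetic(self, scenario_run):
        table, _ = scenario_run
        assert (table["clamp_events"] == 0).all()

    def test_aggregate_mean_inside_band(self, scenario_run):
        _, results = scenario_run
        for res in results.values():
            agg = res.aggregate
            assert ((agg["lower"] <= agg["mean"] + 1e-9) & (agg["mean"] <= agg["upper"] + 1e-9)).all()

    def test_point_mass_posterior_matches_closed_form(self, tiny_dataset):
        """Degenerate elasticity draws reduce the forecast to arithmetic."""
        import dataclasses

        cfg = dataclasses.replace(
            tiny_dataset.config, sigma_y=0.0, Sigma=np.zeros((2, 2)), projection_growth=2.0
        )
        ds = oe.generate_dataset(cfg, seed=6)
        table, results = oe.run_scenarios(
            ds.panel,
            ds.moderators,
            ds.projections,
            scenarios=[oe.ForecastScenario("full_window", (1975, 1990))],
            stratum="overall",
            n_draws=100,
            seed=6,
            mcmc=oe.MCMCConfig(n_iter=1200, burn_in=400, thin=2, seed=6),
        )
        beta = ds.truth.beta["overall"]
        last = ds.panel.subset("overall")
        start = last[last.year == 1990].set_index("country")["prevalence_pct"]
        grid = ds.projections.path_for(ds.truth.countries[0])
        Y = len(grid)
        expect = np.mean(
            [start[c] * (1 + beta[i] * 0.02) ** Y for i, c in enumerate(ds.truth.countries)]
        )
        got = results["full_window"].aggregate["mean"].iloc[-1]
        assert got == pytest.approx(expect, rel=0.02)
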