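"""Elasticity-draw forecasting of obesity prevalence.

For each posterior draw b of a country's income elasticity beta_b, prevalence
is compounded yearly along the projected income path:

    prev_{y+1} = prev_y * (1 + (s_y * beta_b) * g_y / 100)

where g_y is the projected annual GDPPC growth in % and s_y a scenario
"ramp" factor representing a policy-driven decline in elasticities (linear
ramp reaching the full drop d in the final horizon year; bridge years —
actual growth between the estimation window and the projection horizon —
always use s_y = 1).  Aggregation across countries is an unweighted mean per
draw; bands are 2.5/97.5 percentiles across draws.  Prevalence is clamped to
(0, 100] with an event counter rather than silently truncated.

The five standard sensitivity scenarios re-estimate elasticities from the
full window and from the most recent 15 and 10 years of panel data, and
apply 10% / 20% total elasticity declines to the recent-10-year estimates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .gibbs import HierModelSpec, MCMCConfig, PosteriorDraws, PriorConfig, run_gibbs
from .panel import CountryYearPanel, IncomeProjectionTable, ModeratorTable, compute_cagr

__all__ = [
    "ForecastScenario",
    "ForecastResult",
    "default_scenarios",
    "apply_ramp",
    "project_country",
    "aggregate_forecast",
    "select_elasticity_draws",
    "run_scenarios",
]


@dataclass
class ForecastScenario:
    """One sensitivity scenario.

    ``window`` bounds the years used to estimate elasticities; ``decline``
    is the total proportional drop d in elasticities reached by the end of
    the horizon (0 ≤ d < 1); ``ramp`` is 'linear' (gradual) or 'step'
    (full drop from the first horizon year).
    """

    label: str
    window: tuple[int, int]
    decline: float = 0.0
    ramp: str = "linear"

    def __post_init__(self) -> None:
        if not 0 <= self.decline < 1:
            raise ValueError("decline must satisfy 0 ≤ d < 1")
        if self.ramp not in ("linear", "step"):
            raise ValueError("ramp must be 'linear' or 'step'")


def default_scenarios(panel_start: int = 1975, panel_end: int = 2014) -> list[ForecastScenario]:
    """The five standard scenarios, in presentation order."""
    recent10 = (panel_end - 9, panel_end)
    return [
        ForecastScenario("full_window", (panel_start, panel_end)),
        ForecastScenario("recent_15y", (panel_end - 14, panel_end)),
        ForecastScenario("recent_10y", recent10),
        ForecastScenario("drop_10pct", recent10, decline=0.10),
        ForecastScenario("drop_20pct", recent10, decline=0.20),
    ]


@dataclass
class ForecastResult:
    """Per-scenario trajectories and growth summary."""

    scenario: ForecastScenario
    years: np.ndarray
    aggregate: pd.DataFrame  # year, mean, lower, upper
    country_mean: pd.DataFrame  # index country, columns years
    avg_annual_growth_pct: float  # CAGR of the aggregate mean trajectory over the horizon
    growth_lower_pct: float  # 2.5 / 97.5 percentiles of per-draw CAGRs
    growth_upper_pct: float
    mean_annual_growth_pct: float  # mean of per-year growth rates (alternative summary)
    clamp_events: int = 0


def apply_ramp(d: float, horizon_years: int, mode: str = "linear") -> np.ndarray:
    """Per-year elasticity factors s_y over the horizon.

    Linear: s_y = 1 − d*(y_index/K) for y_index = 1..K, so the final year is
    exactly 1−d.  Step: every year at 1−d.
    """
    if not 0 <= d < 1:
        raise ValueError("decline must satisfy 0 ≤ d < 1")
    if horizon_years < 1:
        raise ValueError("horizon must span at least one year")
    if mode == "linear":
        return 1.0 - d * np.arange(1, horizon_years + 1) / horizon_years
    if mode == "step":
        return np.full(horizon_years, 1.0 - d)
    raise ValueError("ramp mode must be 'linear' or 'step'")


def project_country(
    start_prev: float,
    elasticity_draws: np.ndarray,
    growth_pct: np.ndarray,
    scenario_factors: np.ndarray | None = None,
) -> tuple[np.ndarray, int]:
    """Compound one country's prevalence along a growth path, per draw.

    Returns (trajectories, clamp_events) with trajectories of shape
    (n_draws, n_years): column y holds prevalence after the y-th projected
    year.  ``scenario_factors`` defaults to all ones.
    """
    if not 0 < start_prev < 100:
        raise ValueError("start_prev must lie in (0, 100)")
    beta = np.atleast_1d(np.asarray(elasticity_draws, float))
    g = np.asarray(growth_pct, float)
    if np.any(g <= -100):
        raise ValueError("income growth must exceed −100%")
    s = np.ones_like(g) if scenario_factors is None else np.asarray(scenario_factors, float)
    if s.shape != g.shape:
        raise ValueError("scenario factors must align with the growth path")

    factors = 1.0 + (s[None, :] * beta[:, None]) * g[None, :] / 100.0
    traj = start_prev * np.cumprod(factors, axis=1)
    clamped = int(np.sum(traj >= 100.0) + np.sum(traj <= 0.0))
    traj = np.clip(traj, np.nextafter(0.0, 1.0), 100.0)
    return traj, clamped


def aggregate_forecast(
    trajectories: dict[str, np.ndarray],
    years: np.ndarray,
    start_prevs: dict[str, float],
    scenario: ForecastScenario,
    horizon_mask: np.ndarray,
    clamp_events: int = 0,
) -> ForecastResult:
    """Unweighted cross-country aggregation with prediction bands.

    Every country must share the same year grid; the per-draw aggregate is
    the mean across countries of that draw's trajectories, from which the
    mean trajectory, 2.5/97.5% bands, and horizon growth summaries follow.
    """
    countries = sorted(trajectories)
    shapes = {trajectories[c].shape for c in countries}
    if len(shapes) != 1:
        raise ValueError("mismatched year grids / draw counts across countries")
    (B, Y) = shapes.pop()
    if Y != len(years) or Y != len(horizon_mask):
        raise ValueError("year grid does not match trajectory width")

    stack = np.stack([trajectories[c] for c in countries])  # (C, B, Y)
    agg = stack.mean(axis=0)  # (B, Y)
    agg_mean = agg.mean(axis=0)
    agg_lo = np.percentile(agg, 2.5, axis=0)
    agg_hi = np.percentile(agg, 97.5, axis=0)

    start_agg = float(np.mean([start_prevs[c] for c in countries]))
    h_idx = np.where(horizon_mask)[0]
    K = len(h_idx)
    # growth over the horizon: from the last pre-horizon value to the final year
    pre = agg_mean[h_idx[0] - 1] if h_idx[0] > 0 else start_agg
    growth = compute_cagr(pre, agg_mean[h_idx[-1]], K)
    pre_draws = agg[:, h_idx[0] - 1] if h_idx[0] > 0 else np.full(B, start_agg)
    draw_growth = 100.0 * ((agg[:, h_idx[-1]] / pre_draws) ** (1.0 / K) - 1.0)

    path = np.concatenate([[pre], agg_mean[h_idx]])
    per_year = 100.0 * (path[1:] / path[:-1] - 1.0)

    return ForecastResult(
        scenario=scenario,
        years=np.asarray(years),
        aggregate=pd.DataFrame(
            {"year": years, "mean": agg_mean, "lower": agg_lo, "upper": agg_hi}
        ),
        country_mean=pd.DataFrame(
            stack.mean(axis=1), index=countries, columns=list(years)
        ),
        avg_annual_growth_pct=float(growth),
        growth_lower_pct=float(np.percentile(draw_growth, 2.5)),
        growth_upper_pct=float(np.percentile(draw_growth, 97.5)),
        mean_annual_growth_pct=float(per_year.mean()),
        clamp_events=clamp_events,
    )


def select_elasticity_draws(
    draws: PosteriorDraws, n_draws: int, seed: int
) -> np.ndarray:
    """Exactly ``n_draws`` joint elasticity draws, (n_draws, n_countries).

    Retained draws are thinned to the requested count by even spacing; if
    fewer are available they are resampled with replacement (seeded).  Draw
    indices are shared across countries so each row is a coherent joint
    posterior draw.
    """
    S = draws.n_draws
    if S >= n_draws:
        idx = np.unique(np.linspace(0, S - 1, n_draws).round().astype(int))
        # even spacing can collide after rounding; pad deterministically
        if len(idx) < n_draws:
            extra = np.setdiff1d(np.arange(S), idx)[: n_draws - len(idx)]
            idx = np.sort(np.concatenate([idx, extra]))
    else:
        rng = np.random.default_rng(np.random.SeedSequence([seed, 404]))
        idx = rng.integers(0, S, size=n_draws)
    return draws.beta[idx]


def run_scenarios(
    panel: CountryYearPanel,
    moderators: ModeratorTable,
    projections: IncomeProjectionTable,
    scenarios: list[ForecastScenario] | None = None,
    stratum: str = "overall",
    n_draws: int = 1000,
    seed: int = 0,
    priors: PriorConfig | None = None,
    mcmc: MCMCConfig | None = None,
    moderator_subset: list[str] | None = None,
    fits: dict[tuple[int, int], PosteriorDraws] | None = None,
) -> tuple[pd.DataFrame, dict[str, ForecastResult]]:
    """Run the full scenario table.

    For every distinct estimation window a hierarchical fit is produced
    (reusing entries of ``fits`` when supplied), 1000 joint elasticity draws
    are taken per scenario, each country's prevalence is compounded from its
    last observed value along the bridge-plus-horizon growth path, and the
    aggregate growth summary is tabulated in scenario order.
    """
    scenarios = scenarios or default_scenarios(panel.years[0], panel.years[-1])
    mcmc = mcmc or MCMCConfig()
    fits = dict(fits) if fits else {}

    for sc in scenarios:
        lo, hi = sc.window
        if lo < panel.years[0] or hi > panel.years[-1] or hi - lo + 1 < 3:
            raise ValueError(f"scenario {sc.label!r}: window {sc.window} invalid for this panel")
        if sc.window not in fits:
            sub = panel.window(lo, hi)
            fits[sc.window] = run_gibbs(
                sub,
                moderators,
                HierModelSpec(stratum=stratum, moderators=moderator_subset),
                priors=priors,
                mcmc=mcmc,
            )

    # last observed prevalence per country, and the common year grid
    last_year = panel.years[-1]
    obs = panel.subset(stratum=stratum)
    start_prev = (
        obs[obs["year"] == last_year].set_index("country")["prevalence_pct"].to_dict()
    )

    rows = []
    results: dict[str, ForecastResult] = {}
    for sc in scenarios:
        fit = fits[sc.window]
        beta_draws = select_elasticity_draws(fit, n_draws, seed)
        country_index = {c: i for i, c in enumerate(fit.countries)}

        trajs: dict[str, np.ndarray] = {}
        years_grid = None
        horizon_mask = None
        clamp_total = 0
        for country in fit.countries:
            if country not in start_prev:
                raise ValueError(f"no {last_year} prevalence observation for {country}")
            path = projections.path_for(country)
            yrs = path["year"].to_numpy(int)
            if years_grid is None:
                years_grid = yrs
                is_bridge = path["is_bridge"].to_numpy(bool)
                horizon_mask = ~is_bridge
                K = int(horizon_mask.sum())
                s = np.ones(len(yrs))
                s[horizon_mask] = apply_ramp(sc.decline, K, sc.ramp)
            elif not np.array_equal(yrs, years_grid):
                raise ValueError(f"projection year grid for {country} differs")
            traj, clamped = project_country(
                start_prev[country],
                beta_draws[:, country_index[country]],
                path["growth_pct"].to_numpy(float),
                s,
            )
            trajs[country] = traj
            clamp_total += clamped

        result = aggregate_forecast(
            trajs, years_grid, start_prev, sc, horizon_mask, clamp_events=clamp_total
        )
        results[sc.label] = result
        rows.append(
            (
                sc.label,
                sc.window[0],
                sc.window[1],
                sc.decline,
                result.avg_annual_growth_pct,
                result.growth_lower_pct,
                result.growth_upper_pct,
                result.mean_annual_growth_pct,
                result.clamp_events,
            )
        )

    table = pd.DataFrame(
        rows,
        columns=[
            "scenario",
            "window_start",
            "window_end",
            "decline",
            "avg_annual_growth_pct",
            "growth_lower_pct",
            "growth_upper_pct",
            "mean_annual_growth_pct",
            "clamp_events",
        ],
    )
    return table, results
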