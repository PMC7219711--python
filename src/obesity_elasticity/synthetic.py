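"""Synthetic country-year panels with known ground truth.

The generator produces data with exactly the structure the hierarchical
estimator assumes:

* first stage, per country ``c`` and year ``t``::

      ln(prev_ct) = alpha_c + beta_c * ln(gdppc_ct) + eps_ct,
      eps_ct ~ N(0, sigma_y^2)

* second stage::

      (alpha_c, beta_c) = (z_c' theta_alpha, z_c' theta_beta) + pi_c,
      pi_c ~ MVN(0, Sigma)

  where ``z_c`` is an intercept plus standardized moderators.

GDPPC trajectories are geometric with Gaussian log-shocks: each country gets
a mean annual log-growth ``g_c ~ N(0.02, 0.01^2)`` plus i.i.d. ``N(0, 0.02^2)``
yearly shocks.  Baseline log-income is, by default, tied to the first
continuous moderator (``ln gdppc_0 = 8 + 1.5 * z_1``), and the default
``theta_alpha`` carries an offsetting loading on that moderator.  This makes
country intercepts negatively correlated with income, which is both what real
cross-country data show (within-country elasticities near 1.2 coexist with a
much flatter cross-sectional income gradient) and what keeps simulated
prevalence inside (0, 100) without distorting the log-log law.  Countries
whose prevalence would still exit (0, 100) are rejected and redrawn
(coefficient deviations and noise only), never truncated.

Everything is reproducible bit-exactly from ``(GeneratorConfig, seed)``.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from itertools import product
from string import ascii_uppercase

import numpy as np
import pandas as pd

from .panel import (
    DIMENSIONS,
    INCOME_GROUPS,
    CountryGroupTable,
    CountryYearPanel,
    IncomeProjectionTable,
    ModeratorTable,
    standardize_moderators,
)

__all__ = [
    "GeneratorConfig",
    "SyntheticTruth",
    "SyntheticDataset",
    "ConfigError",
    "ConfigInfeasibleError",
    "generate_moderators",
    "generate_panel",
    "generate_projections",
    "generate_groups",
    "generate_dataset",
    "write_dataset",
]

_REGIONS = (
    "East Asia & Pacific",
    "Europe & Central Asia",
    "Latin America & Caribbean",
    "Middle East & North Africa",
    "South Asia",
    "Sub-Saharan Africa",
)


class ConfigError(ValueError):
    """The generator configuration is internally inconsistent."""


class ConfigInfeasibleError(RuntimeError):
    """A country exceeded the redraw budget while enforcing prevalence bounds."""


@dataclass
class GeneratorConfig:
    """Study-condition parameters for the synthetic panel.

    Defaults emulate the WHO/World-Bank panel the analysis targets: 147
    countries observed over 40 years (labelled 1975–2014), a log-log
    prevalence–income law with true mean elasticity 1.2, multiplicative
    observation noise with sd 0.05 on the log scale, baseline log-income
    ~ N(8, 1.5²), and ten moderators (two per dimension, the last two
    binary).  One moderator per dimension carries a real effect on the
    elasticity (|theta| = 0.1 by default) so that moderation is present but
    does not dominate.
    """

    n_countries: int = 147
    n_years: int = 40
    start_year: int = 1975
    strata: tuple[str, ...] = ("male", "female", "overall")

    # moderators
    n_moderators: int = 10
    n_dummy: int = 2
    dummy_p: float = 0.5
    moderator_rho: float = 0.0  # common pairwise correlation of continuous vars

    # second stage truth; None → built by resolved_theta()
    theta_alpha: np.ndarray | None = None
    theta_beta: np.ndarray | None = None
    mean_elasticity: float = 1.2
    active_moderator_effect: float = 0.1
    income_moderator_effect: float = -0.15  # elasticity loading on the income-linked moderator
    n_active: int = 5
    base_prevalence_pct: float = 5.41  # mean first-year prevalence at reference income
    Sigma: np.ndarray = field(
        default_factory=lambda: np.array([[0.68, -0.08], [-0.08, 0.01]])
    )

    # first stage noise
    sigma_y: float = 0.05

    # income process
    gdppc_log_mean: float = 8.0
    gdppc_log_sd: float = 1.5
    growth_mean: float = 0.02
    growth_sd: float = 0.01
    growth_shock_sd: float = 0.02
    income_linked_moderator: bool = True

    # projections
    bridge_years: tuple[int, int] = (2015, 2018)
    horizon_years: tuple[int, int] = (2019, 2024)
    projection_growth: float | None = None  # constant growth %, overrides the growth law

    max_redraws: int = 1000

    def __post_init__(self) -> None:
        self.Sigma = np.asarray(self.Sigma, float)
        if self.n_years < 3:
            raise ConfigError("n_years must be ≥ 3")
        if self.sigma_y < 0:
            raise ConfigError("sigma_y must be ≥ 0")
        if self.Sigma.shape != (2, 2) or not np.allclose(self.Sigma, self.Sigma.T):
            raise ConfigError("Sigma must be a symmetric 2×2 matrix")
        if np.any(np.linalg.eigvalsh(self.Sigma) < -1e-12):
            raise ConfigError("Sigma must be positive semi-definite")
        if not 0 < self.n_moderators:
            raise ConfigError("need at least one moderator")
        if self.n_moderators - self.n_dummy < 1:
            raise ConfigError("need at least one continuous moderator")
        if self.n_moderators < len(DIMENSIONS):
            raise ConfigError("need ≥ 1 moderator per dimension (≥ 5 total)")

    # -- derived structure ---------------------------------------------------

    @property
    def n_continuous(self) -> int:
        return self.n_moderators - self.n_dummy

    def moderator_names(self) -> list[str]:
        return [f"m{i:02d}" for i in range(1, self.n_moderators + 1)]

    def moderator_dimensions(self) -> list[str]:
        return [DIMENSIONS[i % len(DIMENSIONS)] for i in range(self.n_moderators)]

    def moderator_is_dummy(self) -> list[bool]:
        return [i >= self.n_continuous for i in range(self.n_moderators)]

    def resolved_theta(self) -> tuple[np.ndarray, np.ndarray]:
        """True second-stage coefficient vectors (theta_alpha, theta_beta).

        When not supplied explicitly, ``theta_beta`` puts ``mean_elasticity``
        on the intercept, ``income_moderator_effect`` (negative by default —
        elasticities attenuate with affluence, the urbanization-style
        pattern) on the income-linked first moderator, and
        ``±active_moderator_effect`` on the remaining actives among the
        first ``n_active`` continuous moderators (one per dimension for the
        default layout).  ``theta_alpha`` is the level counterpart: each
        moderator loading offsets its elasticity loading at the reference
        income (−mu_x * theta_beta_j), and with the income-linked moderator
        an extra −sd_x * mean_elasticity on that moderator flattens the
        cross-sectional gradient at baseline.
        """
        k = self.n_moderators
        if self.theta_beta is not None and self.theta_alpha is not None:
            tb = np.asarray(self.theta_beta, float)
            ta = np.asarray(self.theta_alpha, float)
            if tb.shape != (1 + k,) or ta.shape != (1 + k,):
                raise ConfigError(f"theta vectors must have length {1 + k}")
            return ta, tb
        if (self.theta_beta is None) != (self.theta_alpha is None):
            raise ConfigError("supply both theta_alpha and theta_beta, or neither")

        signs = [+1.0, -1.0, -1.0, +1.0, -1.0]
        tb = np.zeros(1 + k)
        tb[0] = self.mean_elasticity
        n_active = min(self.n_active, self.n_continuous)
        for j in range(n_active):
            tb[1 + j] = signs[j % len(signs)] * self.active_moderator_effect
        if self.income_linked_moderator and n_active >= 1:
            tb[1] = self.income_moderator_effect

        ta = np.zeros(1 + k)
        ta[0] = np.log(self.base_prevalence_pct) - self.mean_elasticity * self.gdppc_log_mean
        ta[1:] = -self.gdppc_log_mean * tb[1:]
        if self.income_linked_moderator:
            ta[1] -= self.gdppc_log_sd * self.mean_elasticity
        return ta, tb

    def to_jsonable(self) -> dict:
        d = dataclasses.asdict(self)
        for key, val in d.items():
            if isinstance(val, np.ndarray):
                d[key] = val.tolist()
        return d


@dataclass
class SyntheticTruth:
    """The generating parameter set, recorded for recovery tests."""

    theta_alpha: np.ndarray
    theta_beta: np.ndarray
    Sigma: np.ndarray
    sigma_y: float
    alpha: dict[str, np.ndarray]  # stratum -> per-country intercepts
    beta: dict[str, np.ndarray]  # stratum -> per-country elasticities
    countries: list[str]
    moderators: pd.DataFrame  # standardized values actually used
    n_rejections: int = 0

    def to_jsonable(self) -> dict:
        return {
            "theta_alpha": self.theta_alpha.tolist(),
            "theta_beta": self.theta_beta.tolist(),
            "Sigma": self.Sigma.tolist(),
            "sigma_y": self.sigma_y,
            "alpha": {s: a.tolist() for s, a in self.alpha.items()},
            "beta": {s: b.tolist() for s, b in self.beta.items()},
            "countries": list(self.countries),
            "moderators": self.moderators.to_dict(orient="index"),
            "n_rejections": self.n_rejections,
        }


def _country_codes(n: int) -> list[str]:
    """ISO3-like synthetic codes: SAA, SAB, ... (S prefix marks synthetic)."""
    codes = []
    for a, b in product(ascii_uppercase, repeat=2):
        codes.append("S" + a + b)
        if len(codes) == n:
            return codes
    raise ConfigError("too many countries for the synthetic code space")


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------


def generate_moderators(config: GeneratorConfig, seed: int) -> ModeratorTable:
    """Draw and standardize a moderator table.

    Continuous moderators come from a multivariate normal with common
    pairwise correlation ``moderator_rho`` and are z-scored in-sample;
    dummies are Bernoulli(``dummy_p``).  Dimensions are assigned round-robin.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 101]))
    n, kc = config.n_countries, config.n_continuous
    rho = config.moderator_rho
    corr = np.full((kc, kc), rho)
    np.fill_diagonal(corr, 1.0)
    try:
        L = np.linalg.cholesky(corr)
    except np.linalg.LinAlgError as exc:
        raise ConfigError(f"moderator correlation matrix is not positive definite (rho={rho})") from exc
    cont = rng.standard_normal((n, kc)) @ L.T
    dummies = (rng.random((n, config.n_dummy)) < config.dummy_p).astype(float)

    values = pd.DataFrame(
        np.column_stack([cont, dummies]) if config.n_dummy else cont,
        index=_country_codes(n),
        columns=config.moderator_names(),
    )
    table = ModeratorTable(
        values=values,
        dimensions=pd.Series(config.moderator_dimensions(), index=config.moderator_names()),
        is_dummy=pd.Series(config.moderator_is_dummy(), index=config.moderator_names()),
    )
    return standardize_moderators(table)


def _draw_coeff_deviations(rng: np.random.Generator, Sigma: np.ndarray, size: int) -> np.ndarray:
    """MVN(0, Sigma) deviations; a zero Sigma degenerates to exact zeros."""
    if np.allclose(Sigma, 0.0):
        return np.zeros((size, 2))
    # eigh-based root tolerates the near-singular default Sigma
    w, V = np.linalg.eigh(Sigma)
    root = V @ np.diag(np.sqrt(np.clip(w, 0.0, None)))
    return rng.standard_normal((size, 2)) @ root.T


def generate_panel(
    config: GeneratorConfig, moderators: ModeratorTable, seed: int
) -> tuple[CountryYearPanel, SyntheticTruth]:
    """Simulate the prevalence/GDPPC panel for every configured stratum.

    GDPPC paths are shared across strata (they are the same economy);
    coefficients and noise are drawn independently per stratum from the same
    second-stage law.  Countries whose prevalence would leave (0, 100) have
    their coefficient deviation and noise redrawn, up to ``max_redraws``
    attempts each, and the total redraw count is recorded on the truth
    object.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 202]))
    n, T = config.n_countries, config.n_years
    countries = list(moderators.countries)
    if len(countries) != n:
        raise ConfigError(
            f"moderator table has {len(countries)} countries, config expects {n}"
        )
    ta, tb = config.resolved_theta()
    Z = moderators.design_matrix(countries)
    if Z.shape[1] != len(ta):
        raise ConfigError("theta length does not match moderator count")

    # income paths (log scale), shared across strata
    if config.income_linked_moderator:
        z1 = moderators.values.iloc[:, 0].to_numpy(float)
        x0 = config.gdppc_log_mean + config.gdppc_log_sd * z1
    else:
        x0 = rng.normal(config.gdppc_log_mean, config.gdppc_log_sd, size=n)
    g = rng.normal(config.growth_mean, config.growth_sd, size=n)
    shocks = rng.normal(0.0, config.growth_shock_sd, size=(n, T - 1))
    steps = g[:, None] + shocks
    x = np.concatenate([x0[:, None], x0[:, None] + np.cumsum(steps, axis=1)], axis=1)

    mean_delta = Z @ np.column_stack([ta, tb])  # (n, 2)
    ln_hi = np.log(100.0)

    years = np.arange(config.start_year, config.start_year + T)
    frames = []
    alpha_truth: dict[str, np.ndarray] = {}
    beta_truth: dict[str, np.ndarray] = {}
    total_rejections = 0

    for stratum in config.strata:
        dev = _draw_coeff_deviations(rng, config.Sigma, n)
        noise = rng.normal(0.0, config.sigma_y, size=(n, T)) if config.sigma_y > 0 else np.zeros((n, T))
        alpha = mean_delta[:, 0] + dev[:, 0]
        beta = mean_delta[:, 1] + dev[:, 1]
        lnprev = alpha[:, None] + beta[:, None] * x + noise

        bad = np.where(lnprev.max(axis=1) >= ln_hi)[0]
        for c in bad:
            for attempt in range(config.max_redraws):
                dev_c = _draw_coeff_deviations(rng, config.Sigma, 1)[0]
                noise_c = (
                    rng.normal(0.0, config.sigma_y, size=T)
                    if config.sigma_y > 0
                    else np.zeros(T)
                )
                a_c = mean_delta[c, 0] + dev_c[0]
                b_c = mean_delta[c, 1] + dev_c[1]
                ln_c = a_c + b_c * x[c] + noise_c
                total_rejections += 1
                if ln_c.max() < ln_hi:
                    alpha[c], beta[c] = a_c, b_c
                    lnprev[c] = ln_c
                    break
            else:
                raise ConfigInfeasibleError(
                    f"country index {c} exceeded {config.max_redraws} redraws; "
                    "the configuration cannot keep prevalence inside (0, 100)"
                )

        alpha_truth[stratum] = alpha.copy()
        beta_truth[stratum] = beta.copy()
        frames.append(
            pd.DataFrame(
                {
                    "country": np.repeat(countries, T),
                    "year": np.tile(years, n),
                    "stratum": stratum,
                    "prevalence_pct": np.exp(lnprev).ravel(),
                    "gdppc": np.exp(np.broadcast_to(x, (n, T))).ravel(),
                }
            )
        )

    panel = CountryYearPanel.from_frame(pd.concat(frames, ignore_index=True))
    if len(panel.rejected):
        raise ConfigInfeasibleError(
            "generated panel failed its own validation: "
            + panel.rejected["reason"].value_counts().to_dict().__repr__()
        )
    truth = SyntheticTruth(
        theta_alpha=ta,
        theta_beta=tb,
        Sigma=config.Sigma.copy(),
        sigma_y=config.sigma_y,
        alpha=alpha_truth,
        beta=beta_truth,
        countries=countries,
        moderators=moderators.values.copy(),
        n_rejections=total_rejections,
    )
    return panel, truth


def generate_projections(
    config: GeneratorConfig, seed: int, countries: list[str] | None = None
) -> IncomeProjectionTable:
    """Annual GDPPC growth (%) for bridge plus horizon years per country.

    Bridge years stand in for observed growth between the panel's last year
    and the projection window; horizon years emulate IMF-style forecasts.
    ``projection_growth`` (if set) makes every entry that constant, which is
    useful for closed-form forecast checks.
    """
    if config.horizon_years[1] < config.horizon_years[0]:
        raise ConfigError("horizon must span at least one year")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 303]))
    if countries is None:
        countries = _country_codes(config.n_countries)
    years = list(range(config.bridge_years[0], config.bridge_years[1] + 1)) + list(
        range(config.horizon_years[0], config.horizon_years[1] + 1)
    )
    is_bridge = [y <= config.bridge_years[1] for y in years]
    rows = []
    for country in countries:
        if config.projection_growth is not None:
            growth = np.full(len(years), float(config.projection_growth))
        else:
            g_c = rng.normal(config.growth_mean, config.growth_sd)
            growth = 100.0 * (g_c + rng.normal(0.0, config.growth_shock_sd, size=len(years)))
        for y, gp, br in zip(years, growth, is_bridge):
            rows.append((country, y, gp, br))
    return IncomeProjectionTable(
        pd.DataFrame(rows, columns=["country", "year", "growth_pct", "is_bridge"])
    )


def generate_groups(panel: CountryYearPanel) -> CountryGroupTable:
    """Income groups by baseline-GDPPC quartile; regions cycled round-robin."""
    first_year = panel.years[0]
    base = (
        panel.data[panel.data["year"] == first_year]
        .groupby("country")["gdppc"]
        .first()
        .sort_index()
    )
    quartiles = base.rank(pct=True)
    cuts = [0.25, 0.5, 0.75]
    labels = list(reversed(INCOME_GROUPS))  # low .. high by rising income

    def classify(p: float) -> str:
        for i, c in enumerate(cuts):
            if p <= c:
                return labels[i]
        return labels[-1]

    groups = pd.DataFrame(
        {
            "income_group": [classify(p) for p in quartiles],
            "region": [_REGIONS[i % len(_REGIONS)] for i in range(len(base))],
        },
        index=base.index,
    )
    return CountryGroupTable(groups)


@dataclass
class SyntheticDataset:
    """One coherent draw of every input the analysis pipeline consumes."""

    config: GeneratorConfig
    seed: int
    panel: CountryYearPanel
    moderators: ModeratorTable
    groups: CountryGroupTable
    projections: IncomeProjectionTable
    truth: SyntheticTruth


def generate_dataset(config: GeneratorConfig, seed: int) -> SyntheticDataset:
    """Moderators → panel → groups → projections, all from one seed."""
    moderators = generate_moderators(config, seed)
    panel, truth = generate_panel(config, moderators, seed)
    projections = generate_projections(config, seed, countries=truth.countries)
    groups = generate_groups(panel)
    return SyntheticDataset(
        config=config,
        seed=seed,
        panel=panel,
        moderators=moderators,
        groups=groups,
        projections=projections,
        truth=truth,
    )


def write_dataset(dataset: SyntheticDataset, outdir) -> dict[str, str]:
    """Write the four CSV inputs plus a JSON ground-truth sidecar."""
    from pathlib import Path

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "panel": out / "panel.csv",
        "moderators": out / "moderators.csv",
        "groups": out / "groups.csv",
        "projections": out / "projections.csv",
        "truth": out / "truth.json",
    }
    dataset.panel.write_csv(paths["panel"])
    dataset.moderators.write_csv(paths["moderators"])
    dataset.groups.write_csv(paths["groups"])
    dataset.projections.write_csv(paths["projections"])
    sidecar = {
        "seed": dataset.seed,
        "config": dataset.config.to_jsonable(),
        "truth": dataset.truth.to_jsonable(),
    }
    paths["truth"].write_text(json.dumps(sidecar, indent=1))
    return {k: str(v) for k, v in paths.items()}
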