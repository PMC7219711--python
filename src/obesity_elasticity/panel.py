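"""Country-year panel containers, tabular I/O, validation and descriptives.

The central object is the :class:`CountryYearPanel`: a long-format table of
adult obesity prevalence (%, by sex stratum) and GDP per capita (GDPPC,
constant currency units) observations, one row per (country, year, stratum).
Both quantities are strictly positive because the downstream analysis works on
their natural logarithms.

Cross-sectional country covariates live in a :class:`ModeratorTable`, each
variable tagged with one of five macro-environmental dimensions
(globalization, demographic, economic, labor, health_policy) and a dummy flag.
Income-group/region assignments and projected income growth paths get their
own small containers.

All file formats are plain CSV with a header row, UTF-8, '.' decimal
separator; floats are written with 12+ significant digits so that a
write/read round trip is lossless at double precision for practical values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "STRATA",
    "DIMENSIONS",
    "INCOME_GROUPS",
    "SchemaError",
    "PanelValidationError",
    "DegenerateCovariateError",
    "PartialCoverageWarning",
    "CountryYearPanel",
    "ModeratorTable",
    "CountryGroupTable",
    "IncomeProjectionTable",
    "read_panel",
    "standardize_moderators",
    "compute_cagr",
    "group_summary",
]

STRATA = ("male", "female", "overall")
DIMENSIONS = ("globalization", "demographic", "economic", "labor", "health_policy")
INCOME_GROUPS = ("high", "upper_middle", "lower_middle", "low")

PANEL_COLUMNS = ("country", "year", "stratum", "prevalence_pct", "gdppc")

# float format giving ≥ 12 significant digits for lossless round trips
FLOAT_FMT = "%.17g"


class SchemaError(ValueError):
    """A required column is missing or mis-declared in an input file."""


class PanelValidationError(ValueError):
    """The panel violates a structural invariant (e.g. duplicate keys)."""


class DegenerateCovariateError(ValueError):
    """A non-dummy covariate has zero sample variance and cannot be z-scored."""


class PartialCoverageWarning(UserWarning):
    """A summary was requested for a year that some countries do not cover."""


# ---------------------------------------------------------------------------
# CountryYearPanel
# ---------------------------------------------------------------------------


@dataclass
class CountryYearPanel:
    """Long-format obesity-prevalence / GDPPC panel.

    Attributes
    ----------
    data:
        Validated rows with columns ``country, year, stratum,
        prevalence_pct, gdppc``, sorted by (country, stratum, year).
    rejected:
        Rows dropped during validation, with a ``reason`` column.  Empty for
        panels built programmatically from clean data.
    """

    data: pd.DataFrame
    rejected: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=list(PANEL_COLUMNS) + ["reason"])
    )

    # -- construction -------------------------------------------------------

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "CountryYearPanel":
        """Validate a raw frame, rejecting bad rows and raising on duplicates.

        Row-level problems (non-positive prevalence, prevalence ≥ 100,
        non-positive GDPPC, missing values, unknown stratum, or a
        country/stratum series left with fewer than 3 distinct years) are
        collected into ``rejected`` with a per-row reason.  Duplicate
        (country, year, stratum) keys are a structural error and raise.
        """
        missing = [c for c in PANEL_COLUMNS if c not in frame.columns]
        if missing:
            raise SchemaError(f"panel file is missing columns: {missing}")
        df = frame.loc[:, list(PANEL_COLUMNS)].copy()

        reasons = pd.Series("", index=df.index, dtype=object)

        def _mark(mask: pd.Series, reason: str) -> None:
            fresh = mask & (reasons == "")
            reasons[fresh] = reason

        _mark(df[list(PANEL_COLUMNS)].isna().any(axis=1), "missing value")
        _mark(~df["stratum"].isin(STRATA), "unknown stratum")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # NaN comparisons
            _mark(df["prevalence_pct"] <= 0, "non-positive prevalence")
            _mark(df["prevalence_pct"] >= 100, "prevalence at or above 100")
            _mark(df["gdppc"] <= 0, "non-positive gdppc")

        ok = reasons == ""
        good = df[ok].copy()
        good["year"] = good["year"].astype(int)
        good["prevalence_pct"] = good["prevalence_pct"].astype(float)
        good["gdppc"] = good["gdppc"].astype(float)

        dup = good.duplicated(subset=["country", "year", "stratum"], keep=False)
        if dup.any():
            offenders = (
                good.loc[dup, ["country", "year", "stratum"]]
                .drop_duplicates()
                .to_records(index=False)
                .tolist()
            )
            raise PanelValidationError(
                f"duplicate (country, year, stratum) keys: {offenders[:20]}"
            )

        # every country needs ≥ 3 distinct years per stratum for a
        # two-parameter regression plus a residual degree of freedom
        counts = good.groupby(["country", "stratum"])["year"].nunique()
        short = counts[counts < 3]
        if len(short):
            bad_keys = set(short.index)
            mask = good.set_index(["country", "stratum"]).index.isin(bad_keys)
            _mark(pd.Series(mask, index=good.index), "fewer than 3 years in stratum")
            for idx in good.index[mask]:
                reasons[idx] = "fewer than 3 years in stratum"
            good = good[~mask]

        rejected = df[reasons != ""].copy()
        rejected["reason"] = reasons[reasons != ""]
        good = good.sort_values(["country", "stratum", "year"]).reset_index(drop=True)
        return cls(data=good, rejected=rejected.reset_index(drop=True))

    # -- accessors -----------------------------------------------------------

    @property
    def countries(self) -> list[str]:
        return sorted(self.data["country"].unique())

    @property
    def years(self) -> list[int]:
        return sorted(self.data["year"].unique())

    @property
    def strata(self) -> list[str]:
        present = set(self.data["stratum"].unique())
        return [s for s in STRATA if s in present]

    def subset(
        self,
        stratum: str | None = None,
        year_range: tuple[int, int] | None = None,
    ) -> pd.DataFrame:
        """Return panel rows for one stratum and/or an inclusive year window."""
        df = self.data
        if stratum is not None:
            if stratum not in STRATA:
                raise ValueError(f"unknown stratum {stratum!r}")
            df = df[df["stratum"] == stratum]
        if year_range is not None:
            lo, hi = year_range
            df = df[(df["year"] >= lo) & (df["year"] <= hi)]
        return df.reset_index(drop=True)

    def window(self, start: int, end: int) -> "CountryYearPanel":
        """A new panel restricted to years in [start, end] (re-validated)."""
        return CountryYearPanel.from_frame(
            self.data[(self.data["year"] >= start) & (self.data["year"] <= end)]
        )

    # -- I/O -----------------------------------------------------------------

    def write_csv(self, path) -> None:
        self.data.to_csv(path, index=False, float_format=FLOAT_FMT)


def read_panel(path, schema: Mapping[str, str] | None = None) -> CountryYearPanel:
    """Read and validate a CSV panel file.

    ``schema`` maps the canonical roles (``country, year, stratum,
    prevalence_pct, gdppc``) to the column names used in the file; omit it
    when the file already uses canonical names.
    """
    raw = pd.read_csv(path, comment="#", float_precision="round_trip")
    if schema:
        missing = [src for src in schema.values() if src not in raw.columns]
        if missing:
            raise SchemaError(f"columns named in schema not found in file: {missing}")
        raw = raw.rename(columns={src: role for role, src in schema.items()})
    return CountryYearPanel.from_frame(raw)


# ---------------------------------------------------------------------------
# ModeratorTable
# ---------------------------------------------------------------------------


@dataclass
class ModeratorTable:
    """Per-country macro-environmental covariates.

    ``values`` is a wide frame (index = country, columns = variables);
    ``dimensions`` and ``is_dummy`` are per-variable metadata.  Each of the
    five dimensions must be represented by at least one variable.
    """

    values: pd.DataFrame
    dimensions: pd.Series
    is_dummy: pd.Series

    def __post_init__(self) -> None:
        vars_ = list(self.values.columns)
        if list(self.dimensions.index) != vars_ or list(self.is_dummy.index) != vars_:
            self.dimensions = self.dimensions.reindex(vars_)
            self.is_dummy = self.is_dummy.reindex(vars_)
        unknown = set(self.dimensions) - set(DIMENSIONS)
        if unknown - {np.nan}:
            raise PanelValidationError(f"unknown moderator dimensions: {unknown}")
        missing_dims = [d for d in DIMENSIONS if (self.dimensions == d).sum() == 0]
        if missing_dims:
            raise PanelValidationError(
                f"every dimension needs ≥ 1 covariate; missing: {missing_dims}"
            )

    @property
    def variables(self) -> list[str]:
        return list(self.values.columns)

    @property
    def countries(self) -> list[str]:
        return list(self.values.index)

    def design_matrix(
        self, countries: Sequence[str], variables: Sequence[str] | None = None
    ) -> np.ndarray:
        """Intercept-plus-covariates matrix aligned to ``countries`` (n, 1+k)."""
        variables = list(variables) if variables is not None else self.variables
        missing = [c for c in countries if c not in self.values.index]
        if missing:
            raise PanelValidationError(f"countries without moderator rows: {missing[:10]}")
        X = self.values.loc[list(countries), variables].to_numpy(float)
        return np.column_stack([np.ones(len(countries)), X])

    # -- I/O (long format: country, variable, dimension, is_dummy, value) ----

    def to_long(self) -> pd.DataFrame:
        long = self.values.stack().rename("value").reset_index()
        long.columns = ["country", "variable", "value"]
        long["dimension"] = long["variable"].map(self.dimensions)
        long["is_dummy"] = long["variable"].map(self.is_dummy).astype(bool)
        return long[["country", "variable", "dimension", "is_dummy", "value"]]

    def write_csv(self, path) -> None:
        self.to_long().to_csv(path, index=False, float_format=FLOAT_FMT)

    @classmethod
    def read_csv(cls, path) -> "ModeratorTable":
        long = pd.read_csv(path, comment="#", float_precision="round_trip")
        required = {"country", "variable", "dimension", "is_dummy", "value"}
        missing = required - set(long.columns)
        if missing:
            raise SchemaError(f"moderator file is missing columns: {sorted(missing)}")
        values = long.pivot(index="country", columns="variable", values="value")
        meta = long.drop_duplicates("variable").set_index("variable")
        order = [v for v in long["variable"].drop_duplicates()]
        values = values[order]
        return cls(
            values=values,
            dimensions=meta["dimension"].reindex(order),
            is_dummy=meta["is_dummy"].astype(bool).reindex(order),
        )


def standardize_moderators(table: ModeratorTable) -> ModeratorTable:
    """Z-score non-dummy covariates (sample sd, denominator n−1).

    Dummy covariates pass through unchanged.  A non-dummy covariate with zero
    sample variance cannot be scored and raises
    :class:`DegenerateCovariateError` naming it.
    """
    values = table.values.copy()
    for var in table.variables:
        if bool(table.is_dummy[var]):
            continue
        col = values[var].to_numpy(float)
        sd = col.std(ddof=1)
        if not np.isfinite(sd) or sd == 0.0:
            raise DegenerateCovariateError(
                f"covariate {var!r} has zero sample variance and is not a dummy"
            )
        values[var] = (col - col.mean()) / sd
    return ModeratorTable(
        values=values, dimensions=table.dimensions.copy(), is_dummy=table.is_dummy.copy()
    )


# ---------------------------------------------------------------------------
# CountryGroupTable / IncomeProjectionTable
# ---------------------------------------------------------------------------


@dataclass
class CountryGroupTable:
    """World-Bank-style income group and region per country."""

    data: pd.DataFrame  # index country, columns income_group, region

    def __post_init__(self) -> None:
        for col in ("income_group", "region"):
            if col not in self.data.columns:
                raise SchemaError(f"group table is missing column {col!r}")
        bad = set(self.data["income_group"]) - set(INCOME_GROUPS)
        if bad:
            raise PanelValidationError(f"unknown income groups: {sorted(bad)}")
        if self.data.index.duplicated().any():
            raise PanelValidationError("a country appears in more than one group row")

    def write_csv(self, path) -> None:
        out = self.data.reset_index().rename(columns={"index": "country"})
        out.columns = ["country", "income_group", "region"]
        out.to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path) -> "CountryGroupTable":
        df = pd.read_csv(path, comment="#")
        if "country" not in df.columns:
            raise SchemaError("group file is missing column 'country'")
        return cls(df.set_index("country"))


@dataclass
class IncomeProjectionTable:
    """Projected (and bridging actual) annual GDPPC growth, % per year."""

    data: pd.DataFrame  # columns country, year, growth_pct, is_bridge

    def __post_init__(self) -> None:
        required = {"country", "year", "growth_pct", "is_bridge"}
        missing = required - set(self.data.columns)
        if missing:
            raise SchemaError(f"projection table is missing columns: {sorted(missing)}")
        if (self.data["growth_pct"] <= -100).any():
            raise PanelValidationError("growth_pct must exceed −100")
        for country, grp in self.data.groupby("country"):
            yrs = np.sort(grp["year"].to_numpy(int))
            if len(yrs) > 1 and not np.all(np.diff(yrs) == 1):
                raise PanelValidationError(
                    f"projection years for {country} are not consecutive: {yrs.tolist()}"
                )

    def path_for(self, country: str) -> pd.DataFrame:
        """Growth path (year-sorted) for one country."""
        grp = self.data[self.data["country"] == country]
        if grp.empty:
            raise PanelValidationError(f"no projection rows for country {country!r}")
        return grp.sort_values("year").reset_index(drop=True)

    def write_csv(self, path) -> None:
        self.data.to_csv(path, index=False, float_format=FLOAT_FMT)

    @classmethod
    def read_csv(cls, path) -> "IncomeProjectionTable":
        return cls(pd.read_csv(path, comment="#", float_precision="round_trip"))


# ---------------------------------------------------------------------------
# Descriptives
# ---------------------------------------------------------------------------


def compute_cagr(start_value: float, end_value: float, n_intervals: int) -> float:
    """Compounded annual growth rate, % per year.

    ``100 * ((end/start)**(1/n_intervals) − 1)``, where ``n_intervals`` is the
    number of year-to-year steps between the two endpoints (39 for a
    1975→2014 comparison).
    """
    if start_value <= 0 or end_value <= 0:
        raise ValueError("CAGR endpoints must be strictly positive")
    if n_intervals < 1:
        raise ValueError("n_intervals must be ≥ 1")
    return 100.0 * ((end_value / start_value) ** (1.0 / n_intervals) - 1.0)


def group_summary(
    panel: CountryYearPanel, groups: CountryGroupTable, year: int, by: str = "income_group"
) -> pd.DataFrame:
    """Unweighted cross-country mean and sample sd of prevalence per group.

    One row per (group, stratum).  Countries missing the requested year
    trigger a :class:`PartialCoverageWarning` listing them; single-country
    groups report an NaN sd (flagged via ``n_countries``).
    """
    if by not in ("income_group", "region"):
        raise ValueError("by must be 'income_group' or 'region'")
    df = panel.data[panel.data["year"] == year]
    covered = set(df["country"].unique())
    missing = sorted(set(panel.countries) - covered)
    if missing:
        warnings.warn(
            f"year {year} absent for {len(missing)} countries: {missing[:10]}",
            PartialCoverageWarning,
            stacklevel=2,
        )
    unassigned = sorted(covered - set(groups.data.index))
    if unassigned:
        raise PanelValidationError(f"countries without group assignment: {unassigned[:10]}")
    merged = df.merge(
        groups.data[[by]], left_on="country", right_index=True, how="left"
    )
    out = (
        merged.groupby([by, "stratum"], observed=True)["prevalence_pct"]
        .agg(mean_prevalence="mean", sd_prevalence=lambda s: s.std(ddof=1), n_countries="size")
        .reset_index()
        .rename(columns={by: "group"})
    )
    return out
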