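"""First-stage functional-form contest: linear vs quadratic vs log-log.

Each candidate form is fit by ordinary least squares separately for every
country, and the forms are compared by the mean absolute percentage error
(MAPE) of the fitted prevalence values on the original percentage scale:

* linear:      prev = a_c + b_c * gdppc
* quadratic:   prev = a_c + b1_c * gdppc + b2_c * gdppc^2
* log-log:     ln(prev) = a_c + b_c * ln(gdppc)   (fitted values exp-transformed)

GDPPC is rescaled to thousands inside the quadratic fit so the squared
column stays well conditioned; its coefficients are reported in those
rescaled units.  No smearing correction is applied to the log-log
back-transform.  The log-log slope b_c is the income elasticity of obesity
prevalence, which is why that form's per-country fit doubles as the quick
(non-Bayesian) elasticity estimator used elsewhere.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .panel import CountryYearPanel

__all__ = [
    "FORMS",
    "FormFit",
    "FormSelection",
    "fit_form",
    "compute_mape",
    "select_form",
    "ols_elasticities",
]

FORMS = ("linear", "quadratic", "loglog")

_TIE_TOL = 1e-9


@dataclass
class FormFit:
    """Per-country OLS fit of one candidate form, with its panel-wide MAPE."""

    form: str
    coefficients: pd.DataFrame  # index country; columns alpha, beta [, beta2]
    fitted: pd.Series  # fitted prevalence (%), aligned to the panel rows used
    mape: float
    excluded: list[str]

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.fitted.to_numpy(float))):
            raise ValueError("fitted values must be finite")
        if self.mape < 0:
            raise ValueError("MAPE cannot be negative")


@dataclass
class FormSelection:
    best: str
    table: pd.DataFrame  # columns form, mape
    tie: bool


def compute_mape(actual, predicted) -> float:
    """100 · mean(|predicted − actual| / actual); actual must be positive."""
    a = np.asarray(actual, float)
    p = np.asarray(predicted, float)
    if a.shape != p.shape:
        raise ValueError("actual and predicted must have equal length")
    if np.any(a <= 0):
        raise ValueError("MAPE requires strictly positive actual values")
    return float(100.0 * np.mean(np.abs(p - a) / a))


def _design(form: str, gdppc: np.ndarray) -> np.ndarray:
    if form == "linear":
        return np.column_stack([np.ones_like(gdppc), gdppc])
    if form == "quadratic":
        gk = gdppc / 1000.0  # thousands; keeps gdppc^2 conditioned
        return np.column_stack([np.ones_like(gk), gk, gk**2])
    if form == "loglog":
        return np.column_stack([np.ones_like(gdppc), np.log(gdppc)])
    raise ValueError(f"unknown form {form!r}; expected one of {FORMS}")


def fit_form(panel: CountryYearPanel, form: str, stratum: str = "overall") -> FormFit:
    """Fit one functional form country-by-country and score it by MAPE.

    Countries with fewer observations than the form's parameter count are
    excluded with a warning (the panel invariant of ≥ 3 years makes this
    rare).
    """
    df = panel.subset(stratum=stratum)
    if df.empty:
        raise ValueError(f"panel has no rows for stratum {stratum!r}")
    coef_cols = ["alpha", "beta"] if form != "quadratic" else ["alpha", "beta", "beta2"]
    n_par = len(coef_cols)

    coefs: dict[str, np.ndarray] = {}
    fitted_parts: list[pd.Series] = []
    excluded: list[str] = []
    for country, grp in df.groupby("country", sort=True):
        prev = grp["prevalence_pct"].to_numpy(float)
        if len(prev) < n_par:
            excluded.append(country)
            continue
        X = _design(form, grp["gdppc"].to_numpy(float))
        y = np.log(prev) if form == "loglog" else prev
        b, *_ = np.linalg.lstsq(X, y, rcond=None)
        yhat = X @ b
        if form == "loglog":
            yhat = np.exp(yhat)  # back to the % scale before MAPE
        coefs[country] = b
        fitted_parts.append(pd.Series(yhat, index=grp.index))
    if excluded:
        warnings.warn(
            f"{form}: excluded {len(excluded)} countries with too few observations: "
            f"{excluded[:10]}",
            stacklevel=2,
        )
    if not coefs:
        raise ValueError("no country had enough observations to fit")

    fitted = pd.concat(fitted_parts).sort_index()
    used = df.loc[fitted.index, "prevalence_pct"]
    mape = compute_mape(used.to_numpy(float), fitted.to_numpy(float))
    coefficients = pd.DataFrame.from_dict(coefs, orient="index", columns=coef_cols)
    coefficients.index.name = "country"
    return FormFit(form=form, coefficients=coefficients, fitted=fitted, mape=mape, excluded=excluded)


def select_form(fits: list[FormFit]) -> FormSelection:
    """Pick the minimum-MAPE form; ties within 1e-9 are flagged.

    On a tie the first-listed of the tied forms is returned, mirroring how a
    fit table would be read top to bottom.
    """
    if not fits:
        raise ValueError("select_form needs at least one fit")
    table = pd.DataFrame({"form": [f.form for f in fits], "mape": [f.mape for f in fits]})
    best_idx = int(np.argmin(table["mape"].to_numpy()))
    best_mape = table["mape"].iloc[best_idx]
    tie = bool((np.abs(table["mape"] - best_mape) < _TIE_TOL).sum() > 1)
    return FormSelection(best=table["form"].iloc[best_idx], table=table, tie=tie)


def ols_elasticities(panel: CountryYearPanel, stratum: str = "overall") -> pd.DataFrame:
    """Per-country log-log OLS intercepts and slopes (quick elasticities).

    These classical estimates seed the Gibbs sampler and serve as the
    response in the fast moderator-selection step.
    """
    fit = fit_form(panel, "loglog", stratum=stratum)
    return fit.coefficients[["alpha", "beta"]]
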