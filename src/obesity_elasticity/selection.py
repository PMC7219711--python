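"""Forward selection of macro-environmental moderators.

The second-stage regression relates per-country income elasticities to
cross-sectional moderators.  Candidate moderators are screened for pairwise
collinearity (|Pearson r| above a threshold makes a pair mutually
exclusive), then chosen by an iterative forward procedure in two phases:

* phase 1 — five rounds, each adding the best candidate (by information
  criterion, among dimensions not yet represented and not conflicting with
  the current selection) whose coefficient is significant at the 5% level;
  if no candidate in a round is significant, the best-criterion one is taken
  with a warning.  After phase 1 every dimension contributes ≥ 1 variable.
* phase 2 — keep adding the best remaining admissible candidate while it
  improves the criterion; stop otherwise.

Selection runs in fast two-step mode: the response is the vector of
per-country classical (OLS) elasticities, candidate fits are ordinary
least-squares regressions scored by AIC and BIC (BIC decides when they
disagree), and the full Gibbs model is re-estimated once afterwards with
the final set.  The procedure is deterministic given its inputs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .panel import DIMENSIONS, ModeratorTable

__all__ = [
    "SelectionState",
    "DimensionConstraintError",
    "correlation_screen",
    "forward_select",
]


class DimensionConstraintError(RuntimeError):
    """A dimension has no admissible candidate left."""


@dataclass
class SelectionState:
    """Outcome of the forward-selection procedure."""

    selected: list[str]
    trace: pd.DataFrame  # phase, round, candidate, dimension, aic, bic, tstat, chosen
    warnings: list[str] = field(default_factory=list)
    final_fit: object | None = None  # statsmodels results for the final set

    @property
    def n_selected(self) -> int:
        return len(self.selected)


def correlation_screen(table: ModeratorTable, threshold: float = 0.7) -> pd.DataFrame:
    """Pairwise Pearson correlations with mutual-exclusion flags.

    Pairs with |r| > threshold are marked ``excluded`` (mutually exclusive
    for selection).  ``threshold = 0`` therefore excludes every pair.
    """
    vars_ = table.variables
    X = table.values.to_numpy(float)
    rows = []
    for i, j in combinations(range(len(vars_)), 2):
        xi, xj = X[:, i], X[:, j]
        si, sj = xi.std(), xj.std()
        r = 0.0 if si == 0 or sj == 0 else float(np.corrcoef(xi, xj)[0, 1])
        rows.append((vars_[i], vars_[j], r, abs(r) > threshold))
    return pd.DataFrame(rows, columns=["var1", "var2", "r", "excluded"])


def _conflicts(var: str, selected: list[str], pairs: pd.DataFrame) -> bool:
    if not selected:
        return False
    mask = (
        ((pairs["var1"] == var) & pairs["var2"].isin(selected))
        | ((pairs["var2"] == var) & pairs["var1"].isin(selected))
    ) & pairs["excluded"]
    return bool(mask.any())


def _fit(response: np.ndarray, table: ModeratorTable, variables: list[str]):
    X = sm.add_constant(
        table.values.loc[:, variables].to_numpy(float), has_constant="add"
    ) if variables else np.ones((len(response), 1))
    return sm.OLS(response, X).fit()


def forward_select(
    elasticities: pd.Series,
    table: ModeratorTable,
    threshold: float = 0.7,
    alpha: float = 0.05,
    criterion: str = "bic",
) -> SelectionState:
    """Two-phase forward selection of moderators for the elasticity equation.

    Parameters
    ----------
    elasticities:
        Per-country response values indexed by country (classical
        per-country elasticity estimates).
    table:
        Standardized moderator table covering every country in the response.
    threshold:
        |Pearson r| above which two moderators are mutually exclusive.
    alpha:
        Nominal significance level for the phase-1 coefficient check.
    criterion:
        'bic' (default) or 'aic'; the named criterion breaks AIC/BIC
        disagreements and drives the phase-2 stopping rule.
    """
    if criterion not in ("aic", "bic"):
        raise ValueError("criterion must be 'aic' or 'bic'")
    missing = [c for c in table.countries if c not in elasticities.index]
    if missing:
        raise ValueError(f"response does not cover countries: {missing[:10]}")
    y = elasticities.loc[table.countries].to_numpy(float)

    pairs = correlation_screen(table, threshold)
    dims = dict(table.dimensions)
    selected: list[str] = []
    represented: set[str] = set()
    notes: list[str] = []
    trace_rows: list[tuple] = []
    current = _fit(y, table, selected)
    tcrit = stats.t.ppf(1 - alpha / 2, df=max(len(y) - 2, 1))

    def candidate_scores(cands: list[str], phase: str, round_no: int):
        scored = []
        for var in cands:
            fit = _fit(y, table, selected + [var])
            tstat = float(fit.tvalues[-1])
            scored.append((var, fit, float(fit.aic), float(fit.bic), tstat))
            trace_rows.append(
                (phase, round_no, var, dims[var], float(fit.aic), float(fit.bic), tstat, False)
            )
        return scored

    # -- phase 1: one variable per dimension --------------------------------
    round_no = 0
    while represented != set(DIMENSIONS):
        round_no += 1
        cands = [
            v
            for v in table.variables
            if v not in selected
            and dims[v] not in represented
            and not _conflicts(v, selected, pairs)
        ]
        empty_dims = [
            d
            for d in DIMENSIONS
            if d not in represented
            and not any(dims[v] == d and not _conflicts(v, selected, pairs)
                        for v in table.variables if v not in selected)
        ]
        if empty_dims:
            raise DimensionConstraintError(
                f"no admissible candidate for dimension(s): {empty_dims}"
            )
        scored = candidate_scores(cands, "phase1", round_no)
        key = 3 if criterion == "bic" else 2
        significant = [s for s in scored if abs(s[4]) > tcrit]
        pool = significant if significant else scored
        if not significant:
            notes.append(
                f"phase1 round {round_no}: no significant candidate; "
                "taking the best-criterion one"
            )
        best = min(pool, key=lambda s: (s[key], s[2]))
        selected.append(best[0])
        represented.add(dims[best[0]])
        current = best[1]
        for i in range(len(trace_rows) - len(scored), len(trace_rows)):
            if trace_rows[i][2] == best[0]:
                trace_rows[i] = trace_rows[i][:7] + (True,)

    # -- phase 2: free additions while the criterion improves ---------------
    while True:
        round_no += 1
        cands = [
            v
            for v in table.variables
            if v not in selected and not _conflicts(v, selected, pairs)
        ]
        if not cands:
            break
        scored = candidate_scores(cands, "phase2", round_no)
        key = 3 if criterion == "bic" else 2
        best = min(scored, key=lambda s: (s[key], s[2]))
        current_crit = current.bic if criterion == "bic" else current.aic
        if best[key] < current_crit:
            selected.append(best[0])
            current = best[1]
            for i in range(len(trace_rows) - len(scored), len(trace_rows)):
                if trace_rows[i][2] == best[0]:
                    trace_rows[i] = trace_rows[i][:7] + (True,)
        else:
            break

    for note in notes:
        warnings.warn(note, stacklevel=2)
    trace = pd.DataFrame(
        trace_rows,
        columns=["phase", "round", "candidate", "dimension", "aic", "bic", "tstat", "chosen"],
    )
    return SelectionState(selected=selected, trace=trace, warnings=notes, final_fit=current)
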