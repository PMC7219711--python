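"""Geweke convergence diagnostic for MCMC chains.

The diagnostic compares the mean of an early chain segment (first 10% by
default) with that of a late segment (last 50%), standardized by
spectral-density-at-zero estimates of each segment-mean's variance:

    Z = (mean_first − mean_last) / sqrt(S_first/n_first + S_last/n_last)

For a converged, stationary chain Z is approximately standard normal;
convergence is declared when |Z| < 1.96.  The spectral density at zero is
estimated by a Bartlett-windowed autocovariance sum with window length
ceil(4 * (n_segment/100)^0.25).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "DegenerateChainError",
    "spectral_density_at_zero",
    "geweke_z",
    "geweke_table",
    "GEWEKE_CRITICAL",
]

GEWEKE_CRITICAL = 1.96


class DegenerateChainError(ValueError):
    """The chain is constant; the diagnostic's variance estimate is zero."""


def spectral_density_at_zero(x: np.ndarray) -> float:
    """Bartlett-windowed estimate of the spectral density at frequency zero.

    Returns S(0) such that Var(mean(x)) ≈ S(0)/len(x) for a stationary
    series with short-range dependence.
    """
    x = np.asarray(x, float)
    n = len(x)
    if n < 2:
        raise ValueError("segment too short for a variance estimate")
    xc = x - x.mean()
    L = int(np.ceil(4.0 * (n / 100.0) ** 0.25))
    L = min(L, n - 1)
    s = float(xc @ xc) / n  # gamma_0
    for lag in range(1, L + 1):
        gamma = float(xc[:-lag] @ xc[lag:]) / n
        s += 2.0 * (1.0 - lag / (L + 1.0)) * gamma
    return max(s, 0.0)


def geweke_z(chain, first_frac: float = 0.1, last_frac: float = 0.5) -> float:
    """Geweke Z score for one chain.

    Requires length ≥ 200 and a non-constant chain; segment fractions
    default to the diagnostic's conventional 10% / 50%.
    """
    x = np.asarray(chain, float)
    n = len(x)
    if n < 200:
        raise ValueError(f"chain length {n} < 200; the diagnostic is unreliable")
    if not 0 < first_frac < 1 or not 0 < last_frac < 1 or first_frac + last_frac > 1:
        raise ValueError("segment fractions must be in (0,1) and non-overlapping")
    if np.ptp(x) == 0:
        raise DegenerateChainError("chain is constant")
    n1 = int(np.floor(first_frac * n))
    n2 = int(np.floor(last_frac * n))
    a, b = x[:n1], x[n - n2 :]
    var = spectral_density_at_zero(a) / n1 + spectral_density_at_zero(b) / n2
    if var == 0.0:
        raise DegenerateChainError("both segments are constant")
    return float((a.mean() - b.mean()) / np.sqrt(var))


def geweke_table(chains: dict[str, np.ndarray], **kwargs) -> pd.DataFrame:
    """Z scores and pass flags for a named set of chains."""
    rows = []
    for name, chain in chains.items():
        z = geweke_z(chain, **kwargs)
        rows.append((name, z, abs(z) < GEWEKE_CRITICAL))
    return pd.DataFrame(rows, columns=["chain", "z", "converged"])
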