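"""Litterbag biomass decomposition kinetics.

Interval mass-loss rates (percent of interval-start mass per day),
per-component compositional change rates (microgram per milligram of
remaining biomass), and first-order decay fitting M(t) = M0 * exp(-k t)
by least squares on log mass.  Decomposition below 0.4 %/day marks the
refractory phase of litter decay.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ParameterError

#: Decomposition rates below this (percent of mass per day) are
#: conventionally assigned to the refractory phase.
REFRACTORY_RATE_MAX = 0.4

COMPONENTS = ("cellulose_frac", "hemicellulose_frac", "lignin_frac", "ash_frac")


def interval_loss_rate(
    m_start: float, m_end: float, days: float, *, anchor_mass: float | None = None
) -> float:
    """Mass-loss rate over an interval, percent per day.

    (m_start - m_end) / denominator * 100 / days, where the denominator
    is the interval-start mass, or ``anchor_mass`` (e.g. the deployed
    mass) when given.  Mass gain yields a negative rate.
    """
    if m_start <= 0 or days <= 0:
        raise ParameterError("m_start and days must be positive")
    denom = anchor_mass if anchor_mass is not None else m_start
    if denom <= 0:
        raise ParameterError("anchor mass must be positive")
    return (m_start - m_end) / denom * 100.0 / days


def is_refractory(rate_pct_per_day: float) -> bool:
    """Whether a loss rate falls in the refractory phase (< 0.4 %/day)."""
    return 0 <= rate_pct_per_day < REFRACTORY_RATE_MAX


def composition_rate(frac_t1: dict, frac_t2: dict) -> dict:
    """Per-component compositional change between consecutive points.

    (fraction_t2 - fraction_t1) * 1000, i.e. micrograms per milligram of
    remaining biomass; negative = loss, positive = relative enrichment.
    Components missing on either side report NA.
    """
    out = {}
    for comp in COMPONENTS:
        a, b = frac_t1.get(comp), frac_t2.get(comp)
        out[comp] = float("nan") if a is None or b is None else (b - a) * 1000.0
    return out


@dataclass(frozen=True)
class DecayFit:
    k: float          # day^-1
    m0: float         # fitted initial mass
    r_squared: float
    n_points: int


def fit_first_order(weeks, masses) -> DecayFit:
    """First-order decay fit: least squares on ln(M) vs t (days).

    Non-positive masses are excluded; at least three usable points are
    required.  Recovery is exact on noise-free exponential input, and k
    is invariant to uniform mass rescaling.
    """
    t = np.asarray(weeks, dtype=float) * 7.0
    m = np.asarray(masses, dtype=float)
    ok = m > 0
    if ok.sum() < 3:
        raise ParameterError(
            f"need >= 3 time points with positive mass, have {int(ok.sum())}"
        )
    t, m = t[ok], m[ok]
    if np.allclose(m, m[0]):
        return DecayFit(k=0.0, m0=float(m[0]), r_squared=1.0, n_points=len(m))
    res = stats.linregress(t, np.log(m))
    return DecayFit(
        k=-float(res.slope),
        m0=float(np.exp(res.intercept)),
        r_squared=float(res.rvalue**2),
        n_points=len(m),
    )


def decay_summary(biomass: pd.DataFrame) -> pd.DataFrame:
    """Per-cage total-mass decay fits plus pooled interval loss rates.

    ``biomass`` is the standard long table (cage, week, total_mg,
    component fractions).  Returns one row per cage with k, m0 and r^2.
    """
    rows = []
    for cage, grp in biomass.groupby("cage"):
        grp = grp.sort_values("week")
        fit = fit_first_order(grp["week"], grp["total_mg"])
        rows.append({"cage": cage, "k_per_day": fit.k, "m0_mg": fit.m0,
                     "r_squared": fit.r_squared})
    return pd.DataFrame(rows)


def interval_rates(biomass: pd.DataFrame) -> pd.DataFrame:
    """Week-to-week loss rates per cage (percent of interval-start mass/day)."""
    rows = []
    for cage, grp in biomass.groupby("cage"):
        grp = grp.sort_values("week")
        wk = grp["week"].to_numpy(dtype=float)
        mg = grp["total_mg"].to_numpy(dtype=float)
        for i in range(1, len(wk)):
            days = (wk[i] - wk[i - 1]) * 7.0
            rate = interval_loss_rate(mg[i - 1], mg[i], days)
            rows.append({
                "cage": cage, "week_start": wk[i - 1], "week_end": wk[i],
                "rate_pct_per_day": rate, "refractory": is_refractory(rate),
            })
    return pd.DataFrame(rows)
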