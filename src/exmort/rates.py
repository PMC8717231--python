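"""Month-length-adjusted crude death rates.

The monthly crude death rate (CDR) is annualized deaths per 100,000:

    CDR(y, m, a) = D*(y, m, a) / (P(y, a) / 12) * 100000

where ``D*`` rescales the raw monthly count to the average month length of
its calendar year, ``D* = D * (days_in_year / 12) / days_in_month`` (leap
aware), so that differences in calendar-month duration do not distort the
monthly rate, and monthly exposure is one-twelfth of annual person-years.
"""

from __future__ import annotations

import calendar

import numpy as np
import pandas as pd

RATE_SCALE = 100_000.0


def days_in_month(year: int, month: int) -> int:
    return calendar.monthrange(int(year), int(month))[1]


def days_in_year(year: int) -> int:
    return 366 if calendar.isleap(int(year)) else 365


def adjust_deaths(deaths, year, month):
    """Rescale monthly death counts to the average month length (D*)."""
    year = np.asarray(year, dtype=int)
    month = np.asarray(month, dtype=int)
    diy = np.where([calendar.isleap(y) for y in np.atleast_1d(year)], 366, 365)
    dim = np.array(
        [days_in_month(y, m) for y, m in zip(np.atleast_1d(year), np.atleast_1d(month))]
    )
    return np.asarray(deaths, dtype=float) * (diy / 12.0) / dim


def compute_cdr(panel: pd.DataFrame) -> pd.DataFrame:
    """Compute the annualized monthly CDR series from a validated panel.

    Returns the panel with two added columns: ``adjusted_deaths`` (D*) and
    ``cdr`` (per 100,000 per year).
    """
    if (panel["exposure"] <= 0).any():
        raise ValueError("exposure must be positive")
    out = panel.copy()
    out["adjusted_deaths"] = adjust_deaths(
        out["deaths"].to_numpy(), out["year"].to_numpy(), out["month"].to_numpy()
    )
    out["cdr"] = out["adjusted_deaths"] / (out["exposure"] / 12.0) * RATE_SCALE
    return out


def cdr_matrix(rates: pd.DataFrame, unit_id: str, years) -> np.ndarray:
    """Extract a (n_years, 12) CDR matrix for one unit, ordered by year/month.

    Raises if any (year, month) cell is absent.
    """
    years = list(years)
    sub = rates[(rates["unit_id"] == unit_id) & (rates["year"].isin(years))]
    pivot = sub.pivot(index="year", columns="month", values="cdr")
    try:
        pivot = pivot.loc[years, range(1, 13)]
    except KeyError as exc:
        raise ValueError(
            f"unit {unit_id!r}: incomplete CDR coverage for years {years}"
        ) from exc
    if pivot.isna().to_numpy().any():
        raise ValueError(f"unit {unit_id!r}: missing months in years {years}")
    return pivot.to_numpy(dtype=float)
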