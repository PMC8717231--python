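"""Reading, validation and writing of mortality panels and covariate tables.

All tabular interchange uses long-format delimited text (UTF-8, delimiter
auto-detected among comma/semicolon/tab).  The canonical monthly panel has
columns ``unit_id, year, month, deaths, exposure`` with exactly one row per
(unit, year, month); exposure is annual person-years, constant within a
unit-year.  Weekly input follows the STMF layout ``unit_id, iso_year,
iso_week, deaths`` and is disaggregated to calendar months by allocating each
ISO week's deaths proportionally to the number of its seven days falling in
each month (uniform-daily-deaths assumption); the resulting monthly counts
are fractional and are deliberately not rounded.
"""

from __future__ import annotations

import csv
import datetime as _dt
import logging
import warnings
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

PANEL_COLUMNS = ["unit_id", "year", "month", "deaths", "exposure"]
WEEKLY_COLUMNS = ["unit_id", "iso_year", "iso_week", "deaths"]
COVARIATE_COLUMNS = ["unit_id", "cases_per_100k", "deaths_per_100k"]


class SchemaError(ValueError):
    """A required column is missing or unmappable."""


class IntegrityError(ValueError):
    """Duplicate keys or otherwise inconsistent records."""


class CoverageError(ValueError):
    """The input does not cover the requested period completely."""


def _sniff_delimiter(path: Path) -> str:
    with open(path, "r", encoding="utf-8", newline="") as fh:
        sample = fh.read(8192)
    try:
        return csv.Sniffer().sniff(sample, delimiters=",;\t").delimiter
    except csv.Error:
        return ","


def _read_delimited(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    return pd.read_csv(path, sep=_sniff_delimiter(path))


def validate_panel(panel: pd.DataFrame) -> pd.DataFrame:
    """Validate a monthly panel in place and return it sorted.

    Enforces the panel invariants: one record per (unit, year, month),
    months in 1..12, non-negative deaths, positive exposure constant within
    each unit-year, and contiguous years per unit.
    """
    missing = [c for c in PANEL_COLUMNS if c not in panel.columns]
    if missing:
        raise SchemaError(f"panel is missing columns: {missing}")
    panel = panel[PANEL_COLUMNS].copy()
    panel["year"] = panel["year"].astype(int)
    panel["month"] = panel["month"].astype(int)

    dup = panel.duplicated(subset=["unit_id", "year", "month"])
    if dup.any():
        keys = panel.loc[dup, ["unit_id", "year", "month"]].head(5).values.tolist()
        raise IntegrityError(f"duplicate (unit, year, month) keys, e.g. {keys}")
    if not panel["month"].between(1, 12).all():
        raise ValueError("month must be in 1..12")
    if (panel["deaths"] < 0).any():
        raise ValueError("deaths must be non-negative")
    if (panel["exposure"] <= 0).any():
        raise ValueError("exposure must be positive")

    nuniq = panel.groupby(["unit_id", "year"])["exposure"].nunique()
    if (nuniq > 1).any():
        bad = nuniq[nuniq > 1].index.tolist()[:5]
        raise IntegrityError(f"exposure varies within unit-year, e.g. {bad}")

    for unit, grp in panel.groupby("unit_id"):
        years = np.sort(grp["year"].unique())
        if len(years) > 1 and not np.array_equal(years, np.arange(years[0], years[-1] + 1)):
            raise IntegrityError(f"unit {unit!r}: years are not contiguous ({years.tolist()})")

    return panel.sort_values(["unit_id", "year", "month"], ignore_index=True)


def read_monthly_panel(
    path: str | Path, schema: Mapping[str, str] | None = None
) -> pd.DataFrame:
    """Read and validate a long-format monthly mortality panel.

    Parameters
    ----------
    path
        Delimited text file with one row per (unit, year, month).
    schema
        Optional mapping from canonical column names (``unit_id``, ``year``,
        ``month``, ``deaths``, ``exposure``) to the file's column names.
    """
    df = _read_delimited(path)
    if schema:
        rename = {src: canon for canon, src in schema.items()}
        missing = [src for src in schema.values() if src not in df.columns]
        if missing:
            raise SchemaError(f"file lacks mapped columns: {missing}")
        df = df.rename(columns=rename)
    return validate_panel(df)


def write_monthly_panel(panel: pd.DataFrame, path: str | Path) -> None:
    panel[PANEL_COLUMNS].to_csv(path, index=False)


def drop_incomplete_units(
    panel: pd.DataFrame, years: Iterable[int]
) -> pd.DataFrame:
    """Drop units that do not cover all 12 months of every year in ``years``.

    Incomplete units are logged (one warning per unit) rather than imputed.
    """
    years = sorted(set(years))
    required = 12 * len(years)
    keep = []
    for unit, grp in panel.groupby("unit_id"):
        got = grp[grp["year"].isin(years)][["year", "month"]].drop_duplicates()
        if len(got) == required:
            keep.append(unit)
        else:
            logger.warning(
                "dropping unit %r: %d/%d month records in %s–%s",
                unit, len(got), required, years[0], years[-1],
            )
    return panel[panel["unit_id"].isin(keep)].reset_index(drop=True)


# ---------------------------------------------------------------------------
# Weekly (STMF-style) input
# ---------------------------------------------------------------------------

def read_weekly_series(path: str | Path) -> pd.DataFrame:
    df = _read_delimited(path)
    missing = [c for c in WEEKLY_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"weekly series is missing columns: {missing}")
    df = df[WEEKLY_COLUMNS].copy()
    if (df["deaths"] < 0).any():
        raise ValueError("weekly deaths must be non-negative")
    if df.duplicated(subset=["unit_id", "iso_year", "iso_week"]).any():
        raise IntegrityError("duplicate (unit, iso_year, iso_week) keys")
    return df


def weekly_to_monthly(
    weekly: pd.DataFrame, target_years: Iterable[int]
) -> pd.DataFrame:
    """Disaggregate ISO-week death counts to calendar months.

    Each week's deaths are spread uniformly over its seven days and summed
    by calendar month, so a week straddling a month boundary is split
    day-proportionally.  Totals are conserved exactly over any fully covered
    span.  Raises :class:`CoverageError` if any day of a requested month is
    not covered by an input week.

    Returns a frame with columns ``unit_id, year, month, deaths`` (fractional
    counts) restricted to ``target_years``.
    """
    target_years = sorted(set(int(y) for y in target_years))
    missing = [c for c in WEEKLY_COLUMNS if c not in weekly.columns]
    if missing:
        raise SchemaError(f"weekly series is missing columns: {missing}")

    frames = []
    for unit, grp in weekly.groupby("unit_id"):
        week_start = [
            _dt.date.fromisocalendar(int(y), int(w), 1)
            for y, w in zip(grp["iso_year"], grp["iso_week"])
        ]
        starts = pd.to_datetime(week_start)
        per_day = np.repeat(grp["deaths"].to_numpy(dtype=float) / 7.0, 7)
        days = (
            starts.values[:, None] + np.arange(7) * np.timedelta64(1, "D")
        ).ravel()
        daily = pd.DataFrame({"date": days, "deaths": per_day})
        if daily["date"].duplicated().any():
            raise IntegrityError(f"unit {unit!r}: overlapping weeks")
        daily["year"] = daily["date"].dt.year
        daily["month"] = daily["date"].dt.month
        daily = daily[daily["year"].isin(target_years)]

        # every day of every target month must be covered
        for (y, m), sub in daily.groupby(["year", "month"]):
            ndays = pd.Period(f"{y}-{m:02d}").days_in_month
            if len(sub) != ndays:
                raise CoverageError(
                    f"unit {unit!r}: month {y}-{m:02d} covered on "
                    f"{len(sub)}/{ndays} days"
                )
        expected_months = {(y, m) for y in target_years for m in range(1, 13)}
        got_months = set(map(tuple, daily[["year", "month"]].drop_duplicates().values))
        absent = sorted(expected_months - got_months)
        if absent:
            raise CoverageError(f"unit {unit!r}: months not covered at all: {absent[:5]}")

        out = (
            daily.groupby(["year", "month"], as_index=False)["deaths"].sum()
        )
        out.insert(0, "unit_id", unit)
        frames.append(out)
    return pd.concat(frames, ignore_index=True).sort_values(
        ["unit_id", "year", "month"], ignore_index=True
    )


# ---------------------------------------------------------------------------
# Covariates (reported COVID-19 burden)
# ---------------------------------------------------------------------------

def read_covariates(path: str | Path) -> pd.DataFrame:
    """Read per-unit cumulative reported cases/deaths per 100,000."""
    df = _read_delimited(path)
    missing = [c for c in COVARIATE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"covariate table is missing columns: {missing}")
    df = df[COVARIATE_COLUMNS].copy()
    if df.duplicated(subset="unit_id").any():
        raise IntegrityError("duplicate unit_id in covariate table")
    if (df[["cases_per_100k", "deaths_per_100k"]] < 0).to_numpy().any():
        raise ValueError("covariate rates must be non-negative")
    return df.reset_index(drop=True)


def write_covariates(cov: pd.DataFrame, path: str | Path) -> None:
    cov[COVARIATE_COLUMNS].to_csv(path, index=False)


def join_covariates(units: Iterable[str], cov: pd.DataFrame) -> pd.DataFrame:
    """Inner-join a covariate table against a set of panel units.

    Emits a warning listing units present on only one side; the result is
    restricted to the intersection.
    """
    units = set(units)
    cov_units = set(cov["unit_id"])
    unmatched = sorted((units - cov_units) | (cov_units - units))
    if unmatched:
        warnings.warn(
            f"units without a match in the join: {unmatched}", stacklevel=2
        )
        logger.warning("units without a match in the join: %s", unmatched)
    return cov[cov["unit_id"].isin(units)].reset_index(drop=True)
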