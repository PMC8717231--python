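"""Absolute and relative excess mortality with bootstrap confidence limits.

Excess mortality for a period is the difference between the observed and the
expected (baseline) death rate, both expressed per 100,000 population per
year as unweighted means of the annualized monthly CDRs over the period's
months (months are already normalized to equal length by the D* adjustment).
Period definitions follow the study design: the annual period is Jan-Dec and
the second "quarter" spans four months, March-June (first pandemic wave),
with Q3 = Jul-Sep and Q4 = Oct-Dec.

Confidence limits come from a residual bootstrap of the baseline fit: the
reference-period residuals are resampled with replacement (pooled within the
unit), pseudo reference CDRs are rebuilt around the fitted values, the
baseline is refitted and the expected rate recomputed.  For the excess the
interval is prediction-type: each replicate additionally perturbs the
observed period rate with resampled residuals (one per period month), so the
bounds account for both baseline-estimation uncertainty and the count noise
of the target-year months.  Without the latter term the interval would
systematically undercover the true excess whenever the target-year rates
carry sampling noise comparable to the baseline's.  On a noiseless panel all
residuals vanish and the interval collapses to the point estimate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from .baselines import (
    LeeCarterBaseline,
    SeasonalAverageBaseline,
    SeasonalTrendBaseline,
    make_baseline,
)
from .rates import compute_cdr

PERIOD_MONTHS: dict[str, tuple[int, ...]] = {
    "year": tuple(range(1, 13)),
    "JanFeb": (1, 2),
    "Q2": (3, 4, 5, 6),
    "Q3": (7, 8, 9),
    "Q4": (10, 11, 12),
}


@dataclass
class ExcessEstimate:
    """Observed, expected and excess death rates for one unit and period."""

    unit_id: str
    period: str
    method: str
    observed_rate: float
    expected_rate: float
    excess_abs: float
    excess_rel: float
    ci_low: float = field(default=np.nan)
    ci_high: float = field(default=np.nan)

    def as_dict(self) -> dict:
        return asdict(self)


def _period_months(period: str) -> tuple[int, ...]:
    try:
        return PERIOD_MONTHS[period]
    except KeyError:
        raise ValueError(
            f"unknown period {period!r}; expected one of {list(PERIOD_MONTHS)}"
        )


def _observed_monthly(observed: pd.DataFrame, target_year: int) -> np.ndarray:
    """12 observed monthly CDRs of the target year for a single unit."""
    sub = observed[observed["year"] == target_year]
    if "unit_id" in sub.columns and sub["unit_id"].nunique() > 1:
        raise ValueError("expected rates for a single unit")
    series = sub.set_index("month")["cdr"]
    out = series.reindex(range(1, 13)).to_numpy(dtype=float)
    return out


def compute_excess(
    observed: pd.DataFrame,
    model,
    period: str = "year",
    target_year: int = 2020,
) -> ExcessEstimate:
    """Point estimate of absolute and relative excess for one unit/period.

    ``observed`` is a CDR frame (from :func:`exmort.rates.compute_cdr`) for a
    single unit containing the target year; ``model`` is a fitted baseline.
    """
    months = _period_months(period)
    monthly = _observed_monthly(observed, target_year)
    idx = np.asarray(months) - 1
    if np.isnan(monthly[idx]).any():
        missing = [m for m in months if np.isnan(monthly[m - 1])]
        raise ValueError(
            f"observed year {target_year} is missing months {missing} "
            f"for period {period!r}"
        )
    expected_monthly = model.predict(target_year)
    observed_rate = float(monthly[idx].mean())
    expected_rate = float(expected_monthly[idx].mean())
    excess_abs = observed_rate - expected_rate
    excess_rel = 100.0 * excess_abs / expected_rate
    return ExcessEstimate(
        unit_id=getattr(model, "unit_id_", ""),
        period=period,
        method=model.method,
        observed_rate=observed_rate,
        expected_rate=expected_rate,
        excess_abs=excess_abs,
        excess_rel=excess_rel,
    )


# ---------------------------------------------------------------------------
# Residual bootstrap
# ---------------------------------------------------------------------------

def _dof_scale(model) -> float:
    """Inflate fitted residuals to unbiased scale, sqrt(n / (n - p))."""
    n = model.residuals_.size
    p = getattr(model, "n_params_", 0)
    return float(np.sqrt(n / max(n - p, 1)))


def _bootstrap_expected(model, target_year: int, months, B: int, rng) -> np.ndarray:
    """B bootstrap replicates of the expected period rate for one unit."""
    F = model.fitted_
    E = model.residuals_ * _dof_scale(model)
    T, twelve = F.shape
    flat = E.ravel()
    idx = rng.integers(0, flat.size, size=(B, flat.size))
    pseudo = F.ravel()[None, :] + flat[idx]  # (B, T*12)
    midx = np.asarray(months) - 1

    if isinstance(model, SeasonalAverageBaseline):
        alphas = pseudo.reshape(B, T, twelve).mean(axis=1)  # (B, 12)
        return alphas[:, midx].mean(axis=1)

    if isinstance(model, SeasonalTrendBaseline):
        yv = np.asarray(model.ref_years_, dtype=float)
        yc = yv - yv.mean()
        P = pseudo.reshape(B, T, twelve)
        month_means = P.mean(axis=1)  # (B, 12)
        dev = P - month_means[:, None, :]
        beta = (yc[None, :, None] * dev).sum(axis=(1, 2)) / (
            twelve * (yc**2).sum()
        )
        # expected monthly at target year: month_mean + beta * (y* - ybar)
        shift = float(target_year) - yv.mean()
        exp_m = month_means + beta[:, None] * shift
        return exp_m[:, midx].mean(axis=1)

    if isinstance(model, LeeCarterBaseline):
        out = np.empty(B)
        P = pseudo.reshape(B, T, twelve)
        tiny = 1e-8 * max(1.0, float(np.abs(F).max()))
        for b in range(B):
            M = np.maximum(P[b], tiny)  # log requires positivity
            rep = LeeCarterBaseline(ref_years=tuple(model.ref_years_))
            frame = pd.DataFrame(
                {
                    "year": np.repeat(model.ref_years_, twelve),
                    "month": np.tile(np.arange(1, 13), T),
                    "cdr": M.ravel(),
                }
            )
            rep.fit(frame)
            out[b] = rep.predict(target_year)[midx].mean()
        return out

    raise TypeError(f"unsupported model type {type(model).__name__}")


def bootstrap_ci(
    panel: pd.DataFrame,
    method: str,
    target_year: int,
    period: str,
    B: int = 1000,
    seed: int = 0,
    ref_years: Sequence[int] = tuple(range(2015, 2020)),
) -> tuple[float, float]:
    """Percentile 95% CI for the absolute excess of a single-unit panel.

    Residual bootstrap, deterministic given ``seed``.  Raises for ``B < 100``;
    degenerate zero-variance residuals collapse the interval to the point
    estimate with a warning.
    """
    if B < 100:
        raise ValueError(f"B must be at least 100, got {B}")
    if panel["unit_id"].nunique() != 1:
        raise ValueError("bootstrap_ci expects a single-unit panel")
    rates = compute_cdr(panel)
    model = make_baseline(method, ref_years=tuple(ref_years)).fit(rates)
    est = compute_excess(rates, model, period=period, target_year=target_year)
    if np.allclose(model.residuals_, 0.0):
        warnings.warn(
            "zero-variance residuals: bootstrap CI collapses to the point estimate",
            stacklevel=2,
        )
        return est.excess_abs, est.excess_abs

    rng = np.random.default_rng(seed)
    months = _period_months(period)
    lo, hi = _excess_interval(model, est, target_year, months, B, rng)
    return lo, hi


def _excess_interval(model, est, target_year, months, B, rng) -> tuple[float, float]:
    exp_rep = _bootstrap_expected(model, target_year, months, B, rng)
    flat = model.residuals_.ravel() * _dof_scale(model)
    obs_idx = rng.integers(0, flat.size, size=(B, len(months)))
    obs_noise = flat[obs_idx].mean(axis=1)
    excess_rep = (est.observed_rate + obs_noise) - exp_rep
    lo, hi = np.percentile(excess_rep, [2.5, 97.5])
    return float(lo), float(hi)


def estimate_unit(
    panel: pd.DataFrame,
    method: str,
    target_year: int,
    periods: Sequence[str],
    ref_years: Sequence[int],
    B: int | None = 1000,
    seed: int = 0,
) -> list[ExcessEstimate]:
    """Point estimates (and CIs when ``B`` is given) for one unit, all periods.

    Shares one baseline fit and one residual-resampling stream across periods.
    """
    if panel["unit_id"].nunique() != 1:
        raise ValueError("estimate_unit expects a single-unit panel")
    rates = compute_cdr(panel)
    model = make_baseline(method, ref_years=tuple(ref_years)).fit(rates)
    out = []
    degenerate = np.allclose(model.residuals_, 0.0)
    for period in periods:
        est = compute_excess(rates, model, period=period, target_year=target_year)
        if B is not None:
            if degenerate:
                est.ci_low = est.ci_high = est.excess_abs
            else:
                rng = np.random.default_rng(seed)
                est.ci_low, est.ci_high = _excess_interval(
                    model, est, target_year, _period_months(period), B, rng
                )
        out.append(est)
    return out


def estimate_panel(
    panel: pd.DataFrame,
    methods: Sequence[str],
    target_year: int,
    periods: Sequence[str],
    ref_years: Sequence[int],
    B: int | None = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Excess estimates for every unit, method and period, as a tidy frame."""
    rows = []
    for i, (unit, grp) in enumerate(panel.groupby("unit_id")):
        for method in methods:
            ests = estimate_unit(
                grp, method, target_year, periods, ref_years, B=B,
                seed=seed + i,
            )
            rows.extend(e.as_dict() for e in ests)
    return pd.DataFrame(rows)


def rank_units(estimates: pd.DataFrame | Sequence[ExcessEstimate]) -> pd.DataFrame:
    """Rank units by absolute excess, descending; lexicographic tie-break.

    All estimates must share one period and one method.
    """
    if not isinstance(estimates, pd.DataFrame):
        estimates = pd.DataFrame([e.as_dict() for e in estimates])
    if estimates["period"].nunique() > 1 or estimates["method"].nunique() > 1:
        raise ValueError("rank_units requires a single period and method")
    if estimates["unit_id"].duplicated().any():
        raise ValueError("rank_units requires one estimate per unit")
    ranked = estimates.sort_values(
        ["excess_abs", "unit_id"], ascending=[False, True], ignore_index=True
    )
    ranked["rank"] = np.arange(1, len(ranked) + 1)
    return ranked
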