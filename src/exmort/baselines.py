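"""Expected-mortality (baseline) models for a single geographic unit.

Three baselines project the counterfactual, pandemic-free 2020 monthly CDR
from a reference window of pre-pandemic years (default 2015-2019):

* **Method A** — month-specific averages, the fixed-effects model
  ``CDR(t, m) = alpha_m + eps(t, m)``; expected CDR is ``alpha_m`` regardless
  of target year.
* **Method B** — Method A with a common linear secular trend,
  ``CDR(t, m) = alpha_m + beta * t + eps(t, m)`` fitted by OLS on a
  month-dummy + year design; expected CDR is ``alpha_m + beta * y*``.
* **Lee-Carter** — sensitivity baseline on log rates with months as strata:
  ``log CDR(t, m) = a_m + b_m * k_t + eps`` with the first singular component
  of the centered log-rate matrix, identification ``sum(b) = 1``,
  ``sum(k) = 0``, and random-walk-with-drift extrapolation of ``k``.

All three are scikit-learn style estimators: hyper-parameters in
``__init__``, data in ``fit``, fitted attributes with trailing underscores,
and a ``predict(target_year)`` returning the 12 expected monthly CDRs.
``fit`` accepts the output of :func:`exmort.rates.compute_cdr` restricted to
one unit (a frame with ``year``, ``month``, ``cdr`` and optionally
``unit_id`` columns).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from sklearn.base import BaseEstimator


class NotFittedError(RuntimeError):
    """predict() was called before fit()."""


def _check_fitted(est) -> None:
    if not hasattr(est, "alphas_"):
        raise NotFittedError(
            f"{type(est).__name__} must be fitted before calling predict()"
        )


def _extract_matrix(rates: pd.DataFrame, ref_years: Sequence[int]) -> tuple[np.ndarray, str]:
    """Pivot a one-unit rate frame to a (n_years, 12) CDR matrix."""
    if "unit_id" in rates.columns:
        units = rates["unit_id"].unique()
        if len(units) > 1:
            raise ValueError(
                f"baseline estimators fit one unit at a time, got {len(units)}"
            )
        unit_id = str(units[0])
    else:
        unit_id = ""
    years = list(ref_years)
    sub = rates[rates["year"].isin(years)]
    pivot = sub.pivot(index="year", columns="month", values="cdr")
    missing_years = [y for y in years if y not in pivot.index]
    if missing_years:
        raise ValueError(f"reference years missing from data: {missing_years}")
    pivot = pivot.reindex(index=years, columns=range(1, 13))
    if pivot.isna().to_numpy().any():
        raise ValueError("incomplete reference panel: every month of every "
                         "reference year is required")
    return pivot.to_numpy(dtype=float), unit_id


def _resolve_ref_years(ref_years) -> list[int]:
    ref_years = [int(y) for y in ref_years]
    if ref_years != sorted(ref_years):
        raise ValueError("ref_years must be sorted ascending")
    return ref_years


class SeasonalAverageBaseline(BaseEstimator):
    """Method A: expected monthly CDR = average of the same month over the
    reference years.  The trend slope is identically zero.

    Parameters
    ----------
    ref_years : sequence of int
        Reference (pre-pandemic) years, e.g. ``range(2015, 2020)``.
    """

    method = "A"

    def __init__(self, ref_years=tuple(range(2015, 2020))):
        self.ref_years = ref_years

    def fit(self, rates: pd.DataFrame, y=None):
        years = _resolve_ref_years(self.ref_years)
        M, unit_id = _extract_matrix(rates, years)
        self.unit_id_ = unit_id
        self.ref_years_ = years
        self.alphas_ = M.mean(axis=0)
        self.beta_ = 0.0
        self.fitted_ = np.broadcast_to(self.alphas_, M.shape).copy()
        self.residuals_ = M - self.fitted_
        self.n_params_ = 12
        return self

    def predict(self, target_year: int) -> np.ndarray:
        _check_fitted(self)
        return self.alphas_.copy()


class SeasonalTrendBaseline(BaseEstimator):
    """Method B: month fixed effects plus a common linear trend in the year,
    fitted by ordinary least squares (no exposure weighting).

    Predictions are invariant to affine recoding of the year covariate; the
    stored ``alphas_`` are parametrized against the uncentered calendar year,
    so expected CDR for year ``y*`` and month ``m`` is
    ``alphas_[m-1] + beta_ * y*``.
    """

    method = "B"

    def __init__(self, ref_years=tuple(range(2015, 2020))):
        self.ref_years = ref_years

    def fit(self, rates: pd.DataFrame, y=None):
        years = _resolve_ref_years(self.ref_years)
        if len(years) < 2:
            raise np.linalg.LinAlgError(
                "method B needs at least 2 reference years to identify a trend"
            )
        M, unit_id = _extract_matrix(rates, years)
        T = len(years)
        yv = np.asarray(years, dtype=float)
        yc = yv - yv.mean()  # centered internally for conditioning only

        # Balanced design: month dummies are orthogonal to the centered year,
        # so OLS decouples into per-month means plus a pooled slope.
        beta = float(
            (yc[:, None] * (M - M.mean(axis=0))).sum() / (12.0 * (yc**2).sum())
        )
        month_means = M.mean(axis=0)
        self.unit_id_ = unit_id
        self.ref_years_ = years
        self.beta_ = beta
        self.alphas_ = month_means - beta * yv.mean()
        self.fitted_ = self.alphas_[None, :] + beta * yv[:, None]
        self.residuals_ = M - self.fitted_
        self.n_params_ = 13
        return self

    def predict(self, target_year: int) -> np.ndarray:
        _check_fitted(self)
        return self.alphas_ + self.beta_ * float(target_year)


class LeeCarterBaseline(BaseEstimator):
    """Lee-Carter sensitivity baseline with calendar months as strata.

    The centered log-CDR matrix is decomposed by SVD into the leading
    bilinear component ``b_m * k_t`` under the identification constraints
    ``sum(b) = 1`` and ``sum(k) = 0``; the mortality index ``k`` is
    extrapolated to the target year as a random walk with drift
    ``(k_last - k_first) / (N - 1)``.  Expected CDR is
    ``exp(a_m + b_m * k_target)``.
    """

    method = "lee_carter"

    def __init__(self, ref_years=tuple(range(2015, 2020))):
        self.ref_years = ref_years

    def fit(self, rates: pd.DataFrame, y=None):
        years = _resolve_ref_years(self.ref_years)
        if len(years) < 3:
            raise ValueError("Lee-Carter needs at least 3 reference years")
        M, unit_id = _extract_matrix(rates, years)
        if (M <= 0).any():
            raise ValueError(
                "Lee-Carter requires strictly positive reference CDRs "
                "(log of zero or negative rate is undefined)"
            )
        L = np.log(M)
        a = L.mean(axis=0)
        C = L - a
        U, s, Vt = np.linalg.svd(C, full_matrices=False)
        if s[0] <= 1e-12 * max(1.0, np.abs(L).max()):
            # constant panel: no time variation, flat index
            b = np.full(12, 1.0 / 12.0)
            k = np.zeros(len(years))
        else:
            v = Vt[0]
            scale = v.sum()
            if abs(scale) < 1e-12:
                # degenerate orientation; fall back to unit-norm b with
                # positive mean sign
                scale = 1.0 if v.mean() >= 0 else -1.0
            b = v / scale
            k = U[:, 0] * s[0] * scale
            # re-center k so that sum(k) = 0 exactly
            kbar = k.mean()
            a = a + b * kbar
            k = k - kbar
        T = len(years)
        drift = (k[-1] - k[0]) / (T - 1)
        self.unit_id_ = unit_id
        self.ref_years_ = years
        self.a_ = a
        self.b_ = b
        self.k_ = k
        self.drift_ = float(drift)
        self.alphas_ = np.exp(a)  # level profile, for reporting only
        self.beta_ = 0.0
        self.fitted_ = np.exp(a[None, :] + np.outer(k, b))
        self.residuals_ = M - self.fitted_
        # a_m (12) + b_m (11 free under sum(b)=1) + k_t (T-1 free under sum(k)=0)
        self.n_params_ = 23 + T - 1
        return self

    def k_at(self, target_year: int) -> float:
        _check_fitted(self)
        return float(self.k_[-1] + self.drift_ * (int(target_year) - self.ref_years_[-1]))

    def predict(self, target_year: int) -> np.ndarray:
        _check_fitted(self)
        return np.exp(self.a_ + self.b_ * self.k_at(target_year))


_METHODS = {
    "A": SeasonalAverageBaseline,
    "B": SeasonalTrendBaseline,
    "lee_carter": LeeCarterBaseline,
}


def make_baseline(method: str, ref_years=tuple(range(2015, 2020))):
    try:
        cls = _METHODS[method]
    except KeyError:
        raise ValueError(f"unknown method {method!r}; expected one of {list(_METHODS)}")
    return cls(ref_years=ref_years)


# ---------------------------------------------------------------------------
# Thin functional wrappers (multi-unit)
# ---------------------------------------------------------------------------

def _fit_per_unit(rates: pd.DataFrame, ref_years, method: str) -> dict:
    out = {}
    for unit, grp in rates.groupby("unit_id"):
        out[unit] = make_baseline(method, ref_years).fit(grp)
    return out


def fit_method_a(rates: pd.DataFrame, ref_years) -> dict:
    """Fit the Method A baseline per unit; returns ``{unit_id: estimator}``."""
    return _fit_per_unit(rates, ref_years, "A")


def fit_method_b(rates: pd.DataFrame, ref_years) -> dict:
    """Fit the Method B baseline per unit; returns ``{unit_id: estimator}``."""
    return _fit_per_unit(rates, ref_years, "B")


def fit_lee_carter(rates: pd.DataFrame, ref_years) -> dict:
    """Fit the Lee-Carter baseline per unit; returns ``{unit_id: estimator}``."""
    return _fit_per_unit(rates, ref_years, "lee_carter")


def predict_expected(model, target_year: int) -> np.ndarray:
    """Expected monthly CDRs (12 values) for ``target_year`` from a fitted model."""
    return model.predict(target_year)


# ---------------------------------------------------------------------------
# JSON serialization of fitted models
# ---------------------------------------------------------------------------

def model_to_dict(model) -> dict:
    _check_fitted(model)
    d = {
        "method": model.method,
        "unit_id": model.unit_id_,
        "ref_years": list(model.ref_years_),
        "alphas": np.asarray(model.alphas_).tolist(),
        "beta": float(model.beta_),
        "residuals": np.asarray(model.residuals_).tolist(),
    }
    if model.method == "lee_carter":
        d["lc_params"] = {
            "a": model.a_.tolist(),
            "b": model.b_.tolist(),
            "k": model.k_.tolist(),
            "drift": model.drift_,
        }
    return d


def model_from_dict(d: dict):
    model = make_baseline(d["method"], ref_years=tuple(d["ref_years"]))
    model.unit_id_ = d.get("unit_id", "")
    model.ref_years_ = list(d["ref_years"])
    model.alphas_ = np.asarray(d["alphas"], dtype=float)
    model.beta_ = float(d["beta"])
    model.residuals_ = np.asarray(d["residuals"], dtype=float)
    if d["method"] == "lee_carter":
        lc = d["lc_params"]
        model.a_ = np.asarray(lc["a"], dtype=float)
        model.b_ = np.asarray(lc["b"], dtype=float)
        model.k_ = np.asarray(lc["k"], dtype=float)
        model.drift_ = float(lc["drift"])
        model.fitted_ = np.exp(model.a_[None, :] + np.outer(model.k_, model.b_))
    elif d["method"] == "A":
        model.fitted_ = np.broadcast_to(
            model.alphas_, model.residuals_.shape
        ).copy()
    else:
        yv = np.asarray(model.ref_years_, dtype=float)
        model.fitted_ = model.alphas_[None, :] + model.beta_ * yv[:, None]
    return model


def save_models(models: dict, path: str | Path) -> None:
    payload = {unit: model_to_dict(m) for unit, m in models.items()}
    Path(path).write_text(json.dumps(payload, indent=1))


def load_models(path: str | Path) -> dict:
    payload = json.loads(Path(path).read_text())
    return {unit: model_from_dict(d) for unit, d in payload.items()}
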