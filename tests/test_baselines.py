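import json

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.base import clone

from exmort import (
    LeeCarterBaseline,
    SeasonalAverageBaseline,
    SeasonalTrendBaseline,
    fit_method_a,
    fit_method_b,
    load_models,
    make_baseline,
    predict_expected,
    save_models,
)
from exmort.baselines import NotFittedError

from conftest import REF_YEARS, rates_frame

RNG = np.random.default_rng


def brute_force_ols(rates, ref_years, target_year):
    """Independent oracle: normal-equations solve on the dummy-encoded design.

    Returns (beta, expected monthly CDRs at target_year)."""
    sub = rates[rates["year"].isin(ref_years)]
    y = sub["cdr"].to_numpy()
    months = sub["month"].to_numpy()
    years = sub["year"].to_numpy(dtype=float)
    X = np.zeros((len(sub), 13))
    for j in range(12):
        X[:, j] = months == j + 1
    X[:, 12] = years
    coef = np.linalg.solve(X.T @ X, X.T @ y)
    return coef[12], coef[:12] + coef[12] * target_year


class TestMethodA:
    def test_constant_panel_recovers_constant(self):
        m = SeasonalAverageBaseline(ref_years=REF_YEARS).fit(
            rates_frame(lambda t, mo: 123.0)
        )
        assert m.alphas_ == pytest.approx([123.0] * 12)
        assert m.beta_ == 0.0

    def test_alpha_is_month_mean(self):
        vals = {2015: 90, 2016: 100, 2017: 110, 2018: 95, 2019: 105}
        m = SeasonalAverageBaseline(ref_years=REF_YEARS).fit(
            rates_frame(lambda t, mo: vals[t] if mo == 1 else 50.0)
        )
        assert m.alphas_[0] == pytest.approx(100.0)
        assert m.alphas_[1:] == pytest.approx([50.0] * 11)

    def test_prediction_independent_of_target_year(self, tiny_rates):
        rates, _, _ = tiny_rates
        m = SeasonalAverageBaseline(ref_years=REF_YEARS).fit(
            rates[rates.unit_id == "unit0"]
        )
        assert np.array_equal(m.predict(2020), m.predict(2050))

    def test_residuals_mean_zero_per_month(self, tiny_rates):
        rates, _, _ = tiny_rates
        m = SeasonalAverageBaseline(ref_years=REF_YEARS).fit(
            rates[rates.unit_id == "unit1"]
        )
        assert m.residuals_.mean(axis=0) == pytest.approx([0.0] * 12, abs=1e-9)


class TestMethodB:
    def test_noiseless_identifiability(self):
        alpha = 1000 + 30 * np.sin(np.arange(12))
        beta = -1.5
        m = SeasonalTrendBaseline(ref_years=REF_YEARS).fit(
            rates_frame(lambda t, mo: alpha[mo - 1] + beta * t)
        )
        assert m.beta_ == pytest.approx(beta, rel=1e-12)
        assert m.alphas_ == pytest.approx(alpha, rel=1e-10)
        # one year past the reference end: each month lower by 1.5 than the
        # end-of-reference fitted value
        assert m.predict(2020) == pytest.approx(m.fitted_[-1] - 1.5, rel=1e-12)

    def test_trendless_data_reduces_to_method_a(self):
        profile = 1200 + 50 * np.cos(np.arange(12))
        rates = rates_frame(lambda t, mo: profile[mo - 1])
        a = SeasonalAverageBaseline(ref_years=REF_YEARS).fit(rates)
        b = SeasonalTrendBaseline(ref_years=REF_YEARS).fit(rates)
        assert b.beta_ == pytest.approx(0.0, abs=1e-9)
        assert b.predict(2020) == pytest.approx(a.predict(2020), rel=1e-9)

    def test_matches_statsmodels_ols(self):
        import statsmodels.formula.api as smf

        rng = RNG(3)
        rates = rates_frame(
            lambda t, mo: 1000 + 20 * mo - 12.0 * t + rng.normal(0, 2)
        )
        m = SeasonalTrendBaseline(ref_years=REF_YEARS).fit(rates)
        fit = smf.ols("cdr ~ C(month) + year", data=rates).fit()
        assert m.beta_ == pytest.approx(fit.params["year"], rel=1e-9)
        pred = fit.predict(
            pd.DataFrame({"month": range(1, 13), "year": 2020})
        ).to_numpy()
        assert m.predict(2020) == pytest.approx(pred, rel=1e-9)

    @settings(max_examples=20, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_matches_normal_equations_oracle(self, seed):
        rng = RNG(seed)
        rates = rates_frame(
            lambda t, mo: 900
            + 15 * np.cos(mo)
            - 8.0 * (t - 2015)
            + rng.normal(0, 2.0)
        )
        m = SeasonalTrendBaseline(ref_years=REF_YEARS).fit(rates)
        beta_star, pred_star = brute_force_ols(rates, REF_YEARS, 2020)
        assert m.beta_ == pytest.approx(beta_star, rel=1e-9, abs=1e-9)
        assert m.predict(2020) == pytest.approx(pred_star, rel=1e-9)

    @settings(max_examples=10, deadline=None)
    @given(shift=st.integers(-3000, 3000))
    def test_prediction_invariant_to_affine_year_recoding(self, shift):
        rng = RNG(11)
        noise = rng.normal(0, 3, size=(5, 12))
        base = rates_frame(
            lambda t, mo: 1100 - 9.0 * t + noise[t - 2015, mo - 1]
        )
        shifted = base.copy()
        shifted["year"] = shifted["year"] + shift
        m0 = SeasonalTrendBaseline(ref_years=REF_YEARS).fit(base)
        m1 = SeasonalTrendBaseline(
            ref_years=[y + shift for y in REF_YEARS]
        ).fit(shifted)
        assert m1.predict(2020 + shift) == pytest.approx(
            m0.predict(2020), rel=1e-9
        )

    def test_single_reference_year_is_rank_error(self):
        rates = rates_frame(lambda t, mo: 100.0, years=[2019])
        with pytest.raises(np.linalg.LinAlgError):
            SeasonalTrendBaseline(ref_years=[2019]).fit(rates)

    def test_declining_trend_makes_method_a_exceed_method_b(self):
        """With declining mortality the plain seasonal average overstates the
        2020 baseline, hence understates excess."""
        rng = RNG(5)
        noise = rng.normal(0, 1, size=(5, 12))
        rates = rates_frame(
            lambda t, mo: 1300 - 14.0 * (t - 2015) + noise[t - 2015, mo - 1]
        )
        a = SeasonalAverageBaseline(ref_years=REF_YEARS).fit(rates)
        b = SeasonalTrendBaseline(ref_years=REF_YEARS).fit(rates)
        assert a.predict(2020).mean() > b.predict(2020).mean()


class TestLeeCarter:
    def test_common_log_linear_decline_is_rank_one(self):
        a = np.log(1200) + 0.05 * np.sin(np.arange(12))
        c = -0.012
        m = LeeCarterBaseline(ref_years=REF_YEARS).fit(
            rates_frame(lambda t, mo: np.exp(a[mo - 1] + c * (t - 2017)))
        )
        assert m.b_ == pytest.approx([1 / 12] * 12, rel=1e-8)
        # k linear in t
        dk = np.diff(m.k_)
        assert dk == pytest.approx([dk[0]] * 4, rel=1e-8)
        # forecast equals the exact log-linear extrapolation
        assert m.predict(2020) == pytest.approx(
            np.exp(a + c * 3), rel=1e-8
        )

    def test_constant_panel_forecasts_constant(self):
        m = LeeCarterBaseline(ref_years=REF_YEARS).fit(
            rates_frame(lambda t, mo: 1000.0)
        )
        assert m.k_ == pytest.approx([0.0] * 5, abs=1e-9)
        assert m.predict(2020) == pytest.approx([1000.0] * 12, rel=1e-10)

    def test_identification_constraints(self, tiny_rates):
        rates, _, _ = tiny_rates
        m = LeeCarterBaseline(ref_years=REF_YEARS).fit(
            rates[rates.unit_id == "unit2"]
        )
        assert m.b_.sum() == pytest.approx(1.0, rel=1e-12)
        assert m.k_.sum() == pytest.approx(0.0, abs=1e-9)

    def test_parameter_recovery_under_small_noise(self):
        rng = RNG(17)
        a = np.log(1100) + 0.08 * np.cos(2 * np.pi * np.arange(12) / 12)
        b = np.full(12, 1 / 12) + 0.01 * np.sin(np.arange(12))
        b /= b.sum()
        k = np.array([2.0, 1.0, 0.2, -1.0, -2.2])
        k -= k.mean()
        noise = rng.normal(0, 0.002, size=(5, 12))
        m = LeeCarterBaseline(ref_years=REF_YEARS).fit(
            rates_frame(
                lambda t, mo: np.exp(
                    a[mo - 1] + b[mo - 1] * k[t - 2015] + noise[t - 2015, mo - 1]
                )
            )
        )
        assert m.a_ == pytest.approx(a, abs=0.01)
        assert m.b_ == pytest.approx(b, abs=0.01)
        assert m.k_ == pytest.approx(k, abs=0.05)

    def test_nonpositive_rate_is_domain_error(self):
        rates = rates_frame(lambda t, mo: 0.0 if (t, mo) == (2016, 3) else 900.0)
        with pytest.raises(ValueError, match="positive"):
            LeeCarterBaseline(ref_years=REF_YEARS).fit(rates)

    def test_too_few_years_rejected(self):
        rates = rates_frame(lambda t, mo: 900.0, years=[2018, 2019])
        with pytest.raises(ValueError):
            LeeCarterBaseline(ref_years=[2018, 2019]).fit(rates)


class TestEstimatorContract:
    def test_predict_before_fit_raises(self):
        with pytest.raises(NotFittedError):
            SeasonalTrendBaseline().predict(2020)

    def test_sklearn_params_and_clone(self):
        m = SeasonalTrendBaseline(ref_years=(2016, 2017, 2018, 2019))
        assert m.get_params()["ref_years"] == (2016, 2017, 2018, 2019)
        c = clone(m)
        assert c.get_params() == m.get_params()
        m.set_params(ref_years=REF_YEARS)
        assert list(m.get_params()["ref_years"]) == REF_YEARS

    def test_incomplete_reference_panel_rejected(self):
        rates = rates_frame(lambda t, mo: 100.0)
        rates = rates[~((rates.year == 2017) & (rates.month == 6))]
        for method in ("A", "B", "lee_carter"):
            with pytest.raises(ValueError):
                make_baseline(method, REF_YEARS).fit(rates)

    def test_multi_unit_frame_rejected(self, tiny_rates):
        rates, _, _ = tiny_rates
        with pytest.raises(ValueError, match="one unit"):
            SeasonalAverageBaseline(ref_years=REF_YEARS).fit(rates)

    def test_functional_wrappers_fit_every_unit(self, tiny_rates):
        rates, _, _ = tiny_rates
        for fn, method in [
            (fit_method_a, "A"),
            (fit_method_b, "B"),
        ]:
            models = fn(rates, REF_YEARS)
            assert set(models) == {"unit0", "unit1", "unit2"}
            assert all(m.method == method for m in models.values())
        m = models["unit0"]
        assert np.array_equal(predict_expected(m, 2020), m.predict(2020))


class TestSerialization:
    @pytest.mark.parametrize("method", ["A", "B", "lee_carter"])
    def test_json_round_trip_preserves_predictions(self, tmp_path, tiny_rates, method):
        rates, _, _ = tiny_rates
        m = make_baseline(method, REF_YEARS).fit(rates[rates.unit_id == "unit0"])
        save_models({"unit0": m}, tmp_path / "models.json")
        back = load_models(tmp_path / "models.json")["unit0"]
        assert back.method == method
        assert back.predict(2020) == pytest.approx(m.predict(2020), rel=1e-12)
        assert back.residuals_ == pytest.approx(m.residuals_, rel=1e-12)
        # layout is documented plain JSON
        payload = json.loads((tmp_path / "models.json").read_text())
        assert set(payload["unit0"]) >= {"method", "alphas", "beta", "ref_years"}
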