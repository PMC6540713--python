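"""Correlations, curve fits, stepwise selection, class summaries."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from snowcept.errors import InputError
from snowcept.stand_stats import (
    efficiency_by_class,
    fit_exp_decay,
    fit_linear,
    fit_power,
    pearson,
    per_event_density_regression,
    significance_stars,
    stepwise_regression,
)


class TestPearson:
    def test_perfect_positive_and_negative(self):
        x = [1.0, 2.0, 3.0, 4.0]
        assert pearson(x, x).r == pytest.approx(1.0)
        assert pearson(x, [-v for v in x]).r == pytest.approx(-1.0)

    def test_constant_vector_rejected(self):
        with pytest.raises(InputError):
            pearson([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_star_coding(self):
        assert significance_stars(0.001) == "**"
        assert significance_stars(0.03) == "*"
        assert significance_stars(0.2) == "n.s."

    def test_fixture_canopy_density_pair(self, trough_df):
        # the canopy-density column carries the strongest signals in the
        # campaign averages: throughfall falls and interception rises with
        # denser canopies
        r_tf = pearson(trough_df.avg_throughfall_mm, trough_df.canopy_density_pct)
        r_i = pearson(trough_df.avg_interception_mm, trough_df.canopy_density_pct)
        assert r_tf.r == pytest.approx(-0.44, abs=0.02)
        assert r_tf.stars == "**"
        assert r_i.r == pytest.approx(0.51, abs=0.02)
        assert r_i.stars == "**"


class TestFitLinear:
    def test_exact_line(self):
        x = np.array([0.0, 1.0, 2.0, 3.0])
        res = fit_linear(x, 2 * x + 1)
        assert res.coefficients["intercept"] == pytest.approx(1.0)
        assert res.coefficients["slope"] == pytest.approx(2.0)
        assert res.r_squared == pytest.approx(1.0)

    def test_three_point_normal_equations_oracle(self):
        x = np.array([0.0, 1.0, 2.0])
        y = np.array([1.0, 2.0, 2.5])
        # closed-form OLS for n=3
        slope = np.sum((x - x.mean()) * (y - y.mean())) / np.sum((x - x.mean()) ** 2)
        intercept = y.mean() - slope * x.mean()
        res = fit_linear(x, y)
        assert res.coefficients["slope"] == pytest.approx(slope)
        assert res.coefficients["intercept"] == pytest.approx(intercept)
        resid = y - (intercept + slope * x)
        assert res.s_yx == pytest.approx(np.sqrt(np.sum(resid**2) / 1))

    @settings(max_examples=50, derandomize=True)
    @given(seed=st.integers(min_value=0, max_value=10_000))
    def test_r_squared_is_pearson_r_squared(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=12)
        y = 0.5 * x + rng.normal(size=12)
        res = fit_linear(x, y)
        r = pearson(x, y).r
        assert abs(res.r_squared - r**2) < 1e-12


class TestCurveFits:
    def test_power_exact(self):
        x = np.array([0.5, 1.0, 2.0, 4.0, 8.0])
        res = fit_power(x, 2.0 * x**1.5)
        assert res.coefficients["a"] == pytest.approx(2.0)
        assert res.coefficients["b"] == pytest.approx(1.5)
        assert res.r_squared == pytest.approx(1.0)

    def test_power_identity(self):
        x = np.array([1.0, 2.0, 3.0, 5.0])
        res = fit_power(x, x)
        assert res.coefficients["a"] == pytest.approx(1.0)
        assert res.coefficients["b"] == pytest.approx(1.0)

    def test_power_noisy_recovery(self):
        rng = np.random.default_rng(11)
        x = rng.uniform(1.0, 20.0, size=200)
        y = 2.0 * x**1.5 * np.exp(rng.normal(0, 0.05, size=200))
        res = fit_power(x, y)
        assert res.coefficients["a"] == pytest.approx(2.0, rel=0.05)
        assert res.coefficients["b"] == pytest.approx(1.5, abs=0.05)

    def test_power_rejects_nonpositive(self):
        with pytest.raises(InputError):
            fit_power([1.0, 2.0, 0.0], [1.0, 2.0, 3.0])

    def test_exp_decay_exact(self):
        x = np.array([0.0, 1.0, 2.0, 5.0, 10.0])
        res = fit_exp_decay(x, 3.0 * np.exp(-0.2 * x))
        assert res.coefficients["a"] == pytest.approx(3.0)
        assert res.coefficients["b"] == pytest.approx(0.2)
        assert res.r_squared == pytest.approx(1.0)

    def test_exp_decay_constant_y(self):
        res = fit_exp_decay([1.0, 2.0, 3.0], [4.0, 4.0, 4.0])
        assert res.coefficients["b"] == 0.0
        assert res.coefficients["a"] == pytest.approx(4.0)

    def test_exp_decay_noisy_recovery(self):
        rng = np.random.default_rng(13)
        x = rng.uniform(0.0, 25.0, size=200)
        y = 3.0 * np.exp(-0.2 * x) * np.exp(rng.normal(0, 0.05, size=200))
        res = fit_exp_decay(x, y)
        assert res.coefficients["b"] == pytest.approx(0.2, abs=0.01)

    def test_refined_fit_matches_on_exact_data(self):
        x = np.array([0.5, 1.0, 2.0, 4.0])
        y = 2.0 * x**1.5
        res = fit_power(x, y, refine=True)
        assert res.coefficients["a"] == pytest.approx(2.0, rel=1e-6)
        assert res.coefficients["b"] == pytest.approx(1.5, abs=1e-6)


class TestStepwise:
    def test_single_strong_candidate_equals_simple_fit(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=30)
        y = 2.0 + 1.5 * x + rng.normal(0, 0.2, size=30)
        steps = stepwise_regression(y, pd.DataFrame({"x": x}))
        assert len(steps) == 1
        simple = fit_linear(x, y)
        assert steps[0].coefficients["x"] == pytest.approx(simple.coefficients["slope"])
        assert steps[0].r_squared == pytest.approx(simple.r_squared)

    def test_orthogonal_predictors_exact(self):
        # noiseless orthogonal design: both enter, coefficients exact
        x1 = np.array([1.0, 1.0, -1.0, -1.0, 1.0, -1.0, 1.0, -1.0])
        x2 = np.array([1.0, -1.0, 1.0, -1.0, 1.0, -1.0, -1.0, 1.0])
        y = 0.5 + 2.0 * x1 - 3.0 * x2
        steps = stepwise_regression(y, pd.DataFrame({"x1": x1, "x2": x2}))
        final = steps[-1]
        assert final.coefficients["x1"] == pytest.approx(2.0)
        assert final.coefficients["x2"] == pytest.approx(-3.0)
        assert final.coefficients["intercept"] == pytest.approx(0.5)
        assert final.r_squared == pytest.approx(1.0)

    def test_alpha_one_reduces_to_full_ols(self):
        rng = np.random.default_rng(5)
        X = pd.DataFrame(rng.normal(size=(40, 3)), columns=["a", "b", "c"])
        y = rng.normal(size=40)
        steps = stepwise_regression(y, X, alpha_enter=1.0, alpha_remove=1.0)
        import statsmodels.api as sm

        full = sm.OLS(y, sm.add_constant(X)).fit()
        assert set(steps[-1].coefficients) == {"intercept", "a", "b", "c"}
        assert steps[-1].r_squared == pytest.approx(float(full.rsquared))

    def test_alpha_zero_returns_intercept_only(self):
        rng = np.random.default_rng(6)
        X = pd.DataFrame(rng.normal(size=(30, 2)), columns=["a", "b"])
        y = rng.normal(size=30)
        steps = stepwise_regression(y, X, alpha_enter=0.0, alpha_remove=0.0)
        assert len(steps) == 1
        assert set(steps[0].coefficients) == {"intercept"}
        assert steps[0].coefficients["intercept"] == pytest.approx(float(np.mean(y)))

    def test_null_model_false_entry_rate(self):
        # with pure-noise candidates at alpha_enter = 0.05 the family-wise
        # entry rate over 4 candidates is inflated above 5% but stays modest
        rng = np.random.default_rng(42)
        entered = 0
        reps = 200
        for _ in range(reps):
            X = pd.DataFrame(rng.normal(size=(30, 4)), columns=list("abcd"))
            y = rng.normal(size=30)
            steps = stepwise_regression(y, X, alpha_enter=0.05, alpha_remove=0.10)
            if set(steps[-1].coefficients) != {"intercept"}:
                entered += 1
        assert 0.05 * reps * 0.5 <= entered <= 0.20 * reps

    def test_collinear_candidate_warned_and_excluded(self):
        rng = np.random.default_rng(8)
        x = rng.normal(size=30)
        y = 1.0 + 2.0 * x + rng.normal(0, 0.1, size=30)
        X = pd.DataFrame({"x": x, "x_copy": x})
        with pytest.warns(UserWarning, match="collinear"):
            steps = stepwise_regression(y, X, condition_threshold=1e6)
        assert len(steps[-1].coefficients) == 2  # intercept + one of the twins

    def test_alpha_order_enforced(self):
        with pytest.raises(InputError):
            stepwise_regression(
                np.zeros(10), pd.DataFrame({"a": np.arange(10.0)}),
                alpha_enter=0.2, alpha_remove=0.1,
            )


class TestEfficiencyByClass:
    def test_single_event_per_class(self):
        out = efficiency_by_class([5.0, 15.0, 25.0], [35.1, 28.4, 18.1])
        assert out == {"<10": pytest.approx(35.1), "10–20": pytest.approx(28.4),
                       ">20": pytest.approx(18.1)}

    def test_constructed_class_means_recovered(self):
        swe = [4.0, 8.0, 12.0, 18.0, 22.0, 30.0]
        eff = [34.1, 36.1, 27.4, 29.4, 17.1, 19.1]
        out = efficiency_by_class(swe, eff)
        assert out["<10"] == pytest.approx(35.1)
        assert out["10–20"] == pytest.approx(28.4)
        assert out[">20"] == pytest.approx(18.1)

    def test_empty_class_absent_not_zero(self):
        out = efficiency_by_class([5.0, 7.0], [30.0, 40.0])
        assert set(out) == {"<10"}


class TestPerEventDensityRegression:
    def test_matches_per_group_fit(self):
        rng = np.random.default_rng(9)
        rows = []
        for eid, slope in [("E1", 0.05), ("E2", 0.02)]:
            cc = rng.uniform(30, 70, size=10)
            i = 0.5 + slope * cc + rng.normal(0, 0.1, size=10)
            rows += [
                {"event_id": eid, "canopy_density_pct": c, "interception_mm": v}
                for c, v in zip(cc, i)
            ]
        panel = pd.DataFrame(rows)
        fits = per_event_density_regression(panel)
        for eid in ("E1", "E2"):
            grp = panel[panel.event_id == eid]
            direct = fit_linear(grp.canopy_density_pct, grp.interception_mm)
            assert fits[eid].coefficients["slope"] == pytest.approx(
                direct.coefficients["slope"]
            )

    def test_constant_density_event_rejected(self):
        panel = pd.DataFrame(
            {
                "event_id": ["E1"] * 3,
                "canopy_density_pct": [50.0, 50.0, 50.0],
                "interception_mm": [1.0, 2.0, 3.0],
            }
        )
        with pytest.raises(InputError, match="E1"):
            per_event_density_regression(panel)

    def test_too_few_troughs_rejected(self):
        panel = pd.DataFrame(
            {
                "event_id": ["E1"] * 2,
                "canopy_density_pct": [40.0, 60.0],
                "interception_mm": [1.0, 2.0],
            }
        )
        with pytest.raises(InputError, match="troughs"):
            per_event_density_regression(panel)
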