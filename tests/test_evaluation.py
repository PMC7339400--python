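"""Evaluation statistics and regression-based global sensitivity."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from hypothesis import given, settings
from hypothesis import strategies as st

from sedcarb import (
    PairedSeries,
    global_sensitivity,
    monthly_totals,
    nash_sutcliffe,
    pbias,
    sample_parameters,
)


def series(o, p):
    return PairedSeries(np.asarray(o, float), np.asarray(p, float))


class TestNashSutcliffe:
    def test_perfect_fit(self):
        o = np.array([1.0, 5.0, 2.0, 8.0])
        assert nash_sutcliffe(series(o, o)) == 1.0

    def test_hand_value(self):
        # numerator = denominator = 2
        assert nash_sutcliffe(series([1, 2, 3], [2, 2, 2])) == pytest.approx(0.0)

    def test_mean_predictor_scores_zero(self):
        o = np.array([3.0, 7.0, 1.0, 9.0])
        assert nash_sutcliffe(series(o, np.full_like(o, o.mean()))) == pytest.approx(0.0)

    def test_constant_observations_rejected(self):
        with pytest.raises(ValueError):
            nash_sutcliffe(series([2, 2, 2], [1, 2, 3]))

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(shift=st.floats(-1e3, 1e3, allow_nan=False))
    def test_invariant_under_common_shift(self, shift):
        o = np.array([1.0, 4.0, 2.0, 6.0])
        p = np.array([1.5, 3.0, 2.5, 5.0])
        assert nash_sutcliffe(series(o + shift, p + shift)) == pytest.approx(
            nash_sutcliffe(series(o, p)), rel=1e-6, abs=1e-9
        )


class TestPbias:
    def test_perfect_fit(self):
        assert pbias(series([1, 2, 3], [1, 2, 3])) == 0.0

    def test_underestimation_is_positive(self):
        # O_avg = 2, P_avg = 1.5 -> +25%
        assert pbias(series([1, 3], [1, 2])) == pytest.approx(25.0)

    def test_double_prediction(self):
        o = np.array([1.0, 2.0, 3.0])
        assert pbias(series(o, 2 * o)) == pytest.approx(-100.0)

    def test_zero_mean_rejected(self):
        with pytest.raises(ValueError):
            pbias(series([-1, 1], [0, 0]))

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(scale=st.floats(1e-3, 1e3, allow_nan=False))
    def test_invariant_under_positive_scaling(self, scale):
        o = np.array([1.0, 4.0, 2.0])
        p = np.array([1.5, 3.0, 2.5])
        assert pbias(series(o * scale, p * scale)) == pytest.approx(
            pbias(series(o, p)), rel=1e-9
        )


class TestMonthlyTotals:
    def test_calendar_month_sums(self):
        idx = pd.date_range("2014-01-01", periods=62, freq="D")
        s = pd.Series(1.0, index=idx)
        m = monthly_totals(s)
        assert list(m) == [31.0, 28.0, 3.0]


class TestSampleParameters:
    RANGES = {"a": (0.0, 1.0), "b": (10.0, 20.0)}

    def test_single_row_within_ranges(self):
        row = sample_parameters(self.RANGES, 1, seed=0)
        assert 0.0 <= row["a"].iloc[0] <= 1.0
        assert 10.0 <= row["b"].iloc[0] <= 20.0

    def test_seed_determinism(self):
        a = sample_parameters(self.RANGES, 25, seed=42)
        b = sample_parameters(self.RANGES, 25, seed=42)
        pd.testing.assert_frame_equal(a, b)

    def test_stratified_coverage(self):
        s = sample_parameters(self.RANGES, 1000, seed=1)
        assert s["a"].min() < 0.01 and s["a"].max() > 0.99
        assert s["b"].min() < 10.1 and s["b"].max() > 19.9

    def test_degenerate_range_rejected(self):
        with pytest.raises(ValueError, match="a"):
            sample_parameters({"a": (1.0, 1.0)}, 5, seed=0)


class TestGlobalSensitivity:
    def test_exact_linear_dependence(self):
        """g = 2*b1 exactly: b1 overwhelmingly significant, noise column not."""
        rng = np.random.default_rng(0)
        b = pd.DataFrame({"b1": rng.uniform(0, 1, 50), "b2": rng.uniform(0, 1, 50)})
        g = 2.0 * b["b1"].to_numpy()
        out = global_sensitivity(b, g)
        assert out.loc["b1", "p_value"] < 1e-10
        assert out.loc["b1", "rank"] == 1
        assert not out.loc["b2", "sensitive"]

    def test_constant_objective_flags_nothing(self):
        rng = np.random.default_rng(1)
        b = pd.DataFrame({"x": rng.uniform(0, 1, 20), "y": rng.uniform(0, 1, 20)})
        out = global_sensitivity(b, np.full(20, 3.14))
        assert (out["p_value"] == 1.0).all()
        assert not out["sensitive"].any()

    def test_collinear_design_rejected(self):
        rng = np.random.default_rng(2)
        x = rng.uniform(0, 1, 30)
        b = pd.DataFrame({"x": x, "twice_x": 2 * x})
        with pytest.raises(ValueError, match="collinear"):
            global_sensitivity(b, rng.uniform(0, 1, 30))

    def test_ordering_matches_permutation_oracle(self):
        """Parametric p-value ordering agrees with a brute-force permutation
        test of the regression t-statistics on a small ensemble."""
        rng = np.random.default_rng(3)
        k = 25
        b = pd.DataFrame({
            "strong": rng.uniform(0, 1, k),
            "weak": rng.uniform(0, 1, k),
            "none": rng.uniform(0, 1, k),
        })
        g = (5.0 * b["strong"] + 1.0 * b["weak"]).to_numpy() + rng.normal(0, 0.5, k)

        out = global_sensitivity(b, g)

        # oracle: permutation distribution of |t| per coefficient
        x = sm.add_constant(b.to_numpy())
        t_obs = np.abs(sm.OLS(g, x).fit().tvalues[1:])
        n_perm = 500
        exceed = np.zeros(3)
        for _ in range(n_perm):
            t_perm = np.abs(sm.OLS(rng.permutation(g), x).fit().tvalues[1:])
            exceed += t_perm >= t_obs
        p_perm = (exceed + 1) / (n_perm + 1)

        assert list(np.argsort(p_perm, kind="stable")) == list(
            np.argsort(out.loc[b.columns, "p_value"].to_numpy(), kind="stable")
        )

    def test_too_few_runs_rejected(self):
        b = pd.DataFrame({"a": [0.1, 0.5, 0.9], "b": [0.2, 0.8, 0.4]})
        with pytest.raises(ValueError):
            global_sensitivity(b, np.array([1.0, 2.0, 3.0]))
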