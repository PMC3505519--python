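"""Classical layer: correlations, partial correlations, t tests, R^2."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from corrbf.corr_stats import (
    SampleMoments,
    p_from_t,
    partial_r,
    pearson_r,
    r1_squared_from_partial,
    r_squared_pair,
    t_from_partial_r,
    t_from_r,
)
from conftest import MEDITATION_N, MEDITATION_R, RESUMPTION


class TestPearsonR:
    @pytest.mark.parametrize(
        "x, y, expected",
        [
            ((1, 2, 3, 4), (2, 4, 6, 8), 1.0),
            ((1, 2, 3, 4), (-2, -4, -6, -8), -1.0),
            # hand evaluation: cross_sum = 5.5, (n-1) s_X s_Y = sqrt(43.75)
            ((1, 2, 3, 4), (1, 3, 2, 5), 5.5 / math.sqrt(43.75)),
        ],
    )
    def test_textbook_values(self, x, y, expected):
        assert pearson_r(x, y) == pytest.approx(expected, abs=1e-14)

    def test_matches_scipy(self):
        rng = np.random.default_rng(7)
        x, y = rng.standard_normal((2, 50))
        assert pearson_r(x, y) == pytest.approx(stats.pearsonr(x, y).statistic, abs=1e-13)

    @given(
        a=st.floats(0.1, 10.0),
        b=st.floats(-5.0, 5.0),
        seed=st.integers(0, 100),
    )
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_affine_equivariance(self, a, b, seed):
        """r is invariant under positive-slope affine maps, flips sign under negative."""
        rng = np.random.default_rng(seed)
        x, y = rng.standard_normal((2, 20))
        r = pearson_r(x, y)
        assert pearson_r(a * x + b, y) == pytest.approx(r, abs=1e-9)
        assert pearson_r(-a * x + b, y) == pytest.approx(-r, abs=1e-9)

    @pytest.mark.parametrize(
        "x, y",
        [
            ((1, 2, 3), (1, 2)),  # length mismatch
            ((1, 2), (3, 4)),  # n < 3
            ((1, 1, 1), (1, 2, 3)),  # zero variance
        ],
    )
    def test_invalid_inputs(self, x, y):
        with pytest.raises(ValueError):
            pearson_r(x, y)

    def test_moments_container_rejects_cauchy_schwarz_violation(self):
        with pytest.raises(ValueError):
            SampleMoments(n=10, mean_x=0, mean_y=0, var_x=1, var_y=1, cross_sum=20)


class TestPartialR:
    def test_rapid_resumption_example(self):
        """The age-controlled search-time correlation collapses to ~ -.01."""
        rp = partial_r(RESUMPTION["r_xy"], RESUMPTION["r_xz"], RESUMPTION["r_yz"])
        assert round(rp, 2) == -0.01
        assert rp == pytest.approx(-0.0102, abs=5e-5)

    def test_uncorrelated_control_is_identity(self):
        assert partial_r(0.37, 0.0, 0.0) == pytest.approx(0.37)

    def test_direct_formula_evaluation(self):
        # (0.6 - 0.25) / sqrt(0.75 * 0.75)
        assert partial_r(0.6, 0.5, 0.5) == pytest.approx(0.35 / 0.75, abs=1e-15)

    def test_unit_control_correlation_rejected(self):
        with pytest.raises(ValueError):
            partial_r(0.5, 1.0, 0.2)

    def test_inconsistent_triple_rejected(self):
        # (0.9 + 0.81) / 0.19 = 9 > 1: not a PSD correlation matrix
        with pytest.raises(ValueError, match="inconsistent"):
            partial_r(0.9, 0.9, -0.9)

    def test_agrees_with_regression_residual_definition(self):
        """Formula-based partial r equals the correlation of least-squares
        residuals after regressing X and Y on Z."""
        rng = np.random.default_rng(11)
        for _ in range(5):
            z = rng.standard_normal(60)
            x = 0.8 * z + rng.standard_normal(60)
            y = -0.5 * z + rng.standard_normal(60)
            via_corrs = partial_r(pearson_r(x, y), pearson_r(x, z), pearson_r(y, z))
            design = np.column_stack([np.ones_like(z), z])
            rx = x - design @ np.linalg.lstsq(design, x, rcond=None)[0]
            ry = y - design @ np.linalg.lstsq(design, y, rcond=None)[0]
            via_residuals = float(
                rx @ ry / np.sqrt((rx @ rx) * (ry @ ry))
            )
            assert via_corrs == pytest.approx(via_residuals, abs=1e-12)


class TestTStatistics:
    def test_meditation_t(self):
        assert round(t_from_r(MEDITATION_R, MEDITATION_N), 2) == -2.80

    def test_zero_r_gives_zero_t(self):
        assert t_from_r(0.0, 17) == 0.0
        assert t_from_partial_r(0.0, 40) == 0.0

    def test_facebook_t_is_highly_significant(self):
        t = t_from_r(0.48, 40)
        assert t == pytest.approx(0.48 * math.sqrt(38 / (1 - 0.48**2)), abs=1e-14)
        assert p_from_t(t, 38) < 0.01

    def test_partial_t_from_exact_partial_r(self):
        rp = partial_r(RESUMPTION["r_xy"], RESUMPTION["r_xz"], RESUMPTION["r_yz"])
        assert round(t_from_partial_r(rp, RESUMPTION["n"]), 2) == -0.06

    def test_partial_t_direct_evaluation(self):
        assert t_from_partial_r(0.3, 20) == pytest.approx(
            0.3 * math.sqrt(17 / (1 - 0.09)), abs=1e-14
        )

    def test_perfect_correlation_is_signed_infinity(self):
        with pytest.warns(RuntimeWarning):
            assert t_from_r(-1.0, 10) == -math.inf

    def test_monotone_in_r_and_n(self):
        rs = np.linspace(-0.95, 0.95, 21)
        ts = [t_from_r(r, 30) for r in rs]
        assert np.all(np.diff(ts) > 0)
        mags = [abs(t_from_r(0.4, n)) for n in range(3, 60)]
        assert np.all(np.diff(mags) > 0)

    def test_minimum_sample_sizes(self):
        with pytest.raises(ValueError):
            t_from_r(0.5, 2)
        with pytest.raises(ValueError):
            t_from_partial_r(0.5, 3)


class TestPValues:
    def test_meditation_p_rounds_to_01(self):
        t = t_from_r(MEDITATION_R, MEDITATION_N)
        assert round(p_from_t(t, 52), 2) == 0.01

    def test_resumption_p_rounds_to_95(self):
        assert round(p_from_t(-0.06, 37), 2) == 0.95

    def test_null_center(self):
        assert p_from_t(0.0, 10) == 1.0

    @given(t=st.floats(-30, 30), df=st.integers(1, 200))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_symmetric_and_complementary(self, t, df):
        p = p_from_t(t, df)
        assert 0.0 <= p <= 1.0
        assert p == pytest.approx(p_from_t(-t, df), abs=1e-15)
        central = float(stats.t.cdf(abs(t), df) - stats.t.cdf(-abs(t), df))
        assert p + central == pytest.approx(1.0, abs=1e-12)

    def test_invalid_df(self):
        with pytest.raises(ValueError):
            p_from_t(1.0, 0)


class TestRSquared:
    def test_square_of_control_correlation(self):
        assert r_squared_pair(-0.78) == pytest.approx(0.6084, abs=1e-15)
        assert r_squared_pair(0.0) == 0.0

    def test_from_sums_of_squares(self):
        assert r_squared_pair(ss_err=5.0, ss_tot=5.0) == 0.0
        assert r_squared_pair(ss_err=1.0, ss_tot=4.0) == pytest.approx(0.75)
        with pytest.raises(ValueError):
            r_squared_pair(ss_err=-1.0, ss_tot=4.0)

    def test_alternative_model_r2_matches_printed_value(self):
        """R1^2 from the exact partial correlation reproduces 0.6084408."""
        rp = partial_r(RESUMPTION["r_xy"], RESUMPTION["r_xz"], RESUMPTION["r_yz"])
        r1 = r1_squared_from_partial(rp, RESUMPTION["r_xz"])
        assert round(r1, 7) == 0.6084408

    @pytest.mark.parametrize(
        "rp, rc, expected",
        [(0.0, 0.6, 0.36), (1.0, 0.6, 1.0), (1.0, -0.3, 1.0)],
    )
    def test_degenerate_partials(self, rp, rc, expected):
        assert r1_squared_from_partial(rp, rc) == pytest.approx(expected)

    @given(rp=st.floats(-0.99, 0.99), rc=st.floats(-0.99, 0.99))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_nested_models_never_lose_fit(self, rp, rc):
        assert r1_squared_from_partial(rp, rc) >= r_squared_pair(rc) - 1e-15
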