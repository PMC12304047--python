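import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import growthssd as g
from growthssd.design import DesignError


class TestBuildTimeGrid:
    @pytest.mark.parametrize(
        "duration,frequency,expected",
        [
            (4, 1, [0.0, 1.0, 2.0, 3.0, 4.0]),
            (1, 4, [0.0, 0.25, 0.5, 0.75, 1.0]),
            (2, 2, [0.0, 0.5, 1.0, 1.5, 2.0]),
        ],
    )
    def test_grid_values(self, duration, frequency, expected):
        np.testing.assert_allclose(g.build_time_grid(duration, frequency), expected)

    def test_length_and_endpoints(self):
        grid = g.build_time_grid(8, 1)
        assert grid.size == 9
        assert grid[0] == 0.0
        assert grid[-1] == 8.0

    @given(
        d=st.integers(min_value=1, max_value=20),
        f=st.sampled_from([0.5, 1, 2, 3, 4]),
    )
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_n_equals_fd_plus_one(self, d, f):
        if abs(f * d - round(f * d)) > 1e-9:
            return
        grid = g.build_time_grid(d, f)
        assert grid.size == int(round(f * d)) + 1
        assert grid[-1] == pytest.approx((grid.size - 1) / f)

    def test_non_integer_count_rejected(self):
        with pytest.raises(DesignError, match="whole number"):
            g.build_time_grid(1.5, 1)


class TestTransformTimes:
    def test_identity_without_log(self):
        np.testing.assert_array_equal(
            g.transform_times([0.0, 1.0, 2.0], log_growth=False), [0.0, 1.0, 2.0]
        )

    def test_natural_log(self):
        out = g.transform_times([1.0, 2.0, 4.0], log_growth=True)
        np.testing.assert_allclose(out, [0.0, 0.6931, 1.3863], atol=5e-5)

    def test_log_with_shift(self):
        out = g.transform_times([0.0, 5.0, 13.0, 638.0], log_growth=True, log_shift=1.0)
        np.testing.assert_allclose(out, [0.0, 1.7918, 2.6391, 6.4599], atol=5e-5)

    def test_log_of_zero_rejected_with_offending_time(self):
        with pytest.raises(DesignError, match="time 0"):
            g.transform_times([0.0, 5.0, 13.0], log_growth=True)

    @given(
        start=st.floats(min_value=0.0, max_value=100.0, allow_nan=False),
        steps=st.lists(
            st.floats(min_value=1e-3, max_value=100.0, allow_nan=False),
            min_size=1,
            max_size=9,
        ),
    )
    @settings(max_examples=80, deadline=None, derandomize=True)
    def test_order_preserving(self, start, steps):
        times = start + np.cumsum([0.0] + steps)
        out = g.transform_times(times, log_growth=True, log_shift=0.5)
        assert np.all(np.diff(out) > 0)


class TestEffectSize:
    @pytest.mark.parametrize(
        "delta,var_u1,expected",
        [(0.8, 0.001, 0.0253), (0.40, 0.0030, 0.0219), (0.0, 0.5, 0.0)],
    )
    def test_beta2_from_effect(self, delta, var_u1, expected):
        assert g.beta2_from_effect(delta, var_u1) == pytest.approx(expected, abs=5e-5)

    def test_negative_delta_points_to_direction_flag(self):
        with pytest.raises(DesignError, match="direction"):
            g.beta2_from_effect(-0.5, 0.01)


class TestAnalyticSE:
    def test_uncentered_collapse_without_slope_variance(self):
        vc = g.VarianceComponents(var_e=0.02, var_u0=0.0, var_u1=0.0)
        se = g.analytic_se_beta2(vc, [0.0, 1.0, 2.0], 100, centered=False)
        assert se == pytest.approx(np.sqrt(4 * 0.02 / (100 * 5)), rel=1e-12)
        assert se == pytest.approx(0.012649, abs=5e-7)

    def test_scaling_in_n(self):
        vc = g.VarianceComponents(var_e=0.0262, var_u0=0.0333, var_u1=0.003)
        t = [0.0, 1.0, 2.0, 3.0, 4.0]
        assert g.analytic_se_beta2(vc, t, 200) == pytest.approx(
            g.analytic_se_beta2(vc, t, 100) / np.sqrt(2), rel=1e-12
        )

    def test_monotone_in_n_and_variances(self):
        t = [0.0, 1.0, 2.0, 3.0, 4.0]
        ses = [
            g.analytic_se_beta2(
                g.VarianceComponents(var_e=0.02, var_u0=0.03, var_u1=0.005), t, n
            )
            for n in (50, 100, 200, 400)
        ]
        assert all(a > b for a, b in zip(ses, ses[1:]))
        for attr, hi in (("var_e", 0.2), ("var_u1", 0.05)):
            lo_vc = g.VarianceComponents(var_e=0.02, var_u0=0.03, var_u1=0.005)
            hi_vc = g.VarianceComponents(
                **{**lo_vc.__dict__, attr: hi}
            )
            assert g.analytic_se_beta2(hi_vc, t, 100) > g.analytic_se_beta2(lo_vc, t, 100)

    def test_degenerate_grid_rejected(self):
        vc = g.VarianceComponents(var_e=0.02)
        with pytest.raises(DesignError, match="sum of squares"):
            g.analytic_se_beta2(vc, [0.0, 0.0], 100)

    def test_gls_variant_lies_between_centered_and_uncentered(self):
        # the common-intercept information is bracketed by the two printed
        # sum-of-squares conventions for these components
        vc = g.VarianceComponents(var_e=0.0262, var_u0=0.0333, var_u1=0.003)
        t = [0.0, 1.0, 2.0, 3.0, 4.0]
        unc = g.analytic_se_beta2(vc, t, 100, centered=False)
        cen = g.analytic_se_beta2(vc, t, 100, centered=True)
        exact = g.gls_se_beta2(vc, t, 100, condition_main_effect=False)
        assert unc < exact < cen
        # with the condition main effect the centered formula is exact
        assert g.gls_se_beta2(vc, t, 100) == pytest.approx(cen, rel=1e-12)


class TestEffectiveSampleSize:
    def test_clamp_over_random_designs(self):
        rng = np.random.default_rng(2024)
        for _ in range(1000):
            n = int(rng.integers(2, 200))
            t = np.sort(rng.uniform(0, 10, size=int(rng.integers(2, 8))))
            if np.any(np.diff(t) <= 0):
                continue
            v0, v1 = rng.uniform(0, 0.5, size=2)
            cov = rng.uniform(-1, 1) * np.sqrt(v0 * v1)
            vc = g.VarianceComponents(
                var_e=rng.uniform(0.001, 0.5), var_u0=v0, var_u1=v1, cov_u01=cov
            )
            n_eff = g.effective_sample_size(vc, t, n)
            assert n <= n_eff <= n * t.size

    def test_independence_limit(self):
        vc = g.VarianceComponents(var_e=0.05, var_u0=0.0, var_u1=0.0)
        t = [0.0, 1.0, 2.0, 3.0]
        assert g.effective_sample_size(vc, t, 50) == pytest.approx(50 * 4)

    def test_hand_arithmetic_interior_case(self):
        # sigma_bar^2 = 0.02 + (1/5)*30*0.01 = 0.08; actual = 0.02 + 0.01*10 = 0.12
        # weight = 2/3 -> N_eff = (2/3)*100*5 = 1000/3, inside the clamp
        vc = g.VarianceComponents(var_e=0.02, var_u0=0.0, var_u1=0.01)
        t = [0.0, 1.0, 2.0, 3.0, 4.0]
        assert g.effective_sample_size(vc, t, 100) == pytest.approx(1000 / 3, rel=1e-12)

    def test_replication_design_clamps_to_total(self, make_example1):
        design = make_example1()
        # weight = 0.0775/0.0562 > 1 for these components, so the clamp binds
        assert design.n_eff(100) == pytest.approx(500.0)


class TestBFraction:
    @pytest.mark.parametrize("j,expected", [(1, 0.01), (2, 0.02), (3, 0.03)])
    def test_values(self, j, expected):
        assert g.b_fraction(j, 100) == pytest.approx(expected, rel=1e-12)

    def test_invalid_j(self):
        with pytest.raises(DesignError):
            g.b_fraction(4, 100)


class TestTypes:
    def test_time_grid_invariants(self):
        grid = g.TimeGrid(np.array([0.0, 1.0, 3.0]))
        np.testing.assert_array_equal(grid.raw_times, grid.transformed_times)
        with pytest.raises(DesignError):
            g.TimeGrid(np.array([1.0, 1.0, 2.0]))
        with pytest.raises(DesignError):
            g.TimeGrid(np.array([-1.0, 0.0]))

    def test_variance_components_psd(self):
        with pytest.raises(DesignError, match="semi-definite"):
            g.VarianceComponents(var_e=0.1, var_u0=0.01, var_u1=0.01, cov_u01=0.02)

    def test_design_validation(self, make_example1):
        with pytest.raises(DesignError):
            make_example1(eta_target=1.5)
        with pytest.raises(DesignError):
            make_example1(test="twosided")

    def test_explicit_beta2_overrides_standardized(self, make_example1):
        d = make_example1(effect=g.EffectSpec(delta=0.0, beta2=0.2))
        assert d.beta2 == 0.2
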