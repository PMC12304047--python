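import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import integrate, stats

import growthssd as g
from growthssd.design import DesignError

# shared worked-example inputs: estimate 0.5, squared SE 0.1, N = 100 subjects
B2, SE2 = 0.5, 0.1


class TestFitAndComplexity:
    @pytest.mark.parametrize("b,comp0", [(0.01, 0.126), (0.02, 0.178), (0.03, 0.219)])
    def test_equality_complexity(self, b, comp0):
        fit0, c0 = g.fit_and_complexity(B2, SE2, b, "H0")
        assert c0 == pytest.approx(comp0, abs=5e-4)
        assert fit0 == pytest.approx(0.36, abs=2e-3)

    def test_inequality_complexity_is_half_exactly(self):
        for b in (0.001, 0.01, 0.5, 1.0):
            _, c1 = g.fit_and_complexity(B2, SE2, b, "H1")
            assert c1 == 0.5

    def test_boundary_estimate_gives_half_fit(self):
        fit1, _ = g.fit_and_complexity(0.0, 0.04, 0.01, "H1")
        assert fit1 == pytest.approx(0.5, abs=1e-15)

    def test_quadrature_oracle(self):
        """fit1 and comp0 agree with direct numerical integration to 1e-8."""
        se = math.sqrt(SE2)
        fit1, _ = g.fit_and_complexity(B2, SE2, 0.01, "H1")
        quad, _ = integrate.quad(lambda x: stats.norm.pdf(x, B2, se), 0, np.inf)
        assert fit1 == pytest.approx(quad, abs=1e-8)
        _, comp0 = g.fit_and_complexity(B2, SE2, 0.01, "H0")
        prior_var = SE2 / 0.01
        assert comp0 == pytest.approx(
            math.exp(-0.0) / math.sqrt(2 * math.pi * prior_var), abs=1e-12
        )

    def test_invalid_fraction_rejected(self):
        with pytest.raises(DesignError):
            g.fit_and_complexity(B2, SE2, 0.0, "H0")
        with pytest.raises(DesignError):
            g.fit_and_complexity(B2, SE2, 1.5, "H0")


class TestAAFBF:
    def test_worked_example_bayes_factors(self):
        r1 = g.aafbf(B2, SE2, 0.01)
        assert r1.bf_0u == pytest.approx(2.86, abs=0.02)
        assert r1.bf_1u == pytest.approx(1.88, abs=0.01)
        assert r1.bf_01 == pytest.approx(1.52, abs=0.01)
        r2 = g.aafbf(B2, SE2, 0.02)
        assert r2.bf_0u == pytest.approx(2.02, abs=0.01)
        assert r2.bf_01 == pytest.approx(1.07, abs=0.01)
        r3 = g.aafbf(B2, SE2, 0.03)
        assert r3.bf_0u == pytest.approx(1.64, abs=0.02)
        assert r3.bf_01 == pytest.approx(0.87, abs=0.01)

    def test_null_estimate_neutral_for_inequalities(self):
        r = g.aafbf(0.0, 0.25, 0.02)
        assert r.bf_1u == pytest.approx(1.0, abs=1e-12)
        assert r.bf_1c == pytest.approx(1.0, abs=1e-12)

    def test_savage_dickey_identity(self):
        """BF_0u equals the posterior/prior density ratio at zero."""
        r = g.aafbf(0.31, 0.02, 0.05)
        post = stats.norm.pdf(0.0, 0.31, math.sqrt(0.02))
        prior = stats.norm.pdf(0.0, 0.0, math.sqrt(0.02 / 0.05))
        assert r.bf_0u == pytest.approx(post / prior, rel=1e-12)

    def test_direction_reflection(self):
        neg = g.aafbf(-0.4, 0.09, 0.02, direction=-1)
        pos = g.aafbf(0.4, 0.09, 0.02, direction=1)
        assert neg.bf_1u == pos.bf_1u
        assert neg.bf_01 == pos.bf_01

    def test_extreme_estimates_do_not_underflow(self):
        # 12.5 posterior SDs from the boundary: log-scale evaluation keeps
        # the result finite and correctly ordered
        r = g.aafbf(5.0, 0.16, 0.01)
        assert np.isfinite(r.bf_10) and r.bf_10 > 1e6
        r = g.aafbf(-5.0, 0.16, 0.01)
        # a strongly negative estimate contradicts both the point null and
        # the positive-effect hypothesis; H0 wins but only moderately
        assert np.isfinite(r.bf_01) and r.bf_01 > 1.0
        assert np.isfinite(r.bf_1c) and r.bf_1c < 1e-30
        # beyond float range the BF saturates to inf / 0, never NaN
        r = g.aafbf(50.0, 0.01, 0.01)
        assert not np.isnan(r.bf_10) and r.bf_10 > 1e100


@st.composite
def bf_inputs(draw):
    # keep |z| = |beta2|/SE below 4.5 so 1 - fit1 stays well away from
    # floating-point saturation; the saturation regime has its own test
    se2 = draw(st.floats(1e-3, 4.0, allow_nan=False))
    z = draw(st.floats(-4.5, 4.5, allow_nan=False))
    b = draw(st.floats(1e-4, 1.0, exclude_min=True, allow_nan=False))
    return z * float(np.sqrt(se2)), se2, b


class TestInvariants:
    @given(bf_inputs())
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_algebraic_identities(self, inputs):
        beta2, se2, b = inputs
        r = g.aafbf(beta2, se2, b)
        assert r.comp1 == 0.5
        assert 0.0 < r.fit1 < 1.0
        assert r.bf_1u < 2.0
        assert r.bf_10 == pytest.approx(1.0 / r.bf_01, rel=1e-10)
        assert r.bf_01 == pytest.approx(r.bf_0u / r.bf_1u, rel=1e-10)
        assert r.bf_1c == pytest.approx(r.fit1 / (1.0 - r.fit1), rel=1e-9)

    @given(bf_inputs())
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_inequality_bfs_independent_of_b(self, inputs):
        beta2, se2, b = inputs
        b = min(b, 1 / 3)
        rs = [g.aafbf(beta2, se2, j * b) for j in (1, 2, 3)]
        for r in rs[1:]:
            assert abs(r.bf_1u - rs[0].bf_1u) < 1e-12 * max(1.0, rs[0].bf_1u)
            assert abs(r.bf_1c - rs[0].bf_1c) < 1e-12 * max(1.0, rs[0].bf_1c)

    @given(bf_inputs())
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_equality_bf_strictly_decreasing_in_b(self, inputs):
        beta2, se2, b = inputs
        b = min(b, 1 / 3)
        bf = [g.aafbf(beta2, se2, j * b).bf_0u for j in (1, 2, 3)]
        assert bf[0] > bf[1] > bf[2]


class TestVectorizedTruthBF:
    def test_matches_scalar_route(self):
        est = np.array([-0.2, 0.0, 0.3, 1.1])
        se2 = np.array([0.04, 0.09, 0.02, 0.5])
        b = 0.02
        for truth, test, attr in [
            ("H0", "alt", "bf_01"),
            ("H1", "alt", "bf_10"),
            ("H1", "Hc", "bf_1c"),
            ("H1", "Hu", "bf_1u"),
            ("H0", "Hu", "bf_0u"),
            ("H0", "Hc", "bf_0u"),
        ]:
            vec = g.bf_for_truth(est, se2, b, truth, test)
            scal = [getattr(g.aafbf(e, s, b), attr) for e, s in zip(est, se2)]
            np.testing.assert_allclose(vec, scal, rtol=1e-12)
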