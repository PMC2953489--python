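"""Analytic equilibrium enumeration, Jacobians and stability labels."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from popgames import (
    GameParams,
    classify_stability,
    enumerate_fixed_points,
    find_attractor,
    jacobian,
    nash_check,
    overall_cooperation,
    rhs,
)

param_vals = st.floats(min_value=-5, max_value=5, allow_nan=False)


def _random_params(vals, f):
    b1, c1, b2, c2, B1, C1, B2, C2 = vals
    return GameParams(b1=b1, c1=c1, b2=b2, c2=c2,
                      B1=B1, C1=C1, B2=B2, C2=C2, f=f)


class TestJacobian:
    @given(st.tuples(*[param_vals] * 8),
           st.floats(min_value=0, max_value=1),
           st.floats(min_value=0, max_value=1),
           st.floats(min_value=0, max_value=1))
    def test_matches_central_differences(self, vals, f, p, q):
        g = _random_params(vals, f)
        J = jacobian(g, (p, q))
        h = 1e-6
        J_fd = np.empty((2, 2))
        for j, dv in enumerate([(h, 0), (0, h)]):
            fp = rhs(g, p + dv[0], q + dv[1])
            fm = rhs(g, p - dv[0], q - dv[1])
            J_fd[0, j] = (float(fp[0]) - float(fm[0])) / (2 * h)
            J_fd[1, j] = (float(fp[1]) - float(fm[1])) / (2 * h)
        np.testing.assert_allclose(J, J_fd, atol=1e-6 * (1 + np.abs(J).max()))

    def test_corner_is_diagonal(self):
        g = GameParams.shorthand(-1, -1, 0.8)
        J = jacobian(g, (0.0, 0.0))
        # p(1-p) vanishes: diagonal is (1-2p) G1 = G1 = -1, off-diagonal 0
        np.testing.assert_allclose(J, np.diag([-1.0, -1.0]))


class TestClassifyStability:
    @pytest.mark.parametrize(
        "diag, expected",
        [((-1, -2), "stable"), ((-1, 1), "saddle"),
         ((1, 2), "unstable"), ((0, -1), "nonhyperbolic")],
    )
    def test_diagonal_cases(self, diag, expected):
        label, eigs = classify_stability(np.diag(diag))
        assert label == expected
        assert sorted(e.real for e in eigs) == sorted(diag)

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            classify_stability(np.array([[np.nan, 0], [0, 1.0]]))


class TestEnumeration:
    def test_all_points_have_tiny_residual(self, fixtures):
        for fx in fixtures.values():
            eq = enumerate_fixed_points(fx.params)
            for fp in eq.points:
                dp, dq = rhs(fx.params, *fp.location)
                assert max(abs(float(dp)), abs(float(dq))) < 1e-10

    def test_continuum_line_for_C_equal_minus_B(self):
        """C = -B shorthand: both brackets vanish on
        f(1-2p) + (1-f)(2q-1) = 0; for f = 0.8 this is 1.6p - 0.4q = 0.6."""
        eq = enumerate_fixed_points(GameParams.shorthand(-1, 1, 0.8))
        line = eq.continuum
        assert line is not None
        resid = [line.signed_residual(p, (1.6 * p - 0.6) / 0.4)
                 for p in (0.4, 0.5, 0.6)]
        assert np.max(np.abs(resid)) < 1e-12

    @given(st.floats(min_value=0.05, max_value=0.95),
           st.floats(min_value=0.2, max_value=3))
    def test_continuum_reported_for_all_f(self, f, B):
        for sign in (1, -1):
            eq = enumerate_fixed_points(GameParams.shorthand(sign * B,
                                                             -sign * B, f))
            assert eq.continuum is not None

    def test_snowdrift_line_attracts_stag_hunt_line_repels(self):
        sd = enumerate_fixed_points(GameParams.shorthand(1, -1, 0.8))
        sh = enumerate_fixed_points(GameParams.shorthand(-1, 1, 0.8))
        assert sd.continuum.transverse_stability == "stable"
        assert sh.continuum.transverse_stability == "unstable"

    def test_no_interior_point_when_bracket_sum_constant(self):
        """At f = 1/2 with shorthand parameters, G1 + G2 = B + C identically;
        if that constant is nonzero the brackets cannot vanish together."""
        eq = enumerate_fixed_points(GameParams.shorthand(-1, 2, 0.5))
        assert eq.continuum is None
        assert all(fp.kind != "interior" for fp in eq.points)

    def test_snowdrift_edge_points(self):
        eq = enumerate_fixed_points(GameParams.shorthand(1, -2, 0.8))
        edge = sorted((fp.location for fp in eq.points if fp.kind == "edge"))
        assert edge[0] == pytest.approx((1 / 6, 0.0), abs=1e-12)
        assert edge[1] == pytest.approx((5 / 12, 1.0), abs=1e-12)

    def test_three_stable_corners_under_punishment(self, fixtures):
        eq = enumerate_fixed_points(fixtures["fig7A"].params)
        stable = sorted(fp.location for fp in eq.stable_points())
        assert stable == [(0.0, 0.0), (0.0, 1.0), (1.0, 0.0)]

    def test_harmony_corner_stability(self, fixtures):
        eq = enumerate_fixed_points(fixtures["fig2B"].params)
        by_loc = {fp.location: fp.stability for fp in eq.points}
        assert by_loc[(1.0, 1.0)] == "stable"
        assert by_loc[(0.0, 0.0)] == "unstable"


class TestAgreementWithFlow:
    @pytest.mark.parametrize("name", ["fig2A", "fig3C", "fig5C", "fig5D",
                                      "fig7A", "fig7B"])
    def test_random_starts_land_on_stable_points(self, fixtures, name, rng):
        """Attractors reached from 100 random interior starts coincide with
        enumerated stable points (or the continuum)."""
        g = fixtures[name].params
        eq = enumerate_fixed_points(g)
        stable = [fp.location for fp in eq.stable_points()]
        for _ in range(100):
            s0 = rng.uniform(0.01, 0.99, size=2)
            res = find_attractor(g, s0)
            assert res.converged
            d = min((np.hypot(res.state[0] - s[0], res.state[1] - s[1])
                     for s in stable), default=np.inf)
            if eq.continuum is not None:
                d = min(d, eq.continuum.distance(*res.state))
            assert d < 1e-4

    @pytest.mark.parametrize("B, C", [(1.0, -2.0), (2.0, -1.0), (3.0, -1.0)])
    def test_msd_overall_cooperation_matches_expectation(self, B, C):
        """Strong-population snowdrift: q* is extremal and the weighted
        cooperation f p* + (1-f)(1-q*) equals |B|/(|B|+|C|) exactly."""
        g = GameParams.shorthand(B, C, 0.8)
        res = find_attractor(g, (0.5, 0.5))
        assert res.converged
        assert min(res.state[1], 1 - res.state[1]) < 1e-6
        assert overall_cooperation(g, res.state) == pytest.approx(
            abs(B) / (abs(B) + abs(C)), abs=1e-6)


class TestNash:
    def test_stable_points_are_nash_across_fixtures(self, fixtures):
        for fx in fixtures.values():
            eq = enumerate_fixed_points(fx.params)
            for fp in eq.stable_points():
                assert nash_check(fx.params, fp), (fx.name, fp.location)

    def test_breakdown_corner_of_pd_is_nash(self):
        g = GameParams.shorthand(-1, -1, 0.8)
        eq = enumerate_fixed_points(g)
        corner = next(fp for fp in eq.points if fp.location == (0.0, 0.0))
        assert nash_check(g, corner)

    def test_unstable_interior_point_evaluated(self):
        """A stag-hunt interior saddle is a fixed point whose Nash property
        is still checked (interior mixtures require both brackets zero)."""
        g = GameParams.shorthand(-1, 2, 0.8)
        eq = enumerate_fixed_points(g)
        interior = [fp for fp in eq.points if fp.kind == "interior"]
        if interior:
            assert nash_check(g, interior[0])
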