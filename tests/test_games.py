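"""Payoff parameters, game classification and the payoff transformations."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from popgames import (
    GameClass,
    GameParams,
    PayoffMatrix,
    PunishmentParams,
    apply_group_pressure,
    apply_punishment,
    classify_game,
    params_from_benefit_coordination,
    params_from_payoffs,
    payoff_matrices,
    predict_one_population,
)

finite = st.floats(min_value=-50, max_value=50, allow_nan=False)


@pytest.mark.parametrize(
    "payoffs, expected",
    [
        ((3, 0, 5, 1), (-1, -2)),  # canonical PD ordering T>R>P>S
        ((0, 0, 0, 0), (0, 0)),
        ((3, 1, 0, 2), (-1, 3)),  # b+c, b, 0, c with b=1, c=2
    ],
)
def test_params_from_payoffs(payoffs, expected):
    R, S, T, P = payoffs
    assert params_from_payoffs(PayoffMatrix(R=R, S=S, T=T, P=P)) == expected


@given(finite, finite, finite, finite, finite)
def test_params_invariant_under_payoff_shift(R, S, T, P, shift):
    """B and C depend only on payoff differences."""
    base = params_from_payoffs(PayoffMatrix(R=R, S=S, T=T, P=P))
    shifted = params_from_payoffs(
        PayoffMatrix(R=R + shift, S=S + shift, T=T + shift, P=P + shift))
    assert shifted == pytest.approx(base, abs=1e-9)


@pytest.mark.parametrize(
    "B, C, expected",
    [
        (-1, -1, GameClass.PD),
        (1, 1, GameClass.HG),
        (1, -1, GameClass.SD),
        (-1, 1, GameClass.SH),
        (0, 5, GameClass.DEGENERATE),
        (3, 0, GameClass.DEGENERATE),
        (1e-13, 1, GameClass.DEGENERATE),
    ],
)
def test_classify_game(B, C, expected):
    assert classify_game(B, C) is expected


def test_classify_rejects_non_finite():
    with pytest.raises(ValueError):
        classify_game(float("nan"), 1.0)


@given(finite, finite)
def test_conformity_and_disapproval_agree(b, c):
    """The conformity-reward and discoordination-penalty payoff readings give
    the same (B, C) = (b - c, b + c)."""
    m1, B1, C1 = params_from_benefit_coordination(b, c, "conformity")
    m2, B2, C2 = params_from_benefit_coordination(b, c, "disapproval")
    assert (B1, C1) == pytest.approx((b - c, b + c), abs=1e-9)
    assert (B2, C2) == pytest.approx((B1, C1), abs=1e-9)
    # the matrices themselves differ (unless c = 0)
    assert (m1.R, m1.S, m1.T, m1.P) == (b + c, b, 0, c)
    assert (m2.R, m2.S, m2.T, m2.P) == (b, b - c, -c, 0)


class TestPunishment:
    def test_pd_to_stag_hunt_in_group_pd_out_group(self):
        g = GameParams.shorthand(-1, -2, 0.8)
        pun = PunishmentParams.uniform(gamma=2.5, beta=12.5)
        g2 = apply_punishment(g, pun)
        assert (g2.b1, g2.c1) == (-3.5, 10.5)
        assert (g2.B1, g2.C1) == (-16.0, -2.0)
        assert classify_game(g2.b1, g2.c1) is GameClass.SH
        assert classify_game(g2.B1, g2.C1) is GameClass.PD
        assert g2.f == g.f

    def test_one_sided_cross_mode(self):
        g = GameParams.shorthand(-1, -2, 0.8)
        pun = PunishmentParams.uniform(gamma=2.5, beta=12.5)
        g2 = apply_punishment(g, pun, cross="one_sided")
        assert g2.B1 == -3.5  # only the punisher's own cost
        assert (g2.b1, g2.c1) == (-3.5, 10.5)

    def test_zero_punishment_is_identity(self):
        g = GameParams.shorthand(-1, -2, 0.6)
        assert apply_punishment(g, PunishmentParams.uniform(0, 0)) == g

    def test_boundary_fine_gives_degenerate_in_group(self):
        g = GameParams.shorthand(-1, -2, 0.5)
        with pytest.warns(UserWarning):
            pun = PunishmentParams.uniform(gamma=2.5, beta=2.0)
        g2 = apply_punishment(g, pun)
        assert g2.c1 == 0.0
        assert classify_game(g2.b1, g2.c1) is GameClass.DEGENERATE

    @given(st.floats(min_value=-10, max_value=-0.01),
           st.floats(min_value=-10, max_value=-0.01),
           st.floats(min_value=0, max_value=5),
           st.floats(min_value=5, max_value=20))
    def test_pd_becomes_sh_iff_fine_exceeds_c(self, b, c, gamma, beta):
        """In-group PD turns into SH exactly when beta > |c|; cross-group PD
        signs only harden (B' < B <= 0, C' = C)."""
        g = GameParams.shorthand(b, c, 0.5)
        g2 = apply_punishment(g, PunishmentParams.uniform(gamma, beta))
        in_class = classify_game(g2.b1, g2.c1)
        if beta > abs(c) + 1e-9:
            assert in_class is GameClass.SH
        elif beta < abs(c) - 1e-9:
            assert in_class is GameClass.PD
        assert g2.B1 <= g.B1
        assert g2.C1 == g.C1


class TestGroupPressure:
    def test_pd_to_sh(self):
        assert apply_group_pressure(-1, -2, 3) == (-4, 1)
        assert classify_game(-4, 1) is GameClass.SH

    def test_zero_is_identity(self):
        assert apply_group_pressure(-1, -2, 0) == (-1, -2)

    def test_boundary(self):
        B, C = apply_group_pressure(-1, -2, 2)
        assert (B, C) == (-3, 0)
        assert classify_game(B, C) is GameClass.DEGENERATE

    def test_negative_pressure_rejected(self):
        with pytest.raises(ValueError):
            apply_group_pressure(-1, -2, -0.5)

    @given(st.floats(min_value=-10, max_value=-0.01),
           st.floats(min_value=-10, max_value=-0.01),
           st.floats(min_value=0, max_value=25))
    def test_pd_becomes_sh_iff_pressure_exceeds_C(self, B, C, g):
        B2, C2 = apply_group_pressure(B, C, g)
        cls = classify_game(B2, C2)
        if g > abs(C) + 1e-9:
            assert cls is GameClass.SH
        elif g < abs(C) - 1e-9:
            assert cls is GameClass.PD


class TestOnePopulationPrediction:
    @pytest.mark.parametrize(
        "B, C, p0, expected",
        [
            (1, -1, 0.9, 0.5),        # snowdrift coexistence |B|/(|B|+|C|)
            (-1, -2, 0.99, 0.0),      # prisoner's dilemma
            (2, 3, 0.01, 1.0),        # harmony
            (-1, 2, 1 / 3, 1 / 3),    # stag hunt threshold is stationary
            (-1, 2, 0.5, 1.0),        # above threshold
            (-1, 2, 0.2, 0.0),        # below threshold
            (-1, 2, 0.0, 0.0),        # boundary states are invariant
            (-1, -2, 1.0, 1.0),
        ],
    )
    def test_outcomes(self, B, C, p0, expected):
        assert predict_one_population(B, C, p0) == pytest.approx(expected)

    def test_degenerate_rejected(self):
        with pytest.raises(ValueError):
            predict_one_population(0.0, 1.0, 0.5)


def test_payoff_matrices_are_mirrored():
    """Population 2's matrices are the double flip of a population-1-style
    matrix built from its own parameters."""
    g = GameParams(b1=-1, c1=2, b2=-3, c2=4, B1=5, C1=-6, B2=7, C2=-8, f=0.3)
    mats = payoff_matrices(g)
    assert params_from_payoffs(PayoffMatrix(
        R=mats["11"][0, 0], S=mats["11"][0, 1],
        T=mats["11"][1, 0], P=mats["11"][1, 1])) == (g.b1, g.c1)
    # for population 2 the cooperative behavior is behavior 2: bottom-right
    # corner is R, top-left is P
    m22 = mats["22"]
    assert (m22[1, 1] - m22[0, 1], m22[1, 0] - m22[0, 0]) == (g.c2, g.b2)
    np.testing.assert_allclose(
        mats["21"],
        np.flip(payoff_matrices(
            GameParams(b1=g.B2, c1=g.C2, b2=0, c2=0, B1=0, C1=0, B2=0, C2=0,
                       f=0.5))["11"], axis=(0, 1)))


def test_power_out_of_range_rejected():
    with pytest.raises(ValueError):
        GameParams.shorthand(1, 1, 1.2)
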