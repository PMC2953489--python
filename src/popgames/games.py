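"""Payoff parameters for two-population 2x2 games with incompatible preferences.

Symmetric 2x2 games are fully characterised (up to a payoff shift and time
rescaling) by two differences of the classical payoffs T, R, P, S:

    B = S - P   gain from abandoning coordinated but non-preferred behavior,
    C = R - T   gain from coordinating on one's own preferred behavior.

The signs of (B, C) select the game: prisoner's dilemma (both negative),
snowdrift (B>0, C<0), stag hunt (B<0, C>0) and harmony (both positive).

The two-population model keeps separate parameters for interactions within a
population (lower case ``b_a, c_a``) and across populations (upper case
``B_a, C_a``), plus the relative power ``f`` of population 1.  Population 2's
payoff matrices are the mirrored forms of population 1's: its preferred
("cooperative") behavior is behavior 2, so behavior labels are swapped.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace
from enum import Enum
from typing import Tuple

import numpy as np

__all__ = [
    "PayoffMatrix",
    "GameParams",
    "PunishmentParams",
    "GameClass",
    "DEGENERACY_TOL",
    "params_from_payoffs",
    "classify_game",
    "params_from_benefit_coordination",
    "apply_punishment",
    "apply_group_pressure",
    "apply_group_pressure_params",
    "predict_one_population",
    "payoff_matrices",
]

#: absolute tolerance below which B or C is treated as exactly zero
DEGENERACY_TOL = 1e-12


def _require_finite(**values: float) -> None:
    for name, v in values.items():
        if not math.isfinite(v):
            raise ValueError(f"parameter {name!r} must be finite, got {v!r}")


@dataclass(frozen=True)
class PayoffMatrix:
    """Payoffs of a symmetric 2x2 game: R (reward), S (sucker), T (temptation),
    P (mutual-defection punishment)."""

    R: float
    S: float
    T: float
    P: float

    def __post_init__(self) -> None:
        _require_finite(R=self.R, S=self.S, T=self.T, P=self.P)

    def as_array(self) -> np.ndarray:
        """Row = focal behavior (cooperative first), column = partner behavior."""
        return np.array([[self.R, self.S], [self.T, self.P]], dtype=float)


class GameClass(str, Enum):
    PD = "PD"
    SD = "SD"
    SH = "SH"
    HG = "HG"
    DEGENERATE = "degenerate"


@dataclass(frozen=True)
class GameParams:
    """Complete specification of the two-population model.

    ``b_a, c_a`` apply to interactions within population ``a``; ``B_a, C_a``
    to interactions of population ``a`` with the other population; ``f`` in
    [0, 1] is the relative power (interaction/influence weight) of
    population 1.
    """

    b1: float
    c1: float
    b2: float
    c2: float
    B1: float
    C1: float
    B2: float
    C2: float
    f: float

    def __post_init__(self) -> None:
        _require_finite(
            b1=self.b1, c1=self.c1, b2=self.b2, c2=self.c2,
            B1=self.B1, C1=self.C1, B2=self.B2, C2=self.C2, f=self.f,
        )
        if not 0.0 <= self.f <= 1.0:
            raise ValueError(f"power f must lie in [0, 1], got {self.f}")

    @classmethod
    def shorthand(cls, B: float, C: float, f: float) -> "GameParams":
        """No difference between in-group and out-group payoffs:
        b_a = B_a = B and c_a = C_a = C for both populations."""
        return cls(b1=B, c1=C, b2=B, c2=C, B1=B, C1=C, B2=B, C2=C, f=f)

    @classmethod
    def per_population(
        cls, B1: float, C1: float, B2: float, C2: float, f: float
    ) -> "GameParams":
        """Each population has its own (B, C), identical in- and out-group."""
        return cls(b1=B1, c1=C1, b2=B2, c2=C2, B1=B1, C1=C1, B2=B2, C2=C2, f=f)

    def scaled(self, lam: float) -> "GameParams":
        """Multiply all eight payoff parameters by ``lam`` (time rescaling)."""
        return replace(
            self,
            b1=lam * self.b1, c1=lam * self.c1, b2=lam * self.b2, c2=lam * self.c2,
            B1=lam * self.B1, C1=lam * self.C1, B2=lam * self.B2, C2=lam * self.C2,
        )

    def classes(self) -> dict:
        """Game classification of each context (in-group / out-group, per population)."""
        return {
            "in_1": classify_game(self.b1, self.c1),
            "in_2": classify_game(self.b2, self.c2),
            "out_1": classify_game(self.B1, self.C1),
            "out_2": classify_game(self.B2, self.C2),
        }

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in
             ("b1", "c1", "b2", "c2", "B1", "C1", "B2", "C2", "f")}
        return d


@dataclass(frozen=True)
class PunishmentParams:
    """Costly-punishment parameters: cost gamma_a paid by the punisher,
    fine beta_a imposed on the punished partner, per population."""

    gamma1: float
    gamma2: float
    beta1: float
    beta2: float

    def __post_init__(self) -> None:
        _require_finite(gamma1=self.gamma1, gamma2=self.gamma2,
                        beta1=self.beta1, beta2=self.beta2)
        for name in ("gamma1", "gamma2", "beta1", "beta2"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        # Convention only: fines usually exceed costs, but this is not enforced.
        if self.beta1 < self.gamma1 or self.beta2 < self.gamma2:
            warnings.warn(
                "punishment fine smaller than punishment cost "
                "(beta_a < gamma_a); unusual but allowed",
                stacklevel=2,
            )

    @classmethod
    def uniform(cls, gamma: float, beta: float) -> "PunishmentParams":
        return cls(gamma1=gamma, gamma2=gamma, beta1=beta, beta2=beta)


def params_from_payoffs(m: PayoffMatrix) -> Tuple[float, float]:
    """Return (B, C) = (S - P, R - T) for a symmetric 2x2 game."""
    return m.S - m.P, m.R - m.T


def classify_game(B: float, C: float, tol: float = DEGENERACY_TOL) -> GameClass:
    """Classify a 2x2 game by the signs of (B, C).

    A coordinate within ``tol`` of zero makes the game degenerate: it sits on
    a boundary between classes and is never silently binned into one of them.
    """
    _require_finite(B=B, C=C)
    if abs(B) <= tol or abs(C) <= tol:
        return GameClass.DEGENERATE
    if B < 0 and C < 0:
        return GameClass.PD
    if B > 0 and C < 0:
        return GameClass.SD
    if B < 0 and C > 0:
        return GameClass.SH
    return GameClass.HG


def params_from_benefit_coordination(
    b: float, c: float, variant: str = "conformity"
) -> Tuple[PayoffMatrix, float, float]:
    """Benefit/coordination parametrization of the coordination-norm games.

    ``b`` is the benefit of showing one's preferred behavior, ``c`` the
    benefit of coordinating with the interaction partner.  Two readings give
    the same (B, C) = (b - c, b + c):

    - ``conformity``: a reward for matching the partner's behavior,
      payoffs P = c, R = b + c, S = b, T = 0;
    - ``disapproval``: a penalty for discoordinated behavior,
      payoffs P = 0, R = b, S = b - c, T = -c.
    """
    if variant == "conformity":
        m = PayoffMatrix(R=b + c, S=b, T=0.0, P=c)
    elif variant == "disapproval":
        m = PayoffMatrix(R=b, S=b - c, T=-c, P=0.0)
    else:
        raise ValueError(f"unknown variant {variant!r}")
    B, C = params_from_payoffs(m)
    return m, B, C


def apply_punishment(
    g: GameParams, pp: PunishmentParams, cross: str = "both"
) -> GameParams:
    """Transform the payoff parameters under costly peer punishment.

    An individual receiving the sucker's payoff (unilateral cooperation from
    its own viewpoint) punishes its partner: the punisher pays cost gamma_a,
    the punished partner loses the fine beta_a.  Within population ``a`` this
    gives b_a' = b_a - gamma_a and c_a' = c_a + beta_a, which turns an
    in-group prisoner's dilemma into a stag hunt once beta_a > |c_a|.

    In a cross encounter where the two sides show different behaviors, each
    perceives itself as the unilateral cooperator, so by default *both*
    punish (``cross="both"``): B_a' = B_a - gamma_a - beta_other, C_a' = C_a.
    ``cross="one_sided"`` applies only the punisher's own cost:
    B_a' = B_a - gamma_a.  Either way a cross-group prisoner's dilemma stays
    a prisoner's dilemma.  ``f`` is unchanged.
    """
    if cross == "both":
        B1 = g.B1 - pp.gamma1 - pp.beta2
        B2 = g.B2 - pp.gamma2 - pp.beta1
    elif cross == "one_sided":
        B1 = g.B1 - pp.gamma1
        B2 = g.B2 - pp.gamma2
    else:
        raise ValueError(f"unknown cross-punishment mode {cross!r}")
    return replace(
        g,
        b1=g.b1 - pp.gamma1, c1=g.c1 + pp.beta1,
        b2=g.b2 - pp.gamma2, c2=g.c2 + pp.beta2,
        B1=B1, B2=B2,
    )


def apply_group_pressure(B: float, C: float, g: float) -> Tuple[float, float]:
    """Group pressure of strength ``g >= 0`` discourages discoordinated
    behavior by subtracting ``g`` from the off-diagonal payoffs S and T,
    hence (B, C) -> (B - g, C + g).  A prisoner's dilemma becomes a stag
    hunt once g > |C|."""
    _require_finite(B=B, C=C, g=g)
    if g < 0:
        raise ValueError(f"group pressure must be >= 0, got {g}")
    return B - g, C + g


def apply_group_pressure_params(params: GameParams, g: float) -> GameParams:
    """Apply group pressure to all four (B, C) pairs of a GameParams."""
    b1, c1 = apply_group_pressure(params.b1, params.c1, g)
    b2, c2 = apply_group_pressure(params.b2, params.c2, g)
    B1, C1 = apply_group_pressure(params.B1, params.C1, g)
    B2, C2 = apply_group_pressure(params.B2, params.C2, g)
    return replace(params, b1=b1, c1=c1, b2=b2, c2=c2, B1=B1, C1=C1, B2=B2, C2=C2)


def predict_one_population(B: float, C: float, p0_init: float) -> float:
    """Long-run fraction of cooperators in the one-population replicator game.

    PD -> 0, HG -> 1, SD -> coexistence at |B|/(|B|+|C|); SH -> 1 above the
    threshold |B|/(|B|+|C|), 0 below, and the threshold itself is stationary.
    The boundary states p0 in {0, 1} are invariant and returned unchanged.
    """
    if not 0.0 <= p0_init <= 1.0:
        raise ValueError(f"initial fraction must lie in [0, 1], got {p0_init}")
    cls = classify_game(B, C)
    if cls is GameClass.DEGENERATE:
        raise ValueError("degenerate game: outcome not determined by (B, C) signs")
    if p0_init in (0.0, 1.0):
        return p0_init
    theta = abs(B) / (abs(B) + abs(C))
    if cls is GameClass.PD:
        return 0.0
    if cls is GameClass.HG:
        return 1.0
    if cls is GameClass.SD:
        return theta
    # stag hunt: bistable with unstable threshold theta
    if p0_init > theta:
        return 1.0
    if p0_init < theta:
        return 0.0
    return theta


def payoff_matrices(g: GameParams, T: float = 0.0, P: float = 0.0) -> dict:
    """Construct explicit payoff matrices from the difference parameters.

    Fixing T and P (defaults 0) gives R = C + T and S = B + P for each
    context.  Matrices are indexed by behavior labels (behavior 1 first) with
    rows for the focal individual and columns for the partner.  Population 1
    matrices are built directly; population 2's are generated by mirroring
    (both axes flipped), reflecting that its preferred behavior is behavior 2.

    Returns a dict with keys "11", "12", "22", "21" where "ab" means a focal
    individual of population a meeting a partner of population b.
    """

    def base(B: float, C: float) -> np.ndarray:
        return PayoffMatrix(R=C + T, S=B + P, T=T, P=P).as_array()

    return {
        "11": base(g.b1, g.c1),
        "12": base(g.B1, g.C1),
        "22": np.flip(base(g.b2, g.c2), axis=(0, 1)),
        "21": np.flip(base(g.B2, g.C2), axis=(0, 1)),
    }
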