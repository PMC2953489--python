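"""Named scenario fixtures: the benchmark parameter sets of the model.

Each fixture bundles a parameter set, optional punishment, representative
initial conditions and (where known analytically) the attractor those
initial conditions reach.  Expected attractors are consistency anchors: the
test suite re-derives every one of them with the integrator.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

from .games import GameParams, PunishmentParams, apply_punishment

__all__ = ["ScenarioFixture", "generate_fixtures"]


@dataclass(frozen=True)
class ScenarioFixture:
    name: str
    params: GameParams  # effective parameters (punishment already applied)
    description: str
    inits: Tuple[Tuple[Tuple[float, float], Optional[Tuple[float, float]]], ...]
    base_params: Optional[GameParams] = None  # pre-punishment parameters
    punishment: Optional[PunishmentParams] = None
    has_continuum: bool = False

    def to_dict(self) -> dict:
        d = {
            "name": self.name,
            "description": self.description,
            "params": self.params.to_dict(),
            "inits": [
                {"start": list(s), "expected_attractor":
                    list(a) if a is not None else None}
                for s, a in self.inits
            ],
            "has_continuum": self.has_continuum,
        }
        if self.punishment is not None:
            d["punishment"] = {
                "gamma1": self.punishment.gamma1, "gamma2": self.punishment.gamma2,
                "beta1": self.punishment.beta1, "beta2": self.punishment.beta2,
            }
            d["base_params"] = self.base_params.to_dict()
        return d


def generate_fixtures() -> Dict[str, ScenarioFixture]:
    """Construct the benchmark scenario set covering all four game regimes,
    the punishment transformation and the mixed-game case."""
    fx: Dict[str, ScenarioFixture] = {}

    def add(name: str, params: GameParams, description: str, inits,
            base: Optional[GameParams] = None,
            pun: Optional[PunishmentParams] = None,
            has_continuum: bool = False) -> None:
        fx[name] = ScenarioFixture(
            name=name, params=params, description=description,
            inits=tuple(inits), base_params=base, punishment=pun,
            has_continuum=has_continuum,
        )

    add("fig2A", GameParams.shorthand(-1, -1, 0.8),
        "Two-population prisoner's dilemma (B=C=-1, f=0.8): cooperation "
        "breaks down from any interior start.",
        [((0.5, 0.5), (0.0, 0.0)), ((0.9, 0.9), (0.0, 0.0))])

    add("fig2B", GameParams.shorthand(1, 1, 0.8),
        "Two-population harmony game (B=C=1, f=0.8): each population keeps "
        "its own preferred behavior (subcultures).",
        [((0.5, 0.5), (1.0, 1.0)), ((0.1, 0.1), (1.0, 1.0))])

    add("fig3A", GameParams.shorthand(-1, 1, 0.8),
        "Two-population stag hunt, |B|=|C|=1, f=0.8: a shared norm always "
        "forms; the diagonal line is a continuum of unstable equilibria.",
        [((0.95, 0.05), (1.0, 0.0)), ((0.05, 0.95), (0.0, 1.0))],
        has_continuum=True)

    add("fig3B", GameParams.shorthand(-1, 2, 0.5),
        "Two-population stag hunt, |C|=2|B|=2, f=1/2: equally strong "
        "populations; symmetric starts keep separate subcultures.",
        [((0.5, 0.5), (1.0, 1.0))])

    add("fig3C", GameParams.shorthand(-1, 2, 0.8),
        "Two-population stag hunt, |C|=2|B|=2, f=0.8.",
        [((0.5, 0.5), (1.0, 0.0))])

    add("fig3D", GameParams.shorthand(-2, 1, 0.8),
        "Two-population stag hunt, 2|C|=|B|=2, f=0.8.",
        [((0.5, 0.5), (0.0, 1.0))])

    add("fig5A", GameParams.shorthand(1, -1, 0.8),
        "Two-population snowdrift, |B|=|C|=1, f=0.8: a solid line of stable "
        "equilibria; the outcome depends continuously on the history.",
        [((0.5, 0.5), None)], has_continuum=True)

    add("fig5B", GameParams.shorthand(1, -2, 0.5),
        "Two-population snowdrift, |C|=2|B|=2, f=1/2: everybody ends up "
        "non-cooperative.",
        [((0.5, 0.5), (0.0, 0.0))])

    add("fig5C", GameParams.shorthand(1, -2, 0.8),
        "Two-population snowdrift, |C|=2|B|=2, f=0.8: the stronger "
        "population polarizes at (1/6, 0); the weaker one coordinates with "
        "its minority.",
        [((0.5, 0.5), (1.0 / 6.0, 0.0))])

    add("fig5D", GameParams.shorthand(2, -1, 0.8),
        "Two-population snowdrift, 2|C|=|B|=2, f=0.8: after the "
        "revolutionary transition the weaker population shows its own "
        "preferred behavior; attractor (5/6, 1).",
        [((0.5, 0.5), (5.0 / 6.0, 1.0))])

    base7A = GameParams.shorthand(-1, -2, 0.8)
    pun7A = PunishmentParams.uniform(gamma=2.5, beta=12.5)
    add("fig7A", apply_punishment(base7A, pun7A),
        "Prisoner's dilemma (B=-1, C=-2, f=0.8) with costly punishment "
        "(cost 2.5, fine 12.5): in-group play becomes a stag hunt, "
        "cross-group play stays a prisoner's dilemma; three stable corners "
        "(0,0), (1,0), (0,1).",
        [((0.95, 0.05), (1.0, 0.0)), ((0.1, 0.1), (0.0, 0.0)),
         ((0.05, 0.95), (0.0, 1.0))],
        base=base7A, pun=pun7A)

    add("fig7B", GameParams.per_population(B1=-1, C1=2, B2=-1, C2=-2, f=0.5),
        "Population 1 plays a stag hunt (B=-1, C=2), population 2 a "
        "prisoner's dilemma (B=-1, C=-2), f=1/2: population 1's preference "
        "becomes the norm.",
        [((0.5, 0.5), (1.0, 0.0))])

    return fx
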