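"""Finite-population stochastic counterpart: proportional imitation.

Each elementary event picks a population (with probability proportional to
its size), draws a focal and a role-model agent from it without replacement,
and lets the focal agent copy the model's behavior with probability
max(0, dE) / dmax, where dE is the model-minus-focal difference in expected
payoff at the current state and dmax is the largest payoff difference the
parameter set can produce anywhere in the unit square.  Only same-population
imitation occurs; out-group individuals influence payoffs but are never
copied.  One generation is N1 + N2 elementary events, which aligns the chain
with the replicator clock up to the constant factor 1/dmax.

The large-N drift of this chain is exactly the replicator right-hand side
(divided by dmax), so ensembles concentrate on the deterministic flow as the
populations grow.  States with k in {0, N} in both populations are jointly
absorbing: there is no mutation.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Tuple

import numpy as np
import pandas as pd

from .games import GameParams, payoff_matrices
from .replicator import bracket_coefficients

__all__ = [
    "AgentState",
    "expected_payoff",
    "delta_max",
    "step",
    "run",
    "run_replicates",
]

try:  # pragma: no cover - exercised implicitly when numba is present
    from numba import njit

    _HAVE_NUMBA = True
except Exception:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):  # type: ignore[misc]
        if args and callable(args[0]):
            return args[0]
        return lambda fn: fn


@dataclass(frozen=True)
class AgentState:
    """Counts of preferred-behavior adopters in two finite populations.

    ``k1`` agents of population 1 (size N1) show behavior 1; ``k2`` agents of
    population 2 (size N2) show behavior 2.  ``seed`` identifies the random
    stream."""

    N1: int
    N2: int
    k1: int
    k2: int
    seed: int = 0

    def __post_init__(self) -> None:
        if self.N1 < 2 or self.N2 < 2:
            raise ValueError("population sizes must be >= 2")
        if not (0 <= self.k1 <= self.N1 and 0 <= self.k2 <= self.N2):
            raise ValueError("adopter counts must lie in [0, N]")

    @classmethod
    def from_fractions(cls, N1: int, N2: int, p: float, q: float,
                       seed: int = 0) -> "AgentState":
        return cls(N1=N1, N2=N2, k1=round(p * N1), k2=round(q * N2), seed=seed)

    @property
    def p_hat(self) -> float:
        return self.k1 / self.N1

    @property
    def q_hat(self) -> float:
        return self.k2 / self.N2


def expected_payoff(g: GameParams, population: int, behavior: int,
                    s: Tuple[float, float]) -> float:
    """Expected payoff of a pure behavior against the current state.

    Mixes the in-group and out-group payoff rows with weights (f, 1-f) for
    population 1 and (1-f, f) for population 2.  An in-group partner of
    population 1 shows behavior 1 with probability p; an out-group partner
    shows it with probability 1 - q (and mirrored for population 2).  The
    behavior difference of this quantity is the growth bracket G_a.
    """
    if population not in (1, 2) or behavior not in (1, 2):
        raise ValueError("population and behavior must be 1 or 2")
    p, q = float(s[0]), float(s[1])
    mats = payoff_matrices(g)
    i = behavior - 1
    if population == 1:
        e_in = mats["11"][i, 0] * p + mats["11"][i, 1] * (1 - p)
        e_out = mats["12"][i, 0] * (1 - q) + mats["12"][i, 1] * q
        return g.f * e_in + (1 - g.f) * e_out
    e_in = mats["22"][i, 0] * (1 - q) + mats["22"][i, 1] * q
    e_out = mats["21"][i, 0] * p + mats["21"][i, 1] * (1 - p)
    return (1 - g.f) * e_in + g.f * e_out


def delta_max(g: GameParams) -> float:
    """Largest |G_a| over the unit square (attained at a corner, since the
    brackets are affine): the global normalization of imitation
    probabilities."""
    A1, a1p, a1q, A2, a2p, a2q = bracket_coefficients(g)
    best = 0.0
    for p in (0.0, 1.0):
        for q in (0.0, 1.0):
            best = max(best, abs(A1 + a1p * p + a1q * q),
                       abs(A2 + a2p * p + a2q * q))
    return best


@njit(cache=False)
def _chain(k1: int, k2: int, N1: int, N2: int,
           A1: float, a1p: float, a1q: float,
           A2: float, a2p: float, a2q: float,
           dmax: float, u: np.ndarray) -> Tuple[int, int]:
    """Advance the imitation chain by u.shape[0] elementary events.

    ``u`` holds four uniforms per event: population choice, focal index,
    model index, adoption draw."""
    frac1 = N1 / (N1 + N2)
    for m in range(u.shape[0]):
        p = k1 / N1
        q = k2 / N2
        if u[m, 0] < frac1:
            focal = int(u[m, 1] * N1)
            model = int(u[m, 2] * (N1 - 1))
            if model >= focal:
                model += 1
            focal_coop = focal < k1
            model_coop = model < k1
            if focal_coop == model_coop:
                continue
            G1 = A1 + a1p * p + a1q * q
            dE = G1 if model_coop else -G1
            if dE > 0.0 and u[m, 3] < dE / dmax:
                k1 += 1 if model_coop else -1
        else:
            focal = int(u[m, 1] * N2)
            model = int(u[m, 2] * (N2 - 1))
            if model >= focal:
                model += 1
            focal_coop = focal < k2
            model_coop = model < k2
            if focal_coop == model_coop:
                continue
            G2 = A2 + a2p * p + a2q * q
            dE = G2 if model_coop else -G2
            if dE > 0.0 and u[m, 3] < dE / dmax:
                k2 += 1 if model_coop else -1
    return k1, k2


def step(a: AgentState, g: GameParams,
         rng: Optional[np.random.Generator] = None) -> AgentState:
    """One asynchronous elementary update.  A degenerate game (dmax = 0) makes
    the step the identity."""
    dmax = delta_max(g)
    if dmax == 0.0:
        return a
    if rng is None:
        rng = np.random.default_rng(a.seed)
    A1, a1p, a1q, A2, a2p, a2q = bracket_coefficients(g)
    u = rng.random((1, 4))
    k1, k2 = _chain(a.k1, a.k2, a.N1, a.N2, A1, a1p, a1q, A2, a2p, a2q,
                    dmax, u)
    return replace(a, k1=int(k1), k2=int(k2))


def run(a0: AgentState, g: GameParams, n_generations: int,
        record_every: int = 1) -> pd.DataFrame:
    """Simulate the chain for ``n_generations`` (one generation = N1 + N2
    elementary events) and record (p_hat, q_hat) every ``record_every``
    generations.  Fully reproducible under a fixed ``a0.seed``."""
    if n_generations < 1:
        raise ValueError("n_generations must be >= 1")
    dmax = delta_max(g)
    rng = np.random.default_rng(a0.seed)
    A1, a1p, a1q, A2, a2p, a2q = bracket_coefficients(g)
    steps_per_gen = a0.N1 + a0.N2
    k1, k2 = a0.k1, a0.k2
    recs = [(0, k1 / a0.N1, k2 / a0.N2)]
    for gen in range(1, n_generations + 1):
        if dmax > 0.0:
            u = rng.random((steps_per_gen, 4))
            k1, k2 = _chain(k1, k2, a0.N1, a0.N2, A1, a1p, a1q,
                            A2, a2p, a2q, dmax, u)
        if gen % record_every == 0 or gen == n_generations:
            recs.append((gen, k1 / a0.N1, k2 / a0.N2))
    return pd.DataFrame(recs, columns=["generation", "p_hat", "q_hat"])


def run_replicates(a0: AgentState, g: GameParams, n_generations: int,
                   n_replicates: int, record_every: int = 1) -> pd.DataFrame:
    """Independent replicates with deterministically offset seeds; returns the
    concatenated series with a ``replicate`` column."""
    frames = []
    for r in range(n_replicates):
        a_r = replace(a0, seed=(a0.seed + 1_000_003 * r) % (2 ** 31))
        df = run(a_r, g, n_generations, record_every=record_every)
        df.insert(0, "replicate", r)
        frames.append(df)
    return pd.concat(frames, ignore_index=True)
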