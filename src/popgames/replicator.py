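"""Coupled replicator equations for two populations with mirrored preferences.

State is a point (p, q) in the unit square: p is the fraction of population 1
showing its preferred behavior 1, q the fraction of population 2 showing its
preferred behavior 2 (so an out-group partner of population 1 shows behavior 1
with probability 1 - q).  The dynamics are

    dp/dt = p (1 - p) G1(p, q),      dq/dt = q (1 - q) G2(p, q),

where G_a is the expected-payoff difference between the two behaviors for
population a, mixing in-group and out-group encounters with weights (f, 1-f)
for population 1 and (1-f, f) for population 2:

    G1 = f [c1 p + b1 (1-p)] + (1-f) [C1 (1-q) + B1 q],
    G2 = (1-f) [c2 q + b2 (1-q)] + f [C2 (1-p) + B2 p].

Both brackets are affine in (p, q); the unit square, its edges and corners are
invariant.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy.integrate import solve_ivp

from .games import GameParams

__all__ = [
    "Trajectory",
    "AttractorResult",
    "bracket_coefficients",
    "growth_brackets",
    "rhs",
    "integrate",
    "find_attractor",
    "DEFAULT_RTOL",
    "DEFAULT_ATOL",
    "DEFAULT_EPS_CONV",
]

DEFAULT_RTOL = 1e-9
DEFAULT_ATOL = 1e-11
#: convergence threshold on the sup-norm of the vector field
DEFAULT_EPS_CONV = 1e-9
#: states may leave [0,1]^2 by at most this much before clamping
CLAMP_TOL = 1e-12


@dataclass
class Trajectory:
    """Time-indexed solution of the replicator flow, clamped to [0,1]^2."""

    times: np.ndarray
    states: np.ndarray  # shape (n, 2), columns (p, q)
    converged: bool
    attractor: Optional[Tuple[float, float]] = None
    n_steps: int = 0
    params: Optional[GameParams] = None

    @property
    def p(self) -> np.ndarray:
        return self.states[:, 0]

    @property
    def q(self) -> np.ndarray:
        return self.states[:, 1]

    def final_state(self) -> Tuple[float, float]:
        return float(self.states[-1, 0]), float(self.states[-1, 1])

    def summary(self) -> dict:
        d = {
            "converged": bool(self.converged),
            "attractor": list(self.attractor) if self.attractor is not None else None,
            "t_final": float(self.times[-1]),
            "steps": int(self.n_steps),
            "final_state": list(self.final_state()),
        }
        if self.params is not None:
            d["params"] = self.params.to_dict()
        return d


@dataclass
class AttractorResult:
    state: Tuple[float, float]
    converged: bool
    t_total: float = 0.0
    n_steps: int = 0


def bracket_coefficients(g: GameParams) -> Tuple[float, float, float, float, float, float]:
    """Affine coefficients (A1, a1p, a1q, A2, a2p, a2q) of the growth brackets:
    G1 = A1 + a1p p + a1q q and G2 = A2 + a2p p + a2q q."""
    f = g.f
    A1 = f * g.b1 + (1.0 - f) * g.C1
    a1p = f * (g.c1 - g.b1)
    a1q = (1.0 - f) * (g.B1 - g.C1)
    A2 = (1.0 - f) * g.b2 + f * g.C2
    a2q = (1.0 - f) * (g.c2 - g.b2)
    a2p = f * (g.B2 - g.C2)
    return A1, a1p, a1q, A2, a2p, a2q


def growth_brackets(g: GameParams, p, q):
    """Expected-payoff difference G_a between the two behaviors, per population.

    Accepts scalars or arrays (broadcast)."""
    A1, a1p, a1q, A2, a2p, a2q = bracket_coefficients(g)
    G1 = A1 + a1p * np.asarray(p) + a1q * np.asarray(q)
    G2 = A2 + a2p * np.asarray(p) + a2q * np.asarray(q)
    return G1, G2


def rhs(g: GameParams, p, q):
    """Right-hand side (dp/dt, dq/dt) of the replicator equations."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    G1, G2 = growth_brackets(g, p, q)
    return p * (1.0 - p) * G1, q * (1.0 - q) * G2


def _sup_norm_rhs(g: GameParams, p: float, q: float) -> float:
    dp, dq = rhs(g, p, q)
    return max(abs(float(dp)), abs(float(dq)))


def _validate_state(s: Sequence[float]) -> Tuple[float, float]:
    p, q = float(s[0]), float(s[1])
    if not (np.isfinite(p) and np.isfinite(q)):
        raise ValueError(f"non-finite state {s!r}")
    if not (-CLAMP_TOL <= p <= 1 + CLAMP_TOL and -CLAMP_TOL <= q <= 1 + CLAMP_TOL):
        raise ValueError(f"state {s!r} outside the unit square")
    return min(max(p, 0.0), 1.0), min(max(q, 0.0), 1.0)


def integrate(
    g: GameParams,
    s0: Sequence[float],
    t_end: float,
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
    eps_conv: Optional[float] = DEFAULT_EPS_CONV,
    t_eval: Optional[Sequence[float]] = None,
) -> Trajectory:
    """Integrate the replicator flow from ``s0`` up to ``t_end``.

    Uses an adaptive Runge-Kutta scheme; the vector field clamps its input to
    the unit square, so round-off never pushes the dynamics outside.  When
    ``eps_conv`` is set, integration terminates early once the sup-norm of the
    vector field falls below it and the trajectory is marked converged with
    the final state as attractor.
    """
    if t_end <= 0:
        raise ValueError("t_end must be positive")
    p0, q0 = _validate_state(s0)

    def field(t, y):
        p = min(max(y[0], 0.0), 1.0)
        q = min(max(y[1], 0.0), 1.0)
        dp, dq = rhs(g, p, q)
        return (float(dp), float(dq))

    events = None
    if eps_conv is not None and eps_conv > 0:
        if _sup_norm_rhs(g, p0, q0) < eps_conv:
            state = np.array([[p0, q0]])
            return Trajectory(
                times=np.array([0.0]), states=state, converged=True,
                attractor=(p0, q0), n_steps=0, params=g,
            )

        def settled(t, y):
            p = min(max(y[0], 0.0), 1.0)
            q = min(max(y[1], 0.0), 1.0)
            dp, dq = rhs(g, p, q)
            return max(abs(float(dp)), abs(float(dq))) - eps_conv

        settled.terminal = True
        settled.direction = -1
        events = [settled]

    sol = solve_ivp(
        field, (0.0, float(t_end)), [p0, q0],
        method="RK45", rtol=rtol, atol=atol, t_eval=t_eval, events=events,
        dense_output=False,
    )
    if not sol.success:
        raise RuntimeError(f"integration failed: {sol.message}")
    states = np.clip(sol.y.T, 0.0, 1.0)
    if not np.all(np.isfinite(states)):
        raise RuntimeError("non-finite state encountered during integration")
    converged = bool(events is not None and len(sol.t_events[0]) > 0)
    attractor = tuple(states[-1]) if converged else None
    return Trajectory(
        times=sol.t, states=states, converged=converged,
        attractor=attractor, n_steps=sol.t.size, params=g,
    )


def find_attractor(
    g: GameParams,
    s0: Sequence[float],
    budgets: Sequence[float] = (1e2, 1e3, 1e4),
    eps_conv: float = DEFAULT_EPS_CONV,
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
) -> AttractorResult:
    """Run the flow with escalating time budgets until the vector field's
    sup-norm drops below ``eps_conv``.  Non-convergence within the total
    budget is reported, never silently rounded to a nearby point."""
    state = tuple(_validate_state(s0))
    t_total = 0.0
    n_steps = 0
    for t_end in budgets:
        traj = integrate(g, state, t_end, rtol=rtol, atol=atol, eps_conv=eps_conv)
        t_total += float(traj.times[-1])
        n_steps += traj.n_steps
        state = traj.final_state()
        if traj.converged:
            return AttractorResult(state=state, converged=True,
                                   t_total=t_total, n_steps=n_steps)
    return AttractorResult(state=state, converged=False,
                           t_total=t_total, n_steps=n_steps)


def write_trajectory_csv(traj: Trajectory, path) -> None:
    """Write a trajectory as CSV with columns t, p, q."""
    arr = np.column_stack([traj.times, traj.states])
    header = "t,p,q"
    np.savetxt(path, arr, delimiter=",", header=header, comments="")
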