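"""Basins of attraction, parameter sweeps and discontinuous-transition detection.

Outcome labels name the socially meaningful attractors of the (p, q) square:

* ``norm_pop1``   -> (1, 0): everybody adopts population 1's preferred behavior;
* ``norm_pop2``   -> (0, 1): everybody adopts population 2's preferred behavior;
* ``subcultures`` -> (1, 1): each population keeps its own preferred behavior;
* ``breakdown``   -> (0, 0): everybody abandons its preferred behavior
  (mutual defection in the prisoner's dilemma reading);
* ``mixed_edge``  -> any other discrete attractor (polarized states such as
  the snowdrift edge equilibria (u, 0) and (v, 1));
* ``continuum``   -> convergence onto a line of equilibria;
* ``unresolved``  -> the trajectory did not converge within the budget.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .games import GameParams, params_from_benefit_coordination
from .equilibria import EquilibriumSet, enumerate_fixed_points
from .replicator import find_attractor

__all__ = [
    "OUTCOME_LABELS",
    "BasinGrid",
    "SweepResult",
    "basin_map",
    "label_outcome",
    "phase_diagram_norms",
    "sweep",
    "movie_sweep",
    "detect_discontinuity",
    "overall_cooperation",
    "MATCH_TOL",
    "JUMP_TOL",
]

MATCH_TOL = 1e-3
JUMP_TOL = 0.5
#: perturbation applied to stationary starting corners in phase-diagram sweeps
DEFAULT_EPSILON = 1e-3

OUTCOME_LABELS = (
    "breakdown", "norm_pop1", "norm_pop2", "subcultures",
    "mixed_edge", "continuum", "unresolved",
)

_CORNER_LABELS = {
    (0, 0): "breakdown",
    (1, 0): "norm_pop1",
    (0, 1): "norm_pop2",
    (1, 1): "subcultures",
}


def overall_cooperation(g: GameParams, s: Sequence[float]) -> float:
    """Population-weighted fraction showing behavior 1 (cooperative from
    population 1's viewpoint): f*p + (1-f)*(1-q)."""
    p, q = float(s[0]), float(s[1])
    return g.f * p + (1.0 - g.f) * (1.0 - q)


def label_outcome(
    state: Sequence[float],
    eq: Optional[EquilibriumSet] = None,
    converged: bool = True,
    match_tol: float = MATCH_TOL,
) -> str:
    """Classify an attractor state into an outcome label.

    A label is assigned only when the state lies within ``match_tol`` of the
    named point (or of the continuum segment); non-converged states are
    ``unresolved``."""
    if not converged:
        return "unresolved"
    p, q = float(state[0]), float(state[1])
    for corner, name in _CORNER_LABELS.items():
        if np.hypot(p - corner[0], q - corner[1]) <= match_tol:
            return name
    if eq is not None:
        if eq.continuum is not None and eq.continuum.distance(p, q) <= match_tol:
            return "continuum"
        for fp in eq.stable_points():
            if np.hypot(p - fp.location[0], q - fp.location[1]) <= match_tol:
                return "mixed_edge"
    return "unresolved"


@dataclass
class BasinGrid:
    """Grid of initial conditions labeled by the attractor they reach."""

    n: int
    p0: np.ndarray  # length n
    q0: np.ndarray  # length n
    labels: np.ndarray  # shape (n, n), labels[i, j] for (p0[j], q0[i])
    endpoints: np.ndarray  # shape (n, n, 2): attractor coordinates
    params: GameParams
    n_unresolved: int = 0

    def fractions(self) -> dict:
        vals, counts = np.unique(self.labels, return_counts=True)
        total = self.labels.size
        return {str(v): int(c) / total for v, c in zip(vals, counts)}

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for i, q0 in enumerate(self.q0):
            for j, p0 in enumerate(self.p0):
                rows.append({
                    "p0": p0, "q0": q0,
                    "label": self.labels[i, j],
                    "p_star": self.endpoints[i, j, 0],
                    "q_star": self.endpoints[i, j, 1],
                })
        return pd.DataFrame(rows)

    def plot(self, path) -> None:
        """Heat map of outcome labels (PNG)."""
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
        from matplotlib.colors import ListedColormap

        palette = {
            "breakdown": "#d62728", "norm_pop1": "#2ca02c",
            "norm_pop2": "#1f77b4", "subcultures": "#ffdd44",
            "mixed_edge": "#fa8072", "continuum": "#9467bd",
            "unresolved": "#7f7f7f",
        }
        idx = np.vectorize({k: i for i, k in enumerate(OUTCOME_LABELS)}.get)(self.labels)
        cmap = ListedColormap([palette[k] for k in OUTCOME_LABELS])
        fig, ax = plt.subplots(figsize=(5, 4.5))
        ax.imshow(idx, origin="lower", extent=(0, 1, 0, 1), cmap=cmap,
                  vmin=-0.5, vmax=len(OUTCOME_LABELS) - 0.5, aspect="equal")
        ax.set_xlabel("p(0)")
        ax.set_ylabel("q(0)")
        present = sorted(set(self.labels.ravel()))
        handles = [plt.Rectangle((0, 0), 1, 1, color=palette[k]) for k in present]
        ax.legend(handles, present, loc="center left", bbox_to_anchor=(1.02, 0.5),
                  fontsize=8)
        fig.tight_layout()
        fig.savefig(path, dpi=150)
        plt.close(fig)


def basin_map(
    g: GameParams,
    n: int = 21,
    eq: Optional[EquilibriumSet] = None,
    match_tol: float = MATCH_TOL,
) -> BasinGrid:
    """Integrate from every point of an n x n lattice over [0,1]^2 (edges and
    corners included; they are invariant and label themselves) and label each
    cell by the attractor it reaches."""
    if n < 3:
        raise ValueError("grid size must be >= 3")
    if eq is None:
        eq = enumerate_fixed_points(g)
    p_vals = np.linspace(0.0, 1.0, n)
    q_vals = np.linspace(0.0, 1.0, n)
    labels = np.empty((n, n), dtype=object)
    endpoints = np.empty((n, n, 2))
    n_unresolved = 0
    for i, q0 in enumerate(q_vals):
        for j, p0 in enumerate(p_vals):
            res = find_attractor(g, (p0, q0))
            endpoints[i, j] = res.state
            lab = label_outcome(res.state, eq, converged=res.converged,
                                match_tol=match_tol)
            labels[i, j] = lab
            if lab == "unresolved":
                n_unresolved += 1
    return BasinGrid(n=n, p0=p_vals, q0=q_vals, labels=labels,
                     endpoints=endpoints, params=g, n_unresolved=n_unresolved)


def phase_diagram_norms(
    f_values: Sequence[float],
    b_over_c_values: Sequence[float],
    epsilon: float = DEFAULT_EPSILON,
    c: float = 1.0,
) -> pd.DataFrame:
    """Norm-formation phase diagram over power f and benefit ratio b/c.

    For each (f, b/c), shorthand parameters are built from the
    benefit/coordination payoffs (B = b - c, C = b + c) and the flow is
    started at (1 - eps, 1 - eps): everybody initially shows the behavior it
    prefers, infinitesimally perturbed because (1, 1) itself is stationary.
    Returns a tidy DataFrame with columns f, b_over_c, B, C, p_star, q_star,
    label.
    """
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    rows = []
    for ratio in b_over_c_values:
        b = ratio * c
        _, B, C = params_from_benefit_coordination(b, c, "conformity")
        for f in f_values:
            if not 0.0 < f < 1.0:
                raise ValueError("f values must lie strictly inside (0, 1)")
            g = GameParams.shorthand(B, C, f)
            eq = enumerate_fixed_points(g)
            res = find_attractor(g, (1.0 - epsilon, 1.0 - epsilon))
            rows.append({
                "f": f, "b_over_c": ratio, "B": B, "C": C,
                "p_star": res.state[0], "q_star": res.state[1],
                "label": label_outcome(res.state, eq, converged=res.converged),
            })
    return pd.DataFrame(rows)


@dataclass
class SweepResult:
    """Attractor record along a strictly monotone parameter sweep."""

    param_name: str
    values: np.ndarray
    p_star: np.ndarray
    q_star: np.ndarray
    labels: List[str]
    converged: np.ndarray
    start: Tuple[float, float]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({
            self.param_name: self.values,
            "p_star": self.p_star,
            "q_star": self.q_star,
            "label": self.labels,
            "converged": self.converged,
        })


def sweep(
    param_name: str,
    values: Sequence[float],
    make_params: Callable[[float], GameParams],
    start: Sequence[float] = (0.5, 0.5),
) -> SweepResult:
    """Record the attractor reached from a fixed start for each value of a
    swept parameter."""
    values = np.asarray(values, dtype=float)
    if values.size >= 2 and not (np.all(np.diff(values) > 0)
                                 or np.all(np.diff(values) < 0)):
        raise ValueError("sweep values must be strictly monotone")
    p_star = np.empty(values.size)
    q_star = np.empty(values.size)
    conv = np.zeros(values.size, dtype=bool)
    labels: List[str] = []
    for k, v in enumerate(values):
        g = make_params(float(v))
        eq = enumerate_fixed_points(g)
        res = find_attractor(g, start)
        p_star[k], q_star[k] = res.state
        conv[k] = res.converged
        labels.append(label_outcome(res.state, eq, converged=res.converged))
    return SweepResult(param_name=param_name, values=values, p_star=p_star,
                       q_star=q_star, labels=labels, converged=conv,
                       start=(float(start[0]), float(start[1])))


def movie_sweep(
    f: float,
    B_values: Optional[Sequence[float]] = None,
    start: Sequence[float] = (0.5, 0.5),
    n_values: int = 101,
) -> SweepResult:
    """Shorthand sweep with the cubic coupling C = -B^3: as B crosses the
    |B| = |C| locus inside the snowdrift quadrant the weaker population's
    equilibrium coordinate jumps discontinuously (the "revolutionary"
    transition)."""
    if B_values is None:
        B_values = np.linspace(-1.5, 1.5, n_values)
    return sweep(
        "B", B_values,
        lambda B: GameParams.shorthand(B, -B ** 3, f),
        start=start,
    )


def detect_discontinuity(
    sr: SweepResult,
    coordinate: str = "q",
    jump_tol: float = JUMP_TOL,
) -> List[Tuple[float, float]]:
    """Parameter intervals (v_k, v_{k+1}) across which the recorded attractor
    coordinate jumps by more than ``jump_tol``.  Non-converged entries never
    participate in a detected jump."""
    if coordinate not in ("p", "q"):
        raise ValueError("coordinate must be 'p' or 'q'")
    coord = sr.p_star if coordinate == "p" else sr.q_star
    loci: List[Tuple[float, float]] = []
    for k in range(coord.size - 1):
        if not (sr.converged[k] and sr.converged[k + 1]):
            continue
        if abs(coord[k + 1] - coord[k]) > jump_tol:
            loci.append((float(sr.values[k]), float(sr.values[k + 1])))
    return loci
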