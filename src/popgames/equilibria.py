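"""Analytic enumeration and stability classification of stationary states.

Because the growth brackets G1, G2 are affine in (p, q), every stationary
state of the flow can be found in closed form:

* the four corners of the unit square (always stationary);
* points in the interior of an edge where the tangential bracket vanishes
  (one linear solve per edge);
* an interior point where both brackets vanish (a 2x2 linear solve), or a
  whole line of stationary states when the two zero-sets coincide (the
  rank-1, consistent case) -- e.g. for |B| = |C| in the shorthand model the
  line f(1-2p) + (1-f)(2q-1) = 0 carries a continuum of equilibria.

Stability is read off the eigenvalues of the closed-form Jacobian; edge and
corner points use the full 2D Jacobian so that transversally unstable edge
points are correctly reported as saddles.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np

from .games import GameParams
from .replicator import bracket_coefficients, growth_brackets, rhs

__all__ = [
    "FixedPoint",
    "ContinuumLine",
    "EquilibriumSet",
    "enumerate_fixed_points",
    "jacobian",
    "classify_stability",
    "nash_check",
    "HYPERBOLICITY_TOL",
]

#: eigenvalue real parts within this of zero make a point nonhyperbolic
HYPERBOLICITY_TOL = 1e-8
#: residual bound: every reported point must satisfy sup|rhs| < this
RESIDUAL_TOL = 1e-10
#: determinant threshold (on sup-norm-normalized rows) for coincident zero-sets
COINCIDENCE_TOL = 1e-10
#: minimum separation between distinct reported points
SEPARATION_TOL = 1e-8


@dataclass
class FixedPoint:
    location: Tuple[float, float]
    kind: str  # "corner" | "edge" | "interior"
    eigenvalues: Tuple[complex, complex]
    stability: str  # "stable" | "unstable" | "saddle" | "nonhyperbolic"

    def to_dict(self) -> dict:
        return {
            "p": self.location[0],
            "q": self.location[1],
            "kind": self.kind,
            "eigenvalues": [[ev.real, ev.imag] for ev in self.eigenvalues],
            "stability": self.stability,
        }


@dataclass
class ContinuumLine:
    """Affine line a*p + b*q = c of stationary states, clipped to the unit
    square.  ``transverse_stability`` labels the sign of the nonzero
    eigenvalue across the line (the tangential one is zero)."""

    a: float
    b: float
    c: float
    endpoints: List[Tuple[float, float]]
    transverse_stability: str = "nonhyperbolic"

    def signed_residual(self, p, q):
        norm = float(np.hypot(self.a, self.b))
        return (self.a * np.asarray(p) + self.b * np.asarray(q) - self.c) / norm

    def distance(self, p: float, q: float) -> float:
        """Euclidean distance from (p, q) to the clipped segment."""
        (p0, q0), (p1, q1) = self.endpoints[0], self.endpoints[-1]
        d = np.array([p1 - p0, q1 - q0])
        L2 = float(d @ d)
        if L2 == 0.0:
            return float(np.hypot(p - p0, q - q0))
        t = float(np.clip(((p - p0) * d[0] + (q - q0) * d[1]) / L2, 0.0, 1.0))
        proj = np.array([p0, q0]) + t * d
        return float(np.hypot(p - proj[0], q - proj[1]))

    def to_dict(self) -> dict:
        return {
            "a": self.a, "b": self.b, "c": self.c,
            "endpoints": [list(e) for e in self.endpoints],
            "transverse_stability": self.transverse_stability,
        }


@dataclass
class EquilibriumSet:
    points: List[FixedPoint]
    continuum: Optional[ContinuumLine] = None
    everywhere_stationary: bool = False

    def stable_points(self) -> List[FixedPoint]:
        return [fp for fp in self.points if fp.stability == "stable"]

    def to_report(self, params: Optional[GameParams] = None) -> dict:
        rep = {
            "fixed_points": [fp.to_dict() for fp in self.points],
            "continuum": self.continuum.to_dict() if self.continuum else None,
            "everywhere_stationary": self.everywhere_stationary,
        }
        if params is not None:
            rep["params"] = params.to_dict()
        return rep


def jacobian(g: GameParams, s) -> np.ndarray:
    """Closed-form Jacobian of (dp/dt, dq/dt) at state ``s = (p, q)``."""
    p, q = float(s[0]), float(s[1])
    A1, a1p, a1q, A2, a2p, a2q = bracket_coefficients(g)
    G1 = A1 + a1p * p + a1q * q
    G2 = A2 + a2p * p + a2q * q
    return np.array([
        [(1 - 2 * p) * G1 + p * (1 - p) * a1p, p * (1 - p) * a1q],
        [q * (1 - q) * a2p, (1 - 2 * q) * G2 + q * (1 - q) * a2q],
    ])


def classify_stability(J: np.ndarray, tol: float = HYPERBOLICITY_TOL):
    """Stability label from the Jacobian eigenvalue real parts.

    Returns (label, eigenvalues).  Any real part within ``tol`` of zero makes
    the point nonhyperbolic; otherwise both negative -> stable, both positive
    -> unstable, mixed signs -> saddle.
    """
    if not np.all(np.isfinite(J)):
        raise ValueError("Jacobian has non-finite entries")
    eigs = np.linalg.eigvals(J)
    re = np.real(eigs)
    if np.any(np.abs(re) <= tol):
        label = "nonhyperbolic"
    elif np.all(re < -tol):
        label = "stable"
    elif np.all(re > tol):
        label = "unstable"
    else:
        label = "saddle"
    return label, (complex(eigs[0]), complex(eigs[1]))


def _clip_line_to_square(a: float, b: float, c: float) -> List[Tuple[float, float]]:
    """Intersection points of a*p + b*q = c with the unit square boundary."""
    pts = []
    # edges q=0, q=1 -> solve for p; edges p=0, p=1 -> solve for q
    if abs(a) > 0:
        for q0 in (0.0, 1.0):
            p0 = (c - b * q0) / a
            if -1e-12 <= p0 <= 1 + 1e-12:
                pts.append((min(max(p0, 0.0), 1.0), q0))
    if abs(b) > 0:
        for p0 in (0.0, 1.0):
            q0 = (c - a * p0) / b
            if -1e-12 <= q0 <= 1 + 1e-12:
                pts.append((p0, min(max(q0, 0.0), 1.0)))
    # dedupe
    uniq: List[Tuple[float, float]] = []
    for pt in pts:
        if all(np.hypot(pt[0] - u[0], pt[1] - u[1]) > 1e-9 for u in uniq):
            uniq.append(pt)
    if len(uniq) < 2:
        return []
    # order along the line and keep the extremes
    d = np.array([uniq[-1][0] - uniq[0][0], uniq[-1][1] - uniq[0][1]])
    ts = [float(np.array([u[0] - uniq[0][0], u[1] - uniq[0][1]]) @ d) for u in uniq]
    lo, hi = uniq[int(np.argmin(ts))], uniq[int(np.argmax(ts))]
    return [lo, hi]


def _normalize_row(coeffs: Tuple[float, float, float]) -> Tuple[float, float, float]:
    s = max(abs(x) for x in coeffs)
    if s == 0.0:
        return coeffs
    return tuple(x / s for x in coeffs)  # type: ignore[return-value]


def _continuum(g: GameParams) -> Optional[ContinuumLine]:
    """Detect a shared zero-line of both growth brackets."""
    A1, a1p, a1q, A2, a2p, a2q = bracket_coefficients(g)
    r1 = _normalize_row((a1p, a1q, A1))
    r2 = _normalize_row((a2p, a2q, A2))
    triv1 = max(abs(x) for x in (a1p, a1q, A1)) <= COINCIDENCE_TOL
    triv2 = max(abs(x) for x in (a2p, a2q, A2)) <= COINCIDENCE_TOL
    if triv1 and triv2:
        return None  # handled as everywhere_stationary by the caller
    if triv1 or triv2:
        # one bracket vanishes identically: the other's zero line is stationary
        ap, aq, A = (a2p, a2q, A2) if triv1 else (a1p, a1q, A1)
    else:
        det = r1[0] * r2[1] - r1[1] * r2[0]
        aug1 = r1[0] * (-r2[2]) - (-r1[2]) * r2[0]
        aug2 = r1[1] * (-r2[2]) - (-r1[2]) * r2[1]
        if max(abs(det), abs(aug1), abs(aug2)) > COINCIDENCE_TOL:
            return None
        ap, aq, A = (a1p, a1q, A1)
    if max(abs(ap), abs(aq)) <= COINCIDENCE_TOL:
        return None  # "line" would be empty or everything
    endpoints = _clip_line_to_square(ap, aq, -A)
    if not endpoints:
        return None
    scale = max(abs(ap), abs(aq), abs(A))
    line = ContinuumLine(a=ap / scale, b=aq / scale, c=-A / scale,
                         endpoints=endpoints)
    # transverse stability from the Jacobian at the segment midpoint
    mid = (np.array(endpoints[0]) + np.array(endpoints[1])) / 2.0
    eigs = np.linalg.eigvals(jacobian(g, mid))
    re = sorted(np.real(eigs), key=abs)  # [~0, transverse]
    trans = re[-1]
    if trans < -HYPERBOLICITY_TOL:
        line.transverse_stability = "stable"
    elif trans > HYPERBOLICITY_TOL:
        line.transverse_stability = "unstable"
    return line


def enumerate_fixed_points(g: GameParams) -> EquilibriumSet:
    """All stationary states: corners, edge solves, interior solve or
    continuum.  Every returned point is re-checked to have residual
    sup|rhs| < 1e-10."""
    A1, a1p, a1q, A2, a2p, a2q = bracket_coefficients(g)
    candidates: List[Tuple[Tuple[float, float], str]] = [
        ((0.0, 0.0), "corner"), ((1.0, 0.0), "corner"),
        ((0.0, 1.0), "corner"), ((1.0, 1.0), "corner"),
    ]
    interior_margin = 1e-9

    # edge q=0 and q=1: solve G1 affine in p
    for q0 in (0.0, 1.0):
        const = A1 + a1q * q0
        if abs(a1p) > COINCIDENCE_TOL:
            p0 = -const / a1p
            if interior_margin < p0 < 1 - interior_margin:
                candidates.append(((p0, q0), "edge"))
    # edge p=0 and p=1: solve G2 affine in q
    for p0 in (0.0, 1.0):
        const = A2 + a2p * p0
        if abs(a2q) > COINCIDENCE_TOL:
            q0 = -const / a2q
            if interior_margin < q0 < 1 - interior_margin:
                candidates.append(((p0, q0), "edge"))

    everywhere = (max(abs(x) for x in (a1p, a1q, A1)) <= COINCIDENCE_TOL
                  and max(abs(x) for x in (a2p, a2q, A2)) <= COINCIDENCE_TOL)
    continuum = None if everywhere else _continuum(g)

    # interior: unique solution of the 2x2 affine system when nondegenerate
    if continuum is None and not everywhere:
        r1 = _normalize_row((a1p, a1q, A1))
        r2 = _normalize_row((a2p, a2q, A2))
        det_n = r1[0] * r2[1] - r1[1] * r2[0]
        if abs(det_n) > COINCIDENCE_TOL:
            det = a1p * a2q - a1q * a2p
            p0 = (-A1 * a2q + A2 * a1q) / det
            q0 = (-A2 * a1p + A1 * a2p) / det
            if (interior_margin < p0 < 1 - interior_margin
                    and interior_margin < q0 < 1 - interior_margin):
                candidates.append(((p0, q0), "interior"))

    points: List[FixedPoint] = []
    for loc, kind in candidates:
        dp, dq = rhs(g, loc[0], loc[1])
        if max(abs(float(dp)), abs(float(dq))) >= RESIDUAL_TOL:
            continue
        if any(np.hypot(loc[0] - fp.location[0], loc[1] - fp.location[1])
               < SEPARATION_TOL for fp in points):
            continue
        label, eigs = classify_stability(jacobian(g, loc))
        points.append(FixedPoint(location=loc, kind=kind,
                                 eigenvalues=eigs, stability=label))

    return EquilibriumSet(points=points, continuum=continuum,
                          everywhere_stationary=everywhere)


def nash_check(g: GameParams, fp: FixedPoint, tol: float = 1e-9) -> bool:
    """True if no unilateral pure-behavior deviation improves the expected
    payoff of either population's representative individual at the point.

    For population 1 this reduces to sign conditions on G1: an interior
    mixture requires G1 = 0; p = 1 requires G1 >= 0; p = 0 requires G1 <= 0
    (analogously for population 2 and G2), all within ``tol``.
    """
    p, q = fp.location
    G1, G2 = growth_brackets(g, p, q)
    G1, G2 = float(G1), float(G2)

    def ok(x: float, G: float) -> bool:
        if x >= 1.0 - tol:
            return G >= -tol
        if x <= tol:
            return G <= tol
        return abs(G) <= tol

    return ok(p, G1) and ok(q, G2)
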