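"""Equilibria, stability, regime classification, and attractor prediction.

The replicator system always has the four corner fixed points E(0,0),
S(0,1), N(1,0), K(1,1); an interior fixed point P(x*, y*) exists when both
coordinates lie strictly inside (0, 1).  Writing the patient-side numerator
and denominator as

    A2 = C2 - g K0 - N1 + P2 + beta2 N1 + N0,   B2 = -H + (1-alpha) M - R2 - g K0 + f N0,

and the doctor-side pair as

    A1 = C1 - f N0 - K1 + P1 + beta1 K1 + K0,   B1 = H + alpha M - R1 + g K0 - f N0,

the interior point is x* = A2 / B2, y* = A1 / B1.  Three parameter regimes
are distinguished by the sign/order structure of these four values:

* case 1 (A2 > B2 > 0 and A1 > B1 > 0): honesty dominates; the origin is
  the unique evolutionarily stable state.
* case 2 (A1 < 0, A2 < 0, B1 > 0, B2 > 0): fraud dominates; (1,1) is the
  unique evolutionarily stable state.
* case 3 (0 < A2 < B2 and 0 < A1 < B1): bistable; both (0,0) and (1,1) are
  stable and the interior point is a saddle whose position partitions the
  unit square into the two basins.

Stability of a fixed point follows the planar determinant/trace criterion:
det > 0 with trace < 0 is asymptotically stable (an ESS of the game),
det > 0 with trace > 0 is unstable, det < 0 is a saddle, and det > 0 with
zero trace is treated as a saddle by convention.

In the bistable regime the long-run outcome from uninformative initial
conditions is predicted by a quadrilateral-area rule: the unit square is
split by the saddle into the quadrilateral S-E-N-P (basin proxy of the
honest corner, shoelace area (x* + y*)/2) and its complement; the corner
with the larger share is predicted to absorb the population.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model_core import (
    GameParameters,
    StrategyState,
    bracket_coefficients,
    replicator_rhs,
)

__all__ = [
    "CORNERS",
    "SIGN_TOL",
    "NotAnEquilibriumError",
    "RegimeError",
    "InteriorEquilibrium",
    "EquilibriumReport",
    "CaseLabel",
    "AttractorPrediction",
    "condition_values",
    "interior_equilibrium",
    "enumerate_equilibria",
    "jacobian",
    "classify_point",
    "classify_equilibria",
    "classify_case",
    "area_rule",
    "predict_attractor",
]

#: The four corner fixed points, in conventional order E, S, N, K.
CORNERS = ((0.0, 0.0), (0.0, 1.0), (1.0, 0.0), (1.0, 1.0))

#: Tolerance for every sign test on determinants, traces and case
#: inequalities; boundary hits are reported as indeterminate/other rather
#: than forced into a class.
SIGN_TOL = 1e-9


class NotAnEquilibriumError(ValueError):
    """classify_point was handed a state that is not a fixed point."""


class RegimeError(ValueError):
    """An operation requiring a specific parameter regime was misapplied."""


@dataclass(frozen=True)
class InteriorEquilibrium:
    """The interior fixed point candidate and its four condition values.

    ``exists`` is true only when both coordinates are finite and strictly
    inside (0, 1); the condition values are always reported, including for
    degenerate denominators (coordinates are then NaN).
    """

    x_star: float
    y_star: float
    A1: float
    B1: float
    A2: float
    B2: float
    exists: bool


@dataclass(frozen=True)
class EquilibriumReport:
    """A fixed point with its Jacobian, determinant, trace and label."""

    point: tuple[float, float]
    jacobian: tuple[tuple[float, float], tuple[float, float]]
    det: float
    trace: float
    label: str  # "ESS" | "unstable" | "saddle" | "indeterminate"


@dataclass(frozen=True)
class CaseLabel:
    """Which inequality regime a parameter set occupies."""

    case_id: str  # "case1" | "case2" | "case3" | "other"
    A1: float
    B1: float
    A2: float
    B2: float


@dataclass(frozen=True)
class AttractorPrediction:
    """Outcome of the quadrilateral-area rule in the bistable regime."""

    corner: tuple[float, float] | None  # (0,0), (1,1), or None if undetermined
    area_PSEN: float
    area_PSKN: float


def condition_values(p: GameParameters) -> tuple[float, float, float, float]:
    """The four regime condition values (A1, B1, A2, B2).

    Evaluated from their own closed forms (not via the replicator
    brackets), so tests can cross-check the algebraic identity
    A1 = -a1, B1 = b1, A2 = -a2, B2 = b2.
    """
    A1 = p.C1 - p.f * p.N0 - p.K1 + p.P1 + p.beta1 * p.K1 + p.K0
    B1 = p.H + p.alpha * p.M - p.R1 + p.g * p.K0 - p.f * p.N0
    A2 = p.C2 - p.g * p.K0 - p.N1 + p.P2 + p.beta2 * p.N1 + p.N0
    B2 = -p.H + (1.0 - p.alpha) * p.M - p.R2 - p.g * p.K0 + p.f * p.N0
    return A1, B1, A2, B2


def interior_equilibrium(p: GameParameters) -> InteriorEquilibrium:
    """The interior fixed point x* = A2/B2, y* = A1/B1, if it exists.

    Degenerate denominators or coordinates outside the open unit square are
    reported via ``exists=False`` rather than raised; the condition values
    are always populated.
    """
    A1, B1, A2, B2 = condition_values(p)
    x_star = A2 / B2 if abs(B2) > SIGN_TOL else float("nan")
    y_star = A1 / B1 if abs(B1) > SIGN_TOL else float("nan")
    exists = (
        np.isfinite(x_star) and np.isfinite(y_star)
        and SIGN_TOL < x_star < 1.0 - SIGN_TOL
        and SIGN_TOL < y_star < 1.0 - SIGN_TOL
    )
    return InteriorEquilibrium(x_star=x_star, y_star=y_star,
                               A1=A1, B1=B1, A2=A2, B2=B2, exists=bool(exists))


def enumerate_equilibria(p: GameParameters) -> list[tuple[float, float]]:
    """All fixed points: the four corners, plus the interior point if any."""
    points = [tuple(c) for c in CORNERS]
    interior = interior_equilibrium(p)
    if interior.exists:
        points.append((interior.x_star, interior.y_star))
    return points


def jacobian(p: GameParameters, s: StrategyState) -> np.ndarray:
    """Analytic Jacobian of the replicator field at state ``s``.

    With F = x(1-x)(a1 + b1 y) and G = y(1-y)(a2 + b2 x):

        dF/dx = (1 - 2x)(a1 + b1 y)      dF/dy = x(1-x) b1
        dG/dx = y(1-y) b2                dG/dy = (1 - 2y)(a2 + b2 x)
    """
    a1, b1, a2, b2 = bracket_coefficients(p)
    x, y = s.x, s.y
    return np.array([
        [(1.0 - 2.0 * x) * (a1 + b1 * y), x * (1.0 - x) * b1],
        [y * (1.0 - y) * b2, (1.0 - 2.0 * y) * (a2 + b2 * x)],
    ])


def classify_point(p: GameParameters, point: tuple[float, float], *,
                   eq_tol: float = 1e-8, tol: float = SIGN_TOL) -> EquilibriumReport:
    """Stability label of a fixed point via the determinant/trace criterion.

    Raises :class:`NotAnEquilibriumError` (reporting the field magnitude)
    if ``point`` is not a fixed point to within ``eq_tol``.
    """
    s = StrategyState(x=point[0], y=point[1])
    v = replicator_rhs(p, s)
    speed = float(np.hypot(v.F, v.G))
    if speed > eq_tol:
        raise NotAnEquilibriumError(
            f"point {point} is not an equilibrium: |(F, G)| = {speed:.3e}")
    J = jacobian(p, s)
    det = float(np.linalg.det(J))
    trace = float(np.trace(J))
    if abs(det) <= tol:
        label = "indeterminate"
    elif det < -tol:
        label = "saddle"
    elif trace < -tol:
        label = "ESS"
    elif trace > tol:
        label = "unstable"
    else:  # det > 0, trace within tolerance of zero: saddle by convention
        label = "saddle"
    return EquilibriumReport(
        point=(float(point[0]), float(point[1])),
        jacobian=tuple(tuple(row) for row in J.tolist()),
        det=det, trace=trace, label=label,
    )


def classify_equilibria(p: GameParameters) -> list[EquilibriumReport]:
    """Classify every fixed point of the system."""
    return [classify_point(p, pt) for pt in enumerate_equilibria(p)]


def classify_case(p: GameParameters, *, tol: float = SIGN_TOL) -> CaseLabel:
    """Identify the inequality regime of a parameter set.

    Strict inequalities are tested with tolerance ``tol``; parameter sets on
    a regime boundary are labelled ``other``.
    """
    A1, B1, A2, B2 = condition_values(p)
    if (B2 > tol and A2 > B2 + tol and B1 > tol and A1 > B1 + tol):
        case_id = "case1"
    elif (A1 < -tol and B1 > tol and A2 < -tol and B2 > tol):
        case_id = "case2"
    elif (tol < A2 < B2 - tol and tol < A1 < B1 - tol):
        case_id = "case3"
    else:
        case_id = "other"
    return CaseLabel(case_id=case_id, A1=A1, B1=B1, A2=A2, B2=B2)


def area_rule(x_star: float, y_star: float, *, tol: float = 1e-9) -> AttractorPrediction:
    """Quadrilateral-area comparison for a saddle at (x*, y*).

    The quadrilateral with vertices S(0,1), E(0,0), N(1,0), P(x*,y*) has
    shoelace area (x* + y*)/2; its complement in the unit square has area
    1 - (x* + y*)/2.  The corner bordering the larger region is predicted:
    K(1,1) when the S-E-N-P area is smaller, E(0,0) when larger, undetermined
    (``corner=None``) at equality within ``tol``.
    """
    verts = np.array([(0.0, 1.0), (0.0, 0.0), (1.0, 0.0), (x_star, y_star)])
    xs, ys = verts[:, 0], verts[:, 1]
    area_psen = 0.5 * abs(np.dot(xs, np.roll(ys, -1)) - np.dot(np.roll(xs, -1), ys))
    area_pskn = 1.0 - area_psen
    if area_psen < area_pskn - tol:
        corner: tuple[float, float] | None = (1.0, 1.0)
    elif area_psen > area_pskn + tol:
        corner = (0.0, 0.0)
    else:
        corner = None
    return AttractorPrediction(corner=corner, area_PSEN=float(area_psen),
                               area_PSKN=float(area_pskn))


def predict_attractor(p: GameParameters) -> AttractorPrediction:
    """Predict the long-run corner in the bistable regime via the area rule.

    Raises :class:`RegimeError` outside case 3, where the rule is undefined
    (the unique ESS is the attractor there).
    """
    label = classify_case(p)
    if label.case_id != "case3":
        raise RegimeError(
            f"attractor prediction requires the bistable regime (case3); "
            f"parameters are {label.case_id}")
    interior = interior_equilibrium(p)
    return area_rule(interior.x_star, interior.y_star)
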