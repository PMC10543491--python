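"""Numerical integration of the replicator system and basin mapping.

The vector field is a smooth cubic polynomial on the unit square, with the
square's edges invariant; a fixed-step classical Runge-Kutta (RK4) scheme
is ample.  Trajectories started strictly inside the square stay inside up
to roundoff; states are clamped back onto the square after each step and an
error is raised if the clamp ever exceeds ``CLAMP_TOL`` (a symptom of too
large a step, not of the model).

Convergence is declared when the state comes within ``convergence_tol``
(Euclidean) of one of the four corners.  A trajectory whose velocity drops
below ``stall_tol`` away from any corner is reported as an interior stall
(it started at, or rode the stable manifold into, the interior saddle).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model_core import GameParameters, StrategyState, bracket_coefficients

__all__ = [
    "CLAMP_TOL",
    "SolverConfig",
    "Trajectory",
    "BasinSummary",
    "StepSizeError",
    "NumericError",
    "integrate",
    "detect_convergence",
    "basin_map",
    "terminal_states",
]

#: Maximum distance a state may be clamped back onto the unit square per
#: step before the step size is declared too coarse.
CLAMP_TOL = 1e-9

_CORNERS = np.array([(0.0, 0.0), (0.0, 1.0), (1.0, 0.0), (1.0, 1.0)])


class StepSizeError(RuntimeError):
    """A step carried the state off the unit square by more than CLAMP_TOL."""


class NumericError(RuntimeError):
    """The state became non-finite during integration."""


@dataclass(frozen=True)
class SolverConfig:
    """Fixed-step RK4 solver settings.

    ``dt`` is the integration step in replicator time units;
    ``convergence_tol`` the Euclidean distance to a corner at which the run
    is declared converged; ``stall_tol`` the velocity norm below which an
    interior state is declared stalled.
    """

    dt: float = 0.01
    max_steps: int = 100_000
    convergence_tol: float = 1e-3
    stall_tol: float = 1e-10

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError(f"dt must be positive, got {self.dt}")
        if self.max_steps < 1:
            raise ValueError(f"max_steps must be >= 1, got {self.max_steps}")
        if self.convergence_tol <= 0 or self.stall_tol <= 0:
            raise ValueError("tolerances must be positive")


@dataclass(frozen=True)
class Trajectory:
    """A sampled solution path with its terminal status.

    ``status`` is one of ``"converged"`` (within ``convergence_tol`` of the
    ``corner``), ``"interior-stall"``, or ``"max-steps"``.  ``steps`` is the
    number of RK4 steps actually taken.
    """

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    status: str
    corner: tuple[float, float] | None
    steps: int

    @property
    def final_state(self) -> tuple[float, float]:
        return float(self.x[-1]), float(self.y[-1])


@dataclass(frozen=True)
class BasinSummary:
    """Fractions of a grid of initial conditions absorbed by each corner."""

    grid: int
    fractions: dict[tuple[float, float], float]
    unresolved: float = 0.0

    def __post_init__(self) -> None:
        total = sum(self.fractions.values()) + self.unresolved
        if abs(total - 1.0) > 1e-12:
            raise ValueError(f"basin fractions must sum to 1, got {total}")


def _rk4_step(x: np.ndarray, y: np.ndarray, dt: float,
              a1: float, b1: float, a2: float, b2: float) -> tuple[np.ndarray, np.ndarray]:
    def f(x, y):
        return x * (1.0 - x) * (a1 + b1 * y), y * (1.0 - y) * (a2 + b2 * x)

    k1x, k1y = f(x, y)
    k2x, k2y = f(x + 0.5 * dt * k1x, y + 0.5 * dt * k1y)
    k3x, k3y = f(x + 0.5 * dt * k2x, y + 0.5 * dt * k2y)
    k4x, k4y = f(x + dt * k3x, y + dt * k3y)
    return (x + dt * (k1x + 2 * k2x + 2 * k3x + k4x) / 6.0,
            y + dt * (k1y + 2 * k2y + 2 * k3y + k4y) / 6.0)


def _nearest_corner(x: float, y: float) -> tuple[tuple[float, float], float]:
    d = np.hypot(_CORNERS[:, 0] - x, _CORNERS[:, 1] - y)
    i = int(np.argmin(d))
    return (float(_CORNERS[i, 0]), float(_CORNERS[i, 1])), float(d[i])


def integrate(p: GameParameters, init: StrategyState,
              cfg: SolverConfig = SolverConfig()) -> Trajectory:
    """Integrate the replicator system forward from ``init``.

    ``init`` must lie strictly inside the unit square (the boundary is
    invariant, so boundary starts never leave it and would make corner
    convergence trivial or impossible).
    """
    if not (0.0 < init.x < 1.0 and 0.0 < init.y < 1.0):
        raise ValueError(
            f"initial state must be strictly inside (0,1)^2, got ({init.x}, {init.y})")
    a1, b1, a2, b2 = bracket_coefficients(p)
    dt = cfg.dt

    ts = [0.0]
    xs = [init.x]
    ys = [init.y]
    x, y = init.x, init.y
    status = "max-steps"
    corner: tuple[float, float] | None = None
    steps = 0

    for step in range(1, cfg.max_steps + 1):
        xn, yn = _rk4_step(np.float64(x), np.float64(y), dt, a1, b1, a2, b2)
        if not (np.isfinite(xn) and np.isfinite(yn)):
            raise NumericError(f"state became non-finite at step {step}")
        excess = max(0.0, -xn, xn - 1.0, -yn, yn - 1.0)
        if excess > CLAMP_TOL:
            raise StepSizeError(
                f"state left the unit square by {excess:.3e} at step {step}; "
                f"reduce dt (currently {dt})")
        x = float(min(max(xn, 0.0), 1.0))
        y = float(min(max(yn, 0.0), 1.0))
        ts.append(step * dt)
        xs.append(x)
        ys.append(y)
        steps = step

        c, dist = _nearest_corner(x, y)
        if dist <= cfg.convergence_tol:
            status, corner = "converged", c
            break
        Fx = x * (1.0 - x) * (a1 + b1 * y)
        Gy = y * (1.0 - y) * (a2 + b2 * x)
        if np.hypot(Fx, Gy) < cfg.stall_tol:
            status = "interior-stall"
            break

    return Trajectory(t=np.asarray(ts), x=np.asarray(xs), y=np.asarray(ys),
                      status=status, corner=corner, steps=steps)


def detect_convergence(traj: Trajectory, tol: float) -> tuple[float, float] | None:
    """The unique corner within ``tol`` of the trajectory's final state.

    ``tol`` must be below 0.5, otherwise two corners could match the same
    state and the answer would be ambiguous.
    """
    if tol >= 0.5:
        raise ValueError(f"tol must be < 0.5 to identify a unique corner, got {tol}")
    if traj.t.size == 0:
        raise ValueError("trajectory is empty")
    x, y = traj.final_state
    corner, dist = _nearest_corner(x, y)
    return corner if dist <= tol else None


def terminal_states(p: GameParameters, x0: np.ndarray, y0: np.ndarray,
                    cfg: SolverConfig = SolverConfig()
                    ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Batch-integrate many initial conditions without storing paths.

    Runs the same fixed-step RK4 on all points simultaneously, freezing each
    point once it converges to a corner or stalls.  Returns final ``x``,
    ``y``, an integer status array (0 = still running at max_steps,
    1 = converged, 2 = interior stall), and the step count at termination.
    """
    a1, b1, a2, b2 = bracket_coefficients(p)
    x = np.array(x0, dtype=float).ravel().copy()
    y = np.array(y0, dtype=float).ravel().copy()
    if np.any((x <= 0) | (x >= 1) | (y <= 0) | (y >= 1)):
        raise ValueError("all initial states must be strictly inside (0,1)^2")
    n = x.size
    status = np.zeros(n, dtype=np.int8)
    steps = np.full(n, cfg.max_steps, dtype=np.int64)
    active = np.ones(n, dtype=bool)

    for step in range(1, cfg.max_steps + 1):
        idx = np.flatnonzero(active)
        if idx.size == 0:
            break
        xa, ya = x[idx], y[idx]
        xn, yn = _rk4_step(xa, ya, cfg.dt, a1, b1, a2, b2)
        if not (np.all(np.isfinite(xn)) and np.all(np.isfinite(yn))):
            bad = idx[~(np.isfinite(xn) & np.isfinite(yn))][0]
            raise NumericError(
                f"state became non-finite at step {step} "
                f"for initial condition ({x0.ravel()[bad]}, {y0.ravel()[bad]})")
        excess = np.maximum.reduce([np.zeros_like(xn), -xn, xn - 1.0, -yn, yn - 1.0])
        worst = int(np.argmax(excess))
        if excess[worst] > CLAMP_TOL:
            bad = idx[worst]
            raise StepSizeError(
                f"state left the unit square by {excess[worst]:.3e} at step {step} "
                f"for initial condition ({x0.ravel()[bad]}, {y0.ravel()[bad]}); "
                f"reduce dt (currently {cfg.dt})")
        xn = np.clip(xn, 0.0, 1.0)
        yn = np.clip(yn, 0.0, 1.0)
        x[idx], y[idx] = xn, yn

        dist2 = np.minimum.reduce([
            xn**2 + yn**2, xn**2 + (1 - yn)**2,
            (1 - xn)**2 + yn**2, (1 - xn)**2 + (1 - yn)**2,
        ])
        conv = dist2 <= cfg.convergence_tol**2
        Fn = xn * (1.0 - xn) * (a1 + b1 * yn)
        Gn = yn * (1.0 - yn) * (a2 + b2 * xn)
        stall = ~conv & (np.hypot(Fn, Gn) < cfg.stall_tol)
        done = conv | stall
        if np.any(done):
            di = idx[done]
            status[di] = np.where(conv[done], 1, 2)
            steps[di] = step
            active[di] = False

    return x, y, status, steps


def basin_map(p: GameParameters, n: int,
              cfg: SolverConfig = SolverConfig()) -> BasinSummary:
    """Fraction of an n x n interior grid of starts absorbed by each corner.

    Grid nodes are placed uniformly strictly inside the square (the exact
    boundary is a fixed line of the dynamics and is excluded).  Starts that
    neither converge nor stall within ``max_steps``, or that stall in the
    interior, count toward ``unresolved``.
    """
    if n < 3:
        raise ValueError(f"grid resolution must be >= 3, got {n}")
    g = np.linspace(0.0, 1.0, n + 2)[1:-1]
    X, Y = np.meshgrid(g, g)
    xf, yf, status, _ = terminal_states(p, X.ravel(), Y.ravel(), cfg)

    total = xf.size
    fractions: dict[tuple[float, float], float] = {}
    resolved = 0
    for cx, cy in _CORNERS:
        hit = (status == 1) & (np.hypot(xf - cx, yf - cy) <= cfg.convergence_tol)
        fractions[(float(cx), float(cy))] = hit.sum() / total
        resolved += int(hit.sum())
    return BasinSummary(grid=n, fractions=fractions,
                        unresolved=(total - resolved) / total)
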