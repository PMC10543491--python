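"""One-parameter sweep experiments over the replicator dynamics.

Each sweep varies a single model constant over a list of values, holding
every other constant at a common base (by default the reference baseline),
integrates the system from a shared initial state, and tabulates per value:
the regime, the interior saddle position, the area-rule prediction, and the
simulated terminal state with its step count.  "Terminal fraud frequency"
means the doctor frequency x (or patient frequency y) at convergence from
the shared start (0.5, 0.5) — the maximally uninformative strategy mix.

The nine built-in sweeps cover the policy levers: fraud costs C1/C2,
moral hazard f/g (down to the no-moral-hazard endpoint 0, which relaxes
the open-interval bound on f and g locally to these specs), penalties
P1/P2, rewards R1/R2, and the bribe H.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import pandas as pd

from .dynamics import SolverConfig, Trajectory, integrate
from .equilibria import (
    RegimeError,
    classify_case,
    interior_equilibrium,
    predict_attractor,
)
from .model_core import (
    PARAM_NAMES,
    GameParameters,
    ParameterValidationError,
    StrategyState,
)
from .scenarios import baseline_params

__all__ = [
    "SweepSpec",
    "SweepRecord",
    "SweepResult",
    "run_sweep",
    "builtin_figures",
]


@dataclass(frozen=True)
class SweepSpec:
    """A one-parameter sweep: base set, swept name, values, start, solver."""

    base: GameParameters
    param: str
    values: tuple[float, ...]
    init: StrategyState = StrategyState(0.5, 0.5)
    solver: SolverConfig = SolverConfig()
    allow_boundary: bool = False

    def __post_init__(self) -> None:
        if self.param not in PARAM_NAMES:
            raise ValueError(f"{self.param!r} is not a model parameter; "
                             f"expected one of {', '.join(PARAM_NAMES)}")
        if len(self.values) == 0:
            raise ValueError("values list must be non-empty")


@dataclass(frozen=True)
class SweepRecord:
    """Outcome at a single swept value."""

    param: str
    value: float
    valid: bool
    error: str | None = None
    case_id: str | None = None
    x_star: float | None = None
    y_star: float | None = None
    predicted_corner: tuple[float, float] | None = None
    terminal_x: float | None = None
    terminal_y: float | None = None
    terminal_corner: tuple[float, float] | None = None
    status: str | None = None
    steps: int | None = None
    trajectory: Trajectory | None = None


@dataclass(frozen=True)
class SweepResult:
    """All records of a sweep, with a tidy-table view."""

    spec: SweepSpec
    records: tuple[SweepRecord, ...]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            rows.append({
                "param": r.param, "value": r.value, "valid": r.valid,
                "case_id": r.case_id, "x_star": r.x_star, "y_star": r.y_star,
                "predicted_corner": _fmt_corner(r.predicted_corner),
                "terminal_x": r.terminal_x, "terminal_y": r.terminal_y,
                "terminal_corner": _fmt_corner(r.terminal_corner),
                "status": r.status, "steps": r.steps, "error": r.error,
            })
        return pd.DataFrame(rows)


def _fmt_corner(corner: tuple[float, float] | None) -> str | None:
    if corner is None:
        return None
    return f"({corner[0]:g},{corner[1]:g})"


def _predicted_corner(p: GameParameters) -> tuple[float, float] | None:
    """Area-rule prediction in the bistable regime; the unique ESS elsewhere."""
    case = classify_case(p).case_id
    if case == "case3":
        return predict_attractor(p).corner
    if case == "case1":
        return (0.0, 0.0)
    if case == "case2":
        return (1.0, 1.0)
    return None


def run_sweep(spec: SweepSpec, *, keep_trajectories: bool = False) -> SweepResult:
    """Run one integration per swept value from the common initial state.

    A value that violates a parameter-domain constraint is recorded as
    invalid instead of aborting the sweep; if every value is invalid the
    sweep itself is in error.
    """
    records: list[SweepRecord] = []
    for value in spec.values:
        try:
            p = spec.base.replace(allow_boundary=spec.allow_boundary,
                                  **{spec.param: value})
        except ParameterValidationError as exc:
            records.append(SweepRecord(param=spec.param, value=value,
                                       valid=False, error=str(exc)))
            continue
        interior = interior_equilibrium(p)
        traj = integrate(p, spec.init, spec.solver)
        records.append(SweepRecord(
            param=spec.param, value=value, valid=True,
            case_id=classify_case(p).case_id,
            x_star=interior.x_star if interior.exists else None,
            y_star=interior.y_star if interior.exists else None,
            predicted_corner=_predicted_corner(p),
            terminal_x=traj.final_state[0], terminal_y=traj.final_state[1],
            terminal_corner=traj.corner, status=traj.status, steps=traj.steps,
            trajectory=traj if keep_trajectories else None,
        ))
    if not any(r.valid for r in records):
        raise ValueError(
            f"every swept value of {spec.param} violated a parameter constraint")
    return SweepResult(spec=spec, records=tuple(records))


def builtin_figures(base: GameParameters | None = None,
                    solver: SolverConfig = SolverConfig()) -> dict[str, SweepSpec]:
    """The nine built-in sweeps over the baseline.

    The moral-hazard sweeps include the endpoint 0, which sits on the
    boundary of the f/g domain; those two specs carry ``allow_boundary``.
    """
    if base is None:
        base = baseline_params()

    def spec(param: str, values: tuple[float, ...], *, boundary: bool = False) -> SweepSpec:
        return SweepSpec(base=base, param=param, values=values,
                         solver=solver, allow_boundary=boundary)

    return {
        "fraud_cost_doctor": spec("C1", (3.0, 4.0, 5.0, 6.0, 7.0)),
        "fraud_cost_patient": spec("C2", (2.0, 2.5, 3.0, 3.5, 4.0)),
        "moral_hazard_doctor": spec("f", (0.8, 0.6, 0.4, 0.2, 0.0), boundary=True),
        "moral_hazard_patient": spec("g", (0.6, 0.5, 0.4, 0.3, 0.0), boundary=True),
        "penalty_doctor": spec("P1", (5.0, 5.5, 6.0, 6.5, 7.0)),
        "penalty_patient": spec("P2", (3.0, 4.0, 5.0, 6.0, 7.0)),
        "reward_doctor": spec("R1", (5.0, 6.0, 7.0, 8.0, 9.0)),
        "reward_patient": spec("R2", (3.0, 4.0, 5.0, 6.0, 7.0)),
        "bribery": spec("H", (2.0, 3.0, 4.0, 5.0, 6.0)),
    }
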