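"""Payoff structure and replicator field of the doctor-patient fraud game.

The model is an asymmetric 2x2 evolutionary game between a population of
doctors and a population of patients, each choosing between a *fraud* and a
*non-fraud* strategy when settling health-insurance claims.  Seventeen
constants describe honest payoffs (``K0``, ``N0``), fraudulent payoffs
(``K1``, ``N1``), fraud costs (``C1``, ``C2``), moral-hazard coefficients
(``f``, ``g``), insurer penalties (``P1``, ``P2``) and rewards (``R1``,
``R2``), risk coefficients (``beta1``, ``beta2``), the bribe ``H`` a patient
pays a colluding doctor, the collusion surplus ``M``, and the doctor's share
``alpha`` of that surplus.

Strategy frequencies evolve under two-population replicator dynamics: the
fraction ``x`` of fraudulent doctors grows in proportion to the payoff
advantage of fraud over the doctors' population average (and symmetrically
``y`` for patients), giving the planar polynomial system

    dx/dt = x (1 - x) [ a1 + b1 y ]
    dy/dt = y (1 - y) [ a2 + b2 x ]

whose bracket coefficients are fixed affine combinations of the model
constants (see :func:`bracket_coefficients`).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, fields, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import yaml

__all__ = [
    "PARAM_NAMES",
    "FRAUD",
    "NON_FRAUD",
    "ConfigurationError",
    "ParameterValidationError",
    "GameParameters",
    "StrategyState",
    "PayoffMatrix",
    "UtilityProfile",
    "VelocityVector",
    "validate_params",
    "load_params",
    "payoff_matrix",
    "utilities",
    "bracket_coefficients",
    "replicator_rhs",
    "replicator_field",
]

#: Canonical parameter names, in the order they are conventionally listed.
PARAM_NAMES = (
    "K0", "K1", "N0", "N1", "C1", "C2", "f", "g",
    "P1", "P2", "R1", "R2", "beta1", "beta2", "H", "M", "alpha",
)

FRAUD = "fraud"
NON_FRAUD = "non-fraud"
_STRATEGY_INDEX = {NON_FRAUD: 0, FRAUD: 1}


class ConfigurationError(KeyError):
    """A required parameter is missing from (or unknown in) a configuration."""


class ParameterValidationError(ValueError):
    """A parameter value violates one of the model's domain constraints."""


@dataclass(frozen=True)
class GameParameters:
    """The seventeen constants of the fraud game.

    Instances are plain records; domain constraints are enforced by
    :func:`validate_params` (or :meth:`validate`), which is the constructor
    of record.  ``K0 < K1`` and ``N0 < N1`` (fraud pays more than honesty
    before costs and penalties), the coefficients ``f``, ``g``, ``beta1``,
    ``beta2``, ``alpha`` live in the open unit interval, and every monetary
    quantity is non-negative.
    """

    K0: float
    K1: float
    N0: float
    N1: float
    C1: float
    C2: float
    f: float
    g: float
    P1: float
    P2: float
    R1: float
    R2: float
    beta1: float
    beta2: float
    H: float
    M: float
    alpha: float

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in PARAM_NAMES}

    def replace(self, *, allow_boundary: bool = False, **changes: float) -> "GameParameters":
        """Return a validated copy with ``changes`` applied."""
        return validate_params(replace(self, **changes).as_dict(),
                               allow_boundary=allow_boundary)

    def validate(self, *, allow_boundary: bool = False) -> "GameParameters":
        return validate_params(self.as_dict(), allow_boundary=allow_boundary)


@dataclass(frozen=True)
class StrategyState:
    """Population frequencies of the fraud strategy.

    ``x`` is the fraction of doctors playing fraud, ``y`` the fraction of
    patients; both must lie in the closed unit interval.
    """

    x: float
    y: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.x <= 1.0 and 0.0 <= self.y <= 1.0):
            raise ValueError(
                f"strategy frequencies must lie in [0, 1]; got (x, y) = "
                f"({self.x}, {self.y})"
            )


@dataclass(frozen=True)
class PayoffMatrix:
    """The eight payoffs of the 2x2 asymmetric game.

    ``doctor[i, j]`` (resp. ``patient[i, j]``) is the doctor's (patient's)
    payoff when the doctor plays strategy ``i`` and the patient plays ``j``,
    with index 0 = non-fraud and 1 = fraud.  Use :meth:`entry` for
    name-based access.
    """

    doctor: tuple[tuple[float, float], tuple[float, float]]
    patient: tuple[tuple[float, float], tuple[float, float]]

    def entry(self, doctor_strategy: str, patient_strategy: str, role: str) -> float:
        i = _STRATEGY_INDEX[doctor_strategy]
        j = _STRATEGY_INDEX[patient_strategy]
        if role == "doctor":
            return self.doctor[i][j]
        if role == "patient":
            return self.patient[i][j]
        raise KeyError(f"role must be 'doctor' or 'patient', got {role!r}")


@dataclass(frozen=True)
class UtilityProfile:
    """Expected utilities of each pure strategy, plus population means.

    ``U11``/``U12`` are the doctor's expected payoffs from fraud/non-fraud
    against a patient population playing fraud with frequency ``y``;
    ``U21``/``U22`` are the patient analogues against doctor frequency
    ``x``.  ``U1bar = x U11 + (1-x) U12`` and ``U2bar = y U21 + (1-y) U22``
    are the population-average payoffs.
    """

    U11: float
    U12: float
    U1bar: float
    U21: float
    U22: float
    U2bar: float


@dataclass(frozen=True)
class VelocityVector:
    """The replicator vector field (F, G) = (dx/dt, dy/dt)."""

    F: float
    G: float


def validate_params(raw: Mapping[str, float], *, allow_boundary: bool = False) -> GameParameters:
    """Build a :class:`GameParameters` from a name->value mapping.

    Parameters
    ----------
    raw
        Mapping containing exactly the seventeen canonical names (extra keys
        are rejected to catch typos).
    allow_boundary
        When true, the open-interval constraints on the moral-hazard
        coefficients ``f`` and ``g`` are relaxed to the half-open ``[0, 1)``
        so that the no-moral-hazard endpoints can be studied.

    Raises
    ------
    ConfigurationError
        If a required name is missing or an unknown name is present.
    ParameterValidationError
        If a value violates a domain constraint; the message names the
        constraint.
    """
    missing = [name for name in PARAM_NAMES if name not in raw]
    if missing:
        raise ConfigurationError(f"missing parameter(s): {', '.join(missing)}")
    unknown = [name for name in raw if name not in PARAM_NAMES]
    if unknown:
        raise ConfigurationError(f"unknown parameter(s): {', '.join(unknown)}")

    values = {name: float(raw[name]) for name in PARAM_NAMES}
    for name, v in values.items():
        if not np.isfinite(v):
            raise ParameterValidationError(f"{name} must be finite, got {v}")

    def _open_unit(name: str) -> None:
        v = values[name]
        lo_ok = v >= 0.0 if (allow_boundary and name in ("f", "g")) else v > 0.0
        if not (lo_ok and v < 1.0):
            bound = "[0, 1)" if (allow_boundary and name in ("f", "g")) else "(0, 1)"
            raise ParameterValidationError(f"constraint violated: {name} in {bound} (got {v})")

    if not values["K1"] > values["K0"]:
        raise ParameterValidationError(
            f"constraint violated: K1 > K0 (got K1={values['K1']}, K0={values['K0']})")
    if not values["N1"] > values["N0"]:
        raise ParameterValidationError(
            f"constraint violated: N1 > N0 (got N1={values['N1']}, N0={values['N0']})")
    for name in ("f", "g", "beta1", "beta2", "alpha"):
        _open_unit(name)
    for name in ("C1", "C2", "P1", "P2", "R1", "R2", "H", "M", "K0", "N0"):
        if values[name] < 0.0:
            raise ParameterValidationError(
                f"constraint violated: {name} >= 0 (got {values[name]})")

    return GameParameters(**values)


def load_params(path: str | Path, *, allow_boundary: bool = False) -> GameParameters:
    """Read a flat key-value parameter file (YAML or JSON) and validate it."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        raw = json.loads(text)
    else:
        raw = yaml.safe_load(text)
    if not isinstance(raw, Mapping):
        raise ConfigurationError(
            f"{path} must contain a flat mapping of parameter names to numbers")
    return validate_params(raw, allow_boundary=allow_boundary)


def payoff_matrix(p: GameParameters) -> PayoffMatrix:
    """The payoff matrix of the stage game.

    Honest play yields the base payoffs ``(K0, N0)``.  A lone fraudulent
    doctor extracts ``f N0`` from the patient under information asymmetry,
    bears risk ``beta1 K1`` and penalty ``P1``; the honest patient collects
    the reward ``R2`` but loses ``f N0``.  Symmetrically for a lone
    fraudulent patient.  Under collusion the bribe ``H`` flows from patient
    to doctor and the surplus ``M`` is split ``alpha : 1 - alpha``.
    """
    d_ff = -p.C1 + p.H + p.alpha * p.M + p.K1 - p.beta1 * p.K1 - p.P1
    d_fn = -p.C1 + p.f * p.N0 + p.K1 - p.P1 - p.beta1 * p.K1
    d_nf = p.K0 + p.R1 - p.g * p.K0
    d_nn = p.K0
    # Collusion cell: the patient *pays* the bribe, hence -H.
    p_ff = -p.C2 - p.H + (1.0 - p.alpha) * p.M + p.N1 - p.beta2 * p.N1 - p.P2
    p_nf = -p.C2 + p.g * p.K0 - p.P2 - p.beta2 * p.N1 + p.N1
    p_fn = p.N0 + p.R2 - p.f * p.N0
    p_nn = p.N0
    return PayoffMatrix(
        doctor=((d_nn, d_nf), (d_fn, d_ff)),
        patient=((p_nn, p_nf), (p_fn, p_ff)),
    )


def utilities(p: GameParameters, s: StrategyState) -> UtilityProfile:
    """Expected utilities of each role's pure strategies at state ``s``.

    Computed by averaging the payoff-matrix rows/columns against the
    opponent population's strategy mix, which keeps this route independent
    of the expanded bracket form used by :func:`replicator_rhs`.
    """
    m = payoff_matrix(p)
    x, y = s.x, s.y
    U11 = y * m.doctor[1][1] + (1.0 - y) * m.doctor[1][0]
    U12 = y * m.doctor[0][1] + (1.0 - y) * m.doctor[0][0]
    U21 = x * m.patient[1][1] + (1.0 - x) * m.patient[0][1]
    U22 = x * m.patient[1][0] + (1.0 - x) * m.patient[0][0]
    return UtilityProfile(
        U11=U11, U12=U12, U1bar=x * U11 + (1.0 - x) * U12,
        U21=U21, U22=U22, U2bar=y * U21 + (1.0 - y) * U22,
    )


def bracket_coefficients(p: GameParameters) -> tuple[float, float, float, float]:
    """Coefficients (a1, b1, a2, b2) of the replicator brackets.

    ``dx/dt = x(1-x)(a1 + b1 y)`` and ``dy/dt = y(1-y)(a2 + b2 x)``.  ``a1``
    is the doctor's payoff gain from fraud against an all-honest patient
    population; ``b1`` is the extra gain per unit of patient fraud
    frequency (and symmetrically ``a2``, ``b2`` for patients, where the
    patient bracket depends on the *doctor* frequency ``x``).
    """
    a1 = -p.C1 + p.f * p.N0 + p.K1 - p.P1 - p.beta1 * p.K1 - p.K0
    b1 = p.H + p.alpha * p.M - p.R1 + p.g * p.K0 - p.f * p.N0
    a2 = -p.C2 + p.g * p.K0 + p.N1 - p.P2 - p.beta2 * p.N1 - p.N0
    b2 = -p.H + (1.0 - p.alpha) * p.M - p.R2 - p.g * p.K0 + p.f * p.N0
    return a1, b1, a2, b2


def replicator_rhs(p: GameParameters, s: StrategyState) -> VelocityVector:
    """Evaluate the replicator vector field at state ``s``."""
    a1, b1, a2, b2 = bracket_coefficients(p)
    F = s.x * (1.0 - s.x) * (a1 + b1 * s.y)
    G = s.y * (1.0 - s.y) * (a2 + b2 * s.x)
    return VelocityVector(F=F, G=G)


def replicator_field(p: GameParameters, x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised replicator field for arrays of states (used by the solver)."""
    a1, b1, a2, b2 = bracket_coefficients(p)
    F = x * (1.0 - x) * (a1 + b1 * y)
    G = y * (1.0 - y) * (a2 + b2 * x)
    return F, G
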