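"""Scenario generation: the reference baseline and sampled parameter regimes.

Every downstream module is testable without external data: the baseline
parameter set occupies the bistable regime, and
rejection sampling over plausible uniform boxes produces parameter sets
occupying any requested regime (case 1: honesty-dominant, case 2:
fraud-dominant, case 3: bistable).

Rejection sampling keeps the conditional distribution exactly uniform on
the feasible region of the box, at the cost of a regime-dependent
acceptance rate; infeasibility under a user-supplied box is reported with
the observed acceptance rate rather than looping forever.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .equilibria import classify_case
from .model_core import GameParameters, validate_params

__all__ = [
    "DEFAULT_RANGES",
    "FeasibilityError",
    "ScenarioSpec",
    "ScenarioSample",
    "baseline_params",
    "sample_params",
    "sample_scenarios",
]

#: Uniform sampling boxes bracketing the baseline.  ``K1`` and ``N1`` are
#: sampled as offsets above ``K0``/``N0`` so the fraud-pays-more constraint
#: holds by construction.
DEFAULT_RANGES: dict[str, tuple[float, float]] = {
    "K0": (1.0, 5.0),
    "N0": (1.0, 5.0),
    "K1_offset": (1.0, 10.0),
    "N1_offset": (1.0, 10.0),
    "C1": (0.0, 10.0),
    "C2": (0.0, 10.0),
    "P1": (0.0, 10.0),
    "P2": (0.0, 10.0),
    "R1": (0.0, 10.0),
    "R2": (0.0, 10.0),
    "H": (0.0, 8.0),
    "M": (5.0, 40.0),
    "f": (0.05, 0.95),
    "g": (0.05, 0.95),
    "beta1": (0.05, 0.95),
    "beta2": (0.05, 0.95),
    "alpha": (0.05, 0.95),
}


class FeasibilityError(RuntimeError):
    """Rejection sampling exhausted its attempt budget."""


@dataclass(frozen=True)
class ScenarioSpec:
    """What to sample: target regime, sampling boxes, seed, budget."""

    case: str = "any"  # "case1" | "case2" | "case3" | "any"
    ranges: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_RANGES))
    seed: int = 0
    max_attempts: int = 100_000

    def __post_init__(self) -> None:
        if self.case not in ("case1", "case2", "case3", "any"):
            raise ValueError(f"unknown target case {self.case!r}")
        if self.max_attempts < 1:
            raise ValueError("max_attempts must be >= 1")
        unknown = set(self.ranges) - set(DEFAULT_RANGES)
        if unknown:
            raise ValueError(f"unknown range key(s): {', '.join(sorted(unknown))}")


@dataclass(frozen=True)
class ScenarioSample:
    """A sampled parameter set plus sampling metadata."""

    params: GameParameters
    case_id: str
    attempts: int
    seed: int


def baseline_params() -> GameParameters:
    """The reference bistable baseline parameter set.

    C1=3, C2=2, N0=2, N1=5, K0=2, K1=8, f=0.8, g=0.6, alpha=0.5,
    beta1=beta2=0.5, P1=5, P2=3, R1=5, R2=3, H=2, M=25.
    """
    return validate_params({
        "C1": 3.0, "C2": 2.0, "N0": 2.0, "N1": 5.0, "K0": 2.0, "K1": 8.0,
        "f": 0.8, "g": 0.6, "alpha": 0.5, "beta1": 0.5, "beta2": 0.5,
        "P1": 5.0, "P2": 3.0, "R1": 5.0, "R2": 3.0, "H": 2.0, "M": 25.0,
    })


def _draw(rng: np.random.Generator, ranges: dict[str, tuple[float, float]]) -> GameParameters:
    u = {k: rng.uniform(lo, hi) for k, (lo, hi) in ranges.items()}
    raw = {k: v for k, v in u.items() if not k.endswith("_offset")}
    raw["K1"] = u["K0"] + u["K1_offset"]
    raw["N1"] = u["N0"] + u["N1_offset"]
    return validate_params(raw)


def sample_scenarios(spec: ScenarioSpec, n: int = 1) -> list[ScenarioSample]:
    """Draw ``n`` parameter sets from the spec's target regime.

    A single seeded stream drives the whole call, so the same spec and
    ``n`` always reproduce the same samples.
    """
    rng = np.random.default_rng(spec.seed)
    ranges = {**DEFAULT_RANGES, **spec.ranges}
    samples: list[ScenarioSample] = []
    attempts = 0
    accepted = 0
    while len(samples) < n:
        if attempts >= spec.max_attempts:
            rate = accepted / attempts if attempts else 0.0
            raise FeasibilityError(
                f"no {spec.case} sample after {attempts} attempts "
                f"(acceptance rate {rate:.2%}); the binding inequalities are the "
                f"{spec.case} conditions on (A1, B1, A2, B2) — widen the ranges "
                f"or raise max_attempts")
        attempts += 1
        params = _draw(rng, ranges)
        case_id = classify_case(params).case_id
        if spec.case in ("any", case_id):
            accepted += 1
            samples.append(ScenarioSample(params=params, case_id=case_id,
                                          attempts=attempts, seed=spec.seed))
    return samples


def sample_params(spec: ScenarioSpec) -> GameParameters:
    """Draw a single parameter set from the spec's target regime."""
    return sample_scenarios(spec, 1)[0].params
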