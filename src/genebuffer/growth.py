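"""Phenotype trajectories and the transfer/buffer decomposition over time.

Three trajectory families are supported for a growing quantity ``x``:

* linear      ``x(t) = x0 * r * t``
* quadratic   ``x(t) = x0 * r * t**2``
* exponential ``x(t) = x0 * exp(r * t)`` (the solution of ``dx/dt = r x``)

The reference (wild-type) trajectory plays the role of the sigma function
``sigma(t)``; the mutant trajectory is the transfer function ``tau(t)``;
their difference ``beta(t) = sigma(t) - tau(t)`` is the buffer function —
the phenotype hidden by the mutation.  ``sigma = tau + beta`` holds
pointwise by construction.

For linear and quadratic growth the transfer fraction ``tau/sigma`` is
constant in time (it equals the rate ratio), so a fitness measured from
colony area at any time is a valid transfer fraction.  For exponential
growth it decays as ``exp((r_mut - r_ref) t)`` and time matters.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from enum import Enum
from typing import Callable

from .errors import DegenerateInputError, ValidationError
from .params import BufferingState, state_from_t_bar

__all__ = [
    "GrowthKind",
    "GrowthModel",
    "SchmittTriple",
    "evaluate",
    "schmitt_triple",
    "buffering_state_at",
    "cumulative_phenotype",
    "time_dilation",
]


class GrowthKind(str, Enum):
    LINEAR = "linear"
    QUADRATIC = "quadratic"
    EXPONENTIAL = "exponential"


@dataclass(frozen=True)
class GrowthModel:
    """One trajectory family with rate ``r`` (per hour) and initial size ``x0``.

    ``r`` may be negative (mortality exceeding proliferation); downstream
    parameter code accepts the resulting negative transfer fractions.
    """

    kind: GrowthKind
    r: float
    x0: float = 1.0

    def __post_init__(self):
        object.__setattr__(self, "kind", GrowthKind(self.kind))
        if not math.isfinite(self.r):
            raise ValidationError(f"r must be finite, got {self.r}")
        if not (math.isfinite(self.x0) and self.x0 > 0):
            raise ValidationError(f"x0 must be positive and finite, got {self.x0}")

    @property
    def degree_n(self) -> int | None:
        """Time exponent of the polynomial families (None for exponential)."""
        if self.kind is GrowthKind.LINEAR:
            return 1
        if self.kind is GrowthKind.QUADRATIC:
            return 2
        return None

    def __call__(self, t: float) -> float:
        return evaluate(self, t)

    def to_json(self) -> str:
        return json.dumps({"kind": self.kind.value, "r": self.r, "x0": self.x0})

    @classmethod
    def from_json(cls, text: str) -> "GrowthModel":
        d = json.loads(text)
        return cls(kind=d["kind"], r=d["r"], x0=d.get("x0", 1.0))


@dataclass(frozen=True)
class SchmittTriple:
    """Reference/mutant/difference trajectories: sigma(t) = tau(t) + beta(t)."""

    sigma: Callable[[float], float]
    tau: Callable[[float], float]
    beta: Callable[[float], float]


def evaluate(model: GrowthModel, t: float) -> float:
    """Trajectory value at time ``t`` (hours, non-negative)."""
    if t < 0:
        raise ValidationError(f"t must be non-negative, got {t}")
    if model.kind is GrowthKind.LINEAR:
        return model.x0 * model.r * t
    if model.kind is GrowthKind.QUADRATIC:
        return model.x0 * model.r * t * t
    return model.x0 * math.exp(model.r * t)


def schmitt_triple(reference: GrowthModel, mutant: GrowthModel) -> SchmittTriple:
    """Decompose a mutant trajectory against its reference.

    Both models must share the same family and initial size so that the
    difference is attributable to the rate alone.
    """
    if reference.kind is not mutant.kind:
        raise ValidationError(
            f"reference and mutant must share a growth kind "
            f"({reference.kind.value} vs {mutant.kind.value})"
        )
    if reference.x0 != mutant.x0:
        raise ValidationError("reference and mutant must share x0")
    sigma = lambda t: evaluate(reference, t)
    tau = lambda t: evaluate(mutant, t)
    return SchmittTriple(sigma=sigma, tau=tau,
                         beta=lambda t: sigma(t) - tau(t))


def buffering_state_at(reference: GrowthModel, mutant: GrowthModel,
                       t: float) -> BufferingState:
    """Buffering state of the mutant at time ``t``: ``t_bar = tau(t)/sigma(t)``.

    For the polynomial families the ratio is the rate ratio, independent of
    time; for exponential growth it is ``exp((r_mut - r_ref) t)``.
    """
    if reference.kind is not mutant.kind:
        raise ValidationError("reference and mutant must share a growth kind")
    if reference.kind is GrowthKind.EXPONENTIAL:
        return state_from_t_bar(math.exp((mutant.r - reference.r) * t))
    # tau/sigma = r_mut/r_ref for all t > 0; t = 0 gives 0/0.
    sigma_t = evaluate(reference, t)
    if sigma_t == 0.0:
        raise DegenerateInputError(f"sigma({t}) = 0; transfer fraction undefined")
    if reference.r == 0.0:
        raise DegenerateInputError("reference rate is zero; t_bar undefined")
    return state_from_t_bar(mutant.r / reference.r)


def cumulative_phenotype(model: GrowthModel, t_start: float, t_end: float) -> float:
    """Definite integral of the trajectory over [t_start, t_end].

    The integrated ("plenary") expression of the phenotype — for cells, the
    accumulated cell·hours over the observation window.  Closed forms:
    ``x0 r (t2^2 - t1^2)/2`` (linear), ``x0 r (t2^3 - t1^3)/3`` (quadratic),
    ``x0 (exp(r t2) - exp(r t1))/r`` (exponential; ``x0 (t2 - t1)`` if r=0).
    """
    if t_start > t_end:
        raise ValidationError(f"t_start must not exceed t_end ({t_start} > {t_end})")
    if t_start < 0:
        raise ValidationError("t_start must be non-negative")
    if model.kind is GrowthKind.LINEAR:
        return model.x0 * model.r * (t_end**2 - t_start**2) / 2.0
    if model.kind is GrowthKind.QUADRATIC:
        return model.x0 * model.r * (t_end**3 - t_start**3) / 3.0
    if model.r == 0.0:
        return model.x0 * (t_end - t_start)
    return model.x0 * (math.exp(model.r * t_end) - math.exp(model.r * t_start)) / model.r


def time_dilation(t_bar: float, degree_n: int, t_wt: float) -> float:
    """Time for the mutant to reach the wild type's phenotype at ``t_wt``.

    For polynomial growth of degree ``n``, ``t_mut = (t_wt**n / t_bar)**(1/n)``;
    with ``n = 1`` this is the familiar ``t_wt / t_bar`` (a half-fit mutant
    takes twice as long).  Requires ``t_bar > 0``: inverted phenotypes never
    reach the wild-type value.
    """
    if not (t_bar > 0):
        raise ValidationError(
            f"time dilation needs t_bar > 0, got {t_bar} (inverted phenotype)"
        )
    if degree_n < 1 or int(degree_n) != degree_n:
        raise ValidationError(f"degree_n must be a positive integer, got {degree_n}")
    if t_wt < 0:
        raise ValidationError("t_wt must be non-negative")
    return (t_wt**degree_n / t_bar) ** (1.0 / degree_n)
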