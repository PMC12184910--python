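"""Neutrality models: the expected phenotype of a multi-mutant absent interaction.

Two mutually exclusive rules predict a double (or k-fold) mutant's
buffering state when the alleles act independently:

* serial   — the output of one allele's process feeds the next; transfer
  fractions multiply: ``t_bar_expected = prod(t_bar_i)``.
* parallel — the alleles act simultaneously on the same input; the
  buffer-to-transfer ratios, a ratio-scale measure, add:
  ``B_expected = sum(B_i)``, equivalently
  ``t_bar_expected = 1 / (sum(1/t_bar_i) - (k-1))``.

For linear/quadratic growth the serial rule coincides with the classical
multiplicative ("product") model.  For exponential growth serial action
adds rates (``r_iv = r_ii + r_iii - r_i``) while parallel action yields a
time-varying effective rate, returned here as a trajectory.

A third, "hybrid" rule defined per measured cross (pick whichever of
serial/parallel the data contradict least) lives in the SGA pipeline.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Callable, Sequence

from .errors import DegenerateInputError, UndefinedParameterError, ValidationError
from .params import UNDEFINED, BufferingState, Undefined, state_from_B, state_from_t_bar

__all__ = [
    "NeutralityModel",
    "ExpectedState",
    "expected_serial",
    "expected_parallel",
    "expected_exponential_serial_rate",
    "expected_exponential_parallel_trajectory",
    "expected_double_fitness",
]


class NeutralityModel(str, Enum):
    SERIAL = "serial"
    PARALLEL = "parallel"
    HYBRID = "hybrid"


@dataclass(frozen=True)
class ExpectedState:
    """Expected multi-mutant buffering state under one neutrality model.

    ``trajectory`` is populated (and ``time_varying`` set) only for the
    exponential-parallel case, where the combined fitness is not a constant.
    """

    model: NeutralityModel
    state: BufferingState
    time_varying: bool = False
    trajectory: Callable[[float], float] | None = None


def _require_states(states: Sequence[BufferingState]) -> Sequence[BufferingState]:
    if len(states) < 2:
        raise ValidationError(
            f"need at least two states to combine, got {len(states)}"
        )
    return states


def expected_serial(states: Sequence[BufferingState]) -> ExpectedState:
    """Serial combination: product of transfer fractions. Order-independent."""
    _require_states(states)
    t = 1.0
    for s in states:
        t *= s.t_bar
    return ExpectedState(model=NeutralityModel.SERIAL, state=state_from_t_bar(t))


def expected_parallel(states: Sequence[BufferingState]) -> ExpectedState:
    """Parallel combination: sum of buffer-to-transfer ratios. Order-independent."""
    _require_states(states)
    B_sum = 0.0
    for s in states:
        if isinstance(s.B, Undefined):
            raise UndefinedParameterError(
                "parallel combination needs a defined B for every allele "
                "(t_bar = 0 makes B undefined)"
            )
        B_sum += s.B
    return ExpectedState(model=NeutralityModel.PARALLEL, state=state_from_B(B_sum))


def expected_exponential_serial_rate(r_ref: float, r1: float, r2: float) -> float:
    """Expected exponential rate of a serial double mutant.

    Multiplying the time-dependent transfer fractions
    ``exp((r1-r_ref)t) * exp((r2-r_ref)t)`` gives a single exponential with
    rate ``r1 + r2 - r_ref``.
    """
    for name, v in (("r_ref", r_ref), ("r1", r1), ("r2", r2)):
        if not math.isfinite(v):
            raise ValidationError(f"{name} must be finite")
    return r1 + r2 - r_ref


def expected_exponential_parallel_trajectory(
    r_ref: float, r1: float, r2: float, x0: float = 1.0
) -> Callable[[float], float]:
    """Expected population trajectory of a parallel double mutant (exponential).

    Summing the time-varying B values and converting back gives

        N(t) = x0 * exp(r_ref t) / (exp((r_ref-r1) t) + exp((r_ref-r2) t) - 1)

    whose effective rate is not constant; callers extract scalars at an
    explicit time.  Raises at any ``t`` where the denominator is not
    positive (the combined transfer fraction would vanish or invert).
    """
    if x0 <= 0:
        raise ValidationError("x0 must be positive")

    def trajectory(t: float) -> float:
        denom = math.exp((r_ref - r1) * t) + math.exp((r_ref - r2) * t) - 1.0
        if denom <= 0.0:
            raise DegenerateInputError(
                f"parallel trajectory undefined at t={t}: denominator {denom} <= 0"
            )
        return x0 * math.exp(r_ref * t) / denom

    return trajectory


def expected_double_fitness(f1: float, f2: float,
                            model: NeutralityModel | str) -> float:
    """Expected double-mutant fitness from two single-mutant fitnesses.

    Fitness here is the transfer fraction relative to wild type (colony
    area scales linearly with both time and fitness, so the serial and
    product rules coincide).  Serial: ``f1*f2``.  Parallel:
    ``1/(1/f1 + 1/f2 - 1)``, which dominates the serial expectation on
    (0, 1]^2.
    """
    model = NeutralityModel(model)
    if model is NeutralityModel.SERIAL:
        if not (math.isfinite(f1) and math.isfinite(f2)):
            raise ValidationError("fitnesses must be finite")
        return f1 * f2
    if model is NeutralityModel.PARALLEL:
        if f1 <= 0 or f2 <= 0:
            raise UndefinedParameterError(
                "parallel expectation needs positive fitnesses (B undefined at 0)"
            )
        return 1.0 / (1.0 / f1 + 1.0 / f2 - 1.0)
    raise ValidationError(
        "hybrid expectation is defined per measured cross; see the sga module"
    )
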