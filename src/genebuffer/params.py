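"""Algebra of the five buffering parameters.

A single allele's effect on a measured trait is described by partitioning
the trait between an observable "transfer" compartment and a hidden
"buffer" compartment.  Five equivalent parameters describe the state:

* ``t_bar`` — transfer fraction, the trait observed in the mutant relative
  to the reference (may be negative or exceed 1 for inverted/amplified
  phenotypes);
* ``b``     — buffer fraction, ``1 - t_bar``;
* ``T``     — transfer-to-buffer ratio, ``t_bar / b``;
* ``B``     — buffer-to-transfer ratio, ``b / t_bar``;
* ``alpha`` — the buffering angle, the polar angle of the point
  ``(t_bar, b)`` on the line ``t_bar + b = 1``, in degrees.

``T`` and ``B`` live on a ratio scale but are undefined at perfect
buffering and perfect transfer respectively; the angle covers the whole
spectrum, from amplification (−45°..0°) through moderation (0°..90°) to
inversion (90°..135°), without discontinuities.  Any one parameter
determines the other four.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .errors import (
    DegenerateInputError,
    DivergenceError,
    UndefinedParameterError,
    ValidationError,
)

__all__ = [
    "UNDEFINED",
    "Undefined",
    "BufferingState",
    "Partition",
    "state_from_t_bar",
    "state_from_b",
    "state_from_T",
    "state_from_B",
    "state_from_partition",
    "state_from_angle",
    "angle_from_state",
]


class Undefined:
    """Sentinel for a buffering parameter undefined by division by zero.

    Distinct from NaN: it is a meaningful state (perfect transfer or
    perfect buffering), and any arithmetic on it raises
    :class:`UndefinedParameterError` instead of propagating silently.
    """

    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:
        return "UNDEFINED"

    def _refuse(self, *args, **kwargs):
        raise UndefinedParameterError(
            "arithmetic on an UNDEFINED buffering parameter"
        )

    __add__ = __radd__ = __sub__ = __rsub__ = _refuse
    __mul__ = __rmul__ = __truediv__ = __rtruediv__ = _refuse
    __neg__ = __pos__ = __abs__ = _refuse
    __lt__ = __le__ = __gt__ = __ge__ = _refuse
    __float__ = __int__ = _refuse

    def __bool__(self) -> bool:
        return False

    def __reduce__(self):
        return (Undefined, ())


UNDEFINED = Undefined()


def _check_finite(name: str, value: float) -> float:
    try:
        value = float(value)
    except (TypeError, ValueError) as exc:
        raise ValidationError(f"{name} must be a real number, got {value!r}") from exc
    if not math.isfinite(value):
        raise ValidationError(f"{name} must be finite, got {value!r}")
    return value


@dataclass(frozen=True)
class BufferingState:
    """The five-parameter description of one allele's buffering effect.

    Attributes
    ----------
    t_bar : float
        Transfer fraction (dimensionless).
    b : float
        Buffer fraction, ``1 - t_bar``.
    T : float or Undefined
        Transfer-to-buffer ratio; UNDEFINED when ``b == 0``.
    B : float or Undefined
        Buffer-to-transfer ratio; UNDEFINED when ``t_bar == 0``.
    alpha_deg : float
        Buffering angle in degrees, in the half-open interval (−45, 135].
    """

    t_bar: float
    b: float
    T: float | Undefined
    B: float | Undefined
    alpha_deg: float

    def __post_init__(self):
        if abs(self.t_bar + self.b - 1.0) > 1e-9:
            raise ValidationError(
                f"t_bar + b must equal 1, got {self.t_bar} + {self.b}"
            )

    def to_dict(self) -> dict:
        """JSON-friendly mapping; UNDEFINED ratios serialize as None."""
        return {
            "t_bar": self.t_bar,
            "b": self.b,
            "T": None if isinstance(self.T, Undefined) else self.T,
            "B": None if isinstance(self.B, Undefined) else self.B,
            "alpha_deg": self.alpha_deg,
        }


@dataclass(frozen=True)
class Partition:
    """A measured trait split between transfer and buffer compartments."""

    transfer_amount: float
    buffer_amount: float

    @property
    def total(self) -> float:
        return self.transfer_amount + self.buffer_amount


def angle_from_state(t_bar: float, b: float) -> float:
    """Buffering angle in degrees for a point on the line ``t_bar + b = 1``.

    The angle is measured between the transfer axis and the ray from the
    origin through ``(t_bar, b)``.  For ``t_bar <= 1`` it equals
    ``arccos(t_bar / sqrt(t_bar**2 + b**2))``; for ``t_bar > 1`` the sign
    flips (amplifying systems have negative angles).  The result lies in
    (−45, 135]; −45° itself requires an infinite transfer fraction and is
    unattainable.
    """
    t_bar = _check_finite("t_bar", t_bar)
    b = _check_finite("b", b)
    if abs(t_bar + b - 1.0) > 1e-9:
        raise ValidationError(f"t_bar + b must equal 1, got {t_bar} + {b}")
    norm = math.hypot(t_bar, b)
    if norm == 0.0:
        raise DegenerateInputError("t_bar = b = 0 has no direction")
    alpha = math.degrees(math.acos(t_bar / norm))
    if t_bar > 1.0:
        alpha = -alpha
    return alpha


def state_from_t_bar(t_bar: float) -> BufferingState:
    """Build the full buffering state from the transfer fraction."""
    t_bar = _check_finite("t_bar", t_bar)
    b = 1.0 - t_bar
    T = UNDEFINED if b == 0.0 else t_bar / b
    B = UNDEFINED if t_bar == 0.0 else b / t_bar
    return BufferingState(t_bar=t_bar, b=b, T=T, B=B,
                          alpha_deg=angle_from_state(t_bar, b))


def state_from_b(b: float) -> BufferingState:
    """Build the full buffering state from the buffer fraction."""
    return state_from_t_bar(1.0 - _check_finite("b", b))


def state_from_B(B: float) -> BufferingState:
    """Build the full buffering state from the buffer-to-transfer ratio.

    ``t_bar = 1 / (1 + B)``; at ``B = -1`` the transfer fraction diverges.
    """
    B = _check_finite("B", B)
    if B == -1.0:
        raise DivergenceError(
            "B = -1 is a singularity: t_bar = 1/(1+B) diverges "
            "(alpha = 135 deg is reachable only as an angle input)"
        )
    return state_from_t_bar(1.0 / (1.0 + B))


def state_from_T(T: float) -> BufferingState:
    """Build the full buffering state from the transfer-to-buffer ratio."""
    T = _check_finite("T", T)
    if T == -1.0:
        raise DivergenceError("T = -1 is a singularity: t_bar = T/(1+T) diverges")
    return state_from_t_bar(T / (1.0 + T))


def state_from_partition(p: Partition) -> BufferingState:
    """Buffering state of a concrete transfer/buffer partition."""
    total = p.total
    if total == 0.0:
        raise DegenerateInputError("partition total is zero; t_bar undefined")
    return state_from_t_bar(p.transfer_amount / total)


def state_from_angle(alpha_deg: float) -> BufferingState:
    """Invert the buffering angle back to the full parameter set.

    ``t_bar = cos(a) / (cos(a) + sin(a))``, ``b = sin(a) / (cos(a) + sin(a))``,
    ``T = cos(a)/sin(a)``, ``B = tan(a)``.  The angle must lie in (−45, 135];
    at exactly 135° the denominator ``cos + sin`` vanishes and the transfer
    fraction diverges.
    """
    alpha_deg = _check_finite("alpha_deg", alpha_deg)
    if not (-45.0 < alpha_deg <= 135.0):
        raise ValidationError(
            f"alpha_deg must lie in (-45, 135], got {alpha_deg}"
        )
    a = math.radians(alpha_deg)
    denom = math.cos(a) + math.sin(a)
    # 135 deg exactly: cos + sin = 0, the limit point of B -> -1.
    if abs(denom) < 1e-12:
        raise DivergenceError(
            "alpha = 135 deg sits at the cos(a) + sin(a) = 0 singularity; "
            "t_bar and b diverge"
        )
    # Snap the right-angle cases so that 90 deg gives exactly t_bar = 0.
    cos_a = 0.0 if abs(math.cos(a)) < 1e-15 else math.cos(a)
    sin_a = 0.0 if abs(math.sin(a)) < 1e-15 else math.sin(a)
    t_bar = cos_a / denom
    return state_from_t_bar(t_bar)
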