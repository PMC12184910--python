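"""Interaction scales: epsilon scores, landmarks, classification, and
quantification of genetic buffering via the buffering angle.

Epistasis is the case where the observed double-mutant state deviates from
the neutrality expectation: ``B_cd != B_c + B_d`` (parallel) or
``t_cd != t_c * t_d`` (serial).  The deviation is expressed as a relative
error ``epsilon`` oriented so that aggravating interactions (more severe
than expected) are positive on both scales and ameliorating ones negative:

    epsilon_parallel = (B_cd - (B_c + B_d)) / (B_c + B_d)
    epsilon_serial   = -(t_cd - t_c * t_d) / (t_c * t_d)

On either scale, +1 means the phenotype is twice as severe as expected;
-1 (parallel) means a wild-type-like double mutant, and +1 (serial) means
no measurable growth at all.  Landmark values mark where the double mutant
matches the weaker or the stronger single mutant.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum

from .errors import DivergenceError, UndefinedParameterError, ValidationError
from .neutrality import NeutralityModel, expected_parallel, expected_serial
from .params import BufferingState, Undefined

__all__ = [
    "InteractionLabel",
    "InteractionSubLabel",
    "InteractionAssessment",
    "BufferingQuantification",
    "epsilon_parallel",
    "epsilon_serial",
    "epsilon_landmarks",
    "classify",
    "quantify_buffering",
    "DEFAULT_LETHALITY_FLOOR",
    "DEFAULT_Q_THRESHOLD",
]

#: Double-mutant fitness at or below this fraction of wild type counts as
#: "not observably greater than zero" (synthetic lethality).
DEFAULT_LETHALITY_FLOOR = 0.01

#: Default FDR threshold separating epistatic from neutral calls.
DEFAULT_Q_THRESHOLD = 0.05


class InteractionLabel(str, Enum):
    NEUTRAL_ADDITIVE = "neutral_additive"            # parallel model holds
    NEUTRAL_MULTIPLICATIVE = "neutral_multiplicative"  # serial model holds
    EPISTATIC_AGGRAVATING = "epistatic_aggravating"
    EPISTATIC_AMELIORATING = "epistatic_ameliorating"


class InteractionSubLabel(str, Enum):
    SYNTHETIC_SICK = "synthetic_sick"
    SYNTHETIC_LETHAL = "synthetic_lethal"
    SUPPRESSION = "suppression"
    NONE = "none"


@dataclass(frozen=True)
class InteractionAssessment:
    """Epsilon score, landmarks, and class label for one double mutant."""

    model: NeutralityModel
    epsilon: float
    epsilon_weak: float | None
    epsilon_strong: float | None
    label: InteractionLabel
    sub_label: InteractionSubLabel = InteractionSubLabel.NONE


@dataclass(frozen=True)
class BufferingQuantification:
    """Angular bookkeeping of how much variation a gene pair can hide.

    ``cryptic_range_deg`` is the angular span between the neutral
    expectation and the observation — phenotypic deviation that only
    becomes visible once the partner gene is disabled.
    """

    alpha_single_c: float
    alpha_single_d: float
    alpha_expected: float
    alpha_observed: float
    cryptic_range_deg: float


def epsilon_parallel(B_c: float, B_d: float, B_cd: float | Undefined) -> float:
    """Relative error of the observed B against the additive expectation.

    A lethal double mutant (t_cd = 0) has an undefined, effectively
    infinite B; pass ``UNDEFINED`` to obtain ``+inf``.
    """
    expected = B_c + B_d
    if expected == 0.0:
        raise DivergenceError("B_c + B_d = 0: epsilon_parallel diverges")
    if isinstance(B_cd, Undefined):
        return math.inf
    return (B_cd - expected) / expected


def epsilon_serial(t_c: float, t_d: float, t_cd: float) -> float:
    """Relative error of the observed t_bar against the multiplicative
    expectation, sign-flipped so aggravating interactions are positive."""
    expected = t_c * t_d
    if expected == 0.0:
        raise DivergenceError("t_c * t_d = 0: epsilon_serial diverges")
    return -(t_cd - expected) / expected


def epsilon_landmarks(B_c: float, B_d: float) -> tuple[float, float]:
    """Epsilon values at which the double mutant equals the weaker / stronger
    single mutant on the parallel scale.

        epsilon_weak   = (min(|B_c|, |B_d|) - |B_c + B_d|) / |B_c + B_d|
        epsilon_strong = (max(|B_c|, |B_d|) - |B_c + B_d|) / |B_c + B_d|
    """
    denom = abs(B_c + B_d)
    if denom == 0.0:
        raise DivergenceError("|B_c + B_d| = 0: landmarks diverge")
    weak = (min(abs(B_c), abs(B_d)) - denom) / denom
    strong = (max(abs(B_c), abs(B_d)) - denom) / denom
    return weak, strong


def classify(
    model: NeutralityModel | str,
    epsilon: float,
    q_value: float,
    *,
    q_threshold: float = DEFAULT_Q_THRESHOLD,
    t_cd: float | None = None,
    t_singles: tuple[float, float] | None = None,
    lethality_floor: float = DEFAULT_LETHALITY_FLOOR,
    epsilon_weak: float | None = None,
    epsilon_strong: float | None = None,
) -> InteractionAssessment:
    """Label a double mutant neutral or epistatic from epsilon and its q-value.

    Non-significant crosses (``q > q_threshold``) are neutral — additive
    under the parallel model, multiplicative under the serial one.
    Significant crosses are aggravating (epsilon > 0) or ameliorating
    (epsilon < 0); aggravating crosses are synthetic-lethal when the
    double-mutant fitness is at or below ``lethality_floor`` and
    synthetic-sick otherwise, while ameliorating crosses whose double
    mutant outgrows the fitter single mutant are flagged as suppression.
    """
    model = NeutralityModel(model)
    if not (0.0 <= q_value <= 1.0):
        raise ValidationError(f"q_value must lie in [0, 1], got {q_value}")

    if q_value > q_threshold or epsilon == 0.0:
        label = (InteractionLabel.NEUTRAL_ADDITIVE
                 if model is NeutralityModel.PARALLEL
                 else InteractionLabel.NEUTRAL_MULTIPLICATIVE)
        return InteractionAssessment(model=model, epsilon=epsilon,
                                     epsilon_weak=epsilon_weak,
                                     epsilon_strong=epsilon_strong,
                                     label=label)

    if epsilon > 0:
        label = InteractionLabel.EPISTATIC_AGGRAVATING
        sub = InteractionSubLabel.NONE
        if t_cd is not None:
            sub = (InteractionSubLabel.SYNTHETIC_LETHAL
                   if t_cd <= lethality_floor
                   else InteractionSubLabel.SYNTHETIC_SICK)
    else:
        label = InteractionLabel.EPISTATIC_AMELIORATING
        sub = InteractionSubLabel.NONE
        if t_cd is not None and t_singles is not None and t_cd > max(t_singles):
            sub = InteractionSubLabel.SUPPRESSION
    return InteractionAssessment(model=model, epsilon=epsilon,
                                 epsilon_weak=epsilon_weak,
                                 epsilon_strong=epsilon_strong,
                                 label=label, sub_label=sub)


def quantify_buffering(
    state_c: BufferingState,
    state_d: BufferingState,
    state_cd_observed: BufferingState,
    model: NeutralityModel | str,
) -> BufferingQuantification:
    """Angular measure of cryptic variation hidden by a gene pair.

    The expected double-mutant angle comes from the chosen neutrality
    model; any observed deviation beyond it is phenotypic range that the
    genetic relationship buffered (zero when the observation does not
    exceed the expectation).
    """
    model = NeutralityModel(model)
    if model is NeutralityModel.SERIAL:
        expected = expected_serial([state_c, state_d])
    elif model is NeutralityModel.PARALLEL:
        expected = expected_parallel([state_c, state_d])
    else:
        raise UndefinedParameterError(
            "hybrid model has no single expectation; quantify per model"
        )
    alpha_expected = expected.state.alpha_deg
    alpha_observed = state_cd_observed.alpha_deg
    return BufferingQuantification(
        alpha_single_c=state_c.alpha_deg,
        alpha_single_d=state_d.alpha_deg,
        alpha_expected=alpha_expected,
        alpha_observed=alpha_observed,
        cryptic_range_deg=max(0.0, alpha_observed - alpha_expected),
    )
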