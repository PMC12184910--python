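"""Synthetic SGA-style cross tables with known ground truth.

Every pipeline stage is testable without the multi-million-row yeast
supplement: the generator emulates its statistical structure — single
fitnesses spanning the informative band, double-mutant fitnesses produced
by a serial or parallel neutrality rule (a minority perturbed by a true
epsilon), plus Gaussian measurement noise with a reported per-cross
standard deviation.  The true generating relationship of every cross is
emitted alongside, so model-selection and bias-recovery behavior can be
checked against ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError
from .neutrality import NeutralityModel
from .sga import run_pipeline

__all__ = ["SimulationSpec", "generate", "bias_recovery_experiment"]


@dataclass(frozen=True)
class SimulationSpec:
    """Parameters of one synthetic cross table.

    Defaults mirror the regime the residual analysis targets: single
    fitnesses uniform on [0.1, 0.9] (inside the informative band, where
    the serial/parallel predictions differ most), a 50/50 serial/parallel
    split among non-epistatic crosses, a small minority of true
    interactions, and additive Gaussian noise of 0.05 fitness units on
    the double-mutant measurement.  The epsilon distribution for the
    epistatic minority is a placeholder (half-normal severity scale 0.5,
    aggravating and ameliorating equally likely); real interaction-effect
    distributions are not characterized here.
    """

    n_crosses: int = 20_000
    frac_parallel: float = 0.5
    frac_epistatic: float = 0.0
    epsilon_scale: float = 0.5
    fitness_range: tuple[float, float] = (0.1, 0.9)
    noise_sd: float = 0.05
    replicate_sd_sd: float = 0.2
    seed: int = 0

    def __post_init__(self):
        if self.n_crosses < 1:
            raise ValidationError("n_crosses must be positive")
        for name in ("frac_parallel", "frac_epistatic"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValidationError(f"{name} must lie in [0, 1], got {v}")
        lo, hi = self.fitness_range
        if not (0.0 < lo <= hi <= 1.0):
            raise ValidationError("fitness_range must satisfy 0 < low <= high <= 1")
        if self.noise_sd < 0 or self.replicate_sd_sd < 0:
            raise ValidationError("noise/replicate dispersions must be >= 0")


def generate(spec: SimulationSpec) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw one cross table plus its ground-truth labels.

    Returns ``(table, truth)``.  ``table`` carries the canonical pipeline
    columns; ``truth`` has per-cross ``true_model`` ("serial"/"parallel"),
    ``is_epistatic``, ``true_epsilon``, and the noise-free ``f_double_true``.
    Deterministic given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_crosses
    lo, hi = spec.fitness_range
    f_query = rng.uniform(lo, hi, n)
    f_array = rng.uniform(lo, hi, n)
    is_parallel = rng.random(n) < spec.frac_parallel
    is_epistatic = rng.random(n) < spec.frac_epistatic

    expected_serial = f_query * f_array
    expected_parallel = 1.0 / (1.0 / f_query + 1.0 / f_array - 1.0)
    f_true = np.where(is_parallel, expected_parallel, expected_serial)

    # True interactions perturb the neutral value on the serial epsilon
    # scale: t_cd = expected * (1 - eps), eps symmetric around 0.
    true_eps = np.zeros(n)
    if is_epistatic.any():
        k = int(is_epistatic.sum())
        eps = np.abs(rng.normal(0.0, spec.epsilon_scale, k))
        eps *= rng.choice([-1.0, 1.0], k)
        true_eps[is_epistatic] = eps
        f_true = f_true * (1.0 - true_eps)
    f_true = np.clip(f_true, 0.0, None)

    f_double = np.clip(f_true + rng.normal(0.0, spec.noise_sd, n), 0.0, None)
    # Reported dispersion scatters multiplicatively around the true noise sd.
    if spec.noise_sd > 0:
        sd_double = spec.noise_sd * np.exp(
            rng.normal(0.0, spec.replicate_sd_sd, n))
    else:
        sd_double = np.zeros(n)

    table = pd.DataFrame({
        "query_id": [f"Q{i:06d}" for i in range(n)],
        "array_id": [f"A{i:06d}" for i in range(n)],
        "f_query": f_query,
        "f_array": f_array,
        "f_double": f_double,
        "sd_double": sd_double,
    })
    truth = pd.DataFrame({
        "true_model": np.where(is_parallel, "parallel", "serial"),
        "is_epistatic": is_epistatic,
        "true_epsilon": true_eps,
        "f_double_true": f_true,
    })
    return table, truth


def bias_recovery_experiment(spec: SimulationSpec, *,
                             fitness_low: float = 0.1, fitness_high: float = 0.9,
                             q_min: float | None = 0.5,
                             df_t: int | None = None) -> dict:
    """Generate a table and run the full residual pipeline on it.

    With a serial/parallel mixture the serial-model residuals should be
    biased positive (parallel-truth crosses grow faster than the serial
    rule predicts), the parallel-model residuals negative, and the
    per-cross hybrid nearer zero than either — the directional signature
    the pipeline exists to detect.  Returns the ``run_pipeline`` dict plus
    the generated ``truth`` table.
    """
    table, truth = generate(spec)
    result = run_pipeline(table, fitness_low=fitness_low,
                          fitness_high=fitness_high, q_min=q_min, df_t=df_t)
    result["truth"] = truth
    return result
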