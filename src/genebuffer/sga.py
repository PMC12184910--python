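"""Residual analysis of SGA (synthetic genetic array) cross tables.

The pipeline ingests a delimited table of yeast double-mutant crosses —
query and array single-mutant fitnesses, the measured double-mutant
fitness, and its standard deviation — and asks which neutrality model
(serial/multiplicative or parallel/additive-in-B) better explains the
measurements:

1. drop incomplete rows;
2. compute each cross's expected double-mutant fitness under both models;
3. per-cross two-tailed tests of observed vs expected, Benjamini–Hochberg
   corrected to q-values within each model family;
4. filter to informative crosses (single fitnesses inside a band where the
   two models actually disagree, q-values large enough that true epistasis
   is unlikely to confound);
5. standardized residuals per model, with the scale estimated once per
   model over the filtered set;
6. a per-cross "hybrid" model that keeps whichever prediction the data
   contradict least (largest q);
7. distribution summaries and two-sample Cramér–von Mises comparisons.

A systematic positive bias of serial-model residuals paired with a
negative parallel-model bias — with the hybrid sitting nearer zero — is
the signature that both relationship types coexist in the data.

Tables are plain pandas DataFrames with canonical columns
(``query_id, array_id, f_query, f_array, f_double, sd_double``); a column
map adapts arbitrary input headers.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import DegenerateInputError, InsufficientDataError, SchemaError, ValidationError
from .neutrality import NeutralityModel

__all__ = [
    "CANONICAL_COLUMNS",
    "DEFAULT_COLUMN_MAP",
    "ResidualSummary",
    "load_crosses",
    "compute_expectations",
    "compute_qvalues",
    "apply_filters",
    "standardized_residuals",
    "hybrid_expectation",
    "summarize_residuals",
    "compare_distributions",
    "run_pipeline",
]

logger = logging.getLogger(__name__)

#: Canonical column roles used throughout the pipeline.
CANONICAL_COLUMNS = ("query_id", "array_id", "f_query", "f_array",
                     "f_double", "sd_double")

#: Input-header -> role mapping for the Costanzo-2009-style supplement
#: export.  Override via ``column_map`` for other dialects; tables already
#: using the canonical names need no mapping at all.
DEFAULT_COLUMN_MAP = {
    "Query ORF": "query_id",
    "Array ORF": "array_id",
    "Query single mutant fitness (SMF)": "f_query",
    "Array SMF": "f_array",
    "Double mutant fitness": "f_double",
    "Double mutant fitness standard deviation": "sd_double",
}

_ID_ROLES = ("query_id", "array_id")
_NUMERIC_ROLES = ("f_query", "f_array", "f_double", "sd_double")


@dataclass(frozen=True)
class ResidualSummary:
    """Location summary of one model's standardized-residual distribution."""

    model: NeutralityModel
    n: int
    median: float
    mean: float
    frac_le_zero: float

    def to_dict(self) -> dict:
        return {"model": self.model.value, "n": self.n, "median": self.median,
                "mean": self.mean, "frac_le_zero": self.frac_le_zero}


def load_crosses(path, column_map: dict | None = None,
                 delimiter: str | None = None) -> tuple[pd.DataFrame, int]:
    """Read a delimited cross table and normalize it to canonical columns.

    Rows with any mapped field missing or unparseable are dropped and
    counted.  Returns ``(table, n_dropped)``.
    """
    df = pd.read_csv(path, sep=delimiter, engine="python")
    if column_map is None:
        if all(c in df.columns for c in CANONICAL_COLUMNS):
            column_map = {c: c for c in CANONICAL_COLUMNS}
        else:
            column_map = DEFAULT_COLUMN_MAP
    missing = [src for src in column_map if src not in df.columns]
    if missing:
        raise SchemaError(
            f"mapped columns {missing} not found; available headers: "
            f"{list(df.columns)}"
        )
    df = df[list(column_map)].rename(columns=column_map)
    for role in _NUMERIC_ROLES:
        if role in df.columns:
            df[role] = pd.to_numeric(df[role], errors="coerce")
    n_raw = len(df)
    df = df.dropna().reset_index(drop=True)
    n_dropped = n_raw - len(df)
    logger.info("load_crosses: %d rows read, %d incomplete rows dropped, %d kept",
                n_raw, n_dropped, len(df))
    return df, n_dropped


def compute_expectations(df: pd.DataFrame) -> pd.DataFrame:
    """Add serial and parallel expected double-mutant fitness columns.

    Serial: product of the single fitnesses.  Parallel: singles converted
    to buffer-to-transfer ratios ``B = (1-f)/f``, summed, converted back
    (``1/(1/f_q + 1/f_a - 1)``).  Crosses with a non-positive single
    fitness get NaN for the parallel expectation (B undefined) and are
    excluded from parallel summaries downstream.
    """
    out = df.copy()
    out["f_expected_serial"] = out["f_query"] * out["f_array"]
    fq, fa = out["f_query"].to_numpy(float), out["f_array"].to_numpy(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        parallel = 1.0 / (1.0 / fq + 1.0 / fa - 1.0)
    parallel = np.where((fq > 0) & (fa > 0), parallel, np.nan)
    out["f_expected_parallel"] = parallel
    n_flagged = int(np.isnan(parallel).sum())
    if n_flagged:
        logger.info("compute_expectations: %d crosses flagged (non-positive "
                    "fitness; parallel expectation undefined)", n_flagged)
    return out


def compute_qvalues(df: pd.DataFrame, model: NeutralityModel | str,
                    df_t: int | None = None) -> pd.DataFrame:
    """Two-tailed per-cross tests of observed vs expected, BH-corrected.

    The per-cross statistic is ``(f_double - f_expected) / sd_double``.
    The null reference is the standard normal by default; pass ``df_t`` to
    use a Student t with that many degrees of freedom instead.  Crosses
    with ``sd_double <= 0`` or an undefined expectation are flagged (NaN
    p and q) and excluded from the BH family.
    """
    model = NeutralityModel(model)
    if model is NeutralityModel.HYBRID:
        raise ValidationError("q-values are computed per serial/parallel family")
    exp_col = f"f_expected_{model.value}"
    if exp_col not in df.columns:
        raise ValidationError(f"run compute_expectations first ({exp_col} missing)")
    out = df.copy()
    sd = out["sd_double"].to_numpy(float)
    expected = out[exp_col].to_numpy(float)
    valid = (sd > 0) & np.isfinite(expected)
    z = np.full(len(out), np.nan)
    z[valid] = (out["f_double"].to_numpy(float)[valid] - expected[valid]) / sd[valid]
    if df_t is None:
        p_valid = 2.0 * stats.norm.sf(np.abs(z[valid]))
    else:
        p_valid = 2.0 * stats.t.sf(np.abs(z[valid]), df=df_t)
    p = np.full(len(out), np.nan)
    p[valid] = p_valid
    q = np.full(len(out), np.nan)
    if valid.any():
        q[valid] = multipletests(p_valid, method="fdr_bh")[1]
    out[f"z_{model.value}"] = z
    out[f"p_{model.value}"] = p
    out[f"q_{model.value}"] = q
    n_excluded = int((~valid).sum())
    if n_excluded:
        logger.info("compute_qvalues[%s]: %d crosses excluded (sd<=0 or "
                    "undefined expectation)", model.value, n_excluded)
    return out


def apply_filters(df: pd.DataFrame, fitness_low: float = 0.1,
                  fitness_high: float = 0.9, q_min: float | None = 0.5,
                  model: NeutralityModel | str | None = None) -> pd.DataFrame:
    """Restrict to informative, likely-non-epistatic crosses.

    Keeps crosses whose single-mutant fitnesses both lie in the closed
    band ``[fitness_low, fitness_high]`` (the models disagree most there;
    the predicted gap vanishes toward 0 and 1) and whose q-value strictly
    exceeds ``q_min``, so that crosses a model already rejects — plausible
    true interactions — cannot confound the bias estimate.

    ``model`` picks the q used: a model name filters on that model's own
    q (the set its residuals are evaluated on — filtering on the rival
    model's q would select noise in the rival's direction and bias the
    estimate); ``"hybrid"`` uses the per-cross larger of the two; ``None``
    demands every computed q exceed the threshold (one conservative
    shared set).  Pass ``q_min=None`` to skip the significance filter.
    """
    mask = (df["f_query"].between(fitness_low, fitness_high)
            & df["f_array"].between(fitness_low, fitness_high))
    if q_min is not None:
        qcols = [c for c in ("q_serial", "q_parallel") if c in df.columns]
        if not qcols:
            raise ValidationError("run compute_qvalues before the q filter")
        if model is None:
            for qcol in qcols:
                mask &= df[qcol] > q_min
        elif NeutralityModel(model) is NeutralityModel.HYBRID:
            mask &= df[qcols].max(axis=1) > q_min
        else:
            qcol = f"q_{NeutralityModel(model).value}"
            if qcol not in df.columns:
                raise ValidationError(f"run compute_qvalues for {model} first")
            mask &= df[qcol] > q_min
    kept = df[mask].reset_index(drop=True)
    logger.info("apply_filters[%s]: %d of %d crosses retained",
                model, len(kept), len(df))
    return kept


def standardized_residuals(df: pd.DataFrame,
                           model: NeutralityModel | str) -> np.ndarray:
    """Residuals ``f_double - f_expected`` scaled by the model's RMS residual.

    The scale ``s = sqrt(sum((obs - exp)^2) / (n - 2))`` is estimated once
    over the (filtered) table handed in, so the residuals of one model
    share a common unit.  Needs at least three crosses; if every cross
    sits exactly on the model (s = 0) the residuals are all zero.
    """
    model = NeutralityModel(model)
    exp_col = f"f_expected_{model.value}"
    if exp_col not in df.columns:
        raise ValidationError(f"run the expectation step first ({exp_col} missing)")
    raw = (df["f_double"] - df[exp_col]).to_numpy(float)
    raw = raw[np.isfinite(raw)]
    n = raw.size
    if n < 3:
        raise InsufficientDataError(
            f"standardized residuals need n >= 3 crosses, got {n}"
        )
    s = math.sqrt(float(np.sum(raw**2)) / (n - 2))
    if s == 0.0:
        return np.zeros(n)
    return raw / s


def hybrid_expectation(df: pd.DataFrame) -> pd.DataFrame:
    """Per cross, keep whichever model's prediction the data contradict least.

    The model with the larger q-value (least evidence of deviation) wins;
    exact ties go to serial, the incumbent model.  Adds
    ``f_expected_hybrid`` and ``hybrid_model`` columns.
    """
    for col in ("q_serial", "q_parallel"):
        if col not in df.columns:
            raise ValidationError(f"run compute_qvalues for both models first "
                                  f"({col} missing)")
    out = df.copy()
    qs = out["q_serial"].to_numpy(float)
    qp = out["q_parallel"].to_numpy(float)
    # NaN q (undefined parallel expectation) never beats a finite serial q.
    pick_parallel = np.where(np.isnan(qp), False,
                             np.where(np.isnan(qs), True, qp > qs))
    out["hybrid_model"] = np.where(pick_parallel, "parallel", "serial")
    out["f_expected_hybrid"] = np.where(
        pick_parallel, out["f_expected_parallel"], out["f_expected_serial"])
    return out


def summarize_residuals(residuals: np.ndarray,
                        model: NeutralityModel | str = NeutralityModel.SERIAL
                        ) -> ResidualSummary:
    """Median, mean, and fraction <= 0 of a residual sample."""
    residuals = np.asarray(residuals, float)
    residuals = residuals[np.isfinite(residuals)]
    if residuals.size == 0:
        raise InsufficientDataError("cannot summarize an empty residual set")
    return ResidualSummary(
        model=NeutralityModel(model),
        n=int(residuals.size),
        median=float(np.median(residuals)),
        mean=float(np.mean(residuals)),
        frac_le_zero=float(np.mean(residuals <= 0.0)),
    )


def compare_distributions(residuals_a: np.ndarray,
                          residuals_b: np.ndarray) -> float:
    """Two-sample Cramér–von Mises p-value for two residual distributions."""
    a = np.asarray(residuals_a, float)
    b = np.asarray(residuals_b, float)
    if a.size == 0 or b.size == 0:
        raise InsufficientDataError("both samples must be nonempty")
    if np.ptp(a) == 0 and np.ptp(b) == 0 and a[0] == b[0]:
        logger.warning("compare_distributions: both samples are the same "
                       "constant; the test is degenerate (p = 1)")
        return 1.0
    return float(stats.cramervonmises_2samp(a, b).pvalue)


def run_pipeline(df: pd.DataFrame, *, fitness_low: float = 0.1,
                 fitness_high: float = 0.9, q_min: float | None = 0.5,
                 df_t: int | None = None) -> dict:
    """Run expectation -> q-value -> filter -> residual analysis end to end.

    Each model's residuals are computed over the set its own q-filter
    retains (see :func:`apply_filters`); ``n_retained`` reports those
    per-model counts plus the conservative shared set.  Returns a dict
    with the augmented table (``table``), counts (``n_retained``),
    per-model :class:`ResidualSummary` objects (``summaries``), the
    residual arrays (``residuals``), and pairwise Cramér–von Mises
    p-values (``cvm``).
    """
    df = compute_expectations(df)
    df = compute_qvalues(df, NeutralityModel.SERIAL, df_t=df_t)
    df = compute_qvalues(df, NeutralityModel.PARALLEL, df_t=df_t)
    df = hybrid_expectation(df)
    residuals = {}
    summaries = {}
    n_retained = {}
    for model in (NeutralityModel.SERIAL, NeutralityModel.PARALLEL,
                  NeutralityModel.HYBRID):
        filtered = apply_filters(df, fitness_low=fitness_low,
                                 fitness_high=fitness_high, q_min=q_min,
                                 model=model)
        n_retained[model.value] = len(filtered)
        try:
            res = standardized_residuals(filtered, model)
        except InsufficientDataError:
            continue
        residuals[model.value] = res
        summaries[model.value] = summarize_residuals(res, model)
    n_retained["shared"] = len(apply_filters(
        df, fitness_low=fitness_low, fitness_high=fitness_high,
        q_min=q_min, model=None)) if q_min is not None else n_retained["serial"]
    cvm = {}
    names = list(residuals)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            cvm[f"{a}_vs_{b}"] = compare_distributions(residuals[a], residuals[b])
    return {"table": df, "n_retained": n_retained,
            "summaries": summaries, "residuals": residuals, "cvm": cvm}
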