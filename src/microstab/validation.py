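"""Method-validation statistics and threshold-based acceptance.

Covers intra-/inter-batch precision and accuracy of QC replicates,
extraction recovery and matrix effect from paired two-group designs,
the IS-normalized matrix effect, a quantitative carryover check on the
blank injected after a high standard, and an overall pass/fail report.

Formulas:
  precision  %RSD     = 100 * SD / mean
  accuracy   %error   = 100 * (mean - nominal) / nominal
  recovery   %        = 100 * mean / nominal
  matrix effect %     = 100 * mean(set1 matrix) / mean(set2 neat)
  IS-normalized ME    = ME(analyte) / ME(IS)      (unitless, not x100)
  carryover fraction  = blank response / LLOQ response
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np

from .calibration import summarize_level
from .datatypes import AcceptanceThresholds, AnalyteMeasurement
from .errors import DegenerateFitError, IncompleteRunError, InsufficientDataError

__all__ = [
    "QcStatistics",
    "MatrixEffectResult",
    "CarryoverResult",
    "CriterionResult",
    "AcceptanceReport",
    "qc_statistics",
    "extraction_recovery",
    "matrix_effect",
    "is_normalized_me",
    "carryover_check",
    "evaluate_acceptance",
]


@dataclass(frozen=True)
class QcStatistics:
    """Precision/accuracy of one QC level at one batch scope."""

    level_name: str  # LLQC / LQC / MQC / HQC
    scope: str  # intra_batch / inter_batch
    nominal: float
    n: int
    mean: float
    sd: float
    precision_rsd_pct: float
    accuracy_pct: float
    recovery_pct: float


@dataclass(frozen=True)
class MatrixEffectResult:
    me_analyte_pct: float
    me_is_pct: float
    is_normalized_me: float


@dataclass(frozen=True)
class CarryoverResult:
    fraction_of_lloq: float
    limit: float
    passed: bool


@dataclass(frozen=True)
class CriterionResult:
    name: str
    value: float
    limit: str
    passed: bool


@dataclass(frozen=True)
class AcceptanceReport:
    criteria: list[CriterionResult] = field(default_factory=list)

    @property
    def overall_pass(self) -> bool:
        return all(c.passed for c in self.criteria)

    @property
    def failures(self) -> list[CriterionResult]:
        return [c for c in self.criteria if not c.passed]


def qc_statistics(
    qc_back_calcs: Sequence[float],
    nominal: float,
    scope: str = "intra_batch",
    level_name: str = "",
) -> QcStatistics:
    """Precision/accuracy statistics for QC replicates at one level.

    Inter-batch statistics pool all replicates across batches rather
    than averaging per-batch means.
    """
    if scope not in ("intra_batch", "inter_batch"):
        raise ValueError(f"unknown scope {scope!r}")
    s = summarize_level(qc_back_calcs, nominal)
    return QcStatistics(
        level_name=level_name,
        scope=scope,
        nominal=s.nominal,
        n=s.n,
        mean=s.mean_back_calc,
        sd=s.sd,
        precision_rsd_pct=s.rsd_pct,
        accuracy_pct=s.accuracy_pct,
        recovery_pct=s.recovery_pct,
    )


def _mean_response(values: Sequence[float], what: str) -> float:
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise InsufficientDataError(f"{what}: empty response group")
    return float(arr.mean())


def extraction_recovery(
    matrix_qcs: Sequence[float], neat_qcs: Sequence[float]
) -> float:
    """Percent recovery: 100 * mean(matrix-extracted) / mean(neat)."""
    b = _mean_response(matrix_qcs, "matrix")
    a = _mean_response(neat_qcs, "neat")
    if a == 0:
        raise DegenerateFitError("neat reference mean is zero")
    return 100.0 * b / a


def matrix_effect(
    set1_matrix: Sequence[float], set2_neat: Sequence[float]
) -> float:
    """Matrix effect %: 100 * mean(set 1, matrix) / mean(set 2, neat).

    Both groups must carry the same response type (areas or ratios).
    """
    return extraction_recovery(set1_matrix, set2_neat)


def is_normalized_me(me_analyte_pct: float, me_is_pct: float) -> float:
    """IS-normalized matrix effect: analyte ME / IS ME (unitless ratio)."""
    if me_is_pct == 0:
        raise ZeroDivisionError("IS matrix effect is zero")
    return me_analyte_pct / me_is_pct


def carryover_check(
    blank_after_high: Union[AnalyteMeasurement, float],
    lloq_response: float,
    thresholds: Optional[AcceptanceThresholds] = None,
) -> CarryoverResult:
    """Blank signal after a high sample as a fraction of the LLOQ response."""
    thresholds = thresholds or AcceptanceThresholds()
    if lloq_response <= 0:
        raise ValueError("LLOQ response must be positive")
    blank = (
        blank_after_high.analyte_area
        if isinstance(blank_after_high, AnalyteMeasurement)
        else float(blank_after_high)
    )
    frac = blank / lloq_response
    limit = thresholds.carryover_max_fraction_of_lloq
    return CarryoverResult(fraction_of_lloq=frac, limit=limit, passed=frac <= limit)


def evaluate_acceptance(
    qc_stats: Sequence[QcStatistics],
    thresholds: Optional[AcceptanceThresholds] = None,
    calibration_r2: Optional[float] = None,
    matrix_result: Optional[MatrixEffectResult] = None,
    carryover: Optional[CarryoverResult] = None,
    required_levels: Sequence[str] = ("LLQC", "LQC", "MQC", "HQC"),
) -> AcceptanceReport:
    """Score every validation statistic against its threshold.

    The report lists every criterion as (value, limit, verdict); the
    overall verdict is the conjunction. Failures are listed, never
    hidden. Raises :class:`IncompleteRunError` naming the first QC level
    with no statistics.
    """
    thresholds = thresholds or AcceptanceThresholds()
    present = {s.level_name for s in qc_stats}
    for level in required_levels:
        if level not in present:
            raise IncompleteRunError(f"no QC statistics for level {level!r}")

    criteria: list[CriterionResult] = []
    for s in qc_stats:
        is_lloq = s.level_name == "LLQC"
        bias_lim = thresholds.max_bias_pct_lloq if is_lloq else thresholds.max_bias_pct
        rsd_lim = thresholds.max_rsd_pct_lloq if is_lloq else thresholds.max_rsd_pct
        criteria.append(
            CriterionResult(
                name=f"{s.level_name}:{s.scope}:accuracy",
                value=s.accuracy_pct,
                limit=f"|bias| <= {bias_lim}%",
                passed=abs(s.accuracy_pct) <= bias_lim,
            )
        )
        criteria.append(
            CriterionResult(
                name=f"{s.level_name}:{s.scope}:precision",
                value=s.precision_rsd_pct,
                limit=f"RSD <= {rsd_lim}%",
                passed=s.precision_rsd_pct <= rsd_lim,
            )
        )
    if calibration_r2 is not None:
        criteria.append(
            CriterionResult(
                name="calibration:r2",
                value=calibration_r2,
                limit=f"r2 >= {thresholds.min_r2}",
                passed=calibration_r2 >= thresholds.min_r2,
            )
        )
    if matrix_result is not None:
        lo, hi = thresholds.me_normalized_low, thresholds.me_normalized_high
        criteria.append(
            CriterionResult(
                name="matrix_effect:is_normalized",
                value=matrix_result.is_normalized_me,
                limit=f"{lo} <= ME_norm <= {hi}",
                passed=lo <= matrix_result.is_normalized_me <= hi,
            )
        )
    if carryover is not None:
        criteria.append(
            CriterionResult(
                name="carryover:fraction_of_lloq",
                value=carryover.fraction_of_lloq,
                limit=f"fraction <= {carryover.limit}",
                passed=carryover.passed,
            )
        )
    return AcceptanceReport(criteria=criteria)
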