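"""Domain types and unit conventions shared by all pipeline stages.

Units are fixed globally: concentration in ng/mL, time in minutes,
detector responses in arbitrary counts, intrinsic clearance reported in
mL/min/kg (headline) and uL/min/mg (per-mg incubation scale).
"""

from __future__ import annotations

import enum
from typing import Optional

from pydantic import BaseModel, ConfigDict, Field, model_validator

from .errors import MissingInternalStandardError

__all__ = [
    "Role",
    "AnalyteMeasurement",
    "StudyDesign",
    "AcceptanceThresholds",
    "ClearanceBands",
    "area_ratio",
]


class Role(str, enum.Enum):
    """What a sample row represents in the study design."""

    standard = "standard"
    qc = "qc"
    blank = "blank"
    blank_with_is = "blank_with_is"
    matrix_set1 = "matrix_set1"  # analyte spiked into biological matrix
    neat_set2 = "neat_set2"  # analyte in neat solvent / mobile phase
    timepoint = "timepoint"  # metabolic-stability incubation stop point


class AnalyteMeasurement(BaseModel):
    """One integrated-peak-area observation for one sample.

    Quantification uses the analyte/IS peak-area ratio, so ``is_area`` is
    required for every role except plain blanks. ``time_min`` is present
    exactly for incubation time points.
    """

    model_config = ConfigDict(frozen=True)

    sample_id: str
    role: Role
    nominal_conc: Optional[float] = Field(default=None, gt=0)
    analyte_area: float = Field(ge=0)
    is_area: Optional[float] = Field(default=None, ge=0)
    replicate_id: int = Field(default=1, ge=1)
    batch_id: int = Field(default=1, ge=1)
    time_min: Optional[float] = Field(default=None, ge=0)

    @model_validator(mode="after")
    def _role_requirements(self) -> "AnalyteMeasurement":
        if self.role is Role.timepoint:
            if self.time_min is None:
                raise ValueError("timepoint rows require time_min")
        elif self.time_min is not None:
            raise ValueError(f"time_min only allowed for timepoint rows, not {self.role.value}")
        if self.role in (Role.standard, Role.qc) and self.nominal_conc is None:
            raise ValueError(f"{self.role.value} rows require nominal_conc")
        if self.role in (Role.blank, Role.blank_with_is, Role.timepoint) and self.nominal_conc is not None:
            raise ValueError(f"{self.role.value} rows must not carry nominal_conc")
        return self


def area_ratio(m: AnalyteMeasurement) -> float:
    """Analyte/IS peak-area ratio, the response used for quantification.

    Raises :class:`MissingInternalStandardError` when the IS area is
    absent or zero.
    """
    if m.is_area is None or m.is_area == 0:
        raise MissingInternalStandardError(
            f"sample {m.sample_id!r}: internal-standard area absent or zero"
        )
    return m.analyte_area / m.is_area


class StudyDesign(BaseModel):
    """Concentration levels and physiological scaling constants.

    Defaults reproduce the published selpercatinib/HLM study design:
    eleven standards over 1-3000 ng/mL, four QC levels, and well-stirred
    scaling constants of 45 mg microsomal protein per g liver and
    26 g liver per kg body weight with a 1 mL / 1 mg protein incubation.
    """

    calibration_levels: list[float] = Field(
        default=[1, 3, 15, 50, 100, 300, 500, 900, 1500, 2400, 3000]
    )
    qc_levels: dict[str, float] = Field(
        default={"LLQC": 1.0, "LQC": 3.0, "MQC": 900.0, "HQC": 2400.0}
    )
    incubation_volume_mL: float = Field(default=1.0, gt=0)
    microsomal_protein_mg: float = Field(default=1.0, gt=0)
    mg_protein_per_g_liver: float = Field(default=45.0, gt=0)
    g_liver_per_kg_bw: float = Field(default=26.0, gt=0)

    @model_validator(mode="after")
    def _levels_valid(self) -> "StudyDesign":
        lv = self.calibration_levels
        if len(lv) < 2:
            raise ValueError("need >= 2 calibration levels")
        if any(b <= a for a, b in zip(lv, lv[1:])):
            raise ValueError("calibration levels must be strictly increasing")
        if any(v <= 0 for v in lv):
            raise ValueError("calibration levels must be positive")
        if any(v <= 0 for v in self.qc_levels.values()):
            raise ValueError("QC levels must be positive")
        return self


class AcceptanceThresholds(BaseModel):
    """Numeric pass/fail limits for method validation.

    Defaults follow common bioanalytical-guideline practice (15% bias and
    RSD, relaxed to 20% at the LLOQ); they are configuration, not
    constants, and every limit can be overridden per run.
    """

    max_bias_pct: float = Field(default=15.0, gt=0)
    max_bias_pct_lloq: float = Field(default=20.0, gt=0)
    max_rsd_pct: float = Field(default=15.0, gt=0)
    max_rsd_pct_lloq: float = Field(default=20.0, gt=0)
    min_r2: float = Field(default=0.98, gt=0)
    carryover_max_fraction_of_lloq: float = Field(default=0.20, gt=0)
    me_normalized_low: float = Field(default=0.85, gt=0)
    me_normalized_high: float = Field(default=1.15, gt=0)

    @model_validator(mode="after")
    def _lloq_relaxed(self) -> "AcceptanceThresholds":
        if self.max_bias_pct_lloq < self.max_bias_pct:
            raise ValueError("LLOQ bias threshold must be >= non-LLOQ threshold")
        if self.max_rsd_pct_lloq < self.max_rsd_pct:
            raise ValueError("LLOQ RSD threshold must be >= non-LLOQ threshold")
        if self.me_normalized_high <= self.me_normalized_low:
            raise ValueError("normalized-ME range must have low < high")
        return self


class ClearanceBands(BaseModel):
    """Cut-points (mL/min/kg) for low / intermediate / high clearance.

    Defaults place the low/intermediate boundary at 15 and the
    intermediate/high boundary at 45 mL/min/kg (McNaney-style scoring);
    both are configurable because published scoring schemes vary.
    """

    low_max: float = Field(default=15.0, gt=0)
    high_min: float = Field(default=45.0, gt=0)

    @model_validator(mode="after")
    def _ordered(self) -> "ClearanceBands":
        if not self.low_max < self.high_min:
            raise ValueError("bands require low_max < high_min")
        return self
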