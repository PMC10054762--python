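"""Synthetic instrument-output generators.

No public repository of raw LC-MS/MS peak areas exists for this assay,
so every input table the pipeline consumes can be simulated with the
statistical structure the analysis assumes:

* calibration standards: linear response ratio over 1-3000 ng/mL with
  additive + proportional Gaussian noise on the ratio;
* QC replicates: the same response model at the four QC levels, over one
  or several batches;
* paired matrix-effect sets: matrix-spiked (set 1) vs neat-solvent
  (set 2) responses with a configurable true matrix effect;
* depletion time course: a fast first-order phase decaying toward a
  non-depleting plateau, C(t) = c0 * ((1-p) * exp(-k t) + p), with
  multiplicative lognormal replicate noise (concentrations are positive
  and dispersion is roughly proportional to the mean).

All generators are deterministic given their seed.
"""

from __future__ import annotations

import logging
from typing import Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator

from .datatypes import AnalyteMeasurement, Role, StudyDesign
from .io import measurements_to_frame

__all__ = [
    "CalibrationSimParams",
    "DepletionSimParams",
    "simulate_calibration",
    "simulate_qc",
    "simulate_matrix_effect_sets",
    "simulate_depletion",
]

logger = logging.getLogger(__name__)

#: fixed internal-standard response used to back-derive analyte areas
IS_AREA = 40000.0


class CalibrationSimParams(BaseModel):
    """True line and noise model for simulated calibration standards.

    The default slope/intercept reproduce the published regression
    (ratio = 1.7298 * conc + 3.62941). Noise on the ratio at level x is
    Normal with SD = additive_sd + proportional_cv * slope_true * x.
    The additive default gives ~2% replicate RSD at the 1 ng/mL LLOQ;
    the proportional default is pinned by the published intercept
    dispersion (LOD 0.26 ng/mL implies SD(intercept) ~ 0.14 ratio
    units): with unweighted fitting over a 3000-fold range the intercept
    SD scales as ~160 x proportional_cv, so cv must stay near 0.001 for
    the low end of the curve to remain quantifiable.
    """

    slope_true: float = Field(default=1.7298, gt=0)
    intercept_true: float = 3.62941
    additive_sd: float = Field(default=0.03, ge=0)
    proportional_cv: float = Field(default=0.001, ge=0, lt=1)
    n_replicates: int = Field(default=6, ge=1)
    seed: int = 0


class DepletionSimParams(BaseModel):
    """Biphasic substrate-depletion model parameters.

    Defaults emulate the published time course: c0 = 626 ng/mL,
    k = 0.0291 /min over the initial log-linear phase, with ~30% of the
    starting material persisting as a plateau by 70 min.
    """

    c0: float = Field(default=626.0, gt=0)
    k_dep: float = Field(default=0.0291, gt=0)
    plateau_fraction: float = Field(default=0.30, ge=0, lt=1)
    replicate_cv: float = Field(default=0.05, ge=0)
    times_min: list[float] = Field(
        default=[0, 2.5, 7.5, 15, 20, 30, 40, 50, 60, 70]
    )
    n_replicates: int = Field(default=3, ge=1)
    seed: int = 0

    @model_validator(mode="after")
    def _times_ok(self) -> "DepletionSimParams":
        if 0 not in self.times_min:
            raise ValueError("times_min must include t = 0")
        if sorted(self.times_min) != list(self.times_min):
            raise ValueError("times_min must be ascending")
        return self


def _noisy_ratio(rng, mean_ratio: float, sd: float) -> float:
    """Draw one non-negative ratio; resample (never truncate) negatives
    so low-concentration levels stay unbiased."""
    for _ in range(1000):
        r = rng.normal(mean_ratio, sd)
        if r >= 0:
            return float(r)
        logger.warning("resampling negative simulated ratio at mean %.4g", mean_ratio)
    raise RuntimeError("noise model keeps producing negative ratios")


def simulate_calibration(
    params: CalibrationSimParams, design: Optional[StudyDesign] = None
) -> pd.DataFrame:
    """Simulate a standards table (one batch, all levels x replicates)."""
    design = design or StudyDesign()
    rng = np.random.default_rng(params.seed)
    rows = []
    for level in design.calibration_levels:
        mean_ratio = params.slope_true * level + params.intercept_true
        sd = params.additive_sd + params.proportional_cv * params.slope_true * level
        for rep in range(1, params.n_replicates + 1):
            ratio = mean_ratio if sd == 0 else _noisy_ratio(rng, mean_ratio, sd)
            rows.append(
                AnalyteMeasurement(
                    sample_id=f"std_{level:g}_{rep}",
                    role=Role.standard,
                    nominal_conc=level,
                    analyte_area=ratio * IS_AREA,
                    is_area=IS_AREA,
                    replicate_id=rep,
                )
            )
    return measurements_to_frame(rows)


def simulate_qc(
    params: CalibrationSimParams,
    design: Optional[StudyDesign] = None,
    n_replicates: int = 12,
    n_batches: int = 1,
    seed: Optional[int] = None,
) -> pd.DataFrame:
    """Simulate QC replicate tables at the four QC levels.

    ``n_batches > 1`` yields inter-batch data (e.g. 6 replicates on each
    of 3 days); batch ids are 1-based.
    """
    design = design or StudyDesign()
    rng = np.random.default_rng(params.seed if seed is None else seed)
    rows = []
    for batch in range(1, n_batches + 1):
        for name, level in design.qc_levels.items():
            mean_ratio = params.slope_true * level + params.intercept_true
            sd = params.additive_sd + params.proportional_cv * params.slope_true * level
            for rep in range(1, n_replicates + 1):
                ratio = mean_ratio if sd == 0 else _noisy_ratio(rng, mean_ratio, sd)
                rows.append(
                    AnalyteMeasurement(
                        sample_id=f"{name}_b{batch}_{rep}",
                        role=Role.qc,
                        nominal_conc=level,
                        analyte_area=ratio * IS_AREA,
                        is_area=IS_AREA,
                        replicate_id=rep,
                        batch_id=batch,
                    )
                )
    return measurements_to_frame(rows)


def simulate_matrix_effect_sets(
    true_me_analyte: float = 100.0,
    true_me_is: float = 100.0,
    cv: float = 0.0,
    n: int = 6,
    seed: int = 0,
    neat_analyte_area: float = 50000.0,
    neat_is_area: float = IS_AREA,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Paired matrix-spiked (set 1) and neat-solvent (set 2) tables.

    Set-2 responses sit at their nominal areas; set-1 responses are
    scaled by true_me/100 with lognormal noise of the given CV, so the
    mean-ratio matrix-effect estimator recovers true_me in expectation.
    """
    if n < 2:
        raise ValueError("need n >= 2 paired samples")
    rng = np.random.default_rng(seed)
    sigma = np.sqrt(np.log1p(cv**2))

    def _draw(mean: float) -> float:
        if cv == 0:
            return mean
        return float(mean * rng.lognormal(-0.5 * sigma**2, sigma))

    set1, set2 = [], []
    for rep in range(1, n + 1):
        set1.append(
            AnalyteMeasurement(
                sample_id=f"matrix_{rep}",
                role=Role.matrix_set1,
                analyte_area=_draw(neat_analyte_area * true_me_analyte / 100.0),
                is_area=_draw(neat_is_area * true_me_is / 100.0),
                replicate_id=rep,
            )
        )
        set2.append(
            AnalyteMeasurement(
                sample_id=f"neat_{rep}",
                role=Role.neat_set2,
                analyte_area=_draw(neat_analyte_area),
                is_area=_draw(neat_is_area),
                replicate_id=rep,
            )
        )
    return measurements_to_frame(set1), measurements_to_frame(set2)


def simulate_depletion(params: DepletionSimParams) -> pd.DataFrame:
    """Simulate a depletion time course (time_min, replicate_id, conc_ng_ml).

    Mean curve: C(t) = c0 * ((1 - plateau) * exp(-k t) + plateau).
    Replicates multiply the mean by lognormal noise with the given CV
    (unit mean), so the t = 0 expectation equals c0 for any settings.
    """
    rng = np.random.default_rng(params.seed)
    sigma = np.sqrt(np.log1p(params.replicate_cv**2))
    rows = []
    for t in params.times_min:
        mean = params.c0 * (
            (1.0 - params.plateau_fraction) * np.exp(-params.k_dep * t)
            + params.plateau_fraction
        )
        for rep in range(1, params.n_replicates + 1):
            noise = 1.0 if sigma == 0 else rng.lognormal(-0.5 * sigma**2, sigma)
            rows.append(
                {"time_min": t, "replicate_id": rep, "conc_ng_ml": mean * noise}
            )
    return pd.DataFrame(rows, columns=["time_min", "replicate_id", "conc_ng_ml"])
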