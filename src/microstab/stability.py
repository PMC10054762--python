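"""Metabolic-stability kinetics from substrate-depletion time courses.

The workflow mirrors the in vitro t1/2 ("substrate depletion") method:

1. average replicate concentrations per stop time and normalize to the
   t = 0 mean as % remaining;
2. select the log-linear depletion phase (manually, e.g. 0-30 min, or
   automatically as the longest prefix anchored at t = 0 whose ln-linear
   fit clears an r-squared floor);
3. fit ln(% remaining) on time by unweighted OLS (the same kernel as the
   calibration line); the first-order rate constant k is |slope|;
4. in vitro t1/2 = ln 2 / k;
5. scale to intrinsic clearance with the well-stirred constants:
   CLint [mL/min/kg] = (0.693 / t1/2) * (mL incubation / mg protein)
                       * (mg microsomal protein / g liver)
                       * (g liver / kg body weight),
   and per-mg CLint [uL/min/mg] = 1000 * (0.693 / t1/2) * (mL/mg);
6. classify clearance as low / intermediate / high against configurable
   band cut-points (defaults: < 15, 15-45, > 45 mL/min/kg).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from ._regression import ols_line
from .datatypes import ClearanceBands, StudyDesign
from .errors import (
    ConfigError,
    InsufficientDataError,
    NoDepletionError,
    NoLinearPhaseError,
    NormalizationError,
)

__all__ = [
    "DepletionTimeCourse",
    "StabilityResult",
    "DepletionKinetics",
    "percent_remaining",
    "select_linear_phase",
    "fit_depletion",
    "half_life",
    "intrinsic_clearance",
    "classify_clearance",
]

#: literal constant of the printed well-stirred scaling formula
_CL_CONST = 0.693


@dataclass(frozen=True)
class DepletionTimeCourse:
    """Replicate-averaged depletion time course normalized to t = 0."""

    times_min: np.ndarray
    mean_conc: np.ndarray
    pct_remaining: np.ndarray  # 100 at t = 0 by construction
    ln_pct_remaining: np.ndarray

    def subset(self, mask) -> "DepletionTimeCourse":
        mask = np.asarray(mask, dtype=bool)
        return DepletionTimeCourse(
            self.times_min[mask],
            self.mean_conc[mask],
            self.pct_remaining[mask],
            self.ln_pct_remaining[mask],
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_min": self.times_min,
                "mean_conc_ng_ml": self.mean_conc,
                "pct_remaining": self.pct_remaining,
                "ln_pct_remaining": self.ln_pct_remaining,
            }
        )


@dataclass(frozen=True)
class StabilityResult:
    """Ln-linear fit over the selected phase and derived kinetics."""

    window: tuple[float, float]
    slope: float  # signed, per minute
    intercept_ln: float
    r2: float
    k_dep: float  # |slope|
    t_half_min: float
    clint_ml_min_kg: float
    clint_ul_min_mg: float
    clearance_class: str


def percent_remaining(
    timecourse: pd.DataFrame, time_col: str = "time_min", conc_col: str = "conc_ng_ml"
) -> DepletionTimeCourse:
    """Average replicates per stop time and normalize to the t = 0 mean.

    pct(t) = 100 * mean_conc(t) / mean_conc(0); ln_pct is its natural log.
    """
    df = timecourse[[time_col, conc_col]].dropna()
    means = df.groupby(time_col, sort=True)[conc_col].mean()
    times = means.index.to_numpy(float)
    conc = means.to_numpy(float)
    if 0.0 not in times:
        raise NormalizationError("time course must include t = 0")
    c0 = conc[times == 0.0][0]
    if c0 <= 0:
        raise NormalizationError("t = 0 mean concentration must be positive")
    pct = 100.0 * conc / c0
    with np.errstate(divide="ignore"):
        ln_pct = np.log(pct)
    return DepletionTimeCourse(times, conc, pct, ln_pct)


def select_linear_phase(
    tc: DepletionTimeCourse,
    mode: str = "manual",
    window: Optional[tuple[float, float]] = None,
    min_points: int = 4,
    r2_floor: float = 0.98,
) -> DepletionTimeCourse:
    """Pick the log-linear depletion phase.

    manual: all points with t_start <= t <= t_end.
    auto: the longest prefix of time points starting at t = 0 whose
    ln-linear fit has r2 >= r2_floor (ties broken toward more points);
    prefixes are anchored at the baseline so internal windows cannot be
    cherry-picked.
    """
    if mode == "manual":
        if window is None:
            raise ValueError("manual selection requires a window")
        t0, t1 = window
        sub = tc.subset((tc.times_min >= t0) & (tc.times_min <= t1))
        if sub.times_min.size < 2:
            raise InsufficientDataError("window contains < 2 points")
        return sub
    if mode != "auto":
        raise ValueError(f"unknown mode {mode!r}")
    n = tc.times_min.size
    if n < min_points:
        raise InsufficientDataError(
            f"auto selection needs >= {min_points} points, got {n}"
        )
    best = None
    for end in range(min_points, n + 1):
        sub = tc.subset(np.arange(n) < end)
        fit = ols_line(sub.times_min, sub.ln_pct_remaining)
        if fit.r2 >= r2_floor:
            best = sub  # longest qualifying prefix wins
    if best is None:
        raise NoLinearPhaseError(
            f"no prefix of >= {min_points} points reaches r2 >= {r2_floor}; "
            "select the window manually"
        )
    return best


def fit_depletion(subset: DepletionTimeCourse) -> tuple[float, float, float]:
    """Unweighted OLS of ln(% remaining) on time: (slope, intercept, r2)."""
    n = subset.times_min.size
    if n < 2:
        raise InsufficientDataError("need >= 2 points to fit depletion")
    if n == 2:
        warnings.warn("two-point depletion fit is exact by construction")
    fit = ols_line(subset.times_min, subset.ln_pct_remaining)
    return fit.slope, fit.intercept, fit.r2


def half_life(slope: float, slope_decimals: Optional[int] = None) -> float:
    """In vitro half-life (min) from the ln-linear slope: t1/2 = ln2/|slope|.

    ``slope_decimals`` rounds the slope first, reproducing the
    reported-precision arithmetic chain (e.g. 4 d.p. gives 23.82 min for
    the published fit instead of the full-precision 23.85 min).
    """
    if slope >= 0:
        raise NoDepletionError(
            "slope is non-negative: no measurable depletion, t1/2 undefined"
        )
    k = abs(slope if slope_decimals is None else round(slope, slope_decimals))
    return float(np.log(2) / k)


def intrinsic_clearance(
    t_half: float, design: Optional[StudyDesign] = None
) -> tuple[float, float]:
    """Scale t1/2 to intrinsic clearance: (mL/min/kg, uL/min/mg)."""
    if t_half <= 0:
        raise ValueError("t_half must be positive")
    design = design or StudyDesign()
    per_mg = (_CL_CONST / t_half) * (
        design.incubation_volume_mL / design.microsomal_protein_mg
    )
    ml_min_kg = per_mg * design.mg_protein_per_g_liver * design.g_liver_per_kg_bw
    return float(ml_min_kg), float(per_mg * 1000.0)


def classify_clearance(
    clint_ml_min_kg: float,
    bands: Optional[Union[ClearanceBands, dict]] = None,
) -> str:
    """low / intermediate / high against the band cut-points."""
    if bands is None:
        bands = ClearanceBands()
    elif isinstance(bands, dict):
        try:
            bands = ClearanceBands(**bands)
        except Exception as exc:
            raise ConfigError(f"malformed clearance bands: {exc}") from exc
    if clint_ml_min_kg < bands.low_max:
        return "low"
    if clint_ml_min_kg > bands.high_min:
        return "high"
    return "intermediate"


class DepletionKinetics(BaseEstimator):
    """Estimator for first-order depletion kinetics and intrinsic clearance.

    Parameters
    ----------
    mode : {"manual", "auto"}
        Phase selection strategy; manual uses ``window``.
    window : (t_start, t_end), default (0, 30)
        Minutes; used in manual mode.
    min_points, r2_floor
        Auto-mode prefix requirements.
    slope_decimals : int or None
        Round the fitted slope before deriving t1/2 (reported-precision
        mode); None carries full precision.
    thalf_decimals : int or None
        Round t1/2 before the clearance scaling (reported-precision
        chain); None carries full precision.
    design : StudyDesign
        Incubation and well-stirred scaling constants.
    bands : ClearanceBands
        Clearance classification cut-points.

    Attributes (after ``fit``)
    --------------------------
    slope_, intercept_ln_, r2_, k_dep_, t_half_min_, clint_ml_min_kg_,
    clint_ul_min_mg_, clearance_class_, window_, timecourse_
    """

    def __init__(
        self,
        mode: str = "manual",
        window: tuple[float, float] = (0.0, 30.0),
        min_points: int = 4,
        r2_floor: float = 0.98,
        slope_decimals: Optional[int] = None,
        thalf_decimals: Optional[int] = None,
        design: Optional[StudyDesign] = None,
        bands: Optional[ClearanceBands] = None,
    ):
        self.mode = mode
        self.window = window
        self.min_points = min_points
        self.r2_floor = r2_floor
        self.slope_decimals = slope_decimals
        self.thalf_decimals = thalf_decimals
        self.design = design
        self.bands = bands

    def fit(self, X: pd.DataFrame, y=None) -> "DepletionKinetics":
        """Fit from a time-course table (time_min, [replicate_id], conc_ng_ml)."""
        tc = percent_remaining(X)
        sub = select_linear_phase(
            tc,
            mode=self.mode,
            window=self.window if self.mode == "manual" else None,
            min_points=self.min_points,
            r2_floor=self.r2_floor,
        )
        slope, intercept, r2 = fit_depletion(sub)
        t_half = half_life(slope, self.slope_decimals)
        if self.thalf_decimals is not None:
            t_half = round(t_half, self.thalf_decimals)
        cl_kg, cl_mg = intrinsic_clearance(t_half, self.design)
        self.timecourse_ = tc
        self.phase_ = sub
        self.window_ = (float(sub.times_min.min()), float(sub.times_min.max()))
        self.slope_ = slope
        self.intercept_ln_ = intercept
        self.r2_ = r2
        self.k_dep_ = abs(slope)
        self.t_half_min_ = t_half
        self.clint_ml_min_kg_ = cl_kg
        self.clint_ul_min_mg_ = cl_mg
        self.clearance_class_ = classify_clearance(cl_kg, self.bands)
        return self

    @property
    def result_(self) -> StabilityResult:
        check_is_fitted(self, "slope_")
        return StabilityResult(
            window=self.window_,
            slope=self.slope_,
            intercept_ln=self.intercept_ln_,
            r2=self.r2_,
            k_dep=self.k_dep_,
            t_half_min=self.t_half_min_,
            clint_ml_min_kg=self.clint_ml_min_kg_,
            clint_ul_min_mg=self.clint_ul_min_mg_,
            clearance_class=self.clearance_class_,
        )
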