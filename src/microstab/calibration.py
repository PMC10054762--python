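"""Calibration curve fitting, back-calculation, linearity statistics, LOD/LOQ.

The response is the analyte/IS peak-area ratio; the calibration model is
an unweighted straight line ratio = slope * conc + intercept fitted by
ordinary least squares. Unknowns are back-calculated by inverting the
line. Per-level summaries report mean, SD (n-1), %RSD (precision),
%error (accuracy = 100*(mean-nominal)/nominal) and %recovery
(= 100*mean/nominal, i.e. accuracy + 100).

Detection limits follow the intercept-dispersion convention:
LOD = 3.3 * SD(intercept) / slope, LOQ = 10 * SD(intercept) / slope,
with the intercept SD taken across replicate calibration curves.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from ._regression import LineFit, ols_line
from .datatypes import AnalyteMeasurement, Role, area_ratio
from .errors import DegenerateFitError, InsufficientDataError
from .io import measurements_to_frame

__all__ = [
    "CalibrationFit",
    "LevelSummary",
    "CalibrationCurve",
    "fit_calibration",
    "back_calculate",
    "summarize_level",
    "lod_loq",
]


@dataclass(frozen=True)
class CalibrationFit:
    """Fitted calibration line plus pooled intercept dispersion."""

    slope: float
    intercept: float
    r2: float
    n_points: int
    residual_sd: float
    intercept_sd_across_curves: Optional[float] = None

    def back_calculate(self, ratio) -> Union[float, np.ndarray]:
        if self.slope == 0:
            raise DegenerateFitError("zero slope: cannot back-calculate")
        out = (np.asarray(ratio, dtype=float) - self.intercept) / self.slope
        return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class LevelSummary:
    """Back-calculation statistics at one nominal concentration."""

    nominal: float
    n: int
    mean_back_calc: float
    sd: float
    rsd_pct: float
    accuracy_pct: float
    recovery_pct: float


def _standards_xy(
    standards: Union[Sequence[AnalyteMeasurement], pd.DataFrame],
    average_replicates: bool,
) -> tuple[np.ndarray, np.ndarray]:
    if not isinstance(standards, pd.DataFrame):
        df = measurements_to_frame(standards)
    else:
        df = standards.copy()
    if "role" in df.columns:
        df = df[df["role"] == Role.standard.value]
    if df.empty:
        raise InsufficientDataError("no standard rows to fit")
    if df["is_area"].isna().any() or (df["is_area"] == 0).any():
        # delegate to area_ratio for the canonical error
        bad = df.index[df["is_area"].isna() | (df["is_area"] == 0)][0]
        row = df.loc[bad]
        area_ratio(
            AnalyteMeasurement(
                sample_id=str(row.get("sample_id", "?")),
                role=Role.blank,
                analyte_area=float(row["analyte_area"]),
                is_area=None if pd.isna(row["is_area"]) else float(row["is_area"]),
            )
        )
    df = df.assign(ratio=df["analyte_area"] / df["is_area"])
    if average_replicates:
        grouped = df.groupby("nominal_conc", sort=True)["ratio"].mean()
        x, y = grouped.index.to_numpy(float), grouped.to_numpy(float)
    else:
        x = df["nominal_conc"].to_numpy(float)
        y = df["ratio"].to_numpy(float)
    if np.unique(x).size < 2:
        raise InsufficientDataError("need >= 2 distinct nominal levels")
    return x, y


class CalibrationCurve(BaseEstimator, RegressorMixin):
    """Unweighted linear calibration of response ratio on concentration.

    Parameters
    ----------
    average_replicates : bool, default True
        Average replicate ratios to one value per level before fitting
        (one line per curve from the level means); ``False`` fits every
        replicate point.

    Attributes
    ----------
    slope_, intercept_, r2_, n_points_, residual_sd_ : float
        Fitted line and goodness of fit (r2 = regression SS / total SS).

    The estimator accepts either plain arrays ``fit(conc, ratio)`` or a
    measurement table ``fit(standards)``.
    """

    def __init__(self, average_replicates: bool = True):
        self.average_replicates = average_replicates

    def fit(self, X, y=None) -> "CalibrationCurve":
        if y is None:
            x, yy = _standards_xy(X, self.average_replicates)
        else:
            x = np.asarray(X, dtype=float).ravel()
            yy = np.asarray(y, dtype=float).ravel()
            if np.unique(x).size < 2:
                raise InsufficientDataError("need >= 2 distinct nominal levels")
        fit = ols_line(x, yy)
        self.slope_ = fit.slope
        self.intercept_ = fit.intercept
        self.r2_ = fit.r2
        self.n_points_ = fit.n_points
        self.residual_sd_ = fit.residual_sd
        return self

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "slope_")
        return self.slope_ * np.asarray(X, dtype=float) + self.intercept_

    def back_calculate(self, ratio):
        """Invert the line: concentration = (ratio - intercept) / slope."""
        check_is_fitted(self, "slope_")
        return self.result_.back_calculate(ratio)

    @property
    def result_(self) -> CalibrationFit:
        check_is_fitted(self, "slope_")
        return CalibrationFit(
            slope=self.slope_,
            intercept=self.intercept_,
            r2=self.r2_,
            n_points=self.n_points_,
            residual_sd=self.residual_sd_,
        )


def fit_calibration(
    standards: Union[Sequence[AnalyteMeasurement], pd.DataFrame],
    average_replicates: bool = True,
) -> CalibrationFit:
    """Fit the calibration line from a standards table."""
    return CalibrationCurve(average_replicates).fit(standards).result_


def back_calculate(fit: CalibrationFit, ratio):
    """Concentration (ng/mL) from a response ratio; may be negative
    (values below LOD are reported and flagged downstream, never clipped)."""
    return fit.back_calculate(ratio)


def summarize_level(back_calcs: Sequence[float], nominal: float) -> LevelSummary:
    """Mean / SD / %RSD / accuracy / recovery for one level.

    SD uses the n-1 denominator. Accuracy is the signed percent error;
    recovery = accuracy + 100 by algebraic identity.
    """
    vals = np.asarray(back_calcs, dtype=float)
    if vals.size < 2:
        raise InsufficientDataError(f"need >= 2 replicates, got {vals.size}")
    if nominal <= 0:
        raise ValueError("nominal concentration must be positive")
    mean = float(vals.mean())
    sd = float(vals.std(ddof=1))
    rsd = 100.0 * sd / mean if mean != 0 else float("inf")
    accuracy = 100.0 * (mean - nominal) / nominal
    return LevelSummary(
        nominal=float(nominal),
        n=int(vals.size),
        mean_back_calc=mean,
        sd=sd,
        rsd_pct=rsd,
        accuracy_pct=accuracy,
        recovery_pct=accuracy + 100.0,
    )


def lod_loq(fits: Sequence[Union[CalibrationFit, LineFit]]) -> tuple[float, float]:
    """Detection and quantification limits from replicate curves.

    LOD = 3.3 * SD(intercepts) / mean(slopes),
    LOQ = 10  * SD(intercepts) / mean(slopes);
    LOQ/LOD = 10/3.3 by construction. Requires >= 2 curves.
    """
    if len(fits) < 2:
        raise InsufficientDataError("intercept SD needs >= 2 calibration curves")
    intercepts = np.array([f.intercept for f in fits], dtype=float)
    slope = float(np.mean([f.slope for f in fits]))
    if slope == 0:
        raise DegenerateFitError("mean slope is zero")
    sd_intercept = float(intercepts.std(ddof=1))
    return 3.3 * sd_intercept / slope, 10.0 * sd_intercept / slope
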