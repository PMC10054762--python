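"""Shared ordinary-least-squares kernel.

Both the calibration curve (area ratio vs nominal concentration) and the
metabolic-stability fit (ln %-remaining vs time) go through this single
unweighted straight-line fit, so their numerics agree by construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import DegenerateFitError, InsufficientDataError

__all__ = ["LineFit", "ols_line"]


@dataclass(frozen=True)
class LineFit:
    """Unweighted straight-line fit y = slope * x + intercept."""

    slope: float
    intercept: float
    r2: float
    n_points: int
    residual_sd: float

    def predict(self, x):
        return self.slope * np.asarray(x, dtype=float) + self.intercept


def ols_line(x, y) -> LineFit:
    """Fit y = a*x + b by ordinary (unweighted) least squares.

    r-squared is regression sum of squares over total sum of squares.
    A two-point fit is exact (r2 = 1, residual_sd = 0).

    Raises
    ------
    InsufficientDataError
        Fewer than two points.
    DegenerateFitError
        All x identical (singular design).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    n = x.size
    if n < 2:
        raise InsufficientDataError(f"need >= 2 points for a line fit, got {n}")
    if np.ptp(x) == 0:
        raise DegenerateFitError("all x values identical: singular design")

    res = stats.linregress(x, y)
    resid = y - (res.slope * x + res.intercept)
    # constant y: linregress returns rvalue 0 but the fit is exact
    sst = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if sst == 0 else float(res.rvalue) ** 2
    residual_sd = 0.0 if n <= 2 else float(np.sqrt(np.sum(resid**2) / (n - 2)))
    return LineFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r2=r2,
        n_points=int(n),
        residual_sd=residual_sd,
    )
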