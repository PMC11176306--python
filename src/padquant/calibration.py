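"""Linear calibration of analytical signals and figures of merit.

The model is ordinary least squares of signal on concentration,

    AS = intercept + sensitivity * c + error,

fitted per data-treatment method on replicate-level points (unweighted).
Figures of merit:

* sensitivity            – the slope, in signal units per concentration unit
* sensitivity error (%)  – 100 * SE(slope) / |slope|
* LOD                    – k * sigma / |slope| (k = 3.3 by default); sigma is
                           the SD of the blank signals when at least three
                           blank replicates are available, otherwise the
                           residual SD s_yx of the fit
* usability              – two-sided t-test of slope = 0 at level alpha; a
                           method whose slope is indistinguishable from zero
                           carries no analytical information for the assay
* 95% confidence limit of the fitted signal at a concentration x0 (mean
  response): t(0.975, n-2) * s_yx * sqrt(1/n + (x0 - xbar)^2 / Sxx).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm

from .exceptions import (
    InsufficientDataError,
    SingularDesignError,
    UndefinedCIError,
    UndefinedLODError,
)

__all__ = [
    "LinearCalibration",
    "CalibrationResults",
    "PredictedSignal",
    "fit_calibration",
    "lod",
    "sensitivity_error_pct",
]


def sensitivity_error_pct(slope: float, slope_se: float) -> float:
    """Relative standard error of the calibration slope, in percent."""
    if slope == 0:
        raise UndefinedLODError("sensitivity error undefined for zero slope")
    return 100.0 * slope_se / abs(slope)


@dataclass
class PredictedSignal:
    """Fitted signal at one concentration with its confidence half-width."""

    concentration: float
    value: float
    ci_half_width: float
    df: int
    level: float = 0.95


@dataclass
class CalibrationResults:
    """OLS calibration estimates and figures of merit for one method."""

    slope: float
    slope_se: float
    intercept: float
    intercept_se: float
    r2: float
    s_yx: float
    n: int
    df: int
    slope_p: float
    alpha: float
    usable: bool
    sensitivity_error_pct: float
    lod: float
    lod_k: float
    lod_sigma_source: str
    method_id: int | None = None
    label: str | None = None
    unit: str = ""
    x: np.ndarray = field(repr=False, default=None)
    y: np.ndarray = field(repr=False, default=None)

    @property
    def x_mean(self) -> float:
        return float(np.mean(self.x))

    @property
    def sxx(self) -> float:
        return float(np.sum((self.x - self.x_mean) ** 2))

    def predict(self, x0: float, level: float = 0.95) -> PredictedSignal:
        """Fitted signal at ``x0`` with the mean-response confidence limit."""
        if self.df < 1:
            raise UndefinedCIError("confidence limit undefined with zero residual df")
        t = scipy.stats.t.ppf(0.5 + level / 2.0, self.df)
        half = t * self.s_yx * math.sqrt(1.0 / self.n + (x0 - self.x_mean) ** 2 / self.sxx)
        return PredictedSignal(
            concentration=x0,
            value=self.intercept + self.slope * x0,
            ci_half_width=float(half),
            df=self.df,
            level=level,
        )

    def summary(self) -> str:
        """Plain-text summary in the style of a calibration report row."""
        lines = [
            "Linear calibration (OLS)",
            "========================",
        ]
        if self.method_id is not None:
            lines.append(f"method:            {self.method_id} ({self.label})")
        unit = f" [{self.unit}]" if self.unit else ""
        lines += [
            f"n points:          {self.n}   (df = {self.df})",
            f"sensitivity:       {self.slope:.6g} (+/- {self.slope_se:.3g}){unit}",
            f"sensitivity error: {self.sensitivity_error_pct:.2f} %",
            f"intercept:         {self.intercept:.6g} (+/- {self.intercept_se:.3g})",
            f"R^2:               {self.r2:.4f}",
            f"residual SD s_yx:  {self.s_yx:.6g}",
            f"slope p-value:     {self.slope_p:.3g}  (alpha = {self.alpha})",
            f"usable:            {self.usable}",
            f"LOD:               {self.lod:.6g}  ({self.lod_k} * sigma / |slope|, "
            f"sigma from {self.lod_sigma_source})"
            if self.usable
            else "LOD:               undefined (method unusable)",
        ]
        return "\n".join(lines)

    def plot(self, ax=None, ci: bool = True, n_grid: int = 100):
        """Scatter the calibration points with the fitted line (and CI band)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.x, self.y, "o", label="data")
        grid = np.linspace(float(np.min(self.x)), float(np.max(self.x)), n_grid)
        fitted = self.intercept + self.slope * grid
        ax.plot(grid, fitted, "-", label="fit")
        if ci and self.s_yx > 0:
            halves = np.array([self.predict(g).ci_half_width for g in grid])
            ax.fill_between(grid, fitted - halves, fitted + halves, alpha=0.2, label="95% CI")
        ax.set_xlabel(f"concentration{f' [{self.unit}]' if self.unit else ''}")
        ax.set_ylabel(f"signal{f' ({self.label})' if self.label else ''}")
        ax.legend()
        return ax


class LinearCalibration:
    """Unweighted OLS calibration model for one signal transform.

    Parameters
    ----------
    concentration, signal
        Replicate-level calibration points. At least 3 points spanning at
        least 2 distinct concentrations are required.
    method_id, label, unit
        Optional metadata carried into the results.
    """

    def __init__(
        self,
        concentration: Sequence[float],
        signal: Sequence[float],
        *,
        method_id: int | None = None,
        label: str | None = None,
        unit: str = "",
    ) -> None:
        x = np.asarray(concentration, dtype=float)
        y = np.asarray(signal, dtype=float)
        if x.shape != y.shape or x.ndim != 1:
            raise InsufficientDataError("concentration and signal must be equal-length 1-D")
        keep = np.isfinite(x) & np.isfinite(y)
        x, y = x[keep], y[keep]
        if len(x) < 3:
            raise InsufficientDataError(f"need >= 3 finite calibration points, got {len(x)}")
        if np.ptp(x) == 0:
            raise SingularDesignError("all concentrations identical; slope undefined")
        self.x = x
        self.y = y
        self.method_id = method_id
        self.label = label
        self.unit = unit

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        y: str,
        x: str = "concentration",
        **metadata,
    ) -> "LinearCalibration":
        return cls(df[x].to_numpy(), df[y].to_numpy(), **metadata)

    def fit(
        self,
        alpha: float = 0.05,
        *,
        lod_k: float = 3.3,
        blank_sd: float | None = None,
        n_blank: int = 0,
    ) -> CalibrationResults:
        """Fit the line and derive the figures of merit.

        ``blank_sd``/``n_blank`` feed the LOD: the blank-signal SD is used
        as sigma when at least 3 blank replicates back it, otherwise the
        residual SD of the fit.
        """
        X = sm.add_constant(self.x)
        # constant signals yield 0/0 in R^2; keep the NaN, silence the warning
        with np.errstate(divide="ignore", invalid="ignore"):
            res = sm.OLS(self.y, X).fit()
            r_squared = float(res.rsquared)
        slope = float(res.params[1])
        slope_se = float(res.bse[1])
        n = len(self.x)
        df = n - 2
        s_yx = math.sqrt(float(res.ssr) / df) if df > 0 else 0.0
        slope_p = float(res.pvalues[1])
        usable = bool(slope_p < alpha) and slope != 0

        if blank_sd is not None and n_blank >= 3:
            sigma, source = float(blank_sd), "blank replicate SD"
        else:
            sigma, source = s_yx, "residual SD (s_yx)"
        lod_value = lod_k * sigma / abs(slope) if usable else math.nan

        return CalibrationResults(
            slope=slope,
            slope_se=slope_se,
            intercept=float(res.params[0]),
            intercept_se=float(res.bse[0]),
            r2=r_squared,
            s_yx=s_yx,
            n=n,
            df=df,
            slope_p=slope_p,
            alpha=alpha,
            usable=usable,
            sensitivity_error_pct=sensitivity_error_pct(slope, slope_se)
            if slope != 0
            else math.inf,
            lod=lod_value,
            lod_k=lod_k,
            lod_sigma_source=source,
            method_id=self.method_id,
            label=self.label,
            unit=self.unit,
            x=self.x,
            y=self.y,
        )


def fit_calibration(
    points: Iterable[tuple[float, float]] | tuple[Sequence[float], Sequence[float]],
    alpha: float = 0.05,
    **fit_kwargs,
) -> CalibrationResults:
    """Convenience wrapper: fit a calibration from (concentration, signal) pairs."""
    pts = list(points)
    if len(pts) == 2 and not np.isscalar(pts[0]) and len(pts[0]) != 2:
        x, y = pts  # two parallel sequences
    else:
        arr = np.asarray(pts, dtype=float)
        if arr.ndim != 2 or arr.shape[1] != 2:
            raise InsufficientDataError("points must be (concentration, signal) pairs")
        x, y = arr[:, 0], arr[:, 1]
    return LinearCalibration(x, y).fit(alpha=alpha, **fit_kwargs)


def lod(
    result: CalibrationResults,
    blank_sd: float | None = None,
    n_blank: int = 0,
    k: float = 3.3,
) -> float:
    """Limit of detection, k * sigma / |slope|.

    sigma is the blank-signal SD when at least 3 blank replicates support
    it, otherwise the residual SD of the calibration. Raises
    :class:`UndefinedLODError` for unusable calibrations.
    """
    if not result.usable or result.slope == 0:
        raise UndefinedLODError("LOD undefined: calibration unusable or zero slope")
    sigma = blank_sd if (blank_sd is not None and n_blank >= 3) else result.s_yx
    return k * sigma / abs(result.slope)
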