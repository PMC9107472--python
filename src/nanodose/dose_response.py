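"""Dose dependence of the vaporization contrast.

The integrated grayscale peak (area of the fitted Gaussian above baseline)
grows with dose, linearly at low doses and saturating once the acoustic
signal is dense enough; a four-parameter logistic (4PL) is the canonical
saturating form fitted here, with ordinary least squares on the restricted
low-dose points for the linear range.  Exposed statsmodels-style through
:class:`DoseResponseModel` whose ``fit()`` returns a results object.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.optimize import curve_fit

from nanodose.profiles import PeakMetrics

__all__ = [
    "DoseResponsePoint",
    "DoseResponseFit",
    "DoseResponseModel",
    "DoseResponseResult",
    "integrate_peak",
    "fit_dose_response",
    "linear_range_fit",
    "fwhm_vs_dose",
]


@dataclass(frozen=True)
class DoseResponsePoint:
    """One dose level of the response curve."""

    dose: float  # Gy
    integral: float  # grey mm (area of the fitted peak)
    fwhm: float  # mm
    n_replicates: int = 1

    def __post_init__(self) -> None:
        if self.dose < 0 or self.integral < 0:
            raise ValueError("dose and integral must be non-negative")


def integrate_peak(metrics: PeakMetrics) -> float:
    """Analytic area of the fitted Gaussian above baseline (grey mm)."""
    return metrics.amplitude * metrics.sigma * math.sqrt(2.0 * math.pi)


def _logistic4(dose, floor, ceiling, ed50, slope):
    dose = np.asarray(dose, dtype=float)
    return floor + (ceiling - floor) / (1.0 + (ed50 / np.clip(dose, 1e-12, None)) ** slope)


@dataclass(frozen=True)
class DoseResponseFit:
    """Fitted 4PL parameters plus an optional low-dose linear sub-fit."""

    floor: float
    ceiling: float
    ed50: float  # Gy
    slope: float
    r_squared: float
    linear_sub_fit: dict | None = None

    def __post_init__(self) -> None:
        if self.ceiling < self.floor:
            raise ValueError("ceiling must be >= floor")
        if self.ed50 <= 0:
            raise ValueError("ed50 must be positive")

    def predict(self, dose):
        return _logistic4(dose, self.floor, self.ceiling, self.ed50, self.slope)


class DoseResponseModel:
    """Saturating dose-response model for integrated-peak data."""

    def __init__(self, points: list[DoseResponsePoint]):
        if len(points) < 4:
            raise ValueError("need at least 4 dose levels for a 4PL fit")
        self.points = sorted(points, key=lambda p: p.dose)
        self.dose = np.array([p.dose for p in self.points])
        self.response = np.array([p.integral for p in self.points])
        if np.allclose(self.response, self.response[0]):
            raise ValueError("degenerate (all-equal) responses")

    def fit(self) -> "DoseResponseResult":
        y = self.response
        p0 = (max(y.min(), 1e-6), y.max(), float(np.median(self.dose)), 1.5)
        popt, pcov = curve_fit(
            _logistic4,
            self.dose,
            y,
            p0=p0,
            bounds=([0, 0, 1e-6, 0.1], [np.inf, np.inf, np.inf, 20.0]),
            maxfev=20000,
        )
        return DoseResponseResult(self, popt, pcov)


@dataclass
class DoseResponseResult:
    model: DoseResponseModel
    params: np.ndarray  # floor, ceiling, ed50, slope
    cov: np.ndarray
    param_names = ("floor", "ceiling", "ed50", "slope")

    @property
    def bse(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov))

    def predict(self, dose=None):
        if dose is None:
            dose = self.model.dose
        return _logistic4(dose, *self.params)

    @property
    def r_squared(self) -> float:
        y = self.model.response
        resid = y - self.predict()
        ss_tot = float(np.sum((y - y.mean()) ** 2))
        return 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot else 1.0

    def as_fit(self, linear_sub_fit: dict | None = None) -> DoseResponseFit:
        floor, ceiling, ed50, slope = self.params
        return DoseResponseFit(
            floor=float(floor),
            ceiling=float(ceiling),
            ed50=float(ed50),
            slope=float(slope),
            r_squared=self.r_squared,
            linear_sub_fit=linear_sub_fit,
        )

    def summary(self) -> str:
        lines = ["4-parameter logistic dose-response fit", "=" * 44]
        for name, value, se in zip(self.param_names, self.params, self.bse):
            lines.append(f"{name:>8}: {value:12.4f} +/- {se:.4f}")
        lines.append(f"{'R^2':>8}: {self.r_squared:12.6f}")
        return "\n".join(lines)


def fit_dose_response(
    points: list[DoseResponsePoint], *, linear_dose_max: float | None = 1.0
) -> DoseResponseFit:
    """4PL fit over all points, plus OLS over doses <= ``linear_dose_max``."""
    result = DoseResponseModel(points).fit()
    sub = None
    if linear_dose_max is not None:
        try:
            sub = linear_range_fit(points, linear_dose_max)
            sub["dose_max"] = linear_dose_max
        except ValueError:
            sub = None
    return result.as_fit(linear_sub_fit=sub)


def linear_range_fit(points: list[DoseResponsePoint], dose_max: float) -> dict:
    """Ordinary least squares of integral on dose, restricted to
    dose <= ``dose_max``; returns slope, intercept and r_squared."""
    sel = [p for p in points if p.dose <= dose_max]
    if len(sel) < 3:
        raise ValueError(f"need >= 3 points with dose <= {dose_max} Gy")
    x = np.array([p.dose for p in sel])
    y = np.array([p.integral for p in sel])
    fit = stats.linregress(x, y)
    return {
        "slope": float(fit.slope),
        "intercept": float(fit.intercept),
        "r_squared": float(fit.rvalue**2),
        "n": len(sel),
    }


def fwhm_vs_dose(points: list[DoseResponsePoint]) -> dict:
    """Trend of the fitted peak FWHM with dose.

    Returns the (dose, FWHM) sequence, a Spearman rank correlation, a 4PL
    saturating-fit summary of FWHM vs dose, and whether the trend is
    non-decreasing within noise (rho >= 0).
    """
    if len(points) < 3:
        raise ValueError("need at least 3 dose levels")
    pts = sorted(points, key=lambda p: p.dose)
    dose = np.array([p.dose for p in pts])
    fwhm = np.array([p.fwhm for p in pts])
    if np.allclose(fwhm, fwhm[0]):
        rho, pval = 0.0, 1.0
    else:
        rho, pval = stats.spearmanr(dose, fwhm)
    sat = None
    if len(pts) >= 4 and not np.allclose(fwhm, fwhm[0]):
        try:
            popt, _ = curve_fit(
                _logistic4,
                dose,
                fwhm,
                p0=(fwhm.min(), fwhm.max(), float(np.median(dose)), 1.0),
                bounds=([0, 0, 1e-6, 0.1], [np.inf, np.inf, np.inf, 20.0]),
                maxfev=20000,
            )
            sat = dict(zip(("floor", "ceiling", "ed50", "slope"), map(float, popt)))
        except RuntimeError:
            sat = None
    return {
        "dose": dose.tolist(),
        "fwhm": fwhm.tolist(),
        "spearman_rho": float(rho),
        "spearman_p": float(pval),
        "non_decreasing": bool(rho >= 0),
        "saturating_fit": sat,
    }
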