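"""Grayscale-profile quantification and range verification.

Implements the image-processing chain used to turn pre/post-irradiation
B-mode frames into a depth-resolved vaporization readout: automatic
(isodata/intermeans) thresholding, depth-aggregated lateral grey-value
profiles, pre-scan background subtraction, calibration of image columns to
beam-axis millimetres via the container mid-line and front-wall thickness,
replicate averaging, Gaussian peak fitting, and distal 50%-fall range
metrics.

The peak fit is exposed statsmodels-style: ``GaussianPeakModel(profile)``
with ``.fit()`` returning a :class:`PeakFitResult` that carries parameter
estimates, standard errors, derived peak descriptors and a ``summary()``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from skimage.filters import threshold_isodata

from nanodose.beam import BraggCurve, curve_metrics
from nanodose.imaging import USImage, USImagingConfig
from nanodose.phantom import PhantomSpec

__all__ = [
    "GrayscaleProfile",
    "PeakMetrics",
    "GaussianPeakModel",
    "PeakFitResult",
    "default_threshold",
    "extract_profile",
    "subtract_background",
    "calibrate_positions",
    "average_profiles",
    "distal_fall50",
    "fit_peak",
    "range_shift_between",
]

# width-at-fraction factors of a Gaussian: full width at f*amplitude is
# 2*sigma*sqrt(2*ln(1/f))
FWHM_PER_SIGMA = 2.0 * math.sqrt(2.0 * math.log(2.0))
W80_PER_SIGMA = 2.0 * math.sqrt(2.0 * math.log(1.0 / 0.8))


class NoPeakError(ValueError):
    """No detectable peak in the profile."""


class FitError(RuntimeError):
    """Peak fit did not converge; carries diagnostics in the message."""


@dataclass
class GrayscaleProfile:
    """Depth-aggregated lateral grey-value profile."""

    position: np.ndarray  # strictly increasing; px or calibrated mm
    mean_grey: np.ndarray
    sd_grey: np.ndarray
    n: int = 1
    calibrated: bool = False

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        self.mean_grey = np.asarray(self.mean_grey, dtype=float)
        self.sd_grey = np.asarray(self.sd_grey, dtype=float)
        if not np.all(np.diff(self.position) > 0):
            raise ValueError("positions must be strictly increasing")
        if np.any(self.mean_grey < 0):
            raise ValueError("mean grey must be non-negative")
        if self.n < 1:
            raise ValueError("n must be >= 1")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "position": self.position,
                "mean_grey": self.mean_grey,
                "sd_grey": self.sd_grey,
                "n": self.n,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "GrayscaleProfile":
        t = pd.read_csv(path)
        return cls(
            t["position"].to_numpy(),
            t["mean_grey"].to_numpy(),
            t["sd_grey"].to_numpy(),
            n=int(t["n"].iloc[0]),
        )


@dataclass(frozen=True)
class PeakMetrics:
    """Descriptors of a fitted vaporization (or dose) peak."""

    x_c: float  # fitted center, mm
    sigma: float  # fitted Gaussian width, mm
    FWHM: float
    W80: float
    amplitude: float  # grey above baseline
    baseline: float  # grey
    area: float  # grey mm (analytic, above baseline)
    r_squared: float
    x_end: float  # distal baseline+10%-amplitude point of the fit (a
    # package definition; the quantity has no unique standard definition)
    fall50: float  # distal 50% position of the measured profile, mm
    onset: float  # proximal detection-threshold position, mm
    plateau_to_peak_vap: float
    plateau_to_peak_dose: float | None = None
    shift50: float | None = None  # |fall50 - R50_distal(reference)|, mm

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")


# --------------------------------------------------------------------------
# pixel-level operations


def default_threshold(image, *, threshold_value: float | None = None) -> np.ndarray:
    """Isodata (intermeans) auto-threshold; sub-threshold pixels set to 0.

    This is the classic iterative scheme: threshold = mean of the two class
    means, iterated to a fixed point on the grey histogram.  Passing
    ``threshold_value`` skips the automatic estimate (used to threshold the
    frames of a pre/post pair at one common level).
    """
    pixels = image.pixels if isinstance(image, USImage) else np.asarray(image)
    if threshold_value is None:
        if pixels.min() == pixels.max():
            warnings.warn("constant image: threshold undefined, returning unchanged")
            return pixels.copy()
        threshold_value = threshold_isodata(pixels)
    out = pixels.copy()
    out[pixels < threshold_value] = 0
    return out


def extract_profile(
    image, *, threshold: bool = True, threshold_value: float | None = None
) -> GrayscaleProfile:
    """Per-column mean grey over the full probe depth (pixel coordinates)."""
    pixels = image.pixels if isinstance(image, USImage) else np.asarray(image)
    if pixels.size == 0:
        raise ValueError("empty image")
    data = (
        default_threshold(pixels, threshold_value=threshold_value)
        if threshold
        else pixels
    )
    data = data.astype(float)
    return GrayscaleProfile(
        position=np.arange(data.shape[1], dtype=float) + 0.5,
        mean_grey=data.mean(axis=0),
        sd_grey=data.std(axis=0),
        n=1,
    )


def subtract_background(
    post: GrayscaleProfile, pre: GrayscaleProfile
) -> GrayscaleProfile:
    """Post-minus-pre profile, clipped at zero (profile-level background
    correction; no pixel registration)."""
    if post.position.shape != pre.position.shape or not np.allclose(
        post.position, pre.position
    ):
        raise ValueError("profiles are on different grids")
    return GrayscaleProfile(
        position=post.position.copy(),
        mean_grey=np.clip(post.mean_grey - pre.mean_grey, 0.0, None),
        sd_grey=np.hypot(post.sd_grey, pre.sd_grey),
        n=post.n,
        calibrated=post.calibrated,
    )


def calibrate_positions(
    profile: GrayscaleProfile, spec: PhantomSpec, cfg: USImagingConfig
) -> GrayscaleProfile:
    """Map pixel columns to beam-axis mm.

    The probe center is aligned with the container's inner mid-length, so
    the window center sits at ``entrance_position + front_wall_thickness +
    inner_length/2`` on the beam axis, and the left image edge is half a
    window proximal of it.
    """
    center = spec.mid_length_beam_axis
    left = center - cfg.window_length / 2.0
    return GrayscaleProfile(
        position=left + profile.position * cfg.mm_per_pixel,
        mean_grey=profile.mean_grey.copy(),
        sd_grey=profile.sd_grey.copy(),
        n=profile.n,
        calibrated=True,
    )


def average_profiles(profiles: list[GrayscaleProfile]) -> GrayscaleProfile:
    """Pointwise mean and sd over replicate profiles (n = count)."""
    if not profiles:
        raise ValueError("need at least one profile")
    ref = profiles[0]
    for p in profiles[1:]:
        if p.position.shape != ref.position.shape or not np.allclose(
            p.position, ref.position
        ):
            raise ValueError("profiles are on different grids")
    stack = np.stack([p.mean_grey for p in profiles])
    return GrayscaleProfile(
        position=ref.position.copy(),
        mean_grey=stack.mean(axis=0),
        sd_grey=stack.std(axis=0, ddof=1) if len(profiles) > 1 else np.zeros_like(ref.mean_grey),
        n=len(profiles),
        calibrated=ref.calibrated,
    )


# --------------------------------------------------------------------------
# range metrics


def distal_fall50(profile: GrayscaleProfile) -> float:
    """Most distal crossing of the (max+min)/2 mid-level, interpolated.

    The mid-level follows the midpoint-of-extreme-grey-values rule; the
    most distal downward crossing is the range-verification coordinate.
    """
    y = profile.mean_grey
    mid = 0.5 * (y.max() + y.min())
    above = y > mid
    down = np.flatnonzero(above[:-1] & ~above[1:])
    if down.size == 0:
        raise NoPeakError("no distal descending crossing of the mid-level")
    i = int(down[-1])
    x0, x1 = profile.position[i], profile.position[i + 1]
    y0, y1 = y[i], y[i + 1]
    return float(x0 + (mid - y0) / (y1 - y0) * (x1 - x0))


def range_shift_between(a: GrayscaleProfile, b: GrayscaleProfile) -> float:
    """Signed distance between the distal 50% falls of two profiles (mm)."""
    return distal_fall50(a) - distal_fall50(b)


# --------------------------------------------------------------------------
# peak fitting


def _gauss_baseline(x, amplitude, center, sigma, baseline):
    return baseline + amplitude * np.exp(-0.5 * ((x - center) / sigma) ** 2)


class GaussianPeakModel:
    """Gaussian-plus-constant-baseline model of a grayscale profile.

    Parameters are initialized from the data (center at the argmax, sigma
    from the second central moment, baseline from the proximal-quartile
    median) and estimated by nonlinear least squares.
    """

    def __init__(
        self,
        profile: GrayscaleProfile,
        reference: BraggCurve | None = None,
        *,
        onset_k: float = 3.0,
        detection_k: float | None = None,
    ):
        self.profile = profile
        self.reference = reference
        self.onset_k = onset_k
        # the existence gate can be stricter than the onset rule: the max
        # of a few hundred noise columns reaches 3 sd by chance alone
        self.detection_k = detection_k if detection_k is not None else onset_k

    def _initial_params(self):
        x, y = self.profile.position, self.profile.mean_grey
        q = max(len(y) // 4, 1)
        baseline = float(np.median(y[:q]))
        amplitude = float(y.max() - baseline)
        center = float(x[np.argmax(y)])
        w = np.clip(y - baseline, 0, None)
        if w.sum() > 0:
            var = float(np.sum(w * (x - center) ** 2) / w.sum())
            sigma = max(math.sqrt(var), (x[1] - x[0]))
        else:
            sigma = (x[-1] - x[0]) / 10
        return amplitude, center, sigma, baseline

    def background_sd(self) -> float:
        """Noise level of the proximal (pre-onset) quartile of the profile."""
        y = self.profile.mean_grey
        q = max(len(y) // 4, 2)
        return float(np.std(y[:q], ddof=1))

    def robust_noise(self) -> float:
        """Robust global noise level of the profile.

        Median over contiguous segments of each segment's own scaled MAD:
        insensitive both to a localized peak and to broad elevated regions
        (e.g. a spread-out plateau), while a pure-noise profile is compared
        against its own spread rather than a possibly quiet proximal
        corner."""
        y = self.profile.mean_grey
        segments = np.array_split(y, 8)
        mads = [
            float(np.median(np.abs(seg - np.median(seg)))) for seg in segments
        ]
        return 1.4826 * float(np.median(mads))

    def fit(self, maxiter: int = 500) -> "PeakFitResult":
        x, y = self.profile.position, self.profile.mean_grey
        p0 = self._initial_params()
        bg_sd = self.background_sd()
        noise = max(bg_sd, self.robust_noise())
        if p0[0] <= self.detection_k * noise or p0[0] <= 0:
            raise NoPeakError(
                f"no detectable peak: amplitude {p0[0]:.2f} <= "
                f"{self.detection_k} x noise {noise:.2f}"
            )
        try:
            popt, pcov = curve_fit(
                _gauss_baseline,
                x,
                y,
                p0=p0,
                bounds=([0, x[0], 1e-9, 0], [np.inf, x[-1], x[-1] - x[0], np.inf]),
                maxfev=maxiter * (len(p0) + 1),
                xtol=1e-8,
            )
        except RuntimeError as exc:
            raise FitError(
                f"peak fit did not converge after {maxiter} iterations "
                f"(initial params {p0})"
            ) from exc
        return PeakFitResult(self, popt, pcov, bg_sd)


@dataclass
class PeakFitResult:
    """Results object of :class:`GaussianPeakModel`."""

    model: GaussianPeakModel
    params: np.ndarray  # amplitude, center, sigma, baseline
    cov: np.ndarray
    background_sd: float
    param_names = ("amplitude", "center", "sigma", "baseline")

    @property
    def bse(self) -> np.ndarray:
        """Standard errors of the fitted parameters."""
        return np.sqrt(np.diag(self.cov))

    def predict(self, x=None) -> np.ndarray:
        if x is None:
            x = self.model.profile.position
        return _gauss_baseline(np.asarray(x, dtype=float), *self.params)

    @property
    def r_squared(self) -> float:
        y = self.model.profile.mean_grey
        resid = y - self.predict()
        ss_tot = float(np.sum((y - y.mean()) ** 2))
        if ss_tot == 0:
            return 1.0
        return 1.0 - float(np.sum(resid**2)) / ss_tot

    def _onset(self) -> tuple[float, float]:
        """(onset position, profile value at onset): first proximal sample
        above baseline + k * background sd."""
        x, y = self.model.profile.position, self.model.profile.mean_grey
        amplitude, center, sigma, baseline = self.params
        level = baseline + self.model.onset_k * self.background_sd
        idx = np.flatnonzero((y > level) & (x <= center))
        if idx.size == 0:
            idx = np.flatnonzero(y > level)
        i = int(idx[0])
        return float(x[i]), float(y[i])

    @property
    def metrics(self) -> PeakMetrics:
        amplitude, center, sigma, baseline = self.params
        fall50 = distal_fall50(self.model.profile)
        onset_x, onset_y = self._onset()
        peak_value = float(self.model.profile.mean_grey.max())
        ref = self.model.reference
        if ref is not None:
            m = curve_metrics(ref)
            plateau_dose = float(ref.dose_at(onset_x) / ref.dose.max())
            shift50 = abs(fall50 - m.R50_distal)
        else:
            plateau_dose = None
            shift50 = None
        return PeakMetrics(
            x_c=float(center),
            sigma=float(sigma),
            FWHM=float(FWHM_PER_SIGMA * sigma),
            W80=float(W80_PER_SIGMA * sigma),
            amplitude=float(amplitude),
            baseline=float(baseline),
            area=float(amplitude * sigma * math.sqrt(2 * math.pi)),
            r_squared=self.r_squared,
            x_end=float(center + sigma * math.sqrt(2 * math.log(10.0))),
            fall50=fall50,
            onset=onset_x,
            plateau_to_peak_vap=onset_y / peak_value if peak_value > 0 else 0.0,
            plateau_to_peak_dose=plateau_dose,
            shift50=shift50,
        )

    def summary(self) -> str:
        m = self.metrics
        lines = ["Gaussian peak fit", "=" * 40]
        for name, value, se in zip(self.param_names, self.params, self.bse):
            lines.append(f"{name:>10}: {value:10.4f} +/- {se:.4f}")
        lines += [
            f"{'FWHM':>10}: {m.FWHM:10.4f}",
            f"{'W80':>10}: {m.W80:10.4f}",
            f"{'area':>10}: {m.area:10.4f}",
            f"{'x_end':>10}: {m.x_end:10.4f}  (baseline + 10% amplitude)",
            f"{'fall50':>10}: {m.fall50:10.4f}",
            f"{'R^2':>10}: {m.r_squared:10.6f}",
        ]
        if m.shift50 is not None:
            lines.append(f"{'shift50':>10}: {m.shift50:10.4f}")
        return "\n".join(lines)


def fit_peak(
    profile: GrayscaleProfile,
    reference: BraggCurve | None = None,
    *,
    onset_k: float = 3.0,
    detection_k: float | None = None,
) -> PeakMetrics:
    """Fit a Gaussian-plus-baseline peak and derive all peak descriptors."""
    model = GaussianPeakModel(
        profile, reference, onset_k=onset_k, detection_k=detection_k
    )
    return model.fit().metrics
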