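"""Synthetic B-mode frame rendering of nanodroplet phantoms.

Renders calibrated 8-bit grayscale frames emulating a linear-array scan:
fully developed speckle (Rayleigh envelope, correlated over one PSF),
bubbles as point scatterers blurred by the PSF, saturation of the local
echo amplitude where bubbles are dense, acoustic shadowing below dense
clusters, and log compression at a gain held fixed across all frames of an
experiment.

Image convention: rows are probe depth (increasing downward, the probe
sits on top of the phantom), columns are lateral position along the beam
(the beam enters at the left edge).  The probe is centered on the
container's inner mid-length, so a frame sees the central ``window_length``
millimetres of the phantom.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import tifffile
from scipy.integrate import quad
from scipy.ndimage import gaussian_filter

from nanodose.phantom import BubbleField, PhantomSpec

__all__ = [
    "USImagingConfig",
    "USImage",
    "render_frame",
    "scan_phantom",
    "frame_slabs",
    "save_frame",
    "load_frame",
]


class AcousticVaporizationRiskError(ValueError):
    """Refused: imaging at MI >= 0.4 would itself vaporize the droplets."""


def _rayleigh_log_mean() -> float:
    """E[log1p(r)] for a Rayleigh envelope with E[r^2] = 1 (unit backscatter
    power); fixes the log-compression gain."""
    sigma = 1.0 / math.sqrt(2.0)
    val, _ = quad(
        lambda r: math.log1p(r) * (r / sigma**2) * math.exp(-(r**2) / (2 * sigma**2)),
        0,
        20,
    )
    return val


_RAYLEIGH_LOG_MEAN = _rayleigh_log_mean()


@dataclass(frozen=True)
class USImagingConfig:
    """Acquisition and rendering parameters of the synthetic scanner."""

    center_frequency: float = 7.5  # MHz
    mechanical_index: float = 0.1
    window_length: float = 30.0  # mm, lateral
    window_depth: float = 23.0  # mm
    pixels_per_mm: float = 10.0
    speckle_mean: float = 30.0  # target mean grey of pure speckle
    psf_width: float = 0.12  # mm (lateral Gaussian sigma of the PSF)
    psf_axial: float = 0.06  # mm (axial sigma; the pulse is shorter than
    # the lateral focus is wide)
    gain: float | None = None  # grey per log-amplitude; derived if None
    slab_thickness: float = 1.0  # mm, elevational slice seen by one frame
    n_frames: int = 3
    bubble_amp: float = 30.0  # envelope amplitude of a 2 um bubble
    bubble_ref_radius_um: float = 2.0
    sat_ceiling: float = 60.0  # envelope amplitude saturation asymptote
    shadow_coef: float = 0.002  # attenuation per (amplitude mm) overhead

    def __post_init__(self) -> None:
        if self.window_length <= 0 or self.window_depth <= 0:
            raise ValueError("window dimensions must be positive")
        if self.pixels_per_mm <= 0:
            raise ValueError("resolution must be positive")

    @property
    def mm_per_pixel(self) -> float:
        return 1.0 / self.pixels_per_mm

    @property
    def shape(self) -> tuple[int, int]:
        return (
            int(round(self.window_depth * self.pixels_per_mm)),
            int(round(self.window_length * self.pixels_per_mm)),
        )

    @property
    def effective_gain(self) -> float:
        if self.gain is not None:
            return self.gain
        return self.speckle_mean / _RAYLEIGH_LOG_MEAN


@dataclass
class USImage:
    """Calibrated 8-bit grayscale frame of the acoustic window."""

    pixels: np.ndarray  # uint8, (rows=depth, cols=lateral)
    mm_per_pixel: float
    frame_index: int = 1
    phantom_id: str = ""
    phase: str = "post"  # 'pre' | 'post'

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.dtype != np.uint8:
            raise ValueError("pixels must be 8-bit grey")
        if self.phase not in ("pre", "post"):
            raise ValueError("phase must be 'pre' or 'post'")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


def frame_slabs(spec: PhantomSpec, cfg: USImagingConfig) -> list[tuple[float, float]]:
    """(y_lo, y_hi) of each frame's elevational slab, evenly spaced across
    the phantom width."""
    centers = [
        spec.inner_width * (2 * i - 1) / (2 * cfg.n_frames)
        for i in range(1, cfg.n_frames + 1)
    ]
    half = cfg.slab_thickness / 2.0
    return [(c - half, c + half) for c in centers]


def _window_x_extent(spec: PhantomSpec, cfg: USImagingConfig) -> tuple[float, float]:
    """Lateral extent of the acoustic window in phantom-frame x (mm)."""
    left = spec.inner_length / 2.0 - cfg.window_length / 2.0
    return left, left + cfg.window_length


def speckle_envelope(
    rng: np.random.Generator, shape: tuple[int, int], sigma_px
) -> np.ndarray:
    """Fully developed speckle envelope, Rayleigh with E[r^2] = 1.

    A complex white Gaussian scatterer field smoothed by the PSF stays
    Gaussian, so its magnitude stays Rayleigh while acquiring the PSF's
    spatial correlation; the deterministic renormalization uses the
    Gaussian kernel's l2 norm.  ``sigma_px`` may be a scalar or an
    (axial, lateral) pair.
    """
    sig_r, sig_c = np.broadcast_to(np.asarray(sigma_px, dtype=float), (2,))
    pad = max(int(math.ceil(4 * max(sig_r, sig_c))), 1)  # boundary bias
    padded = (shape[0] + 2 * pad, shape[1] + 2 * pad)
    re = gaussian_filter(rng.standard_normal(padded), (sig_r, sig_c))
    im = gaussian_filter(rng.standard_normal(padded), (sig_r, sig_c))
    # l2 norm of the separable 2-D kernel
    norm = 1.0 / (2.0 * math.sqrt(math.pi) * math.sqrt(sig_r * sig_c))
    env = np.hypot(re, im) / (math.sqrt(2.0) * norm)
    return env[pad:-pad, pad:-pad]


def render_frame(
    bubbles: BubbleField,
    spec: PhantomSpec,
    cfg: USImagingConfig,
    frame_index: int = 1,
    seed=None,
    *,
    phase: str = "post",
    phantom_id: str = "",
    restrict_to_slab: bool = True,
) -> USImage:
    """Render one B-mode frame of the bubbles visible in its slab."""
    if cfg.mechanical_index >= 0.4:
        raise AcousticVaporizationRiskError(
            f"MI = {cfg.mechanical_index} >= 0.4 would trigger acoustic "
            "droplet vaporization; refuse to image"
        )
    rng = np.random.default_rng(seed)
    n_rows, n_cols = cfg.shape
    sigma_px = (
        cfg.psf_axial * cfg.pixels_per_mm,  # rows = probe depth
        cfg.psf_width * cfg.pixels_per_mm,  # cols = lateral
    )
    envelope = speckle_envelope(rng, (n_rows, n_cols), sigma_px)

    # bubble scatterers: impulses convolved with the PSF
    amp = np.zeros((n_rows, n_cols), dtype=np.float64)
    if len(bubbles):
        sel = bubbles
        if restrict_to_slab:
            y_lo, y_hi = frame_slabs(spec, cfg)[frame_index - 1]
            y = bubbles.positions[:, 1]
            sel = bubbles.select((y >= y_lo) & (y < y_hi))
        if len(sel):
            x_left, _ = _window_x_extent(spec, cfg)
            cols = np.round(
                (sel.positions[:, 0] - x_left) * cfg.pixels_per_mm - 0.5
            ).astype(int)
            rows = np.round(sel.positions[:, 2] * cfg.pixels_per_mm - 0.5).astype(int)
            ok = (cols >= 0) & (cols < n_cols) & (rows >= 0) & (rows < n_rows)
            strength = cfg.bubble_amp * (
                sel.radii_um[ok].astype(np.float64) / cfg.bubble_ref_radius_um
            )
            np.add.at(amp, (rows[ok], cols[ok]), strength)
            amp = gaussian_filter(amp, sigma_px) * (
                2.0 * math.pi * sigma_px[0] * sigma_px[1]
            )

    # local saturation of the echo amplitude where bubbles are dense
    amp_sat = cfg.sat_ceiling * np.tanh(amp / cfg.sat_ceiling)

    # acoustic shadowing: attenuate everything below strong scatterers
    overhead = np.cumsum(amp_sat, axis=0) - amp_sat
    atten = np.exp(-cfg.shadow_coef * overhead * cfg.mm_per_pixel)

    total = (envelope + amp_sat) * atten
    grey = np.clip(cfg.effective_gain * np.log1p(total), 0, 255)
    return USImage(
        pixels=grey.astype(np.uint8),
        mm_per_pixel=cfg.mm_per_pixel,
        frame_index=frame_index,
        phantom_id=phantom_id,
        phase=phase,
    )


def scan_phantom(
    bubbles: BubbleField,
    spec: PhantomSpec,
    cfg: USImagingConfig,
    seed=None,
    *,
    phase: str = "post",
    phantom_id: str = "",
) -> list[USImage]:
    """Emulate the scan protocol: parallel frames evenly spaced across the
    phantom width, probe centered on the container mid-length."""
    streams = np.random.SeedSequence(seed).spawn(cfg.n_frames)
    return [
        render_frame(
            bubbles,
            spec,
            cfg,
            frame_index=i + 1,
            seed=streams[i],
            phase=phase,
            phantom_id=phantom_id,
        )
        for i in range(cfg.n_frames)
    ]


def save_frame(image: USImage, path) -> None:
    """Write a frame as single-channel 8-bit TIFF plus a key=value sidecar."""
    path = str(path)
    tifffile.imwrite(path, image.pixels)
    with open(path + ".meta.txt", "w") as fh:
        fh.write(
            f"mm_per_pixel={image.mm_per_pixel}\n"
            f"frame_index={image.frame_index}\n"
            f"phantom_id={image.phantom_id}\n"
            f"phase={image.phase}\n"
        )


def load_frame(path) -> USImage:
    path = str(path)
    pixels = tifffile.imread(path)
    meta = {}
    with open(path + ".meta.txt") as fh:
        for line in fh:
            key, _, value = line.strip().partition("=")
            meta[key] = value
    return USImage(
        pixels=pixels.astype(np.uint8),
        mm_per_pixel=float(meta["mm_per_pixel"]),
        frame_index=int(meta["frame_index"]),
        phantom_id=meta.get("phantom_id", ""),
        phase=meta.get("phase", "post"),
    )
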