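"""Publication-style plots of profiles, dose-response curves and frames."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

from nanodose.beam import BraggCurve
from nanodose.dose_response import DoseResponseFit, DoseResponsePoint
from nanodose.imaging import USImage
from nanodose.profiles import GrayscaleProfile

__all__ = ["plot_profile", "plot_dose_response", "plot_frame"]


def plot_profile(
    profile: GrayscaleProfile,
    reference: BraggCurve | None = None,
    path=None,
    *,
    title: str = "",
):
    """Vaporization grayscale profile, optionally overlaid on the
    peak-normalized reference depth-dose curve."""
    fig, ax = plt.subplots(figsize=(7, 4))
    ax.plot(profile.position, profile.mean_grey, color="tab:orange",
            label="vaporization profile")
    if profile.n > 1:
        sem = profile.sd_grey
        ax.fill_between(
            profile.position,
            np.clip(profile.mean_grey - sem, 0, None),
            profile.mean_grey + sem,
            alpha=0.25, color="tab:orange", linewidth=0,
        )
    ax.set_xlabel("beam-axis depth (mm)")
    ax.set_ylabel("mean grey value")
    if reference is not None:
        ax2 = ax.twinx()
        ax2.plot(reference.depth, reference.dose / reference.dose.max(),
                 color="tab:blue", alpha=0.7, label="relative dose")
        ax2.set_ylabel("relative dose")
        ax2.set_ylim(0, 1.1)
        lo = max(profile.position[0], reference.depth[0])
        hi = min(profile.position[-1], reference.depth[-1])
        ax.set_xlim(lo, hi)
    if title:
        ax.set_title(title)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def plot_dose_response(
    points: list[DoseResponsePoint],
    fit: DoseResponseFit | None = None,
    path=None,
):
    """Integrated peak area vs dose with the saturating fit."""
    fig, ax = plt.subplots(figsize=(6, 4))
    dose = [p.dose for p in points]
    ax.plot(dose, [p.integral for p in points], "o", color="k",
            label="peak integrals")
    if fit is not None:
        grid = np.linspace(min(dose), max(dose), 200)
        ax.plot(grid, fit.predict(grid), "-", color="tab:red",
                label=f"dose-response fit (R$^2$={fit.r_squared:.3f})")
        if fit.linear_sub_fit:
            sub = fit.linear_sub_fit
            g = np.linspace(0, sub["dose_max"], 50)
            ax.plot(g, sub["intercept"] + sub["slope"] * g, "--",
                    color="tab:green",
                    label=f"linear fit $\\leq$ {sub['dose_max']:g} Gy "
                          f"(R$^2$={sub['r_squared']:.3f})")
    ax.set_xlabel("dose at Bragg peak (Gy)")
    ax.set_ylabel("peak integral (grey mm)")
    ax.legend(fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def plot_frame(image: USImage, path=None, *, title: str = ""):
    """Grayscale rendering of a single frame with mm axes."""
    fig, ax = plt.subplots(figsize=(6, 4.5))
    rows, cols = image.shape
    extent = (0, cols * image.mm_per_pixel, rows * image.mm_per_pixel, 0)
    ax.imshow(image.pixels, cmap="gray", vmin=0, vmax=255, extent=extent)
    ax.set_xlabel("lateral (mm, beam direction)")
    ax.set_ylabel("probe depth (mm)")
    ax.set_title(title or f"{image.phantom_id} {image.phase} f{image.frame_index}")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
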