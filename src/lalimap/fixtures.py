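"""Synthetic test images with analytic ground truth.

Surrogates for spot-pattern photographs: two-level spot images with
known fractional area and eccentricity, periodic stripe images with
known wavelength, shaded-photo surrogates exercising illumination
correction, and head-silhouette masks with a known inscribed disk.
Every generator returns the image together with its ground truth so
measurement error can be bounded without any external data.

Rasterization is hard-edged by default (no anti-aliasing) so that
pixel-counting oracles are exact; pass ``soft_px`` for smoothed edges in
robustness tests.  Spots are placed on a jittered hexagonal lattice,
mimicking the spacing regularity of patterns produced by local
activation / long-range inhibition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .morphometrics import GrayImage

__all__ = [
    "make_spot_image",
    "make_stripe_image",
    "make_shaded_photo",
    "make_head_silhouette",
    "SpotTruth",
]

_DARK = 0.1
_LIGHT = 0.9


@dataclass(frozen=True)
class SpotTruth:
    """Ground truth accompanying a generated spot image."""

    mask: np.ndarray
    FA: float
    EE: float
    centers: tuple[tuple[float, float], ...]


def _ellipse_mask(shape, cy, cx, a, b, angle=0.0):
    """Hard-edged filled ellipse; a, b are the row/column semi-axes."""
    yy, xx = np.indices(shape)
    dy, dx = yy - cy, xx - cx
    if angle:
        c, s = np.cos(angle), np.sin(angle)
        dy, dx = c * dy - s * dx, s * dy + c * dx
    return (dy / a) ** 2 + (dx / b) ** 2 <= 1.0


def make_spot_image(
    n_spots: int,
    axes: tuple[float, float] = (6.0, 6.0),
    jitter: float = 0.0,
    size: tuple[int, int] = (200, 200),
    seed: int | None = None,
    *,
    domain: str = "square",
    soft_px: float = 0.0,
    max_tries: int = 200,
) -> tuple[GrayImage, SpotTruth]:
    """Dark ellipses on a light background with exact FA/EE ground truth.

    ``axes = (a, b)`` are the semi-axes in pixels (row, column); the
    analytic eccentricity is sqrt(1 - (min/max)^2).  Spots sit on a
    hexagonal lattice whose pitch accommodates ``n_spots``, each
    displaced by a seeded uniform jitter; placements that would overlap
    another spot or leave the frame are rejected and re-drawn, erroring
    after ``max_tries`` failures.  ``domain="disk"`` restricts the
    analysis region to the largest centered disk.
    """
    ny, nx = size
    rng = np.random.default_rng(seed)
    a, b = float(axes[0]), float(axes[1])
    big, small = max(a, b), min(a, b)
    truth_ee = float(np.sqrt(1.0 - (small / big) ** 2))

    dom = np.ones(size, dtype=bool)
    if domain == "disk":
        yy, xx = np.indices(size)
        r = min(ny, nx) / 2.0 - 1.0
        dom = (yy - (ny - 1) / 2.0) ** 2 + (xx - (nx - 1) / 2.0) ** 2 <= r**2
    elif domain != "square":
        raise ValueError("domain must be 'square' or 'disk'")

    mask = np.zeros(size, dtype=bool)
    centers: list[tuple[float, float]] = []
    if n_spots > 0:
        # hexagonal lattice with pitch sized to fit n_spots comfortably
        margin = big + 2.0
        pitch = max(
            2.2 * big + 2.0 + 2.0 * jitter,
            np.sqrt((ny - 2 * margin) * (nx - 2 * margin) / max(n_spots, 1) / 1.1),
        )
        sites = []
        y = margin
        row = 0
        while y <= ny - margin:
            x0 = margin + (pitch / 2.0 if row % 2 else 0.0)
            x = x0
            while x <= nx - margin:
                sites.append((y, x))
                x += pitch
            y += pitch * np.sqrt(3.0) / 2.0
            row += 1
        if len(sites) < n_spots:
            raise ValueError(
                f"cannot place {n_spots} spots of semi-axes ({a}, {b}) "
                f"in a {ny}x{nx} image"
            )
        order = rng.permutation(len(sites))[:n_spots]
        for idx in order:
            sy, sx = sites[idx]
            for _ in range(max_tries):
                cy = sy + rng.uniform(-jitter, jitter)
                cx = sx + rng.uniform(-jitter, jitter)
                cand = _ellipse_mask(size, cy, cx, a, b)
                if not (cand & mask).any() and cand.sum() > 0:
                    mask |= cand
                    centers.append((cy, cx))
                    break
            else:
                raise ValueError("unplaceable spot configuration (jitter too large?)")

    img = np.where(mask, _DARK, _LIGHT)
    if soft_px > 0:
        img = ndimage.gaussian_filter(img, soft_px)
    truth_mask = mask & dom
    fa = float(truth_mask.sum()) / float(dom.sum())
    return (
        GrayImage(intensities=np.clip(img, 0, 1), domain_mask=dom),
        SpotTruth(mask=truth_mask, FA=fa, EE=truth_ee if n_spots else 0.0,
                  centers=tuple(centers)),
    )


def make_stripe_image(
    period: float,
    orientation: str = "vertical",
    duty_cycle: float = 0.5,
    size: tuple[int, int] = (200, 200),
) -> tuple[GrayImage, float]:
    """Binary-valued stripes of a known period (returned as ground truth).

    ``duty_cycle`` is the dark fraction of each period; vertical stripes
    vary along columns, horizontal along rows.
    """
    if period < 4:
        raise ValueError("period must be >= 4 px")
    ny, nx = size
    coord = np.arange(nx) if orientation == "vertical" else np.arange(ny)
    dark = (coord % period) < duty_cycle * period
    img = np.where(dark, _DARK, _LIGHT)
    img = np.tile(img, (ny, 1)) if orientation == "vertical" else np.tile(img[:, None], (1, nx))
    return GrayImage(intensities=img), float(period)


def make_shaded_photo(
    base: tuple[GrayImage, SpotTruth] | GrayImage,
    gradient_amp: float = 0.3,
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> tuple[GrayImage, np.ndarray | None]:
    """A photo surrogate: base pattern + illumination ramp + pixel noise.

    The linear ramp spans ``gradient_amp`` across the columns (centered,
    so mean illumination is unchanged); Gaussian pixel noise of standard
    deviation ``noise_sd`` is added with the given seed, and the result
    is clipped to [0, 1].  Returns the image and the base truth mask (if
    the base carried one).
    """
    if isinstance(base, tuple):
        base_img, truth = base
        truth_mask = truth.mask
    else:
        base_img, truth_mask = base, None
    contrast = float(base_img.intensities.max() - base_img.intensities.min())
    if gradient_amp >= contrast:
        raise ValueError(
            f"gradient amplitude {gradient_amp} must stay below the base contrast {contrast:g}"
        )
    ny, nx = base_img.intensities.shape
    ramp = gradient_amp * (np.arange(nx) / max(nx - 1, 1) - 0.5)
    img = base_img.intensities + ramp[None, :]
    if noise_sd > 0:
        img = img + np.random.default_rng(seed).normal(0.0, noise_sd, (ny, nx))
    return (
        GrayImage(
            intensities=np.clip(img, 0.0, 1.0),
            domain_mask=base_img.domain_mask.copy(),
            pixel_scale=base_img.pixel_scale,
        ),
        truth_mask,
    )


def make_head_silhouette(
    shape: str = "square",
    size: tuple[int, int] = (200, 200),
    *,
    extent: tuple[int, int] | None = None,
) -> tuple[np.ndarray, tuple[tuple[float, float], float]]:
    """A filled convex silhouette with its analytic inscribed disk.

    ``shape`` is one of "square", "rectangle", "ellipse", "circle";
    ``extent`` gives the silhouette's (height, width) in pixels (default
    ~70% of the frame).  Returns (mask, ((cy, cx), radius)) where the
    disk is the largest one centered at the centroid.
    """
    ny, nx = size
    if extent is None:
        extent = (int(0.7 * ny), int(0.7 * nx))
    h, w = extent
    if shape == "square":
        h = w = min(h, w)
    if shape == "circle":
        h = w = min(h, w)
    cy, cx = ny // 2, nx // 2
    mask = np.zeros(size, dtype=bool)
    if shape in ("square", "rectangle"):
        mask[cy - h // 2 : cy - h // 2 + h, cx - w // 2 : cx - w // 2 + w] = True
        true_c = (cy - h // 2 + (h - 1) / 2.0, cx - w // 2 + (w - 1) / 2.0)
        radius = min(h, w) / 2.0
    elif shape in ("ellipse", "circle"):
        mask = _ellipse_mask(size, cy, cx, h / 2.0, w / 2.0)
        true_c = (float(cy), float(cx))
        radius = min(h, w) / 2.0
    else:
        raise ValueError(f"unknown shape {shape!r}")
    return mask, (true_c, radius)
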