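"""Spot-pattern morphometrics.

Turns grayscale photographs or binarized simulation fields into cleaned
binary spot patterns and computes the pattern statistics used throughout
the package:

* **fractional area** FA — pigmented pixels / domain pixels,
* **mean eccentricity** EE — per-spot eccentricity of the
  second-central-moment equivalent ellipse, averaged over spots,
* **mean spot size** — mean equivalent diameter 2*sqrt(area/pi),
* **peak length** — 2 * total pixels / (peak-skeleton + valley-skeleton
  pixels) after replacing each spot by its convex hull,
* **Fourier wavelength** — inverse of the frequency maximizing the
  radially averaged magnitude spectrum of the zero-mean image, with the
  90%-of-peak interval as an uncertainty band.

The phenotype of a pattern is the pair [FA, EE]; both are dimensionless
and scale-free, so patterns of different physical size are comparable.
Conventions: photographs are thresholded downward (pigment is dark),
simulated fields upward (pigment is high morphogen); both produce the
same ``BinaryPattern`` with True = pigmented.  Spots use 8-connectivity,
holes/background 4-connectivity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import exposure, measure, morphology

__all__ = [
    "GrayImage",
    "BinaryPattern",
    "Spot",
    "Phenotype",
    "WavelengthEstimate",
    "enhance_contrast",
    "photo_threshold",
    "clean_pattern",
    "find_spots",
    "fractional_area",
    "mean_eccentricity",
    "mean_spot_size",
    "peak_length",
    "fourier_wavelength",
    "threshold_sensitivity",
    "extract_inscribed_disk",
    "cut_scaled_disk",
    "measure_phenotype",
]


class EmptyPatternError(ValueError):
    """Raised when a statistic requires at least one spot and none exist."""


# --------------------------------------------------------------------------
# containers
# --------------------------------------------------------------------------

@dataclass
class GrayImage:
    """A grayscale image with intensities in [0, 1].

    ``pixel_scale`` is the physical size of one pixel (cm/px) when known.
    ``domain_mask`` restricts analysis to a region of interest (e.g. the
    disk inscribed in a head silhouette); it defaults to the full frame.
    """

    intensities: np.ndarray
    pixel_scale: float | None = None
    domain_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.ndim != 2:
            raise ValueError("intensities must be a 2-D array")
        if self.intensities.min() < -1e-9 or self.intensities.max() > 1 + 1e-9:
            raise ValueError("intensities must lie in [0, 1]")
        if self.domain_mask is None:
            self.domain_mask = np.ones(self.intensities.shape, dtype=bool)
        else:
            self.domain_mask = np.asarray(self.domain_mask, dtype=bool)
            if self.domain_mask.shape != self.intensities.shape:
                raise ValueError("domain_mask must match image shape")


@dataclass
class BinaryPattern:
    """A pigmented/background mask (True = pigmented) with optional
    region-of-interest mask and physical pixel scale."""

    mask: np.ndarray
    domain_mask: np.ndarray | None = None
    pixel_scale: float | None = None

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ValueError("mask must be a 2-D array")
        if self.domain_mask is None:
            self.domain_mask = np.ones(self.mask.shape, dtype=bool)
        else:
            self.domain_mask = np.asarray(self.domain_mask, dtype=bool)
            if self.domain_mask.shape != self.mask.shape:
                raise ValueError("domain_mask must match mask shape")
            self.mask = self.mask & self.domain_mask


@dataclass(frozen=True)
class Spot:
    """One connected pigmented component."""

    label: int
    area: int
    eccentricity: float
    equivalent_diameter: float
    centroid: tuple[float, float]


@dataclass(frozen=True)
class Phenotype:
    """A point [FA, EE] in phenotype space."""

    FA: float
    EE: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.FA <= 1.0 and 0.0 <= self.EE <= 1.0):
            raise ValueError(f"FA and EE must lie in [0, 1]: got {self.FA}, {self.EE}")

    def as_array(self) -> np.ndarray:
        return np.array([self.FA, self.EE])


@dataclass(frozen=True)
class WavelengthEstimate:
    """Wavelength measurements of a pattern (all lengths in pixels)."""

    peak_length: float | None
    fourier_wavelength: float
    fourier_interval_lo: float
    fourier_interval_hi: float
    total_pixels: int = 0
    peak_skeleton_pixels: int = 0
    valley_skeleton_pixels: int = 0


# --------------------------------------------------------------------------
# image -> binary pattern
# --------------------------------------------------------------------------

def enhance_contrast(
    img: GrayImage, tile_grid: int | tuple[int, int] = 8, clip_limit: float = 0.01
) -> GrayImage:
    """Tile-based adaptive histogram equalization (CLAHE).

    Corrects shadows and uneven illumination before thresholding.
    ``tile_grid`` gives the number of tiles per image side.
    """
    shape = img.intensities.shape
    if isinstance(tile_grid, int):
        tile_grid = (tile_grid, tile_grid)
    kernel = (max(1, shape[0] // tile_grid[0]), max(1, shape[1] // tile_grid[1]))
    out = exposure.equalize_adapthist(
        np.clip(img.intensities, 0.0, 1.0), kernel_size=kernel, clip_limit=clip_limit
    )
    return GrayImage(
        intensities=np.clip(out, 0.0, 1.0),
        pixel_scale=img.pixel_scale,
        domain_mask=img.domain_mask.copy(),
    )


def photo_threshold(img: GrayImage, *, delta_sigma: float = 0.0) -> BinaryPattern:
    """Binarize a photograph at the threshold T = mu - sigma.

    mu and sigma are the mean and standard deviation of pixel intensity
    over the domain mask; a pixel is pigmented iff its intensity is at
    most ``mu - (1 - delta_sigma) * sigma`` (spots are dark, so the rule
    requires a pixel to be a full standard deviation darker than
    average).  ``delta_sigma`` shifts the threshold in units of sigma and
    is used by :func:`threshold_sensitivity`.
    """
    dom = img.domain_mask
    if not dom.any():
        raise ValueError("domain mask is empty")
    vals = img.intensities[dom]
    mu, sigma = float(vals.mean()), float(vals.std())
    if sigma == 0.0:
        warnings.warn("constant image: sigma = 0, no pixels pigmented")
        return BinaryPattern(
            mask=np.zeros_like(dom), domain_mask=dom.copy(), pixel_scale=img.pixel_scale
        )
    thr = mu - sigma + delta_sigma * sigma
    return BinaryPattern(
        mask=(img.intensities <= thr) & dom,
        domain_mask=dom.copy(),
        pixel_scale=img.pixel_scale,
    )


def clean_pattern(
    p: BinaryPattern,
    min_spot_area: int = 10,
    *,
    fill_holes: bool = True,
    strict: bool = True,
) -> BinaryPattern:
    """Remove threshold noise: fill interior holes, then delete strays.

    Holes (background pixels 4-connected only to a surrounding spot) are
    filled first; connected components (8-connectivity) smaller than the
    cut-off are then removed.  With ``strict=True`` the comparison is
    area < ``min_spot_area`` (a 10-px component survives the default
    cut-off of 10); ``strict=False`` uses <=.  Idempotent.
    """
    mask = p.mask
    if fill_holes:
        mask = ndimage.binary_fill_holes(mask)  # cross structure: 4-connected holes
    lab = measure.label(mask, connectivity=2)
    if lab.max() > 0:
        areas = np.bincount(lab.ravel())
        areas[0] = min_spot_area + 1  # keep background
        small = areas < min_spot_area if strict else areas <= min_spot_area
        mask = mask & ~small[lab]
    return BinaryPattern(
        mask=mask, domain_mask=p.domain_mask.copy(), pixel_scale=p.pixel_scale
    )


# --------------------------------------------------------------------------
# spot statistics
# --------------------------------------------------------------------------

def find_spots(p: BinaryPattern) -> list[Spot]:
    """Connected pigmented components (8-connectivity) as Spot records."""
    lab = measure.label(p.mask, connectivity=2)
    return [
        Spot(
            label=r.label,
            area=int(r.area),
            eccentricity=float(r.eccentricity),
            equivalent_diameter=float(r.equivalent_diameter_area),
            centroid=tuple(r.centroid),
        )
        for r in measure.regionprops(lab)
    ]


def fractional_area(p: BinaryPattern) -> float:
    """Pigmented pixels divided by domain pixels."""
    n_dom = int(p.domain_mask.sum())
    if n_dom == 0:
        raise ValueError("domain mask is empty")
    return float(p.mask.sum()) / n_dom


def mean_eccentricity(p: BinaryPattern, *, area_weighted: bool = False) -> float:
    """Mean spot eccentricity, 0 = perfect circle, 1 = perfect line.

    Each spot's eccentricity is that of the ellipse with the same second
    central moments, e = sqrt(1 - (b/a)^2) with a >= b the semi-axes.
    The default is the unweighted mean over spots.
    """
    spots = find_spots(p)
    if not spots:
        raise EmptyPatternError("no spots: eccentricity undefined")
    ecc = np.array([s.eccentricity for s in spots])
    if area_weighted:
        w = np.array([s.area for s in spots], dtype=float)
        return float((ecc * w).sum() / w.sum())
    return float(ecc.mean())


def mean_spot_size(p: BinaryPattern) -> float:
    """Mean equivalent diameter 2*sqrt(area/pi); cm if pixel_scale is set."""
    spots = find_spots(p)
    if not spots:
        raise EmptyPatternError("no spots: spot size undefined")
    d = float(np.mean([s.equivalent_diameter for s in spots]))
    return d * p.pixel_scale if p.pixel_scale is not None else d


def peak_length(p: BinaryPattern) -> float:
    """Wavelength from skeletonized peaks and valleys.

    Each spot is replaced by its convex hull (the skeleton should reflect
    spot spacing, not spot contour), the hull image and its complement
    are skeletonized, and the estimate is

        2 * total pixels / (valley pixels + peak pixels).

    Masked (e.g. disk-shaped) domains are embedded in the full bounding
    rectangle with background fill; ``total pixels`` counts the whole
    rectangle.
    """
    mask = p.mask
    if not mask.any():
        raise EmptyPatternError("no spots: peak length undefined")
    if mask.all():
        raise EmptyPatternError("no background: peak length undefined")
    hulls = np.zeros_like(mask)
    lab = measure.label(mask, connectivity=2)
    regions = measure.regionprops(lab)
    for r in regions:
        sl = r.slice
        hulls[sl] |= r.image_convex
    if len(regions) < 3:
        warnings.warn(
            f"only {len(regions)} spot(s): peak length is a poor sample of spacing"
        )
    peaks = morphology.skeletonize(hulls)
    valleys = morphology.skeletonize(~hulls)
    n_peak, n_valley = int(peaks.sum()), int(valleys.sum())
    if n_peak + n_valley == 0:
        raise EmptyPatternError("degenerate skeletons: peak length undefined")
    return 2.0 * mask.size / (n_valley + n_peak)


def _radial_profile(spectrum: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Radially averaged spectrum in annular bins of one index width.

    Returns (freq, profile) where freq is in cycles per pixel.
    """
    ny, nx = spectrum.shape
    fy = np.fft.fftfreq(ny)[:, None]
    fx = np.fft.fftfreq(nx)[None, :]
    r = np.hypot(fy, fx)
    df = 1.0 / max(ny, nx)
    idx = np.round(r / df).astype(int)
    counts = np.bincount(idx.ravel())
    sums = np.bincount(idx.ravel(), spectrum.ravel())
    prof = sums / np.maximum(counts, 1)
    freq = np.arange(prof.size) * df
    return freq, prof


def fourier_wavelength(img: GrayImage | np.ndarray, *, interp_factor: int = 10) -> WavelengthEstimate:
    """Dominant wavelength from the radially averaged Fourier spectrum.

    The rectangular image is scaled to zero mean, the magnitude spectrum
    is averaged over annular frequency bins, the profile is linearly
    interpolated (``interp_factor`` points per bin) and the wavelength is
    1/f* at the interpolated peak, excluding the zero-frequency bin.
    ``fourier_interval_lo/hi`` bound the contiguous interval around the
    peak where the profile stays within 90% of its maximum.
    """
    arr = img.intensities if isinstance(img, GrayImage) else np.asarray(img, dtype=float)
    arr = arr - arr.mean()
    if not arr.any():
        raise ValueError("constant image: no spectral peak")
    spec = np.abs(np.fft.fft2(arr))
    freq, prof = _radial_profile(spec)
    # drop the DC bin and unresolved tail beyond Nyquist
    nyq = 0.5
    keep = (freq > 0) & (freq <= nyq)
    freq, prof = freq[keep], prof[keep]
    f_fine = np.linspace(freq[0], freq[-1], interp_factor * freq.size)
    p_fine = np.interp(f_fine, freq, prof)
    i_pk = int(np.argmax(p_fine))
    f_star = f_fine[i_pk]
    level = 0.9 * p_fine[i_pk]
    lo = i_pk
    while lo > 0 and p_fine[lo - 1] >= level:
        lo -= 1
    hi = i_pk
    while hi < p_fine.size - 1 and p_fine[hi + 1] >= level:
        hi += 1
    return WavelengthEstimate(
        peak_length=None,
        fourier_wavelength=1.0 / f_star,
        fourier_interval_lo=1.0 / f_fine[hi],
        fourier_interval_hi=1.0 / f_fine[lo],
        total_pixels=arr.size,
    )


# --------------------------------------------------------------------------
# full-photo statistics and threshold sensitivity
# --------------------------------------------------------------------------

_STAT_NAMES = ("fractional_area", "mean_eccentricity", "mean_spot_size", "peak_length")


def _pattern_stats(p: BinaryPattern) -> dict[str, float]:
    out: dict[str, float] = {}
    try:
        out["fractional_area"] = fractional_area(p)
    except ValueError:
        pass
    for name, fn in (
        ("mean_eccentricity", mean_eccentricity),
        ("mean_spot_size", mean_spot_size),
        ("peak_length", peak_length),
    ):
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                out[name] = fn(p)
        except (EmptyPatternError, ValueError):
            pass
    return out


def threshold_sensitivity(
    img: GrayImage,
    delta_fracs: tuple[float, ...] = (0.25, 0.1),
    *,
    min_spot_area: int = 10,
) -> dict[str, tuple[float, float]]:
    """Envelope of the pattern statistics as the threshold is varied.

    Recomputes FA, EE, spot size and peak length at thresholds
    mu - sigma +- delta*sigma for every delta in ``delta_fracs`` (and at
    the baseline), after the standard cleanup, and returns per-statistic
    (min, max) intervals — the error bars on each statistic.  A statistic
    that is undefined at every threshold is reported as a missing entry.
    """
    deltas = {0.0}
    for d in delta_fracs:
        deltas.update((-d, +d))
    per_stat: dict[str, list[float]] = {k: [] for k in _STAT_NAMES}
    for d in sorted(deltas):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            pat = photo_threshold(img, delta_sigma=d)
        pat = clean_pattern(pat, min_spot_area=min_spot_area)
        for k, val in _pattern_stats(pat).items():
            per_stat[k].append(val)
    return {
        k: (min(v), max(v)) for k, v in per_stat.items() if v
    }


# --------------------------------------------------------------------------
# region-of-interest selection
# --------------------------------------------------------------------------

def _disk_mask(shape: tuple[int, int], center: tuple[float, float], radius: float) -> np.ndarray:
    yy, xx = np.indices(shape)
    return (yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= radius**2


def extract_inscribed_disk(boundary_mask: np.ndarray, img: GrayImage) -> GrayImage:
    """Restrict an image to the largest centroid-centered inscribed disk.

    The disk is centered at the centroid of ``boundary_mask`` (e.g. a
    head silhouette) with radius equal to the distance from the centroid
    to the nearest boundary pixel.
    """
    boundary_mask = np.asarray(boundary_mask, dtype=bool)
    if boundary_mask.shape != img.intensities.shape:
        raise ValueError("boundary mask must match image shape")
    lab = measure.label(boundary_mask, connectivity=2)
    regions = measure.regionprops(lab)
    if len(regions) != 1:
        raise ValueError(f"boundary mask must be one connected region, found {len(regions)}")
    cy, cx = regions[0].centroid
    iy, ix = int(round(cy)), int(round(cx))
    if not boundary_mask[iy, ix]:
        raise ValueError("region centroid lies outside the region")
    radius = float(ndimage.distance_transform_edt(boundary_mask)[iy, ix])
    return GrayImage(
        intensities=img.intensities,
        pixel_scale=img.pixel_scale,
        domain_mask=_disk_mask(boundary_mask.shape, (cy, cx), radius),
    )


def cut_scaled_disk(
    sim: BinaryPattern,
    target_spot_size_cm: float,
    target_radius_cm: float,
    seed: int | None = None,
) -> BinaryPattern:
    """Cut a disk from a simulated pattern at a matched physical scale.

    The pattern's pixel scale is fixed so that its mean spot size equals
    ``target_spot_size_cm``; a disk of radius ``target_radius_cm`` (in
    the resulting cm units) is then cut at a uniformly random center for
    which the disk fits inside the simulated domain.  This matches the
    field of view of an observed pattern so that simulated and observed
    phenotypes sample comparable numbers of spots.
    """
    spot_px = mean_spot_size(
        BinaryPattern(mask=sim.mask, domain_mask=sim.domain_mask, pixel_scale=None)
    )
    pixel_scale = target_spot_size_cm / spot_px  # cm per pixel
    radius_px = target_radius_cm / pixel_scale
    ny, nx = sim.mask.shape
    r_int = int(np.ceil(radius_px))
    if 2 * r_int >= min(ny, nx):
        raise ValueError(
            f"required disk radius {radius_px:.1f} px does not fit the "
            f"{ny}x{nx} domain; rerun the simulation on a larger grid"
        )
    rng = np.random.default_rng(seed)
    cy = rng.integers(r_int, ny - r_int)
    cx = rng.integers(r_int, nx - r_int)
    disk = _disk_mask((ny, nx), (float(cy), float(cx)), radius_px)
    return BinaryPattern(mask=sim.mask & disk, domain_mask=disk, pixel_scale=pixel_scale)


# --------------------------------------------------------------------------
# phenotype
# --------------------------------------------------------------------------

def measure_phenotype(p: BinaryPattern) -> Phenotype:
    """The [FA, EE] phenotype of a binary pattern."""
    return Phenotype(FA=fractional_area(p), EE=mean_eccentricity(p))
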