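"""DAB immunostain quantification inside fascicle ROIs.

Two chains are provided, mirroring routine neuropathological practice:

* **NF70** (axonal neurofilament, chronic axonal loss): color deconvolution
  to the DAB channel, Laplacian-of-Gaussian sharpening of small structures,
  Otsu binarization within the fascicle ROI union, connected-component
  filtering to objects between 20 and 30,000 um^2, and the stained area
  expressed as a percentage of the total fascicular area.
* **CD68** (macrophage infiltration, acute degeneration): DAB channel,
  rolling-ball background subtraction, Yen thresholding within the ROI
  union, a 3x3 median despeckle of the binary mask, and the area fraction
  per section; section values are then normalized to the dataset maximum
  (%max) and the transverse/longitudinal values averaged.

Thresholds are computed from within-ROI pixels only, since quantification
is restricted to fascicles and non-fascicular background would bias them.
A minimum optical-density floor under the automatic threshold keeps
blank or noise-only slides at 0% instead of binarizing sensor noise.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage.filters import threshold_otsu, threshold_yen
from skimage.measure import label, regionprops
from skimage.restoration import rolling_ball
from skimage.transform import rescale, resize

from .render import HDAB_STAIN_VECTORS, FascicleROI, SlideImage, roi_mask

__all__ = [
    "Nf70Params",
    "Cd68Params",
    "AreaFractionResult",
    "color_deconvolve",
    "nf70_area_fraction",
    "cd68_area_fraction",
    "normalize_to_dataset_max",
    "combine_orientations",
]

DAB_CHANNEL = 2  # H-DAB stain order: hematoxylin, eosin, DAB


@dataclass(frozen=True)
class Nf70Params:
    """Parameters of the NF70 %-area chain.

    ``min_object_area``/``max_object_area`` gate connected components by
    their physical area (inclusive bounds, um^2). ``log_sigma`` is the
    scale (px) of the Laplacian-of-Gaussian sharpening. ``min_threshold_od``
    floors the automatic threshold in optical-density units.
    """

    min_object_area: float = 20.0
    max_object_area: float = 30_000.0
    log_sigma: float = 2.0
    min_threshold_od: float = 0.1
    stain_vectors: np.ndarray = field(default_factory=lambda: HDAB_STAIN_VECTORS.copy())

    def __post_init__(self) -> None:
        if not (0 < self.min_object_area < self.max_object_area):
            raise ValueError("need 0 < min_object_area < max_object_area")


@dataclass(frozen=True)
class Cd68Params:
    """Parameters of the CD68 %-area chain.

    The rolling-ball radius must exceed the largest stained structure that
    is not background; confluent macrophage clusters can be large, so the
    default is generous. Large balls are affordable because the background
    is estimated on a downscaled image (it is smooth by construction).
    """

    rolling_ball_radius: float = 120.0
    min_threshold_od: float = 0.1
    stain_vectors: np.ndarray = field(default_factory=lambda: HDAB_STAIN_VECTORS.copy())


@dataclass(frozen=True)
class AreaFractionResult:
    """Stained area as % of fascicular area, per fascicle and pooled.

    The pooled value is total stained area over total fascicular area
    (not the mean of per-fascicle percentages).
    """

    pct_area: float
    per_fascicle_pct: dict[str, float]
    fascicle_areas_um2: dict[str, float]
    object_count: int


def _rolling_ball_background(channel: np.ndarray, radius: float) -> np.ndarray:
    """Rolling-ball background, estimated on a downscaled copy for speed.

    The illumination/counterstain background varies slowly, so estimating
    it at reduced resolution (ball radius scaled accordingly) and
    upsampling loses nothing while making large radii cheap.
    """
    factor = max(1, int(radius // 15))
    if factor == 1:
        return rolling_ball(channel, radius=radius)
    small = rescale(channel, 1.0 / factor, order=1, anti_aliasing=True)
    bg_small = rolling_ball(small, radius=radius / factor)
    return resize(bg_small, channel.shape, order=1)


def color_deconvolve(image: SlideImage | np.ndarray, stain_vectors: np.ndarray | None = None) -> np.ndarray:
    """Unmix an RGB brightfield image into per-stain optical densities.

    Pixel RGB is converted to optical density ``-log10(I/255)`` (zero light
    flux clipped at 1/255) and unmixed with the inverse of ``stain_vectors``
    (rows = per-stain RGB absorbance unit vectors; default the published
    H-DAB matrix). Returns an H x W x 3 stain-space image, clipped at 0.
    """
    S = HDAB_STAIN_VECTORS if stain_vectors is None else np.asarray(stain_vectors, dtype=float)
    if S.shape != (3, 3):
        raise ValueError(f"stain_vectors must be 3x3, got {S.shape}")
    if np.linalg.cond(S) > 1e8:
        raise ValueError("stain matrix is singular or near-singular; cannot unmix")
    pixels = image.pixels if isinstance(image, SlideImage) else np.asarray(image)
    od = -np.log10(np.maximum(pixels.astype(float), 1.0) / 255.0)
    channels = od @ np.linalg.inv(S)
    return np.clip(channels, 0.0, None)


def _threshold_in_roi(
    channel: np.ndarray, mask: np.ndarray, method, min_threshold: float
) -> tuple[np.ndarray, bool]:
    """Binarize ``channel`` inside ``mask`` with a floored automatic threshold.

    Returns (binary mask, degenerate) where degenerate marks an ROI whose
    intensity range was too small to threshold (result forced to empty).
    """
    values = channel[mask]
    if values.size == 0:
        raise ValueError("no usable ROI pixels")
    if np.ptp(values) < 1e-9:
        warnings.warn("degenerate single-intensity ROI; automatic threshold undefined, area set to 0")
        return np.zeros_like(mask), True
    thr = max(float(method(values)), min_threshold)
    return (channel > thr) & mask, False


def _area_result(
    binary: np.ndarray, rois: list[FascicleROI], shape: tuple[int, int], um2_per_px: float,
    object_count: int,
) -> AreaFractionResult:
    per_pct: dict[str, float] = {}
    areas: dict[str, float] = {}
    total_stained = 0.0
    total_area = 0.0
    for roi in rois:
        if not roi.usable:
            continue
        fmask = roi_mask(shape, [roi])
        a = float(fmask.sum() * um2_per_px)
        s = float((binary & fmask).sum() * um2_per_px)
        areas[roi.label] = a
        per_pct[roi.label] = 100.0 * s / a if a else 0.0
        total_stained += s
        total_area += a
    pooled = 100.0 * total_stained / total_area if total_area else 0.0
    return AreaFractionResult(pooled, per_pct, areas, object_count)


def nf70_area_fraction(
    image: SlideImage, rois: list[FascicleROI], params: Nf70Params | None = None
) -> AreaFractionResult:
    """Percent of fascicular area covered by NF70+ staining (chronic axonal loss).

    Chain: color deconvolution -> DAB optical density -> LoG sharpening ->
    Otsu threshold over within-ROI pixels -> 8-connected components ->
    size gate [min_object_area, max_object_area] um^2 -> area fraction.
    """
    params = params or Nf70Params()
    usable = [r for r in rois if r.usable]
    if not usable:
        raise ValueError("at least one usable fascicle ROI is required")
    shape = image.pixels.shape[:2]
    mask = roi_mask(shape, usable)
    dab = color_deconvolve(image, params.stain_vectors)[..., DAB_CHANNEL]
    # unsharp masking with a LoG kernel: flat regions are untouched,
    # small structures and edges are enhanced
    enhanced = dab - params.log_sigma**2 * ndi.gaussian_laplace(dab, params.log_sigma)
    binary, degenerate = _threshold_in_roi(enhanced, mask, threshold_otsu, params.min_threshold_od)

    kept = np.zeros_like(binary)
    n_obj = 0
    if not degenerate:
        labels = label(binary, connectivity=2)
        if labels.max():
            sizes = np.bincount(labels.ravel())
            lo = params.min_object_area / image.um2_per_px
            hi = params.max_object_area / image.um2_per_px
            good = np.zeros(sizes.size, dtype=bool)
            good[1:] = (sizes[1:] >= lo) & (sizes[1:] <= hi)
            kept = good[labels]
            n_obj = int(good[1:].sum())
    return _area_result(kept, rois, shape, image.um2_per_px, n_obj)


def cd68_area_fraction(
    image: SlideImage, rois: list[FascicleROI], params: Cd68Params | None = None
) -> AreaFractionResult:
    """Percent of fascicular area covered by CD68+ staining (macrophages).

    Chain: DAB optical density -> rolling-ball background subtraction ->
    Yen threshold over within-ROI pixels -> 3x3 median despeckle of the
    binary mask -> area fraction per section.
    """
    params = params or Cd68Params()
    usable = [r for r in rois if r.usable]
    if not usable:
        raise ValueError("at least one usable fascicle ROI is required")
    shape = image.pixels.shape[:2]
    mask = roi_mask(shape, usable)
    dab = color_deconvolve(image, params.stain_vectors)[..., DAB_CHANNEL]
    corrected = dab - _rolling_ball_background(dab, params.rolling_ball_radius)
    binary, degenerate = _threshold_in_roi(corrected, mask, threshold_yen, params.min_threshold_od)
    if not degenerate:
        binary = ndi.median_filter(binary, size=3)
    labels = label(binary, connectivity=2)
    return _area_result(binary, rois, shape, image.um2_per_px, int(labels.max()))


def normalize_to_dataset_max(values) -> np.ndarray:
    """Express each value as a percentage of the dataset's maximum.

    Missing values (NaN) are ignored for the maximum and propagated in the
    output. An all-zero dataset has no defined maximum; zeros are returned
    with a warning.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("cannot normalize an empty dataset")
    finite = arr[np.isfinite(arr)]
    if finite.size == 0:
        raise ValueError("cannot normalize a dataset with no finite values")
    m = finite.max()
    if m <= 0:
        warnings.warn("dataset maximum is 0; %max undefined, returning zeros")
        return np.where(np.isfinite(arr), 0.0, np.nan)
    return arr * 100.0 / m


def combine_orientations(transverse_pctmax: float | None, longitudinal_pctmax: float | None) -> float:
    """Average transverse and longitudinal %max CD68 values into one
    total-macrophage-infiltration value; a single available orientation
    passes through unchanged, both missing propagates NaN."""
    vals = [
        v
        for v in (transverse_pctmax, longitudinal_pctmax)
        if v is not None and not (isinstance(v, float) and math.isnan(v))
    ]
    if not vals:
        return float("nan")
    return float(sum(vals) / len(vals))
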