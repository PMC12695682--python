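"""Synthetic brightfield micrograph renderer with construction-time ground truth.

Renders the four preparation types used in sural-nerve workup:

* DAB immunostains (axonal NF70 or macrophage CD68) — brown chromogen blobs
  over a pale hematoxylin counterstain inside elliptical fascicles;
* methylene-blue semithin sections — healthy myelinated fibers as dark
  annuli with a pale axoplasm lumen, acutely degenerating fibers as filled
  dark profiles (myelin collapse);
* teased single-fiber strips — parallel horizontal fibers, Wallerian
  ovoid fibers drawn as fragment chains.

Every render returns a :class:`RenderTruth` measured from the actually
painted masks (never from the request), so downstream segmentation and
morphometry can be validated against exact ground truth.

The chromogen compositing uses the standard published H-DAB optical-density
stain vectors (imported from ``skimage.color``): an optical-density image in
stain space is converted to RGB transmittance as ``255 * 10**(-OD @ M)``
where the rows of ``M`` are the per-stain RGB absorbance vectors.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy import ndimage as ndi
from shapely.geometry import Polygon as ShapelyPolygon
from skimage.color import rgb_from_hed
from skimage.draw import disk as draw_disk
from skimage.draw import polygon as draw_polygon

__all__ = [
    "SlideImage",
    "FascicleROI",
    "RenderTruth",
    "HDAB_STAIN_VECTORS",
    "DEFAULT_MICRONS_PER_PIXEL",
    "render_ihc_slide",
    "render_semithin",
    "render_teased_fibers",
    "roi_mask",
]

#: Rows: hematoxylin, eosin, DAB optical-density unit vectors in RGB.
HDAB_STAIN_VECTORS = np.asarray(rgb_from_hed, dtype=float)

#: 40x-scan analogue.
DEFAULT_MICRONS_PER_PIXEL = 0.5

STAINS = ("nf70_dab", "cd68_dab", "methylene_blue_semithin", "teased_ppd")
ORIENTATIONS = ("transverse", "longitudinal")


@dataclass
class SlideImage:
    """A calibrated RGB micrograph."""

    pixels: np.ndarray  # uint8, H x W x 3
    microns_per_pixel: float
    orientation: str
    stain: str

    def __post_init__(self) -> None:
        if self.microns_per_pixel <= 0:
            raise ValueError("microns_per_pixel must be > 0")
        if self.stain not in STAINS:
            raise ValueError(f"stain must be one of {STAINS}, got {self.stain!r}")
        if self.orientation not in ORIENTATIONS:
            raise ValueError(f"orientation must be one of {ORIENTATIONS}")
        self.pixels = np.asarray(self.pixels, dtype=np.uint8)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError("pixels must be an H x W x 3 RGB raster")

    @property
    def um2_per_px(self) -> float:
        return self.microns_per_pixel**2


@dataclass
class FascicleROI:
    """A polygonal nerve-fascicle region of interest.

    Vertices are 0-based pixel coordinates, x rightward (column), y downward
    (row). The polygon must be simple and closed with positive area.
    ``usable=False`` marks fascicles excluded from quantification (e.g.,
    inaccurate automated detection on review).
    """

    polygon: list[tuple[float, float]]
    label: str
    usable: bool = True

    def __post_init__(self) -> None:
        poly = ShapelyPolygon(self.polygon)
        if not poly.is_valid or poly.area <= 0:
            raise ValueError(f"ROI {self.label!r}: polygon must be simple with area > 0")

    @property
    def shapely(self) -> ShapelyPolygon:
        return ShapelyPolygon(self.polygon)

    def area_px(self) -> float:
        """Polygon area in px^2 by the shoelace formula (via shapely)."""
        return self.shapely.area


@dataclass
class RenderTruth:
    """Exact construction-time ground truth, keyed by fascicle label."""

    stained_area_um2: dict[str, float] = field(default_factory=dict)
    fascicle_area_um2: dict[str, float] = field(default_factory=dict)
    fiber_count: dict[str, int] = field(default_factory=dict)
    degenerating_count: dict[str, int] = field(default_factory=dict)
    ovoid_fiber_count: int | None = None
    total_fiber_count: int | None = None

    @property
    def total_stained_area_um2(self) -> float:
        return float(sum(self.stained_area_um2.values()))

    @property
    def pct_area(self) -> float:
        """Pooled stained %-of-fascicular-area over all fascicles."""
        total = sum(self.fascicle_area_um2.values())
        return 100.0 * self.total_stained_area_um2 / total if total else 0.0

    @property
    def ovoid_fraction(self) -> float | None:
        if self.total_fiber_count is None or not self.total_fiber_count:
            return None
        return self.ovoid_fiber_count / self.total_fiber_count


@lru_cache(maxsize=1024)
def _polygon_mask(shape: tuple[int, int], vertices: tuple[tuple[float, float], ...]) -> np.ndarray:
    xs = np.array([p[0] for p in vertices])
    ys = np.array([p[1] for p in vertices])
    mask = np.zeros(shape, dtype=bool)
    rr, cc = draw_polygon(ys, xs, shape=shape)
    mask[rr, cc] = True
    mask.setflags(write=False)
    return mask


def roi_mask(shape: tuple[int, int], rois: list[FascicleROI], usable_only: bool = True) -> np.ndarray:
    """Rasterize ROI polygons to a boolean mask (pixel-center containment)."""
    mask = np.zeros(shape, dtype=bool)
    for roi in rois:
        if usable_only and not roi.usable:
            continue
        mask |= _polygon_mask(shape, tuple((float(x), float(y)) for x, y in roi.polygon))
    return mask


def _ellipse_polygon(cx: float, cy: float, rx: float, ry: float, n: int = 72) -> list[tuple[float, float]]:
    t = np.linspace(0, 2 * np.pi, n, endpoint=False)
    return [(cx + rx * np.cos(a), cy + ry * np.sin(a)) for a in t]


def _make_fascicles(
    shape: tuple[int, int], n_fascicles: int, rng: np.random.Generator
) -> list[FascicleROI]:
    """Lay out non-overlapping elliptical fascicles on a grid with jitter."""
    h, w = shape
    cols = int(np.ceil(np.sqrt(n_fascicles)))
    rows_n = int(np.ceil(n_fascicles / cols))
    cell_w, cell_h = w / cols, h / rows_n
    rois = []
    for k in range(n_fascicles):
        i, j = divmod(k, cols)
        cx = (j + 0.5) * cell_w + rng.uniform(-0.04, 0.04) * cell_w
        cy = (i + 0.5) * cell_h + rng.uniform(-0.04, 0.04) * cell_h
        rx = rng.uniform(0.33, 0.42) * cell_w
        ry = rng.uniform(0.33, 0.42) * cell_h
        rois.append(FascicleROI(_ellipse_polygon(cx, cy, rx, ry), label=f"fascicle_{k}"))
    return rois


def _od_to_rgb(od: np.ndarray) -> np.ndarray:
    """Stain-space optical densities (H x W x 3: hema, eosin, DAB) to uint8 RGB."""
    transmittance = np.power(10.0, -(od @ HDAB_STAIN_VECTORS))
    return np.clip(np.round(transmittance * 255.0), 0, 255).astype(np.uint8)


def _apply_sensor_effects(
    rgb: np.ndarray, rng: np.random.Generator, noise_sd: float, illumination: float
) -> np.ndarray:
    """Additive Gaussian sensor noise plus a mild left-right illumination ramp."""
    out = rgb.astype(float)
    if illumination > 0:
        h, w = rgb.shape[:2]
        ramp = 1.0 + illumination * (np.linspace(-1, 1, w))[None, :, None]
        out = out * ramp
    if noise_sd > 0:
        out = out + rng.normal(0.0, noise_sd, size=out.shape)
    return np.clip(np.round(out), 0, 255).astype(np.uint8)


def _paint_exact_area(
    mask: np.ndarray, center: tuple[int, int], n_pixels: int, allowed: np.ndarray
) -> None:
    """Paint a compact connected blob of exactly ``n_pixels`` pixels.

    Candidate pixels around ``center`` (restricted to ``allowed``) are taken
    in order of increasing distance, which yields an approximately circular
    connected object with an exact pixel count.
    """
    r = int(np.ceil(np.sqrt(n_pixels / np.pi))) + 3
    cy, cx = center
    rr, cc = draw_disk((cy, cx), r, shape=mask.shape)
    ok = allowed[rr, cc]
    rr, cc = rr[ok], cc[ok]
    if rr.size < n_pixels:
        raise ValueError("not enough room inside the fascicle for the requested object")
    d2 = (rr - cy) ** 2 + (cc - cx) ** 2
    order = np.argsort(d2, kind="stable")[:n_pixels]
    mask[rr[order], cc[order]] = True


def render_ihc_slide(
    target_pct_area: float | None = None,
    object_areas_um2: list[float] | None = None,
    stain: str = "nf70_dab",
    seed: int = 0,
    shape: tuple[int, int] = (512, 512),
    n_fascicles: int = 2,
    microns_per_pixel: float = DEFAULT_MICRONS_PER_PIXEL,
    orientation: str = "transverse",
    blob_radius_px: tuple[float, float] = (6.0, 14.0),
    dab_od: float = 1.0,
    counterstain_od: float = 0.15,
    noise_sd: float = 3.0,
    illumination: float = 0.03,
) -> tuple[SlideImage, list[FascicleROI], RenderTruth]:
    """Render a DAB immunostain with known stained area per fascicle.

    Either ``target_pct_area`` (percent of each fascicle's area to cover
    with chromogen, achieved within 5% relative) or ``object_areas_um2``
    (explicit per-object areas, painted with exact pixel counts — used for
    size-gate verification) must be given. Truth is measured from the final
    painted mask. ``noise_sd=0`` with ``illumination=0`` gives a noiseless
    render.
    """
    if (target_pct_area is None) == (object_areas_um2 is None):
        raise ValueError("give exactly one of target_pct_area or object_areas_um2")
    if target_pct_area is not None and not (0 <= target_pct_area <= 80):
        raise ValueError(f"target_pct_area must be in [0, 80], got {target_pct_area}")
    if stain not in ("nf70_dab", "cd68_dab"):
        raise ValueError(f"IHC stain must be nf70_dab or cd68_dab, got {stain!r}")
    rng = np.random.default_rng(seed)
    um2_per_px = microns_per_pixel**2

    rois = _make_fascicles(shape, n_fascicles, rng)
    stained = np.zeros(shape, dtype=bool)
    truth = RenderTruth()
    r_min, r_max = blob_radius_px

    fmasks = {}
    dists = {}
    for roi in rois:
        fmask = roi_mask(shape, [roi])
        fmasks[roi.label] = fmask
        # distance to fascicle boundary, to keep painted objects fully inside
        dists[roi.label] = ndi.distance_transform_edt(fmask)
        truth.fascicle_area_um2[roi.label] = int(fmask.sum()) * um2_per_px

    if object_areas_um2 is not None:
        # the object list is painted once per slide, each object into a
        # randomly chosen fascicle; objects are isolated and fully inside
        total_px = sum(fm.sum() for fm in fmasks.values())
        areas_px = [int(round(a / um2_per_px)) for a in object_areas_um2]
        if sum(areas_px) > 0.8 * total_px:
            raise ValueError("requested object area exceeds what fits in the fascicles")
        for a_px in sorted(areas_px, reverse=True):  # biggest first for packing
            if a_px <= 0:
                continue
            r = np.sqrt(a_px / np.pi) + 4.0
            placed = False
            for _ in range(500):
                roi = rois[rng.integers(len(rois))]
                cand_y, cand_x = np.nonzero(dists[roi.label] > r)
                if cand_y.size == 0:
                    continue
                k = rng.integers(cand_y.size)
                cy, cx = int(cand_y[k]), int(cand_x[k])
                rr, cc = draw_disk((cy, cx), r, shape=shape)
                if stained[rr, cc].any():
                    continue
                _paint_exact_area(stained, (cy, cx), a_px, fmasks[roi.label] & ~stained)
                placed = True
                break
            if not placed:
                raise ValueError("could not place object; lower the requested area")
    else:
        for roi in rois:
            fmask = fmasks[roi.label]
            dist = dists[roi.label]
            fascicle_px = int(fmask.sum())
            target_px = int(round(target_pct_area / 100.0 * fascicle_px))
            if target_px > 0.85 * fascicle_px:
                raise ValueError("requested stained area exceeds the fascicle area")
            guard = 0
            while True:
                remaining = target_px - int((stained & fmask).sum())
                if remaining <= 0:
                    break
                guard += 1
                if guard > 10_000:  # pragma: no cover - packing safety valve
                    raise ValueError("packing failed; lower target_pct_area")
                r = rng.uniform(r_min, r_max)
                if np.pi * r * r > remaining:
                    r = max(r_min, np.sqrt(remaining / np.pi))
                cand_y, cand_x = np.nonzero(dist > r + 1)
                if cand_y.size == 0:
                    raise ValueError("fascicle too small for the requested blob size")
                k = rng.integers(cand_y.size)
                rr, cc = draw_disk((cand_y[k], cand_x[k]), r, shape=shape)
                stained[rr, cc] = True

    for roi in rois:
        truth.stained_area_um2[roi.label] = float(
            (stained & fmasks[roi.label]).sum() * um2_per_px
        )

    all_fascicles = roi_mask(shape, rois)
    od = np.zeros((*shape, 3), dtype=float)
    od[..., 0][all_fascicles] = counterstain_od  # pale hematoxylin counterstain
    od[..., 0][stained] = 0.0  # chromogen pixels are pure DAB
    od[..., 2][stained] = dab_od
    rgb = _od_to_rgb(od)
    rgb = _apply_sensor_effects(rgb, rng, noise_sd, illumination)
    slide = SlideImage(rgb, microns_per_pixel, orientation, stain)
    return slide, rois, truth


def render_semithin(
    fiber_count: int,
    degenerating_count: int = 0,
    seed: int = 0,
    shape: tuple[int, int] = (512, 512),
    n_fascicles: int = 1,
    microns_per_pixel: float = DEFAULT_MICRONS_PER_PIXEL,
    outer_radius_px: tuple[float, float] = (5.0, 9.0),
    lumen_ratio: float = 0.55,
    noise_sd: float = 3.0,
    illumination: float = 0.03,
    max_tries: int = 2000,
) -> tuple[SlideImage, list[FascicleROI], RenderTruth]:
    """Render a methylene-blue semithin section with exact fiber counts.

    ``fiber_count`` healthy annuli (dark myelin ring, pale lumen) and
    ``degenerating_count`` filled dark profiles are placed without overlap
    across the fascicles; counts are split proportionally to fascicle area.
    Raises if placement fails after bounded retries (density too high).
    """
    rng = np.random.default_rng(seed)
    um2_per_px = microns_per_pixel**2
    rois = _make_fascicles(shape, n_fascicles, rng)

    background = np.array([232, 230, 238], dtype=float)
    myelin = np.array([42, 44, 118], dtype=float)
    lumen_color = np.array([218, 218, 232], dtype=float)
    degen_color = np.array([88, 72, 124], dtype=float)  # grayish-violaceous collapse
    fascicle_bg = np.array([226, 224, 234], dtype=float)

    img = np.tile(background, (*shape, 1))
    truth = RenderTruth()

    areas = []
    masks = []
    for roi in rois:
        m = roi_mask(shape, [roi])
        masks.append(m)
        areas.append(m.sum())
        img[m] = fascicle_bg
        truth.fascicle_area_um2[roi.label] = float(m.sum() * um2_per_px)
    areas = np.asarray(areas, dtype=float)
    share = areas / areas.sum()

    # largest-remainder split of the requested counts across fascicles
    def split(total: int) -> list[int]:
        raw = share * total
        base = np.floor(raw).astype(int)
        for k in np.argsort(raw - base)[::-1][: total - base.sum()]:
            base[k] += 1
        return base.tolist()

    per_f_healthy = split(fiber_count)
    per_f_degen = split(degenerating_count)

    r_lo, r_hi = outer_radius_px
    for roi, fmask, n_h, n_d in zip(rois, masks, per_f_healthy, per_f_degen):
        occupied = np.zeros(shape, dtype=bool)
        ys, xs = np.nonzero(fmask)
        placed_h = placed_d = 0
        kinds = ["d"] * n_d + ["h"] * n_h
        for kind in kinds:
            r = rng.uniform(r_lo, r_hi)
            for _ in range(max_tries):
                k = rng.integers(ys.size)
                cy, cx = int(ys[k]), int(xs[k])
                rr, cc = draw_disk((cy, cx), r + 2.0, shape=shape)
                if not fmask[rr, cc].all() or occupied[rr, cc].any():
                    continue
                occupied[rr, cc] = True
                rr, cc = draw_disk((cy, cx), r, shape=shape)
                if kind == "h":
                    img[rr, cc] = myelin
                    lr, lc = draw_disk((cy, cx), lumen_ratio * r, shape=shape)
                    img[lr, lc] = lumen_color
                    placed_h += 1
                else:
                    img[rr, cc] = degen_color
                    placed_d += 1
                break
            else:
                raise ValueError(
                    f"could not place fiber in {roi.label} after {max_tries} tries; "
                    "lower the fiber density"
                )
        truth.fiber_count[roi.label] = placed_h
        truth.degenerating_count[roi.label] = placed_d

    rgb = np.clip(np.round(img), 0, 255).astype(np.uint8)
    rgb = _apply_sensor_effects(rgb, rng, noise_sd, illumination)
    slide = SlideImage(rgb, microns_per_pixel, "transverse", "methylene_blue_semithin")
    return slide, rois, truth


def render_teased_fibers(
    total_fibers: int,
    ovoid_fibers: int,
    seed: int = 0,
    width: int = 600,
    fiber_spacing_px: int = 14,
    fiber_thickness_px: int = 4,
    microns_per_pixel: float = DEFAULT_MICRONS_PER_PIXEL,
    noise_sd: float = 3.0,
    illumination: float = 0.03,
) -> tuple[SlideImage, RenderTruth]:
    """Render a teased-fiber strip: parallel horizontal fibers, some ovoid.

    Intact fibers are continuous dark bands across the full strip width;
    ovoid (Wallerian) fibers are chains of dark fragments separated by
    cleared gaps. Which fibers are ovoid is randomized by ``seed``.
    """
    if not (0 <= ovoid_fibers <= total_fibers):
        raise ValueError("need 0 <= ovoid_fibers <= total_fibers")
    if total_fibers == 0:
        raise ValueError("total_fibers must be >= 1")
    rng = np.random.default_rng(seed)
    height = total_fibers * fiber_spacing_px + fiber_spacing_px
    img = np.full((height, width, 3), 242.0)
    fiber_color = np.array([70.0, 62.0, 58.0])  # osmicated/PPD dark fiber

    ovoid_idx = set(rng.choice(total_fibers, size=ovoid_fibers, replace=False).tolist())
    for i in range(total_fibers):
        y0 = fiber_spacing_px // 2 + i * fiber_spacing_px
        rows = slice(y0, y0 + fiber_thickness_px)
        if i in ovoid_idx:
            x = 0
            while x < width:
                seg = int(rng.integers(18, 42))
                gap = int(rng.integers(8, 16))
                img[rows, x : min(x + seg, width)] = fiber_color
                x += seg + gap
        else:
            img[rows, :] = fiber_color

    rgb = np.clip(np.round(img), 0, 255).astype(np.uint8)
    rgb = _apply_sensor_effects(rgb, rng, noise_sd, illumination)
    slide = SlideImage(rgb, microns_per_pixel, "longitudinal", "teased_ppd")
    truth = RenderTruth(ovoid_fiber_count=ovoid_fibers, total_fiber_count=total_fibers)
    return slide, truth
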