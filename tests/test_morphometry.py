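"""Fiber detection/classification on semithin renders and teased-fiber tracing."""

import numpy as np
import pytest
from shapely.geometry import Polygon, box

from nervequant.morphometry import (
    FiberDetection,
    FiberParams,
    OvoidParams,
    count_degenerating,
    detect_fibers,
    fiber_density,
    ovoid_fraction,
)
from nervequant.render import (
    FascicleROI,
    SlideImage,
    render_semithin,
    render_teased_fibers,
)

NOISELESS = dict(noise_sd=0.0, illumination=0.0)


def _counts(detections):
    h = sum(d.classification == "healthy_myelinated" for d in detections)
    d = sum(d.classification == "degenerating" for d in detections)
    return h, d


class TestDetectFibers:
    def test_blank_fascicle_yields_no_detections(self):
        slide, rois, _ = render_semithin(0, 0, seed=1, **NOISELESS)
        assert detect_fibers(slide, rois) == []

    @pytest.mark.parametrize("n_healthy,n_degen", [(50, 0), (40, 7), (0, 12)])
    def test_noiseless_counts_exact(self, n_healthy, n_degen):
        slide, rois, truth = render_semithin(n_healthy, n_degen, seed=2, **NOISELESS)
        h, d = _counts(detect_fibers(slide, rois))
        assert h == sum(truth.fiber_count.values())
        assert d == sum(truth.degenerating_count.values())

    def test_noisy_counts_within_ten_percent(self):
        slide, rois, truth = render_semithin(60, 8, seed=3)
        h, d = _counts(detect_fibers(slide, rois))
        assert h == pytest.approx(sum(truth.fiber_count.values()), rel=0.1)
        assert d == pytest.approx(sum(truth.degenerating_count.values()), abs=1)

    def test_lumen_fraction_exactly_at_threshold_is_healthy(self):
        # a ring whose lumen is exactly 10% of the outer disk area
        img = np.full((64, 64, 3), 230, dtype=np.uint8)
        yy, xx = np.mgrid[0:64, 0:64]
        d2 = (yy - 32) ** 2 + (xx - 32) ** 2
        outer = d2 <= 8**2  # 197 px
        n_out = int(outer.sum())
        n_lumen = int(round(0.10 * n_out))
        order = np.argsort(d2[outer], kind="stable")
        ys, xs = np.nonzero(outer)
        img[ys, xs] = (45, 45, 120)
        img[ys[order[:n_lumen]], xs[order[:n_lumen]]] = (225, 225, 235)
        slide = SlideImage(img, 0.5, "transverse", "methylene_blue_semithin")
        roi = FascicleROI([(2, 2), (62, 2), (62, 62), (2, 62)], "f")
        dets = detect_fibers(slide, [roi])
        assert len(dets) == 1
        assert dets[0].lumen_area / dets[0].outer_area == pytest.approx(0.10, abs=0.005)
        assert dets[0].classification == "healthy_myelinated"

    def test_degenerating_count_conservative_in_threshold(self):
        slide, rois, _ = render_semithin(40, 8, seed=4)
        counts = []
        for thr in (0.30, 0.10, 0.05, 0.0):
            dets = detect_fibers(slide, rois, FiberParams(lumen_fraction_threshold=thr))
            counts.append(_counts(dets)[1])
        assert counts == sorted(counts, reverse=True)

    def test_no_roi_rejected(self):
        slide, _, _ = render_semithin(5, 0, seed=5, **NOISELESS)
        with pytest.raises(ValueError):
            detect_fibers(slide, [])


class TestFiberDensity:
    @staticmethod
    def _square_roi(side_px, label="f", usable=True, offset=0.0):
        return FascicleROI(
            [(offset, 0), (offset + side_px, 0), (offset + side_px, side_px), (offset, side_px)],
            label,
            usable,
        )

    @staticmethod
    def _detection(x, y, cls="healthy_myelinated"):
        return FiberDetection(centroid=(y, x), outer_area=30.0, lumen_area=10.0, classification=cls)

    def test_density_arithmetic(self):
        # 0.1 mm^2 = 1e5 um^2: a 632.46 px square at 0.5 um/px
        side = np.sqrt(1e5) / 0.5
        roi = self._square_roi(side)
        dets = [self._detection(10 + i, 10) for i in range(50)]
        res = fiber_density(dets, [roi], microns_per_pixel=0.5)
        assert res.fiber_density == pytest.approx(500.0, rel=1e-3)

    def test_unusable_fascicle_excluded_from_counts_and_area(self):
        side = np.sqrt(1e5) / 0.5
        usable = self._square_roi(side, "good")
        bad = self._square_roi(side, "bad", usable=False, offset=side + 10)
        dets = [self._detection(10 + i, 10) for i in range(30)]
        dets += [self._detection(side + 20 + i, 10) for i in range(99)]
        res = fiber_density(dets, [usable, bad], microns_per_pixel=0.5)
        assert res.fiber_density == pytest.approx(300.0, rel=1e-3)
        assert res.excluded_fascicles == 1
        assert res.usable_fascicles == 1

    def test_zero_fibers_gives_zero_density(self):
        res = fiber_density([], [self._square_roi(100)], microns_per_pixel=0.5)
        assert res.fiber_density == 0.0

    def test_zero_usable_area_rejected(self):
        with pytest.raises(ValueError, match="usable"):
            fiber_density([], [self._square_roi(100, usable=False)], 0.5)

    def test_degenerating_density_arithmetic(self):
        # 0.05 mm^2 usable area with 7 degenerating profiles -> 140 /mm^2
        side = np.sqrt(5e4) / 0.5
        roi = self._square_roi(side)
        dets = [self._detection(10 + i, 10, "degenerating") for i in range(7)]
        density, count = count_degenerating(dets, [roi], microns_per_pixel=0.5)
        assert density == pytest.approx(140.0, rel=1e-3)
        assert count == 7

    def test_density_invariant_to_splitting_roi(self):
        slide, rois, _ = render_semithin(30, 5, seed=6, **NOISELESS)
        dets = detect_fibers(slide, rois)
        whole = fiber_density(dets, rois, slide.microns_per_pixel)
        ellipse = rois[0].shapely
        left = ellipse.intersection(box(-1, -1, ellipse.centroid.x, slide.pixels.shape[0] + 1))
        right = ellipse.difference(left)
        halves = [
            FascicleROI(list(Polygon(g).exterior.coords)[:-1], f"half_{i}")
            for i, g in enumerate((left, right))
        ]
        split = fiber_density(dets, halves, slide.microns_per_pixel)
        assert split.fiber_count + split.degen_count >= whole.fiber_count + whole.degen_count - 1
        assert split.fiber_density == pytest.approx(whole.fiber_density, rel=0.05)


class TestOvoidFraction:
    def test_noiseless_render_recovers_exact_fraction(self):
        slide, truth = render_teased_fibers(25, 5, seed=1, **NOISELESS)
        res = ovoid_fraction(slide)
        assert res.fraction == truth.ovoid_fraction == 0.2
        assert res.assessable_count == 25

    def test_no_ovoids(self):
        slide, _ = render_teased_fibers(20, 0, seed=2)
        assert ovoid_fraction(slide).fraction == 0.0

    def test_all_ovoid(self):
        slide, _ = render_teased_fibers(22, 22, seed=3)
        assert ovoid_fraction(slide).fraction == 1.0

    def test_low_fiber_count_warns(self):
        slide, _ = render_teased_fibers(19, 4, seed=4)
        with pytest.warns(UserWarning, match="19 assessable"):
            ovoid_fraction(slide)

    def test_blank_strip_rejected(self):
        img = np.full((100, 300, 3), 242, dtype=np.uint8)
        slide = SlideImage(img, 0.5, "longitudinal", "teased_ppd")
        with pytest.raises(ValueError, match="no fibers"):
            ovoid_fraction(slide)
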