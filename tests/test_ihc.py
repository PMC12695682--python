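"""Color deconvolution and the NF70/CD68 area-fraction chains."""

import numpy as np
import pytest

from nervequant.ihc import (
    Cd68Params,
    Nf70Params,
    cd68_area_fraction,
    color_deconvolve,
    combine_orientations,
    nf70_area_fraction,
    normalize_to_dataset_max,
)
from nervequant.render import (
    HDAB_STAIN_VECTORS,
    FascicleROI,
    SlideImage,
    render_ihc_slide,
    roi_mask,
)

NOISELESS = dict(noise_sd=0.0, illumination=0.0)
SMALL = dict(shape=(256, 256), n_fascicles=1)


class TestColorDeconvolve:
    def test_white_pixel_has_zero_optical_density(self):
        img = np.full((2, 2, 3), 255, dtype=np.uint8)
        assert color_deconvolve(img).max() == 0.0

    def test_identity_matrix_returns_raw_od(self):
        img = np.full((1, 1, 3), 128, dtype=np.uint8)
        od = -np.log10(128 / 255)
        channels = color_deconvolve(img, np.eye(3))
        assert channels[0, 0] == pytest.approx([od, od, od], rel=1e-6)

    def test_dab_synthesized_pixel_unmixes_to_dab(self):
        # forward-composite a pure-DAB pixel with the same stain model
        od = np.zeros((1, 1, 3))
        od[0, 0, 2] = 1.0
        rgb = np.clip(np.round(255 * 10 ** -(od @ HDAB_STAIN_VECTORS)), 0, 255).astype(np.uint8)
        channels = color_deconvolve(rgb)
        assert channels[0, 0, 2] / channels[0, 0].sum() >= 0.95

    def test_singular_stain_matrix_rejected(self):
        bad = np.ones((3, 3))
        with pytest.raises(ValueError, match="singular"):
            color_deconvolve(np.zeros((1, 1, 3), dtype=np.uint8), bad)


class TestNf70AreaFraction:
    def test_blank_slide_measures_zero(self):
        slide, rois, _ = render_ihc_slide(target_pct_area=0.0, seed=1, **SMALL, **NOISELESS)
        with pytest.warns(UserWarning, match="degenerate"):
            assert nf70_area_fraction(slide, rois).pct_area == 0.0

    def test_object_below_size_floor_is_excluded(self):
        slide, rois, _ = render_ihc_slide(object_areas_um2=[10.0], seed=2, **SMALL, **NOISELESS)
        assert nf70_area_fraction(slide, rois).pct_area == 0.0

    def test_noiseless_recovery_within_five_percent(self):
        slide, rois, truth = render_ihc_slide(target_pct_area=10.0, seed=3, **SMALL, **NOISELESS)
        res = nf70_area_fraction(slide, rois)
        assert res.pct_area == pytest.approx(truth.pct_area, rel=0.05)

    def test_noisy_recovery_within_fifteen_percent(self):
        slide, rois, truth = render_ihc_slide(target_pct_area=10.0, seed=4, **SMALL)
        res = nf70_area_fraction(slide, rois)
        assert res.pct_area == pytest.approx(truth.pct_area, rel=0.15)

    def test_adding_an_object_never_decreases_area(self):
        slide, rois, _ = render_ihc_slide(target_pct_area=5.0, seed=5, **SMALL, **NOISELESS)
        before = nf70_area_fraction(slide, rois).pct_area
        # paint one extra in-gate DAB object into an unstained fascicle region
        augmented = slide.pixels.copy()
        dab_rgb = np.clip(
            np.round(255 * 10 ** -(np.array([0.0, 0.0, 1.0]) @ HDAB_STAIN_VECTORS)), 0, 255
        ).astype(np.uint8)
        mask = roi_mask(augmented.shape[:2], rois)
        dab = color_deconvolve(slide)[..., 2]
        free = mask & (dab < 0.1)
        ys, xs = np.nonzero(free)
        cy, cx = ys[len(ys) // 2], xs[len(xs) // 2]
        yy, xx = np.mgrid[0:augmented.shape[0], 0:augmented.shape[1]]
        blob = (yy - cy) ** 2 + (xx - cx) ** 2 <= 8**2
        augmented[blob & mask] = dab_rgb
        after = nf70_area_fraction(
            SlideImage(augmented, slide.microns_per_pixel, "transverse", "nf70_dab"), rois
        ).pct_area
        assert after >= before

    def test_rotation_invariance(self):
        slide, rois, _ = render_ihc_slide(target_pct_area=10.0, seed=6, **SMALL, **NOISELESS)
        res = nf70_area_fraction(slide, rois)
        h = slide.pixels.shape[0]
        rot_pixels = np.rot90(slide.pixels).copy()
        # rot90 maps (x, y) -> (y, h-1-x) in (col,row)=(x,y) convention
        rot_rois = [
            FascicleROI([(y, h - 1 - x) for x, y in r.polygon], r.label) for r in rois
        ]
        rot = nf70_area_fraction(
            SlideImage(rot_pixels, slide.microns_per_pixel, "transverse", "nf70_dab"),
            rot_rois,
        )
        assert rot.pct_area == pytest.approx(res.pct_area, rel=0.01)

    def test_no_usable_roi_rejected(self):
        slide, rois, _ = render_ihc_slide(target_pct_area=5.0, seed=7, **SMALL, **NOISELESS)
        unusable = [FascicleROI(r.polygon, r.label, usable=False) for r in rois]
        with pytest.raises(ValueError, match="usable"):
            nf70_area_fraction(slide, unusable)

    def test_invalid_size_gate_rejected(self):
        with pytest.raises(ValueError):
            Nf70Params(min_object_area=100, max_object_area=50)


class TestCd68AreaFraction:
    def test_blank_slide_measures_zero(self):
        slide, rois, _ = render_ihc_slide(
            target_pct_area=0.0, stain="cd68_dab", seed=1, **SMALL, **NOISELESS
        )
        with pytest.warns(UserWarning, match="degenerate"):
            assert cd68_area_fraction(slide, rois).pct_area == 0.0

    def test_noisy_recovery_within_twenty_percent(self):
        slide, rois, truth = render_ihc_slide(
            target_pct_area=5.0, stain="cd68_dab", seed=2, **SMALL
        )
        res = cd68_area_fraction(slide, rois)
        assert res.pct_area == pytest.approx(truth.pct_area, rel=0.20)

    def test_isolated_single_pixels_removed_by_despeckle(self):
        # pale counterstained fascicle with scattered single-pixel DAB specks
        slide, rois, _ = render_ihc_slide(
            target_pct_area=0.0, stain="cd68_dab", seed=3, **SMALL, **NOISELESS
        )
        pixels = slide.pixels.copy()
        dab_rgb = np.clip(
            np.round(255 * 10 ** -(np.array([0.0, 0.0, 1.0]) @ HDAB_STAIN_VECTORS)), 0, 255
        ).astype(np.uint8)
        mask = roi_mask(pixels.shape[:2], rois)
        ys, xs = np.nonzero(mask)
        for k in range(0, len(ys), 97):  # widely separated singletons
            pixels[ys[k], xs[k]] = dab_rgb
        speckled = SlideImage(pixels, slide.microns_per_pixel, "transverse", "cd68_dab")
        assert cd68_area_fraction(speckled, rois).pct_area == 0.0


class TestNormalizeToDatasetMax:
    @pytest.mark.parametrize(
        "values,expected",
        [([2, 4], [50, 100]), ([7], [100]), ([0, 0, 5], [0, 0, 100])],
    )
    def test_examples(self, values, expected):
        assert normalize_to_dataset_max(values) == pytest.approx(expected)

    def test_maximum_maps_to_100_with_ties(self):
        out = normalize_to_dataset_max([3, 3, 1])
        assert list(out) == pytest.approx([100, 100, 100 / 3])

    def test_nan_propagates_without_affecting_max(self):
        out = normalize_to_dataset_max([np.nan, 2, 4])
        assert np.isnan(out[0]) and out[1] == 50 and out[2] == 100

    def test_all_zero_warns_and_returns_zeros(self):
        with pytest.warns(UserWarning, match="maximum is 0"):
            assert list(normalize_to_dataset_max([0.0, 0.0])) == [0.0, 0.0]

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            normalize_to_dataset_max([])


class TestCombineOrientations:
    @pytest.mark.parametrize(
        "t,l,expected", [(60, 40, 50.0), (80, None, 80.0), (0, 0, 0.0), (None, 30, 30.0)]
    )
    def test_averaging_and_pass_through(self, t, l, expected):
        assert combine_orientations(t, l) == expected

    def test_both_missing_propagates_nan(self):
        assert np.isnan(combine_orientations(None, None))
        assert np.isnan(combine_orientations(float("nan"), None))
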