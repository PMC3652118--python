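"""Image pipeline: enhancement, segmentation, morphometry, features."""

import numpy as np
import pytest

import cervidx as cx
from cervidx.fuzzy import InputError
from cervidx.imaging import (
    NoNucleiError,
    ParameterError,
    PipelineParams,
    compute_features,
    detect_nucleoli,
    enhance_levels,
    extract_features,
    label_nuclei,
    morph_cleanup,
    split_channels,
    staining_raster,
    threshold_nuclei,
    to_grayscale,
)
from cervidx.synthetic import ImageSpec, generate_image

from conftest import sized_spec


@pytest.fixture(scope="module")
def noiseless_pair():
    spec = ImageSpec(
        width=420, height=420, n_nuclei=4,
        area_dist=(3000, 400), eccentricity_dist=(0.6, 0.03),
        noise_sd=0.0, seed=21,
    )
    return generate_image(spec)


class TestPixelSteps:
    def test_identity_enhancement(self, noiseless_pair):
        image, _ = noiseless_pair
        assert np.array_equal(enhance_levels(image, PipelineParams()), image)

    def test_percentile_stretch_hits_full_range(self, noiseless_pair):
        image, _ = noiseless_pair
        out = enhance_levels(image, PipelineParams(stretch=(1, 99)))
        assert out.min() == 0 and out.max() == 255

    def test_degenerate_stretch_rejected(self):
        flat = np.full((8, 8, 3), 77, dtype=np.uint8)
        with pytest.raises(ParameterError):
            enhance_levels(flat, PipelineParams(stretch=(1, 99)))

    def test_channel_split_is_lossless(self):
        img = np.zeros((2, 2, 3), dtype=np.uint8)
        img[0, 0] = (0, 255, 0)
        r, g, b = split_channels(img)
        assert g[0, 0] == 255 and r[0, 0] == 0 and b[0, 0] == 0
        assert np.array_equal(np.dstack([r, g, b]), img)

    def test_split_rejects_grayscale(self):
        with pytest.raises(InputError):
            split_channels(np.zeros((4, 4), dtype=np.uint8))

    @pytest.mark.parametrize("value, expected", [(255, 255), (0, 0), (100, 100)])
    def test_grayscale_of_equal_channels(self, value, expected):
        img = np.full((2, 2, 3), value, dtype=np.uint8)
        assert to_grayscale(img)[0, 0] == pytest.approx(expected, abs=0.5)

    def test_nuclei_darkest_in_green_channel(self, noiseless_pair):
        image, truth = noiseless_pair
        nucleus = truth.labels > 0
        r, g, b = split_channels(image)
        assert g[nucleus].mean() < r[nucleus].mean()
        assert g[nucleus].mean() < b[nucleus].mean()


class TestThresholdAndMorphology:
    def test_otsu_recovers_ground_truth_mask(self, noiseless_pair):
        image, truth = noiseless_pair
        _, green, _ = split_channels(image)
        mask = threshold_nuclei(green)
        assert np.array_equal(mask, truth.labels > 0)

    def test_manual_between_modes_equals_otsu(self, noiseless_pair):
        image, _ = noiseless_pair
        _, green, _ = split_channels(image)
        otsu_mask = threshold_nuclei(green)
        manual = threshold_nuclei(green, "manual", manual_value=170)
        assert np.array_equal(otsu_mask, manual)

    def test_manual_without_value_rejected(self):
        with pytest.raises(ParameterError):
            threshold_nuclei(np.zeros((4, 4)), "manual")

    def test_uniform_raster_gives_empty_mask(self):
        assert not threshold_nuclei(np.full((8, 8), 50)).any()

    def test_cleanup_identity_with_zero_params(self):
        rng = np.random.default_rng(0)
        mask = rng.uniform(size=(30, 30)) < 0.3
        assert np.array_equal(morph_cleanup(mask, radius=0, min_area=0), mask)

    def test_single_pixel_removed_by_min_area(self):
        mask = np.zeros((9, 9), dtype=bool)
        mask[4, 4] = True
        assert not morph_cleanup(mask, radius=0, min_area=2).any()

    def test_salt_noise_cleaned_to_ground_truth(self, noiseless_pair):
        image, truth = noiseless_pair
        gt = truth.labels > 0
        rng = np.random.default_rng(5)
        noisy = gt | (rng.uniform(size=gt.shape) < 0.001)
        cleaned = morph_cleanup(noisy, radius=2, min_area=50)
        # cleanup must remove the specks; the opening/closing may shave a
        # one-pixel rim off true nuclei
        mismatch = (cleaned ^ gt).sum() / gt.sum()
        assert mismatch < 0.02
        assert len(label_nuclei(cleaned)) == len(truth.nuclei)


class TestRegions:
    def test_disjoint_ellipse_areas_recovered(self, noiseless_pair):
        image, truth = noiseless_pair
        _, green, _ = split_channels(image)
        regions = label_nuclei(threshold_nuclei(green))
        assert len(regions) == len(truth.nuclei)
        for region, t in zip(
            sorted(regions, key=lambda r: r.centroid),
            sorted(truth.nuclei, key=lambda t: t.centroid),
        ):
            assert region.area == pytest.approx(t.area, rel=0.02)

    def test_disc_eccentricity_near_zero(self):
        spec = ImageSpec(width=256, height=256, n_nuclei=1, noise_sd=0,
                         area_dist=(4000, 0), eccentricity_dist=(0.0, 0.0), seed=3)
        image, _ = generate_image(spec)
        _, regions, _ = extract_features(image)
        assert regions[0].eccentricity <= 0.05

    def test_elongated_ellipse_eccentricity(self):
        # a 5:1 axis ratio has e = sqrt(1 - 1/25) ~ 0.98
        mask = np.zeros((160, 320), dtype=bool)
        from skimage.draw import ellipse

        rr, cc = ellipse(80, 160, 25, 125)
        mask[rr, cc] = True
        regions = label_nuclei(mask)
        assert regions[0].eccentricity >= 0.9
        assert regions[0].eccentricity == pytest.approx(np.sqrt(1 - 1 / 25), abs=0.01)

    def test_empty_mask_gives_no_regions(self):
        assert label_nuclei(np.zeros((10, 10), dtype=bool)) == []


class TestNucleoli:
    def test_uniform_nucleus_has_none(self):
        raster = np.full((50, 50), 80.0)
        mask = np.zeros((50, 50), dtype=bool)
        mask[10:40, 10:40] = True
        regions = label_nuclei(mask)
        assert detect_nucleoli(raster, regions) == [0]

    def test_planted_spots_counted_exactly(self):
        spec = ImageSpec(width=300, height=300, n_nuclei=2, noise_sd=4.0,
                         area_dist=(6000, 200), eccentricity_dist=(0.5, 0.02),
                         nucleoli_per_nucleus=2, seed=9)
        image, truth = generate_image(spec)
        fv, _, _ = extract_features(image)
        assert fv.pn == truth.pn == 4

    def test_oversized_spot_filtered(self):
        raster = np.full((60, 60), 80.0)
        mask = np.zeros((60, 60), dtype=bool)
        mask[5:55, 5:55] = True
        raster[15:45, 15:45] = 140.0  # "spot" covering 36% of the nucleus
        regions = label_nuclei(mask)
        assert detect_nucleoli(raster, regions, max_frac=0.3) == [0]


class TestFeatures:
    def test_mean_area_of_two_regions(self):
        mask = np.zeros((200, 120), dtype=bool)
        mask[10:50, 10:110] = True    # 4000 px
        mask[80:140, 10:110] = True   # 6000 px
        regions = label_nuclei(mask)
        fv = compute_features(np.full(mask.shape, 70.0), regions)
        assert fv.dn == pytest.approx(5000)
        assert fv.tn == pytest.approx(70.0)

    def test_zero_regions_is_an_error(self):
        with pytest.raises(NoNucleiError):
            compute_features(np.zeros((5, 5)), [])

    def test_brute_force_accumulation_matches(self, noiseless_pair):
        image, truth = noiseless_pair
        fv, _, _ = extract_features(image)
        stain = staining_raster(to_grayscale(image))
        # independent per-pixel accumulation over the ground-truth masks
        areas, means = [], []
        for t in truth.nuclei:
            pix = truth.labels == t.label
            areas.append(pix.sum())
            means.append(stain[pix].mean())
        assert fv.dn == pytest.approx(np.mean(areas), rel=0.02)
        assert fv.tn == pytest.approx(np.mean(means), rel=0.02)

    def test_pipeline_deterministic(self, noiseless_pair):
        image, _ = noiseless_pair
        fv1, _, _ = extract_features(image)
        fv2, _, _ = extract_features(image)
        assert fv1 == fv2

    def test_translation_and_rotation_invariance(self):
        spec = sized_spec(cx.REGIMES["normal"], n_nuclei=6, seed=31)
        image, _ = generate_image(spec)
        fv, _, _ = extract_features(image)
        shifted = np.roll(image, (17, -23), axis=(0, 1))
        rotated = np.rot90(image, axes=(0, 1))
        for variant in (shifted, rotated):
            fv2, _, _ = extract_features(variant)
            assert fv2.n_nuclei == fv.n_nuclei
            assert fv2.dn == pytest.approx(fv.dn, rel=0.02)
            assert fv2.hn == pytest.approx(fv.hn, abs=0.02)
            assert fv2.pn == fv.pn

    def test_ground_truth_recovery_with_noise(self):
        spec = sized_spec(cx.REGIMES["agc"], n_nuclei=10, seed=13)
        image, truth = generate_image(spec)
        fv, _, _ = extract_features(image)
        assert fv.n_nuclei == len(truth.nuclei)
        assert fv.dn == pytest.approx(truth.dn, rel=0.02)
        assert fv.hn == pytest.approx(truth.hn, abs=0.05)
        assert fv.pn == truth.pn
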