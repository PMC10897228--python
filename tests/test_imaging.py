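"""Image statistics: thresholding, enrichment ratios, crop CoV."""

import numpy as np
import pytest

from elfscan.imaging import (
    ImageChannel,
    RegionMask,
    crop_cov_heterogeneity,
    crop_side_pixels,
    mito_enrichment_ratio,
    punctum_enrichment,
    read_tiff_channels,
    threshold_mask,
)
from elfscan.synthetic import gen_cell_image, write_image


def two_level_image():
    img = np.full((20, 20), 10.0)
    img[5:10, 5:10] = 100.0
    return ImageChannel(img, pixel_size=0.1)


class TestThresholdMask:
    def test_otsu_separates_bimodal(self):
        ch = two_level_image()
        mask = threshold_mask(ch)
        assert np.array_equal(mask.mask, ch.pixels == 100.0)

    def test_manual_matches_otsu_on_bimodal(self):
        ch = two_level_image()
        auto = threshold_mask(ch)
        manual = threshold_mask(ch, method="manual", manual_threshold=50.0)
        assert np.array_equal(auto.mask, manual.mask)

    def test_constant_image_rejected(self):
        ch = ImageChannel(np.zeros((5, 5)), pixel_size=0.1)
        with pytest.raises(ValueError, match="manual"):
            threshold_mask(ch)


class TestMitoEnrichment:
    def _masks(self, shape):
        mito = np.zeros(shape, bool)
        mito[2:5, 2:5] = True
        cell = np.ones(shape, bool)
        return RegionMask(mito), RegionMask(cell, kind="cell")

    def test_uniform_image_gives_one(self):
        ch = ImageChannel(np.full((10, 10), 7.0), 0.1)
        mito, cell = self._masks((10, 10))
        assert mito_enrichment_ratio(ch, mito, cell).value == pytest.approx(1.0)

    def test_analytic_threefold(self):
        mito, cell = self._masks((10, 10))
        img = np.ones((10, 10))
        img[mito.mask] = 3.0
        res = mito_enrichment_ratio(ImageChannel(img, 0.1), mito, cell)
        assert res.value == pytest.approx(3.0)

    def test_scale_invariance(self):
        mito, cell = self._masks((10, 10))
        rng = np.random.default_rng(0)
        img = rng.uniform(1, 5, (10, 10))
        r1 = mito_enrichment_ratio(ImageChannel(img, 0.1), mito, cell).value
        r2 = mito_enrichment_ratio(ImageChannel(img * 37.0, 0.1), mito, cell).value
        assert r1 == pytest.approx(r2)

    def test_mask_containment_enforced(self):
        mito = RegionMask(np.ones((5, 5), bool))
        cell = RegionMask(np.zeros((5, 5), bool), kind="cell")
        with pytest.raises(ValueError):
            mito_enrichment_ratio(ImageChannel(np.ones((5, 5)), 0.1), mito, cell)

    @pytest.mark.parametrize("E", [1.0, 2.0, 3.0, 5.0])
    def test_recovers_planted_enrichment_under_poisson_noise(self, E):
        images, truth = gen_cell_image(enrichment=E, seed=42, noise="poisson")
        res = mito_enrichment_ratio(images["client"], images["mito_mask"],
                                    images["cell_mask"])
        assert res.value == pytest.approx(E, rel=0.05)


class TestPunctumEnrichment:
    def test_all_signal_in_puncta(self):
        img = np.zeros((10, 10))
        img[3, 3] = 5.0
        punctum = np.zeros((10, 10), bool)
        punctum[3, 3] = True
        cell = np.ones((10, 10), bool)
        res = punctum_enrichment(ImageChannel(img, 0.1), RegionMask(punctum, kind="punctum"),
                                 RegionMask(cell, kind="cell"))
        assert res.value == pytest.approx(1.0)

    def test_uniform_signal_gives_area_fraction(self):
        img = np.full((10, 10), 4.0)
        punctum = np.zeros((10, 10), bool)
        punctum[:2, :5] = True  # 10 of 100 pixels
        res = punctum_enrichment(ImageChannel(img, 0.1),
                                 RegionMask(punctum, kind="punctum"),
                                 RegionMask(np.ones((10, 10), bool), kind="cell"))
        assert res.value == pytest.approx(0.1)

    def test_monotone_in_mask_growth(self):
        rng = np.random.default_rng(3)
        img = ImageChannel(rng.uniform(0, 10, (20, 20)), 0.1)
        cell = RegionMask(np.ones((20, 20), bool), kind="cell")
        prev = 0.0
        mask = np.zeros((20, 20), bool)
        for k in range(1, 20):
            mask[:k, :] = True
            val = punctum_enrichment(img, RegionMask(mask, kind="punctum"), cell).value
            assert val >= prev - 1e-12
            prev = val

    def test_planted_fraction_recovered_exactly_without_noise(self):
        images, truth = gen_cell_image(punctate_fraction=0.25, seed=7, noise="none")
        res = punctum_enrichment(images["client"], images["punctum_mask"],
                                 images["cell_mask"])
        assert res.value == pytest.approx(0.25, abs=1e-9)

    def test_zero_total_rejected(self):
        img = ImageChannel(np.zeros((5, 5)), 0.1)
        cell = RegionMask(np.ones((5, 5), bool), kind="cell")
        punctum = RegionMask(np.zeros((5, 5), bool), kind="punctum")
        with pytest.raises(ValueError):
            punctum_enrichment(img, punctum, cell)


class TestCropCov:
    def test_constant_crop_zero(self):
        ch = ImageChannel(np.full((60, 60), 9.0), pixel_size=0.1)
        res = crop_cov_heterogeneity(ch, (30, 30))
        assert res.value == 0.0

    def test_two_level_crop_analytic(self):
        # crop of {1, 3} in equal numbers: mean 2, population SD 1 => CoV 0.5
        img = np.ones((60, 60))
        side = crop_side_pixels(8.0, 0.1)
        r0 = c0 = 30 - side // 2
        crop = np.ones((side, side))
        crop[:, : side // 2] = 1.0
        crop[:, side // 2:] = 3.0
        assert side % 2 == 0
        img[r0:r0 + side, c0:c0 + side] = crop
        res = crop_cov_heterogeneity(ImageChannel(img, 0.1), (30, 30))
        assert res.value == pytest.approx(0.5)

    def test_scale_invariance(self):
        rng = np.random.default_rng(5)
        img = rng.uniform(1, 9, (60, 60))
        v1 = crop_cov_heterogeneity(ImageChannel(img, 0.1), (30, 30)).value
        v2 = crop_cov_heterogeneity(ImageChannel(img * 11.0, 0.1), (30, 30)).value
        assert v1 == pytest.approx(v2)

    def test_crop_area_sets_side(self):
        # 8 um^2 at 0.1 um/px: sqrt(8)=2.828 um => 28 px
        assert crop_side_pixels(8.0, 0.1) == 28
        assert crop_side_pixels(8.0, 2.0) == 2  # minimum side

    def test_crop_outside_image_rejected(self):
        ch = ImageChannel(np.ones((30, 30)), pixel_size=0.1)
        with pytest.raises(ValueError):
            crop_cov_heterogeneity(ch, (2, 2))


class TestTiffRoundTrip:
    def test_channels_and_pixel_size_survive(self, tmp_path):
        images, _ = gen_cell_image(seed=1, noise="none", pixel_size=0.2)
        path = tmp_path / "cell.tif"
        write_image(images, path)
        channels = read_tiff_channels(path)
        assert len(channels) == 2
        assert channels[0].pixel_size == pytest.approx(0.2, rel=1e-3)
        assert np.allclose(channels[1].pixels, images["client"].pixels)
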