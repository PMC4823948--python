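"""HE deconvolution, necrosis area, leukocyte counts, percent-positive."""

import numpy as np
import pytest

import icd_profiler as icd
from icd_profiler.histology import EOSIN_OD, HEMATOXYLIN_OD, StainMaps, rgb_to_od


def _float_rgb_from_densities(h, e):
    """Unquantized Beer-Lambert composition (float RGB, 0..255 scale)."""
    od = h[..., None] * HEMATOXYLIN_OD + e[..., None] * EOSIN_OD
    return 256.0 * 10.0 ** (-od) - 1.0


class TestDeconvolveHE:
    def test_white_pixel_has_zero_density(self):
        rgb = np.full((2, 2, 3), 255, dtype=np.uint8)
        maps = icd.deconvolve_he(rgb)
        assert np.allclose(maps.hematoxylin, 0.0, atol=1e-9)
        assert np.allclose(maps.eosin, 0.0, atol=1e-9)

    def test_pure_hematoxylin_pixel_recovers_density(self):
        d = 0.8
        rgb = _float_rgb_from_densities(np.full((3, 3), d), np.zeros((3, 3)))
        maps = icd.deconvolve_he(rgb)
        assert np.allclose(maps.hematoxylin, d, atol=1e-6)
        assert np.allclose(maps.eosin, 0.0, atol=1e-6)

    def test_collinear_vectors_rejected(self):
        S = np.array([[0.5, 0.5, 0.5], [0.5, 0.5, 0.5]])
        with pytest.raises(ValueError, match="collinear"):
            icd.deconvolve_he(np.zeros((2, 2, 3), dtype=np.uint8), S)

    def test_roundtrip_within_one_gray_level(self, tissue_default):
        rgb, _ = tissue_default
        maps = icd.deconvolve_he(rgb)
        back = icd.recompose_he(maps.hematoxylin, maps.eosin, maps.stain_matrix)
        rms = np.sqrt(np.mean((back.astype(float) - rgb.astype(float)) ** 2))
        assert rms <= 1.0

    def test_cross_check_against_skimage_hed(self, tissue_default):
        """Independent stain separation (skimage rgb2hed) must agree with
        ours up to its different OD normalization: per-pixel maps strongly
        correlated."""
        from skimage.color import rgb2hed

        rgb, _ = tissue_default
        ours = icd.deconvolve_he(rgb).hematoxylin.ravel()
        theirs = rgb2hed(rgb)[..., 0].ravel()
        assert np.corrcoef(ours, theirs)[0, 1] > 0.95


class TestEosinHematoxylinRatio:
    def test_uniform_ratio(self):
        maps = StainMaps(np.ones((8, 8)), np.full((8, 8), 2.0),
                         icd.HE_STAIN_MATRIX)
        res = icd.eosin_hematoxylin_ratio(maps, hematoxylin_floor=0.1)
        assert np.allclose(res.ratio_map, 2.0)
        assert res.mean_ratio == pytest.approx(2.0)

    def test_fully_masked_flagged(self):
        maps = StainMaps(np.full((8, 8), 0.01), np.ones((8, 8)),
                         icd.HE_STAIN_MATRIX)
        res = icd.eosin_hematoxylin_ratio(maps, hematoxylin_floor=0.1)
        assert res.fully_masked and np.isnan(res.mean_ratio)

    def test_nonpositive_floor_rejected(self):
        maps = StainMaps(np.ones((4, 4)), np.ones((4, 4)), icd.HE_STAIN_MATRIX)
        with pytest.raises(ValueError):
            icd.eosin_hematoxylin_ratio(maps, hematoxylin_floor=0.0)

    def test_necrotic_region_has_higher_ratio(self, tissue_default):
        rgb, truth = tissue_default
        maps = icd.deconvolve_he(rgb)
        res = icd.eosin_hematoxylin_ratio(maps, hematoxylin_floor=0.05)
        inside = np.nanmean(res.ratio_map[truth.necrotic_mask])
        outside = np.nanmean(res.ratio_map[~truth.necrotic_mask])
        assert inside > outside


class TestLowHematoxylinArea:
    def test_exact_quarter_with_fixed_threshold(self):
        h = np.ones((20, 20))
        h[:10, :10] = 0.1  # exactly 25% of pixels
        maps = StainMaps(h, np.ones_like(h), icd.HE_STAIN_MATRIX)
        frac, _ = icd.low_hematoxylin_area_fraction(
            maps, np.ones_like(h, bool), threshold_method="fixed",
            fixed_threshold=0.5,
        )
        assert frac == 0.25

    @pytest.mark.parametrize("n_leukocytes", [0, 40])
    def test_zero_necrosis_stays_near_zero(self, n_leukocytes):
        """No necrotic mode -> fraction ~ 0, even when dense leukocyte
        puncta add a high-hematoxylin tail that Otsu could latch onto."""
        rgb, _ = icd.generate_he_tissue(
            icd.TissueSpec(necrotic_fraction=0.0, n_leukocytes=n_leukocytes,
                           seed=13)
        )
        maps = icd.deconvolve_he(rgb)
        frac, _ = icd.low_hematoxylin_area_fraction(maps, icd.tissue_mask(maps))
        assert frac < 0.02

    @pytest.mark.parametrize("requested", [0.1, 0.25])
    def test_otsu_recovers_requested_fraction(self, requested):
        rgb, truth = icd.generate_he_tissue(
            icd.TissueSpec(necrotic_fraction=requested, n_leukocytes=0, seed=31)
        )
        maps = icd.deconvolve_he(rgb)
        frac, _ = icd.low_hematoxylin_area_fraction(maps, icd.tissue_mask(maps))
        assert frac == pytest.approx(truth.necrotic_area_fraction, abs=0.02)

    def test_empty_mask_rejected(self):
        maps = StainMaps(np.ones((4, 4)), np.ones((4, 4)), icd.HE_STAIN_MATRIX)
        with pytest.raises(ValueError):
            icd.low_hematoxylin_area_fraction(maps, np.zeros((4, 4), bool))


class TestCountLeukocytes:
    def test_blank_region_counts_zero(self):
        hema = np.full((64, 64), 0.9)
        assert icd.count_leukocytes(hema, np.ones((64, 64), bool)) == 0

    def test_recovers_planted_count(self, tissue_default):
        rgb, truth = tissue_default
        maps = icd.deconvolve_he(rgb)
        n = icd.count_leukocytes(maps.hematoxylin, icd.tissue_mask(maps))
        assert abs(n - truth.leukocyte_count) <= 2

    def test_counts_ordered_with_planted_density(self):
        counts = {}
        for planted in (20, 80):
            rgb, _ = icd.generate_he_tissue(
                icd.TissueSpec(n_leukocytes=planted, seed=37)
            )
            maps = icd.deconvolve_he(rgb)
            counts[planted] = icd.count_leukocytes(
                maps.hematoxylin, icd.tissue_mask(maps)
            )
        assert counts[20] < counts[80]

    def test_invalid_band_rejected(self):
        hema = np.ones((8, 8))
        with pytest.raises(ValueError):
            icd.count_leukocytes(hema, np.ones((8, 8), bool),
                                 min_diameter_px=5, max_diameter_px=2)

    def test_accepts_rgb_input(self, tissue_default):
        rgb, truth = tissue_default
        maps = icd.deconvolve_he(rgb)
        n = icd.count_leukocytes(rgb, icd.tissue_mask(maps))
        assert abs(n - truth.leukocyte_count) <= 2


class TestPercentPositiveCells:
    def test_all_positive_by_construction(self):
        spec = icd.FieldSpec(n_cells=40, assay="MX1_GFP", responder_fraction=1.0,
                             dead_fraction=0.0, seed=41)
        img, _ = icd.generate_field(spec)
        res = icd.percent_positive_cells(img, marker_threshold=100.0,
                                         direction="above", measurement="cell")
        assert res.percent == 100.0

    def test_fraction_recovered_within_binomial_ci(self):
        from scipy import stats

        spec = icd.FieldSpec(n_cells=200, image_shape=(640, 640),
                             assay="MX1_GFP", responder_fraction=0.3,
                             dead_fraction=0.0, seed=43)
        img, truth = icd.generate_field(spec)
        res = icd.percent_positive_cells(img, marker_threshold=100.0,
                                         direction="above", measurement="cell")
        k_true = int(truth.cells.responder.sum())
        lo, hi = stats.binom.interval(0.99, len(truth.cells),
                                      k_true / len(truth.cells))
        assert lo <= res.n_positive / res.n_cells * res.n_cells <= hi

    def test_hmgb1_loss_counted_positive_below_threshold(self):
        """Cells generated with nuclear HMGB1 near background must be the
        ones called positive under the below-direction."""
        spec = icd.FieldSpec(n_cells=60, assay="HMGB1_GFP",
                             responder_fraction=0.5, dead_fraction=0.0, seed=47)
        img, truth = icd.generate_field(spec)
        res = icd.percent_positive_cells(img, marker_threshold=150.0,
                                         direction="below",
                                         measurement="nuclear")
        expected = 100.0 * truth.cells.responder.mean()
        assert res.percent == pytest.approx(expected, abs=10.0)

    def test_no_cells_flagged(self):
        img = icd.FieldImage(channels=dict(
            hoechst=np.zeros((64, 64), np.uint16),
            gfp=np.zeros((64, 64), np.uint16),
            pi=np.zeros((64, 64), np.uint16),
        ))
        res = icd.percent_positive_cells(img, marker_threshold=10.0)
        assert res.no_cells and np.isnan(res.percent)
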