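"""Moment-preserving thresholding and area metrics."""

import numpy as np
import pytest

import mammodense as md
from mammodense.segmentation import DegenerateHistogramError


def oracle_p0(hist):
    """Independent closed-form below-threshold fraction of the two-level
    moment match (coded separately from the implementation)."""
    p = np.asarray(hist, float) / np.sum(hist)
    g = np.arange(256.0)
    m1, m2, m3 = (p * g).sum(), (p * g**2).sum(), (p * g**3).sum()
    cd = m2 - m1**2
    c0 = (-(m2**2) + m1 * m3) / cd
    c1 = (m1 * m2 - m3) / cd
    z0 = (-c1 - np.sqrt(c1**2 - 4 * c0)) / 2
    z1 = (-c1 + np.sqrt(c1**2 - 4 * c0)) / 2
    return (z1 - m1) / (z1 - z0)


def oracle_threshold(hist):
    """Enumerate all 256 candidate thresholds; pick the smallest whose
    cumulative below-fraction reaches the closed-form p0."""
    p0 = oracle_p0(hist)
    total = np.sum(hist)
    running = 0.0
    for g in range(256):
        running += hist[g] / total
        if running >= p0 - 1e-9:
            return g
    return 255


class TestMaskedHistogram:
    def test_uniform_value(self):
        img = np.full((10, 10), 7, dtype=np.uint8)
        mask = np.zeros((10, 10), bool)
        mask[:10, :10] = True
        h = md.masked_histogram(img, mask)
        assert h[7] == 100 and h.sum() == 100

    def test_counts_only_masked_pixels(self):
        rng = np.random.default_rng(0)
        img = rng.integers(0, 256, (20, 30)).astype(np.uint8)
        mask = np.zeros((20, 30), bool)
        mask[:, :15] = True
        h = md.masked_histogram(img, mask)
        assert h.sum() == mask.sum()
        # brute-force tally oracle
        tally = np.zeros(256, int)
        for r in range(20):
            for c in range(15):
                tally[img[r, c]] += 1
        assert np.array_equal(h, tally)

    def test_empty_mask_errors(self):
        with pytest.raises(ValueError):
            md.masked_histogram(np.zeros((4, 4), np.uint8), np.zeros((4, 4), bool))


class TestMomentsThreshold:
    def test_symmetric_bimodal_gives_half_split(self):
        # equal spikes at 10 and 200: p0 = 1/2, threshold = lower spike
        h = np.zeros(256, int)
        h[10] = h[200] = 500
        assert md.moments_threshold(h) == 10
        assert oracle_p0(h) == pytest.approx(0.5, abs=1e-12)

    def test_degenerate_single_level(self):
        h = np.zeros(256, int)
        h[42] = 1000
        with pytest.raises(DegenerateHistogramError):
            md.moments_threshold(h)

    def test_empty_histogram(self):
        with pytest.raises(DegenerateHistogramError):
            md.moments_threshold(np.zeros(256, int))

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        h = rng.integers(0, 50, 256)
        assert md.moments_threshold(h) == oracle_threshold(h)

    def test_bimodal_gaussianish_histograms(self):
        # shapes closer to real masked mammogram histograms
        g = np.arange(256.0)
        for mu1, mu2, w in [(60, 200, 0.6), (80, 180, 0.3), (40, 120, 0.5)]:
            h = (w * np.exp(-((g - mu1) / 15) ** 2)
                 + (1 - w) * np.exp(-((g - mu2) / 20) ** 2)) * 10000
            h = np.rint(h).astype(int)
            t = md.moments_threshold(h)
            assert t == oracle_threshold(h)
            assert mu1 < t < mu2


class TestApplyThreshold:
    def test_extreme_thresholds(self, small_image, small_truth):
        mask = small_truth.mask
        assert not md.apply_threshold(small_image, mask, 255).any()
        lo = int(small_image.pixels[mask].min())
        if lo > 0:
            full = md.apply_threshold(small_image, mask, lo - 1)
            assert np.array_equal(full, mask)

    def test_recovers_ground_truth(self, small_image, small_truth):
        res = md.segment(small_image, small_truth.mask)
        inter = (res.dense_map & small_truth.dense_map).sum()
        union = (res.dense_map | small_truth.dense_map).sum()
        assert inter / union > 0.8

    def test_background_content_is_irrelevant(self, small_image, small_truth):
        """Filling the background with any value changes nothing."""
        res0 = md.segment(small_image, small_truth.mask)
        noisy = small_image.pixels.copy()
        noisy[~small_truth.mask] = 255
        img2 = md.MammogramImage(noisy, small_image.pixel_spacing_cm)
        res1 = md.segment(img2, small_truth.mask)
        assert res0.threshold == res1.threshold
        assert np.array_equal(res0.dense_map, res1.dense_map)


class TestAreaMetrics:
    def test_arithmetic(self):
        mask = np.zeros((40, 40), bool)
        mask.ravel()[:1000] = True
        dense = np.zeros_like(mask)
        dense.ravel()[:250] = True
        res = md.area_metrics(dense, mask, 0.1)
        assert res.breast_area_cm2 == pytest.approx(10.0)
        assert res.dense_area_cm2 == pytest.approx(2.5)
        assert res.lucent_area_cm2 == pytest.approx(7.5)
        assert res.overall_pd == pytest.approx(25.0)

    def test_all_dense(self):
        mask = np.ones((5, 5), bool)
        res = md.area_metrics(mask, mask, 0.2)
        assert res.overall_pd == 100.0 and res.lucent_area_cm2 == 0.0

    def test_conservation_exact(self, small_image, small_truth):
        res = md.segment(small_image, small_truth.mask)
        assert res.dense_px + res.lucent_px == res.breast_px

    def test_scale_equivariance(self, small_image, small_truth):
        """Doubling the pixel spacing quadruples areas, leaves PD unchanged."""
        r1 = md.segment(small_image, small_truth.mask)
        img2 = md.MammogramImage(small_image.pixels, small_image.pixel_spacing_cm * 2)
        r2 = md.segment(img2, small_truth.mask)
        assert r2.breast_area_cm2 == pytest.approx(4 * r1.breast_area_cm2)
        assert r2.dense_area_cm2 == pytest.approx(4 * r1.dense_area_cm2)
        assert r2.overall_pd == pytest.approx(r1.overall_pd)

    def test_dense_outside_mask_rejected(self):
        mask = np.zeros((4, 4), bool)
        mask[0, 0] = True
        dense = np.zeros_like(mask)
        dense[1, 1] = True
        with pytest.raises(ValueError):
            md.area_metrics(dense, mask, 0.1)

    def test_pd_recovery_within_3pp(self):
        p = md.SyntheticParams(target_pd=40.0, noise_sd=5.0)
        mask = md.generate_breast_mask(p)
        gt = md.generate_density_field(mask, 40.0, p.corr_length, p.anterior_weight, 7)
        img = md.render_mammogram(gt, p, 8)
        res = md.segment(img, mask)
        assert abs(res.overall_pd - gt.true_overall_pd) < 3.0


def test_to_uint8_rescales_16bit():
    rng = np.random.default_rng(1)
    deep = rng.integers(0, 4096, (30, 30)).astype(np.uint16)
    mask = np.ones((30, 30), bool)
    out = md.to_uint8(deep, mask)
    assert out.dtype == np.uint8 and out.min() == 0 and out.max() == 255
    # monotone: ordering of pixel values preserved
    flat_in, flat_out = deep.ravel(), out.ravel()
    order = np.argsort(flat_in)
    assert (np.diff(flat_out[order].astype(int)) >= 0).all()
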