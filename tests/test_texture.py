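"""Texture stage: Otsu, segmentation, quantization, GLCM and features."""

import numpy as np
import pytest
from scipy import ndimage

from cardiot1tex.core import T1Map, polar_grid
from cardiot1tex.phantom import HotspotSpec, PhantomConfig, generate_t1_slice
from cardiot1tex.texture import (
    GLCM,
    compute_glcm,
    glcm_features,
    normalize_intensities,
    otsu_threshold,
    segment_myocardium,
)
from oracles import glcm_bruteforce, otsu_bruteforce


class TestOtsu:
    def test_two_value_input_separates(self):
        vals = np.array([100.0] * 7 + [200.0] * 3)
        t = otsu_threshold(vals)
        assert 100.0 < t < 200.0

    def test_matches_exhaustive_search(self, rng):
        for _ in range(30):
            vals = rng.integers(0, 12, size=rng.integers(10, 60)).astype(float)
            if np.unique(vals).size < 2:
                continue
            t = otsu_threshold(vals)
            (lo, hi), _ = otsu_bruteforce(vals)
            assert lo < t <= hi  # same induced partition as the brute force

    def test_bimodal_misclassification_below_one_percent(self, rng):
        n = 10_000
        a = rng.normal(950.0, 30.0, n)
        b = rng.normal(1400.0, 30.0, n)
        t = otsu_threshold(np.concatenate([a, b]))
        mis = (a > t).sum() + (b <= t).sum()
        assert mis / (2 * n) < 0.01

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            otsu_threshold([5.0, 5.0, 5.0])


class TestSegmentation:
    def test_noiseless_phantom_exact_mask(self, noiseless_config):
        m = generate_t1_slice(noiseless_config, [], "mid", seed=0)
        got = segment_myocardium(m)
        r, _ = polar_grid(m.pixels.shape, noiseless_config.center_rc)
        annulus = (r >= noiseless_config.endo_radius) & (r < noiseless_config.epi_radius)
        blood = r < noiseless_config.endo_radius
        expected = annulus & ndimage.binary_erosion(ndimage.binary_fill_holes(annulus))
        np.testing.assert_array_equal(got.mask, expected)
        assert not (got.mask & blood).any()

    def test_dice_above_095_under_noise(self):
        cfg = PhantomConfig(noise_sd=20.0)
        m = generate_t1_slice(cfg, [], "mid", seed=5)
        got = segment_myocardium(m).mask
        r, _ = polar_grid(m.pixels.shape, cfg.center_rc)
        annulus = (r >= cfg.endo_radius) & (r < cfg.epi_radius)
        dice = 2.0 * (got & annulus).sum() / (got.sum() + annulus.sum())
        assert dice > 0.95

    def test_no_annulus_raises(self):
        flat = T1Map(pixels=np.full((32, 32), 0.0))
        flat.pixels[10:20, 10:20] = 1000.0  # solid block, no enclosed blood pool
        with pytest.raises(ValueError):
            segment_myocardium(flat)


class TestNormalization:
    def test_endpoints_map_to_0_and_255(self, default_config):
        m = generate_t1_slice(default_config, [], "mid", seed=2)
        mask = segment_myocardium(m)
        q = normalize_intensities(m, mask)
        lv = q.levels[q.mask]
        assert lv.min() == 0 and lv.max() == 255

    def test_affine_invariance(self, default_config):
        m = generate_t1_slice(default_config, [], "mid", seed=2)
        mask = segment_myocardium(m).mask
        q1 = normalize_intensities(m, mask)
        m2 = T1Map(pixels=2.0 * m.pixels + 100.0)
        q2 = normalize_intensities(m2, mask)
        np.testing.assert_array_equal(q1.levels[mask], q2.levels[mask])

    def test_worked_three_value_example(self):
        px = np.array([[1000.0, 1128.0, 1255.0]])
        q = normalize_intensities(T1Map(pixels=px), np.ones((1, 3), bool))
        assert q.levels.tolist() == [[0, 128, 255]]

    def test_constant_region_flagged_degenerate(self):
        px = np.full((4, 4), 1000.0)
        q = normalize_intensities(T1Map(pixels=px), np.ones((4, 4), bool))
        assert q.degenerate
        assert (q.levels == 0).all()


def tiny_quantized(levels, mask=None, n_levels=4):
    from cardiot1tex.texture import QuantizedImage

    levels = np.asarray(levels, dtype=np.int32)
    if mask is None:
        mask = np.ones(levels.shape, bool)
    return QuantizedImage(levels=levels, mask=np.asarray(mask, bool), n_levels=n_levels)


class TestGLCM:
    def test_worked_2x2_example(self):
        q = tiny_quantized([[0, 0], [0, 1]], n_levels=2)
        g = compute_glcm(q, offsets=((0, 1),), symmetric=True)
        assert g.P[0, 0] == pytest.approx(0.5)
        assert g.P[0, 1] == pytest.approx(0.25)
        assert g.P[1, 0] == pytest.approx(0.25)
        assert g.n_pairs == 4

    def test_constant_image_single_entry(self):
        q = tiny_quantized(np.zeros((3, 3), int), n_levels=4)
        g = compute_glcm(q)
        assert g.P[0, 0] == pytest.approx(1.0)
        assert (g.P[1:, :] == 0).all() and (g.P[:, 1:] == 0).all()

    def test_matches_bruteforce_enumeration(self, rng):
        offsets = ((0, 1), (1, 0), (1, 1), (1, -1))
        for _ in range(20):
            shape = (int(rng.integers(2, 9)), int(rng.integers(2, 9)))
            levels = rng.integers(0, 4, size=shape)
            mask = rng.random(shape) > 0.3
            q = tiny_quantized(levels, mask)
            try:
                g = compute_glcm(q, offsets=offsets, symmetric=True)
            except ValueError:
                continue
            P, n = glcm_bruteforce(levels, mask, offsets, True, 4)
            np.testing.assert_allclose(g.P, P, atol=1e-12)
            assert g.n_pairs == n

    def test_symmetric_matrix_is_symmetric(self, rng):
        levels = rng.integers(0, 4, size=(8, 8))
        g = compute_glcm(tiny_quantized(levels), symmetric=True)
        np.testing.assert_array_equal(g.P, g.P.T)
        assert g.P.sum() == pytest.approx(1.0, abs=1e-12)

    def test_out_of_mask_pairs_skipped(self):
        levels = np.array([[0, 3], [3, 0]])
        mask = np.array([[True, False], [False, True]])
        with pytest.raises(ValueError):
            compute_glcm(tiny_quantized(levels, mask), offsets=((0, 1),))


class TestFeatures:
    def test_worked_2x2_example_features(self):
        q = tiny_quantized([[0, 0], [0, 1]], n_levels=2)
        f = glcm_features(compute_glcm(q, offsets=((0, 1),), symmetric=True))
        assert f.energy == pytest.approx(0.375)
        assert f.entropy == pytest.approx(1.5)
        assert f.contrast == pytest.approx(0.5)
        assert f.homogeneity == pytest.approx(0.75)
        assert f.dissimilarity == pytest.approx(0.5)

    def test_constant_image_limits(self):
        q = tiny_quantized(np.zeros((4, 4), int), n_levels=256)
        f = glcm_features(compute_glcm(q))
        assert f.energy == pytest.approx(1.0)
        assert f.entropy == pytest.approx(0.0)
        assert f.contrast == pytest.approx(0.0)
        assert f.homogeneity == pytest.approx(1.0)
        assert f.variance == pytest.approx(0.0)
        assert f.dissimilarity == pytest.approx(0.0)
        assert np.isnan(f.correlation)  # single level: correlation undefined

    def test_uniform_glcm_maximum_entropy(self):
        P = np.full((256, 256), 1.0 / 256**2)
        g = GLCM(P=P, offsets=((0, 1),), symmetric=True, n_pairs=1)
        f = glcm_features(g)
        assert f.entropy == pytest.approx(16.0)
        assert f.energy == pytest.approx(256.0**-2)

    def test_clumped_image_has_higher_energy_lower_entropy(self):
        # same histogram (half 0s, half 1s), different spatial arrangement
        block = np.zeros((16, 16), int)
        block[:, 8:] = 1
        checker = np.indices((16, 16)).sum(axis=0) % 2
        f_block = glcm_features(compute_glcm(tiny_quantized(block, n_levels=2)))
        f_checker = glcm_features(compute_glcm(tiny_quantized(checker, n_levels=2)))
        assert f_block.energy > f_checker.energy
        assert f_block.entropy < f_checker.entropy

    def test_agrees_with_skimage_on_full_frame(self, rng):
        # independent cross-check against scikit-image on unmasked images
        from skimage.feature import graycomatrix, graycoprops

        img = rng.integers(0, 8, size=(12, 12)).astype(np.uint8)
        q = tiny_quantized(img, n_levels=8)
        g = compute_glcm(q, offsets=((0, 1),), symmetric=True)
        sk = graycomatrix(img, [1], [0], levels=8, symmetric=True, normed=True)
        np.testing.assert_allclose(g.P, sk[:, :, 0, 0], atol=1e-12)
        f = glcm_features(g)
        assert f.contrast == pytest.approx(
            float(graycoprops(sk, "contrast")[0, 0]), abs=1e-10
        )
        # skimage's "homogeneity" is the 1/(1+(i-j)^2) kernel — our "squared" variant
        f_sq = glcm_features(g, homogeneity_variant="squared")
        assert f_sq.homogeneity == pytest.approx(
            float(graycoprops(sk, "homogeneity")[0, 0]), abs=1e-10
        )
        assert f.energy == pytest.approx(
            float(graycoprops(sk, "ASM")[0, 0]), abs=1e-10
        )

    def test_rejection_phantoms_more_heterogeneous(self):
        """Lesion-bearing maps: higher entropy/variance, lower energy."""
        normal_cfg = PhantomConfig(noise_correlation_px=2.0)
        hits = 0
        n = 25
        rng = np.random.default_rng(8)
        for k in range(n):
            diffuse = HotspotSpec(0.0, 360.0, 1.0, 60.0, 0.0, 0.95)
            focal = HotspotSpec(
                270.0, rng.uniform(90, 120), 1.0, rng.uniform(100, 180),
                rng.uniform(30, 50), rng.uniform(0.5, 0.8),
            )
            m0 = generate_t1_slice(normal_cfg, [], "mid", seed=1000 + k)
            m1 = generate_t1_slice(normal_cfg, [diffuse, focal], "mid", seed=2000 + k)
            fs = []
            for m in (m0, m1):
                q = normalize_intensities(m, segment_myocardium(m))
                fs.append(glcm_features(compute_glcm(q)))
            ok = (
                fs[1].entropy > fs[0].entropy
                and fs[1].variance > fs[0].variance
                and fs[1].energy < fs[0].energy
            )
            hits += ok
        assert hits >= int(0.9 * n)
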