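"""Segmental T1 protocol: ROI construction, middle third, metrics, ICC."""

import numpy as np
import pytest

from cardiot1tex.core import NormalRange, polar_grid
from cardiot1tex.phantom import HotspotSpec, PhantomConfig, generate_t1_slice, generate_t1_study
from cardiot1tex.segmental import (
    SegmentROI,
    build_segment_masks,
    build_study_masks,
    extract_middle_third,
    interobserver_icc,
    segmental_t1,
)
from oracles import icc2_closed_form


class TestSegmentMasks:
    def test_sixteen_rois_per_eight_slice_study(self, noiseless_rois):
        assert len(noiseless_rois) == 16
        # 3 ROIs on each basal/mid slice, 2 on each apical slice
        per_slice = {}
        for roi in noiseless_rois:
            per_slice.setdefault(roi.slice_index, []).append(roi.segment_id)
        assert sorted(len(v) for v in per_slice.values()) == [2, 2, 3, 3, 3, 3]

    def test_anterior_and_inferior_sectors_never_sampled(self, noiseless_study, noiseless_config):
        cfg = noiseless_config
        shape = (cfg.image_size, cfg.image_size)
        _, theta = polar_grid(shape, cfg.center_rc)
        d_ant = np.abs((theta - 0.0 + 180.0) % 360.0 - 180.0)
        d_inf = np.abs((theta - 180.0 + 180.0) % 360.0 - 180.0)
        forbidden = (d_ant <= 30.0) | (d_inf <= 30.0)
        for m in noiseless_study.analysis_maps:
            for roi in build_segment_masks(m, cfg):
                assert not (roi.mask & forbidden).any()

    def test_rois_on_one_slice_are_disjoint(self, noiseless_study, noiseless_config):
        for m in noiseless_study.analysis_maps:
            rois = build_segment_masks(m, noiseless_config)
            for i in range(len(rois)):
                for j in range(i + 1, len(rois)):
                    assert not (rois[i].mask & rois[j].mask).any()

    def test_excluded_slice_rejected(self, noiseless_study, noiseless_config):
        excluded = noiseless_study.maps[0]
        assert excluded.slice_level == "excluded"
        with pytest.raises(ValueError):
            build_segment_masks(excluded, noiseless_config)


class TestMiddleThird:
    def test_retained_radii_match_definition(self):
        # annulus endo=20, epi=32 -> middle third keeps radii in [24, 28)
        cfg = PhantomConfig(endo_radius=20.0, epi_radius=32.0, noise_sd=0.0)
        m = generate_t1_slice(cfg, [], "mid", seed=0)
        roi = build_segment_masks(m, cfg)[0]
        mid = extract_middle_third(roi, 20.0, 32.0, cfg.center_rc)
        r, _ = polar_grid(mid.mask.shape, cfg.center_rc)
        assert np.all(r[mid.mask] >= 24.0)
        assert np.all(r[mid.mask] < 28.0)
        assert np.all(mid.mask <= roi.mask)  # subset of the input

    def test_idempotent_on_already_restricted_mask(self):
        cfg = PhantomConfig(endo_radius=20.0, epi_radius=32.0, noise_sd=0.0)
        m = generate_t1_slice(cfg, [], "mid", seed=0)
        roi = build_segment_masks(m, cfg)[0]
        once = extract_middle_third(roi, 20.0, 32.0, cfg.center_rc)
        twice = extract_middle_third(once, 20.0, 32.0, cfg.center_rc)
        np.testing.assert_array_equal(once.mask, twice.mask)

    def test_area_is_one_third_at_fine_resolution(self):
        cfg = PhantomConfig(
            image_size=512, endo_radius=90.0, epi_radius=180.0, noise_sd=0.0
        )
        m = generate_t1_slice(cfg, [], "mid", seed=0)
        roi = build_segment_masks(m, cfg)[0]  # full-wall 60-degree wedge
        mid = extract_middle_third(roi, 90.0, 180.0, cfg.center_rc)
        # the middle radial third of an annulus holds exactly 1/3 of its area
        # ((2e+w)/3 over (2e+w)); pixelization adds a small discretization error
        expected = roi.mask.sum() / 3.0
        assert mid.mask.sum() == pytest.approx(expected, rel=0.10)

    def test_too_thin_wall_raises(self):
        cfg = PhantomConfig(image_size=32, endo_radius=5.0, epi_radius=7.0, noise_sd=0.0)
        m = generate_t1_slice(cfg, [], "mid", seed=0)
        roi = build_segment_masks(m, cfg)[0]
        # a 2-px wall has an (often) empty 0.67-px middle band
        sub = SegmentROI(roi.segment_id, roi.slice_index, roi.mask)
        try:
            out = extract_middle_third(sub, 5.0, 7.0, cfg.center_rc)
        except ValueError:
            return
        assert out.mask.sum() < roi.mask.sum()


class TestSegmentalT1:
    def test_noiseless_uniform_phantom_exact(self, noiseless_study, noiseless_rois, normal_range):
        res = segmental_t1(noiseless_study, noiseless_rois, normal_range)
        assert set(res.segmental_means.values()) == {1000.0}
        assert res.global_mean_t1 == 1000.0
        assert res.peak_t1 == 1000.0
        assert res.n_abnormal == 0

    def test_single_elevated_segment_arithmetic(self, noiseless_config, normal_range):
        # elevate the full septum on one basal slice only; check one segment at 1150
        hot = HotspotSpec(center_angle=300.0, angular_width=60.0, delta_t1=150.0)
        hotspots = [[] for _ in range(8)]
        hotspots[1] = [hot]  # first basal slice
        study = generate_t1_study(noiseless_config, hotspots, seed=0)
        rois = build_study_masks(study, noiseless_config)
        res = segmental_t1(study, rois, normal_range)
        values = sorted(res.segmental_means.values())
        assert values[:15] == [1000.0] * 15
        assert values[15] == pytest.approx(1150.0)
        assert res.peak_t1 == pytest.approx(1150.0)
        assert res.global_mean_t1 == pytest.approx((15 * 1000.0 + 1150.0) / 16)  # 1009.375
        assert res.n_abnormal == 1  # 1150 > 1050

    def test_boundary_value_not_abnormal(self, noiseless_config):
        # abnormality is strict: a segment at exactly the upper bound is normal
        hot = HotspotSpec(center_angle=300.0, angular_width=60.0, delta_t1=50.0)
        hotspots = [[hot] for _ in range(8)]
        study = generate_t1_study(noiseless_config, hotspots, seed=0)
        rois = build_study_masks(study, noiseless_config)
        res = segmental_t1(study, rois, NormalRange(900.0, 1050.0))
        assert res.peak_t1 == pytest.approx(1050.0)
        assert res.n_abnormal == 0

    def test_peak_at_least_mean_and_shift_invariance(self, default_config, normal_range):
        study = generate_t1_study(default_config, seed=11)
        rois = build_study_masks(study, default_config)
        res = segmental_t1(study, rois, normal_range)
        assert res.peak_t1 >= res.global_mean_t1

        shifted = generate_t1_study(default_config, seed=11)
        for m in shifted.maps:
            m.pixels = m.pixels + 37.0
        res2 = segmental_t1(shifted, rois, normal_range)
        assert res2.global_mean_t1 == pytest.approx(res.global_mean_t1 + 37.0, abs=1e-9)
        assert res2.peak_t1 == pytest.approx(res.peak_t1 + 37.0, abs=1e-9)
        for k in res.segmental_means:
            assert res2.segmental_means[k] == pytest.approx(
                res.segmental_means[k] + 37.0, abs=1e-9
            )

    def test_roi_order_irrelevant(self, noiseless_study, noiseless_rois, normal_range):
        res = segmental_t1(noiseless_study, noiseless_rois, normal_range)
        res_rev = segmental_t1(noiseless_study, noiseless_rois[::-1], normal_range)
        assert res.global_mean_t1 == res_rev.global_mean_t1
        assert res.peak_t1 == res_rev.peak_t1

    def test_wrong_roi_count_rejected(self, noiseless_study, noiseless_rois):
        with pytest.raises(ValueError, match="16"):
            segmental_t1(noiseless_study, noiseless_rois[:10])


class TestICC:
    def test_identical_readers_give_one(self, rng):
        x = 1000.0 + rng.normal(0, 30, size=20)
        res = interobserver_icc(x, x.copy())
        assert res.icc == pytest.approx(1.0, abs=1e-9)

    def test_independent_readers_near_zero(self, rng):
        x = rng.normal(1000, 30, size=200)
        y = rng.normal(1000, 30, size=200)
        res = interobserver_icc(x, y)
        assert abs(res.icc) < 0.15

    def test_constant_offset_lowers_agreement_monotonically(self, rng):
        x = rng.normal(1000, 30, size=50)
        iccs = [interobserver_icc(x, x + c).icc for c in (0.0, 20.0, 60.0)]
        assert iccs[0] > iccs[1] > iccs[2]
        assert iccs[1] < 1.0

    def test_matches_closed_form_anova(self, rng):
        x = rng.normal(1000, 30, size=40)
        y = x + rng.normal(5, 15, size=40)
        res = interobserver_icc(x, y)
        assert res.icc == pytest.approx(icc2_closed_form(x, y), abs=1e-9)

    def test_double_constant_input_rejected(self):
        with pytest.raises(ValueError):
            interobserver_icc([1.0] * 5, [1.0] * 5)
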