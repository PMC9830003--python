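"""Tests of the synthetic cohort generator and its forward models."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cario import synth
from cario.dehydration import analyze_stack, roi_mean_curve


class TestPermeability:
    def test_zero_tsl_returns_baseline(self):
        assert synth.permeability_from_tsl(0.0, 1.0) == 1.0

    def test_arrest_regime_at_70_um(self):
        assert synth.permeability_from_tsl(70.0, 1.0) <= 0.05 + 1e-12

    @settings(deadline=None, max_examples=100)
    @given(tsl=st.floats(0, 300), delta=st.floats(0, 50))
    def test_monotone_nonincreasing_and_positive(self, tsl, delta):
        a = synth.permeability_from_tsl(tsl)
        b = synth.permeability_from_tsl(tsl + delta)
        assert a >= b > 0

    def test_negative_tsl_rejected(self):
        with pytest.raises(ValueError):
            synth.permeability_from_tsl(-1.0)


class TestSampleCohort:
    def test_seed_determinism(self):
        cfg = synth.CohortConfig(n_lesions=5, seed=7)
        assert synth.sample_cohort(cfg) == synth.sample_cohort(cfg)

    def test_tsl_range_coverage(self):
        cfg = synth.CohortConfig(n_lesions=100, seed=11, tsl_range_um=(0, 100))
        tsl = [t.tsl_thickness_um for t in synth.sample_cohort(cfg)]
        assert min(tsl) < 20 and max(tsl) > 80

    def test_single_lesion_invariants(self):
        (truth,) = synth.sample_cohort(synth.CohortConfig(n_lesions=1, seed=3))
        assert 0 <= truth.mineral_loss_frac <= 1
        assert 0 <= truth.water_pool_frac <= 1
        assert truth.lesion_depth_um >= truth.tsl_thickness_um
        assert truth.permeability == synth.permeability_from_tsl(truth.tsl_thickness_um)

    def test_water_pooling_only_on_occlusal_and_incisal(self):
        cohort = synth.sample_cohort(synth.CohortConfig(n_lesions=200, seed=5))
        for t in cohort:
            if t.surface_type == "smooth":
                assert t.water_pool_frac == 0.0
        pooled = [t for t in cohort if t.surface_type != "smooth"]
        assert any(t.water_pool_frac > 0 for t in pooled)

    def test_sl_positively_linked_to_tsl(self):
        cohort = synth.sample_cohort(synth.CohortConfig(n_lesions=300, seed=2))
        tsl = np.array([t.tsl_thickness_um for t in cohort])
        sl = np.array([t.sl_thickness_um for t in cohort])
        assert np.corrcoef(tsl, sl)[0, 1] > 0.2

    def test_empty_range_rejected(self):
        with pytest.raises(ValueError):
            synth.CohortConfig(tsl_range_um=(50, 10))


class TestSwirRendering:
    def test_null_lesion_matches_control(self, sound_truth, noise_free_config):
        stack, rois = synth.render_swir_stack(sound_truth, noise_free_config)
        lesion = roi_mean_curve(stack, rois.lesion_mask)
        control = roi_mean_curve(stack, rois.control_mask)
        assert np.allclose(lesion, control, atol=1e-9)

    def test_noise_free_curve_nondecreasing(self, mid_lesion, noise_free_config):
        stack, rois = synth.render_swir_stack(mid_lesion, noise_free_config)
        curve = roi_mean_curve(stack, rois.lesion_mask)
        assert np.all(np.diff(curve) >= -1e-12)
        assert curve.argmin() == 0  # frame 0 is the curve minimum

    def test_high_permeability_reaches_plateau_earlier(self, mid_lesion, noise_free_config):
        fast = dataclasses.replace(mid_lesion, tsl_thickness_um=0.0, permeability=1.0)
        slow = dataclasses.replace(
            mid_lesion, tsl_thickness_um=60.0, permeability=synth.permeability_from_tsl(60.0)
        )

        def time_to_90pct(truth):
            stack, rois = synth.render_swir_stack(truth, noise_free_config)
            curve = roi_mean_curve(stack, rois.lesion_mask)
            span = curve - curve[0]
            target = 0.9 * span[-1]
            return int(np.argmax(span >= target))

        assert time_to_90pct(fast) < time_to_90pct(slow)

    def test_control_amplitude_small_relative_to_active_lesion(self, noise_free_config):
        active = synth.LesionTruth(
            lesion_depth_um=200,
            tsl_thickness_um=0,
            mineral_loss_frac=0.35,
            permeability=1.0,
            surface_type="smooth",
            has_composite=False,
            water_pool_frac=0.0,
        )
        stack, rois = synth.render_swir_stack(
            active, noise_free_config, rng=np.random.default_rng(0)
        )
        lesion = roi_mean_curve(stack, rois.lesion_mask)
        control = roi_mean_curve(stack, rois.control_mask)
        assert np.ptp(control) <= 0.10 * np.ptp(lesion)

    def test_composite_region_outside_both_rois(self, mid_lesion, noise_free_config):
        truth = dataclasses.replace(mid_lesion, has_composite=True)
        stack, rois = synth.render_swir_stack(truth, noise_free_config)
        composite_px = np.isclose(stack.frames[0], synth.SWIR_COMPOSITE)
        assert not (composite_px & rois.lesion_mask).any()
        assert not (composite_px & rois.control_mask).any()
        assert composite_px.any()


class TestThermalRendering:
    def test_arrested_dry_lesion_flat_at_ambient(self, noise_free_config):
        truth = synth.LesionTruth(
            lesion_depth_um=200,
            tsl_thickness_um=300,
            mineral_loss_frac=0.3,
            permeability=1e-6,
            surface_type="smooth",
            has_composite=False,
            water_pool_frac=0.0,
        )
        stack, rois = synth.render_thermal_stack(
            truth, noise_free_config, rng=np.random.default_rng(1)
        )
        curve = roi_mean_curve(stack, rois.lesion_mask)
        assert np.max(np.abs(curve - synth.AMBIENT_K)) < 0.2

    def test_drop_then_recover_shape(self, mid_lesion, noise_free_config):
        stack, rois = synth.render_thermal_stack(mid_lesion, noise_free_config)
        curve = roi_mean_curve(stack, rois.lesion_mask)
        t_min = int(curve.argmin())
        assert t_min > 0
        assert curve[-1] > curve[t_min]
        assert abs(curve[0] - synth.AMBIENT_K) < 0.05

    def test_water_pooling_deepens_the_drop(self, noise_free_config):
        base = synth.LesionTruth(
            lesion_depth_um=200,
            tsl_thickness_um=20,
            mineral_loss_frac=0.2,
            permeability=synth.permeability_from_tsl(20.0),
            surface_type="occlusal",
            has_composite=False,
            water_pool_frac=0.0,
        )
        pooled = dataclasses.replace(base, water_pool_frac=1.0)
        rng = lambda: np.random.default_rng(2)
        s0, rois = synth.render_thermal_stack(base, noise_free_config, rng=rng())
        s1, _ = synth.render_thermal_stack(pooled, noise_free_config, rng=rng())
        drop0 = synth.AMBIENT_K - roi_mean_curve(s0, rois.lesion_mask).min()
        drop1 = synth.AMBIENT_K - roi_mean_curve(s1, rois.lesion_mask).min()
        assert drop1 > drop0

    def test_control_drop_smaller_than_lesion(self, mid_lesion, noise_free_config):
        stack, rois = synth.render_thermal_stack(mid_lesion, noise_free_config)
        lesion_drop = synth.AMBIENT_K - roi_mean_curve(stack, rois.lesion_mask).min()
        control_drop = synth.AMBIENT_K - roi_mean_curve(stack, rois.control_mask).min()
        assert control_drop < lesion_drop


class TestOctRendering:
    def test_zero_tsl_band_starts_at_surface(self, mid_lesion):
        truth = dataclasses.replace(mid_lesion, tsl_thickness_um=0.0)
        img = synth.render_oct_bscan(truth, 5.0, 0.0)
        col = (synth.oct_lesion_cols(img.shape[1]).start + 5)
        body_rows = np.flatnonzero(img[:, col] > 0.4 * synth.OCT_BODY_MAX)
        # surface Fresnel peak, then the body immediately below it
        assert body_rows.min() == synth.OCT_SURFACE_ROW
        assert body_rows[1] == synth.OCT_SURFACE_ROW + 1

    def test_band_geometry_in_optical_units(self, mid_lesion):
        truth = dataclasses.replace(mid_lesion, lesion_depth_um=100.0, tsl_thickness_um=0.0)
        img = synth.render_oct_bscan(truth, 5.0, 0.0)
        col = (synth.oct_lesion_cols(img.shape[1]).start + 5)
        body = np.flatnonzero(
            (img[:, col] > 0.4 * synth.OCT_BODY_MAX)
            & (np.arange(img.shape[0]) > synth.OCT_SURFACE_ROW)
        )
        # 100 um tissue x 1.6 / 5 um optical pitch = 32 rows below the surface
        assert body.size == 32
        assert body.max() == synth.OCT_SURFACE_ROW + 32

    def test_body_reflectivity_saturates_with_mineral_loss(self, mid_lesion):
        a = dataclasses.replace(mid_lesion, mineral_loss_frac=0.15)
        b = dataclasses.replace(mid_lesion, mineral_loss_frac=0.30)
        img_a = synth.render_oct_bscan(a, 5.0, 0.0)
        img_b = synth.render_oct_bscan(b, 5.0, 0.0)
        assert np.array_equal(img_a, img_b)

    def test_sound_columns_show_only_surface_and_attenuation(self, mid_lesion):
        img = synth.render_oct_bscan(mid_lesion, 5.0, 0.0)
        sound_col = 2  # outside the lesion columns
        profile = img[:, sound_col]
        assert profile.argmax() == synth.OCT_SURFACE_ROW
        below = profile[synth.OCT_SURFACE_ROW + 1 :]
        assert np.all(np.diff(below) <= 1e-12)  # pure attenuation


class TestMicroctRendering:
    def test_sound_slice_flat(self, sound_truth):
        img = synth.render_microct_slice(sound_truth, 10.0, noise_sd=0.0)
        tissue = img[synth.CT_SURFACE_ROW :]
        assert np.all(tissue == synth.CT_SOUND)

    def test_surface_layer_pixel_count(self, mid_lesion):
        img = synth.render_microct_slice(mid_lesion, 10.0, sl_thickness_um=70.0, noise_sd=0.0)
        col = synth.microct_lesion_cols(img.shape[1]).start + 5
        sl_rows = np.flatnonzero(img[:, col] == synth.CT_SL)
        assert sl_rows.size == 7

    def test_gray_value_ordering(self, mid_lesion):
        img = synth.render_microct_slice(mid_lesion, 10.0, noise_sd=0.0)
        col = synth.microct_lesion_cols(img.shape[1]).start + 5
        profile = img[:, col]
        body = profile[(profile > synth.CT_AIR) & (profile < synth.CT_SOUND)]
        assert body.size > 0
        assert body.max() < synth.CT_SOUND < synth.CT_SL


class TestDeterminismAndMonotonicity:
    def test_renders_bit_identical_for_same_seed(self, mid_lesion):
        cfg = synth.CohortConfig(n_lesions=1, seed=13, image_shape=(64, 64), frame_count=20)
        a, _ = synth.render_swir_stack(mid_lesion, cfg)
        b, _ = synth.render_swir_stack(mid_lesion, cfg)
        assert np.array_equal(a.frames, b.frames)

    def test_thicker_tsl_gives_smaller_contrasts(self, noise_free_config):
        def contrasts(tsl):
            truth = synth.LesionTruth(
                lesion_depth_um=250,
                tsl_thickness_um=tsl,
                mineral_loss_frac=0.25,
                permeability=synth.permeability_from_tsl(tsl),
                surface_type="smooth",
                has_composite=False,
                water_pool_frac=0.0,
            )
            s, rois = synth.render_swir_stack(truth, noise_free_config, rng=np.random.default_rng(3))
            t, _ = synth.render_thermal_stack(truth, noise_free_config, rng=np.random.default_rng(4))
            return analyze_stack(s, rois).diff, analyze_stack(t, rois).diff

        results = [contrasts(tsl) for tsl in (0.0, 20.0, 45.0, 69.0)]
        di = [r[0] for r in results]
        dq = [r[1] for r in results]
        assert di == sorted(di, reverse=True)
        assert dq == sorted(dq, reverse=True)
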