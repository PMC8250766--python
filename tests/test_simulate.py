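import math
import warnings

import numpy as np
import pytest
from hypothesis import given, settings, strategies as stn

import chromodyn as cd
from chromodyn.simulate import _ellipse_coverage


class TestAreaProfile:
    @pytest.mark.parametrize(
        "t,expected",
        [(-100.0, 100.0),  # pre-onset baseline
         (150.0, 268.0),   # peak: 100 x (1 + 168/100)
         (100.0, 184.0),   # mid-rise of the linear ramp
         (350.0, 100.0),   # fully returned
         (250.0, 184.0)],  # mid-return
    )
    def test_piecewise_linear_trajectory(self, expansion_spec, t, expected):
        assert cd.area_profile(expansion_spec, t) == pytest.approx(expected)

    def test_non_responder_is_constant(self, expansion_spec):
        import dataclasses
        spec = dataclasses.replace(expansion_spec, responds=False)
        t = np.linspace(-500, 500, 101)
        assert np.all(cd.area_profile(spec, t) == 100.0)

    def test_retraction_mirrors_expansion_after_normalization(self):
        kw = dict(organ_id=0, center=(0, 0), aspect_ratio=1.0,
                  baseline_area=200.0, magnitude_pct=43.0, onset_ms=40.0,
                  rise_ms=90.0, return_ms=180.0)
        up = cd.ChromatophoreSpec(direction="expansion", **kw)
        down = cd.ChromatophoreSpec(direction="retraction", **kw)
        t = np.linspace(-100, 500, 200)
        rel_up = cd.area_profile(up, t) / 200.0 - 1.0
        rel_down = cd.area_profile(down, t) / 200.0 - 1.0
        assert np.allclose(rel_up, -rel_down)

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(
        mag=stn.floats(5, 300),
        onset=stn.floats(0, 100),
        rise=stn.floats(1, 200),
        ret=stn.floats(1, 400),
        t=stn.floats(-1000, 2000),
    )
    def test_profile_bounded_by_baseline_and_peak(self, mag, onset, rise, ret, t):
        spec = cd.ChromatophoreSpec(
            organ_id=0, center=(0, 0), aspect_ratio=1.0, baseline_area=100.0,
            direction="expansion", magnitude_pct=mag, onset_ms=onset,
            rise_ms=rise, return_ms=ret)
        a = cd.area_profile(spec, t)
        assert 100.0 - 1e-9 <= a <= spec.peak_area + 1e-9
        if t <= onset or t >= onset + rise + ret:
            assert a == pytest.approx(100.0)

    def test_invalid_specs_rejected(self):
        kw = dict(organ_id=0, center=(0, 0), aspect_ratio=1.0,
                  onset_ms=10, rise_ms=50, return_ms=50)
        with pytest.raises(cd.ChromodynError):
            cd.ChromatophoreSpec(baseline_area=0, direction="expansion",
                                 magnitude_pct=50, **kw)
        with pytest.raises(cd.ChromodynError):
            cd.ChromatophoreSpec(baseline_area=10, direction="retraction",
                                 magnitude_pct=120, **kw)


class TestSampleSpecs:
    def test_zero_density_empty(self):
        cfg = cd.SimConfig(organ_density=0.0)
        assert cd.sample_specs(cfg) == []

    def test_count_is_density_times_area(self):
        # 200x200 px at 5 um/px = 1 mm^2; density 8 -> 8 organs
        cfg = cd.SimConfig(image_size=(200, 200), mm_per_pixel=0.005,
                           organ_density=8.0,
                           diameter_range_um=(60.0, 150.0), seed=3)
        specs = cd.sample_specs(cfg)
        assert len(specs) == 8

    def test_footprints_inside_frame(self):
        cfg = cd.SimConfig(image_size=(200, 200), mm_per_pixel=0.005,
                           organ_density=8.0,
                           diameter_range_um=(60.0, 150.0), seed=4)
        h, w = cfg.image_size
        for s in cd.sample_specs(cfg):
            a = max(s.semi_axes(max(s.peak_area, s.baseline_area)))
            assert a <= s.center[0] <= w - 1 - a
            assert a <= s.center[1] <= h - 1 - a

    def test_field_too_small_raises(self):
        cfg = cd.SimConfig(image_size=(40, 40), mm_per_pixel=0.01,
                           organ_density=200.0, seed=0)
        with pytest.raises(cd.ChromodynError, match="too small"):
            cd.sample_specs(cfg)

    def test_deterministic_given_seed(self):
        cfg = cd.SimConfig(image_size=(200, 200), mm_per_pixel=0.005,
                           organ_density=6.0,
                           diameter_range_um=(60.0, 150.0), seed=9)
        a = cd.sample_specs(cfg)
        b = cd.sample_specs(cfg)
        assert [s.center for s in a] == [s.center for s in b]
        assert [s.magnitude_pct for s in a] == [s.magnitude_pct for s in b]


class TestEllipseCoverage:
    @pytest.mark.parametrize("a,b,theta", [(10, 10, 0), (15, 8, 0.7),
                                           (6, 4, 2.0)])
    def test_total_coverage_matches_analytic_area(self, a, b, theta):
        y0, x0, cov = _ellipse_coverage((120, 120), 60, 60, a, b, theta)
        assert cov.sum() == pytest.approx(math.pi * a * b, rel=0.01)


class TestRenderTrial:
    def test_zero_organs_background_only(self):
        cfg = cd.SimConfig(image_size=(64, 64), organ_density=0.0,
                           noise_sd=0.0, pre_flash_frames=3,
                           post_flash_frames=3, seed=0)
        stack, gt = cd.render_trial(cfg, [])
        assert stack.shape == (8, 64, 64)
        assert gt.specs == [] and gt.areas.shape == (0, 8)
        non_flash = [k for k in range(8) if k not in cfg.flash_frames]
        assert np.all(stack[non_flash] == cfg.background_level)

    def test_flash_frames_saturated(self):
        cfg = cd.SimConfig(image_size=(64, 64), organ_density=0.0,
                           noise_sd=4.0, pre_flash_frames=3,
                           post_flash_frames=3, seed=1)
        stack, _ = cd.render_trial(cfg, [])
        assert np.all(stack[3] == 255) and np.all(stack[4] == 255)

    def test_deterministic_bit_identical(self, expansion_spec):
        import dataclasses
        spec = dataclasses.replace(expansion_spec, center=(60.0, 60.0),
                                   baseline_area=500.0)
        cfg = cd.SimConfig(image_size=(128, 128), organ_density=0.0,
                           noise_sd=6.0, jitter_sd=0.5, seed=11)
        s1, _ = cd.render_trial(cfg, [spec])
        s2, _ = cd.render_trial(cfg, [spec])
        assert np.array_equal(s1, s2)

    def test_area_conservation_noise_free(self):
        """Dark-pixel count of an isolated organ tracks the trajectory
        within 5% in every non-flash frame."""
        spec = cd.ChromatophoreSpec(
            organ_id=0, center=(64.0, 64.0), aspect_ratio=1.2,
            baseline_area=600.0, direction="expansion", magnitude_pct=150.0,
            onset_ms=40.0, rise_ms=100.0, return_ms=200.0, orientation=0.4)
        cfg = cd.SimConfig(image_size=(128, 128), organ_density=0.0,
                           noise_sd=0.0, seed=0)
        stack, gt = cd.render_trial(cfg, [spec])
        mid = (cfg.background_level + cfg.organ_level) / 2
        for k in range(cfg.n_frames):
            if k in cfg.flash_frames:
                continue
            measured = np.sum(stack[k] < mid)
            assert measured == pytest.approx(gt.areas[0, k], rel=0.05)

    def test_impossible_geometry_raises(self, expansion_spec):
        import dataclasses
        spec = dataclasses.replace(expansion_spec, center=(3.0, 3.0),
                                   baseline_area=500.0)
        cfg = cd.SimConfig(image_size=(64, 64), organ_density=0.0)
        with pytest.raises(cd.ChromodynError, match="fit"):
            cd.render_trial(cfg, [spec])

    def test_overlapping_organs_warn(self):
        kw = dict(aspect_ratio=1.0, baseline_area=400.0,
                  direction="expansion", magnitude_pct=150.0, onset_ms=40,
                  rise_ms=100, return_ms=200)
        specs = [cd.ChromatophoreSpec(organ_id=0, center=(60.0, 60.0), **kw),
                 cd.ChromatophoreSpec(organ_id=1, center=(75.0, 60.0), **kw)]
        cfg = cd.SimConfig(image_size=(128, 128), organ_density=0.0,
                           noise_sd=0.0, pre_flash_frames=2,
                           post_flash_frames=2)
        with pytest.warns(UserWarning, match="overlap"):
            cd.render_trial(cfg, specs)


class TestStackAndGroundTruthIO:
    def test_tiff_round_trip(self, tmp_path):
        cfg = cd.SimConfig(image_size=(32, 32), organ_density=0.0,
                           pre_flash_frames=2, post_flash_frames=2, seed=2)
        stack, gt = cd.render_trial(cfg, [])
        cd.write_stack(stack, tmp_path / "s.tiff")
        assert np.array_equal(cd.read_stack(tmp_path / "s.tiff"), stack)

    def test_png_sequence_round_trip(self, tmp_path):
        cfg = cd.SimConfig(image_size=(32, 32), organ_density=0.0,
                           pre_flash_frames=2, post_flash_frames=2, seed=2)
        stack, _ = cd.render_trial(cfg, [])
        cd.write_stack(stack, tmp_path / "frames")
        assert np.array_equal(cd.read_stack(tmp_path / "frames"), stack)

    def test_ground_truth_json_round_trip(self, tmp_path, expansion_spec):
        import dataclasses
        from chromodyn.simulate import save_ground_truth, load_ground_truth
        spec = dataclasses.replace(expansion_spec, center=(40.0, 40.0),
                                   baseline_area=300.0)
        cfg = cd.SimConfig(image_size=(96, 96), organ_density=0.0,
                           pre_flash_frames=4, post_flash_frames=4)
        _, gt = cd.render_trial(cfg, [spec])
        save_ground_truth(gt, tmp_path / "gt.json")
        back = load_ground_truth(tmp_path / "gt.json")
        assert back.flash_frame_index == gt.flash_frame_index
        assert np.allclose(back.areas, gt.areas)
        assert back.specs[0].magnitude_pct == spec.magnitude_pct


class TestSimulatedTraces:
    def test_ground_truth_equals_profile_at_frame_times(self, expansion_spec):
        import dataclasses
        spec = dataclasses.replace(expansion_spec, center=(60.0, 60.0),
                                   baseline_area=400.0)
        cfg = cd.SimConfig(image_size=(128, 128), organ_density=0.0, seed=5)
        traces, gt = cd.simulate_traces(cfg, [spec])
        times = cfg.timeline().frame_times()
        assert np.allclose(gt.areas[0], cd.area_profile(spec, times))
        present = traces[0].present_mask
        assert np.allclose(traces[0].areas[present], gt.areas[0][present])


class TestSyntheticCrossingTrace:
    def test_crossing_frames_are_exact(self):
        tr = cd.synthetic_crossing_trace(268.0, 3, 7, 12, 21)
        b, dev = 100.0, 168.0
        flash = tr.timeline.flash_frame_index
        thr5, thr50 = b + 0.05 * dev, b + 0.50 * dev
        post = tr.areas[flash:]
        assert np.nanargmax(post >= thr5) == 3
        assert np.nanargmax(post >= thr50) == 7
        assert np.nanargmax(post) == 12
        after_peak = np.flatnonzero(post[13:] <= thr5)[0] + 13
        assert after_peak == 21

    def test_misordered_frames_rejected(self):
        with pytest.raises(cd.ChromodynError):
            cd.synthetic_crossing_trace(268.0, 7, 3, 12, 21)
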