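"""Generator ground truth: determinism, target fractions, rendering bounds."""

import numpy as np
import pytest

from porecolony.biomass import preprocess_stack, retention_curve
from porecolony.geometry import DEP
from porecolony.synthetic import (
    GeometryParams,
    generate_biomass_stack,
    generate_geometry,
    generate_reporter_stack,
    three_phase_curve,
)


class TestGeometryGenerator:
    def test_dep_fraction_hits_target(self, toy_params):
        for seed in (1, 7):
            mask, truth = generate_geometry(GeometryParams(seed=seed, **toy_params))
            assert abs(truth.dep_fraction - 0.08) <= 0.02
            # recount from the recorded label map
            grid = truth.true_label_map.grid
            frac = (grid == DEP).sum() / (grid != 0).sum()
            assert frac == pytest.approx(truth.dep_fraction)

    def test_determinism_bit_identical(self, toy_params):
        a = generate_geometry(GeometryParams(seed=11, **toy_params))
        b = generate_geometry(GeometryParams(seed=11, **toy_params))
        assert np.array_equal(a[0].grid, b[0].grid)
        assert np.array_equal(a[1].true_label_map.grid, b[1].true_label_map.grid)
        c = generate_geometry(GeometryParams(seed=12, **toy_params))
        assert not np.array_equal(a[0].grid, c[0].grid)

    def test_percolates_inlet_to_outlet(self, toy_scene):
        from scipy import ndimage

        mask, _ = toy_scene
        comp, _ = ndimage.label(mask.grid)
        assert set(np.unique(comp[:, 0])) & set(np.unique(comp[:, -1])) - {0}

    def test_cavity_aspect_validated(self, toy_params):
        bad = dict(toy_params, cavity_aspect=0.8)
        with pytest.raises(ValueError):
            GeometryParams(seed=0, **bad)

    def test_infeasible_dep_fraction(self, toy_params):
        bad = dict(toy_params, target_dep_fraction=0.45)
        with pytest.raises(ValueError):
            generate_geometry(GeometryParams(seed=0, **bad))

    def test_default_scale_matches_study_conditions(self):
        """Full-scale defaults: 0.65 µm/px, 0.04 mm pores, 0.2 mm DEPs, 8%."""
        params = GeometryParams(seed=2)
        mask, truth = generate_geometry(params)
        assert abs(truth.dep_fraction - 0.08) <= 0.02
        depths = [c.depth_px * params.pixel_size / 1000 for c in truth.cavities]
        assert max(depths) == pytest.approx(0.2, abs=0.01)


class TestBiomassStack:
    def test_uniform_ratio_one_recovers_exactly(self, toy_scene):
        _, truth = toy_scene
        lmap = truth.true_label_map
        times = np.arange(5) * 60.0
        stack, _ = generate_biomass_stack(
            lmap, times, np.array([0, 1, 1, 1, 1.0]), noise_sigma=0.0, seed=0
        )
        corrected = preprocess_stack(stack, lmap)
        rc = retention_curve(corrected, lmap)
        assert np.allclose(rc["ratio"][1:], 1.0)

    def test_zero_biomass_frames_equal_background(self, toy_scene):
        _, truth = toy_scene
        lmap = truth.true_label_map
        times = np.arange(4) * 60.0
        stack, _ = generate_biomass_stack(
            lmap, times, np.zeros(4), tp_mean=0.0, noise_sigma=0.0, seed=0
        )
        for f in stack.frames[1:]:
            assert np.array_equal(f, stack.frames[0])

    def test_ramp_recovered_with_noise(self, toy_scene):
        """1 → 2.5 enrichment over 12 frames survives 1% read noise."""
        _, truth = toy_scene
        lmap = truth.true_label_map
        times = np.arange(13) * 600.0
        ratio = np.concatenate([[0.0], np.linspace(1.0, 2.5, 12)])
        stack, st = generate_biomass_stack(
            lmap, times, ratio, tp_mean=3000.0, noise_sigma=300.0, seed=5
        )
        corrected = preprocess_stack(stack, lmap)
        rc = retention_curve(corrected, lmap)
        rec = rc["ratio"].to_numpy()[1:]
        assert np.all(np.abs(rec - ratio[1:]) / ratio[1:] < 0.05)

    def test_no_intensity_on_solid_and_16bit_bounds(self, toy_scene):
        _, truth = toy_scene
        lmap = truth.true_label_map
        times = np.arange(3) * 60.0
        stack, st = generate_biomass_stack(
            lmap, times, np.array([0, 2.0, 2.5]), noise_sigma=0.0, seed=0
        )
        assert stack.frames.dtype == np.uint16
        solid = lmap.grid == 0
        assert np.all(st.deposits[:, solid] == 0)

    def test_saturation_flagged(self, toy_scene):
        _, truth = toy_scene
        lmap = truth.true_label_map
        times = np.arange(3) * 60.0
        with pytest.warns(UserWarning, match="clipped"):
            _, st = generate_biomass_stack(
                lmap,
                times,
                np.array([0, 1.0, 1.0]),
                tp_mean=40000.0,
                background=30000.0,
                seed=0,
            )
        assert st.saturated


class TestReporterStack:
    def test_front_zero_high_everywhere(self, toy_scene):
        _, truth = toy_scene
        lmap = truth.true_label_map
        times = np.arange(3) * 60.0
        bstack, btruth = generate_biomass_stack(
            lmap, times, np.array([0, 1.5, 1.5]), noise_sigma=0.0, seed=0
        )
        gfp, rtruth = generate_reporter_stack(
            lmap, bstack, btruth, truth.cavities, front_depth_mm=0.0,
            steepness_um=2.0, seed=0,
        )
        dep = lmap.grid == DEP
        sig = gfp.frames[1].astype(float) - gfp.frames[0].astype(float)
        dep_signal = sig[dep]
        # activation ≥ 0.5 everywhere inside DEPs when the front is at s = 0
        deposited = btruth.deposits[1][dep]
        assert np.all(dep_signal[deposited > 0] >= 0.45 * deposited[deposited > 0])

    def test_zero_activation_gives_background_only(self, toy_scene):
        _, truth = toy_scene
        lmap = truth.true_label_map
        times = np.arange(3) * 60.0
        bstack, btruth = generate_biomass_stack(
            lmap, times, np.array([0, 0.0, 0.0]), tp_mean=0.0, noise_sigma=0.0, seed=0
        )
        gfp, _ = generate_reporter_stack(
            lmap, bstack, btruth, truth.cavities, front_depth_mm=0.05, seed=0
        )
        assert np.all(gfp.frames[1] == gfp.frames[0])

    def test_front_deeper_than_dep_rejected(self, toy_scene):
        _, truth = toy_scene
        lmap = truth.true_label_map
        times = np.arange(2) * 60.0
        bstack, btruth = generate_biomass_stack(
            lmap, times, np.array([0, 1.0]), seed=0
        )
        with pytest.raises(ValueError):
            generate_reporter_stack(
                lmap,
                bstack,
                btruth,
                truth.cavities,
                front_depth_mm={c.dep_id: 5.0 for c in truth.cavities},
                seed=0,
            )


class TestTracerStack:
    def test_first_frame_saturated_and_bounded(self, cavity_mask):
        from porecolony.flow import FlowConfig, solve_stokes
        from porecolony.synthetic import generate_tracer_stack

        field = solve_stokes(cavity_mask, FlowConfig(), target_u_m=20.0)
        stack, series = generate_tracer_stack(
            cavity_mask, field, D=6e-4, save_times=[0.0, 30.0, 120.0], seed=0
        )
        assert stack.frames.dtype == np.uint16
        pore = cavity_mask.grid
        # initial condition: uniformly dye-saturated pore space
        assert np.all(stack.frames[0][pore] == 65535)
        assert np.all(stack.frames[:, ~pore] == 0)
        # displacement: intensity decreases at the swept inlet region
        assert stack.frames[-1][pore].mean() < stack.frames[0][pore].mean()


def test_three_phase_curve_shape():
    t = np.linspace(0, 3000, 31)
    c = three_phase_curve(t, t_attach=600, t_growth=1800, level_plateau=2.5)
    assert c[0] == 0.0
    i_attach = np.searchsorted(t, 600)
    assert np.all(np.diff(c[: i_attach + 1]) >= 0)
    assert c[np.searchsorted(t, 1800)] == pytest.approx(2.5)
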