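"""Biomass quantification: background subtraction, clusters, retention, series."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from porecolony.biomass import (
    biomass_timeseries,
    colony_mass_pdf,
    detect_clusters,
    detect_clusters_stack,
    preprocess_stack,
    retention_curve,
)
from porecolony.geometry import DEP, TP
from porecolony.stacks import ImageStack
from porecolony.synthetic import generate_biomass_stack


@pytest.fixture(scope="module")
def truth_lmap(toy_scene):
    return toy_scene[1].true_label_map


class TestPreprocess:
    def test_static_stack_corrects_to_zero(self, truth_lmap):
        frames = np.full((4, *truth_lmap.grid.shape), 30000, dtype=np.uint16)
        stack = ImageStack(frames, np.arange(4.0), "brightfield", 4.0)
        corrected = preprocess_stack(stack, truth_lmap)
        assert np.all(corrected.frames == 0)

    def test_deposited_signal_recovered(self, truth_lmap):
        times = np.arange(3) * 60.0
        stack, st = generate_biomass_stack(
            truth_lmap, times, np.array([0, 1.7, 2.0]), noise_sigma=0.0, seed=0
        )
        corrected = preprocess_stack(stack, truth_lmap)
        assert np.allclose(corrected.frames, st.deposits)

    def test_solid_pixels_exactly_zero(self, truth_lmap):
        times = np.arange(3) * 60.0
        stack, _ = generate_biomass_stack(
            truth_lmap, times, np.array([0, 1.0, 1.0]), noise_sigma=200.0, seed=3
        )
        corrected = preprocess_stack(stack, truth_lmap)
        assert np.all(corrected.frames[:, truth_lmap.grid == 0] == 0)

    def test_shape_mismatch_raises(self, truth_lmap):
        frames = np.zeros((2, 8, 8), dtype=np.uint16)
        stack = ImageStack(frames, np.arange(2.0), "brightfield", 4.0)
        with pytest.raises(ValueError, match="register"):
            preprocess_stack(stack, truth_lmap)


class TestDetectClusters:
    def test_two_disjoint_spots(self):
        frame = np.zeros((64, 64))
        region = np.ones((64, 64), dtype=bool)
        yy, xx = np.mgrid[0:64, 0:64]
        frame += 100 * np.exp(-((yy - 16) ** 2 + (xx - 16) ** 2) / 18.0)
        frame += 100 * np.exp(-((yy - 48) ** 2 + (xx - 44) ** 2) / 18.0)
        cs = detect_clusters(frame, region)
        assert len(cs) == 2
        centers = cs.table[["centroid_row", "centroid_col"]].to_numpy()
        dist = np.hypot(centers[:, 0] - 16, centers[:, 1] - 16).min()
        assert dist < 2.0

    def test_flat_zero_frame_empty(self):
        cs = detect_clusters(np.zeros((32, 32)), np.ones((32, 32), dtype=bool))
        assert len(cs) == 0

    def test_planted_colonies_recovered_exactly(self, toy_scene):
        """Noise-free scene: per-DEP colony count and masses match truth."""
        _, truth = toy_scene
        lmap = truth.true_label_map
        times = np.arange(3) * 600.0
        stack, st = generate_biomass_stack(
            lmap,
            times,
            np.array([0, 2.0, 2.5]),
            tp_mean=20.0,  # low class mean: discs stay below the background
            mode="colonies",
            n_spots_per_dep=2,
            n_spots_tp=6,
            spot_radius_px=2,  # fits inside the 8 px wide cavities
            noise_sigma=0.0,
            seed=4,
        )
        corrected = preprocess_stack(stack, lmap)
        clusters = detect_clusters_stack(corrected, lmap)
        truth_df = pd.DataFrame(
            st.true_cluster_centers, columns=["x", "y", "t", "mass"]
        )
        n_deps = len(lmap.dep_regions)
        for t, sub in clusters.groupby("time_s"):
            tr = truth_df[truth_df["t"] == t]
            # nearly all requested colonies planted (short partial cavities
            # may not fit a disc) and every planted one detected
            assert len(tr) >= 2 * (n_deps - 2) + 6
            assert len(sub) == len(tr)
            # masses agree up to the 16-bit rendering quantization
            assert np.allclose(
                np.sort(sub["integrated_intensity"].to_numpy()),
                np.sort(tr["mass"].to_numpy()),
                rtol=5e-3,
            )


class TestColonyMassPdf:
    def test_identical_clusters_point_mass(self):
        df = pd.DataFrame(
            {"mass_per_area": [5.0] * 8, "time_s": [60.0] * 8}
        )
        pdf = colony_mass_pdf(df)
        dens = pdf["density"].to_numpy()
        edges_width = np.diff(
            np.geomspace(2.5, 10.0, 65)
        )  # internal binning spans lo/2..hi*2
        assert (dens > 0).sum() == 1

    def test_normalization(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(
            {
                "mass_per_area": rng.lognormal(1.0, 0.5, 300),
                "time_s": np.repeat([60.0, 120.0, 180.0], 100),
            }
        )
        pdf = colony_mass_pdf(df)
        lo = df["mass_per_area"].min()
        hi = df["mass_per_area"].max()
        edges = np.geomspace(lo, hi, 65)
        widths = np.diff(edges)
        for _, sub in pdf.groupby("time_s"):
            integral = (sub["density"].to_numpy() * widths).sum()
            assert integral == pytest.approx(1.0, abs=1e-6)

    def test_mode_drifts_up_with_growth(self, toy_scene):
        """Colony mass-per-area densities shift to larger values over time."""
        _, truth = toy_scene
        lmap = truth.true_label_map
        times = np.arange(4) * 600.0
        stack, _ = generate_biomass_stack(
            lmap,
            times,
            np.array([0, 1.0, 1.0, 1.0]),
            tp_mean=np.array([0, 10.0, 20.0, 40.0]),
            mode="colonies",
            n_spots_per_dep=2,
            n_spots_tp=6,
            noise_sigma=0.0,
            seed=4,
        )
        corrected = preprocess_stack(stack, lmap)
        clusters = detect_clusters_stack(corrected, lmap)
        modes = clusters.groupby("time_s")["mass_per_area"].mean()
        assert np.all(np.diff(modes.to_numpy()) > 0)


class TestRetentionCurve:
    def test_uniform_intensity_ratio_one(self, truth_lmap):
        frame = np.where(truth_lmap.grid != 0, 7.0, 0.0)
        stack = ImageStack(frame[None], np.array([0.0]), "brightfield", 4.0)
        rc = retention_curve(stack, truth_lmap)
        assert rc["ratio"][0] == pytest.approx(1.0, abs=1e-12)

    def test_twofold_dep_intensity(self, truth_lmap):
        frame = np.zeros(truth_lmap.grid.shape)
        frame[truth_lmap.grid == TP] = 3.0
        frame[truth_lmap.grid == DEP] = 6.0
        stack = ImageStack(frame[None], np.array([0.0]), "brightfield", 4.0)
        rc = retention_curve(stack, truth_lmap)
        assert rc["ratio"][0] == pytest.approx(2.0, abs=1e-12)

    def test_floor_masks_empty_frames(self, truth_lmap):
        frames = np.zeros((2, *truth_lmap.grid.shape))
        stack = ImageStack(frames, np.arange(2.0), "brightfield", 4.0)
        rc = retention_curve(stack, truth_lmap)
        assert rc["ratio"].isna().all()

    def test_replicate_aggregation(self, truth_lmap):
        frames = []
        for level in (2.0, 4.0):
            f = np.zeros(truth_lmap.grid.shape)
            f[truth_lmap.grid == TP] = 1.0
            f[truth_lmap.grid == DEP] = level
            frames.append(ImageStack(f[None], np.array([0.0]), "brightfield", 4.0))
        rc = retention_curve(frames, truth_lmap)
        assert rc["mean"][0] == pytest.approx(3.0)
        assert rc["sd"][0] == pytest.approx(np.std([2.0, 4.0], ddof=1))


class TestBiomassSeries:
    def test_uniform_partition_equals_area_fraction(self, truth_lmap):
        frame = np.where(truth_lmap.grid != 0, 5.0, 0.0)
        stack = ImageStack(frame[None], np.array([0.0]), "brightfield", 4.0)
        ts = biomass_timeseries(stack, truth_lmap)
        assert ts["dep_partition"][0] == pytest.approx(
            truth_lmap.dep_volume_fraction, abs=1e-15
        )

    def test_all_biomass_in_deps(self, truth_lmap):
        frame = np.where(truth_lmap.grid == DEP, 5.0, 0.0)
        stack = ImageStack(frame[None], np.array([0.0]), "brightfield", 4.0)
        ts = biomass_timeseries(stack, truth_lmap)
        assert ts["dep_partition"][0] == 1.0

    def test_additivity_every_frame(self, truth_lmap):
        times = np.arange(4) * 60.0
        stack, _ = generate_biomass_stack(
            truth_lmap, times, np.array([0, 1.0, 1.8, 2.5]), noise_sigma=150.0, seed=2
        )
        corrected = preprocess_stack(stack, truth_lmap)
        ts = biomass_timeseries(corrected, truth_lmap)
        assert np.allclose(ts["B_tot"], ts["B_tp"] + ts["B_dep"], rtol=0, atol=1e-9)

    @given(st.floats(0.1, 100.0))
    @settings(max_examples=10, deadline=None)
    def test_intensity_scale_equivariance(self, scale):
        """Scaling the stack leaves ratios unchanged, scales sums linearly."""
        grid = np.zeros((20, 30), dtype=np.uint8)
        grid[5:15, :] = TP
        grid[8:12, 10:20] = DEP
        from porecolony.geometry import PoreLabelMap

        lmap = PoreLabelMap(grid=grid, pixel_size=1.0)
        rng = np.random.default_rng(1)
        frame = np.where(grid != 0, rng.random(grid.shape) + 0.5, 0.0)
        s1 = ImageStack(frame[None], np.array([0.0]), "brightfield", 1.0)
        s2 = ImageStack(scale * frame[None], np.array([0.0]), "brightfield", 1.0)
        r1 = retention_curve(s1, lmap)["ratio"][0]
        r2 = retention_curve(s2, lmap)["ratio"][0]
        assert r2 == pytest.approx(r1, rel=1e-12)
        t1 = biomass_timeseries(s1, lmap)
        t2 = biomass_timeseries(s2, lmap)
        assert t2["B_tot"][0] == pytest.approx(scale * t1["B_tot"][0], rel=1e-12)
        assert t2["dep_partition"][0] == pytest.approx(
            t1["dep_partition"][0], rel=1e-12
        )

    def test_wt_like_end_partition_calibration(self, toy_scene):
        """A scene calibrated to a 35% end-time DEP partition reads back 0.35."""
        _, truth = toy_scene
        lmap = truth.true_label_map
        f = lmap.dep_volume_fraction
        # choose the final DEP:TP concentration ratio so that the biomass
        # partition B_dep/B_tot equals 0.35: ratio = p/(1-p) · (1-f)/f
        p = 0.35
        ratio_end = p / (1 - p) * (1 - f) / f
        times = np.arange(4) * 600.0
        stack, _ = generate_biomass_stack(
            lmap,
            times,
            np.array([0, 1.0, 2.0, ratio_end]),
            tp_mean=3000.0,
            noise_sigma=30.0,
            seed=6,
        )
        corrected = preprocess_stack(stack, lmap)
        ts = biomass_timeseries(corrected, lmap)
        assert ts["dep_partition"].iloc[-1] == pytest.approx(0.35, abs=0.02)
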