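import numpy as np
import pytest

from srbeam3d import ScattererSet, VoxelGrid, scenario, simulate_channels
from srbeam3d.forward_model import ChannelDataFrame, required_duration
from srbeam3d.probe import ConfigurationError
from srbeam3d.ulm import (
    FrameStack,
    LocalizationSet,
    PipelineConfig,
    _upsample_patch,
    accumulate,
    detect_and_localize,
    ncc3d,
    run_pipeline,
    svd_clutter_filter,
)


def _stack_from_arrays(arrays, fs=31.2):
    return FrameStack([ChannelDataFrame(a, fs) for a in arrays])


class TestSvdClutterFilter:
    def test_rank_one_clutter_removed(self):
        rng = np.random.default_rng(0)
        static = rng.standard_normal((64, 8))
        stack = _stack_from_arrays([static.copy() for _ in range(6)])
        filtered = svd_clutter_filter(stack, 1)
        residual = sum(np.sum(f.samples**2) for f in filtered)
        total = sum(np.sum(f.samples**2) for f in stack)
        assert residual < 1e-10 * total

    def test_zero_rank_cut_is_identity(self):
        rng = np.random.default_rng(1)
        arrays = [rng.standard_normal((32, 4)) for _ in range(4)]
        stack = _stack_from_arrays(arrays)
        filtered = svd_clutter_filter(stack, 0)
        for a, f in zip(arrays, filtered):
            np.testing.assert_array_equal(a, f.samples)

    def test_threshold_mode_idempotent(self):
        # removing all components above an absolute singular-value threshold
        # is a projection: a second pass finds nothing left to remove
        rng = np.random.default_rng(2)
        static = 10.0 * rng.standard_normal((48, 6))
        stack = _stack_from_arrays([static + rng.standard_normal((48, 6)) for _ in range(8)])
        once = svd_clutter_filter(stack, sv_threshold=50.0)
        twice = svd_clutter_filter(once, sv_threshold=50.0)
        scale = max(np.abs(f.samples).max() for f in once)
        for f1, f2 in zip(once, twice):
            np.testing.assert_allclose(f1.samples, f2.samples, atol=1e-10 * scale)

    def test_rank_mode_removes_the_clutter_subspace(self):
        # the filtered Casorati matrix holds no energy along the removed
        # left singular vectors of the input
        rng = np.random.default_rng(2)
        stack = _stack_from_arrays([rng.standard_normal((48, 6)) for _ in range(8)])
        x = np.stack([f.samples.ravel() for f in stack.frames], axis=1)
        u, _, _ = np.linalg.svd(x, full_matrices=False)
        filtered = svd_clutter_filter(stack, 2)
        xf = np.stack([f.samples.ravel() for f in filtered.frames], axis=1)
        leak = np.abs(u[:, :2].T @ xf).max()
        assert leak < 1e-10 * np.linalg.norm(x)

    def test_static_removed_moving_retained(self):
        # static clutter plus a bubble echo hopping along the trace; the
        # mean bubble signal leaks into the clutter component, so retention
        # is bounded by (1 - 1/n_frames)^2 ~ 0.88 for 16 frames
        rng = np.random.default_rng(3)
        n_frames = 16
        static = 10.0 * rng.standard_normal((200, 8))
        frames = []
        for i in range(n_frames):
            moving = np.zeros((200, 8))
            moving[20 + 5 * i : 28 + 5 * i, :] = rng.standard_normal((8, 8))
            frames.append(static + moving)
        stack = _stack_from_arrays(frames)
        filtered = svd_clutter_filter(stack, 1)
        moving_energy = 0.0
        filtered_moving = 0.0
        static_residual = 0.0
        for i, f in enumerate(filtered):
            window = slice(20 + 5 * i, 28 + 5 * i)
            orig = stack.frames[i].samples
            moving_energy += np.sum((orig[window] - static[window]) ** 2)
            filtered_moving += np.sum(f.samples[window] ** 2)
            mask = np.ones(200, bool)
            mask[window] = False
            static_residual += np.sum(f.samples[mask] ** 2)
        static_energy = n_frames * np.sum(static**2)
        assert filtered_moving >= 0.8 * moving_energy
        assert static_residual <= 0.01 * static_energy

    def test_invalid_configurations_rejected(self):
        stack = _stack_from_arrays([np.ones((8, 2)), np.ones((8, 2))])
        with pytest.raises(ConfigurationError):
            svd_clutter_filter(stack, 2)
        with pytest.raises(ConfigurationError):
            svd_clutter_filter(_stack_from_arrays([np.ones((8, 2))]), 1)
        with pytest.raises(ConfigurationError):
            svd_clutter_filter(stack, rank_cut=1, sv_threshold=1.0)


class TestNcc3d:
    def _template(self):
        g = np.exp(-0.5 * (np.arange(7) - 3) ** 2 / 1.5**2)
        return g[:, None, None] * g[None, :, None] * g[None, None, :]

    def test_exact_template_scores_unity(self):
        t = self._template()
        vol = np.zeros((20, 20, 20))
        vol[5:12, 6:13, 7:14] = 2.5 * t + 0.7  # affine copy still correlates at 1
        coeff = ncc3d(vol, t)
        assert coeff.max() == pytest.approx(1.0, abs=1e-6)
        assert tuple(np.unravel_index(np.argmax(coeff), coeff.shape)) == (8, 9, 10)

    def test_negated_template_scores_minus_one(self):
        t = self._template()
        vol = np.zeros((16, 16, 16))
        vol[4:11, 4:11, 4:11] = -t
        assert ncc3d(vol, t).min() == pytest.approx(-1.0, abs=1e-6)

    def test_bounded_and_low_against_noise(self):
        rng = np.random.default_rng(7)
        t = self._template()
        vol = rng.standard_normal((24, 24, 24))
        coeff = ncc3d(vol, t)
        assert np.all(coeff >= -1.0) and np.all(coeff <= 1.0)
        assert np.abs(coeff).max() < 0.6

    def test_template_larger_than_volume_rejected(self):
        with pytest.raises(ValueError):
            ncc3d(np.zeros((4, 4, 4)), np.ones((5, 5, 5)))


class TestDetectAndLocalize:
    def _blob_volume(self, centre_mm, grid, sigma=0.12):
        gx, gy, gz = np.meshgrid(grid.x, grid.y, grid.z, indexing="ij", sparse=True)
        d2 = (gx - centre_mm[0]) ** 2 + (gy - centre_mm[1]) ** 2 + (gz - centre_mm[2]) ** 2
        return np.exp(-d2 / (2 * sigma**2))

    def test_spline_upsampling_interpolates_knots_exactly(self):
        rng = np.random.default_rng(8)
        patch = rng.random((5, 5, 5))
        up = _upsample_patch(patch, 10)
        np.testing.assert_allclose(up[::10, ::10, ::10], patch, atol=1e-12)

    def test_centred_blob_localized_exactly(self):
        grid = VoxelGrid(origin=(-1, -1, 19.0), pitch=(0.05,) * 3, shape=(41, 41, 41))
        v = self._blob_volume((0.0, 0.0, 20.0), grid)
        locs = detect_and_localize(v, v, grid, ncc_threshold=0.5)
        assert len(locs) == 1
        np.testing.assert_allclose(locs.positions[0], [0, 0, 20.0], atol=1e-6)

    def test_subvoxel_shift_recovered_within_tenth_voxel(self):
        # blob shifted 0.02 mm on a 0.05 mm grid: error must be < 0.005 mm
        grid = VoxelGrid(origin=(-1, -1, 19.0), pitch=(0.05,) * 3, shape=(41, 41, 41))
        truth = np.array([0.02, -0.02, 20.02])
        v = self._blob_volume(truth, grid)
        locs = detect_and_localize(v, v, grid, ncc_threshold=0.5)
        assert len(locs) == 1
        np.testing.assert_allclose(locs.positions[0], truth, atol=0.005)

    def test_empty_volume_gives_empty_set(self):
        grid = VoxelGrid(origin=(0, 0, 10.0), pitch=(0.05,) * 3, shape=(9, 9, 9))
        locs = detect_and_localize(np.zeros((9, 9, 9)), np.zeros((9, 9, 9)), grid)
        assert len(locs) == 0

    def test_counts_monotone_in_thresholds(self):
        rng = np.random.default_rng(9)
        grid = VoxelGrid(origin=(0, 0, 10.0), pitch=(0.05,) * 3, shape=(25, 25, 25))
        v = rng.random((25, 25, 25))
        n_loose = len(detect_and_localize(v, v, grid, ncc_threshold=0.2))
        n_tight = len(detect_and_localize(v, v, grid, ncc_threshold=0.6))
        assert n_tight <= n_loose
        n_bg = len(detect_and_localize(v, v, grid, ncc_threshold=0.2, bg_threshold_db=-3.0))
        assert n_bg <= n_loose

    def test_border_peaks_discarded(self):
        grid = VoxelGrid(origin=(0, 0, 10.0), pitch=(0.05,) * 3, shape=(11, 11, 11))
        v = np.zeros((11, 11, 11))
        v[0, 5, 5] = 1.0
        with pytest.warns(UserWarning):
            locs = detect_and_localize(v, v, grid, ncc_threshold=0.5)
        assert len(locs) == 0


class TestAccumulate:
    def test_counts_and_conservation(self):
        grid = VoxelGrid(origin=(0, 0, 10.0), pitch=(0.01,) * 3, shape=(10, 10, 10))
        import pandas as pd

        recs = pd.DataFrame(
            {"frame": 0, "x_mm": [0.031] * 10, "y_mm": [0.042] * 10, "z_mm": [10.05] * 10, "ncc": 1.0, "intensity": 1.0}
        )
        density = accumulate(LocalizationSet(recs), grid)
        assert density.total == 10
        assert density.counts.max() == 10

    def test_outside_localizations_dropped_and_counted(self):
        grid = VoxelGrid(origin=(0, 0, 10.0), pitch=(0.01,) * 3, shape=(5, 5, 5))
        import pandas as pd

        recs = pd.DataFrame(
            {"frame": 0, "x_mm": [0.01, 9.0], "y_mm": [0.01, 9.0], "z_mm": [10.01, 99.0], "ncc": 1.0, "intensity": 1.0}
        )
        density = accumulate(LocalizationSet(recs), grid)
        assert density.total == 1
        assert density.n_dropped == 1

    def test_empty_set(self):
        grid = VoxelGrid(origin=(0, 0, 10.0), pitch=(0.01,) * 3, shape=(4, 4, 4))
        density = accumulate(LocalizationSet(), grid)
        assert density.total == 0


@pytest.fixture(scope="module")
def tube_data():
    """Crossing-tube bubble frames imaged by the full 32x32 probe."""
    from srbeam3d import make_probe

    probe = make_probe()
    scene = scenario(
        "crossing_tubes",
        {"n_frames": 8, "bubbles_per_tube": 0.8, "x_extent": (-0.8, 0.8), "depth": 20.0},
        seed=11,
    )
    dur = required_duration(probe, 21.5, 1.5)
    frames = [simulate_channels(probe, s, duration=dur) for s in scene]
    return probe, scene, FrameStack(frames)


class TestRunPipeline:
    def test_empty_stack_gives_empty_outputs(self, small_probe):
        grid = VoxelGrid(origin=(-0.5, -0.5, 11.0), pitch=(0.05,) * 3, shape=(21, 21, 21))
        density, locs = run_pipeline(FrameStack([]), small_probe, grid)
        assert density.total == 0 and len(locs) == 0

    def test_deterministic_rerun(self, tube_data):
        probe, scene, stack = tube_data
        grid = VoxelGrid.from_bounds(((-0.9, 0.9), (-0.6, 0.6), (19.6, 20.4)), 0.05)
        cfg = PipelineConfig(method="das", rank_cut=0, ncc_threshold=0.3)
        d1, l1 = run_pipeline(stack, probe, grid, cfg)
        d2, l2 = run_pipeline(stack, probe, grid, cfg)
        np.testing.assert_array_equal(d1.counts, d2.counts)
        assert len(l1) == len(l2)

    def test_localizations_land_in_lumens_and_mass_conserved(self, tube_data):
        probe, scene, stack = tube_data
        grid = VoxelGrid.from_bounds(((-0.9, 0.9), (-0.6, 0.6), (19.6, 20.4)), 0.05)
        cfg = PipelineConfig(method="cv", rank_cut=0, ncc_threshold=0.3, bg_threshold_db=-40.0)
        density, locs = run_pipeline(stack, probe, grid, cfg)
        assert len(locs) > 0
        assert density.total + density.n_dropped == len(locs)
        in_lumen = scene.in_lumen(locs.positions, tolerance=0.02)
        assert in_lumen.mean() >= 0.95

    def test_adaptive_beamformer_confines_localizations_better(self, tube_data):
        # at matched counts, CV leaves fewer localizations outside the lumens
        probe, scene, stack = tube_data
        grid = VoxelGrid.from_bounds(((-0.9, 0.9), (-0.6, 0.6), (19.6, 20.4)), 0.05)
        outside = {}
        counts = {}
        for method, bg_db in (("das", -10.0), ("cv", -40.0)):
            cfg = PipelineConfig(method=method, rank_cut=0, ncc_threshold=0.3, bg_threshold_db=bg_db)
            _, locs = run_pipeline(stack, probe, grid, cfg)
            counts[method] = len(locs)
            outside[method] = int((~scene.in_lumen(locs.positions, tolerance=0.02)).sum())
        n = min(counts.values())
        assert n > 0
        assert outside["cv"] <= outside["das"]
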