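import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from srbeam3d import (
    ChannelGather,
    PdasConfig,
    ScattererSet,
    VoxelGrid,
    beamform_multi,
    beamform_volume,
    cf_weight,
    cv_weight,
    das,
    gather,
    pdas,
    simulate_channels,
)
from srbeam3d.beamformers import CV_WMAX, log_compress
from srbeam3d.probe import ConfigurationError

# ---------------------------------------------------------------------------
# independent brute-force oracles, written from the weight definitions


def oracle_das(s, a):
    total = 0j
    for sn, an in zip(s, a):
        total += an * sn
    return total


def oracle_pdas(s, p):
    y_hat = 0j
    for sn in s:
        m = abs(sn)
        if m > 0:
            y_hat += (sn / m) * m ** (1.0 / p)
    m = abs(y_hat)
    return 0j if m == 0 else (y_hat / m) * m**p


def oracle_cf(s):
    num = abs(sum(s)) ** 2
    den = len(s) * sum(abs(sn) ** 2 for sn in s)
    return 0.0 if den == 0 else num / den


def oracle_cv(s, a, inverse):
    num = abs(sum(s)) ** 2
    x = [sn / an for sn, an in zip(s, a)] if inverse else list(s)
    mean = sum(x) / len(x)
    den = sum(abs(xn - mean) ** 2 for xn in x)
    if num == 0:
        return 0.0
    if den < 1e-12 * num:
        return CV_WMAX
    return min(num / den, CV_WMAX)


complex_channels = st.lists(
    st.complex_numbers(min_magnitude=1e-3, max_magnitude=1e3, allow_nan=False, allow_infinity=False),
    min_size=2,
    max_size=8,
)
sens_values = st.floats(min_value=0.5, max_value=1.0)


class TestScalarOperations:
    def test_das_examples(self):
        assert das(ChannelGather.from_arrays([1, 1, 1, 1])) == pytest.approx(4)
        assert das(ChannelGather.from_arrays([1, -1])) == pytest.approx(0)
        assert das(ChannelGather.from_arrays([1, 2, 3], [1, 0.8, 0.6])) == pytest.approx(4.4)

    def test_pdas_examples(self):
        # single channel: root then power is the identity
        assert pdas(ChannelGather.from_arrays([2.7 - 0.3j])) == pytest.approx(2.7 - 0.3j)
        assert pdas(ChannelGather.from_arrays([16, 16])) == pytest.approx(256)
        assert pdas(ChannelGather.from_arrays([1, -1])) == pytest.approx(0)

    def test_cf_examples(self):
        assert cf_weight(ChannelGather.from_arrays([3, 3, 3])) == pytest.approx(1.0)
        assert cf_weight(ChannelGather.from_arrays([1, -1])) == pytest.approx(0.0)
        assert cf_weight(ChannelGather.from_arrays([1, 2, 3])) == pytest.approx(6 / 7)

    def test_cv_examples(self):
        # mean 2, squared deviations 1 + 0 + 1 = 2, coherent energy 36
        assert cv_weight(ChannelGather.from_arrays([1, 2, 3])) == pytest.approx(18.0)
        assert cv_weight(ChannelGather.from_arrays([1, -1])) == pytest.approx(0.0)
        assert cv_weight(ChannelGather.from_arrays([2, 2, 2])) == CV_WMAX
        assert cv_weight(ChannelGather.from_arrays([5])) == 0.0  # needs >= 2 channels

    @given(complex_channels, st.data())
    def test_brute_force_oracle_equality(self, s, data):
        a = np.array(data.draw(st.lists(sens_values, min_size=len(s), max_size=len(s))))
        g = ChannelGather.from_arrays(s, a)
        s = np.asarray(s, dtype=complex)
        assert das(g) == pytest.approx(oracle_das(s, a), rel=1e-10, abs=1e-12)
        assert pdas(g) == pytest.approx(oracle_pdas(s, 4), rel=1e-10, abs=1e-12)
        assert cf_weight(g) == pytest.approx(oracle_cf(s), rel=1e-10, abs=1e-12)
        assert cv_weight(g, True) == pytest.approx(oracle_cv(s, a, True), rel=1e-10, abs=1e-12)
        assert cv_weight(g, False) == pytest.approx(oracle_cv(s, a, False), rel=1e-10, abs=1e-12)

    @given(complex_channels)
    def test_weight_bounds(self, s):
        g = ChannelGather.from_arrays(s)
        assert 0.0 <= cf_weight(g) <= 1.0 + 1e-12
        assert cv_weight(g) >= 0.0


class TestGather:
    def test_phase_alignment_at_the_scatterer(self, small_probe, point_frame):
        frame, scene = point_frame
        g = gather(frame, small_probe, scene.positions[0])
        assert g.n_active >= 2
        phases = np.exp(1j * np.angle(g.samples))
        circ_std = np.sqrt(-2 * np.log(np.abs(np.mean(phases))))
        assert circ_std < 0.2

    def test_phase_dispersion_off_target(self, small_probe, point_frame):
        frame, scene = point_frame
        g = gather(frame, small_probe, scene.positions[0] + [5.0, 0, 0])
        phases = np.exp(1j * np.angle(g.samples))
        circ_std = np.sqrt(-2 * np.log(np.abs(np.mean(phases))))
        assert circ_std > 1.0

    def test_zero_frame_gathers_zeros(self, small_probe):
        frame = simulate_channels(small_probe, ScattererSet(np.zeros((0, 3)), np.zeros(0)), duration=20.0)
        g = gather(frame, small_probe, (0, 0, 10.0))
        assert g.valid and np.all(g.samples == 0)

    def test_sensitivity_cut_applied(self, small_probe, point_frame):
        frame, _ = point_frame
        g = gather(frame, small_probe, (0, 0, 2.0))  # shallow: wide angles
        assert g.n_active < small_probe.n_elements
        assert np.all(g.sensitivities >= 0.5)


class TestVolumeDriver:
    def test_volume_matches_scalar_ops(self, small_probe, point_frame):
        frame, scene = point_frame
        grid = VoxelGrid.from_bounds(((0.0, 0.2), (-0.2, 0.0), (11.9, 12.1)), 0.1)
        vols = beamform_multi(frame, small_probe, grid, ["das", "cf", "cvn", "cv"])
        for ix, x in enumerate(grid.x):
            for iy, y in enumerate(grid.y):
                for iz, z in enumerate(grid.z):
                    g = gather(frame, small_probe, (x, y, z))
                    y_das = das(g)
                    assert vols["das"].values[ix, iy, iz] == pytest.approx(abs(y_das), rel=1e-10)
                    assert vols["cf"].weight_map[ix, iy, iz] == pytest.approx(cf_weight(g), rel=1e-10)
                    assert vols["cv"].weight_map[ix, iy, iz] == pytest.approx(cv_weight(g, True), rel=1e-10)
                    assert vols["cvn"].weight_map[ix, iy, iz] == pytest.approx(cv_weight(g, False), rel=1e-10)
                    assert vols["cf"].values[ix, iy, iz] == pytest.approx(cf_weight(g) * abs(y_das), rel=1e-10)

    @pytest.mark.parametrize("method", ["das", "pdas", "cf", "cvn", "cv"])
    def test_point_scatterer_peak_on_truth(self, small_probe, point_frame, method):
        frame, scene = point_frame
        truth = scene.positions[0]
        grid = VoxelGrid.from_bounds(
            ((truth[0] - 0.5, truth[0] + 0.5), (truth[1] - 0.5, truth[1] + 0.5), (truth[2] - 0.5, truth[2] + 0.5)),
            0.1,
        )
        vol = beamform_volume(frame, small_probe, grid, method, pdas_config=PdasConfig(axial_oversample_pitch=0.0125))
        peak_mm = grid.index_to_mm(vol.peak_index)
        assert np.all(np.abs(peak_mm - truth) <= np.asarray(grid.pitch) + 1e-9)

    def test_scaling_equivariance(self, small_probe, point_frame):
        from srbeam3d.forward_model import ChannelDataFrame

        frame, scene = point_frame
        alpha = 3.7
        scaled = ChannelDataFrame(frame.samples * alpha, frame.sampling_frequency, frame.t0)
        truth = scene.positions[0]
        grid = VoxelGrid.from_bounds(
            ((truth[0] - 0.2, truth[0] + 0.2), (truth[1], truth[1]), (truth[2] - 0.2, truth[2] + 0.2)), 0.1
        )
        for method in ("das", "pdas", "cf", "cvn", "cv"):
            cfg = PdasConfig(axial_oversample_pitch=0.0125)
            v1 = beamform_volume(frame, small_probe, grid, method, pdas_config=cfg)
            v2 = beamform_volume(scaled, small_probe, grid, method, pdas_config=cfg)
            np.testing.assert_allclose(v2.values, alpha * v1.values, rtol=1e-9)
            if v1.weight_map is not None:  # weights are scale invariant
                np.testing.assert_allclose(v2.weight_map, v1.weight_map, rtol=1e-9)

    def test_weight_maps_present_only_for_weighted_methods(self, small_probe, point_frame):
        frame, scene = point_frame
        grid = VoxelGrid.from_bounds(((0, 0.2), (0, 0.2), (11.9, 12.1)), 0.1)
        vols = beamform_multi(frame, small_probe, grid, ["das", "cf", "cv"])
        assert vols["das"].weight_map is None
        assert np.all((vols["cf"].weight_map >= 0) & (vols["cf"].weight_map <= 1 + 1e-12))
        assert np.all(vols["cv"].weight_map >= 0)

    def test_pdas_oversample_pitch_validated(self, small_probe, point_frame):
        frame, _ = point_frame
        grid = VoxelGrid.from_bounds(((0, 0), (0, 0), (11.9, 12.1)), 0.1)
        with pytest.raises(ConfigurationError):
            beamform_volume(frame, small_probe, grid, "pdas", pdas_config=PdasConfig(axial_oversample_pitch=0.05))

    def test_unknown_method_rejected(self, small_probe, point_frame):
        frame, _ = point_frame
        grid = VoxelGrid.from_bounds(((0, 0), (0, 0), (11.9, 12.1)), 0.1)
        with pytest.raises(ConfigurationError):
            beamform_volume(frame, small_probe, grid, "capon")

    def test_log_compression_range(self, small_probe, point_frame):
        frame, scene = point_frame
        truth = scene.positions[0]
        grid = VoxelGrid.from_bounds(((truth[0] - 0.3, truth[0] + 0.3), (truth[1], truth[1]), (11.8, 12.2)), 0.1)
        vol = beamform_volume(frame, small_probe, grid, "das")
        db = log_compress(vol, 60.0)
        assert db.max() == pytest.approx(0.0)
        assert db.min() >= -60.0
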