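"""Delay-and-sum and adaptive weight-based 3D beamformers.

Five reconstructions are provided for delayed analytic channel signals
``s_n`` with element sensitivities ``a_n`` (channels with ``a_n < 0.5``
are excluded; ``N`` below is the count of the remaining active channels):

``das``
    Apodized coherent sum ``y = sum a_n s_n``; image is the envelope |y|.
``pdas``
    p-th root compression per channel, ``y_hat = sum (s_n/|s_n|) |s_n|^{1/p}``,
    restored by ``y = (y_hat/|y_hat|) |y_hat|^p``; because the nonlinearity
    creates harmonics of the axial carrier, the volume is reconstructed on a
    finer depth grid, band-pass filtered along depth around the fundamental
    axial frequency ``2 f0 / c``, then down-sampled.
``cf``
    Coherence factor ``W_CF = |sum s_n|^2 / (N sum |s_n|^2)`` applied to the
    DAS voxel.  The ``1/N`` normalisation makes fully coherent channels give
    exactly 1.
``cvn``
    Coherence-to-variance weight ``W_VN = |sum s_n|^2 / sum |s_n - mean|^2``
    applied to the DAS voxel.
``cv``
    As ``cvn`` but the variance is computed on inverse-apodized signals
    ``s_n / a_n``, removing the deterministic element-sensitivity amplitude
    profile so that the denominator reflects true channel dispersion.  The
    numerator keeps the plain coherent sum.

The variance denominator vanishes at the centre of a noiseless PSF; the
weight is regularised by clamping at ``W_MAX`` whenever the denominator
falls below ``eps`` times the numerator.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import butter, sosfiltfilt

from . import _kernels
from .forward_model import ChannelDataFrame
from .probe import ConfigurationError, ProbeGeometry, element_sensitivity, sensitivities

__all__ = [
    "element_sensitivity",
    "VoxelGrid",
    "ChannelGather",
    "PdasConfig",
    "BeamformedVolume",
    "gather",
    "das",
    "pdas",
    "cf_weight",
    "cv_weight",
    "beamform_volume",
    "beamform_multi",
    "log_compress",
    "METHODS",
]

METHODS = ("das", "pdas", "cf", "cvn", "cv")

SENSITIVITY_CUT = 0.5
CV_EPS = 1e-12
CV_WMAX = 1e6


@dataclass(frozen=True)
class VoxelGrid:
    """Regular reconstruction lattice: x lateral, y elevation, z depth (mm).

    ``origin`` is the centre of voxel (0, 0, 0); voxel positions are voxel
    centres at ``origin + index * pitch``.
    """

    origin: tuple[float, float, float]
    pitch: tuple[float, float, float]
    shape: tuple[int, int, int]

    def __post_init__(self):
        if any(p <= 0 for p in self.pitch) or any(s < 1 for s in self.shape):
            raise ConfigurationError("voxel pitch and shape must be positive")
        if self.origin[2] <= 0:
            raise ConfigurationError("all voxels must lie at z > 0")

    @classmethod
    def from_bounds(cls, bounds, pitch) -> "VoxelGrid":
        """Grid covering ``bounds = ((x0,x1),(y0,y1),(z0,z1))`` at ``pitch``."""
        if np.isscalar(pitch):
            pitch = (float(pitch),) * 3
        shape = tuple(int(round((hi - lo) / p)) + 1 for (lo, hi), p in zip(bounds, pitch))
        origin = tuple(float(lo) for lo, _ in bounds)
        return cls(origin=origin, pitch=tuple(map(float, pitch)), shape=shape)

    def axis(self, i: int) -> np.ndarray:
        return self.origin[i] + self.pitch[i] * np.arange(self.shape[i])

    @property
    def x(self) -> np.ndarray:
        return self.axis(0)

    @property
    def y(self) -> np.ndarray:
        return self.axis(1)

    @property
    def z(self) -> np.ndarray:
        return self.axis(2)

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.shape))

    def meshgrid_flat(self):
        gx, gy, gz = np.meshgrid(self.x, self.y, self.z, indexing="ij")
        return gx.ravel(), gy.ravel(), gz.ravel()

    def index_to_mm(self, index) -> np.ndarray:
        """Convert (possibly fractional) voxel indices to positions in mm."""
        index = np.asarray(index, dtype=float)
        return np.asarray(self.origin) + index * np.asarray(self.pitch)

    def mm_to_index(self, position) -> np.ndarray:
        position = np.asarray(position, dtype=float)
        return (position - np.asarray(self.origin)) / np.asarray(self.pitch)


@dataclass
class ChannelGather:
    """Delayed analytic samples and sensitivities of the active channels
    contributing to one voxel (after the 0.5-sensitivity cut)."""

    samples: np.ndarray  # complex, (n_active,)
    sensitivities: np.ndarray  # (n_active,), all >= 0.5
    channel_indices: np.ndarray  # (n_active,) indices into the probe
    valid: bool = True

    def __post_init__(self):
        self.samples = np.atleast_1d(np.asarray(self.samples, dtype=complex))
        self.sensitivities = np.atleast_1d(np.asarray(self.sensitivities, dtype=float))
        if self.channel_indices is None:
            self.channel_indices = np.arange(self.samples.size)
        self.channel_indices = np.atleast_1d(np.asarray(self.channel_indices))

    @classmethod
    def from_arrays(cls, samples, sensitivities=None) -> "ChannelGather":
        samples = np.atleast_1d(np.asarray(samples, dtype=complex))
        if sensitivities is None:
            sensitivities = np.ones(samples.size)
        elif np.isscalar(sensitivities):
            sensitivities = np.full(samples.size, float(sensitivities))
        return cls(samples, np.asarray(sensitivities, dtype=float), np.arange(samples.size))

    @property
    def n_active(self) -> int:
        return self.samples.size


@dataclass(frozen=True)
class PdasConfig:
    """p-DAS settings: root order, depth oversampling and band-pass.

    ``axial_oversample_pitch`` must not exceed ``voxel pitch / p`` so that
    harmonics up to order ``p`` of the fundamental axial frequency stay
    below the depth-sampling Nyquist limit.  The pass band is expressed as
    multiples of the fundamental axial spatial frequency ``2 f0 / c``.
    """

    p: float = 4.0
    axial_oversample_pitch: float = 0.01
    band: tuple[float, float] = (0.5, 1.5)
    filter_order: int = 4

    def __post_init__(self):
        if self.p < 1:
            raise ConfigurationError("root order p must be >= 1")
        if self.axial_oversample_pitch <= 0:
            raise ConfigurationError("axial_oversample_pitch must be positive")


@dataclass
class BeamformedVolume:
    """Per-voxel envelope image plus the weight map that produced it."""

    values: np.ndarray  # (nx, ny, nz) envelope, linear scale, >= 0
    grid: VoxelGrid
    method: str
    weight_map: np.ndarray | None = None  # W_CF / W_VN / W_V for weighted methods
    n_active: np.ndarray | None = None
    invalid_mask: np.ndarray | None = None
    complex_values: np.ndarray | None = field(default=None, repr=False)

    @property
    def peak_index(self):
        return np.unravel_index(int(np.argmax(self.values)), self.values.shape)


def log_compress(volume: BeamformedVolume, dynamic_range_db: float = 60.0) -> np.ndarray:
    """Envelope in dB relative to the volume maximum, floored at -DR."""
    peak = volume.values.max()
    if peak <= 0:
        return np.full_like(volume.values, -dynamic_range_db)
    db = 20.0 * np.log10(np.maximum(volume.values, peak * 10 ** (-dynamic_range_db / 20.0 - 1)) / peak)
    return np.maximum(db, -dynamic_range_db)


# ---------------------------------------------------------------------------
# per-voxel operations


def gather(frame: ChannelDataFrame, probe: ProbeGeometry, voxel) -> ChannelGather:
    """Delay the analytic channel signals to one voxel.

    Each channel is sampled at ``tau_n = (z + |r_n - voxel|)/c - t0`` by
    linear interpolation of the complex analytic trace.  Channels with
    element sensitivity below 0.5 or whose delay falls outside the recorded
    window are masked out; if no channel survives, the gather is flagged
    invalid.
    """
    voxel = np.asarray(voxel, dtype=float)
    a = sensitivities(probe, voxel)
    d = voxel[None, :] - probe.element_centers
    r = np.sqrt(np.sum(d * d, axis=1))
    tau = (voxel[2] + r) / probe.sound_speed - frame.t0
    fi = tau * frame.sampling_frequency
    active = (a >= SENSITIVITY_CUT) & (fi >= 0) & (fi < frame.n_samples - 1)
    idx = np.where(active)[0]
    if idx.size == 0:
        return ChannelGather(np.zeros(0, complex), np.zeros(0), idx, valid=False)
    fi = fi[idx]
    i0 = fi.astype(np.int64)
    w = fi - i0
    tr = frame.analytic
    s = tr[i0, idx] * (1.0 - w) + tr[i0 + 1, idx] * w
    return ChannelGather(s, a[idx], idx, valid=True)


def das(g: ChannelGather) -> complex:
    """Apodized coherent sum over the active channels."""
    if not g.valid or g.n_active == 0:
        return 0.0 + 0.0j
    return complex(np.sum(g.sensitivities * g.samples))


def pdas(g: ChannelGather, cfg: PdasConfig | None = None) -> complex:
    """Root-compressed sum raised to the p-th power (single voxel, unfiltered).

    The depth band-pass of the full p-DAS beamformer is a volume-level
    operation; see :func:`beamform_volume`.
    """
    cfg = cfg or PdasConfig()
    if not g.valid or g.n_active == 0:
        return 0.0 + 0.0j
    mag = np.abs(g.samples)
    nz = mag > 0
    y_hat = np.sum(np.where(nz, g.samples * mag ** (1.0 / cfg.p - 1.0), 0.0))
    m = abs(y_hat)
    if m == 0.0:
        return 0.0 + 0.0j
    return complex((y_hat / m) * m**cfg.p)


def cf_weight(g: ChannelGather) -> float:
    """Coherence factor in [0, 1]: coherent over incoherent channel energy."""
    if not g.valid or g.n_active == 0:
        return 0.0
    num = abs(np.sum(g.samples)) ** 2
    den = g.n_active * float(np.sum(np.abs(g.samples) ** 2))
    if den == 0.0:
        return 0.0
    return float(num / den)


def cv_weight(g: ChannelGather, use_inverse_apodization: bool = True) -> float:
    """Coherence-to-variance weight (>= 0).

    Numerator: coherent energy ``|sum s_n|^2``.  Denominator: the summed
    squared deviation of ``x_n`` from its channel mean, with ``x_n = s_n``
    (plain form) or ``x_n = s_n / a_n`` when inverse apodization is on.
    Needs at least two active channels; a vanishing denominator clamps the
    weight at ``CV_WMAX``.
    """
    if not g.valid or g.n_active < 2:
        return 0.0
    num = abs(np.sum(g.samples)) ** 2
    if num == 0.0:
        return 0.0
    x = g.samples / g.sensitivities if use_inverse_apodization else g.samples
    den = float(np.sum(np.abs(x - np.mean(x)) ** 2))
    if den < CV_EPS * num:
        return CV_WMAX
    return float(min(num / den, CV_WMAX))


# ---------------------------------------------------------------------------
# volume drivers


def _combine_coherence(method, n_active, y_das, s_sum, p_sum, x_sum, q_sum):
    """Turn the kernel accumulators into (envelope, weight_map)."""
    env_das = np.abs(y_das)
    n = n_active.astype(float)
    if method == "das":
        return env_das, None
    if method == "cf":
        num = np.abs(s_sum) ** 2
        den = n * p_sum
        with np.errstate(invalid="ignore", divide="ignore"):
            w = np.where(den > 0, num / den, 0.0)
        return w * env_das, w
    if method in ("cvn", "cv"):
        num = np.abs(s_sum) ** 2
        if method == "cvn":
            with np.errstate(invalid="ignore", divide="ignore"):
                den = p_sum - np.abs(s_sum) ** 2 / np.maximum(n, 1)
        else:
            with np.errstate(invalid="ignore", divide="ignore"):
                den = q_sum - np.abs(x_sum) ** 2 / np.maximum(n, 1)
        den = np.maximum(den, 0.0)
        w = np.zeros_like(num)
        ok = (n_active >= 2) & (num > 0)
        clamped = ok & (den < CV_EPS * num)
        w[clamped] = CV_WMAX
        rest = ok & ~clamped
        w[rest] = np.minimum(num[rest] / den[rest], CV_WMAX)
        return w * env_das, w
    raise ConfigurationError(f"unknown coherence method {method!r}")


def _run_coherence_pass(frame, probe, grid):
    vx, vy, vz = grid.meshgrid_flat()
    tr = np.ascontiguousarray(frame.analytic)
    return _kernels.coherence_pass(
        tr,
        frame.sampling_frequency,
        frame.t0,
        np.ascontiguousarray(probe.element_centers[:, 0]),
        np.ascontiguousarray(probe.element_centers[:, 1]),
        vx,
        vy,
        vz,
        probe.element_width,
        probe.wavelength,
        probe.sound_speed,
    )


def _beamform_pdas(frame, probe, grid, cfg: PdasConfig) -> BeamformedVolume:
    pitch_z = grid.pitch[2]
    q = cfg.axial_oversample_pitch
    if q > pitch_z / cfg.p + 1e-12:
        raise ConfigurationError(
            f"axial oversample pitch {q} too coarse for p={cfg.p} harmonics on a "
            f"{pitch_z} mm depth grid (need <= {pitch_z / cfg.p})"
        )
    ratio = int(round(pitch_z / q))
    if abs(ratio * q - pitch_z) > 1e-9:
        raise ConfigurationError("voxel depth pitch must be an integer multiple of the axial oversample pitch")
    fine = VoxelGrid(origin=grid.origin, pitch=(grid.pitch[0], grid.pitch[1], q), shape=(grid.shape[0], grid.shape[1], (grid.shape[2] - 1) * ratio + 1))
    vx, vy, vz = fine.meshgrid_flat()
    tr = np.ascontiguousarray(frame.analytic)
    n_active, y_root = _kernels.pdas_pass(
        tr,
        frame.sampling_frequency,
        frame.t0,
        np.ascontiguousarray(probe.element_centers[:, 0]),
        np.ascontiguousarray(probe.element_centers[:, 1]),
        vx,
        vy,
        vz,
        probe.element_width,
        probe.wavelength,
        probe.sound_speed,
        float(cfg.p),
    )
    mag = np.abs(y_root)
    with np.errstate(invalid="ignore", divide="ignore"):
        y = np.where(mag > 0, y_root * mag ** (cfg.p - 1.0), 0.0)
    y = y.reshape(fine.shape)
    # depth band-pass around the fundamental axial spatial frequency 2 f0 / c
    f_ax = 2.0 * probe.center_frequency / probe.sound_speed  # cycles/mm
    fs_z = 1.0 / q
    sos = butter(cfg.filter_order, (cfg.band[0] * f_ax, cfg.band[1] * f_ax), btype="bandpass", fs=fs_z, output="sos")
    y_filt = sosfiltfilt(sos, y.real, axis=2) + 1j * sosfiltfilt(sos, y.imag, axis=2)
    env = np.abs(y_filt[:, :, ::ratio])
    n_act = n_active.reshape(fine.shape)[:, :, ::ratio]
    return BeamformedVolume(values=env, grid=grid, method="pdas", n_active=n_act, invalid_mask=n_act == 0)


def beamform_multi(
    frame: ChannelDataFrame,
    probe: ProbeGeometry,
    grid: VoxelGrid,
    methods,
    pdas_config: PdasConfig | None = None,
) -> dict[str, BeamformedVolume]:
    """Beamform several methods at once, sharing the channel-sum pass.

    DAS, CF, CV_N and CV all derive from the same per-voxel channel sums, so
    requesting them together costs a single sweep over voxels x channels.
    p-DAS always runs its own depth-oversampled pass.
    """
    methods = [m.lower() for m in methods]
    unknown = set(methods) - set(METHODS)
    if unknown:
        raise ConfigurationError(f"unknown beamforming methods {sorted(unknown)}; choose from {METHODS}")
    out: dict[str, BeamformedVolume] = {}
    linear = [m for m in methods if m != "pdas"]
    if linear:
        acc = _run_coherence_pass(frame, probe, grid)
        n_active = acc[0].reshape(grid.shape)
        invalid = n_active == 0
        if invalid.any():
            warnings.warn(f"{int(invalid.sum())} voxels had no active channel and were flagged invalid")
        for m in linear:
            env, w = _combine_coherence(m, *acc)
            out[m] = BeamformedVolume(
                values=env.reshape(grid.shape),
                grid=grid,
                method=m,
                weight_map=None if w is None else w.reshape(grid.shape),
                n_active=n_active,
                invalid_mask=invalid,
                complex_values=acc[1].reshape(grid.shape) if m == "das" else None,
            )
    if "pdas" in methods:
        out["pdas"] = _beamform_pdas(frame, probe, grid, pdas_config or PdasConfig())
    return out


def beamform_volume(
    frame: ChannelDataFrame,
    probe: ProbeGeometry,
    grid: VoxelGrid,
    method: str = "das",
    pdas_config: PdasConfig | None = None,
) -> BeamformedVolume:
    """Reconstruct one volume with a single beamformer (see module docs)."""
    return beamform_multi(frame, probe, grid, [method], pdas_config=pdas_config)[method.lower()]
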