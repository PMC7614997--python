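"""Synthetic RF channel data for point scatterers under plane-wave transmit.

A single zero-degree plane wave is launched from the full aperture at
``t0``; it reaches a scatterer at depth ``z`` after ``z / c`` and the echo
reaches element ``n`` after a further ``|r_n - r_k| / c``.  Each echo is a
copy of the round-trip waveform (the transmit pulse convolved with the
identical receive impulse response), scaled by the reflection coefficient,
the receive element directivity and spherical spreading ``1 / r``.  The
transmit field of the full-aperture plane wave is taken as uniform over the
imaging volume, so no per-element transmit directivity factor is applied;
receive directivity uses the same sinc-sinc-cosine element model as the
beamformer apodization.  Echoes from multiple scatterers superpose
linearly.

The round-trip waveform is deposited with its envelope peak at the
analytic arrival time ``(z + r)/c``, so beamformed envelope maxima fall on
the true scatterer position rather than half a pulse length deeper.

The pulse is two cycles of a sine at ``f0`` under a Gaussian window whose
+/-3 sigma spans the two cycles.  Exact diffraction (element spatial
impulse responses) is not modelled.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy.signal import hilbert
from scipy.signal.windows import gaussian as gaussian_window

from .probe import ConfigurationError, ProbeGeometry, sensitivities

__all__ = [
    "ScattererSet",
    "ChannelDataFrame",
    "NoiseSpec",
    "simulate_channels",
    "add_noise",
    "scenario",
    "CrossingTubesScene",
    "round_trip_waveform",
    "required_duration",
]


@dataclass
class ScattererSet:
    """Point scatterers: positions in mm and unitless reflection coefficients."""

    positions: np.ndarray  # (K, 3) mm
    reflection_coefficients: np.ndarray  # (K,) in (0, 1]

    def __post_init__(self):
        pos = np.atleast_2d(np.asarray(self.positions, dtype=float))
        if pos.size == 0:
            pos = pos.reshape(0, 3)
        coeff = np.atleast_1d(np.asarray(self.reflection_coefficients, dtype=float))
        if pos.shape[0] != coeff.shape[0]:
            raise ValueError("positions and reflection_coefficients must have equal length")
        if np.any(coeff <= 0):
            raise ValueError("reflection coefficients must be positive")
        self.positions = pos
        self.reflection_coefficients = coeff

    def __len__(self) -> int:
        return self.positions.shape[0]

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {
                "x_mm": self.positions[:, 0],
                "y_mm": self.positions[:, 1],
                "z_mm": self.positions[:, 2],
                "coefficient": self.reflection_coefficients,
            }
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "ScattererSet":
        df = pd.read_csv(path)
        return cls(df[["x_mm", "y_mm", "z_mm"]].to_numpy(), df["coefficient"].to_numpy())


@dataclass
class ChannelDataFrame:
    """Time x element RF data for one transmit event.

    ``samples[i, n]`` is the RF amplitude of channel ``n`` at time
    ``t0 + i / sampling_frequency`` (us).  The analytic (Hilbert) signal is
    computed lazily once per frame and cached.
    """

    samples: np.ndarray  # (n_samples, N) real
    sampling_frequency: float  # MHz
    t0: float = 0.0  # us, launch time of the plane wave at z = 0
    transmit_angle: tuple[float, float] = (0.0, 0.0)
    _analytic: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2:
            raise ValueError("samples must be a (time, element) array")
        if self.sampling_frequency <= 0:
            raise ValueError("sampling_frequency must be positive")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def n_channels(self) -> int:
        return self.samples.shape[1]

    @property
    def analytic(self) -> np.ndarray:
        """Per-channel analytic signal (Hilbert transform along time)."""
        if self._analytic is None or self._analytic.shape != self.samples.shape:
            self._analytic = hilbert(self.samples, axis=0)
        return self._analytic


@dataclass(frozen=True)
class NoiseSpec:
    """Additive white Gaussian channel noise at a given channel SNR (dB)."""

    channel_snr_db: float
    rng_seed: int = 0


@lru_cache(maxsize=8)
def round_trip_waveform(f0: float, oversample: int = 64):
    """Two-way waveform: the Gaussian-windowed two-cycle pulse self-convolved.

    Returns ``(t, w, t_peak)`` where ``t`` is in us on a fine grid
    (``oversample`` samples per carrier cycle), ``w`` the unit-peak-envelope
    waveform and ``t_peak`` the time of its envelope maximum.
    """
    T = 2.0 / f0  # two carrier cycles, us
    dt = 1.0 / (oversample * f0)
    n = int(round(T / dt)) + 1
    tp = np.arange(n) * dt
    win = gaussian_window(n, std=(n - 1) / 6.0)  # +/-3 sigma over the pulse
    pulse = np.sin(2 * np.pi * f0 * tp) * win
    w = np.convolve(pulse, pulse) * dt
    t = np.arange(w.size) * dt
    env = np.abs(hilbert(w))
    peak = int(np.argmax(env))
    w = w / env[peak]
    return t, w, t[peak]


def required_duration(probe: ProbeGeometry, z_max: float, transverse_margin: float = 0.0) -> float:
    """Recording time (us) covering the two-way path to the deepest voxel."""
    ex = probe.element_centers[:, 0]
    ey = probe.element_centers[:, 1]
    half_x = np.max(np.abs(ex)) + transverse_margin
    half_y = np.max(np.abs(ey)) + transverse_margin
    r_max = np.sqrt(half_x**2 + half_y**2 + z_max**2)
    t, _, t_peak = round_trip_waveform(probe.center_frequency)
    return (z_max + r_max) / probe.sound_speed + (t[-1] - t_peak) + 0.5


def simulate_channels(
    probe: ProbeGeometry,
    scatterers: ScattererSet,
    fs: float | None = None,
    duration: float | None = None,
    t0: float = 0.0,
) -> ChannelDataFrame:
    """Simulate RF channel data for one plane-wave transmit event.

    Parameters
    ----------
    probe, scatterers
        Geometry and targets; all scatterers must satisfy ``z > 0``.
    fs
        Sampling frequency in MHz, default ``4 * f0``.
    duration
        Recording length in us; must cover the deepest echo.  Defaults to
        the two-way time of the deepest scatterer plus the pulse tail.
    """
    if fs is None:
        fs = 4.0 * probe.center_frequency
    if fs < 4.0 * probe.center_frequency:
        raise ConfigurationError("fs must be at least 4 x f0")
    if len(scatterers) and np.any(scatterers.positions[:, 2] <= 0):
        raise ValueError("scatterers must lie in front of the probe (z > 0)")

    tw, w, t_peak = round_trip_waveform(probe.center_frequency)
    tail = tw[-1] - t_peak

    if duration is None:
        if len(scatterers):
            duration = required_duration(probe, float(np.max(scatterers.positions[:, 2])))
        else:
            duration = 10.0
    n_samples = int(np.ceil(duration * fs)) + 1
    samples = np.zeros((n_samples, probe.n_elements))

    centers = probe.element_centers
    c = probe.sound_speed
    n_w = int(np.ceil(tw[-1] * fs)) + 2  # samples spanned by the waveform

    for k in range(len(scatterers)):
        pos = scatterers.positions[k]
        coeff = scatterers.reflection_coefficients[k]
        d = pos[None, :] - centers
        r = np.sqrt(np.sum(d * d, axis=1))
        a_rx = sensitivities(probe, pos)
        amp = coeff * a_rx / r
        arrival = (pos[2] + r) / c  # envelope-peak arrival, us
        if np.max(arrival) + tail > t0 + duration:
            raise ValueError(
                "duration too short to capture the deepest echo: need at least "
                f"{np.max(arrival) + tail - t0:.2f} us"
            )
        start = arrival - t_peak
        i0 = np.ceil((start - t0) * fs).astype(np.int64)
        offsets = np.arange(n_w)
        idx = i0[:, None] + offsets[None, :]
        t_rel = (idx / fs + t0) - start[:, None]
        vals = amp[:, None] * np.interp(t_rel, tw, w, left=0.0, right=0.0)
        valid = (idx >= 0) & (idx < n_samples)
        cols = np.broadcast_to(np.arange(probe.n_elements)[:, None], idx.shape)
        np.add.at(samples, (idx[valid], cols[valid]), vals[valid])

    return ChannelDataFrame(samples=samples, sampling_frequency=float(fs), t0=float(t0))


def add_noise(frame: ChannelDataFrame, spec: NoiseSpec) -> ChannelDataFrame:
    """Add white Gaussian noise at a prescribed channel SNR.

    The reference signal power is the mean squared RF amplitude over the
    echo-bearing support, defined as samples whose noiseless envelope
    exceeds 1 % of the frame maximum; white noise of power
    ``P_signal / 10^(SNR/10)`` is then added to every sample.  The same
    seed always produces the same realization.
    """
    if np.isinf(spec.channel_snr_db):
        return ChannelDataFrame(frame.samples.copy(), frame.sampling_frequency, frame.t0, frame.transmit_angle)
    env = np.abs(frame.analytic)
    peak = env.max()
    if peak == 0.0:
        raise ValueError("cannot calibrate noise on an all-zero frame")
    support = env > 0.01 * peak
    p_signal = float(np.mean(frame.samples[support] ** 2))
    p_noise = p_signal / 10.0 ** (spec.channel_snr_db / 10.0)
    rng = np.random.default_rng(spec.rng_seed)
    noisy = frame.samples + rng.normal(0.0, np.sqrt(p_noise), size=frame.samples.shape)
    return ChannelDataFrame(noisy, frame.sampling_frequency, frame.t0, frame.transmit_angle)


# ---------------------------------------------------------------------------
# scenario builders


class CrossingTubesScene:
    """Bubble flow through two 200 um tubes crossing at a small angle.

    Both tubes run along the lateral axis, are slightly separated in
    elevation, and cross in depth at ``crossing_angle_deg``.  Bubbles are
    seeded Poisson-uniformly along each lumen with uniform radial jitter
    and advected at a constant speed per tube; a bubble leaving the far
    end re-enters at the start.  The scene behaves as a sequence of
    :class:`ScattererSet`, one per frame.
    """

    def __init__(
        self,
        n_frames: int = 10,
        bubbles_per_tube: float = 3.0,
        frame_rate: float = 500.0,
        x_extent: tuple[float, float] = (-2.0, 2.0),
        depth: float = 20.0,
        y_offsets: tuple[float, float] = (0.25, -0.25),
        crossing_angle_deg: float = 3.0,
        radius: float = 0.1,
        speeds: tuple[float, float] = (20.0, 25.0),  # mm/s
        seed: int = 0,
    ):
        self.n_frames = int(n_frames)
        self.frame_rate = float(frame_rate)
        self.x_extent = (float(x_extent[0]), float(x_extent[1]))
        self.depth = float(depth)
        self.y_offsets = (float(y_offsets[0]), float(y_offsets[1]))
        self.radius = float(radius)
        self.speeds = (float(speeds[0]), float(speeds[1]))
        # each tube tilts by half the crossing angle, in opposite senses
        half = np.deg2rad(crossing_angle_deg) / 2.0
        self.slopes = (np.tan(half), -np.tan(half))
        rng = np.random.default_rng(seed)
        length = self.x_extent[1] - self.x_extent[0]
        self._frames: list[ScattererSet] = []
        # persistent bubble state per tube: along-axis position + radial offset
        state = []
        for tube in range(2):
            n_b = rng.poisson(bubbles_per_tube)
            x = rng.uniform(0.0, length, n_b)
            rad = self.radius * np.sqrt(rng.uniform(0.0, 1.0, n_b))
            ang = rng.uniform(0.0, 2 * np.pi, n_b)
            coeff = rng.uniform(0.5, 1.0, n_b)
            state.append([x, rad, ang, coeff])
        for f in range(self.n_frames):
            pos_all, coeff_all = [], []
            for tube in range(2):
                x, rad, ang, coeff = state[tube]
                xg = self.x_extent[0] + np.mod(x, length)
                yc = self.y_offsets[tube] + rad * np.cos(ang)
                zc = self.depth + self.slopes[tube] * xg + rad * np.sin(ang)
                pos_all.append(np.column_stack([xg, yc, zc]))
                coeff_all.append(coeff)
                state[tube][0] = x + self.speeds[tube] / self.frame_rate
            pos = np.concatenate(pos_all) if pos_all else np.zeros((0, 3))
            coeff = np.concatenate(coeff_all) if coeff_all else np.zeros(0)
            if pos.shape[0]:
                self._frames.append(ScattererSet(pos, coeff))
            else:
                self._frames.append(ScattererSet(np.zeros((0, 3)), np.zeros(0)))

    def __len__(self) -> int:
        return self.n_frames

    def __getitem__(self, i: int) -> ScattererSet:
        return self._frames[i]

    def __iter__(self):
        return iter(self._frames)

    def tube_centerline(self, tube: int, x: np.ndarray) -> np.ndarray:
        """Centerline points of tube 0 or 1 at lateral positions ``x`` (mm)."""
        x = np.asarray(x, dtype=float)
        y = np.full_like(x, self.y_offsets[tube])
        z = self.depth + self.slopes[tube] * x
        return np.column_stack([x, y, z])

    def in_lumen(self, points: np.ndarray, tolerance: float = 0.0) -> np.ndarray:
        """Boolean mask: which points lie inside either tube lumen."""
        points = np.atleast_2d(np.asarray(points, dtype=float))
        inside = np.zeros(points.shape[0], dtype=bool)
        for tube in range(2):
            dy = points[:, 1] - self.y_offsets[tube]
            dz = points[:, 2] - (self.depth + self.slopes[tube] * points[:, 0])
            # distance to the tilted axis; the tilt is tiny so the transverse
            # plane is taken perpendicular to x to first order
            cos_t = 1.0 / np.sqrt(1.0 + self.slopes[tube] ** 2)
            inside |= np.hypot(dy, dz * cos_t) <= self.radius + tolerance
        return inside


_SCENARIOS = ("single_strong", "single_weak", "five_axial", "random_volume", "crossing_tubes")


def scenario(name: str, params: dict | None = None, seed: int = 0):
    """Build one of the canonical simulation scenes.

    ``single_strong`` / ``single_weak``: one on-axis scatterer at 20 mm with
    reflection coefficient 1 / 0.1.  ``five_axial``: five on-axis scatterers
    at 15, 17.5, 20, 22.5 and 25 mm with coefficients decreasing from 1 to
    0.1 in equal steps.  ``random_volume``: 100 scatterers uniform in a
    10 x 8 x 8 mm^3 box with coefficients uniform on [0.1, 1].
    ``crossing_tubes``: a frame sequence of bubbles flowing through two
    200 um tubes crossing at 3 degrees (returns a
    :class:`CrossingTubesScene`).
    """
    params = dict(params or {})
    if name == "single_strong" or name == "single_weak":
        depth = float(params.pop("depth", 20.0))
        coeff = 1.0 if name == "single_strong" else 0.1
        return ScattererSet(np.array([[0.0, 0.0, depth]]), np.array([coeff]))
    if name == "five_axial":
        depths = np.linspace(15.0, 25.0, 5)
        coeffs = np.linspace(1.0, 0.1, 5)
        pos = np.column_stack([np.zeros(5), np.zeros(5), depths])
        return ScattererSet(pos, coeffs)
    if name == "random_volume":
        box = params.pop("box", ((-5.0, 5.0), (-4.0, 4.0), (16.0, 24.0)))
        n = int(params.pop("n_scatterers", 100))
        rng = np.random.default_rng(seed)
        pos = np.column_stack([rng.uniform(lo, hi, n) for lo, hi in box])
        coeff = rng.uniform(0.1, 1.0, n)
        return ScattererSet(pos, coeff)
    if name == "crossing_tubes":
        return CrossingTubesScene(seed=seed, **params)
    raise ConfigurationError(f"unknown scenario {name!r}; choose from {_SCENARIOS}")
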