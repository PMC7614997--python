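"""Super-resolution localization pipeline.

The processing chain for a multi-frame acquisition is: SVD clutter
filtering of the channel data, beamforming each frame with the chosen
method, 3D normalized cross-correlation (NCC) against a simulated PSF
template of that method, thresholding and regional-maximum detection,
sub-voxel localization by cubic-spline up-sampling of a 5x5x5 patch, and
accumulation of all localizations into a density map on a finer grid.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline
from skimage.feature import match_template
from skimage.morphology import local_maxima

from .beamformers import BeamformedVolume, PdasConfig, VoxelGrid, beamform_volume
from .forward_model import ChannelDataFrame, ScattererSet, simulate_channels
from .probe import ConfigurationError, ProbeGeometry

__all__ = [
    "FrameStack",
    "LocalizationSet",
    "DensityMap",
    "PipelineConfig",
    "svd_clutter_filter",
    "ncc3d",
    "detect_and_localize",
    "accumulate",
    "run_pipeline",
    "psf_template",
]

logger = logging.getLogger(__name__)


@dataclass
class FrameStack:
    """Ordered channel-data frames sharing geometry and sampling."""

    frames: list[ChannelDataFrame]
    frame_rate: float = 500.0  # Hz

    def __post_init__(self):
        if len(self.frames) > 1:
            ref = self.frames[0]
            for f in self.frames[1:]:
                if f.samples.shape != ref.samples.shape or f.sampling_frequency != ref.sampling_frequency:
                    raise ValueError("all frames must share sampling and channel count")

    def __len__(self) -> int:
        return len(self.frames)

    def __iter__(self):
        return iter(self.frames)


@dataclass
class LocalizationSet:
    """Sub-voxel localization records.

    Columns: ``frame`` index, position ``x_mm, y_mm, z_mm`` at 1/10-voxel
    precision, NCC coefficient and peak intensity.
    """

    records: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["frame", "x_mm", "y_mm", "z_mm", "ncc", "intensity"])
    )

    def __len__(self) -> int:
        return len(self.records)

    @property
    def positions(self) -> np.ndarray:
        return self.records[["x_mm", "y_mm", "z_mm"]].to_numpy(dtype=float)

    def to_csv(self, path) -> None:
        self.records.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "LocalizationSet":
        return cls(pd.read_csv(path))

    @classmethod
    def concatenate(cls, sets) -> "LocalizationSet":
        frames = [s.records for s in sets if len(s)]
        if not frames:
            return cls()
        return cls(pd.concat(frames, ignore_index=True))


@dataclass
class DensityMap:
    """Per-voxel localization counts on the super-resolution grid."""

    counts: np.ndarray
    grid: VoxelGrid
    n_dropped: int = 0

    @property
    def total(self) -> int:
        return int(self.counts.sum())


# ---------------------------------------------------------------------------
# SVD clutter filter


def svd_clutter_filter(
    stack: FrameStack,
    rank_cut: int | None = None,
    sv_threshold: float | None = None,
) -> FrameStack:
    """Remove quasi-static clutter by truncating dominant singular components.

    The channel data are arranged as a Casorati matrix (all space-time
    samples of a frame in rows, frames in columns) and decomposed by SVD.
    With ``rank_cut`` the that many largest singular components are zeroed
    (the usual clutter-filter parameterisation); with ``sv_threshold``
    every component whose singular value is at least the threshold is
    zeroed instead.  The removal is a projection onto the complement of
    the clutter subspace: the filtered frames contain no energy along the
    removed singular vectors, and in threshold mode re-applying the same
    filter changes nothing (in rank mode a second application removes the
    *next* ``rank_cut`` largest components, by construction).
    """
    if len(stack) < 2:
        raise ConfigurationError("SVD clutter filtering needs at least 2 frames")
    if (rank_cut is None) == (sv_threshold is None):
        raise ConfigurationError("give exactly one of rank_cut or sv_threshold")
    if rank_cut is not None and rank_cut >= len(stack):
        raise ConfigurationError("rank_cut must be smaller than the frame count")
    if rank_cut == 0:
        return FrameStack(
            [ChannelDataFrame(f.samples.copy(), f.sampling_frequency, f.t0) for f in stack.frames],
            stack.frame_rate,
        )
    shape = stack.frames[0].samples.shape
    x = np.stack([f.samples.ravel() for f in stack.frames], axis=1)
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    s = s.copy()
    if rank_cut is not None:
        s[:rank_cut] = 0.0
    else:
        s[s >= sv_threshold] = 0.0
    filtered = (u * s) @ vt
    frames = [
        ChannelDataFrame(filtered[:, i].reshape(shape), f.sampling_frequency, f.t0)
        for i, f in enumerate(stack.frames)
    ]
    return FrameStack(frames, stack.frame_rate)


# ---------------------------------------------------------------------------
# NCC and detection


def ncc3d(volume, template: np.ndarray) -> np.ndarray:
    """Pearson-type normalized cross-correlation of a PSF template at every
    voxel (sliding window, zero-mean normalised); values lie in [-1, 1].
    Flat windows (zero variance) yield coefficient 0."""
    values = volume.values if isinstance(volume, BeamformedVolume) else np.asarray(volume, dtype=float)
    template = np.asarray(template, dtype=float)
    if any(ts > vs for ts, vs in zip(template.shape, values.shape)):
        raise ValueError("template must be smaller than the volume")
    with np.errstate(invalid="ignore", divide="ignore"):
        coeff = match_template(values, template, pad_input=True)
    return np.clip(np.nan_to_num(coeff), -1.0, 1.0)


@lru_cache(maxsize=16)
def _spline_upsample_matrix(n: int, factor: int) -> np.ndarray:
    """Matrix mapping ``n`` samples to ``(n-1)*factor + 1`` cubic-spline
    (not-a-knot) interpolated samples along one axis."""
    coarse = np.arange(n, dtype=float)
    fine = np.arange((n - 1) * factor + 1, dtype=float) / factor
    m = np.empty((fine.size, n))
    for j in range(n):
        e = np.zeros(n)
        e[j] = 1.0
        m[:, j] = CubicSpline(coarse, e, bc_type="not-a-knot")(fine)
    return m


def _upsample_patch(patch: np.ndarray, factor: int = 10) -> np.ndarray:
    """Separable cubic-spline up-sampling of a cubic patch."""
    out = patch
    for axis in range(3):
        m = _spline_upsample_matrix(patch.shape[axis], factor)
        out = np.moveaxis(np.tensordot(m, np.moveaxis(out, axis, 0), axes=(1, 0)), 0, axis)
    return out


def detect_and_localize(
    coeff: np.ndarray,
    intensity: np.ndarray,
    grid: VoxelGrid,
    ncc_threshold: float = 0.3,
    bg_threshold_db: float | None = None,
    intensity_reference: float | None = None,
    frame_index: int = 0,
    patch_half: int = 2,
    upsample: int = 10,
    max_peaks: int | None = None,
) -> LocalizationSet:
    """Detect correlation peaks and localize them with sub-voxel precision.

    Voxels whose intensity lies below ``bg_threshold_db`` (dB relative to
    ``intensity_reference``, default the volume maximum) are zeroed on the
    coefficient map; regional maxima (26-connectivity) at or above
    ``ncc_threshold`` become candidate peaks.  Peaks within ``patch_half``
    voxels of the border are discarded.  Each surviving peak's
    ``(2*patch_half+1)^3`` patch of the coefficient map is up-sampled
    ``upsample``-fold per axis with a not-a-knot cubic spline and the patch
    argmax gives the localization at 1/``upsample``-voxel precision.
    """
    coeff = np.asarray(coeff, dtype=float)
    intensity = np.asarray(intensity, dtype=float)
    if coeff.shape != intensity.shape:
        raise ValueError("coefficient and intensity volumes must share a shape")
    work = coeff.copy()
    if bg_threshold_db is not None:
        ref = intensity.max() if intensity_reference is None else intensity_reference
        if ref > 0:
            work[intensity < ref * 10.0 ** (bg_threshold_db / 20.0)] = 0.0
    if not np.any(work >= ncc_threshold) or work.max() <= work.min():
        return LocalizationSet()
    peaks = np.argwhere(local_maxima(work, connectivity=3) & (work >= ncc_threshold))
    shape = np.asarray(coeff.shape)
    interior = np.all((peaks >= patch_half) & (peaks <= shape - 1 - patch_half), axis=1)
    if (~interior).any():
        warnings.warn(f"{int((~interior).sum())} peaks within {patch_half} voxels of the border discarded")
    peaks = peaks[interior]
    if peaks.shape[0] == 0:
        return LocalizationSet()
    peak_int = intensity[tuple(peaks.T)]
    order = np.argsort(peak_int, kind="stable")[::-1]
    if max_peaks is not None:
        order = order[:max_peaks]
    peaks = peaks[order]
    peak_int = peak_int[order]
    rows = []
    for (ix, iy, iz), inten in zip(peaks, peak_int):
        patch = coeff[
            ix - patch_half : ix + patch_half + 1,
            iy - patch_half : iy + patch_half + 1,
            iz - patch_half : iz + patch_half + 1,
        ]
        up = _upsample_patch(patch, upsample)
        sub = np.unravel_index(int(np.argmax(up)), up.shape)
        frac_idx = np.array([ix, iy, iz], dtype=float) - patch_half + np.asarray(sub) / upsample
        pos = grid.index_to_mm(frac_idx)
        rows.append((frame_index, pos[0], pos[1], pos[2], coeff[ix, iy, iz], inten))
    return LocalizationSet(pd.DataFrame(rows, columns=["frame", "x_mm", "y_mm", "z_mm", "ncc", "intensity"]))


def accumulate(localizations: LocalizationSet, sr_grid: VoxelGrid) -> DensityMap:
    """Count localizations per super-resolution voxel (mass conserving)."""
    pos = localizations.positions
    if pos.shape[0] == 0:
        return DensityMap(np.zeros(tuple(sr_grid.shape), dtype=np.int64), sr_grid, 0)
    idx = np.round(sr_grid.mm_to_index(pos)).astype(int)
    inside = np.all((idx >= 0) & (idx < np.asarray(sr_grid.shape)), axis=1)
    n_dropped = int((~inside).sum())
    if n_dropped:
        logger.info("%d localizations fell outside the SR grid and were dropped", n_dropped)
    counts = np.zeros(tuple(sr_grid.shape), dtype=np.int64)
    np.add.at(counts, tuple(idx[inside].T), 1)
    return DensityMap(counts, sr_grid, n_dropped)


# ---------------------------------------------------------------------------
# full pipeline


def psf_template(
    probe: ProbeGeometry,
    method: str,
    depth: float,
    pitch,
    size: int = 11,
    fs: float | None = None,
    pdas_config: PdasConfig | None = None,
) -> np.ndarray:
    """Simulated PSF of one beamformer: a single unit point scatterer at
    ``(0, 0, depth)`` reconstructed on a ``size^3`` patch, peak-normalised."""
    if np.isscalar(pitch):
        pitch = (float(pitch),) * 3
    half = (size - 1) / 2.0
    origin = (-half * pitch[0], -half * pitch[1], depth - half * pitch[2])
    grid = VoxelGrid(origin=origin, pitch=tuple(pitch), shape=(size, size, size))
    scat = ScattererSet(np.array([[0.0, 0.0, depth]]), np.array([1.0]))
    frame = simulate_channels(probe, scat, fs=fs)
    vol = beamform_volume(frame, probe, grid, method, pdas_config=pdas_config)
    peak = vol.values.max()
    return vol.values / peak if peak > 0 else vol.values


@dataclass
class PipelineConfig:
    """Settings for :func:`run_pipeline`."""

    method: str = "cv"
    rank_cut: int | None = None  # default: 10% of the frame count
    ncc_threshold: float = 0.3
    bg_threshold_db: float | None = None
    sr_pitch: float | None = None  # default: beamforming pitch / 5
    template_size: int = 11
    template_depth: float | None = None  # default: grid centre depth
    pdas_config: PdasConfig | None = None
    # motion-correction hook: callable(volume, frame_index) -> volume; the
    # default identity leaves frames untouched (no motion in simulation)
    motion_correction: object = None


def run_pipeline(
    stack: FrameStack,
    probe: ProbeGeometry,
    grid: VoxelGrid,
    config: PipelineConfig | None = None,
) -> tuple[DensityMap, LocalizationSet]:
    """SVD filter -> beamform -> NCC -> detect/localize -> density map.

    Stage counts are logged; the background threshold is applied relative
    to the beamformed sequence maximum, as the per-method thresholds are
    in the acquisition protocol.  Returns the density map on the SR grid
    together with all localizations.
    """
    config = config or PipelineConfig()
    if len(stack) == 0:
        sr_grid = _sr_grid(grid, config)
        return DensityMap(np.zeros(tuple(sr_grid.shape), dtype=np.int64), sr_grid, 0), LocalizationSet()
    rank_cut = config.rank_cut
    if rank_cut is None:
        rank_cut = max(len(stack) // 10, 0)
    if rank_cut > 0 and len(stack) > 1:
        stack = svd_clutter_filter(stack, rank_cut)
        logger.info("SVD clutter filter removed %d components over %d frames", rank_cut, len(stack))
    depth = config.template_depth
    if depth is None:
        depth = grid.origin[2] + grid.pitch[2] * (grid.shape[2] - 1) / 2.0
    template = psf_template(
        probe,
        config.method,
        depth,
        grid.pitch,
        size=config.template_size,
        fs=stack.frames[0].sampling_frequency,
        pdas_config=config.pdas_config,
    )
    volumes = []
    for i, frame in enumerate(stack):
        vol = beamform_volume(frame, probe, grid, config.method, pdas_config=config.pdas_config)
        if callable(config.motion_correction):
            vol = config.motion_correction(vol, i)
        volumes.append(vol)
    seq_max = max(v.values.max() for v in volumes)
    per_frame = []
    for i, vol in enumerate(volumes):
        coeff = ncc3d(vol, template)
        locs = detect_and_localize(
            coeff,
            vol.values,
            grid,
            ncc_threshold=config.ncc_threshold,
            bg_threshold_db=config.bg_threshold_db,
            intensity_reference=seq_max,
            frame_index=i,
        )
        logger.info("frame %d: %d localizations", i, len(locs))
        per_frame.append(locs)
    all_locs = LocalizationSet.concatenate(per_frame)
    sr_grid = _sr_grid(grid, config)
    density = accumulate(all_locs, sr_grid)
    logger.info("accumulated %d localizations (%d dropped)", density.total, density.n_dropped)
    return density, all_locs


def _sr_grid(grid: VoxelGrid, config: PipelineConfig) -> VoxelGrid:
    sr_pitch = config.sr_pitch if config.sr_pitch is not None else grid.pitch[0] / 5.0
    if sr_pitch > min(grid.pitch) + 1e-12:
        raise ConfigurationError("SR grid pitch must not exceed the beamforming pitch")
    extent = [grid.pitch[i] * (grid.shape[i] - 1) for i in range(3)]
    shape = tuple(int(np.floor(extent[i] / sr_pitch)) + 1 for i in range(3))
    return VoxelGrid(origin=grid.origin, pitch=(sr_pitch,) * 3, shape=shape)


def background_threshold_for_count(
    sweep_volumes,
    grid: VoxelGrid,
    target_count: int,
    ncc_threshold: float = 0.3,
    db_range=(-60.0, -5.0),
    tolerance: float = 0.02,
    max_iter: int = 20,
) -> float:
    """Find a background threshold (dB) giving ``target_count`` localizations.

    Bisects the threshold so that the total localization count over the
    supplied (coefficient, intensity) volume pairs lands within
    ``tolerance`` (fractional) of the target; used to match localization
    counts across beamformers before comparing density maps.
    """
    seq_max = max(float(np.max(i)) for _, i in sweep_volumes)

    def count_at(db):
        total = 0
        for coeff, inten in sweep_volumes:
            total += len(
                detect_and_localize(
                    coeff, inten, grid, ncc_threshold=ncc_threshold, bg_threshold_db=db, intensity_reference=seq_max
                )
            )
        return total

    lo, hi = db_range  # counts decrease as the threshold rises
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        c = count_at(mid)
        if abs(c - target_count) <= tolerance * target_count:
            return mid
        if c > target_count:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)
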