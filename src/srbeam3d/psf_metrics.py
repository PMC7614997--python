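"""Point-spread-function and image-quality metrics.

Covers the quantities used to compare beamformers on point-target scenes:
full width at half maximum (FWHM), self / cross peak side-to-main-lobe
ratios (SPSMR, CPSMR, max-PSMR), image SNR against a noise-only region,
localization TPR/FPR curves with area under the curve, and Fourier shell
correlation (FSC) with the half-bit resolution threshold.

All widths and positions are in mm on the volume's voxel grid; ratios are
reported in dB (20 log10 of amplitude ratios).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .beamformers import BeamformedVolume, VoxelGrid

__all__ = [
    "PsfReport",
    "RocCurve",
    "FscResult",
    "fwhm",
    "psmr",
    "lobe_analysis",
    "image_snr",
    "noise_region_mask",
    "tpr_fpr",
    "fourier_shell_correlation",
]


# ---------------------------------------------------------------------------
# FWHM


def _half_crossing(profile: np.ndarray, peak: int, half: float, step: int) -> float:
    """Fractional index offset from ``peak`` to the half-max crossing in
    direction ``step`` (+1/-1); NaN if the profile never falls below half."""
    i = peak
    while 0 <= i + step < profile.size:
        j = i + step
        if profile[j] < half:
            # linear interpolation between i and j
            frac = (profile[i] - half) / (profile[i] - profile[j])
            return abs(i - peak) + frac
        i = j
    return np.nan


def fwhm(volume: BeamformedVolume, peak_index, axis: int) -> float:
    """Full width at half maximum (mm) of the profile through ``peak_index``
    along ``axis`` (0 lateral, 1 elevation, 2 axial).

    Half-max crossings are located by linear interpolation between voxels.
    Returns NaN (with a warning) if the profile never falls below half the
    peak inside the grid.
    """
    peak_index = tuple(int(i) for i in peak_index)
    sl = list(peak_index)
    sl[axis] = slice(None)
    profile = np.asarray(volume.values[tuple(sl)], dtype=float)
    p = peak_index[axis]
    half = profile[p] / 2.0
    if profile[p] <= 0:
        raise ValueError("peak value must be positive")
    left = _half_crossing(profile, p, half, -1)
    right = _half_crossing(profile, p, half, +1)
    if np.isnan(left) or np.isnan(right):
        warnings.warn("profile never falls below half maximum inside the grid; FWHM undefined")
        return np.nan
    return float((left + right) * volume.grid.pitch[axis])


# ---------------------------------------------------------------------------
# PSMR


def _null_radius(volume: BeamformedVolume, peak_index, axis: int, fallback: float) -> float:
    """Distance (mm) from the peak to the first beam null along ``axis``.

    Walks outward in both directions until the profile turns upward after
    falling below half the peak; the two distances are averaged.  Falls
    back to ``fallback`` when no null is found before the grid border.
    """
    sl = list(int(i) for i in peak_index)
    p = sl[axis]
    sl[axis] = slice(None)
    profile = np.asarray(volume.values[tuple(sl)], dtype=float)
    half = profile[p] / 2.0
    dists = []
    for step in (-1, 1):
        i = p
        found = np.nan
        while 0 <= i + step < profile.size:
            j = i + step
            if profile[j] > profile[i] and profile[i] < half:
                found = abs(i - p)
                break
            i = j
        dists.append(found)
    dists = [d for d in dists if not np.isnan(d)]
    if not dists:
        return fallback
    return float(np.mean(dists) * volume.grid.pitch[axis])


@dataclass
class _Lobe:
    """Main-lobe descriptor for one scatterer in one volume."""

    peak_index: tuple[int, int, int]
    peak_position: np.ndarray  # mm
    peak_value: float
    fwhm_lateral: float
    fwhm_elevation: float
    fwhm_axial: float
    radii: tuple[float, float, float]  # main-lobe semi-axes, mm
    side_peak: float = np.nan


def lobe_analysis(
    volume: BeamformedVolume,
    truth_mm,
    search_radius: float = 0.5,
    main_lobe_radius: float | None = None,
    depth_halfwidth: float = 1.0,
    exclude_masks: list[np.ndarray] | None = None,
) -> _Lobe:
    """Locate the main lobe belonging to one true scatterer and measure it.

    The peak is the maximum within ``search_radius`` of the truth position.
    The main-lobe extent per axis is the distance to the first beam null
    (fallback: 1.2 x FWHM); the side-lobe peak is the maximum outside the
    main lobe within a ``+/- depth_halfwidth`` depth slab.
    """
    grid = volume.grid
    truth = np.asarray(truth_mm, dtype=float)
    idx = grid.mm_to_index(truth)
    lo = np.maximum(np.round(idx - search_radius / np.asarray(grid.pitch)).astype(int), 0)
    hi = np.minimum(np.round(idx + search_radius / np.asarray(grid.pitch)).astype(int) + 1, grid.shape)
    sub = volume.values[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]]
    if sub.size == 0 or sub.max() <= 0:
        raise ValueError("no detectable peak near the truth position")
    peak = tuple(np.array(np.unravel_index(int(np.argmax(sub)), sub.shape)) + lo)
    widths = [fwhm(volume, peak, ax) for ax in range(3)]
    if main_lobe_radius is not None:
        radii = (main_lobe_radius,) * 3
    else:
        radii = tuple(
            _null_radius(volume, peak, ax, fallback=1.2 * w if np.isfinite(w) else 3 * grid.pitch[ax])
            for ax, w in enumerate(widths)
        )
    lobe = _Lobe(
        peak_index=peak,
        peak_position=grid.index_to_mm(peak),
        peak_value=float(volume.values[peak]),
        fwhm_lateral=widths[0],
        fwhm_elevation=widths[1],
        fwhm_axial=widths[2],
        radii=radii,
    )
    lobe.side_peak = side_lobe_peak(volume, [lobe], lobe, depth_halfwidth, exclude_masks)
    return lobe


def _main_mask(grid: VoxelGrid, lobe: _Lobe) -> np.ndarray:
    """Ellipsoidal main-lobe mask with the lobe's per-axis null radii."""
    axes = [grid.axis(i) - lobe.peak_position[i] for i in range(3)]
    rx, ry, rz = (max(r, grid.pitch[i]) for i, r in enumerate(lobe.radii))
    gx, gy, gz = np.meshgrid(axes[0] / rx, axes[1] / ry, axes[2] / rz, indexing="ij", sparse=True)
    return gx**2 + gy**2 + gz**2 <= 1.0


def side_lobe_peak(
    volume: BeamformedVolume,
    all_lobes: list[_Lobe],
    lobe: _Lobe,
    depth_halfwidth: float = 1.0,
    extra_masks: list[np.ndarray] | None = None,
) -> float:
    """Highest value outside every main lobe within this lobe's depth slab."""
    grid = volume.grid
    mask = np.zeros(volume.values.shape, dtype=bool)
    for lb in all_lobes:
        mask |= _main_mask(grid, lb)
    if extra_masks:
        for m in extra_masks:
            mask |= m
    slab = np.abs(grid.z - lobe.peak_position[2]) <= depth_halfwidth
    search = volume.values[:, :, slab]
    excl = mask[:, :, slab]
    vals = search[~excl]
    if vals.size == 0:
        return np.nan
    return float(vals.max())


@dataclass
class PsfReport:
    """Per-scatterer PSF measurements and the cross-PSMR matrix (dB)."""

    fwhm_lateral: np.ndarray
    fwhm_elevation: np.ndarray
    fwhm_axial: np.ndarray
    peak_values: np.ndarray
    peak_positions: np.ndarray  # (K, 3) mm
    cpsmr: np.ndarray  # (K, K) dB; entry (i, j) = side lobe i over main lobe j
    side_peaks: np.ndarray = field(default=None)

    @property
    def spsmr(self) -> np.ndarray:
        """Self-PSMR per scatterer: the CPSMR diagonal."""
        return np.diag(self.cpsmr)

    @property
    def max_psmr(self) -> float:
        return float(np.nanmax(self.cpsmr))

    @property
    def mean_transverse_fwhm(self) -> float:
        return float(np.nanmean(np.concatenate([self.fwhm_lateral, self.fwhm_elevation])))

    @classmethod
    def from_lobes(cls, lobes: list[_Lobe]) -> "PsfReport":
        mains = np.array([lb.peak_value for lb in lobes])
        sides = np.array([lb.side_peak for lb in lobes])
        with np.errstate(divide="ignore", invalid="ignore"):
            cpsmr = 20.0 * np.log10(sides[:, None] / mains[None, :])
        return cls(
            fwhm_lateral=np.array([lb.fwhm_lateral for lb in lobes]),
            fwhm_elevation=np.array([lb.fwhm_elevation for lb in lobes]),
            fwhm_axial=np.array([lb.fwhm_axial for lb in lobes]),
            peak_values=mains,
            peak_positions=np.array([lb.peak_position for lb in lobes]),
            cpsmr=cpsmr,
            side_peaks=sides,
        )


def psmr(
    volume: BeamformedVolume,
    truth_positions,
    main_lobe_radius: float | None = None,
    depth_halfwidth: float = 1.0,
    search_radius: float = 0.5,
) -> PsfReport:
    """PSF report for a multi-scatterer volume.

    For each truth position the main lobe is located and bounded by its
    beam nulls (or by ``main_lobe_radius`` if given); side-lobe peaks are
    searched outside *all* main lobes within each scatterer's depth slab.
    ``CPSMR[i, j] = 20 log10(side peak of i / main peak of j)``; the
    diagonal is the conventional (self-)PSMR and the matrix maximum is the
    max-PSMR.
    """
    truths = np.atleast_2d(np.asarray(truth_positions, dtype=float))
    lobes = []
    for t in truths:
        lobes.append(
            lobe_analysis(
                volume,
                t,
                search_radius=search_radius,
                main_lobe_radius=main_lobe_radius,
                depth_halfwidth=depth_halfwidth,
            )
        )
    # overlapping main lobes are effectively merged by the OR of the masks
    for lb in lobes:
        lb.side_peak = side_lobe_peak(volume, lobes, lb, depth_halfwidth)
    return PsfReport.from_lobes(lobes)


# ---------------------------------------------------------------------------
# image SNR


def noise_region_mask(grid: VoxelGrid, truth_positions, min_distance: float = 1.5) -> np.ndarray:
    """Voxels farther than ``min_distance`` (mm) from every truth position."""
    truths = np.atleast_2d(np.asarray(truth_positions, dtype=float))
    gx, gy, gz = np.meshgrid(grid.x, grid.y, grid.z, indexing="ij", sparse=True)
    mask = np.ones(tuple(grid.shape), dtype=bool)
    for t in truths:
        d2 = (gx - t[0]) ** 2 + (gy - t[1]) ** 2 + (gz - t[2]) ** 2
        mask &= d2 > min_distance**2
    return mask


def image_snr(volume: BeamformedVolume, psf_positions, noise_mask: np.ndarray, peak_search_radius: float = 0.3) -> float:
    """Image SNR in dB: mean PSF-centre intensity over noise-region RMS.

    ``psf_positions`` are the truth positions (mm); each centre intensity is
    the maximum within ``peak_search_radius`` of the position.  The noise
    region is a boolean voxel mask that must not intersect the PSFs.
    """
    grid = volume.grid
    truths = np.atleast_2d(np.asarray(psf_positions, dtype=float))
    if not noise_mask.any():
        raise ValueError("noise region is empty")
    centres = []
    for t in truths:
        idx = grid.mm_to_index(t)
        lo = np.maximum(np.round(idx - peak_search_radius / np.asarray(grid.pitch)).astype(int), 0)
        hi = np.minimum(np.round(idx + peak_search_radius / np.asarray(grid.pitch)).astype(int) + 1, grid.shape)
        sub = volume.values[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]]
        if sub.size == 0:
            raise ValueError(f"PSF position {t} outside the volume")
        centres.append(sub.max())
    noise_rms = float(np.sqrt(np.mean(volume.values[noise_mask] ** 2)))
    if noise_rms == 0:
        raise ValueError("noise region has zero intensity")
    return float(20.0 * np.log10(np.mean(centres) / noise_rms))


# ---------------------------------------------------------------------------
# localization ROC


@dataclass
class RocCurve:
    """TPR/FPR operating points parameterised by the retained-peak count."""

    fpr: np.ndarray
    tpr: np.ndarray
    peak_counts: np.ndarray

    def __post_init__(self):
        order = np.argsort(self.fpr, kind="stable")
        self.fpr = np.asarray(self.fpr, dtype=float)[order]
        self.tpr = np.asarray(self.tpr, dtype=float)[order]
        self.peak_counts = np.asarray(self.peak_counts)[order]

    def auc(self, fpr_max: float | None = 0.05) -> float:
        """Trapezoidal area under TPR(FPR) up to ``fpr_max``.

        Integration runs over the achieved operating points (no
        extrapolation to FPR = 0); with ``fpr_max=None`` the full curve is
        integrated.
        """
        f, t = self.fpr, self.tpr
        if f.size < 2:
            return 0.0
        if fpr_max is not None and f[-1] > fpr_max:
            if f[0] >= fpr_max:
                return 0.0
            t_at = np.interp(fpr_max, f, t)
            keep = f < fpr_max
            f = np.append(f[keep], fpr_max)
            t = np.append(t[keep], t_at)
        return float(np.trapezoid(t, f))


def _greedy_match(loc_pos: np.ndarray, truth_pos: np.ndarray, radius: float) -> int:
    """One-to-one nearest-first matching; returns the number of matches."""
    if loc_pos.size == 0 or truth_pos.size == 0:
        return 0
    d = np.linalg.norm(loc_pos[:, None, :] - truth_pos[None, :, :], axis=2)
    pairs = np.argwhere(d <= radius)
    if pairs.size == 0:
        return 0
    order = np.argsort(d[pairs[:, 0], pairs[:, 1]], kind="stable")
    used_l = np.zeros(loc_pos.shape[0], dtype=bool)
    used_t = np.zeros(truth_pos.shape[0], dtype=bool)
    matches = 0
    for k in order:
        i, j = pairs[k]
        if not used_l[i] and not used_t[j]:
            used_l[i] = used_t[j] = True
            matches += 1
    return matches


def tpr_fpr(
    localizations_per_frame,
    truths_per_frame,
    wavelength: float,
    peak_counts=None,
) -> RocCurve:
    """Localization ROC over a sweep of retained-peak counts.

    ``localizations_per_frame``: per frame, an ``(n, 4)`` array of
    ``x, y, z, intensity`` sorted arbitrarily; ``truths_per_frame``: per
    frame, ``(m, 3)`` truth positions.  For each count the ``k`` highest
    intensity localizations are kept and matched one-to-one (nearest pair
    first) to truths within half a wavelength.  TPR = matches / truths and
    FPR = unmatched / localizations, averaged over frames.
    """
    if peak_counts is None:
        peak_counts = np.arange(20, 151, 10)
    radius = wavelength / 2.0
    fprs, tprs, counts = [], [], []
    for k in peak_counts:
        f_acc, t_acc, n_frames = 0.0, 0.0, 0
        for locs, truths in zip(localizations_per_frame, truths_per_frame):
            locs = np.asarray(locs, dtype=float).reshape(-1, 4)
            truths = np.atleast_2d(np.asarray(truths, dtype=float))
            if locs.shape[0] == 0:
                warnings.warn(f"no localizations available at operating point {k}; frame skipped")
                continue
            top = locs[np.argsort(locs[:, 3], kind="stable")[::-1][:k]]
            tp = _greedy_match(top[:, :3], truths, radius)
            t_acc += tp / max(truths.shape[0], 1)
            f_acc += (top.shape[0] - tp) / top.shape[0]
            n_frames += 1
        if n_frames == 0:
            continue
        fprs.append(f_acc / n_frames)
        tprs.append(t_acc / n_frames)
        counts.append(k)
    return RocCurve(np.array(fprs), np.array(tprs), np.array(counts))


# ---------------------------------------------------------------------------
# Fourier shell correlation


@dataclass
class FscResult:
    frequency: np.ndarray  # cycles/mm per shell
    fsc: np.ndarray
    half_bit_threshold: np.ndarray
    shell_counts: np.ndarray
    resolution_um: float


def fourier_shell_correlation(volume_a, volume_b, pitch: float | None = None) -> FscResult:
    """FSC between two volumes with the half-bit resolution threshold.

    ``FSC(r)`` is the normalised real part of the cross-spectrum averaged
    over spherical spatial-frequency shells; the resolution is the inverse
    of the first frequency at which the curve drops below the half-bit
    threshold ``T(r) = (0.2071 + 1.9102/sqrt(n_r)) / (1.2071 + 0.9102/sqrt(n_r))``
    with ``n_r`` voxels in shell ``r``.  Volumes are zero-padded to a cube.
    Accepts :class:`BeamformedVolume` (isotropic grids) or plain arrays
    plus an explicit isotropic ``pitch`` in mm.
    """
    arrays = []
    for v in (volume_a, volume_b):
        if isinstance(v, BeamformedVolume):
            p = v.grid.pitch
            if not np.allclose(p, p[0]):
                raise ValueError("FSC needs an isotropic voxel pitch")
            if pitch is None:
                pitch = p[0]
            arrays.append(np.asarray(v.values, dtype=float))
        else:
            arrays.append(np.asarray(v, dtype=float))
    if pitch is None:
        raise ValueError("pitch must be given for plain arrays")
    a, b = arrays
    if a.shape != b.shape:
        raise ValueError("volumes must share the same grid")
    n = max(a.shape)
    pad = [(0, n - s) for s in a.shape]
    fa = np.fft.fftn(np.pad(a, pad))
    fb = np.fft.fftn(np.pad(b, pad))
    k = np.fft.fftfreq(n) * n
    kx, ky, kz = np.meshgrid(k, k, k, indexing="ij", sparse=True)
    r = np.sqrt(kx**2 + ky**2 + kz**2)
    shells = np.round(r).astype(int).ravel()
    n_shells = n // 2 + 1
    keep = shells < n_shells
    shells = shells[keep]
    cross = np.real(fa * np.conj(fb)).ravel()[keep]
    pa = np.abs(fa).ravel()[keep] ** 2
    pb = np.abs(fb).ravel()[keep] ** 2
    num = np.bincount(shells, cross, minlength=n_shells)
    da = np.bincount(shells, pa, minlength=n_shells)
    db = np.bincount(shells, pb, minlength=n_shells)
    counts = np.bincount(shells, minlength=n_shells)
    with np.errstate(invalid="ignore", divide="ignore"):
        fsc = num / np.sqrt(da * db)
    sq = np.sqrt(np.maximum(counts, 1))
    threshold = (0.2071 + 1.9102 / sq) / (1.2071 + 0.9102 / sq)
    freq = np.arange(n_shells) / (n * pitch)
    below = np.where((fsc[1:] < threshold[1:]))[0]
    if below.size == 0:
        resolution = np.inf
    else:
        i = below[0] + 1  # first shell below threshold (skipping DC)
        if i == 1:
            f_cross = freq[1]
        else:
            d_prev = fsc[i - 1] - threshold[i - 1]
            d_here = fsc[i] - threshold[i]
            frac = d_prev / (d_prev - d_here)
            f_cross = freq[i - 1] + frac * (freq[i] - freq[i - 1])
        resolution = 1000.0 / f_cross if f_cross > 0 else np.inf
    return FscResult(freq, fsc, threshold, counts, float(resolution))
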