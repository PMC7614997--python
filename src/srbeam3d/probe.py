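"""Matrix-array probe geometry and the element directivity model.

The probe is a planar grid of square elements in the ``z = 0`` plane.
Coordinates are millimetres throughout: ``x`` lateral, ``y`` elevation,
``z`` depth (into the medium).  Times are in microseconds and frequencies
in MHz, so the sound speed ``c`` is in mm/us and the wavelength
``c / f0`` comes out in mm.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["ProbeGeometry", "make_probe", "element_sensitivity", "sensitivities"]


class ConfigurationError(ValueError):
    """Raised for inconsistent probe / grid / pipeline parameters."""


@dataclass(frozen=True)
class ProbeGeometry:
    """Element layout and acoustic parameters of a matrix array.

    Parameters
    ----------
    element_centers
        ``(N, 3)`` array of element-centre positions in mm.  All centres
        lie in the ``z = 0`` plane.
    element_width
        Width ``L`` of the (square) element in mm; enters the directivity.
    center_frequency
        Transmit/receive centre frequency ``f0`` in MHz.
    sound_speed
        Speed of sound ``c`` in mm/us (1.54 for soft tissue).
    n_lateral, n_elevation
        Element counts along the lateral and elevation axes.
    """

    element_centers: np.ndarray
    element_width: float
    center_frequency: float
    sound_speed: float
    n_lateral: int
    n_elevation: int

    def __post_init__(self):
        centers = np.asarray(self.element_centers, dtype=float)
        if centers.ndim != 2 or centers.shape[1] != 3:
            raise ConfigurationError("element_centers must be (N, 3)")
        if centers.shape[0] != self.n_lateral * self.n_elevation:
            raise ConfigurationError(
                "element count mismatch: "
                f"{centers.shape[0]} != {self.n_lateral} x {self.n_elevation}"
            )
        if np.any(centers[:, 2] != 0.0):
            raise ConfigurationError("all element centres must lie in the z=0 plane")
        if self.element_width <= 0 or self.center_frequency <= 0 or self.sound_speed <= 0:
            raise ConfigurationError("element_width, center_frequency and sound_speed must be positive")
        object.__setattr__(self, "element_centers", centers)

    @property
    def n_elements(self) -> int:
        return self.element_centers.shape[0]

    @property
    def wavelength(self) -> float:
        """Wavelength c/f0 in mm."""
        return self.sound_speed / self.center_frequency


def make_probe(
    n_lateral: int = 32,
    n_elevation: int = 32,
    aperture: tuple[float, float] = (9.6, 10.2),
    center_frequency: float = 7.8,
    sound_speed: float = 1.54,
    element_width: float | None = None,
) -> ProbeGeometry:
    """Build a regular matrix array centred on the origin.

    The element pitch per axis is ``aperture / count``; the default
    32 x 32 grid with a 9.6 mm x 10.2 mm aperture gives a 0.3 mm lateral
    and 0.31875 mm elevation pitch.  The elements are square, so their
    width is common to both axes and smaller than either pitch;
    ``element_width`` defaults to the smaller pitch minus a 25 um kerf
    (the documented design of 32x32 Vermon matrix probes).
    """
    if n_lateral < 1 or n_elevation < 1:
        raise ConfigurationError("element counts must be >= 1")
    ap_x, ap_y = float(aperture[0]), float(aperture[1])
    if ap_x <= 0 or ap_y <= 0:
        raise ConfigurationError("aperture extents must be positive")
    pitch_x = ap_x / n_lateral
    pitch_y = ap_y / n_elevation
    xs = (np.arange(n_lateral) - (n_lateral - 1) / 2.0) * pitch_x
    ys = (np.arange(n_elevation) - (n_elevation - 1) / 2.0) * pitch_y
    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    centers = np.column_stack([gx.ravel(), gy.ravel(), np.zeros(gx.size)])
    if element_width is None:
        element_width = max(min(pitch_x, pitch_y) - 0.025, 0.5 * min(pitch_x, pitch_y))
    return ProbeGeometry(
        element_centers=centers,
        element_width=float(element_width),
        center_frequency=float(center_frequency),
        sound_speed=float(sound_speed),
        n_lateral=int(n_lateral),
        n_elevation=int(n_elevation),
    )


def _sinc(x: np.ndarray) -> np.ndarray:
    # normalised sinc, sin(pi x)/(pi x)
    return np.sinc(x)


def sensitivities(probe: ProbeGeometry, voxel) -> np.ndarray:
    """Element sensitivity a_n for every element towards one voxel.

    The single-element directivity model is

        a = sinc(L u / lambda) * sinc(L v / lambda) * cos(theta)

    with ``u = sin(theta) cos(phi)`` and ``v = sin(theta) sin(phi)``,
    where ``theta`` is the angle between the depth axis and the
    element-to-voxel line and ``phi`` the azimuth of its projection on
    the probe plane.  In Cartesian terms ``u = dx/r``, ``v = dy/r`` and
    ``cos(theta) = z/r``.
    """
    voxel = np.asarray(voxel, dtype=float)
    if voxel[2] <= 0:
        raise ValueError("voxel must lie in front of the probe (z > 0)")
    d = voxel[None, :] - probe.element_centers
    r = np.sqrt(np.sum(d * d, axis=1))
    if np.any(r == 0.0):
        raise ValueError("voxel coincides with an element centre")
    lam = probe.wavelength
    L = probe.element_width
    u = d[:, 0] / r
    v = d[:, 1] / r
    return _sinc(L * u / lam) * _sinc(L * v / lam) * (voxel[2] / r)


def element_sensitivity(probe: ProbeGeometry, voxel, n: int) -> float:
    """Sensitivity of element ``n`` towards ``voxel`` (scalar form)."""
    voxel = np.asarray(voxel, dtype=float)
    if voxel[2] <= 0:
        raise ValueError("voxel must lie in front of the probe (z > 0)")
    d = voxel - probe.element_centers[n]
    r = float(np.sqrt(np.dot(d, d)))
    if r == 0.0:
        raise ValueError("voxel coincides with the element centre")
    lam = probe.wavelength
    L = probe.element_width
    u = d[0] / r
    v = d[1] / r
    return float(np.sinc(L * u / lam) * np.sinc(L * v / lam) * (voxel[2] / r))
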