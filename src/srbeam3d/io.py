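"""File formats: HDF5 channel data, NIfTI volumes, CSV tables.

Channel frames and stacks travel in HDF5 containers with the probe
geometry embedded, so a frame file is self-describing; beamformed volumes
and density maps are written as NIfTI-1 with the voxel pitch in the affine
and the grid origin in the translation column, which any medical-image
viewer can place in space.
"""

from __future__ import annotations

import numpy as np

import h5py
import nibabel as nib

from .beamformers import BeamformedVolume, VoxelGrid
from .forward_model import ChannelDataFrame
from .probe import ProbeGeometry
from .ulm import DensityMap, FrameStack

__all__ = [
    "write_frame",
    "read_frame",
    "write_stack",
    "read_stack",
    "write_volume",
    "read_volume",
    "write_density_map",
]


def _write_probe(group: h5py.Group, probe: ProbeGeometry) -> None:
    group.create_dataset("element_centers", data=probe.element_centers)
    group.attrs["element_width"] = probe.element_width
    group.attrs["f0"] = probe.center_frequency
    group.attrs["c"] = probe.sound_speed
    group.attrs["n_lateral"] = probe.n_lateral
    group.attrs["n_elevation"] = probe.n_elevation


def _read_probe(group: h5py.Group) -> ProbeGeometry:
    return ProbeGeometry(
        element_centers=group["element_centers"][()],
        element_width=float(group.attrs["element_width"]),
        center_frequency=float(group.attrs["f0"]),
        sound_speed=float(group.attrs["c"]),
        n_lateral=int(group.attrs["n_lateral"]),
        n_elevation=int(group.attrs["n_elevation"]),
    )


def write_frame(path, frame: ChannelDataFrame, probe: ProbeGeometry) -> None:
    """Write one RF frame plus the probe geometry to an HDF5 file."""
    with h5py.File(path, "w") as f:
        f.create_dataset("samples", data=frame.samples, compression="gzip")
        f.attrs["fs"] = frame.sampling_frequency
        f.attrs["t0"] = frame.t0
        _write_probe(f.create_group("probe"), probe)


def read_frame(path) -> tuple[ChannelDataFrame, ProbeGeometry]:
    with h5py.File(path, "r") as f:
        frame = ChannelDataFrame(f["samples"][()], float(f.attrs["fs"]), float(f.attrs["t0"]))
        probe = _read_probe(f["probe"])
    return frame, probe


def write_stack(path, stack: FrameStack, probe: ProbeGeometry) -> None:
    """Write a frame stack (time x element x frame) plus probe geometry."""
    with h5py.File(path, "w") as f:
        data = np.stack([fr.samples for fr in stack.frames], axis=2) if len(stack) else np.zeros((0, 0, 0))
        f.create_dataset("samples", data=data, compression="gzip")
        f.attrs["fs"] = stack.frames[0].sampling_frequency if len(stack) else 0.0
        f.attrs["t0"] = stack.frames[0].t0 if len(stack) else 0.0
        f.attrs["frame_rate"] = stack.frame_rate
        _write_probe(f.create_group("probe"), probe)


def read_stack(path) -> tuple[FrameStack, ProbeGeometry]:
    with h5py.File(path, "r") as f:
        data = f["samples"][()]
        fs = float(f.attrs["fs"])
        t0 = float(f.attrs["t0"])
        frames = [ChannelDataFrame(data[:, :, i], fs, t0) for i in range(data.shape[2])]
        stack = FrameStack(frames, float(f.attrs["frame_rate"]))
        probe = _read_probe(f["probe"])
    return stack, probe


def _affine(grid: VoxelGrid) -> np.ndarray:
    aff = np.diag([grid.pitch[0], grid.pitch[1], grid.pitch[2], 1.0])
    aff[:3, 3] = grid.origin
    return aff


def write_volume(path, volume: BeamformedVolume) -> None:
    """Write the envelope volume (and weight map, if any) as NIfTI-1."""
    img = nib.Nifti1Image(volume.values.astype(np.float32), _affine(volume.grid))
    img.header["descrip"] = f"srbeam3d {volume.method}".encode()
    nib.save(img, str(path))
    if volume.weight_map is not None:
        wpath = str(path).replace(".nii", "_weights.nii")
        if wpath == str(path):
            wpath = str(path) + ".weights.nii.gz"
        nib.save(nib.Nifti1Image(volume.weight_map.astype(np.float32), _affine(volume.grid)), wpath)


def read_volume(path, method: str = "unknown") -> BeamformedVolume:
    img = nib.load(str(path))
    aff = img.affine
    pitch = tuple(float(aff[i, i]) for i in range(3))
    origin = tuple(float(aff[i, 3]) for i in range(3))
    data = np.asarray(img.dataobj, dtype=float)
    grid = VoxelGrid(origin=origin, pitch=pitch, shape=data.shape)
    return BeamformedVolume(values=data, grid=grid, method=method)


def write_density_map(path, density: DensityMap) -> None:
    img = nib.Nifti1Image(density.counts.astype(np.float32), _affine(density.grid))
    img.header["descrip"] = b"srbeam3d density"
    nib.save(img, str(path))
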