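"""Multilayer TIFF I/O with physical voxel calibration.

Confocal stacks are stored as one grayscale page per optical section. TIFF
calibration tags are unreliable across acquisition software, so the physical
voxel geometry is always supplied explicitly and carried alongside the voxel
array through the whole pipeline.

Internally arrays are ordered ``(z, y, x)`` (page, row, column); every
coordinate exposed to users is ``(x, y, z)`` in 0-based pixel units.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import tifffile

__all__ = [
    "VoxelGeometry",
    "ImageStack",
    "read_stack",
    "convert_to_8bit",
    "write_stack",
]


@dataclass(frozen=True)
class VoxelGeometry:
    """Physical voxel edge lengths (μm) and voxel counts per axis.

    Parameters
    ----------
    dx, dy, dz : float
        Voxel edge length along x, y, z in μm. Must be strictly positive.
    nx, ny, nz : int
        Voxel counts along x, y, z.
    """

    dx: float
    dy: float
    dz: float
    nx: int
    ny: int
    nz: int

    def __post_init__(self) -> None:
        if min(self.dx, self.dy, self.dz) <= 0:
            raise ValueError(f"voxel spacings must be positive, got "
                             f"({self.dx}, {self.dy}, {self.dz})")
        if min(self.nx, self.ny, self.nz) < 0:
            raise ValueError("voxel counts must be non-negative")

    @property
    def shape_zyx(self) -> tuple[int, int, int]:
        return (self.nz, self.ny, self.nx)

    @property
    def spacing_zyx(self) -> tuple[float, float, float]:
        return (self.dz, self.dy, self.dx)

    @property
    def spacing_xyz(self) -> tuple[float, float, float]:
        return (self.dx, self.dy, self.dz)

    @property
    def extent_um(self) -> tuple[float, float, float]:
        """Physical extent (x, y, z) in μm: spacing × count."""
        return (self.dx * self.nx, self.dy * self.ny, self.dz * self.nz)

    @property
    def anisotropy(self) -> float:
        """Axial-to-lateral spacing ratio dz/dx."""
        return self.dz / self.dx

    def voxel_to_um(self, xyz: np.ndarray) -> np.ndarray:
        """Map 0-based voxel indices (x, y, z) to physical μm positions."""
        return np.asarray(xyz, dtype=float) * np.array(self.spacing_xyz)


@dataclass
class ImageStack:
    """A 3D scalar intensity volume with calibration metadata.

    ``voxels`` is ordered (z, y, x) with non-negative integer gray levels no
    larger than ``2**bit_depth - 1``. ``channel_role`` distinguishes the
    volume-filling morphology channel from the immunosignal channel.
    """

    voxels: np.ndarray
    geometry: VoxelGeometry
    bit_depth: int = 8
    channel_role: str = "morphology"

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValueError(f"expected a 3D array, got ndim={self.voxels.ndim}")
        if self.bit_depth not in (8, 12):
            raise ValueError(f"bit_depth must be 8 or 12, got {self.bit_depth}")
        if self.channel_role not in ("morphology", "signal"):
            raise ValueError(f"unknown channel_role {self.channel_role!r}")
        if self.voxels.shape != self.geometry.shape_zyx:
            raise ValueError(
                f"voxel array shape {self.voxels.shape} does not match geometry "
                f"(nz, ny, nx) = {self.geometry.shape_zyx}")
        if self.voxels.size:
            vmax = int(self.voxels.max())
            if vmax > 2 ** self.bit_depth - 1:
                raise ValueError(
                    f"intensity {vmax} exceeds {self.bit_depth}-bit range")
            if int(self.voxels.min()) < 0:
                raise ValueError("negative intensities are not allowed")

    @property
    def max_gray(self) -> int:
        return 2 ** self.bit_depth - 1

    def with_voxels(self, voxels: np.ndarray) -> "ImageStack":
        """Copy of this stack with a new voxel array, same calibration."""
        return ImageStack(voxels, self.geometry, self.bit_depth, self.channel_role)


def read_stack(path: str | Path, geometry: VoxelGeometry,
               channel_role: str = "morphology") -> ImageStack:
    """Read a single-channel multilayer grayscale TIFF into an ImageStack.

    One TIFF page per z-plane, z slowest axis. No intensity rescaling is
    applied on read; 16-bit containers holding 12-bit data are accepted and
    tagged ``bit_depth=12``.

    Raises
    ------
    ValueError
        If the page count or page shape disagrees with ``geometry``, or the
        TIFF is RGB/float.
    """
    arr = tifffile.imread(str(path))
    if arr.ndim == 2:
        arr = arr[np.newaxis, ...]
    if arr.ndim != 3:
        raise ValueError(
            f"{path}: expected a single-channel multilayer TIFF, got an array "
            f"of shape {arr.shape} (RGB or multi-sample TIFFs are unsupported)")
    if arr.dtype.kind == "f":
        raise ValueError(f"{path}: float TIFFs are unsupported; expected 8- or "
                         f"12-bit integer grayscale")
    if arr.dtype.kind not in "ui":
        raise ValueError(f"{path}: unsupported TIFF sample format {arr.dtype}")
    if arr.shape != geometry.shape_zyx:
        raise ValueError(
            f"{path}: TIFF stack shape (pages, rows, cols) = {arr.shape} does "
            f"not match supplied geometry (nz, ny, nx) = {geometry.shape_zyx}")
    if arr.dtype.itemsize == 1:
        bit_depth = 8
    else:
        if arr.size and int(arr.max()) > 4095:
            raise ValueError(
                f"{path}: intensities exceed the 12-bit range (max "
                f"{int(arr.max())}); only 8- and 12-bit data are supported")
        bit_depth = 12
    return ImageStack(arr, geometry, bit_depth=bit_depth, channel_role=channel_role)


def convert_to_8bit(stack: ImageStack, mode: str = "full-range") -> ImageStack:
    """Convert a 12-bit stack to 8 bits with a linear, monotone mapping.

    ``full-range`` (default) maps [0, 4095] linearly onto [0, 255] with
    round-half-up, independent of image content, so identical inputs always
    convert identically. ``min-max`` instead stretches the stack's own
    [min, max] onto [0, 255], mirroring display-range conversion in common
    viewers; it is content-dependent and off by default.

    8-bit input is returned unchanged (identity).
    """
    if stack.bit_depth == 8:
        return stack
    data = stack.voxels.astype(np.float64)
    if mode == "full-range":
        scaled = data * (255.0 / 4095.0)
    elif mode == "min-max":
        lo, hi = float(data.min()), float(data.max())
        scaled = np.zeros_like(data) if hi == lo else (data - lo) * (255.0 / (hi - lo))
    else:
        raise ValueError(f"unknown conversion mode {mode!r}")
    out = np.floor(scaled + 0.5).clip(0, 255).astype(np.uint8)  # round half up
    return ImageStack(out, stack.geometry, bit_depth=8,
                      channel_role=stack.channel_role)


def write_stack(stack: ImageStack, path: str | Path) -> None:
    """Write an 8-bit stack as an uncompressed multilayer grayscale TIFF.

    One page per z-plane; ``read_stack`` is its inverse on voxel data.
    """
    if stack.bit_depth != 8:
        raise ValueError("only 8-bit stacks are written; convert_to_8bit first")
    if stack.voxels.size == 0:
        raise ValueError("refusing to write a stack with an empty axis")
    tifffile.imwrite(str(path), stack.voxels.astype(np.uint8),
                     photometric="minisblack")
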