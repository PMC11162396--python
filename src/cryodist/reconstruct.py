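"""Resample an anisotropic section stack into the analysis voxel grid.

The acquisition samples the block at the camera's in-plane pixel pitch
(13.66 µm by default) and the sectioning pitch in depth (48 µm), while the
analysis runs on an isotropic-in-plane voxel grid of 27.4 × 27.4 × 35.0 µm.
Because the in-plane factor (13.66 → 27.4) and the axial factor
(48 → 35.0) differ, resampling is done in physical coordinates: each
output voxel centre is placed in µm and mapped back to the source grid,
with clamped edge handling.  The default ``linear`` method uses bilinear
point sampling in-plane and an area-weighted linear kernel along z — the
output value is the exact average of the piecewise-linear z-interpolant
over the output voxel's 35 µm axial support.  Because consecutive axial
windows tile depth without gaps, the summed intensity of an interior
feature is conserved exactly under z-resampling regardless of how the
section phase lines up with the output grid, while constants and value
bounds are still preserved.  ``nearest`` is pure nearest-neighbour on all
axes (useful for mask-like data and for identity resampling).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Literal

import numpy as np
import tifffile
from scipy import ndimage

from .errors import FormatError, GeometryError
from .stack_io import ImageStack

__all__ = [
    "VolumeImage",
    "resample_stack_to_volume",
    "write_volume",
    "read_volume",
]

DEFAULT_TARGET_VOXEL = (27.4, 27.4, 35.0)  # µm (x, y, z)


@dataclass
class VolumeImage:
    """A 3D scalar field on a regular anisotropic voxel grid.

    ``data`` is indexed ``[z, y, x]``; ``voxel_size`` is ordered
    ``(x, y, z)`` in µm, matching the way in-plane/axial resolutions are
    usually quoted.  Values are floating point; segmentation thresholds
    compare against them directly.
    """

    data: np.ndarray
    voxel_size: tuple[float, float, float] = DEFAULT_TARGET_VOXEL
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    channel: str = "fluorescence"

    def __post_init__(self) -> None:
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError(f"voxel_size must be positive, got {self.voxel_size}")
        if self.data.ndim != 3:
            raise ValueError("volume data must be 3-dimensional (z, y, x)")

    @property
    def voxel_volume(self) -> float:
        """Voxel volume in µm³ (27.4 × 27.4 × 35.0 = 26 276.6 for the default grid)."""
        dx, dy, dz = self.voxel_size
        return dx * dy * dz


def resample_stack_to_volume(
    stack: ImageStack,
    channel: str = "fluorescence",
    target_voxel: tuple[float, float, float] = DEFAULT_TARGET_VOXEL,
    method: Literal["linear", "nearest"] = "linear",
) -> VolumeImage:
    """Resample one stack channel onto the target voxel grid.

    The output grid spans the stack's physical extent: along each axis the
    sample positions are ``i * target_voxel`` up to the last source sample
    position, so source pixel (row r, col c) of section k lives at
    ``(x, y, z) = (c * pixel_pitch, r * pixel_pitch, k * slice_thickness)``.

    Raises ``GeometryError`` when a target voxel is larger than the full
    extent along its axis (a degenerate single-sample grid) and
    ``ValueError`` for an unknown channel or method.
    """
    data = stack.channel(channel).astype(np.float64)
    if method not in ("linear", "nearest"):
        raise ValueError(f"unknown method {method!r}; expected 'linear' or 'nearest'")
    if any(v <= 0 for v in target_voxel):
        raise ValueError(f"target_voxel must be positive, got {target_voxel}")

    n_sec, n_rows, n_cols = data.shape
    extent = (
        (n_cols - 1) * stack.pixel_pitch,
        (n_rows - 1) * stack.pixel_pitch,
        (n_sec - 1) * stack.slice_thickness,
    )
    counts = []
    for ext, tv in zip(extent, target_voxel):
        n = int(math.floor(ext / tv + 1e-9)) + 1
        if n < 2:
            raise GeometryError(
                f"target voxel {tv} µm larger than the stack extent {ext} µm"
            )
        counts.append(n)
    nx, ny, nz = counts

    # in-plane stage: point sampling on the pixel grid, section by section
    yi = np.arange(ny) * target_voxel[1] / stack.pixel_pitch
    xi = np.arange(nx) * target_voxel[0] / stack.pixel_pitch
    Yi, Xi = np.meshgrid(yi, xi, indexing="ij")
    order = 1 if method == "linear" else 0
    planes = np.empty((n_sec, ny, nx), dtype=np.float64)
    for k in range(n_sec):
        planes[k] = ndimage.map_coordinates(
            data[k], [Yi, Xi], order=order, mode="nearest"
        )

    z_out = np.arange(nz) * target_voxel[2]
    if method == "nearest":
        src_k = np.rint(z_out / stack.slice_thickness).astype(int)
        out = planes[np.clip(src_k, 0, n_sec - 1)]
    else:
        out = _axial_box_average(planes, stack.slice_thickness, z_out, target_voxel[2])
    return VolumeImage(
        data=out, voxel_size=tuple(target_voxel), origin=(0.0, 0.0, 0.0),
        channel=channel,
    )


def _axial_box_average(
    planes: np.ndarray, src_dz: float, z_out: np.ndarray, out_dz: float
) -> np.ndarray:
    """Average the piecewise-linear z-interpolant over each output window.

    ``planes`` holds the sections at depths ``k * src_dz``; the interpolant
    is linear between sections and clamped (constant) beyond the first and
    last.  Each output value is ``(G(z + dz/2) - G(z - dz/2)) / dz`` where
    ``G`` is the exact antiderivative of the interpolant, so windows that
    tile depth conserve the integral exactly.
    """
    n_sec = planes.shape[0]
    # cumulative integral of the interpolant at the section depths
    G_nodes = np.zeros_like(planes)
    np.cumsum(
        (planes[:-1] + planes[1:]) * (src_dz / 2.0), axis=0, out=G_nodes[1:]
    )
    z_max = (n_sec - 1) * src_dz

    def G(z: float) -> np.ndarray:
        if z <= 0.0:
            return z * planes[0]
        if z >= z_max:
            return G_nodes[-1] + (z - z_max) * planes[-1]
        j = int(z / src_dz)
        f = z - j * src_dz
        cz = planes[j] + (planes[j + 1] - planes[j]) * (f / src_dz)
        return G_nodes[j] + f * (planes[j] + cz) / 2.0

    half = out_dz / 2.0
    out = np.empty((len(z_out),) + planes.shape[1:], dtype=np.float64)
    for i, z in enumerate(z_out):
        out[i] = (G(z + half) - G(z - half)) / out_dz
    return out


def write_volume(volume: VolumeImage, path: str | Path) -> Path:
    """Write a volume as a multi-page float32 TIFF plus a JSON sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, volume.data.astype(np.float32))
    sidecar = {
        "voxel_size": list(volume.voxel_size),
        "origin": list(volume.origin),
        "channel": volume.channel,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))
    return path


def read_volume(path: str | Path) -> VolumeImage:
    path = Path(path)
    sidecar_path = path.with_suffix(".json")
    if not sidecar_path.exists():
        raise FormatError(f"missing volume sidecar {sidecar_path}")
    sidecar = json.loads(sidecar_path.read_text())
    data = tifffile.imread(path).astype(np.float64)
    return VolumeImage(
        data=data,
        voxel_size=tuple(sidecar["voxel_size"]),
        origin=tuple(sidecar.get("origin", (0.0, 0.0, 0.0))),
        channel=sidecar.get("channel", "fluorescence"),
    )
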