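"""Serial-section image stacks on disk: TIFF series + JSON sidecar.

Storage dialect: one uncompressed TIFF per section per channel, named
``<channel>_<index:04d>.tif`` with a zero-padded numeric suffix, plus a
single ``stack.json`` sidecar holding the physical geometry (pixel pitch,
slice thickness), bit depth and channel metadata.  The dialect is an
artifact convention — diff-friendly and streamable — since serial-section
instruments do not share one on-disk format.

Pixel coordinates are 0-based with half-open ranges; section index ``k``
corresponds to cut depth ``k * slice_thickness`` µm.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np
import tifffile
from pydantic import BaseModel, model_validator

from .errors import FormatError, GeometryError, StackOrderError

__all__ = ["ImageStack", "CropRegion", "read_stack", "write_stack", "crop_stack"]

CHANNELS = ("fluorescence", "reflection")
SIDECAR_NAME = "stack.json"
_REQUIRED_KEYS = ("pixel_pitch", "slice_thickness", "bit_depth", "channels")


@dataclass
class ImageStack:
    """An ordered two-channel section series with physical geometry.

    ``fluorescence`` and ``reflection`` are ``(n_sections, rows, cols)``
    unsigned-integer arrays sharing shape and dtype.
    """

    fluorescence: np.ndarray
    reflection: np.ndarray
    pixel_pitch: float  # µm
    slice_thickness: float  # µm
    bit_depth: int
    channel_meta: dict = field(default_factory=dict)
    provenance: str = ""

    def __post_init__(self) -> None:
        if self.fluorescence.shape != self.reflection.shape:
            raise ValueError(
                "channel shapes differ: "
                f"{self.fluorescence.shape} vs {self.reflection.shape}"
            )
        if self.fluorescence.ndim != 3:
            raise ValueError("channel arrays must be (n_sections, rows, cols)")
        if self.pixel_pitch <= 0 or self.slice_thickness <= 0:
            raise ValueError("pixel_pitch and slice_thickness must be > 0")

    @property
    def n_sections(self) -> int:
        return self.fluorescence.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.fluorescence.shape[1:]

    def channel(self, name: str) -> np.ndarray:
        if name not in CHANNELS:
            raise ValueError(f"unknown channel {name!r}; expected one of {CHANNELS}")
        return getattr(self, name)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ImageStack):
            return NotImplemented
        return (
            np.array_equal(self.fluorescence, other.fluorescence)
            and self.fluorescence.dtype == other.fluorescence.dtype
            and np.array_equal(self.reflection, other.reflection)
            and self.pixel_pitch == other.pixel_pitch
            and self.slice_thickness == other.slice_thickness
            and self.bit_depth == other.bit_depth
        )


class CropRegion(BaseModel):
    """Half-open pixel bounds (0-based) with an optional section range."""

    row_start: int = 0
    row_stop: int
    col_start: int = 0
    col_stop: int
    slice_start: Optional[int] = None
    slice_stop: Optional[int] = None

    @model_validator(mode="after")
    def _non_empty(self) -> "CropRegion":
        if self.row_stop <= self.row_start or self.col_stop <= self.col_start:
            raise ValueError("crop region must be non-empty")
        if self.row_start < 0 or self.col_start < 0:
            raise ValueError("crop bounds must be non-negative")
        if (
            self.slice_start is not None
            and self.slice_stop is not None
            and self.slice_stop <= self.slice_start
        ):
            raise ValueError("slice range must be non-empty")
        return self


def write_stack(stack: ImageStack, path: str | Path) -> Path:
    """Write a stack as per-section TIFFs plus the JSON sidecar."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    for name in CHANNELS:
        data = stack.channel(name)
        for k in range(stack.n_sections):
            tifffile.imwrite(path / f"{name}_{k:04d}.tif", data[k])
    sidecar = {
        "pixel_pitch": stack.pixel_pitch,
        "slice_thickness": stack.slice_thickness,
        "bit_depth": stack.bit_depth,
        "channels": list(CHANNELS),
        "n_sections": stack.n_sections,
        "channel_meta": stack.channel_meta,
        "provenance": stack.provenance,
    }
    (path / SIDECAR_NAME).write_text(json.dumps(sidecar, indent=2))
    return path


def read_stack(path: str | Path) -> ImageStack:
    """Read a stack directory written by :func:`write_stack`.

    Round-trips bit-exactly.  Raises :class:`FormatError` when the sidecar
    or a required key is missing, :class:`StackOrderError` when section
    indices are not contiguous from 0, and :class:`ValueError` when image
    shapes are inconsistent.
    """
    path = Path(path)
    sidecar_path = path / SIDECAR_NAME
    if not sidecar_path.exists():
        raise FormatError(f"missing sidecar {SIDECAR_NAME} in {path}")
    sidecar = json.loads(sidecar_path.read_text())
    for key in _REQUIRED_KEYS:
        if key not in sidecar:
            raise FormatError(f"sidecar missing required key {key!r}")

    arrays: dict[str, np.ndarray] = {}
    for name in CHANNELS:
        pattern = re.compile(rf"{name}_(\d+)\.tif$")
        found: dict[int, Path] = {}
        for f in path.iterdir():
            m = pattern.match(f.name)
            if m:
                found[int(m.group(1))] = f
        if not found:
            raise FormatError(f"no {name} TIFFs found in {path}")
        indices = sorted(found)
        if indices != list(range(len(indices))):
            raise StackOrderError(
                f"{name} section indices not contiguous from 0: {indices}"
            )
        frames = [tifffile.imread(found[i]) for i in indices]
        shapes = {f.shape for f in frames}
        if len(shapes) != 1:
            raise ValueError(f"inconsistent {name} image shapes: {sorted(shapes)}")
        arrays[name] = np.stack(frames)

    return ImageStack(
        fluorescence=arrays["fluorescence"],
        reflection=arrays["reflection"],
        pixel_pitch=float(sidecar["pixel_pitch"]),
        slice_thickness=float(sidecar["slice_thickness"]),
        bit_depth=int(sidecar["bit_depth"]),
        channel_meta=sidecar.get("channel_meta", {}),
        provenance=sidecar.get("provenance", ""),
    )


def crop_stack(stack: ImageStack, region: CropRegion) -> ImageStack:
    """Crop every section to the given pixel region (and section range).

    Geometry metadata is preserved; pixel values inside the region are
    unchanged.  Out-of-bounds regions raise :class:`GeometryError`.
    """
    rows, cols = stack.frame_shape
    if region.row_stop > rows or region.col_stop > cols:
        raise GeometryError(
            f"crop region ({region.row_stop}, {region.col_stop}) exceeds "
            f"frame shape ({rows}, {cols})"
        )
    s0 = region.slice_start if region.slice_start is not None else 0
    s1 = region.slice_stop if region.slice_stop is not None else stack.n_sections
    if s0 < 0 or s1 > stack.n_sections:
        raise GeometryError(
            f"slice range [{s0}, {s1}) exceeds section count {stack.n_sections}"
        )
    sl = np.s_[s0:s1, region.row_start : region.row_stop,
               region.col_start : region.col_stop]
    return replace(
        stack,
        fluorescence=stack.fluorescence[sl].copy(),
        reflection=stack.reflection[sl].copy(),
    )
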