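"""Fluorescent-region segmentation with autofluorescence exclusion.

The drug signal is extracted by a fixed intensity threshold (2000 counts
by default, on the resampled intensity scale inherited from 16-bit
acquisition) while excluding, as far as possible, voxels that are bright
only because of intrinsic tissue autofluorescence.  "As far as possible"
is operationalized here as three simple, individually testable rules:

1. tissue gating — candidate voxels must lie inside the tissue border
   reconstructed from the reflection channel (this removes the embedding
   medium outright);
2. minimum component size — supra-threshold specks smaller than
   ``min_component_voxels`` (default 8 voxels ≈ 0.0002 µL on the default
   grid) are dropped as noise/autofluorescent debris;
3. optionally, a reflection-brightness cap — candidate voxels whose
   reflection value exceeds a given percentile of the tissue reflection
   distribution are removed, a heuristic against bright structural tissue.

Thresholding uses strict inequality (``value > threshold``) and connected
components use full 26-connectivity; both choices are fixed here for
reproducibility.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Optional

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

from .errors import DegenerateHistogramError, EmptyMaskError, GeometryError
from .reconstruct import VolumeImage

__all__ = ["Segmentation", "TissueMask", "build_tissue_mask", "segment_fluorescence"]

_CONN26 = np.ones((3, 3, 3), dtype=bool)


@dataclass
class TissueMask:
    """Boolean tissue-interior mask plus the thresholding parameters used."""

    mask: np.ndarray
    method_meta: dict = field(default_factory=dict)


@dataclass
class Segmentation:
    """Supra-threshold fluorescent region after autofluorescence exclusion.

    ``labels`` is nonzero exactly where ``mask`` is true;
    ``excluded_voxel_count`` counts candidate voxels (above threshold and
    inside tissue) that the exclusion rules removed, so that
    ``candidates == mask.sum() + excluded_voxel_count`` always holds.
    """

    mask: np.ndarray
    labels: np.ndarray
    threshold_used: float
    n_components: int
    excluded_voxel_count: int
    voxel_size: tuple[float, float, float]


def build_tissue_mask(
    reflection_volume: VolumeImage,
    method: Literal["otsu", "fixed"] = "otsu",
    fixed_value: Optional[float] = None,
) -> TissueMask:
    """Reconstruct the tissue border from the reflection channel.

    With ``method="otsu"`` the threshold maximizes between-class variance
    on the volume histogram; with ``method="fixed"`` voxels with
    ``value >= fixed_value`` are kept.  The largest 26-connected component
    is retained and interior holes are filled, so the mask is one solid
    tissue body.

    Raises
    ------
    DegenerateHistogramError
        For an all-equal volume under Otsu (use the fixed method instead).
    EmptyMaskError
        When no voxel reaches the threshold.
    """
    data = reflection_volume.data
    if not np.all(np.isfinite(data)):
        raise ValueError("reflection volume contains non-finite values")
    if method == "otsu":
        if data.max() == data.min():
            raise DegenerateHistogramError(
                "constant reflection volume: Otsu thresholding is undefined; "
                "use method='fixed' with an explicit threshold"
            )
        threshold = float(threshold_otsu(data))
    elif method == "fixed":
        if fixed_value is None:
            raise ValueError("method='fixed' requires fixed_value")
        threshold = float(fixed_value)
    else:
        raise ValueError(f"unknown method {method!r}")

    raw = data >= threshold
    if not raw.any():
        raise EmptyMaskError(
            f"no reflection voxel reaches threshold {threshold}; tissue mask empty"
        )
    labels, n = ndimage.label(raw, structure=_CONN26)
    if n > 1:
        sizes = ndimage.sum_labels(raw, labels, index=np.arange(1, n + 1))
        keep = int(np.argmax(sizes)) + 1
        raw = labels == keep
    mask = ndimage.binary_fill_holes(raw)
    return TissueMask(mask=mask, method_meta={"method": method, "threshold": threshold})


def segment_fluorescence(
    fluor_volume: VolumeImage,
    tissue: TissueMask,
    threshold: float = 2000.0,
    min_component_voxels: int = 8,
    autofluor_percentile_cap: Optional[float] = None,
    reflection_volume: Optional[VolumeImage] = None,
) -> Segmentation:
    """Segment the fluorescent drug region above an intensity threshold.

    Candidate voxels are those strictly above ``threshold`` and inside the
    tissue mask; the exclusion rules described in the module docstring are
    then applied and the surviving voxels labelled by 26-connectivity.

    Raises ``GeometryError`` when the volumes/masks are not on the same
    grid, and ``ValueError`` when the reflection cap is requested without a
    reflection volume.
    """
    data = fluor_volume.data
    if data.shape != tissue.mask.shape:
        raise GeometryError(
            f"fluorescence grid {data.shape} does not match tissue mask "
            f"grid {tissue.mask.shape}"
        )
    candidates = (data > threshold) & tissue.mask
    n_candidates = int(candidates.sum())

    kept = candidates
    if autofluor_percentile_cap is not None:
        if reflection_volume is None:
            raise ValueError(
                "autofluor_percentile_cap requires the reflection volume"
            )
        if reflection_volume.data.shape != data.shape:
            raise GeometryError("reflection volume grid does not match")
        cap_value = np.percentile(
            reflection_volume.data[tissue.mask], autofluor_percentile_cap
        )
        kept = kept & ~(reflection_volume.data > cap_value)

    labels, n = ndimage.label(kept, structure=_CONN26)
    if n and min_component_voxels > 1:
        sizes = ndimage.sum_labels(kept, labels, index=np.arange(1, n + 1))
        small = np.flatnonzero(sizes < min_component_voxels) + 1
        if small.size:
            kept = kept & ~np.isin(labels, small)
            labels, n = ndimage.label(kept, structure=_CONN26)

    return Segmentation(
        mask=kept,
        labels=labels,
        threshold_used=float(threshold),
        n_components=int(n),
        excluded_voxel_count=n_candidates - int(kept.sum()),
        voxel_size=tuple(fluor_volume.voxel_size),
    )
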