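"""Global thresholding, component cleanup, and the trabecular VOI.

The trabecular protocol places a volume of interest (VOI) along the bone's
longitudinal axis (axis 0), referenced to the growth-plate plane: the VOI
starts a fixed offset below the plate (default 0.1 mm toward the diaphysis)
and extends a fixed length (default 0.5 mm).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .voxgrid import BinaryMask, VoxelVolume

__all__ = ["VoiSpec", "threshold_mask", "largest_component", "build_voi", "round_half_away"]

DEFAULT_THRESHOLD = 40.0
DEFAULT_VOI_OFFSET_MM = 0.1
DEFAULT_VOI_EXTENT_MM = 0.5


@dataclass
class VoiSpec:
    """Growth-plate-referenced VOI along axis 0.

    ``reference_slice`` is the growth-plate plane; the VOI starts
    ``offset_mm`` from it in ``direction`` (+1 toward increasing slice
    index) and spans ``extent_mm``.
    """

    reference_slice: int
    offset_mm: float = DEFAULT_VOI_OFFSET_MM
    extent_mm: float = DEFAULT_VOI_EXTENT_MM
    direction: int = 1

    def __post_init__(self) -> None:
        if self.offset_mm < 0:
            raise ValueError("offset_mm must be >= 0")
        if self.extent_mm <= 0:
            raise ValueError("extent_mm must be > 0")
        if self.direction not in (1, -1):
            raise ValueError("direction must be +1 or -1")


def round_half_away(x: float) -> int:
    """Round half away from zero (mm -> slice conversions)."""
    return int(np.sign(x) * np.floor(abs(x) + 0.5))


def threshold_mask(vol: VoxelVolume, level: float = DEFAULT_THRESHOLD) -> BinaryMask:
    """Global threshold: foreground iff gray value >= ``level``.

    The comparison is inclusive; thresholding is antitone in ``level``
    (raising the level never adds voxels).
    """
    if not np.isfinite(level):
        raise ValueError("threshold level must be finite")
    return BinaryMask(vol.data >= level, vol.spacing, vol.origin)


_STRUCTS = {
    6: ndimage.generate_binary_structure(3, 1),
    18: ndimage.generate_binary_structure(3, 2),
    26: ndimage.generate_binary_structure(3, 3),
}


def largest_component(mask: BinaryMask, connectivity: int = 26) -> BinaryMask:
    """Keep only the largest connected foreground component.

    Ties are broken deterministically in favour of the component containing
    the lexicographically smallest voxel index.
    """
    if connectivity not in _STRUCTS:
        raise ValueError(f"connectivity must be one of {sorted(_STRUCTS)}")
    if mask.count() == 0:
        raise ValueError("empty mask has no components")
    labels, n = ndimage.label(mask.data, structure=_STRUCTS[connectivity])
    if n == 1:
        return BinaryMask(mask.data.copy(), mask.spacing, mask.origin)
    sizes = np.bincount(labels.ravel())[1:]  # skip background
    best = sizes.max()
    candidates = np.flatnonzero(sizes == best) + 1
    if len(candidates) == 1:
        chosen = candidates[0]
    else:
        # scipy labels in raster order, so the smallest label among the tied
        # components is the one whose first voxel comes earliest.
        chosen = candidates.min()
    return BinaryMask(labels == chosen, mask.spacing, mask.origin)


def build_voi(mask: BinaryMask, spec: VoiSpec) -> BinaryMask:
    """Restrict ``mask`` to the VOI slab defined by ``spec``.

    mm offsets are converted to whole slices on the axis-0 grid by
    round-half-away-from-zero; the retained slice range is half-open with
    the computed width.
    """
    sz = mask.spacing[0]
    n_offset = round_half_away(spec.offset_mm / sz)
    n_extent = round_half_away(spec.extent_mm / sz)
    if n_extent < 1:
        raise ValueError(
            f"VOI extent {spec.extent_mm} mm spans no whole slice at "
            f"spacing {sz} mm"
        )
    start = spec.reference_slice + spec.direction * n_offset
    stop = start + spec.direction * n_extent
    lo, hi = (start, stop) if spec.direction == 1 else (stop + 1, start + 1)
    if lo < 0 or hi > mask.shape[0]:
        raise ValueError(
            f"VOI slices [{lo}, {hi}) exit volume of {mask.shape[0]} slices"
        )
    out = np.zeros_like(mask.data)
    out[lo:hi] = mask.data[lo:hi]
    return BinaryMask(out, mask.spacing, mask.origin)


def voi_region(mask: BinaryMask, spec: VoiSpec) -> BinaryMask:
    """Full (all-true) VOI slab on ``mask``'s grid — the TV denominator."""
    full = BinaryMask(np.ones(mask.shape, dtype=bool), mask.spacing, mask.origin)
    return build_voi(full, spec)
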