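"""Skull, brain, and foramen magnum morphometry.

Skull bone volume is the thresholded, largest-component voxel volume of
the skull scan.  Brain volume follows the slice-wise protocol: per-slice
segmented areas summed and multiplied by the slice thickness.  The foramen
magnum, which does not lie in a flat plane, is measured in 3D: its
circumference is the length of the aperture's boundary loop on the skull
surface mesh, its transverse/sagittal diameters are 3D extents of that
loop, and its area uses the ellipse formula  1/4 * pi * Dt * Ds.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .segmentation import largest_component, threshold_mask
from .voxgrid import BinaryMask, Polyline3D, SurfaceMesh, VoxelVolume

__all__ = [
    "ForamenResult",
    "skull_volume",
    "brain_volume",
    "foramen_boundary",
    "foramen_metrics",
]


@dataclass
class ForamenResult:
    circumference_mm: float   # geodesic length along the aperture rim
    d_t: float                # transverse diameter, mm
    d_s: float                # sagittal diameter, mm
    area_mm2: float           # 1/4 * pi * d_t * d_s


def skull_volume(vol: VoxelVolume, level: float = 40.0) -> float:
    """Skull bone volume (mm^3): threshold, keep largest component, count."""
    mask = threshold_mask(vol, level)
    if mask.count() == 0:
        raise ValueError(f"threshold {level} leaves an empty segmentation")
    return largest_component(mask).volume_mm3()


def brain_volume(
    slice_masks: Sequence[np.ndarray],
    slice_thickness_mm: float,
    in_plane_spacing_mm: tuple[float, float],
) -> float:
    """Brain volume (mm^3) from per-slice segmentations.

    Each 2D mask contributes (pixel count * pixel area * slice thickness);
    this mirrors manual slice-wise segmentation followed by 3D
    reconstruction.
    """
    if slice_thickness_mm <= 0:
        raise ValueError("slice thickness must be > 0")
    sy, sx = in_plane_spacing_mm
    if sy <= 0 or sx <= 0:
        raise ValueError("in-plane spacing must be > 0")
    masks = [np.asarray(m).astype(bool) for m in slice_masks]
    if not masks:
        raise ValueError("no slices supplied")
    shape = masks[0].shape
    if any(m.shape != shape for m in masks):
        raise ValueError("inconsistent slice shapes")
    total_px = sum(int(m.sum()) for m in masks)
    if total_px == 0:
        raise ValueError("all slices empty")
    return total_px * sy * sx * slice_thickness_mm


def foramen_boundary(mesh: SurfaceMesh) -> Polyline3D:
    """Longest closed boundary loop of an (open) skull surface mesh.

    The foramen rim is a closed curve of boundary edges (edges used by one
    face only); among all boundary loops the longest by polyline length is
    returned, ordered and closed.  A watertight mesh has no boundary and
    raises.
    """
    loops = mesh.boundary_loops()
    if not loops:
        raise ValueError("mesh is watertight: no boundary loop to measure")
    best_pts, best_len = None, -1.0
    for loop in loops:
        pts = mesh.vertices[loop]
        poly = Polyline3D(pts, closed=True)
        if poly.length() > best_len:
            best_len = poly.length()
            best_pts = pts
    return Polyline3D(best_pts, closed=True)


def foramen_metrics(
    loop: Polyline3D,
    transverse_axis=(0.0, 1.0, 0.0),
    sagittal_axis=(0.0, 0.0, 1.0),
) -> ForamenResult:
    """Circumference, 3D diameters, and elliptical area of an aperture loop.

    ``d_t`` and ``d_s`` are the extents of the loop points along the two
    supplied orthonormal axes; the area uses 1/4 * pi * d_t * d_s.
    """
    if not loop.closed or len(loop) < 3:
        raise ValueError("need a closed loop of >= 3 points")
    t = np.asarray(transverse_axis, dtype=float)
    s = np.asarray(sagittal_axis, dtype=float)
    t = t / np.linalg.norm(t)
    s = s / np.linalg.norm(s)
    if abs(t @ s) > 1e-8:
        raise ValueError("transverse and sagittal axes must be orthogonal")
    pts = loop.points
    proj_t = pts @ t
    proj_s = pts @ s
    d_t = float(proj_t.max() - proj_t.min())
    d_s = float(proj_s.max() - proj_s.min())
    if d_t <= 0 or d_s <= 0:
        raise ValueError("degenerate loop: zero extent along a measurement axis")
    return ForamenResult(
        circumference_mm=loop.length(),
        d_t=d_t,
        d_s=d_s,
        area_mm2=0.25 * np.pi * d_t * d_s,
    )
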