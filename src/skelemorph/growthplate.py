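"""3D growth-plate morphometry.

The growth plate is treated as a thin 3D plate segmented from micro-CT:
its volume is the voxel-count volume of the mask; its thickness comes from
splitting the plate's isosurface into a proximal and a distal sheet and
measuring, at each proximal vertex, the distance to the nearest point of
the distal sheet.  The volume-to-thickness ratio is a surrogate for the
plate's surface area (exact for a constant-thickness plate), and a
topographic thickness map over the plate footprint localizes where the
plate is thick or thin.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .meshing import mask_to_mesh, outward_face_normals
from .voxgrid import BinaryMask, SurfaceMesh

__all__ = [
    "GrowthPlateResult",
    "gp_volume",
    "split_surfaces",
    "gp_thickness",
    "gp_ratio",
    "analyze",
]

DEFAULT_RIM_TOLERANCE = 0.5  # |cos| below this = rim face, discarded


@dataclass
class GrowthPlateResult:
    volume_mm3: float
    thickness_mean_mm: float
    thickness_histogram: tuple[np.ndarray, np.ndarray]  # (bin edges mm, counts)
    ratio_mm2: float
    thickness_map: np.ndarray          # 2D grid over the in-plane footprint
    thickness_map_edges: tuple[np.ndarray, np.ndarray]


def gp_volume(mask: BinaryMask) -> float:
    """Growth-plate volume in mm^3 (voxel count times voxel volume)."""
    if mask.count() == 0:
        raise ValueError("empty growth-plate mask")
    return mask.volume_mm3()


def _as_axis(axis_direction) -> np.ndarray:
    if isinstance(axis_direction, (int, np.integer)):
        v = np.zeros(3)
        v[int(axis_direction)] = 1.0
        return v
    v = np.asarray(axis_direction, dtype=float)
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError("axis_direction must be non-zero")
    return v / n


def _submesh(mesh: SurfaceMesh, face_sel: np.ndarray) -> SurfaceMesh:
    faces = mesh.faces[face_sel]
    used = np.unique(faces)
    remap = np.full(mesh.n_vertices, -1, dtype=np.int64)
    remap[used] = np.arange(len(used))
    return SurfaceMesh(mesh.vertices[used], remap[faces])


def split_surfaces(
    mask: BinaryMask,
    axis_direction=0,
    rim_tolerance: float = DEFAULT_RIM_TOLERANCE,
) -> tuple[SurfaceMesh, SurfaceMesh]:
    """Split a plate mask's isosurface into proximal and distal sheets.

    Faces are classified by the component of their outward normal along
    ``axis_direction``: positive -> proximal sheet, negative -> distal
    sheet; faces with |component| < ``rim_tolerance`` belong to the plate
    rim and are discarded.
    """
    axis = _as_axis(axis_direction)
    _require_plate_like(mask, axis)
    mesh = mask_to_mesh(mask)
    normals = outward_face_normals(mesh, mask)
    comp = normals @ axis
    prox_sel = comp >= rim_tolerance
    dist_sel = comp <= -rim_tolerance
    if not prox_sel.any() or not dist_sel.any():
        raise ValueError(
            "mask has no plate orientation along the given axis "
            "(one of the split sheets is empty)"
        )
    return _submesh(mesh, prox_sel), _submesh(mesh, dist_sel)


def _require_plate_like(mask: BinaryMask, axis: np.ndarray) -> None:
    """A plate is thin: its maximal inscribed sphere must be small compared
    with the in-plane footprint (a solid blob such as a ball is not a plate)."""
    from scipy import ndimage

    spacing = np.asarray(mask.spacing)
    thickness_proxy = 2.0 * float(
        ndimage.distance_transform_edt(mask.data, sampling=spacing).max()
    )
    idx = np.argwhere(mask.data)
    extents = (idx.max(axis=0) - idx.min(axis=0) + 1) * spacing
    # second-largest bounding-box extent as the footprint scale
    footprint = float(np.sort(extents)[-2])
    if thickness_proxy > 0.5 * footprint:
        raise ValueError(
            "mask is not plate-like: inscribed-sphere thickness "
            f"{thickness_proxy:.3g} mm is not small against its footprint "
            f"{footprint:.3g} mm"
        )


def _surface_samples(mesh: SurfaceMesh) -> np.ndarray:
    """Dense point samples of a mesh: vertices, face centroids, edge midpoints."""
    v = mesh.vertices
    f = mesh.faces
    centroids = v[f].mean(axis=1)
    mids = np.concatenate(
        [
            (v[f[:, 0]] + v[f[:, 1]]) / 2,
            (v[f[:, 1]] + v[f[:, 2]]) / 2,
            (v[f[:, 2]] + v[f[:, 0]]) / 2,
        ]
    )
    return np.concatenate([v, centroids, mids])


def _vertex_area_weights(mesh: SurfaceMesh) -> np.ndarray:
    areas = mesh.face_areas()
    w = np.zeros(mesh.n_vertices)
    for k in range(3):
        np.add.at(w, mesh.faces[:, k], areas / 3.0)
    return w


def gp_thickness(
    proximal: SurfaceMesh,
    distal: SurfaceMesh,
    axis_direction=0,
    n_bins: int = 32,
    map_bin_mm: float | None = None,
) -> tuple[float, tuple[np.ndarray, np.ndarray], np.ndarray, tuple[np.ndarray, np.ndarray]]:
    """Two-surface plate thickness.

    For each proximal vertex the thickness sample is the unsigned distance
    to the nearest point of the distal sheet.  Returns the area-weighted
    mean (mm), a histogram (edges, counts over all samples), and a 2D
    topographic thickness map over the in-plane footprint (orthographic
    projection onto the plane normal to ``axis_direction``).
    """
    if proximal.n_faces == 0 or distal.n_faces == 0:
        raise ValueError("empty sheet")
    axis = _as_axis(axis_direction)
    tree = cKDTree(_surface_samples(distal))
    thick, _ = tree.query(proximal.vertices)
    if (thick <= 0).all():
        raise ValueError("sheets coincide: zero thickness everywhere")
    weights = _vertex_area_weights(proximal)
    mean = float(np.average(thick, weights=weights))
    edges = np.linspace(0.0, float(thick.max()) * 1.001, n_bins + 1)
    counts, edges = np.histogram(thick, bins=edges)
    # in-plane coordinates: the two directions orthogonal to the axis
    basis = _plane_basis(axis)
    uv = proximal.vertices @ basis.T
    if map_bin_mm is None:
        span = uv.max(axis=0) - uv.min(axis=0)
        map_bin_mm = float(max(span) / 50.0) or 1.0
    u_edges = np.arange(uv[:, 0].min(), uv[:, 0].max() + map_bin_mm, map_bin_mm)
    v_edges = np.arange(uv[:, 1].min(), uv[:, 1].max() + map_bin_mm, map_bin_mm)
    sums, _, _ = np.histogram2d(uv[:, 0], uv[:, 1], bins=(u_edges, v_edges), weights=thick)
    nums, _, _ = np.histogram2d(uv[:, 0], uv[:, 1], bins=(u_edges, v_edges))
    with np.errstate(invalid="ignore"):
        tmap = np.where(nums > 0, sums / np.maximum(nums, 1), np.nan)
    return mean, (edges, counts), tmap, (u_edges, v_edges)


def _plane_basis(axis: np.ndarray) -> np.ndarray:
    """Two orthonormal in-plane directions for a given plate axis."""
    ref = np.array([1.0, 0.0, 0.0])
    if abs(axis @ ref) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    u = np.cross(axis, ref)
    u /= np.linalg.norm(u)
    v = np.cross(axis, u)
    return np.stack([u, v])


def gp_ratio(volume_mm3: float, thickness_mm: float) -> float:
    """Volume/thickness ratio (mm^2): surrogate for plate surface area."""
    if volume_mm3 == 0:
        return 0.0
    if thickness_mm <= 0:
        raise ValueError("thickness must be positive")
    return volume_mm3 / thickness_mm


def analyze(
    mask: BinaryMask,
    axis_direction=0,
    rim_tolerance: float = DEFAULT_RIM_TOLERANCE,
    map_bin_mm: float | None = None,
) -> GrowthPlateResult:
    """Full growth-plate panel: volume, thickness, ratio, topographic map."""
    volume = gp_volume(mask)
    prox, dist = split_surfaces(mask, axis_direction, rim_tolerance)
    if map_bin_mm is None:
        map_bin_mm = 2.0 * float(min(mask.spacing))
    mean, hist, tmap, edges = gp_thickness(
        prox, dist, axis_direction, map_bin_mm=map_bin_mm
    )
    return GrowthPlateResult(
        volume_mm3=volume,
        thickness_mean_mm=mean,
        thickness_histogram=hist,
        ratio_mm2=gp_ratio(volume, mean),
        thickness_map=tmap,
        thickness_map_edges=edges,
    )
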