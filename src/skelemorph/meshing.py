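"""Isosurface extraction and mesh orientation utilities."""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from skimage import measure

from .voxgrid import BinaryMask, SurfaceMesh

__all__ = ["mask_to_mesh", "outward_face_normals"]


def mask_to_mesh(mask: BinaryMask, level: float = 0.5) -> SurfaceMesh:
    """Triangulated isosurface of a binary mask (marching cubes at 0.5).

    Vertices are in world mm; degenerate faces are removed.
    """
    if mask.count() == 0:
        raise ValueError("empty mask has no isosurface")
    verts, faces, _, _ = measure.marching_cubes(
        mask.data.astype(np.float32), level=level, spacing=mask.spacing
    )
    verts = verts + np.asarray(mask.origin)
    mesh = SurfaceMesh(verts, faces)
    return mesh.remove_degenerate_faces()


def outward_face_normals(mesh: SurfaceMesh, mask: BinaryMask) -> np.ndarray:
    """Unit face normals oriented to point out of the mask foreground.

    Marching cubes emits a globally consistent winding, so a single global
    flip decides outwardness; the sign is found by probing the mask (with
    trilinear interpolation) a fraction of a voxel on both sides of every
    face centroid and taking the majority vote.
    """
    normals = mesh.face_normals()
    centroids = mesh.face_centroids()
    spacing = np.asarray(mask.spacing)
    eps = 0.75 * spacing.min()
    fg = mask.data.astype(np.float32)

    def sample(points: np.ndarray) -> np.ndarray:
        idx = (points - np.asarray(mask.origin)) / spacing
        return ndimage.map_coordinates(
            fg, idx.T, order=1, mode="constant", cval=0.0
        )

    ahead = sample(centroids + eps * normals)
    behind = sample(centroids - eps * normals)
    votes_outward = int((ahead < behind).sum())
    votes_inward = int((ahead > behind).sum())
    if votes_inward > votes_outward:
        return -normals
    return normals
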