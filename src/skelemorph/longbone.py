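"""Curved 3D bone-length measurement.

Long-bone lengths are measured as the length of a polyline of seed points
placed along the bone (capturing bowing that straight calliper lengths
miss).  For hands-free phantom work, :func:`centerline_from_mask` extracts
an ordered medial-axis polyline from a tubular binary mask.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage, sparse
from scipy.sparse.csgraph import dijkstra
from skimage.morphology import skeletonize

from .voxgrid import BinaryMask, Polyline3D

__all__ = ["curved_length", "centerline_from_mask", "resample_polyline"]


def curved_length(seeds: Polyline3D) -> float:
    """Length (mm) of the seed polyline: sum of straight segments.

    Piecewise-linear by design — no spline smoothing — so the value is the
    deterministic analogue of an interactive 3D length tool.  Always at
    least the straight-line distance between the endpoints.
    """
    if len(seeds) < 2:
        raise ValueError("need at least 2 seed points")
    return seeds.length()


def resample_polyline(points: np.ndarray, n_points: int) -> np.ndarray:
    """Resample a polyline at n_points equal arc-length stations."""
    pts = np.asarray(points, dtype=float)
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    if s[-1] == 0:
        raise ValueError("degenerate (zero-length) polyline")
    targets = np.linspace(0.0, s[-1], n_points)
    out = np.empty((n_points, pts.shape[1]))
    for d in range(pts.shape[1]):
        out[:, d] = np.interp(targets, s, pts[:, d])
    return out


def _skeleton_graph(coords: np.ndarray, spacing: np.ndarray):
    """26-connected graph over skeleton voxels, edge weights in mm."""
    index = {tuple(c): i for i, c in enumerate(coords)}
    offsets = np.array(
        [
            (dz, dy, dx)
            for dz in (-1, 0, 1)
            for dy in (-1, 0, 1)
            for dx in (-1, 0, 1)
            if (dz, dy, dx) != (0, 0, 0)
        ]
    )
    rows, cols, weights = [], [], []
    for i, c in enumerate(coords):
        for off in offsets:
            j = index.get(tuple(c + off))
            if j is not None and j > i:
                w = float(np.linalg.norm(off * spacing))
                rows.append(i)
                cols.append(j)
                weights.append(w)
    n = len(coords)
    g = sparse.coo_matrix((weights, (rows, cols)), shape=(n, n))
    return (g + g.T).tocsr()


def _smooth_path(pts: np.ndarray, step_mm: float, window_mm: float = 0.5) -> np.ndarray:
    """Suppress voxel staircase: dense resample + moving-average smoothing.

    The medial-axis voxel path zig-zags at one-voxel amplitude, inflating
    its polyline length; averaging over a physical window much larger than
    a voxel but much smaller than anatomical curvature radii removes the
    jitter with negligible shortening.  Endpoints stay fixed.
    """
    from scipy.ndimage import uniform_filter1d

    n_dense = max(int(np.linalg.norm(np.diff(pts, axis=0), axis=1).sum() / step_mm), 10)
    dense = resample_polyline(pts, n_dense)
    w = max(3, int(round(window_mm / step_mm)))
    if len(dense) <= w:
        return dense
    sm = dense.copy()
    for _ in range(2):
        for d in range(sm.shape[1]):
            sm[:, d] = uniform_filter1d(sm[:, d], w, mode="nearest")
        sm[0] = dense[0]
        sm[-1] = dense[-1]
    return sm


def _extend_to_boundary(
    path: np.ndarray, mask: BinaryMask, step_mm: float
) -> np.ndarray:
    """Extend both path ends along their tangents to the mask boundary.

    Skeletonization retracts from rounded tube ends by about one tube
    radius; walking the end tangents until the ray exits the foreground
    restores the full anatomical length.
    """
    spacing = np.asarray(mask.spacing)

    def inside(p: np.ndarray) -> bool:
        idx = np.round((p - np.asarray(mask.origin)) / spacing).astype(int)
        if (idx < 0).any() or (idx >= np.asarray(mask.shape)).any():
            return False
        return bool(mask.data[tuple(idx)])

    def extend(end: np.ndarray, tangent: np.ndarray) -> np.ndarray | None:
        t = tangent / np.linalg.norm(tangent)
        p = end.copy()
        last_inside = None
        for _ in range(10000):
            p = p + t * step_mm
            if not inside(p):
                break
            last_inside = p.copy()
        return last_inside

    # tangent from a few points back to average out voxel jitter
    k = min(6, len(path) - 1)
    head = extend(path[0], path[0] - path[k])
    tail = extend(path[-1], path[-1] - path[-1 - k])
    parts = []
    if head is not None:
        parts.append(head[None, :])
    parts.append(path)
    if tail is not None:
        parts.append(tail[None, :])
    return np.concatenate(parts, axis=0)


def centerline_from_mask(mask: BinaryMask, n_points: int = 100) -> Polyline3D:
    """Ordered centerline polyline of a single tubular component.

    Skeletonizes the mask, finds the two skeleton tips farthest apart by
    graph geodesic distance (ties broken by voxel coordinate order), walks
    the geodesic path between them, extends both ends to the mask
    boundary, smooths, and resamples to ``n_points``.

    Raises if the skeleton has no two-tip path (e.g. a sphere mask).
    """
    if n_points < 2:
        raise ValueError("n_points must be >= 2")
    if mask.count() == 0:
        raise ValueError("empty mask")
    skel = skeletonize(mask.data)
    coords = np.argwhere(skel)
    if len(coords) < 2:
        raise ValueError("skeleton degenerate: no tubular axis found")
    spacing = np.asarray(mask.spacing)
    graph = _skeleton_graph(coords, spacing)
    degrees = np.asarray((graph > 0).sum(axis=1)).ravel()
    tips = np.flatnonzero(degrees == 1)
    if len(tips) < 2:
        raise ValueError(
            "skeleton has no two free tips (cycle-dominated or blob-like mask)"
        )
    # geodesic distances between all tips; pick the farthest pair
    dist, pred = dijkstra(graph, indices=tips, return_predecessors=True)
    dist_tips = dist[:, tips]
    dist_tips[~np.isfinite(dist_tips)] = -1.0
    best = np.unravel_index(np.argmax(dist_tips), dist_tips.shape)
    if dist_tips[best] <= 0:
        raise ValueError("skeleton tips are disconnected")
    # tubularity guard: a blob-like mask (e.g. a sphere) may still skeletonize
    # to a short spur; require the axis to be several inscribed radii long
    r_max = float(ndimage.distance_transform_edt(mask.data, sampling=spacing).max())
    if dist_tips[best] < 4.0 * r_max:
        raise ValueError(
            "mask is not tubular: longest skeleton path "
            f"({dist_tips[best]:.3g} mm) is not much longer than the maximal "
            f"inscribed radius ({r_max:.3g} mm)"
        )
    a_row, b_col = best
    src, dst = tips[a_row], tips[b_col]
    # deterministic orientation: start at the lexicographically smaller voxel
    if tuple(coords[dst]) < tuple(coords[src]):
        src_row = np.flatnonzero(tips == dst)[0]
        src, dst = dst, src
        a_row = src_row
    path_idx = [dst]
    while path_idx[-1] != src:
        p = pred[a_row, path_idx[-1]]
        if p < 0:
            raise ValueError("failed to trace skeleton path")
        path_idx.append(int(p))
    path_idx.reverse()
    world = coords[path_idx] * spacing + np.asarray(mask.origin)
    step = float(spacing.min())
    world = _smooth_path(world, step_mm=step)
    world = _extend_to_boundary(world, mask, step_mm=step / 4.0)
    return Polyline3D(resample_polyline(world, n_points))
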