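"""Core data types and I/O for volumetric morphometry.

Conventions used throughout the package:

* Voxel arrays are indexed ``(z, y, x)`` with axis 0 the anatomical /
  scan longitudinal axis.  Voxel indices are 0-based.
* ``spacing`` is ``(sz, sy, sx)`` in mm per voxel, each strictly positive.
* World coordinates are voxel *centers* in mm:
  ``world(i, j, k) = origin + (i * sz, j * sy, k * sx)``.
* All physical outputs are mm, mm^2 or mm^3.
* Slice ranges are half-open ``[start, stop)``.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import nibabel as nib
import numpy as np
import pandas as pd
import tifffile
import trimesh

__all__ = [
    "VoxelVolume",
    "BinaryMask",
    "Polyline3D",
    "SurfaceMesh",
    "LandmarkSet",
    "StudyTable",
    "read_volume",
    "write_volume",
    "read_mesh",
    "write_mesh",
    "read_landmarks",
    "write_landmarks",
    "read_results",
    "write_results",
]


def _validate_spacing(spacing: Sequence[float]) -> tuple[float, float, float]:
    sp = tuple(float(s) for s in spacing)
    if len(sp) != 3:
        raise ValueError(f"spacing must have 3 components, got {len(sp)}")
    if not all(np.isfinite(s) and s > 0 for s in sp):
        raise ValueError(f"spacing components must be finite and > 0, got {sp}")
    return sp  # type: ignore[return-value]


@dataclass
class VoxelVolume:
    """A 3D scalar image with anisotropic voxel spacing.

    Parameters
    ----------
    data : ndarray, shape (nz, ny, nx)
        Scalar gray values, index order ``(z, y, x)``.
    spacing : (sz, sy, sx)
        Voxel size in mm along each axis; all components > 0.
    origin : (z0, y0, x0)
        World coordinate (mm) of the center of voxel ``(0, 0, 0)``.
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"data must be 3D, got ndim={self.data.ndim}")
        self.spacing = _validate_spacing(self.spacing)
        self.origin = tuple(float(o) for o in self.origin)  # type: ignore[assignment]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    def voxel_volume(self) -> float:
        """Volume of one voxel in mm^3."""
        sz, sy, sx = self.spacing
        return sz * sy * sx

    def index_to_world(self, indices: np.ndarray) -> np.ndarray:
        """Map fractional voxel indices (..., 3) to world mm coordinates."""
        idx = np.asarray(indices, dtype=float)
        return idx * np.asarray(self.spacing) + np.asarray(self.origin)

    def world_to_index(self, points: np.ndarray) -> np.ndarray:
        """Inverse of :meth:`index_to_world` (fractional indices)."""
        pts = np.asarray(points, dtype=float)
        return (pts - np.asarray(self.origin)) / np.asarray(self.spacing)


@dataclass
class BinaryMask(VoxelVolume):
    """Segmented foreground on the same grid as its source volume."""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.dtype != bool:
            self.data = self.data.astype(bool)
        super().__post_init__()

    def count(self) -> int:
        return int(np.count_nonzero(self.data))

    def volume_mm3(self) -> float:
        """Foreground volume: voxel count times voxel volume."""
        return self.count() * self.voxel_volume()

    def same_geometry(self, other: VoxelVolume) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing)
            and np.allclose(self.origin, other.origin)
        )


@dataclass
class Polyline3D:
    """An ordered polyline in world coordinates (mm), optionally closed.

    Points may be 2D (projection-plane measurements) or 3D; lengths are
    piecewise-linear sums of consecutive Euclidean segment lengths.
    """

    points: np.ndarray
    closed: bool = False

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[0] < 2 or pts.shape[1] not in (2, 3):
            raise ValueError(
                f"points must be (n>=2, 2 or 3), got shape {pts.shape}"
            )
        if not np.isfinite(pts).all():
            raise ValueError("polyline contains non-finite coordinates")
        self.points = pts

    def __len__(self) -> int:
        return self.points.shape[0]

    def segment_lengths(self) -> np.ndarray:
        diffs = np.diff(self.points, axis=0)
        seg = np.linalg.norm(diffs, axis=1)
        if self.closed:
            seg = np.append(seg, np.linalg.norm(self.points[0] - self.points[-1]))
        return seg

    def length(self) -> float:
        """Total polyline length in mm (includes closing segment if closed)."""
        return float(self.segment_lengths().sum())

    def chord(self) -> float:
        """Straight-line distance between endpoints (open polylines)."""
        return float(np.linalg.norm(self.points[-1] - self.points[0]))


@dataclass
class SurfaceMesh:
    """A triangle mesh with vertices in world mm coordinates."""

    vertices: np.ndarray
    faces: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=float)
        f = np.asarray(self.faces, dtype=np.int64)
        if v.ndim != 2 or v.shape[1] != 3:
            raise ValueError(f"vertices must be (n, 3), got {v.shape}")
        if f.ndim != 2 or f.shape[1] != 3:
            raise ValueError(f"faces must be (m, 3), got {f.shape}")
        if f.size and (f.min() < 0 or f.max() >= len(v)):
            raise ValueError("face indices out of range")
        self.vertices = v
        self.faces = f

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def face_areas(self) -> np.ndarray:
        tri = self.vertices[self.faces]
        cross = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
        return 0.5 * np.linalg.norm(cross, axis=1)

    def area(self) -> float:
        """Total surface area in mm^2."""
        return float(self.face_areas().sum())

    def face_normals(self) -> np.ndarray:
        tri = self.vertices[self.faces]
        cross = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
        norm = np.linalg.norm(cross, axis=1)
        norm[norm == 0] = 1.0
        return cross / norm[:, None]

    def face_centroids(self) -> np.ndarray:
        return self.vertices[self.faces].mean(axis=1)

    def remove_degenerate_faces(self, area_tol: float = 1e-12) -> "SurfaceMesh":
        """Return a copy without (near) zero-area faces."""
        keep = self.face_areas() > area_tol
        return SurfaceMesh(self.vertices, self.faces[keep])

    def boundary_edges(self) -> np.ndarray:
        """Edges used by exactly one face, as (n, 2) sorted vertex pairs."""
        edges = np.concatenate(
            [self.faces[:, [0, 1]], self.faces[:, [1, 2]], self.faces[:, [2, 0]]]
        )
        edges = np.sort(edges, axis=1)
        uniq, counts = np.unique(edges, axis=0, return_counts=True)
        return uniq[counts == 1]

    def boundary_loops(self) -> list[np.ndarray]:
        """Partition boundary edges into closed loops of vertex indices.

        Each loop is an ordered array of vertex indices; the closing edge
        (last -> first) is implicit.
        """
        edges = self.boundary_edges()
        if len(edges) == 0:
            return []
        adj: dict[int, list[int]] = {}
        for a, b in edges:
            adj.setdefault(int(a), []).append(int(b))
            adj.setdefault(int(b), []).append(int(a))
        for v, nbrs in adj.items():
            if len(nbrs) != 2:
                raise ValueError(
                    "boundary edges do not form simple loops "
                    f"(vertex {v} has {len(nbrs)} boundary neighbours)"
                )
        loops: list[np.ndarray] = []
        visited: set[int] = set()
        for start in sorted(adj):
            if start in visited:
                continue
            loop = [start]
            visited.add(start)
            prev, cur = start, adj[start][0]
            while cur != start:
                loop.append(cur)
                visited.add(cur)
                nxt = adj[cur][0] if adj[cur][0] != prev else adj[cur][1]
                prev, cur = cur, nxt
            loops.append(np.asarray(loop, dtype=np.int64))
        return loops

    def to_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(
            vertices=self.vertices, faces=self.faces, process=False
        )


@dataclass
class LandmarkSet:
    """Named anatomical points, all 2D or all 3D, in world mm."""

    points: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        cleaned: dict[str, np.ndarray] = {}
        dim: int | None = None
        for label, p in self.points.items():
            arr = np.asarray(p, dtype=float)
            if arr.shape not in ((2,), (3,)):
                raise ValueError(f"landmark {label!r} must be 2D or 3D")
            if dim is None:
                dim = arr.shape[0]
            elif arr.shape[0] != dim:
                raise ValueError("mixed 2D/3D landmarks in one set")
            cleaned[str(label)] = arr
        self.points = cleaned

    def __getitem__(self, label: str) -> np.ndarray:
        if label not in self.points:
            raise KeyError(f"landmark {label!r} not present")
        return self.points[label]

    def __contains__(self, label: str) -> bool:
        return label in self.points

    def require(self, *labels: str) -> list[np.ndarray]:
        missing = [lb for lb in labels if lb not in self.points]
        if missing:
            raise KeyError(f"missing landmarks: {missing}")
        return [self.points[lb] for lb in labels]


_STUDY_COLUMNS = ["animal_id", "genotype", "sex", "age_weeks", "measurement", "value"]
_GENOTYPES = ("WT", "Ach")


@dataclass
class StudyTable:
    """Long-format per-animal measurement records for a two-group study.

    One row per (animal, measurement, age): columns ``animal_id``,
    ``genotype`` (WT or Ach), ``sex``, ``age_weeks``, ``measurement``,
    ``value``.  Keys ``(animal_id, measurement, age_weeks)`` are unique and
    all values are finite.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.df)
        missing = [c for c in _STUDY_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"study table missing columns: {missing}")
        df = df[_STUDY_COLUMNS].reset_index(drop=True)
        bad = set(df["genotype"].unique()) - set(_GENOTYPES)
        if bad:
            raise ValueError(f"unknown genotypes: {sorted(bad)}")
        if not np.isfinite(df["value"].to_numpy(dtype=float)).all():
            raise ValueError("study table contains non-finite values")
        dup = df.duplicated(subset=["animal_id", "measurement", "age_weeks"])
        if dup.any():
            raise ValueError(
                f"duplicate (animal_id, measurement, age_weeks) keys: "
                f"{df.loc[dup, ['animal_id', 'measurement', 'age_weeks']].values[:5]}"
            )
        self.df = df

    @classmethod
    def from_records(cls, records: Iterable[Mapping]) -> "StudyTable":
        return cls(pd.DataFrame(list(records)))

    def measurements(self) -> list[str]:
        return sorted(self.df["measurement"].unique())

    def __len__(self) -> int:
        return len(self.df)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def read_volume(
    path: str | os.PathLike,
    format: str | None = None,
    spacing: Sequence[float] | None = None,
) -> VoxelVolume:
    """Read a 3D volume from NIfTI or a multi-page TIFF stack.

    NIfTI spacing comes from the header; TIFF stacks carry no reliable 3D
    spacing, so ``spacing`` must be supplied for them.  Missing spacing is
    an error — it is never silently assumed to be 1.0.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        suffixes = "".join(path.suffixes).lower()
        if suffixes.endswith((".nii", ".nii.gz")):
            format = "nifti"
        elif suffixes.endswith((".tif", ".tiff")):
            format = "tiff_stack"
        else:
            raise ValueError(f"cannot infer format from {path.name!r}")
    if format == "nifti":
        img = nib.load(str(path))
        data = np.asarray(img.dataobj)
        if data.ndim != 3:
            raise ValueError(f"expected 3D NIfTI, got ndim={data.ndim}")
        # NIfTI stores (x, y, z); transpose to the package's (z, y, x).
        data = np.transpose(data, (2, 1, 0))
        if spacing is None:
            zooms = img.header.get_zooms()[:3]
            spacing = (float(zooms[2]), float(zooms[1]), float(zooms[0]))
            if not all(np.isfinite(s) and s > 0 for s in spacing):
                raise ValueError(
                    f"NIfTI header of {path.name} has invalid zooms {zooms}; "
                    "supply spacing explicitly"
                )
        return VoxelVolume(data, tuple(spacing))
    if format == "tiff_stack":
        data = tifffile.imread(str(path))
        if data.ndim != 3:
            raise ValueError(f"expected 3D TIFF stack, got ndim={data.ndim}")
        if spacing is None:
            raise ValueError(
                f"TIFF stack {path.name} carries no 3D spacing metadata; "
                "supply spacing=(sz, sy, sx) explicitly"
            )
        return VoxelVolume(data, tuple(spacing))
    raise ValueError(f"unknown format {format!r}")


def write_volume(
    vol: VoxelVolume, path: str | os.PathLike, format: str | None = None
) -> None:
    """Write a volume to NIfTI (spacing in header) or TIFF stack."""
    path = Path(path)
    if format is None:
        suffixes = "".join(path.suffixes).lower()
        format = "nifti" if suffixes.endswith((".nii", ".nii.gz")) else "tiff_stack"
    if format == "nifti":
        sz, sy, sx = vol.spacing
        affine = np.diag([sx, sy, sz, 1.0])
        img = nib.Nifti1Image(np.transpose(vol.data, (2, 1, 0)), affine)
        img.header.set_zooms((sx, sy, sz))
        nib.save(img, str(path))
    elif format == "tiff_stack":
        tifffile.imwrite(str(path), vol.data, photometric="minisblack")
    else:
        raise ValueError(f"unknown format {format!r}")


def write_mesh(mesh: SurfaceMesh, path: str | os.PathLike, format: str | None = None) -> None:
    """Write a mesh as STL or PLY (inferred from the extension)."""
    if mesh.n_faces == 0 or mesh.n_vertices == 0:
        raise ValueError("refusing to write an empty mesh")
    path = Path(path)
    if format is None:
        format = path.suffix.lstrip(".").lower()
    if format not in ("stl", "ply"):
        raise ValueError(f"unsupported mesh format {format!r}")
    tm = mesh.to_trimesh()
    tm.export(str(path), file_type=format)


def read_mesh(path: str | os.PathLike) -> SurfaceMesh:
    tm = trimesh.load_mesh(str(path), process=False)
    return SurfaceMesh(np.asarray(tm.vertices), np.asarray(tm.faces))


def write_landmarks(landmarks: LandmarkSet, path: str | os.PathLike) -> None:
    payload = {k: [float(x) for x in v] for k, v in landmarks.points.items()}
    Path(path).write_text(json.dumps(payload, indent=2))


def read_landmarks(path: str | os.PathLike) -> LandmarkSet:
    payload = json.loads(Path(path).read_text())
    return LandmarkSet({k: np.asarray(v, dtype=float) for k, v in payload.items()})


def write_results(table: StudyTable, path: str | os.PathLike) -> None:
    """Write a study table as CSV with stable column order.

    Values round-trip to 12 significant digits.
    """
    table.df.to_csv(path, index=False, float_format="%.17g")


def read_results(path: str | os.PathLike) -> StudyTable:
    return StudyTable(pd.read_csv(path))
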