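"""Synthetic phantoms with analytic ground truth.

Every input class the morphometry pipeline consumes can be emulated here:
curved tubular bones, plate trabecular lattices, growth-plate slabs,
wedges and shells, skull-like shells, ellipsoidal brains, curved vertebral
columns, aperture plates for foramen work, and two-group study tables.
Each phantom carries the closed-form values of every measurable it
supports, so parameter recovery can be asserted against exact analytic
truth.

Gray-level rendering places foreground at mean 100 and background at mean
20 (clipped to [0, 255]), so the standard segmentation threshold of 40
separates them correctly at zero noise.  All randomness flows from the
seed in the spec; identical specs produce bit-identical volumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy.spatial import cKDTree

from .voxgrid import (
    BinaryMask,
    LandmarkSet,
    Polyline3D,
    StudyTable,
    SurfaceMesh,
    VoxelVolume,
)

__all__ = [
    "PhantomSpec",
    "GroundTruth",
    "PhantomData",
    "generate",
    "generate_study",
    "aperture_plate_mesh",
    "DEFAULT_STUDY_MEASUREMENTS",
]

FOREGROUND_MEAN = 100.0
BACKGROUND_MEAN = 20.0

PHANTOM_KINDS = (
    "curved_tube",
    "plate_lattice",
    "gp_slab",
    "gp_wedge",
    "gp_shell",
    "skull_shell_aperture",
    "ellipsoid",
    "vertebral_column",
)


class GroundTruth(dict):
    """Analytic values for every measurable a phantom supports (mm units)."""


@dataclass
class PhantomSpec:
    """Declarative phantom description.

    ``params`` hold the kind-specific geometry in mm (see the individual
    builders); ``spacing`` is scalar (isotropic) or a (sz, sy, sx) triple;
    ``noise_sd`` is additive Gaussian gray-level noise; ``seed`` drives all
    randomness.
    """

    kind: str
    params: dict = field(default_factory=dict)
    spacing: float | tuple[float, float, float] = 0.05
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in PHANTOM_KINDS:
            raise ValueError(f"unknown phantom kind {self.kind!r}")
        if np.isscalar(self.spacing):
            self.spacing = (float(self.spacing),) * 3  # type: ignore[assignment]

    @property
    def spacing3(self) -> tuple[float, float, float]:
        return self.spacing  # type: ignore[return-value]


@dataclass
class PhantomData:
    volume: VoxelVolume
    mask: BinaryMask
    truth: GroundTruth
    landmarks: LandmarkSet
    aux: dict = field(default_factory=dict)


def _grid(shape, spacing, origin=(0.0, 0.0, 0.0)):
    """World coordinates of voxel centers along each axis."""
    return [
        origin[d] + np.arange(shape[d]) * spacing[d] for d in range(3)
    ]


def _render(mask: np.ndarray, spacing, origin, noise_sd: float, seed: int) -> VoxelVolume:
    rng = np.random.default_rng(seed)
    gray = np.where(mask, FOREGROUND_MEAN, BACKGROUND_MEAN).astype(np.float32)
    if noise_sd > 0:
        gray = gray + rng.normal(0.0, noise_sd, size=mask.shape).astype(np.float32)
    np.clip(gray, 0.0, 255.0, out=gray)
    return VoxelVolume(gray, spacing, origin)


# ---------------------------------------------------------------------------
# individual phantom builders
# ---------------------------------------------------------------------------


def _helix_points(R: float, c: float, theta_max: float, n: int) -> np.ndarray:
    theta = np.linspace(0.0, theta_max, n)
    # (z, y, x) world coordinates
    return np.stack([c * theta, R * np.sin(theta), R * np.cos(theta) - R], axis=1)


def _build_curved_tube(spec: PhantomSpec):
    p = spec.params
    R = float(p.get("helix_radius", 3.0))       # mm
    c = float(p.get("pitch", 1.0))              # mm per radian of turn
    theta_max = float(p.get("theta_max", 2.0 * np.pi))
    tube_r = float(p.get("tube_radius", 0.3))
    sp = spec.spacing3
    margin = tube_r + 2 * max(sp)
    n_curve = max(64, int(np.ceil(theta_max * np.sqrt(R**2 + c**2) / (min(sp) / 2))))
    curve = _helix_points(R, c, theta_max, n_curve)
    lo = curve.min(axis=0) - margin
    hi = curve.max(axis=0) + margin
    shape = tuple(int(np.ceil((hi[d] - lo[d]) / sp[d])) + 1 for d in range(3))
    axes = _grid(shape, sp, lo)
    zz, yy, xx = np.meshgrid(*axes, indexing="ij")
    pts = np.stack([zz.ravel(), yy.ravel(), xx.ravel()], axis=1)
    tree = cKDTree(curve)
    dist, nearest = tree.query(pts, workers=-1)
    # flat ends: drop voxels whose nearest curve point is an endpoint, so the
    # tube terminates on planes through the curve endpoints
    interior = (nearest > 0) & (nearest < len(curve) - 1)
    mask = ((dist <= tube_r) & interior).reshape(shape)
    length = theta_max * np.sqrt(R**2 + c**2)
    truth = GroundTruth(length_mm=length, tube_radius_mm=tube_r)
    landmarks = LandmarkSet({"start": curve[0], "end": curve[-1]})
    aux = {"curve": Polyline3D(curve)}
    return mask, sp, tuple(lo), truth, landmarks, aux


def _build_plate_lattice(spec: PhantomSpec):
    p = spec.params
    t = float(p.get("plate_thickness", 0.1))
    period = float(p.get("period", 0.4))
    n_periods = int(p.get("n_periods", 3))
    lateral = float(p.get("lateral_extent", 0.6))
    sp = spec.spacing3
    n_margin = int(np.ceil(period / sp[0]))  # background pad above and below
    nz_core = int(round(n_periods * period / sp[0]))
    ny = int(round(lateral / sp[1]))
    nx = int(round(lateral / sp[2]))
    z = np.arange(nz_core) * sp[0]
    fg_z = np.mod(z, period) < t - 1e-9 * t  # whole plates, exact fill t/period
    mask = np.zeros((nz_core + 2 * n_margin, ny, nx), dtype=bool)
    mask[n_margin : n_margin + nz_core][fg_z] = True
    truth = GroundTruth(
        bv_tv=t / period,
        tb_th_mm=t,
        tb_n_per_mm=1.0 / period,
        plate_thickness_mm=t,
        period_mm=period,
    )
    aux = {"voi_slices": (n_margin, n_margin + nz_core)}
    return mask, sp, (0.0, 0.0, 0.0), truth, LandmarkSet({}), aux


def _build_gp_slab(spec: PhantomSpec):
    p = spec.params
    X = float(p.get("footprint_x", 10.0))
    Y = float(p.get("footprint_y", 10.0))
    t = float(p.get("thickness", 0.2))
    sp = spec.spacing3
    nz = int(round(t / sp[0]))
    ny = int(round(Y / sp[1]))
    nx = int(round(X / sp[2]))
    m = 2  # background margin voxels on every side
    mask = np.zeros((nz + 2 * m, ny + 2 * m, nx + 2 * m), dtype=bool)
    mask[m : m + nz, m : m + ny, m : m + nx] = True
    area = X * Y
    truth = GroundTruth(
        volume_mm3=area * t,
        thickness_mm=t,
        footprint_area_mm2=area,
        ratio_mm2=area,
    )
    return mask, sp, (0.0, 0.0, 0.0), truth, LandmarkSet({}), {}


def _build_gp_wedge(spec: PhantomSpec):
    p = spec.params
    X = float(p.get("footprint_x", 10.0))
    Y = float(p.get("footprint_y", 10.0))
    t0 = float(p.get("thickness_min", 0.1))
    t1 = float(p.get("thickness_max", 0.3))
    sp = spec.spacing3
    nz = int(np.ceil(t1 / sp[0]))
    ny = int(round(Y / sp[1]))
    nx = int(round(X / sp[2]))
    y = np.arange(ny) * sp[1]
    t_of_y = t0 + (t1 - t0) * y / (Y - sp[1])
    z = np.arange(nz) * sp[0]
    core = (z[:, None] < t_of_y[None, :] - 1e-12)[:, :, None] & np.ones(
        (1, 1, nx), dtype=bool
    )
    m = 2  # background margin voxels on every side
    mask = np.zeros((nz + 2 * m, ny + 2 * m, nx + 2 * m), dtype=bool)
    mask[m : m + nz, m : m + ny, m : m + nx] = core
    area = X * Y
    mean_t = 0.5 * (t0 + t1)
    truth = GroundTruth(
        volume_mm3=area * mean_t,
        thickness_mean_mm=mean_t,
        thickness_min_mm=t0,
        thickness_max_mm=t1,
        footprint_area_mm2=area,
        ratio_mm2=area * mean_t / mean_t,
    )
    return mask, sp, (0.0, 0.0, 0.0), truth, LandmarkSet({}), {}


def _build_gp_shell(spec: PhantomSpec):
    p = spec.params
    R = float(p.get("outer_radius", 3.0))
    t = float(p.get("thickness", 0.2))
    cap_deg = float(p.get("cap_angle_deg", 90.0))
    rim_factor = float(p.get("rim_thickening", 1.0))  # >1: thicker at the rim
    sp = spec.spacing3
    cap = np.deg2rad(cap_deg)
    r_in = R - t
    margin = 2 * max(sp)
    lat = R * np.sin(min(cap, np.pi / 2)) if cap < np.pi / 2 else R
    lo = (R * np.cos(cap) - t - margin if cap <= np.pi / 2 else -R - margin, -lat - margin, -lat - margin)
    hi = (R + margin, lat + margin, lat + margin)
    shape = tuple(int(np.ceil((hi[d] - lo[d]) / sp[d])) + 1 for d in range(3))
    axes = _grid(shape, sp, lo)
    zz, yy, xx = np.meshgrid(*axes, indexing="ij")
    rad = np.sqrt(zz**2 + yy**2 + xx**2)
    with np.errstate(invalid="ignore", divide="ignore"):
        theta = np.arccos(np.clip(zz / np.maximum(rad, 1e-12), -1, 1))
    local_t = t * (1.0 + (rim_factor - 1.0) * (theta / cap) ** 2)
    mask = (rad <= R) & (rad >= R - local_t) & (theta <= cap)
    frac = (1.0 - np.cos(cap)) / 2.0
    vol_const = 4.0 * np.pi / 3.0 * (R**3 - r_in**3) * frac
    truth = GroundTruth(
        thickness_mm=t,
        outer_radius_mm=R,
        inner_radius_mm=r_in,
    )
    if rim_factor == 1.0:
        truth["volume_mm3"] = vol_const
    return mask, sp, tuple(lo), truth, LandmarkSet({}), {}


def _build_skull_shell(spec: PhantomSpec):
    p = spec.params
    R = float(p.get("outer_radius", 5.0))
    r = float(p.get("inner_radius", 4.8))
    ap_deg = float(p.get("aperture_angle_deg", 0.0))  # cone half-angle around -z
    sp = spec.spacing3
    margin = 2 * max(sp)
    lo = (-R - margin,) * 3
    shape = tuple(int(np.ceil(2 * (R + margin) / sp[d])) + 1 for d in range(3))
    axes = _grid(shape, sp, lo)
    zz, yy, xx = np.meshgrid(*axes, indexing="ij")
    rad = np.sqrt(zz**2 + yy**2 + xx**2)
    mask = (rad <= R) & (rad >= r)
    removed = 0.0
    if ap_deg > 0:
        ap = np.deg2rad(ap_deg)
        with np.errstate(invalid="ignore"):
            theta = np.arccos(np.clip(-zz / np.maximum(rad, 1e-12), -1, 1))
        mask &= theta > ap
        removed = (1.0 - np.cos(ap)) / 2.0
    vol = 4.0 * np.pi / 3.0 * (R**3 - r**3) * (1.0 - removed)
    truth = GroundTruth(volume_mm3=vol, outer_radius_mm=R, inner_radius_mm=r)
    if ap_deg > 0:
        sin_ap = np.sin(np.deg2rad(ap_deg))
        truth["aperture_diameter_mm"] = 2 * R * sin_ap
        truth["aperture_circumference_mm"] = 2 * np.pi * R * sin_ap
    return mask, sp, lo, truth, LandmarkSet({}), {}


def _build_ellipsoid(spec: PhantomSpec):
    p = spec.params
    a = float(p.get("semi_x", 8.0))   # in-plane x
    b = float(p.get("semi_y", 6.0))   # in-plane y
    c = float(p.get("semi_z", 5.0))   # along the slice axis (axis 0)
    sp = spec.spacing3
    margin = 2 * max(sp)
    lo = (-c - margin, -b - margin, -a - margin)
    hi = (c + margin, b + margin, a + margin)
    shape = tuple(int(np.ceil((hi[d] - lo[d]) / sp[d])) + 1 for d in range(3))
    axes = _grid(shape, sp, lo)
    zz, yy, xx = np.meshgrid(*axes, indexing="ij")
    mask = (xx / a) ** 2 + (yy / b) ** 2 + (zz / c) ** 2 <= 1.0
    truth = GroundTruth(volume_mm3=4.0 * np.pi / 3.0 * a * b * c)
    aux = {
        "slice_masks": [mask[i] for i in range(shape[0])],
        "slice_thickness_mm": sp[0],
        "in_plane_spacing_mm": (sp[1], sp[2]),
    }
    return mask, sp, lo, truth, LandmarkSet({}), aux


def _build_vertebral_column(spec: PhantomSpec):
    p = spec.params
    chord = float(p.get("chord", 20.0))     # straight span along z
    sagitta = float(p.get("sagitta", 5.0))  # max dorsal deviation
    tube_r = float(p.get("tube_radius", 0.5))
    n = int(p.get("n_profile", 200))
    if sagitta <= 0 or chord <= 0:
        raise ValueError("chord and sagitta must be positive")
    R_arc = (sagitta**2 + (chord / 2.0) ** 2) / (2.0 * sagitta)
    half_angle = np.arcsin(min(1.0, chord / (2.0 * R_arc)))
    if sagitta > R_arc:  # superhemicircular arc: angle beyond pi/2
        half_angle = np.pi - half_angle
    phi = np.linspace(-half_angle, half_angle, n)
    # arc in the sagittal (z, y) plane, bowing toward +y
    z = R_arc * np.sin(phi)
    y = sagitta - R_arc * (1 - np.cos(phi))
    profile2d = np.stack([z, y], axis=1)
    seeds3d = np.stack([z, y, np.zeros_like(z)], axis=1)
    arc_length = 2.0 * R_arc * half_angle
    sp = spec.spacing3
    margin = tube_r + 2 * max(sp)
    lo = (z.min() - margin, min(y.min(), 0) - margin, -tube_r - margin)
    hi = (z.max() + margin, y.max() + margin, tube_r + margin)
    shape = tuple(int(np.ceil((hi[d] - lo[d]) / sp[d])) + 1 for d in range(3))
    axes = _grid(shape, sp, lo)
    zz, yy, xx = np.meshgrid(*axes, indexing="ij")
    pts = np.stack([zz.ravel(), yy.ravel(), xx.ravel()], axis=1)
    dense = np.stack(
        [
            R_arc * np.sin(np.linspace(-half_angle, half_angle, 4 * n)),
            sagitta - R_arc * (1 - np.cos(np.linspace(-half_angle, half_angle, 4 * n))),
            np.zeros(4 * n),
        ],
        axis=1,
    )
    dist, _ = cKDTree(dense).query(pts, workers=-1)
    mask = (dist <= tube_r).reshape(shape)
    truth = GroundTruth(
        kyphosis_index=chord / sagitta,
        arc_length_mm=arc_length,
        chord_mm=chord,
        sagitta_mm=sagitta,
    )
    landmarks = LandmarkSet(
        {"cranial": profile2d[0], "caudal": profile2d[-1]}
    )
    aux = {"profile": Polyline3D(profile2d), "canal_seeds": Polyline3D(seeds3d)}
    return mask, sp, lo, truth, landmarks, aux


_BUILDERS: dict[str, Callable] = {
    "curved_tube": _build_curved_tube,
    "plate_lattice": _build_plate_lattice,
    "gp_slab": _build_gp_slab,
    "gp_wedge": _build_gp_wedge,
    "gp_shell": _build_gp_shell,
    "skull_shell_aperture": _build_skull_shell,
    "ellipsoid": _build_ellipsoid,
    "vertebral_column": _build_vertebral_column,
}


def generate(spec: PhantomSpec) -> PhantomData:
    """Build the phantom described by ``spec``.

    Returns the rendered gray volume, the exact foreground mask, the
    analytic ground truth, any landmarks, plus kind-specific auxiliary
    objects (seed curves, slice masks, profiles).
    """
    mask_arr, sp, origin, truth, landmarks, aux = _BUILDERS[spec.kind](spec)
    if not mask_arr.any():
        raise ValueError("phantom geometry produced an empty mask (exceeds grid?)")
    volume = _render(mask_arr, sp, origin, spec.noise_sd, spec.seed)
    mask = BinaryMask(mask_arr, sp, origin)
    return PhantomData(volume=volume, mask=mask, truth=truth, landmarks=landmarks, aux=aux)


# ---------------------------------------------------------------------------
# parametric aperture plate (foramen magnum stand-in)
# ---------------------------------------------------------------------------


def aperture_plate_mesh(
    semi_transverse: float = 1.0,
    semi_sagittal: float = 1.0,
    outer_radius: float = 4.0,
    thickness: float = 0.5,
    n_angular: int = 256,
    n_radial: int = 12,
) -> SurfaceMesh:
    """Plate with an elliptical through-hole, open only at the hole rims.

    The plate's top and bottom sheets and its outer wall form one surface
    whose only boundary loops are the two hole rims — the situation at the
    foramen magnum after cropping the skull mesh.  The plate normal is x;
    the hole semi-axes lie along y (transverse, ``semi_transverse``) and z
    (sagittal, ``semi_sagittal``).
    """
    a, b = float(semi_transverse), float(semi_sagittal)
    if a <= 0 or b <= 0 or outer_radius <= max(a, b):
        raise ValueError("need 0 < hole semi-axes < outer_radius")
    phi = np.linspace(0.0, 2 * np.pi, n_angular, endpoint=False)
    # ellipse radius at each angle (y = r cos, z = r sin)
    r_hole = a * b / np.sqrt((b * np.cos(phi)) ** 2 + (a * np.sin(phi)) ** 2)
    frac = np.linspace(0.0, 1.0, n_radial + 1)
    rings = r_hole[None, :] + frac[:, None] * (outer_radius - r_hole[None, :])

    def sheet_vertices(x: float) -> np.ndarray:
        y = rings * np.cos(phi)[None, :]
        z = rings * np.sin(phi)[None, :]
        xs = np.full_like(y, x)
        return np.stack([xs.ravel(), y.ravel(), z.ravel()], axis=1)

    verts_top = sheet_vertices(+thickness / 2)
    verts_bot = sheet_vertices(-thickness / 2)
    verts = np.concatenate([verts_top, verts_bot])
    nv_sheet = len(verts_top)

    def vid(sheet: int, j: int, k: int) -> int:
        return sheet * nv_sheet + j * n_angular + (k % n_angular)

    faces = []
    for sheet in (0, 1):
        for j in range(n_radial):
            for k in range(n_angular):
                v00 = vid(sheet, j, k)
                v01 = vid(sheet, j, k + 1)
                v10 = vid(sheet, j + 1, k)
                v11 = vid(sheet, j + 1, k + 1)
                faces.append((v00, v01, v11))
                faces.append((v00, v11, v10))
    # outer wall between the two sheets' outermost rings
    for k in range(n_angular):
        t0 = vid(0, n_radial, k)
        t1 = vid(0, n_radial, k + 1)
        b0 = vid(1, n_radial, k)
        b1 = vid(1, n_radial, k + 1)
        faces.append((t0, t1, b1))
        faces.append((t0, b1, b0))
    return SurfaceMesh(verts, np.asarray(faces))


# ---------------------------------------------------------------------------
# synthetic study tables
# ---------------------------------------------------------------------------

# Realistic per-measurement (WT mean at 3wk, WT mean at 6wk, SD) values for a
# juvenile mouse: lengths in mm, volumes mm^3, BV/TV dimensionless.
DEFAULT_STUDY_MEASUREMENTS: dict[str, tuple[float, float, float]] = {
    "femur_length_mm": (11.0, 14.5, 0.5),
    "tibia_length_mm": (13.0, 17.0, 0.6),
    "bv_tv": (0.12, 0.18, 0.02),
    "gp_volume_mm3": (1.2, 0.9, 0.15),
    "brain_volume_mm3": (420.0, 460.0, 20.0),
    "kyphosis_index": (4.5, 4.8, 0.5),
}


def generate_study(
    n_per_group: int = 14,
    effects: dict[str, tuple[float, float]] | None = None,
    seed: int = 0,
    measurements: dict[str, tuple[float, float, float]] | None = None,
    ages: tuple[int, ...] = (3, 6),
) -> StudyTable:
    """Simulate a two-genotype (WT vs Ach), two-age study table.

    ``effects`` maps measurement name -> (shift at 3 wk, shift at 6 wk) in
    SD units applied to the Ach group; unlisted measurements get zero
    effect.  ``n_per_group`` animals per genotype-age cell (the default of
    14 yields a 56-animal study).  Values are Gaussian with the
    measurement's SD; everything is reproducible under ``seed``.
    """
    if n_per_group < 2:
        raise ValueError("need n_per_group >= 2")
    meas = measurements or DEFAULT_STUDY_MEASUREMENTS
    effects = effects or {}
    unknown = set(effects) - set(meas)
    if unknown:
        raise ValueError(f"effects name unknown measurements: {sorted(unknown)}")
    for name, eff in effects.items():
        if len(eff) != len(ages):
            raise ValueError(
                f"effect for {name!r} must give one shift per age {ages}"
            )
    rng = np.random.default_rng(seed)
    records = []
    animal = 0
    for age_i, age in enumerate(ages):
        for genotype in ("WT", "Ach"):
            for i in range(n_per_group):
                animal += 1
                aid = f"M{animal:03d}"
                sex = "F" if i % 2 else "M"
                for name, (m3, m6, sd) in meas.items():
                    base = m3 if age == 3 else m6 if age == 6 else np.interp(age, [3, 6], [m3, m6])
                    shift = 0.0
                    if genotype == "Ach" and name in effects:
                        shift = effects[name][age_i] * sd
                    records.append(
                        {
                            "animal_id": aid,
                            "genotype": genotype,
                            "sex": sex,
                            "age_weeks": age,
                            "measurement": name,
                            "value": float(base + shift + rng.normal(0.0, sd)),
                        }
                    )
    return StudyTable.from_records(records)
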