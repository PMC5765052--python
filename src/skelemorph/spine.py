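"""Spinal morphometry: kyphosis index, body length, pedicle and L4-L6 lengths.

The kyphosis index (KI) scores spinal curvature on a lateral projection:
KI = AB / CD, where AB is the straight distance between two landmark
points on the dorsal profile and CD is the maximum perpendicular distance
from the line AB to the profile between them.  A lower KI means a more
kyphotic (curved) spine.
"""

from __future__ import annotations

import warnings

import numpy as np

from . import longbone
from .voxgrid import LandmarkSet, Polyline3D

__all__ = ["kyphosis_index", "body_length", "pedicle_length", "l4l6_curved_length"]


def kyphosis_index(
    dorsal_profile: Polyline3D,
    start_landmark: np.ndarray | None = None,
    end_landmark: np.ndarray | None = None,
) -> float:
    """KI = AB / CD on a 2D lateral dorsal profile.

    ``start_landmark``/``end_landmark`` default to the profile endpoints.
    A perfectly straight profile has CD = 0 and returns +inf with a
    warning.
    """
    pts = dorsal_profile.points
    if pts.shape[1] != 2:
        raise ValueError("dorsal profile must be 2D (lateral projection)")
    if len(pts) < 3:
        raise ValueError("profile needs at least 3 points")
    a = pts[0] if start_landmark is None else np.asarray(start_landmark, dtype=float)
    b = pts[-1] if end_landmark is None else np.asarray(end_landmark, dtype=float)
    ab = float(np.linalg.norm(b - a))
    if ab == 0:
        raise ValueError("landmarks coincide")
    # perpendicular distance of each profile point to line AB
    d = b - a
    n = np.array([-d[1], d[0]]) / ab
    # restrict to points between the landmark feet along AB
    t = (pts - a) @ d / (ab * ab)
    between = (t >= 0) & (t <= 1)
    cd = float(np.abs((pts[between] - a) @ n).max()) if between.any() else 0.0
    if cd == 0:
        warnings.warn("straight profile: CD = 0, kyphosis index is infinite")
        return float("inf")
    return ab / cd


def body_length(landmarks: LandmarkSet) -> float:
    """Nose-to-tail-base length (mm) from a 2D radiograph landmark pair."""
    nasal, caudal = landmarks.require("nasal_tip", "first_caudal_base")
    return float(np.linalg.norm(caudal - nasal))


def pedicle_length(landmarks: LandmarkSet) -> float:
    """Mean of the left and right pedicle apex-to-base distances (mm)."""
    la, lb, ra, rb = landmarks.require(
        "left_apex", "left_base", "right_apex", "right_base"
    )
    left = float(np.linalg.norm(la - lb))
    right = float(np.linalg.norm(ra - rb))
    return 0.5 * (left + right)


def l4l6_curved_length(seeds: Polyline3D) -> float:
    """Curved lumbar (L4-L6) length: seed polyline through the canal."""
    return longbone.curved_length(seeds)
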