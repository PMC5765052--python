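"""Shared phantom fixtures (session-scoped: several are expensive to build)."""

from __future__ import annotations

import numpy as np
import pytest

from skelemorph import phantoms


@pytest.fixture(scope="session")
def helix_phantom():
    """Helical tube: R=3 mm, pitch 1 mm/rad, one full turn, 0.3 mm radius."""
    return phantoms.generate(phantoms.PhantomSpec("curved_tube", spacing=0.05))


@pytest.fixture(scope="session")
def straight_tube_phantom():
    """Straight tube of length 10 mm, radius 0.3 mm."""
    return phantoms.generate(
        phantoms.PhantomSpec(
            "curved_tube",
            spacing=0.05,
            params=dict(
                helix_radius=0.0,
                pitch=10.0 / (2 * np.pi),
                theta_max=2 * np.pi,
                tube_radius=0.3,
            ),
        )
    )


@pytest.fixture(scope="session")
def plate_lattice_phantom():
    """Parallel plates: 0.1 mm thick, 0.4 mm period, 0.01 mm voxels."""
    return phantoms.generate(phantoms.PhantomSpec("plate_lattice", spacing=0.01))


@pytest.fixture(scope="session")
def gp_slab_phantom():
    """10 x 10 x 0.2 mm growth-plate slab (0.01 mm axial spacing)."""
    return phantoms.generate(
        phantoms.PhantomSpec("gp_slab", spacing=(0.01, 0.1, 0.1))
    )


@pytest.fixture(scope="session")
def gp_wedge_phantom():
    """Wedge plate: thickness 0.1 -> 0.3 mm across a 10 x 10 mm footprint."""
    return phantoms.generate(
        phantoms.PhantomSpec("gp_wedge", spacing=(0.005, 0.1, 0.1))
    )


@pytest.fixture(scope="session")
def gp_shell_phantom():
    """Spherical-cap shell plate, constant 0.2 mm radial thickness, 40 deg cap."""
    return phantoms.generate(
        phantoms.PhantomSpec(
            "gp_shell",
            spacing=0.05,
            params=dict(outer_radius=3.0, thickness=0.2, cap_angle_deg=40.0),
        )
    )


@pytest.fixture(scope="session")
def skull_shell_phantom():
    """Hollow sphere R=5 mm, r=4.8 mm — skull-like shell."""
    return phantoms.generate(phantoms.PhantomSpec("skull_shell_aperture", spacing=0.05))


@pytest.fixture(scope="session")
def ellipsoid_phantom():
    """Ellipsoid brain (semi-axes 8, 6, 5 mm), 0.5 mm slices, 0.05 mm in-plane."""
    return phantoms.generate(
        phantoms.PhantomSpec("ellipsoid", spacing=(0.5, 0.05, 0.05))
    )
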