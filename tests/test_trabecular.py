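"""Trabecular microarchitecture against analytic phantoms and a brute-force
maximal-sphere oracle."""

import numpy as np
import pytest

from skelemorph import segmentation, trabecular
from skelemorph.voxgrid import BinaryMask


def brute_force_local_thickness(mask: BinaryMask) -> np.ndarray:
    """Independent oracle: for every foreground voxel p, the local thickness
    is 2 * max{ r(q) : |p - q| <= r(q) } over all candidate sphere centers q,
    with r the physical Euclidean distance-transform radius.  Direct O(n^2)
    evaluation, tractable for <= 32^3 grids."""
    from scipy import ndimage

    spacing = np.asarray(mask.spacing)
    dt = ndimage.distance_transform_edt(mask.data, sampling=spacing)
    fg = np.argwhere(mask.data)
    world = fg * spacing
    radii = dt[mask.data]
    out = np.zeros(mask.data.shape)
    for i, p in enumerate(world):
        d = np.linalg.norm(world - p, axis=1)
        covered = d <= radii + 1e-12
        out[tuple(fg[i])] = 2.0 * radii[covered].max()
    return out


def _slab_mask(nz, ny, nx, thickness_vox, spacing):
    arr = np.zeros((nz, ny, nx), dtype=bool)
    lo = (nz - thickness_vox) // 2
    arr[lo : lo + thickness_vox] = True
    return BinaryMask(arr, spacing)


class TestBvTv:
    def test_saturated_mask_gives_one(self):
        voi = BinaryMask(np.ones((4, 4, 4), bool), (1, 1, 1))
        assert trabecular.bv_tv(voi, voi) == 1.0

    def test_empty_mask_gives_zero(self):
        voi = BinaryMask(np.ones((4, 4, 4), bool), (1, 1, 1))
        empty = BinaryMask(np.zeros((4, 4, 4), bool), (1, 1, 1))
        assert trabecular.bv_tv(empty, voi) == 0.0

    def test_empty_voi_rejected(self):
        voi = BinaryMask(np.zeros((4, 4, 4), bool), (1, 1, 1))
        mask = BinaryMask(np.ones((4, 4, 4), bool), (1, 1, 1))
        with pytest.raises(ValueError):
            trabecular.bv_tv(mask, voi)

    def test_plate_lattice_fill_fraction(self, plate_lattice_phantom):
        d = plate_lattice_phantom
        mask = segmentation.threshold_mask(d.volume, 40)
        lo, hi = d.aux["voi_slices"]
        voi = np.zeros(mask.shape, bool)
        voi[lo:hi] = True
        voi = BinaryMask(voi, mask.spacing, mask.origin)
        assert trabecular.bv_tv(mask, voi) == pytest.approx(
            d.truth["bv_tv"], abs=0.5 * mask.spacing[0] / d.truth["period_mm"]
        )


class TestTbTh:
    def test_solid_slab_thickness(self):
        mask = _slab_mask(30, 20, 20, 20, (0.01, 0.01, 0.01))
        assert trabecular.tb_th(mask) == pytest.approx(0.2, abs=0.01)

    def test_solid_sphere_thickness_is_diameter(self):
        zz, yy, xx = np.mgrid[-12:13, -12:13, -12:13]
        sphere = zz**2 + yy**2 + xx**2 <= 9.7**2
        mask = BinaryMask(sphere, (0.01, 0.01, 0.01))
        assert trabecular.tb_th(mask) == pytest.approx(2 * 0.097, abs=0.01)

    def test_plate_phantom_thickness(self, plate_lattice_phantom):
        d = plate_lattice_phantom
        mask = segmentation.threshold_mask(d.volume, 40)
        assert trabecular.tb_th(mask) == pytest.approx(
            d.truth["tb_th_mm"], abs=mask.spacing[0]
        )

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            trabecular.tb_th(BinaryMask(np.zeros((3, 3, 3), bool), (1, 1, 1)))

    @pytest.mark.parametrize(
        "builder",
        [
            lambda: _slab_mask(16, 12, 12, 6, (0.01, 0.01, 0.01)),
            lambda: BinaryMask(
                (lambda g: g[0] ** 2 + g[1] ** 2 + g[2] ** 2 <= 6**2)(
                    np.mgrid[-8:9, -8:9, -8:9]
                ),
                (0.01, 0.01, 0.01),
            ),
            lambda: BinaryMask(
                np.random.default_rng(7).random((14, 14, 14)) > 0.4,
                (0.02, 0.01, 0.01),  # anisotropic, irregular
            ),
        ],
        ids=["slab", "sphere", "random-anisotropic"],
    )
    def test_matches_brute_force_oracle_exactly(self, builder):
        mask = builder()
        expected = brute_force_local_thickness(mask)
        got = trabecular.local_thickness(mask)
        assert np.allclose(got[mask.data], expected[mask.data], atol=1e-9)

    def test_isotropic_rescaling_scales_thickness(self):
        mask1 = _slab_mask(20, 10, 10, 8, (0.01, 0.01, 0.01))
        mask2 = _slab_mask(20, 10, 10, 8, (0.03, 0.03, 0.03))
        assert trabecular.tb_th(mask2) == pytest.approx(3 * trabecular.tb_th(mask1), rel=1e-9)


class TestTbN:
    def test_plate_model_formula(self):
        assert trabecular.tb_n(0.25, 0.1) == pytest.approx(2.5)

    def test_zero_bvtv(self):
        assert trabecular.tb_n(0.0, 0.1) == 0.0

    def test_identity_scale(self):
        assert trabecular.tb_n(1.0, 1.0) == 1.0

    def test_zero_thickness_rejected(self):
        with pytest.raises(ValueError):
            trabecular.tb_n(0.5, 0.0)


class TestAnalyze:
    def test_plate_lattice_full_panel(self, plate_lattice_phantom):
        """The module's core recovery surface: plates of known thickness and
        period reproduce (BV/TV, Tb.Th, Tb.N) = (t/p, t, 1/p)."""
        d = plate_lattice_phantom
        mask = segmentation.threshold_mask(d.volume, 40)
        lo, hi = d.aux["voi_slices"]
        voi = np.zeros(mask.shape, bool)
        voi[lo:hi] = True
        voi = BinaryMask(voi, mask.spacing, mask.origin)
        res = trabecular.analyze(mask, voi)
        vox = mask.spacing[0]
        assert res.bv_tv == pytest.approx(d.truth["bv_tv"], abs=0.5 * vox / d.truth["period_mm"])
        assert res.tb_th == pytest.approx(d.truth["tb_th_mm"], abs=vox)
        assert res.tb_n == pytest.approx(d.truth["tb_n_per_mm"], abs=0.25)
        assert res.bv_tv == res.bone_volume_mm3 / res.total_volume_mm3

    @pytest.mark.parametrize("period", [0.3, 0.4, 0.6])
    def test_plate_period_sweep(self, period):
        from skelemorph import phantoms

        d = phantoms.generate(
            phantoms.PhantomSpec(
                "plate_lattice",
                spacing=0.01,
                params=dict(plate_thickness=0.1, period=period, n_periods=2,
                            lateral_extent=0.4),
            )
        )
        mask = segmentation.threshold_mask(d.volume, 40)
        lo, hi = d.aux["voi_slices"]
        voi = np.zeros(mask.shape, bool)
        voi[lo:hi] = True
        voi = BinaryMask(voi, mask.spacing, mask.origin)
        res = trabecular.analyze(mask, voi)
        assert res.bv_tv == pytest.approx(0.1 / period, abs=0.5 * 0.01 / period)
        assert res.tb_th == pytest.approx(0.1, abs=0.01)
        assert res.tb_n == pytest.approx(1.0 / period, abs=0.25)
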