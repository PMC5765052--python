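"""Core containers: coordinate mapping, invariants, round-trip I/O."""

import numpy as np
import pandas as pd
import pytest

from skelemorph.voxgrid import (
    BinaryMask,
    LandmarkSet,
    Polyline3D,
    StudyTable,
    SurfaceMesh,
    VoxelVolume,
    read_results,
    read_volume,
    write_mesh,
    read_mesh,
    write_results,
    write_volume,
)


class TestVoxelVolume:
    def test_index_world_round_trip_is_identity(self):
        vol = VoxelVolume(
            np.zeros((4, 5, 6)), spacing=(0.5, 0.2, 0.1), origin=(1.0, -2.0, 3.0)
        )
        idx = np.argwhere(np.ones((4, 5, 6), dtype=bool)).astype(float)
        back = vol.world_to_index(vol.index_to_world(idx))
        assert np.abs(back - idx).max() < 1e-12

    @pytest.mark.parametrize("spacing", [(0, 1, 1), (-1, 1, 1), (np.nan, 1, 1)])
    def test_invalid_spacing_rejected(self, spacing):
        with pytest.raises(ValueError):
            VoxelVolume(np.zeros((2, 2, 2)), spacing=spacing)

    def test_full_mask_volume_equals_shape_times_spacing(self):
        mask = BinaryMask(np.ones((10, 20, 30), dtype=bool), spacing=(0.1, 0.2, 0.3))
        assert mask.volume_mm3() == pytest.approx(10 * 20 * 30 * 0.1 * 0.2 * 0.3)
        assert mask.voxel_volume() > 0


class TestPolyline3D:
    def test_length_exceeds_chord_for_bent_line(self):
        poly = Polyline3D([[0, 0, 0], [1, 1, 0], [2, 0, 0]])
        assert poly.length() > poly.chord()

    def test_closed_loop_adds_closing_segment(self):
        square = Polyline3D([[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0]], closed=True)
        assert square.length() == pytest.approx(4.0)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            Polyline3D([[0, 0, 0]])

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            Polyline3D([[0, 0, 0], [np.inf, 0, 0]])


class TestSurfaceMesh:
    def _unit_square_sheet(self):
        # two triangles covering the unit square, one boundary loop
        v = np.array([[0, 0, 0], [0, 1, 0], [0, 1, 1], [0, 0, 1]], dtype=float)
        f = np.array([[0, 1, 2], [0, 2, 3]])
        return SurfaceMesh(v, f)

    def test_boundary_edges_form_one_loop(self):
        loops = self._unit_square_sheet().boundary_loops()
        assert len(loops) == 1
        assert sorted(loops[0]) == [0, 1, 2, 3]

    def test_area(self):
        assert self._unit_square_sheet().area() == pytest.approx(1.0)

    def test_bad_face_index_rejected(self):
        with pytest.raises(ValueError):
            SurfaceMesh(np.zeros((3, 3)), np.array([[0, 1, 5]]))


class TestVolumeIO:
    @pytest.mark.parametrize("fmt,ext", [("nifti", "vol.nii.gz"), ("tiff_stack", "vol.tif")])
    def test_round_trip_identity(self, tmp_path, fmt, ext):
        rng = np.random.default_rng(0)
        vol = VoxelVolume(
            rng.integers(0, 255, (4, 4, 4)).astype(np.float32),
            spacing=(0.0086, 0.0086, 0.0086),
        )
        path = tmp_path / ext
        write_volume(vol, path, format=fmt)
        back = read_volume(path, format=fmt, spacing=vol.spacing if fmt == "tiff_stack" else None)
        assert np.array_equal(back.data, vol.data)
        assert np.allclose(back.spacing, vol.spacing)

    def test_tiff_without_spacing_is_error(self, tmp_path):
        vol = VoxelVolume(np.zeros((3, 3, 3), dtype=np.uint8), spacing=(1, 1, 1))
        path = tmp_path / "stack.tif"
        write_volume(vol, path, format="tiff_stack")
        with pytest.raises(ValueError, match="spacing"):
            read_volume(path)

    def test_tiff_with_supplied_spacing(self, tmp_path):
        vol = VoxelVolume(np.zeros((3, 3, 3), dtype=np.uint8), spacing=(1, 1, 1))
        path = tmp_path / "stack.tif"
        write_volume(vol, path, format="tiff_stack")
        back = read_volume(path, spacing=(0.0086, 0.0086, 0.0086))
        assert back.spacing == (0.0086, 0.0086, 0.0086)

    def test_missing_file_is_error(self):
        with pytest.raises(FileNotFoundError):
            read_volume("no_such_file.nii")


class TestMeshIO:
    def _cube(self):
        import trimesh

        box = trimesh.creation.box(extents=(1, 1, 1))
        return SurfaceMesh(np.asarray(box.vertices), np.asarray(box.faces))

    @pytest.mark.parametrize("ext", ["stl", "ply"])
    def test_cube_round_trip(self, tmp_path, ext):
        cube = self._cube()
        path = tmp_path / f"cube.{ext}"
        write_mesh(cube, path)
        back = read_mesh(path)
        assert back.n_faces == 12
        assert back.area() == pytest.approx(cube.area(), rel=1e-6)

    def test_icosphere_area_preserved(self, tmp_path):
        import trimesh

        ico = trimesh.creation.icosphere(subdivisions=3, radius=2.0)
        mesh = SurfaceMesh(np.asarray(ico.vertices), np.asarray(ico.faces))
        path = tmp_path / "ico.ply"
        write_mesh(mesh, path)
        assert read_mesh(path).area() == pytest.approx(mesh.area(), rel=1e-6)

    def test_empty_mesh_rejected(self, tmp_path):
        empty = SurfaceMesh(np.zeros((0, 3)), np.zeros((0, 3), dtype=int))
        with pytest.raises(ValueError):
            write_mesh(empty, tmp_path / "empty.stl")


class TestStudyTable:
    def _records(self):
        return [
            dict(animal_id="M1", genotype="WT", sex="M", age_weeks=3,
                 measurement="femur_length_mm", value=11.2),
            dict(animal_id="M2", genotype="Ach", sex="F", age_weeks=3,
                 measurement="femur_length_mm", value=9.8),
        ]

    def test_round_trip(self, tmp_path):
        table = StudyTable.from_records(self._records())
        path = tmp_path / "results.csv"
        write_results(table, path)
        back = read_results(path)
        pd.testing.assert_frame_equal(back.df, table.df)

    def test_numeric_round_trip_12_significant_digits(self, tmp_path):
        recs = self._records()
        recs[0]["value"] = 11.234567890123456
        table = StudyTable.from_records(recs)
        path = tmp_path / "results.csv"
        write_results(table, path)
        back = read_results(path)
        assert back.df["value"][0] == pytest.approx(recs[0]["value"], rel=1e-12)

    def test_nan_value_rejected(self):
        recs = self._records()
        recs[0]["value"] = np.nan
        with pytest.raises(ValueError):
            StudyTable.from_records(recs)

    def test_duplicate_key_rejected(self):
        recs = self._records() + [self._records()[0]]
        with pytest.raises(ValueError, match="duplicate"):
            StudyTable.from_records(recs)

    def test_synthetic_study_has_row_per_animal_measurement(self):
        from skelemorph.phantoms import generate_study, DEFAULT_STUDY_MEASUREMENTS

        table = generate_study(n_per_group=14, seed=1)
        n_animals = 14 * 2 * 2
        assert len(table) == n_animals * len(DEFAULT_STUDY_MEASUREMENTS)


class TestLandmarkSet:
    def test_mixed_dimensionality_rejected(self):
        with pytest.raises(ValueError):
            LandmarkSet({"a": [0, 0], "b": [0, 0, 0]})

    def test_missing_landmark_raises(self):
        lms = LandmarkSet({"a": [0.0, 0.0]})
        with pytest.raises(KeyError):
            lms.require("a", "b")
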