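"""Bolus geometry: segmentation, surface offset, STL round trips, air gaps."""

import struct

import numpy as np
import pytest

import bolusqa as bq
from bolusqa.bolus import SurfaceMesh, sample_skin_points
from bolusqa.errors import (
    CoverageError,
    EmptyBodyError,
    EmptyBolusError,
    STLFormatError,
    ValidationError,
)
from bolusqa.grids import ImageVolume, StructureMask


def sphere_mask(radius_mm: float, spacing: float = 1.0, pad_mm: float = 10.0) -> StructureMask:
    half = radius_mm + pad_mm
    n = int(2 * half / spacing) + 1
    origin = (-half, -half, -half)
    ax = np.linspace(-half, half, n)
    x, y, z = np.ix_(ax, ax, ax)
    return StructureMask(x**2 + y**2 + z**2 <= radius_mm**2, (spacing,) * 3, origin, "sphere")


def flat_patch(z_mm: float, extent: float = 50.0, step: float = 5.0) -> SurfaceMesh:
    """A triangulated square patch in the plane z = z_mm."""
    ax = np.arange(-extent, extent + step, step)
    nx = len(ax)
    xx, yy = np.meshgrid(ax, ax, indexing="ij")
    verts = np.column_stack([xx.ravel(), yy.ravel(), np.full(xx.size, z_mm)])
    faces = []
    for i in range(nx - 1):
        for j in range(nx - 1):
            a, b, c, d = i * nx + j, i * nx + j + 1, (i + 1) * nx + j, (i + 1) * nx + j + 1
            faces += [[a, b, c], [b, d, c]]
    return SurfaceMesh(verts, np.asarray(faces))


class TestExtractBodySurface:
    def test_phantom_threshold_recovers_body_mask(self, phantom_default):
        ct, masks = phantom_default
        mask, _ = bq.extract_body_surface(ct, threshold_hu=-300.0)
        assert np.array_equal(mask.mask, masks["body"].mask)

    def test_all_air_raises(self):
        vol = ImageVolume(np.full((8, 8, 8), -1000.0))
        with pytest.raises(EmptyBodyError):
            bq.extract_body_surface(vol, threshold_hu=-300.0)

    def test_mesh_closed_with_spherical_topology(self, body_and_skin):
        _, mesh = body_and_skin
        assert mesh.n_faces > 0
        assert mesh.closed
        assert mesh.euler_characteristic() == 2


class TestDesignBolus:
    def test_sphere_shell_volume_matches_closed_form(self):
        """Offsetting a 50 mm sphere by 5 mm yields the analytic shell volume."""
        body = sphere_mask(50.0, spacing=1.0)
        shell, _ = bq.design_bolus(body, bq.BolusSpec(thickness=5.0))
        expected = 4.0 / 3.0 * np.pi * (55.0**3 - 50.0**3)
        assert shell.volume_mm3 == pytest.approx(expected, rel=0.05)

    def test_one_voxel_shell_is_disjoint_subset_of_dilation(self, phantom_default):
        ct, masks = phantom_default
        body = masks["body"]
        thickness = ct.spacing[0]
        shell, _ = bq.design_bolus(body, bq.BolusSpec(thickness=thickness))
        assert not (shell.mask & body.mask).any()
        from scipy import ndimage

        dist = ndimage.distance_transform_edt(~body.mask, sampling=body.spacing)
        assert not (shell.mask & ~(dist <= thickness)).any()

    @pytest.mark.parametrize("thicknesses", [(3.0, 5.0, 8.0)])
    def test_volume_monotone_in_thickness(self, phantom_default, thicknesses):
        _, masks = phantom_default
        vols = [
            bq.design_bolus(masks["body"], bq.BolusSpec(thickness=t))[0].volume_mm3
            for t in thicknesses
        ]
        assert vols[0] < vols[1] < vols[2]

    def test_mark_outside_body_raises(self, phantom_default):
        _, masks = phantom_default
        mark = bq.AreaMark(z_min_mm=2000.0, z_max_mm=3000.0)
        with pytest.raises((EmptyBolusError, ValidationError)):
            bq.design_bolus(masks["body"], bq.BolusSpec(area_mark=mark))

    def test_empty_body_raises(self):
        empty = StructureMask(np.zeros((5, 5, 5), dtype=bool))
        with pytest.raises(EmptyBodyError):
            bq.design_bolus(empty, bq.BolusSpec())

    def test_bad_mark_angles_raise(self):
        with pytest.raises(ValidationError, match="theta"):
            bq.AreaMark(theta_start_deg=-10.0).validate()


class TestSTLRoundTrip:
    def test_single_triangle(self, tmp_path):
        tri = SurfaceMesh(
            np.array([[0.0, 0.0, 0.0], [10.0, 0.0, 0.0], [0.0, 10.0, 0.0]]),
            np.array([[0, 1, 2]]),
        )
        p = tmp_path / "tri.stl"
        bq.export_stl(tri, p)
        back = bq.import_stl(p)
        assert back.n_faces == 1
        assert np.allclose(
            np.sort(back.vertices, axis=0), np.sort(tri.vertices, axis=0), atol=1e-6
        )

    def test_phantom_bolus_face_count_preserved(self, bolus_design, tmp_path):
        _, mesh = bolus_design
        p = tmp_path / "bolus.stl"
        bq.export_stl(mesh, p)
        back = bq.import_stl(p)
        assert back.n_faces == mesh.n_faces
        # idempotence: a second round trip changes nothing
        p2 = tmp_path / "bolus2.stl"
        bq.export_stl(back, p2)
        again = bq.import_stl(p2)
        assert again.n_faces == back.n_faces
        assert np.array_equal(
            np.sort(again.vertices.view("f8,f8,f8").ravel()),
            np.sort(back.vertices.view("f8,f8,f8").ravel()),
        )

    def test_header_count_matches_independent_byte_parse(self, bolus_design, tmp_path):
        _, mesh = bolus_design
        p = tmp_path / "bolus.stl"
        bq.export_stl(mesh, p)
        raw = p.read_bytes()
        (declared,) = struct.unpack_from("<I", raw, 80)
        assert declared == mesh.n_faces
        assert len(raw) == 84 + 50 * declared

    def test_truncated_file_reports_byte_offset(self, bolus_design, tmp_path):
        _, mesh = bolus_design
        p = tmp_path / "bolus.stl"
        bq.export_stl(mesh, p)
        raw = p.read_bytes()
        cut = len(raw) - 17
        (tmp_path / "trunc.stl").write_bytes(raw[:cut])
        with pytest.raises(STLFormatError) as exc:
            bq.import_stl(tmp_path / "trunc.stl")
        assert exc.value.byte_offset == cut

    def test_short_header_reports_byte_offset(self, tmp_path):
        (tmp_path / "short.stl").write_bytes(b"\x00" * 40)
        with pytest.raises(STLFormatError) as exc:
            bq.import_stl(tmp_path / "short.stl")
        assert exc.value.byte_offset == 40


class TestAirGap:
    def test_coincident_surfaces_zero_gap(self):
        skin = flat_patch(0.0)
        bolus = flat_patch(0.0)
        pts = np.array([[x, y, 0.0] for x in (-20.0, 0.0, 20.0) for y in (-20.0, 20.0)])
        normals = np.tile([0.0, 0.0, 1.0], (len(pts), 1))
        report = bq.air_gap_profile(skin, bolus, pts, normals=normals)
        assert report.mean_gap == pytest.approx(0.0, abs=1e-9)

    def test_translated_bolus_gap_equals_offset(self):
        skin = flat_patch(0.0)
        bolus = flat_patch(2.0)
        pts = np.array([[x, y, 0.0] for x in (-20.0, 0.0, 20.0) for y in (-20.0, 20.0)])
        normals = np.tile([0.0, 0.0, 1.0], (len(pts), 1))
        report = bq.air_gap_profile(skin, bolus, pts, normals=normals)
        assert report.mean_gap == pytest.approx(2.0, abs=1e-9)
        assert report.max_gap >= report.mean_gap

    def test_interpenetration_clamps_mean_but_keeps_sign(self):
        skin = flat_patch(0.0)
        bolus = flat_patch(-1.5)  # bolus surface behind the skin points
        pts = np.array([[0.0, 0.0, 0.0], [10.0, 10.0, 0.0]])
        normals = np.tile([0.0, 0.0, 1.0], (2, 1))
        report = bq.air_gap_profile(skin, bolus, pts, normals=normals)
        assert np.all(report.gaps < 0)
        assert report.mean_gap == 0.0

    def test_phantom_bolus_conforms_within_voxel(self, body_and_skin, bolus_design, area_mark, phantom_default):
        ct, _ = phantom_default
        _, skin = body_and_skin
        _, bolus_mesh = bolus_design
        pts = sample_skin_points(skin, 48, area_mark=area_mark, seed=3)
        report = bq.air_gap_profile(skin, bolus_mesh, pts)
        assert report.mean_gap < max(ct.spacing)

    def test_rigid_rotation_invariance(self):
        from scipy.spatial.transform import Rotation

        skin = flat_patch(0.0)
        bolus = flat_patch(2.0)
        pts = np.array([[x, y, 0.0] for x in (-15.0, 0.0, 15.0) for y in (-15.0, 15.0)])
        normals = np.tile([0.0, 0.0, 1.0], (len(pts), 1))
        base = bq.air_gap_profile(skin, bolus, pts, normals=normals)
        rot = Rotation.from_euler("xyz", [31.0, -17.0, 59.0], degrees=True).as_matrix()
        skin_r = SurfaceMesh(skin.vertices @ rot.T, skin.faces)
        bolus_r = SurfaceMesh(bolus.vertices @ rot.T, bolus.faces)
        rotated = bq.air_gap_profile(skin_r, bolus_r, pts @ rot.T, normals=normals @ rot.T)
        assert rotated.mean_gap == pytest.approx(base.mean_gap, abs=1e-6)

    def test_all_rays_missing_raises(self):
        skin = flat_patch(0.0, extent=20.0)
        bolus = flat_patch(2.0, extent=20.0)
        pts = np.array([[500.0, 500.0, 0.0]])  # far outside the bolus footprint
        normals = np.array([[0.0, 0.0, 1.0]])
        with pytest.raises(CoverageError):
            bq.air_gap_profile(skin, bolus, pts, normals=normals)
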