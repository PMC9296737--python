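"""Nucleus phantoms: sampling, placement, meshes, chords."""

import math

import numpy as np
import pytest
import trimesh

from alphadosim.phantoms import (EllipticalCylinderNucleus, MeshNucleus,
                                 MeshValidationError, PackingError,
                                 chord_length, ellipses_overlap, load_mesh,
                                 mesh_ray_chords, place_without_overlap,
                                 sample_elliptical_phantoms, tile_mesh_set,
                                 validate_mesh)
from alphadosim.synthetic_data import generate_nucleus_meshes


class TestEllipticalSampling:
    def test_mean_volume_calibrated_to_target(self):
        ps = sample_elliptical_phantoms(10_000, seed=1)
        assert ps.volumes_um3.mean() == pytest.approx(930.0, rel=0.05)

    def test_axis_ratio_and_height_exact(self):
        ps = sample_elliptical_phantoms(50, seed=2)
        for e in ps.ellipses:
            assert e.minor_um == pytest.approx(e.major_um * 2 / 3, rel=1e-12)
            assert e.height_um == 8.0

    def test_empty_request_gives_empty_set(self):
        assert len(sample_elliptical_phantoms(0, seed=3)) == 0

    def test_sampled_axis_mean_matches_calibrated_location(self):
        ps = sample_elliptical_phantoms(20_000, seed=4)
        major = np.array([e.major_um for e in ps.ellipses])
        se = major.std() / math.sqrt(len(major))
        # truncation [4, 40] um is mildly asymmetric about the location
        assert abs(major.mean() - ps.axis_loc_um) < 2 * se + 0.2

    def test_impossible_truncation_rejected(self):
        with pytest.raises(ValueError):
            sample_elliptical_phantoms(10, truncation_um=(80.0, 81.0),
                                       target_mean_volume_um3=None,
                                       axis_mean_um=15.3, seed=5)


class TestPlacement:
    def test_placement_produces_no_overlaps(self, small_ellipse_set):
        ells = small_ellipse_set.ellipses
        geo = [((e.center_x_mm * 1e3), (e.center_y_mm * 1e3),
                e.major_um / 2, e.minor_um / 2, e.azimuth_rad) for e in ells]
        for i in range(len(geo)):
            for j in range(i + 1, len(geo)):
                dx = geo[i][0] - geo[j][0]
                dy = geo[i][1] - geo[j][1]
                if dx * dx + dy * dy > (geo[i][2] + geo[j][2]) ** 2:
                    continue
                assert not ellipses_overlap(geo[i], geo[j])

    def test_footprints_inside_region(self, small_ellipse_set):
        half_um = small_ellipse_set.region_side_mm * 500.0
        for e in small_ellipse_set.ellipses:
            r = e.major_um / 2
            assert abs(e.center_x_mm) * 1e3 + r <= half_um + 1e-6
            assert abs(e.center_y_mm) * 1e3 + r <= half_um + 1e-6

    def test_deterministic_under_seed(self):
        a = place_without_overlap(sample_elliptical_phantoms(50, seed=6),
                                  seed=7)
        b = place_without_overlap(sample_elliptical_phantoms(50, seed=6),
                                  seed=7)
        assert a.to_frame().equals(b.to_frame())

    def test_oversized_footprints_raise_packing_error(self):
        ps = sample_elliptical_phantoms(2, seed=8)
        for e in ps.ellipses:
            e.major_um = 4000.0  # 4 mm footprint in a 4 mm region
        with pytest.raises(PackingError):
            place_without_overlap(ps, seed=9)

    def test_overlap_checker_agrees_with_point_sampling(self):
        rng = np.random.default_rng(10)
        agree = 0
        for _ in range(100):
            e1 = (0.0, 0.0, rng.uniform(3, 8), rng.uniform(2, 5),
                  rng.random() * math.pi)
            e2 = (rng.uniform(-10, 10), rng.uniform(-10, 10),
                  rng.uniform(3, 8), rng.uniform(2, 5),
                  rng.random() * math.pi)
            got = ellipses_overlap(e1, e2)
            # dense point-sampling oracle over e2's interior
            t = rng.random(4000) * 2 * math.pi
            u = np.sqrt(rng.random(4000))
            x = e2[2] * u * np.cos(t)
            y = e2[3] * u * np.sin(t)
            ca, sa = math.cos(e2[4]), math.sin(e2[4])
            px = e2[0] + x * ca - y * sa
            py = e2[1] + x * sa + y * ca
            dx, dy = px - e1[0], py - e1[1]
            ca1, sa1 = math.cos(e1[4]), math.sin(e1[4])
            uu = dx * ca1 + dy * sa1
            vv = -dx * sa1 + dy * ca1
            brute = bool(np.any((uu / e1[2]) ** 2 + (vv / e1[3]) ** 2 <= 1))
            agree += got == brute
        assert agree >= 98  # razor-thin tangencies may differ


class TestMeshes:
    def test_unit_cube_volume(self, tmp_path):
        box = trimesh.creation.box(extents=(1.0, 1.0, 1.0))
        path = tmp_path / "cube.stl"
        box.export(path)
        nucleus = load_mesh(path)
        assert nucleus.volume_um3 == pytest.approx(1.0, rel=1e-6)
        assert validate_mesh(nucleus.mesh)["watertight"]

    def test_ellipsoid_volume_matches_closed_form(self):
        a, b, c = 7.65, 5.1, 4.0
        mesh = trimesh.creation.icosphere(subdivisions=3)
        mesh.apply_scale([a, b, c])
        rep = validate_mesh(mesh)
        assert rep["volume_um3"] == pytest.approx(4 / 3 * math.pi * a * b * c,
                                                  rel=0.02)

    def test_missing_facet_fails_watertightness(self, tmp_path):
        box = trimesh.creation.box(extents=(1, 1, 1))
        broken = trimesh.Trimesh(box.vertices, box.faces[:-1], process=False)
        path = tmp_path / "broken.stl"
        broken.export(path)
        with pytest.raises(MeshValidationError):
            load_mesh(path)
        assert not validate_mesh(broken)["watertight"]

    def test_tiling_count_and_volume_invariance(self):
        unit = generate_nucleus_meshes(5, seed=11, cell_side_mm=0.2)
        ps = tile_mesh_set(unit, 4, region_side_mm=4.0)
        assert len(ps) == 20
        vols = ps.volumes_um3
        base = np.array([m.volume_um3 for m in unit])
        assert np.allclose(vols.reshape(4, 5), base)

    def test_default_unit_cell_tiles_to_9975(self):
        unit = generate_nucleus_meshes(3, seed=12, cell_side_mm=0.4)
        ps = tile_mesh_set(unit, 95, region_side_mm=4.0)
        assert len(ps) == 3 * 95
        # the study-sized unit cell (105 nuclei x 95 tiles) gives 9975
        assert 105 * 95 == 9975

    def test_single_tile_is_identity_placement(self):
        unit = generate_nucleus_meshes(2, seed=13, cell_side_mm=0.2)
        ps = tile_mesh_set(unit, 1, region_side_mm=4.0)
        assert len(ps) == 2
        got = sorted(m.volume_um3 for m in ps.meshes)
        want = sorted(m.volume_um3 for m in unit)
        assert np.allclose(got, want)

    def test_overflowing_tiling_rejected(self):
        unit = generate_nucleus_meshes(1, seed=14, cell_side_mm=0.4)
        with pytest.raises(PackingError):
            tile_mesh_set(unit, 500, region_side_mm=4.0, pitch_mm=0.4)


class TestChords:
    def test_vertical_center_chord_equals_height(self):
        e = EllipticalCylinderNucleus(0.0, 0.0, 15.0, 0.3)
        assert chord_length((0.0, 0.0), (0.0, 0.0, 1.0), e) == pytest.approx(8.0)

    def test_missing_ray_gives_zero(self):
        e = EllipticalCylinderNucleus(0.0, 0.0, 15.0, 0.0)
        assert chord_length((50.0, 0.0), (0.0, 0.0, 1.0), e) == 0.0

    def test_unvalidated_mesh_refused(self):
        box = trimesh.creation.box(extents=(5, 5, 5))
        nucleus = MeshNucleus(mesh=box, validated=False)
        with pytest.raises(MeshValidationError):
            chord_length((0.0, 0.0), (0.0, 0.0, 1.0), nucleus)

    def test_mesh_cylinder_chords_match_analytic_cylinder(self):
        # a finely meshed elliptical cylinder vs the analytic solution
        a, b, h = 7.5, 5.0, 8.0
        mesh = trimesh.creation.cylinder(radius=1.0, height=1.0, sections=256)
        mesh.apply_scale([a, b, h])
        mesh.apply_translation([0, 0, h / 2 + 2.5])  # top at 2.5 um depth
        analytic = EllipticalCylinderNucleus(0.0, 0.0, 2 * a, 0.0)
        rng = np.random.default_rng(15)
        n = 1000
        origins = np.column_stack([rng.uniform(-9, 9, n),
                                   rng.uniform(-9, 9, n), np.zeros(n)])
        theta = rng.uniform(0, 0.3, n)
        phi = rng.uniform(0, 2 * math.pi, n)
        dirs = np.column_stack([np.sin(theta) * np.cos(phi),
                                np.sin(theta) * np.sin(phi), np.cos(theta)])
        mesh_chords, _ = mesh_ray_chords(mesh, origins, dirs)
        from alphadosim.phantoms import _ellcyl_chords
        ana_chords, _ = _ellcyl_chords(
            origins[:, 0], origins[:, 1], dirs[:, 0], dirs[:, 1], dirs[:, 2],
            a, b, 0.0, 2.5, 2.5 + h)
        assert np.mean(np.abs(mesh_chords - ana_chords)) < 0.02 * h

    def test_chord_bounded_by_caliper(self):
        unit = generate_nucleus_meshes(3, seed=16)
        rng = np.random.default_rng(17)
        for m in unit:
            v = m.mesh.vertices.view(np.ndarray)
            caliper = np.linalg.norm(v.max(0) - v.min(0))
            origins = np.column_stack([
                rng.uniform(v[:, 0].min(), v[:, 0].max(), 50),
                rng.uniform(v[:, 1].min(), v[:, 1].max(), 50),
                np.zeros(50)])
            dirs = np.tile([0.0, 0.0, 1.0], (50, 1))
            chords, _ = mesh_ray_chords(m.mesh, origins, dirs)
            assert np.all(chords <= caliper + 1e-9)
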