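"""Geometry on voxel masks against analytic and brute-force oracles."""

import itertools
import math

import numpy as np
import pytest

from tsiplan import (
    DegenerateShapeError,
    EmptyMaskError,
    ShapeParams,
    TriMesh,
    VoxelMask,
    extract_mesh,
    generate_tumor_mask,
    max_3d_diameter,
    mesh_surface_area,
    mesh_volume,
    min_enclosing_sphere,
    principal_axes,
)
from tsiplan.mask_geometry import NonClosedMeshError

from conftest import digitized_ball, digitized_ellipsoid, spheroid_surface_area

BALL_VOLUME_MM3 = 4.0 / 3.0 * math.pi * 1000.0  # r = 10 mm


class TestExtractMesh:
    def test_empty_mask_raises(self):
        with pytest.raises(EmptyMaskError):
            extract_mesh(VoxelMask(np.zeros((3, 3, 3), bool)))

    def test_single_voxel_closed_and_small(self):
        occ = np.zeros((3, 3, 3), bool)
        occ[1, 1, 1] = True
        mesh = extract_mesh(VoxelMask(occ))
        assert mesh.is_closed()
        assert 0.0 < mesh_volume(mesh) * 1000.0 <= 1.0  # mm^3

    def test_ball_volume_isotropic(self, ball10):
        vol = mesh_volume(extract_mesh(ball10)) * 1000.0
        assert vol == pytest.approx(BALL_VOLUME_MM3, rel=0.02)

    def test_ball_volume_anisotropic(self):
        mask = digitized_ball(10.0, spacing=(1.0, 1.0, 2.0))
        vol = mesh_volume(extract_mesh(mask)) * 1000.0
        assert vol == pytest.approx(BALL_VOLUME_MM3, rel=0.03)

    def test_multiple_components_warn_and_mesh_union(self):
        occ = np.zeros((9, 9, 9), bool)
        occ[1:3, 1:3, 1:3] = True
        occ[6:8, 6:8, 6:8] = True
        with pytest.warns(UserWarning, match="components"):
            mesh = extract_mesh(VoxelMask(occ))
        assert mesh_volume(mesh) * 1000.0 == pytest.approx(16.0, rel=0.5)


class TestMeshVolumeArea:
    def test_unit_cube(self):
        # explicit cube surface: 8 vertices, 12 triangles, outward-oriented
        v = np.array(list(itertools.product([0.0, 1.0], repeat=3)))
        f = np.array([
            [0, 1, 3], [0, 3, 2],  # x = 0 face (inward normal -x)
            [4, 6, 7], [4, 7, 5],  # x = 1
            [0, 4, 5], [0, 5, 1],  # y = 0
            [2, 3, 7], [2, 7, 6],  # y = 1
            [0, 2, 6], [0, 6, 4],  # z = 0
            [1, 5, 7], [1, 7, 3],  # z = 1
        ])
        cube = TriMesh(v, f)
        assert mesh_volume(cube) == pytest.approx(0.001)
        assert mesh_surface_area(cube) == pytest.approx(0.06)

    def test_open_mesh_raises(self):
        v = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0]], float)
        with pytest.raises(NonClosedMeshError):
            mesh_volume(TriMesh(v, np.array([[0, 1, 2]])))

    def test_large_ball_volume(self):
        mask = digitized_ball(16.8)
        vol = mesh_volume(extract_mesh(mask))
        assert vol == pytest.approx(4.0 / 3.0 * math.pi * 16.8**3 / 1000.0, rel=0.02)

    def test_ball_area(self, ball10):
        area = mesh_surface_area(extract_mesh(ball10)) * 100.0
        assert area == pytest.approx(4.0 * math.pi * 100.0, rel=0.03)

    def test_prolate_spheroid_area_closed_form(self):
        mask = digitized_ellipsoid((20.0, 10.0, 10.0))
        area = mesh_surface_area(extract_mesh(mask)) * 100.0
        assert area == pytest.approx(spheroid_surface_area(20.0, 10.0), rel=0.03)

    def test_mesh_volume_tracks_voxel_count_on_random_tumors(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            params = ShapeParams(
                base_semi_axes=(8.0, 8.0 * rng.uniform(0.5, 1), 8.0 * rng.uniform(0.4, 1)),
                perturbation_amplitude=float(rng.uniform(0, 0.5)),
                pad_mm=3.0,
                seed=int(rng.integers(2**31)),
            )
            mask = generate_tumor_mask(params)
            mesh_v = mesh_volume(extract_mesh(mask))
            voxel_v = mask.voxel_count_volume_cm3()
            assert abs(mesh_v - voxel_v) / voxel_v < 0.05

    def test_volume_gap_shrinks_with_resolution(self):
        """Mesh and voxel-count volumes converge as a ball is re-digitized finer."""
        gaps = []
        for radius_vox in (5, 20):
            spacing = 10.0 / radius_vox  # fixed 10 mm ball, varying lattice
            mask = digitized_ball(10.0, spacing=(spacing,) * 3)
            mesh_v = mesh_volume(extract_mesh(mask))
            gaps.append(abs(mesh_v - 4.0 / 3.0 * math.pi) / (4.0 / 3.0 * math.pi))
        assert gaps[1] < gaps[0]

    def test_rotation_and_translation_invariance(self):
        base = digitized_ellipsoid((9.0, 5.0, 5.0))
        v0 = mesh_volume(extract_mesh(base))
        a0 = mesh_surface_area(extract_mesh(base))
        # same ellipsoid rotated 45 degrees about z, re-digitized
        n = 16
        ax = (np.arange(2 * n + 1) - n) * 1.0
        X, Y, Z = np.meshgrid(ax, ax, ax, indexing="ij")
        c, s = math.cos(math.pi / 4), math.sin(math.pi / 4)
        U, V = c * X + s * Y, -s * X + c * Y
        rot = VoxelMask((U / 9.0) ** 2 + (V / 5.0) ** 2 + (Z / 5.0) ** 2 <= 1.0,
                        origin=(-n, -n, -n))
        shifted = VoxelMask(base.occupancy, base.spacing,
                            tuple(o + 13.5 for o in base.origin))
        assert mesh_volume(extract_mesh(rot)) == pytest.approx(v0, rel=0.02)
        assert mesh_surface_area(extract_mesh(rot)) == pytest.approx(a0, rel=0.02)
        assert mesh_volume(extract_mesh(shifted)) == pytest.approx(v0, rel=1e-9)
        assert mesh_surface_area(extract_mesh(shifted)) == pytest.approx(a0, rel=1e-9)


class TestPrincipalAxes:
    def test_ball_semi_axes(self, ball10):
        axes = principal_axes(ball10)
        expected = 2.0 * 10.0 / math.sqrt(5.0)  # solid-ball moment r^2/5
        assert np.allclose(axes.semi_axes_mm, expected, rtol=0.02)

    def test_ellipsoid_axis_ratios(self):
        mask = digitized_ellipsoid((8.0, 4.0, 4.0), spacing=(0.5, 0.5, 0.5))
        axes = principal_axes(mask)
        ratios = axes.semi_axes_mm / axes.semi_axes_mm[0]
        assert np.allclose(ratios, [1.0, 0.5, 0.5], atol=0.02)

    def test_rotation_invariance_of_eigenvalues(self):
        sp = 0.5
        n = 32
        ax = (np.arange(2 * n + 1) - n) * sp
        X, Y, Z = np.meshgrid(ax, ax, ax, indexing="ij")
        plain = (X / 9.0) ** 2 + (Y / 5.0) ** 2 + (Z / 5.0) ** 2 <= 1.0
        c, s = math.cos(math.pi / 4), math.sin(math.pi / 4)
        U, V = c * X + s * Y, -s * X + c * Y
        rot = (U / 9.0) ** 2 + (V / 5.0) ** 2 + (Z / 5.0) ** 2 <= 1.0
        ev0 = principal_axes(VoxelMask(plain, (sp,) * 3)).eigenvalues
        ev1 = principal_axes(VoxelMask(rot, (sp,) * 3)).eigenvalues
        assert np.allclose(ev0, ev1, rtol=0.02)

    def test_too_few_voxels_raises(self):
        occ = np.zeros((4, 4, 4), bool)
        occ[0, 0, 0] = occ[1, 1, 1] = occ[2, 2, 2] = True
        with pytest.raises(DegenerateShapeError):
            principal_axes(VoxelMask(occ))


class TestDiameterAndEnclosingSphere:
    def test_ball_diameter(self, ball10):
        assert max_3d_diameter(extract_mesh(ball10)) == pytest.approx(20.0, rel=0.02)

    def test_ellipsoid_major_axis(self):
        mask = digitized_ellipsoid((8.0, 4.0, 4.0), spacing=(0.5, 0.5, 0.5))
        assert max_3d_diameter(extract_mesh(mask)) == pytest.approx(16.0, rel=0.02)

    def test_two_point_degenerate(self):
        pts = np.array([[0.0, 0.0, 0.0], [3.0, 4.0, 0.0]])
        assert max_3d_diameter(pts) == pytest.approx(5.0)

    def test_unit_cube_circumsphere(self):
        pts = np.array(list(itertools.product([0.0, 1.0], repeat=3)))
        _, r = min_enclosing_sphere(pts)
        assert r == pytest.approx(math.sqrt(3.0) / 2.0, abs=1e-9)

    def test_single_point(self):
        _, r = min_enclosing_sphere([[1.0, 2.0, 3.0]])
        assert r == 0.0

    def test_matches_brute_force_on_random_points(self):
        rng = np.random.default_rng(3)
        pts = rng.normal(size=(25, 3))

        def brute_force(points):
            # smallest valid circumsphere over all support subsets of size <= 4
            from tsiplan.mask_geometry import _circumsphere

            best = math.inf
            for k in (1, 2, 3, 4):
                for sub in itertools.combinations(range(len(points)), k):
                    res = _circumsphere(points[list(sub)])
                    if res is None:
                        continue
                    c, r = res
                    if np.all(np.linalg.norm(points - c, axis=1) <= r + 1e-9):
                        best = min(best, r)
            return best

        _, r = min_enclosing_sphere(pts)
        assert r == pytest.approx(brute_force(pts), abs=1e-7)

    def test_radius_at_least_half_diameter(self):
        rng = np.random.default_rng(11)
        for _ in range(5):
            pts = rng.normal(size=(40, 3))
            _, r = min_enclosing_sphere(pts)
            assert r >= max_3d_diameter(pts) / 2.0 - 1e-9


def test_diameter_bounds_equal_volume_sphere():
    """Isodiametric bound: max diameter >= diameter of the equal-volume sphere."""
    rng = np.random.default_rng(5)
    for seed in rng.integers(2**31, size=5):
        mask = generate_tumor_mask(
            ShapeParams(perturbation_amplitude=0.4, pad_mm=3.0, seed=int(seed))
        )
        mesh = extract_mesh(mask)
        v_mm3 = mesh_volume(mesh) * 1000.0
        d_equiv = 2.0 * (3.0 * v_mm3 / (4.0 * math.pi)) ** (1.0 / 3.0)
        assert max_3d_diameter(mesh) >= d_equiv * 0.999


def test_volume_area_agree_with_independent_mesh_library():
    """Divergence-theorem volume and triangle-sum area vs the trimesh oracle."""
    trimesh = pytest.importorskip("trimesh")
    mask = generate_tumor_mask(
        ShapeParams(perturbation_amplitude=0.3, pad_mm=3.0, seed=123)
    )
    mesh = extract_mesh(mask)
    oracle = trimesh.Trimesh(vertices=mesh.vertices, faces=mesh.faces, process=False)
    assert mesh_volume(mesh) * 1000.0 == pytest.approx(abs(oracle.volume), rel=1e-9)
    assert mesh_surface_area(mesh) * 100.0 == pytest.approx(oracle.area, rel=1e-9)
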