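"""Structural features: thickness, volume sampling, curvature, LCD, doughnut."""

import numpy as np
import pytest
from scipy import stats

import fcdsurf as f
from fcdsurf.features import welch_t_map
from fcdsurf.io import VolumeImage
from fcdsurf.mesh import VertexMap


def _unit_affine(origin):
    aff = np.eye(4)
    aff[:3, 3] = origin
    return aff


@pytest.fixture(scope="module")
def linear_z_volume():
    """Intensity equals the z coordinate; voxel k sits at z = k - 8."""
    grid = np.broadcast_to(np.arange(20) - 8.0, (20, 20, 20)).copy()
    return VolumeImage(grid, _unit_affine([-8.0, -8.0, -8.0]))


class TestCorticalThickness:
    def test_identical_surfaces_zero(self, sphere50):
        pial = sphere50.with_kind(sphere50.vertices.copy(), "pial")
        th = f.cortical_thickness(sphere50, pial)
        np.testing.assert_allclose(th.values, 0.0, atol=1e-9)

    def test_parallel_sheets_three_mm(self):
        white = f.flat_grid(15, 15)
        pial = f.SurfaceMesh(white.vertices + [0, 0, 3.0], white.faces,
                             kind="pial")
        th = f.cortical_thickness(white, pial).values
        interior = np.flatnonzero(
            (white.vertices[:, 0] > 2) & (white.vertices[:, 0] < 12) &
            (white.vertices[:, 1] > 2) & (white.vertices[:, 1] < 12))
        np.testing.assert_allclose(th[interior], 3.0, atol=1e-9)

    def test_concentric_spheres(self, sphere50):
        pial = f.icosphere(4, 53.0, kind="pial")
        th = f.cortical_thickness(sphere50, pial).values
        assert np.all(np.abs(th - 3.0) < 0.1)

    def test_topology_mismatch_rejected(self, sphere50):
        other = f.icosphere(3, 53.0)
        with pytest.raises(ValueError, match="topology"):
            f.cortical_thickness(sphere50, other)


class TestSampleIntensity:
    def test_constant_volume_everywhere(self):
        vol = VolumeImage(np.full((10, 10, 10), 100.0),
                          _unit_affine([-4, -4, -4]))
        white = f.flat_grid(5, 5)
        pial = f.SurfaceMesh(white.vertices + [0, 0, 3.0], white.faces)
        for pos in f.FLAIR_POSITIONS:
            vm = f.sample_intensity(vol, white, pial, pos)
            np.testing.assert_allclose(vm.values, 100.0)

    def test_linear_gradient_exact_at_depths(self, linear_z_volume):
        white = f.flat_grid(5, 5)
        pial = f.SurfaceMesh(white.vertices + [0, 0, 4.0], white.faces)
        for frac, expect in ((0.25, 1.0), (0.5, 2.0), (0.75, 3.0)):
            vm = f.sample_intensity(linear_z_volume, white, pial,
                                    ("fraction", frac))
            assert vm.values[12] == pytest.approx(expect, abs=1e-9)
        vm = f.sample_intensity(linear_z_volume, white, pial, ("mm", -1.0))
        assert vm.values[12] == pytest.approx(-1.0, abs=1e-9)

    def test_boundary_sample_ignores_thickness(self, linear_z_volume):
        white = f.flat_grid(5, 5)
        thin = f.SurfaceMesh(white.vertices + [0, 0, 1.0], white.faces)
        thick = f.SurfaceMesh(white.vertices + [0, 0, 5.0], white.faces)
        a = f.sample_intensity(linear_z_volume, white, thin, ("fraction", 0.0))
        b = f.sample_intensity(linear_z_volume, white, thick, ("fraction", 0.0))
        np.testing.assert_allclose(a.values, b.values)

    def test_outside_grid_flagged_non_finite(self):
        vol = VolumeImage(np.ones((5, 5, 5)), _unit_affine([0, 0, 0]))
        white = f.flat_grid(3, 3, spacing=10.0)
        pial = f.SurfaceMesh(white.vertices + [0, 0, 1.0], white.faces)
        vm = f.sample_intensity(vol, white, pial, ("fraction", 0.5))
        assert np.isnan(vm.values).any()


class TestGwContrast:
    def _two_phase(self, gm, wm, blur=0.0):
        # boundary at z=0: z<0 -> WM, z>=0 -> GM
        grid = np.where(np.arange(24)[None, None, :] - 10.0 < 0, wm, gm
                        ).astype(float)
        grid = np.broadcast_to(grid, (24, 24, 24)).copy()
        if blur:
            from scipy.ndimage import gaussian_filter
            grid = gaussian_filter(grid, blur)
        return VolumeImage(grid, _unit_affine([-10, -10, -10]))

    def test_uniform_volume_ratio_one(self):
        vol = self._two_phase(80.0, 80.0)
        white = f.flat_grid(5, 5)
        pial = f.SurfaceMesh(white.vertices + [0, 0, 4.0], white.faces)
        np.testing.assert_allclose(f.gw_contrast(vol, white, pial).values, 1.0)

    def test_sharp_two_phase_ratio(self):
        vol = self._two_phase(60.0, 100.0)
        white = f.flat_grid(5, 5)
        pial = f.SurfaceMesh(white.vertices + [0, 0, 4.0], white.faces)
        assert f.gw_contrast(vol, white, pial).values[12] == \
            pytest.approx(0.6, abs=1e-9)

    def test_blurred_boundary_moves_ratio_toward_one(self):
        white = f.flat_grid(5, 5)
        pial = f.SurfaceMesh(white.vertices + [0, 0, 4.0], white.faces)
        sharp = f.gw_contrast(self._two_phase(60, 100), white, pial).values[12]
        blurred = f.gw_contrast(self._two_phase(60, 100, blur=1.5), white,
                                pial).values[12]
        assert sharp < blurred < 1.0


class TestIntrinsicCurvature:
    def test_gauss_bonnet_on_closed_genus_zero(self, sphere50):
        total = f.intrinsic_curvature(sphere50).values.sum()
        assert total == pytest.approx(4 * np.pi, rel=1e-9)

    def test_flat_interior_zero_and_boundary_flagged(self, grid41):
        kap = f.intrinsic_curvature(grid41).values
        assert kap[20 * 41 + 20] == pytest.approx(0.0, abs=1e-12)
        assert np.isnan(kap[0])  # corner is a boundary vertex

    def test_cube_corner_deficit(self):
        import trimesh
        box = trimesh.creation.box((2, 2, 2))
        m = f.SurfaceMesh(np.asarray(box.vertices), np.asarray(box.faces))
        kap = f.intrinsic_curvature(m).values
        np.testing.assert_allclose(kap, np.pi / 2, atol=1e-12)

    def test_per_area_variant_scales_with_vertex_area(self, sphere50):
        dense = f.intrinsic_curvature(sphere50, per_area=True).values
        plain = f.intrinsic_curvature(sphere50).values
        areas = f.vertex_areas(sphere50).values
        np.testing.assert_allclose(dense, plain / areas, rtol=1e-9)


class TestLocalCorticalDeformation:
    def test_flat_sheet_zero_interior(self):
        g = f.flat_grid(41, 41)
        lcd = f.local_cortical_deformation(g, radius=5.0).values
        assert lcd[20 * 41 + 20] == pytest.approx(0.0, abs=1e-9)

    def test_sphere_matches_analytic_cap(self, sphere50):
        lcd = f.local_cortical_deformation(sphere50, radius=25.0).values
        analytic = 2 * np.pi * (1 - np.cos(25.0 / 50.0))
        assert np.nanmean(lcd) == pytest.approx(analytic, rel=0.10)

    def test_rigid_motion_invariance(self):
        m = f.icosphere(3, 30.0)
        from scipy.spatial.transform import Rotation
        rot = Rotation.from_euler("xyz", [0.3, -1.1, 0.7]).as_matrix()
        moved = f.SurfaceMesh(m.vertices @ rot.T + [5, -3, 11], m.faces)
        a = f.local_cortical_deformation(m, 12.0).values
        b = f.local_cortical_deformation(moved, 12.0).values
        np.testing.assert_allclose(a, b, atol=1e-8)

    def test_dimpled_patch_raises_lcd_locally(self):
        m = f.icosphere(4, 50.0)
        verts = m.vertices.copy()
        u = verts / 50.0
        ang = np.arccos(np.clip(u @ [0, 0, 1.0], -1, 1))
        ripple = 0.5 * np.sin(50.0 * u[:, 0] * 2) * np.exp(-(ang / 0.2) ** 2)
        dim = f.SurfaceMesh(verts * (1 + ripple / 50.0)[:, None], m.faces)
        lcd = f.local_cortical_deformation(dim, 20.0).values
        top = int(np.argmax(u[:, 2]))
        bottom = int(np.argmin(u[:, 2]))
        assert lcd[top] > lcd[bottom]


class TestDoughnutMap:
    def test_constant_feature_all_zero(self, sphere50):
        vm = VertexMap(np.full(sphere50.n_vertices, 4.0), "thickness")
        out = f.doughnut_map(vm, sphere50, radius=6.0, fwhm=0.0)
        np.testing.assert_allclose(out.values, 0.0, atol=1e-12)

    def test_matches_scipy_welch_oracle_on_random_cases(self):
        rng = np.random.default_rng(4)
        n_cases = 200
        sizes1 = rng.integers(5, 60, n_cases)
        sizes2 = rng.integers(5, 60, n_cases)
        vals, dp, dm, ap, am = [], [0], [], [0], []
        offset = 0
        for n1, n2 in zip(sizes1, sizes2):
            x = rng.normal(rng.uniform(-5, 5), rng.uniform(0.5, 3), n1)
            y = rng.normal(rng.uniform(-5, 5), rng.uniform(0.5, 3), n2)
            vals.extend(x)
            vals.extend(y)
            dm.extend(range(offset, offset + n1))
            am.extend(range(offset + n1, offset + n1 + n2))
            offset += n1 + n2
            dp.append(len(dm))
            ap.append(len(am))
        stat, _ = welch_t_map(np.array(vals), np.array(dp), np.array(dm),
                              np.array(ap), np.array(am))
        # recompute expected with scipy per case
        offset = 0
        for i, (n1, n2) in enumerate(zip(sizes1, sizes2)):
            x = np.array(vals[offset:offset + n1])
            y = np.array(vals[offset + n1:offset + n1 + n2])
            offset += n1 + n2
            _, p = stats.ttest_ind(x, y, equal_var=False)
            expect = np.sign(x.mean() - y.mean()) * (-np.log10(p))
            assert stat[i] == pytest.approx(expect, abs=1e-9)

    def test_swapping_samples_flips_sign_exactly(self):
        rng = np.random.default_rng(5)
        x = rng.normal(10, 1, 50)
        y = rng.normal(0, 1, 50)
        vals = np.r_[x, y]
        dp = np.array([0, 50])
        ap = np.array([0, 50])
        fwd, _ = welch_t_map(vals, dp, np.arange(50), ap, np.arange(50, 100))
        rev, _ = welch_t_map(vals, dp, np.arange(50, 100), ap, np.arange(50))
        assert fwd[0] == -rev[0]
        assert fwd[0] > 0

    def test_too_few_samples_gives_zero(self):
        vals = np.array([1.0, 2.0, 5.0, 6.0, 7.0, 8.0])
        stat, n_skipped = welch_t_map(vals, np.array([0, 2]), np.arange(2),
                                      np.array([0, 4]), np.arange(2, 6))
        assert stat[0] == 0.0
        assert n_skipped == 1
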