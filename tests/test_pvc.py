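import numpy as np
import pytest

from conftest import gm_core_mask
from earlyframe.pvc import (ProjectionParams, PvcParams, SmoothingParams,
                            extract_roi_means, muller_gartner,
                            project_to_surface, smooth_surface)
from earlyframe.synthetic import generate_phantom


class TestMullerGartner:
    def test_identity_in_delta_psf_limit(self):
        # pure-GM block: with a near-delta PSF corrected equals observed
        shape = (20, 20, 20)
        gm = np.ones(shape)
        wm = np.zeros(shape)
        csf = np.zeros(shape)
        pet = np.random.default_rng(0).uniform(2, 5, shape)
        params = PvcParams(psf_fwhm_mm=1e-6, wm_prob_threshold=0.5)
        wm[0, 0, 0] = 1.0
        gm[0, 0, 0] = 0.0
        params = PvcParams(psf_fwhm_mm=1e-6, wm_prob_threshold=0.5,
                           wm_erosion_mm=0.0)
        out = muller_gartner(pet, gm, wm, csf, voxel_mm=2.0, params=params)
        core = gm > 0.5
        np.testing.assert_allclose(out[core], pet[core], rtol=1e-6)

    @pytest.mark.parametrize("fwhm", [4.0, 6.0, 8.0])
    @pytest.mark.parametrize("contrast", [2.0, 4.0])
    def test_phantom_recovery(self, fwhm, contrast):
        acts = {"gm": contrast, "wm": 1.0, "csf": 0.0}
        p = generate_phantom(psf_fwhm_mm=fwhm, compartment_activities=acts)
        out = muller_gartner(p.activity, p.gm, p.wm, p.csf, p.voxel_mm,
                             PvcParams(psf_fwhm_mm=fwhm))
        core = gm_core_mask(p) & np.isfinite(out)
        rel_err = np.abs(out[core] - contrast) / contrast
        assert np.median(rel_err) < 0.05

    def test_homogeneity_degree_one(self, phantom6):
        p = phantom6
        params = PvcParams(psf_fwhm_mm=6.0)
        a = muller_gartner(p.activity, p.gm, p.wm, p.csf, p.voxel_mm, params)
        b = muller_gartner(2.0 * p.activity, p.gm, p.wm, p.csf, p.voxel_mm, params)
        mask = np.isfinite(a)
        np.testing.assert_allclose(b[mask], 2.0 * a[mask], rtol=1e-9)

    def test_invalid_fwhm_rejected(self):
        with pytest.raises(ValueError):
            PvcParams(psf_fwhm_mm=0.0)

    def test_empty_domain_rejected(self, phantom6):
        p = phantom6
        with pytest.raises(ValueError, match="domain"):
            muller_gartner(p.activity, np.zeros_like(p.gm), p.wm, p.csf,
                           p.voxel_mm, PvcParams(psf_fwhm_mm=6.0))


class TestProjectToSurface:
    def test_constant_volume_projects_to_constant(self, phantom6):
        vol = np.full(phantom6.activity.shape, 2.5)
        vals, clamped = project_to_surface(vol, phantom6.voxel_mm, phantom6.mesh)
        assert np.allclose(vals, 2.5)
        assert not clamped.any()

    def test_infinite_sigma_equals_flat_mean(self, phantom6):
        vol = phantom6.activity
        flat = ProjectionParams(weight_sigma=np.inf)
        vals_flat, _ = project_to_surface(vol, phantom6.voxel_mm, phantom6.mesh, flat)
        acc = np.zeros(phantom6.mesh.n_vertices)
        for d in flat.depth_fractions:
            pts = (phantom6.mesh.vertices
                   + (d - 0.5) * phantom6.mesh.thickness[:, None]
                   * phantom6.mesh.normals)
            from scipy.ndimage import map_coordinates
            acc += map_coordinates(vol, pts.T / phantom6.voxel_mm, order=1,
                                   mode="nearest")
        np.testing.assert_allclose(vals_flat, acc / 7.0, rtol=1e-12)

    def test_linear_gradient_gives_central_value(self, phantom6):
        # volume linear in z: symmetric weights cancel the odd term
        shape = phantom6.activity.shape
        z = np.arange(shape[2]) * phantom6.voxel_mm
        vol = np.broadcast_to(z, shape).astype(float)
        vals, _ = project_to_surface(vol, phantom6.voxel_mm, phantom6.mesh)
        central = phantom6.mesh.vertices[:, 2]
        np.testing.assert_allclose(vals, central, rtol=1e-6)

    def test_outside_samples_clamped_and_flagged(self, phantom6):
        mesh = phantom6.mesh
        shifted = type(mesh)(mesh.vertices + 200.0, mesh.faces, mesh.normals,
                             mesh.thickness, {})
        vals, clamped = project_to_surface(phantom6.activity, phantom6.voxel_mm,
                                           shifted)
        assert clamped.all()
        assert np.all(np.isfinite(vals))

    def test_weights_normalized(self):
        w = ProjectionParams().weights()
        assert w.sum() == pytest.approx(1.0, rel=1e-12)
        assert np.all(w > 0)
        assert w[3] == w.max()  # central surface weighted most


class TestSmoothSurface:
    def test_zero_fwhm_identity(self, closed_mesh):
        x = np.random.default_rng(1).normal(size=closed_mesh.n_vertices)
        out = smooth_surface(x, closed_mesh, SmoothingParams(fwhm_mm=0.0))
        np.testing.assert_array_equal(out, x)

    def test_constant_fixed_point(self, closed_mesh):
        x = np.full(closed_mesh.n_vertices, 4.2)
        out = smooth_surface(x, closed_mesh, SmoothingParams(fwhm_mm=8.0),
                             include=np.ones(closed_mesh.n_vertices, bool))
        np.testing.assert_allclose(out, 4.2, rtol=1e-12)

    def test_area_weighted_mean_conserved(self, closed_mesh):
        rng = np.random.default_rng(2)
        x = rng.uniform(0, 10, closed_mesh.n_vertices)
        inc = np.ones(closed_mesh.n_vertices, bool)
        out = smooth_surface(x, closed_mesh, SmoothingParams(fwhm_mm=10.0), inc)
        a = closed_mesh.vertex_areas
        assert (a * out).sum() == pytest.approx((a * x).sum(), rel=1e-6)

    def test_positivity_preserved(self, closed_mesh):
        rng = np.random.default_rng(3)
        x = rng.uniform(0, 1, closed_mesh.n_vertices)
        inc = np.ones(closed_mesh.n_vertices, bool)
        out = smooth_surface(x, closed_mesh, SmoothingParams(fwhm_mm=12.0), inc)
        assert np.all(out >= -1e-12)

    def test_linearity(self, closed_mesh):
        rng = np.random.default_rng(4)
        x = rng.normal(size=closed_mesh.n_vertices)
        y = rng.normal(size=closed_mesh.n_vertices)
        inc = np.ones(closed_mesh.n_vertices, bool)
        p = SmoothingParams(fwhm_mm=8.0)
        lhs = smooth_surface(2.0 * x + 3.0 * y, closed_mesh, p, inc)
        rhs = (2.0 * smooth_surface(x, closed_mesh, p, inc)
               + 3.0 * smooth_surface(y, closed_mesh, p, inc))
        np.testing.assert_allclose(lhs, rhs, rtol=1e-9, atol=1e-12)

    @pytest.mark.parametrize("fwhm", [6.0, 8.0])
    def test_impulse_half_maximum_radius(self, flat_mesh, fwhm):
        n = flat_mesh.n_vertices
        center = 20 * 41 + 20
        x = np.zeros(n)
        x[center] = 1.0
        inc = np.ones(n, bool)
        out = smooth_surface(x, flat_mesh, SmoothingParams(fwhm_mm=fwhm), inc)
        d = np.linalg.norm(flat_mesh.vertices - flat_mesh.vertices[center], axis=1)
        half = out[center] / 2.0
        order = np.argsort(d)
        below = np.flatnonzero(out[order] < half)
        r_half = d[order][below[0]]
        edge = 1.0
        assert abs(r_half - fwhm / 2.0) <= edge

    def test_negative_fwhm_rejected(self):
        with pytest.raises(ValueError):
            SmoothingParams(fwhm_mm=-1.0)

    def test_medial_wall_untouched(self, small_mesh):
        rng = np.random.default_rng(5)
        x = rng.normal(size=small_mesh.n_vertices)
        out = smooth_surface(x, small_mesh, SmoothingParams(fwhm_mm=8.0))
        wall = small_mesh.patches["medial_wall"]
        np.testing.assert_array_equal(out[wall], x[wall])


class TestExtractRoiMeans:
    def test_constant_map(self, small_mesh):
        means = extract_roi_means(np.full(small_mesh.n_vertices, 2.2), small_mesh)
        assert len(means) == 68
        valid = means.dropna()
        assert np.allclose(valid, 2.2)

    def test_parcel_indicator(self, small_mesh):
        name = "lh_parcel_10"
        x = small_mesh.patches[name].astype(float)
        means = extract_roi_means(x, small_mesh)
        assert means[name] == pytest.approx(1.0)
        others = means.drop(name).dropna()
        # parcels are disjoint, so every other parcel averages zero
        assert np.allclose(others, 0.0)

    def test_matches_brute_force(self, small_mesh):
        rng = np.random.default_rng(6)
        x = rng.normal(size=small_mesh.n_vertices)
        means = extract_roi_means(x, small_mesh)
        a = small_mesh.vertex_areas
        inc = small_mesh.included
        for name in small_mesh.parcel_names():
            mask = small_mesh.patches[name] & inc
            if mask.any():
                expected = (a[mask] * x[mask]).sum() / a[mask].sum()
                assert means[name] == pytest.approx(expected, rel=1e-12)
            else:
                assert np.isnan(means[name])
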