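"""Layer geometry: raw thickness, tilt-component fits and the cosine
correction, checked against analytic constructions and independent
closed-form oracles."""

import numpy as np
import pytest

from retspm.core import LAYERS, TOTAL, SegmentedOCT
from retspm import geometry as G
from retspm.synthetic import generate_subject
from conftest import grid_coords_um, make_slab, no_tilt_params, quiet_spec

PITCH = (11.71875, 46.875, 3.5)


class TestRawThickness:
    def test_coincident_surfaces_zero(self, flat_slab_oct):
        o = flat_slab_oct
        o.surfaces[:, :, 3] = o.surfaces[:, :, 4]
        t = G.raw_thickness(o, "INL")
        assert np.all(t.values == 0)

    def test_flat_offset_is_uniform(self, flat_slab_oct):
        t = G.raw_thickness(flat_slab_oct, "GCL")
        np.testing.assert_allclose(t.values, 30.0)

    def test_layers_telescope_to_total(self):
        spec = quiet_spec(sd_local_frac=0.05, sd_global_frac=0.05)
        o = generate_subject(spec, "control", 3)
        total = G.raw_thickness(o, TOTAL).values
        summed = sum(G.raw_thickness(o, k).values for k in LAYERS)
        np.testing.assert_allclose(summed, total, atol=1e-9)

    def test_order_violation_raises(self, flat_slab_oct):
        o = flat_slab_oct
        o.surfaces[:, :, 5] -= 100.0
        with pytest.raises(ValueError, match="order"):
            G.raw_thickness(o, "OPL")


class TestGlobalTilt:
    def test_horizontal_surface_zero_tilt(self, flat_slab_oct):
        U, gamma = G.fit_global_tilt(flat_slab_oct)
        assert gamma == pytest.approx(0.0, abs=1e-9)
        np.testing.assert_allclose(U, [0, 0, 1], atol=1e-12)

    @pytest.mark.parametrize("deg", [10.0, 45.0])
    def test_inclined_plane_recovers_angle(self, deg):
        x, y = grid_coords_um(64, 256, PITCH)
        z = 500.0 + np.tan(np.radians(deg)) * x
        o = make_slab(z, 300.0, PITCH)
        _, gamma = G.fit_global_tilt(o)
        assert gamma == pytest.approx(deg, abs=1e-9)

    def test_matches_closed_form_normal_equations(self):
        rng = np.random.default_rng(0)
        x, y = grid_coords_um(32, 64, PITCH)
        z = 400.0 + 0.08 * x - 0.05 * y + rng.normal(0, 5.0, x.shape)
        o = make_slab(z, 300.0, PITCH)
        o.valid_mask[5:12, 30:55] = False
        U, gamma = G.fit_global_tilt(o)
        # independent closed-form solution of the normal equations
        m = o.valid_mask
        h = -z[m]
        A = np.column_stack([x[m], y[m], np.ones(m.sum())])
        coef = np.linalg.solve(A.T @ A, A.T @ h)
        n = np.array([-coef[0], -coef[1], 1.0])
        n /= np.linalg.norm(n)
        np.testing.assert_allclose(U, n, rtol=1e-9, atol=1e-12)
        assert gamma == pytest.approx(
            np.degrees(np.arccos(n[2])), rel=1e-9)

    def test_degenerate_points_raise(self):
        o = make_slab(np.full((4, 4), 300.0), 300.0, PITCH)
        o.valid_mask[:] = False
        o.valid_mask[0, :] = True  # collinear row only
        with pytest.raises(G.DegenerateFitError):
            G.fit_global_tilt(o)


def sphere_oct(R_mm, rows=128, cols=512, pitch=PITCH):
    x, y = grid_coords_um(rows, cols, pitch)
    rho2 = x ** 2 + y ** 2
    z = 500.0 + np.sqrt((R_mm * 1000.0) ** 2 - rho2) - R_mm * 1000.0
    return make_slab(z, 300.0, pitch), x, y


class TestSphericalTilt:
    def test_exact_sphere_radius_recovered(self):
        o, x, y = sphere_oct(12.0)
        (center, R), V, sigma = G.fit_spherical_tilt(o)
        # the central B-scan row sits half a pixel off the equator: its
        # section circle has radius sqrt(R^2 - y_row^2)
        y_row = y[o.shape[0] // 2, 0]
        expected = np.sqrt((12000.0) ** 2 - y_row ** 2)
        assert abs(R - expected) < 1e-3  # µm, i.e. within 1e-6 mm
        # sub-centre point: V is parallel to the A-scan axis in x
        irow, jc = o.shape[0] // 2, o.shape[1] // 2
        assert sigma[irow, jc] < 0.05

    def test_sigma_monotone_with_radial_distance(self):
        o, x, y = sphere_oct(12.0)
        _, _, sigma = G.fit_spherical_tilt(o)
        irow = o.shape[0] // 2
        right = sigma[irow, o.shape[1] // 2:]
        assert np.all(np.diff(right) > 0)

    def test_corner_tilt_plausible_for_eye_like_sphere(self):
        # apparent OB_RPE curvature of ~35 mm gives corner tilts of a few
        # degrees, bounded by the ~7 degree observed extreme
        o, x, y = sphere_oct(35.0)
        _, _, sigma = G.fit_spherical_tilt(o)
        assert 4.0 < sigma.max() <= 7.5

    def test_flat_surface_rejected(self, flat_slab_oct):
        with pytest.raises(G.SphericalFitError):
            G.fit_spherical_tilt(flat_slab_oct)

    def test_huge_radius_rejected(self):
        o, _, _ = sphere_oct(2000.0)
        with pytest.raises(G.SphericalFitError, match="maximum"):
            G.fit_spherical_tilt(o, max_radius_mm=500.0)


class TestFlatten:
    def test_obrpe_becomes_zero(self):
        o, _, _ = sphere_oct(20.0)
        f = G.flatten(o)
        np.testing.assert_allclose(f.surfaces[:, :, -1], 0.0, atol=1e-12)

    def test_raw_thickness_invariant(self):
        o, _, _ = sphere_oct(20.0)
        f = G.flatten(o)
        for lid in ("NFL", "ONL", TOTAL):
            np.testing.assert_allclose(G.raw_thickness(f, lid).values,
                                       G.raw_thickness(o, lid).values,
                                       atol=1e-9)

    def test_idempotent(self):
        o, _, _ = sphere_oct(20.0)
        f1 = G.flatten(o)
        f2 = G.flatten(f1)
        np.testing.assert_array_equal(f1.surfaces, f2.surfaces)


class TestMedialSurface:
    def test_midpoint_and_bounds(self, flat_slab_oct):
        f = G.flatten(flat_slab_oct)
        med = G.medial_surface(f, "GCL")
        lo = np.minimum(f.surfaces[:, :, 1], f.surfaces[:, :, 2])
        hi = np.maximum(f.surfaces[:, :, 1], f.surfaces[:, :, 2])
        assert np.all(med >= lo) and np.all(med <= hi)
        np.testing.assert_allclose(med, 0.5 * (lo + hi))

    def test_coincident_surfaces(self, flat_slab_oct):
        o = flat_slab_oct
        o.surfaces[:, :, 2] = o.surfaces[:, :, 1]
        med = G.medial_surface(G.flatten(o), "GCL")
        np.testing.assert_allclose(med, G.flatten(o).surfaces[:, :, 1])


def undulating_layer_oct(amp_um=40.0, period_mm=1.5, t_um=30.0,
                         rows=128, cols=512, pitch=PITCH):
    """GCL with a sinusoidal medial surface of known analytic slope and
    exactly known orthogonal thickness."""
    x, y = grid_coords_um(rows, cols, pitch)
    k = 2 * np.pi / (period_mm * 1000.0)
    med = amp_um * np.sin(k * x)
    lam_true = np.degrees(np.arctan(np.abs(amp_um * k * np.cos(k * x))))
    t_raw = t_um / np.cos(np.radians(lam_true))
    surfaces = np.empty((rows, cols, 11))
    surfaces[:, :, 10] = 500.0
    for kk in range(9, 2, -1):
        surfaces[:, :, kk] = surfaces[:, :, kk + 1] - 20.0
    surfaces[:, :, 1] = med + 250.0 - t_raw / 2.0
    surfaces[:, :, 2] = med + 250.0 + t_raw / 2.0
    surfaces[:, :, 0] = surfaces[:, :, 1] - 20.0
    o = SegmentedOCT(surfaces, np.ones((rows, cols), bool), pitch)
    return o, lam_true, t_um


class TestLocalTilt:
    def test_planar_medial_constant_inclination(self):
        x, y = grid_coords_um(64, 256, PITCH)
        # GCL band tilted 5 degrees inside an otherwise flat stack; the
        # other surfaces are placed far enough away to stay monotone
        slope = np.tan(np.radians(5.0))
        surfaces = np.empty((64, 256, 11))
        surfaces[:, :, 1] = 250.0 + slope * x - 15.0
        surfaces[:, :, 2] = 250.0 + slope * x + 15.0
        surfaces[:, :, 0] = -400.0
        for k in range(3, 11):
            surfaces[:, :, k] = 600.0 + 20.0 * (k - 3)
        o = SegmentedOCT(surfaces, np.ones((64, 256), bool), PITCH)
        W, lam = G.fit_local_tilt(G.flatten(o), "GCL")
        ok = np.isfinite(lam)
        assert np.nanmax(np.abs(lam[ok] - 5.0)) < 1e-6

    def test_sinusoid_matches_analytic_gradient(self):
        o, lam_true, _ = undulating_layer_oct()
        _, lam = G.fit_local_tilt(G.flatten(o), "GCL")
        interior = np.zeros(o.shape, bool)
        interior[6:-6, 25:-25] = True
        m = np.isfinite(lam) & interior
        # window averaging flattens curvature extremes slightly
        assert np.abs(lam - lam_true)[m].max() < 2.0
        # peaks co-located with analytic gradient peaks along a row
        row = o.shape[0] // 2
        jpk_fit = np.argmax(lam[row, 50:-50]) + 50
        assert abs(lam_true[row, jpk_fit] - lam_true[row].max()) < 0.2

    def test_low_validity_windows_marked_invalid(self):
        o, _, _ = undulating_layer_oct()
        o.valid_mask[:, :200] = False
        _, lam = G.fit_local_tilt(G.flatten(o), "GCL")
        assert np.all(~np.isfinite(lam[:, :150]))
        assert np.isfinite(lam[:, 300:]).all()


class TestTotalTilt:
    def test_all_axis_aligned_gives_zero(self):
        A = np.zeros((4, 4, 3))
        A[..., 2] = 1.0
        alpha = G.total_tilt(np.array([0, 0, 1.0]), A, A)
        np.testing.assert_allclose(alpha, 0.0, atol=1e-9)

    def test_one_component_at_30_degrees(self):
        """angle(2A + W) for W 30 deg off-axis: atan(sin30/(2+cos30))."""
        W = np.zeros((2, 2, 3))
        W[..., 0] = np.sin(np.radians(30.0))
        W[..., 2] = np.cos(np.radians(30.0))
        A = np.zeros((2, 2, 3))
        A[..., 2] = 1.0
        alpha = G.total_tilt(np.array([0, 0, 1.0]), A, W)
        expected = np.degrees(np.arctan(np.sin(np.radians(30.0))
                                        / (2.0 + np.cos(np.radians(30.0)))))
        np.testing.assert_allclose(alpha, expected, rtol=1e-12)
        assert expected == pytest.approx(9.896, abs=0.001)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(1)
        v = rng.normal(size=(3, 3, 3, 3))
        v /= np.linalg.norm(v, axis=-1, keepdims=True)
        u = v[0][0, 0]
        a1 = G.total_tilt(u, v[1], v[2])
        a2 = G.total_tilt(u, v[2], v[1])
        np.testing.assert_allclose(a1, a2, atol=1e-12)


class TestCorrectThickness:
    def test_zero_alpha_identity(self, flat_slab_oct):
        t = G.raw_thickness(flat_slab_oct, TOTAL)
        c = G.correct_thickness(t, np.zeros(t.shape))
        np.testing.assert_array_equal(c.values, t.values)

    def test_sixty_degrees_halves(self, flat_slab_oct):
        t = G.raw_thickness(flat_slab_oct, TOTAL)  # 300 µm
        c = G.correct_thickness(t, np.full(t.shape, 60.0))
        np.testing.assert_allclose(c.values, 150.0)

    def test_tilted_slab_recovery(self):
        x, y = grid_coords_um(64, 256, PITCH)
        z = 500.0 + np.tan(np.radians(10.0)) * x
        o = make_slab(z, 100.0 / np.cos(np.radians(10.0)), PITCH)
        t = G.raw_thickness(o, TOTAL)
        assert t.values.mean() == pytest.approx(101.54, abs=0.01)
        _, gamma = G.fit_global_tilt(o)
        c = G.correct_thickness(t, np.full(t.shape, gamma))
        assert np.abs(c.values - 100.0).max() < 0.1

    def test_corrected_never_exceeds_raw(self):
        o, lam_true, _ = undulating_layer_oct()
        t = G.raw_thickness(o, "GCL")
        c = G.correct_thickness(t, lam_true)
        assert np.all(c.values <= t.values + 1e-12)

    def test_alpha_at_least_90_invalid(self, flat_slab_oct):
        t = G.raw_thickness(flat_slab_oct, TOTAL)
        alpha = np.zeros(t.shape)
        alpha[0, 0] = 90.0
        c = G.correct_thickness(t, alpha)
        assert not c.valid_mask[0, 0] and c.valid_mask[1:].all()


class TestEndToEnd:
    def test_default_tilt_recovery_within_one_micron(self):
        """Full estimation chain on a generated subject with default tilt
        scales and no noise: per-layer corrected thickness within 1 µm of
        the known orthogonal truth."""
        spec = quiet_spec()
        o = generate_subject(spec, "control", 17)
        thickness, tilt = G.tilt_correct_subject(o)
        for lid in ("GCL", "ONL", "RPE"):
            truth = o.truth["thickness"][lid]
            g = thickness[lid]
            err = np.abs(g.values - truth)[g.valid_mask]
            assert err.max() < 1.0, lid

    def test_angle_maps_bounded(self):
        spec = quiet_spec()
        o = generate_subject(spec, "control", 23)
        _, tilt = G.tilt_correct_subject(o, layers=["GCL"])
        tf = tilt["GCL"]
        lam = tf.lambda_map[np.isfinite(tf.lambda_map)]
        for arr in (np.array([tf.gamma_deg]), tf.sigma_map.ravel(), lam,
                    tf.alpha_map[np.isfinite(tf.alpha_map)]):
            assert np.all(arr >= 0.0) and np.all(arr < 90.0)

    def test_stored_normals_unit_length(self):
        spec = quiet_spec()
        o = generate_subject(spec, "control", 29)
        _, tilt = G.tilt_correct_subject(o, layers=["GCL"])
        tf = tilt["GCL"]
        assert np.linalg.norm(tf.U) == pytest.approx(1.0, abs=1e-9)
        np.testing.assert_allclose(np.linalg.norm(tf.V_map, axis=-1), 1.0,
                                   atol=1e-9)
        np.testing.assert_allclose(np.linalg.norm(tf.W_map, axis=-1), 1.0,
                                   atol=1e-9)
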