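"""Magnetostatics: Bean closed forms, Biot-Savart quadrature, calibration, maps."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from mdtsim.magnet_field import (
    MU0,
    BulkMagnet,
    FieldMap,
    JcCurve,
    bean_k_factor,
    build_field_map,
    calibrate_jc,
    dipole_moment,
    field_at_point,
    field_at_points,
    magnetize,
    on_axis_field,
    peak_surface_field,
    trapped_field_peak,
)

TABLE3 = [(15e-3, 9e-3, 2.11), (25e-3, 15e-3, 3.02), (32.5e-3, 19e-3, 3.42),
          (40e-3, 23e-3, 3.70), (50e-3, 29e-3, 3.99)]
TABLE4 = [(32.5e-3, 19e-3, 3.42), (32.5e-3, 19e-3, 6.95), (32.5e-3, 19e-3, 10.80)]


class TestBeanClosedForms:
    def test_equal_aspect_value(self):
        # a = t collapses to ln(1 + sqrt 2)/2 for any absolute size
        expected = 0.5 * np.log(1 + np.sqrt(2))
        assert bean_k_factor(1.0, 1.0) == pytest.approx(expected, rel=1e-12)
        assert bean_k_factor(0.007, 0.007) == pytest.approx(expected, rel=1e-12)

    def test_reference_geometry(self):
        assert bean_k_factor(32.5e-3, 19e-3) == pytest.approx(0.38180, abs=5e-5)

    def test_thin_sample_limit(self):
        assert bean_k_factor(0.03, 1e-9) < 1e-6

    @given(st.floats(0.2, 5.0), st.floats(0.2, 5.0))
    def test_k_positive_and_bounded_for_flat_samples(self, a, t):
        k = bean_k_factor(a, t)
        assert k > 0
        if a >= t:
            assert k <= 0.5

    def test_invalid_dimensions_rejected(self):
        with pytest.raises(ValueError):
            bean_k_factor(-1.0, 1.0)
        with pytest.raises(ValueError):
            bean_k_factor(1.0, 0.0)

    def test_trapped_field_linearity(self):
        b1 = trapped_field_peak(1e8, 32.5e-3, 19e-3)
        b2 = trapped_field_peak(2e8, 32.5e-3, 19e-3)
        assert b2 == pytest.approx(2 * b1, rel=1e-12)
        assert trapped_field_peak(0.0, 0.03, 0.02) == 0.0
        assert b2 == pytest.approx(3.1186, abs=2e-3)


class TestBiotSavart:
    def test_on_axis_transverse_components_vanish(self, small_magnet):
        mag, cur = small_magnet
        b = field_at_points(mag, cur, np.array([[0, 0, 0.01], [0, 0, 0.05]]))
        assert np.all(np.abs(b[:, :2]) < 1e-12 * np.abs(b[:, 2:]))

    @pytest.mark.parametrize("a,t,bt", TABLE3)
    def test_surface_center_matches_bean_closed_form(self, a, t, bt):
        jc = calibrate_jc(bt, a, t)
        mag = BulkMagnet(a, t, jc)
        sim = peak_surface_field(mag)
        bean = trapped_field_peak(jc.jc0, a, t)
        assert abs(sim - bean) / bean < 5e-3

    def test_on_axis_closed_form_away_from_surface(self, small_magnet):
        mag, cur = small_magnet
        for z in (0.01, 0.03, 0.08):
            bz = field_at_point(mag, cur, (0, 0, z))[2]
            assert bz == pytest.approx(on_axis_field(mag.jc.jc0, mag.a, mag.t, z),
                                       rel=1e-6)

    def test_far_field_is_dipolar(self, small_magnet):
        mag, cur = small_magnet
        z = 10 * mag.a
        bz = field_at_point(mag, cur, (0, 0, z))[2]
        zc = z + mag.t / 2  # dipole sits at the current centroid
        bdip = MU0 * 2 * dipole_moment(mag.jc.jc0, mag.a, mag.t) / (4 * np.pi * zc**3)
        assert abs(bz - bdip) / bdip < 0.02

    def test_stored_moment_matches_formula(self, small_magnet):
        mag, cur = small_magnet
        assert cur.moment() == pytest.approx(
            dipole_moment(mag.jc.jc0, mag.a, mag.t), rel=1e-10)

    def test_monotone_decay_along_axis(self, small_magnet):
        mag, cur = small_magnet
        z = np.linspace(0.005, 0.2, 40)
        bz = field_at_points(mag, cur, np.column_stack([0 * z, 0 * z, z]))[:, 2]
        assert np.all(np.diff(bz) < 0)


class TestMagnetize:
    def test_constant_mode_single_pass(self):
        mag = BulkMagnet(0.02, 0.01, JcCurve("constant", 1e8))
        cur = magnetize(mag)
        assert cur.iterations == 1
        assert np.all(cur.j == 1e8)

    def test_kim_large_b0_reduces_to_constant(self):
        a, t, jc0 = 0.02, 0.01, 1e8
        const = peak_surface_field(BulkMagnet(a, t, JcCurve("constant", jc0)))
        kim = peak_surface_field(BulkMagnet(a, t, JcCurve("kim", jc0, b0=1e4)))
        assert kim == pytest.approx(const, rel=1e-3)

    def test_kim_self_field_suppression(self):
        a, t, jc0 = 0.02, 0.01, 2e8
        const = peak_surface_field(BulkMagnet(a, t, JcCurve("constant", jc0)))
        kim = peak_surface_field(BulkMagnet(a, t, JcCurve("kim", jc0, b0=1.0)))
        assert kim < const

    def test_jc_curve_validation(self):
        with pytest.raises(ValueError):
            JcCurve("constant", -1.0)
        with pytest.raises(ValueError):
            JcCurve("kim", 1e8)  # missing B0
        curve = JcCurve("kim", 1e8, 2.0)
        b = np.array([0.0, 1.0, 5.0])
        jc = curve(b)
        assert np.all(np.diff(jc) < 0) and np.all(jc > 0)
        assert curve(0.0) == pytest.approx(1e8)


class TestCalibration:
    @pytest.mark.parametrize("a,t,bt", TABLE3 + TABLE4)
    def test_round_trip_reproduces_printed_fields(self, a, t, bt):
        mag = BulkMagnet(a, t, calibrate_jc(bt, a, t))
        assert abs(peak_surface_field(mag) - bt) / bt < 0.01

    def test_constant_mode_closed_form_inversion(self):
        a, t = 32.5e-3, 19e-3
        jc = calibrate_jc(3.42, a, t)
        assert jc.jc0 == pytest.approx(3.42 / (bean_k_factor(a, t) * MU0 * a), rel=1e-12)

    def test_kim_mode_round_trip(self):
        a, t = 15e-3, 9e-3
        jc = calibrate_jc(2.11, a, t, model="kim", b0=1.5)
        mag = BulkMagnet(a, t, jc)
        assert peak_surface_field(mag) == pytest.approx(2.11, rel=1e-2)

    def test_unattainable_target_rejected(self):
        with pytest.raises(ValueError):
            calibrate_jc(-1.0, 0.02, 0.01)


@pytest.fixture(scope="module")
def fmap(small_magnet):
    mag, cur = small_magnet
    box = ((-0.02, -0.02, 0.02), (0.02, 0.02, 0.05))
    return build_field_map(mag, cur, box, spacing=1e-3)


class TestFieldMap:

    def test_b_equals_mu0_h_everywhere(self, fmap):
        np.testing.assert_allclose(fmap.h(), fmap.b / MU0, rtol=1e-12)

    def test_interpolation_matches_direct_integral(self, small_magnet, fmap):
        mag, cur = small_magnet
        pts = np.array([[0.0, 0.0, 0.04], [0.005, -0.003, 0.03]])
        bi = fmap.b_at(pts)
        bd = field_at_points(mag, cur, pts)
        err = np.linalg.norm(bi - bd, axis=1) / np.linalg.norm(bd, axis=1)
        assert np.all(err < 0.01)

    def test_grad_h2_consistent_with_stored_h2(self, fmap):
        g_fd = np.stack(np.gradient(fmap.h2(), fmap.spacing), axis=-1)
        g = fmap.grad_h2
        inner = (slice(1, -1),) * 3
        num = np.linalg.norm(g[inner] - g_fd[inner], axis=-1)
        den = np.linalg.norm(g[inner], axis=-1)
        assert np.median(num / den) < 0.02

    def test_divergence_free(self, fmap):
        div = fmap.divergence()
        scale = np.max(np.linalg.norm(fmap.b, axis=-1)) / fmap.spacing
        assert np.max(np.abs(div)) / scale < 0.01

    def test_on_axis_gradient_points_to_magnet(self, small_magnet, fmap):
        g = fmap.grad_h2_at(np.array([[0.0, 0.0, 0.03]]))[0]
        assert g[2] < 0  # toward the surface (paramagnetic attraction)
        assert abs(g[0]) < 1e-4 * abs(g[2]) and abs(g[1]) < 1e-4 * abs(g[2])

    def test_refinement_convergence(self, small_magnet):
        mag, cur = small_magnet
        box = ((-0.01, -0.01, 0.025), (0.01, 0.01, 0.04))
        probes = np.array([[0.002, 0.001, 0.03], [-0.004, 0.006, 0.035]])
        vals = []
        for spacing in (2e-3, 1e-3):
            fm = build_field_map(mag, cur, box, spacing=spacing)
            vals.append(np.linalg.norm(fm.grad_h2_at(probes), axis=1))
        assert np.all(np.abs(vals[1] - vals[0]) / vals[1] < 0.02)

    def test_lookup_outside_box_raises(self, fmap):
        from mdtsim.magnet_field import FieldMapLookupError

        with pytest.raises(FieldMapLookupError):
            fmap.b_at(np.array([[1.0, 0.0, 0.0]]))

    def test_csv_round_trip(self, fmap, tmp_path):
        path = tmp_path / "map.csv"
        fmap.to_csv(path)
        back = FieldMap.from_csv(path)
        np.testing.assert_allclose(back.b, fmap.b, rtol=1e-6, atol=1e-12)
        np.testing.assert_allclose(back.grad_h2, fmap.grad_h2, rtol=1e-6, atol=1e-6)

    def test_zero_map_for_disabled_magnet(self):
        fm = FieldMap.zero(((-0.01,) * 3, (0.01,) * 3), 2e-3)
        assert fm.is_zero
        assert np.all(fm.grad_h2_at(np.zeros((2, 3))) == 0.0)
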