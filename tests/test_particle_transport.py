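"""Particle dynamics: drag, magnetophoresis, seeding, and the integrator."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.integrate import solve_ivp

from mdtsim.airflow import UniformFlow, solve_flow
from mdtsim.lung_geometry import add_tumor, build_weibel_tree
from mdtsim.magnet_field import MU0, BulkMagnet, build_field_map, calibrate_jc, magnetize
from mdtsim.particle_transport import (
    DtControl,
    ParticleEnsemble,
    ParticleSpec,
    Status,
    contrast_factor,
    drag_force,
    integrate,
    magnetophoretic_force,
    seed_particles,
)

AIR = dict(rho=1.22, eta=1.78e-5)


class TestParticleSpec:
    def test_mass_formula(self):
        spec = ParticleSpec()
        assert spec.mass == pytest.approx(np.pi / 6 * (4e-6) ** 3 * 5230.0, rel=1e-15)

    def test_stokes_time_at_one_micron(self):
        spec = ParticleSpec(d_p=1e-6)
        assert spec.stokes_time(AIR["eta"]) == pytest.approx(1.63e-5, rel=5e-3)

    def test_diamagnetic_particles_rejected(self):
        with pytest.raises(ValueError):
            ParticleSpec(mu_r_p=0.9)


class TestDragForce:
    def test_zero_slip_gives_zero_force(self):
        spec = ParticleSpec()
        f = drag_force(np.array([1.0, 0, 0]), np.array([1.0, 0, 0]), spec, **AIR)
        assert np.all(f == 0.0)

    def test_stokes_limit_reduction(self):
        """F_d reduces to 3 pi eta d_p (u - v) as Re_p -> 0, to 1e-10 relative."""
        spec = ParticleSpec()
        slip = np.array([1e-14, 0, 0])
        f = drag_force(slip, np.zeros(3), spec, **AIR)
        stokes = 3 * np.pi * AIR["eta"] * spec.d_p * slip
        assert np.linalg.norm(f - stokes) / np.linalg.norm(stokes) < 1e-10

    def test_schiller_naumann_correction_at_re_one(self):
        # C_D(Re=1) = 24 * 1.15, i.e. drag is 1.15x Stokes
        spec = ParticleSpec()
        u_re1 = AIR["eta"] / (AIR["rho"] * spec.d_p)
        slip = np.array([u_re1, 0, 0])
        f = drag_force(slip, np.zeros(3), spec, **AIR)
        stokes = 3 * np.pi * AIR["eta"] * spec.d_p * slip
        assert np.linalg.norm(f) / np.linalg.norm(stokes) == pytest.approx(1.15, rel=1e-9)

    @given(st.floats(1e-4, 10.0))
    def test_force_opposes_slip(self, speed):
        spec = ParticleSpec()
        v = np.array([speed, 0, 0])
        f = drag_force(np.zeros(3), v, spec, **AIR)
        assert f[0] < 0 and abs(f[1]) == 0 and abs(f[2]) == 0


class TestMagnetophoresis:
    def test_matched_permeability_gives_zero(self):
        assert contrast_factor(1.0, 1.0) == 0.0

    def test_printed_contrast_factor(self):
        assert contrast_factor(9.0, 1.0) == pytest.approx(8.0 / 11.0, rel=1e-12)

    def test_saturation_toward_unity(self):
        ks = [contrast_factor(mu) for mu in (3, 9, 30, 300, 3e6)]
        assert all(k2 > k1 for k1, k2 in zip(ks, ks[1:]))
        assert all(k < 1.0 for k in ks)
        assert ks[-1] == pytest.approx(1.0, abs=1e-5)

    def test_force_parallel_to_gradient(self):
        spec = ParticleSpec()
        g = np.array([1e11, -2e11, 5e11])
        f = magnetophoretic_force(spec, 1.0, g)
        np.testing.assert_allclose(np.cross(f, g), 0.0, atol=1e-30)
        expected = np.pi / 4 * spec.d_p**3 * MU0 * (8 / 11) * g
        np.testing.assert_allclose(f, expected, rtol=1e-12)


class TestSeeding:
    def test_counts_and_initial_velocity(self, tumor_tree, default_flow):
        ens = seed_particles(500, tumor_tree, default_flow, rng_seed=7)
        assert ens.n == 500
        assert np.all(ens.status == Status.IN_FLIGHT)
        np.testing.assert_allclose(ens.v, default_flow.velocity(ens.x), rtol=1e-12)

    def test_deterministic_under_seed(self, tumor_tree, default_flow):
        a = seed_particles(200, tumor_tree, default_flow, rng_seed=42)
        b = seed_particles(200, tumor_tree, default_flow, rng_seed=42)
        assert np.array_equal(a.x, b.x) and np.array_equal(a.v, b.v)

    def test_flux_weighting_oversamples_fast_core(self, tumor_tree, default_flow):
        """Flux-weighted seeds have mean speed 4/3 of the area mean.

        Poiseuille moments: int u^2 dA / int u dA = (4/3) ubar, above the
        area mean ubar.
        """
        ens = seed_particles(40000, tumor_tree, default_flow, rng_seed=3)
        mean_speed = np.mean(np.linalg.norm(ens.v, axis=1))
        ubar = default_flow.inlet_mean_speed()
        assert mean_speed == pytest.approx(4.0 / 3.0 * ubar, rel=0.01)
        uni = seed_particles(40000, tumor_tree, default_flow, rng_seed=3,
                             sampling="uniform")
        assert np.mean(np.linalg.norm(uni.v, axis=1)) < mean_speed


def _free_ensemble(x, v):
    n = x.shape[0]
    return ParticleEnsemble(x.copy(), v.copy(),
                            np.full(n, int(Status.IN_FLIGHT)), np.zeros(n),
                            [[0] for _ in range(n)])


class TestIntegrator:
    def test_zero_force_straight_line(self):
        flow = UniformFlow(np.array([0.3, 0.0, 0.0]))
        ens = _free_ensemble(np.zeros((1, 3)), np.array([[0.3, 0.0, 0.0]]))
        integrate(ens, flow, None, ParticleSpec(), tree=None, t_max=0.1)
        np.testing.assert_allclose(ens.x[0], [0.03, 0, 0], rtol=1e-9)

    def test_velocity_relaxation_closed_form(self):
        """v(t) = u0 (1 - exp(-t/tau)) within 0.1% for a 1 um particle."""
        u0 = 1e-3  # small speed keeps Re_p negligible (Stokes regime)
        spec = ParticleSpec(d_p=1e-6)
        tau = spec.stokes_time(AIR["eta"])
        flow = UniformFlow(np.array([u0, 0.0, 0.0]))
        for t_end in (tau, 3 * tau, 8 * tau):
            ens = _free_ensemble(np.zeros((1, 3)), np.zeros((1, 3)))
            integrate(ens, flow, None, spec, tree=None, t_max=t_end,
                      dt_control=DtControl(dt_max=tau / 3, ds_max=1.0))
            expected = u0 * (1 - np.exp(-ens.time[0] / tau))
            assert abs(ens.v[0, 0] - expected) / u0 < 1e-3

    def test_particle_seeded_on_wall_deposits_immediately(self, tumor_tree, default_flow):
        g0 = tumor_tree.root
        onwall = g0.start + 0.5 * g0.length * g0.direction + np.array(
            [0, 0, g0.radius * 1.0001])
        ens = _free_ensemble(onwall[None, :], np.zeros((1, 3)))
        integrate(ens, default_flow, None, ParticleSpec(), tree=tumor_tree, t_max=1e-3)
        assert ens.status[0] == Status.DEPOSITED_WALL

    def test_count_conservation(self, tumor_tree, default_flow):
        ens = seed_particles(300, tumor_tree, default_flow, rng_seed=5)
        res = integrate(ens, default_flow, None, ParticleSpec(), tree=tumor_tree,
                        t_max=3 * default_flow.transit_time())
        c = res.counts()
        total = sum(c[k] for k in ("in_flight", "deposited_wall", "deposited_tumor",
                                   "exited_outlet", "suspended", "error"))
        assert total == 300
        assert c["in_flight"] == 0  # run to completion

    def test_trajectory_matches_high_order_reference(self):
        """Straight channel + on-axis magnet: integrator vs solve_ivp < 1%."""
        a, t = 15e-3, 9e-3
        mag = BulkMagnet(a, t, calibrate_jc(2.11, a, t), center=(0.04, 0.0, -0.025))
        cur = magnetize(mag)
        fmap = build_field_map(mag, cur, ((-0.005, -0.01, -0.01), (0.09, 0.01, 0.01)),
                               spacing=1e-3)
        spec = ParticleSpec()
        flow = UniformFlow(np.array([0.5, 0.0, 0.0]))
        cm = np.pi / 4 * spec.d_p**3 * MU0 * contrast_factor(spec.mu_r_p)

        def rhs(t_, y):
            x, v = y[:3], y[3:]
            u = flow.u
            rel = u - v
            re = AIR["rho"] * np.linalg.norm(rel) * spec.d_p / AIR["eta"]
            fd = 3 * np.pi * AIR["eta"] * spec.d_p * (1 + 0.15 * re**0.687) * rel
            fm = cm * fmap.grad_h2_at(x[None, :])[0]
            return np.concatenate([v, (fd + fm) / spec.mass])

        x0 = np.array([0.0, 0.0, 0.004])
        v0 = flow.u.copy()
        t_end = 0.12
        ref = solve_ivp(rhs, (0, t_end), np.concatenate([x0, v0]),
                        rtol=1e-10, atol=1e-14, dense_output=True)
        ens = _free_ensemble(x0[None, :], v0[None, :])
        integrate(ens, flow, fmap, spec, tree=None, t_max=t_end,
                  dt_control=DtControl(dt_max=2e-4, ds_max=1e-4))
        path_len = 0.5 * t_end
        err = np.linalg.norm(ens.x[0] - ref.y[:3, -1])
        assert err / path_len < 0.01

    def test_zero_field_map_equals_no_field(self, tumor_tree, default_flow):
        """A null field map reproduces pure aerosol transport exactly."""
        from mdtsim.magnet_field import FieldMap

        lo, hi = tumor_tree.bounding_box(margin=2e-3)
        zero = FieldMap.zero((lo, hi), 5e-3)
        ens1 = seed_particles(150, tumor_tree, default_flow, rng_seed=9)
        ens2 = seed_particles(150, tumor_tree, default_flow, rng_seed=9)
        integrate(ens1, default_flow, zero, ParticleSpec(), tree=tumor_tree,
                  t_max=2 * default_flow.transit_time())
        integrate(ens2, default_flow, None, ParticleSpec(), tree=tumor_tree,
                  t_max=2 * default_flow.transit_time())
        assert np.array_equal(ens1.status, ens2.status)
        np.testing.assert_allclose(ens1.x, ens2.x, atol=1e-12)

    def test_absorbing_states_are_final(self, tumor_tree, default_flow):
        ens = seed_particles(100, tumor_tree, default_flow, rng_seed=11)
        res = integrate(ens, default_flow, None, ParticleSpec(), tree=tumor_tree,
                        t_max=3 * default_flow.transit_time())
        before = ens.status.copy()
        integrate(res.ensemble, default_flow, None, ParticleSpec(), tree=tumor_tree,
                  t_max=3 * default_flow.transit_time())
        assert np.array_equal(before, ens.status)

    def test_trajectory_export_csv_and_vtk(self, tumor_tree, default_flow, tmp_path):
        from mdtsim.particle_transport import export_trajectories

        ens = seed_particles(10, tumor_tree, default_flow, rng_seed=2)
        res = integrate(ens, default_flow, None, ParticleSpec(), tree=tumor_tree,
                        t_max=0.05, record_stride=5)
        csv = tmp_path / "traj.csv"
        vtk = tmp_path / "traj.vtk"
        export_trajectories(res, csv_path=csv, vtk_path=vtk)
        import pandas as pd

        df = pd.read_csv(csv)
        assert set(df.columns) == {"id", "t", "x", "y", "z", "status"}
        assert df["id"].nunique() > 0
        assert "LINES" in vtk.read_text()

    def test_branch_log_is_path_consistent(self, tumor_tree, default_flow):
        ens = seed_particles(80, tumor_tree, default_flow, rng_seed=13)
        integrate(ens, default_flow, None, ParticleSpec(), tree=tumor_tree,
                  t_max=3 * default_flow.transit_time())
        for log in ens.branch_logs:
            for a, b in zip(log, log[1:]):
                par_ok = b in tumor_tree[a].children or a in tumor_tree[b].children
                assert par_ok, f"non-adjacent branch hop {a}->{b}"
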