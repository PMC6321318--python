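"""MD engine: virtual site, forces, SCF, integrator, coupling baths."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from coswater import md
from coswater.constants import F_ELEC, KB_KJMOL
from coswater.forcefield import build_forcefield


@pytest.fixture(scope="module")
def topo8(ff):
    return md.Topology(ff=ff, n_mol=8)


@pytest.fixture(scope="module")
def dense_state(ff, topo8):
    """Small periodic box with random COS displacements (not SCF-relaxed)."""
    cfg = md.MDConfig(e_field_z=3.0, dispersion_tail=False)
    state = md.initial_lattice(topo8, box=md.box_for_density(8, 900.0), seed=4)
    rng = np.random.default_rng(0)
    state.cos_disp = rng.normal(0, 2e-4, size=(8, 3))
    return state, cfg


def gas_state(ff, n=1, spread=0.0, seed=0):
    topo = md.Topology(ff=ff, n_mol=n)
    rng = np.random.default_rng(seed)
    template = ff.geometry.site_positions()[:3]
    pos = np.empty((n, 3, 3))
    for i in range(n):
        rot = Rotation.random(random_state=rng).as_matrix()
        pos[i] = template @ rot.T + spread * rng.normal(size=3)
    state = md.SystemState(
        pos=pos, vel=np.zeros_like(pos), cos_disp=np.zeros((n, 3)), box=1e3, pbc=False
    )
    return topo, state


class TestVirtualSite:
    def test_symmetric_geometry_on_bisector(self, ff):
        pos = ff.geometry.site_positions()[:3][None]
        m = md.place_virtual_site(pos, ff.geometry.d_OM)
        assert np.allclose(m[0], [ff.geometry.d_OM, 0.0, 0.0], atol=1e-14)

    def test_force_and_torque_preserved(self, ff, rng):
        template = ff.geometry.site_positions()[:3]
        for _ in range(10):
            rot = Rotation.random(random_state=rng).as_matrix()
            pos = (template @ rot.T + rng.normal(size=3))[None]
            f_m = rng.normal(size=(1, 3))
            m = md.place_virtual_site(pos, ff.geometry.d_OM)
            spread = md.redistribute_force(pos, f_m, ff.geometry.d_OM)
            assert np.allclose(spread.sum(axis=1), f_m, atol=1e-12)
            torque_m = np.cross(m[0], f_m[0])
            torque_spread = np.cross(pos[0], spread[0]).sum(axis=0)
            assert np.allclose(torque_spread, torque_m, atol=1e-10)

    def test_degenerate_geometry_rejected(self, ff):
        pos = np.array([[[0.0, 0, 0], [0.1, 0, 0], [-0.1, 0, 0]]])  # collinear
        with pytest.raises(ValueError):
            md.place_virtual_site(pos, ff.geometry.d_OM)


class TestComputeForces:
    def test_two_distant_molecules_no_interaction(self, ff):
        topo, state = gas_state(ff, n=2, seed=3)
        state.pos[1] += 50.0  # far apart
        cfg = md.MDConfig(dispersion_tail=False)
        _, rep = md.compute_forces(state, topo, cfg)
        # gas mode has no cutoff, so only the negligible 50 nm Coulomb tail remains
        assert abs(rep.u_potential) < 1e-4

    def test_forces_match_finite_differences(self, ff, topo8, dense_state):
        state, cfg = dense_state
        f, _ = md.compute_forces(state, topo8, cfg)
        h = 1e-6
        rng = np.random.default_rng(42)
        for _ in range(12):  # random subset of coordinates
            m, s, d = rng.integers(8), rng.integers(3), rng.integers(3)
            sp, sm = state.copy(), state.copy()
            sp.pos[m, s, d] += h
            sm.pos[m, s, d] -= h
            _, rp = md.compute_forces(sp, topo8, cfg)
            _, rm = md.compute_forces(sm, topo8, cfg)
            fd = -(rp.u_potential - rm.u_potential) / (2 * h)
            assert fd == pytest.approx(f[m, s, d], rel=1e-5, abs=1e-4)

    def test_vdw_zero_at_sigma(self, ff):
        # charges off: only the vdW term remains, which vanishes at 2 r_vdw
        ff0 = build_forcefield(
            {
                "geometry": {"r_OH": 0.0962, "theta_HOH": 105.4, "d_OM": 0.0225},
                "charges": {"q_H": 0.0, "q_M": 0.0},
                "vdw": {"r_vdw": 0.1605, "c6_au": 43.44, "c8_au": 1201.3},
                "pol": {"alpha_iso": 1.05e-3},
            }
        )
        topo, state = gas_state(ff0, n=2, seed=5)
        state.pos[1] = state.pos[0] + np.array([ff0.vdw.sigma, 0.0, 0.0])
        cfg = md.MDConfig(dispersion_tail=False)
        _, rep = md.compute_forces(state, topo, cfg)
        assert rep.u_vdw == pytest.approx(0.0, abs=1e-12)

    def test_net_force_zero_on_periodic_system(self, topo8, dense_state):
        state, cfg = dense_state
        f, _ = md.compute_forces(state, topo8, cfg)
        assert np.all(np.abs(f.sum(axis=(0, 1))) < 1e-8)


class TestScf:
    def test_isolated_molecule_zero_field(self, ff):
        topo, state = gas_state(ff)
        cfg = md.MDConfig()
        it, u_self = md.scf_cos(state, topo, cfg)
        assert np.allclose(state.cos_disp, 0.0)
        assert u_self == 0.0

    def test_uniform_field_closed_form(self, ff):
        topo, state = gas_state(ff)
        e_z = 10.0
        cfg = md.MDConfig(e_field_z=e_z, scf_tol=1e-12)
        md.scf_cos(state, topo, cfg)
        mu_ind = ff.pol.q_COS * state.cos_disp[0]
        assert mu_ind[2] == pytest.approx(ff.pol.alpha_iso * e_z / F_ELEC, rel=1e-10)
        # self-polarization energy: alpha E^2 / (2 f_elec)
        _, u_self = md.scf_cos(state, topo, cfg)
        assert u_self == pytest.approx(0.5 * ff.pol.alpha_iso * e_z**2 / F_ELEC, rel=1e-10)

    def test_two_molecule_fixed_point_matches_linear_solve(self, ff):
        topo, state = gas_state(ff, n=2, seed=5)
        state.pos[1] = state.pos[0] + np.array([0.35, 0.1, 0.05])
        cfg = md.MDConfig(scf_tol=1e-12, dispersion_tail=False)
        md.scf_cos(state, topo, cfg)
        d_scf = state.cos_disp.copy()

        # oracle: build the coupled linear response system numerically
        def field(dflat):
            s = state.copy()
            s.cos_disp = dflat.reshape(2, 3)
            return md._field_at_m(s, topo, cfg).ravel()

        e0 = field(np.zeros(6))
        m = np.zeros((6, 6))
        h = 1e-8
        for k in range(6):
            dv = np.zeros(6)
            dv[k] = h
            m[:, k] = (field(dv) - e0) / h
        c = ff.pol.alpha_iso / (F_ELEC * ff.pol.q_COS)
        d_direct = np.linalg.solve(np.eye(6) - c * m, c * e0)
        assert np.all(np.abs(d_scf.ravel() - d_direct) < 1e-8)

    def test_nonconvergence_raises(self, ff):
        topo, state = gas_state(ff, n=2, seed=5)
        state.pos[1] = state.pos[0] + np.array([0.3, 0.0, 0.0])
        cfg = md.MDConfig(scf_tol=1e-30, scf_max_iter=1, dispersion_tail=False)
        with pytest.raises(RuntimeError, match="SCF"):
            md.scf_cos(state, topo, cfg)


class TestIntegrator:
    def test_zero_forces_zero_velocities_no_motion(self, ff):
        topo, state = gas_state(ff)
        before = state.pos.copy()
        md.leapfrog_step(state, np.zeros_like(state.pos), topo, md.MDConfig())
        assert np.allclose(state.pos, before)

    def test_constraints_hold_after_step(self, ff, topo8, dense_state):
        state, cfg = dense_state
        state = state.copy()
        md.assign_velocities(state, topo8, 300.0, seed=2)
        f, _ = md.compute_forces(state, topo8, cfg)
        md.leapfrog_step(state, f, topo8, cfg)
        for a, b, dref in topo8.constraints:
            r = np.linalg.norm(state.pos[:, a] - state.pos[:, b], axis=1)
            assert np.all(np.abs(r / dref - 1.0) <= 1e-4)

    def test_free_flight_rigid_linear_com(self, ff):
        # analytic oracle: with no forces the COM moves linearly, geometry rigid
        topo, state = gas_state(ff)
        v = np.array([0.1, -0.2, 0.05])
        state.vel[:] = v  # pure translation
        cfg = md.MDConfig(thermostat=False)
        com0 = md._molecule_com(state.pos, topo.masses)[0]
        traj = md.run_simulation(topo, cfg, 100, state, sample_stride=100)
        com1 = md._molecule_com(state.pos, topo.masses)[0]
        assert np.allclose(com1 - com0, v * state.time, atol=1e-10)
        r01 = np.linalg.norm(state.pos[0, 0] - state.pos[0, 1])
        assert r01 == pytest.approx(ff.geometry.r_OH, rel=1e-6)

    def test_momentum_conserved_without_thermostat(self, ff, topo8, dense_state):
        state, _ = dense_state
        state = state.copy()
        md.assign_velocities(state, topo8, 300.0, seed=3)
        cfg = md.MDConfig(thermostat=False, barostat=False, dispersion_tail=False)
        m = topo8.masses[None, :, None]
        p0 = (state.vel * m).sum(axis=(0, 1))
        md.run_simulation(topo8, cfg, 50, state, sample_stride=50)
        p1 = (state.vel * m).sum(axis=(0, 1))
        assert np.allclose(p0, p1, atol=1e-9)


class TestCouplingBaths:
    def test_unity_factors_at_targets(self):
        assert md.berendsen_thermostat_factor(300.0, 300.0, 0.1, 0.002) == 1.0
        assert md.berendsen_barostat_factor(1.01325, 1.01325, 0.5, 0.002, 4.5e-5) == 1.0

    def test_hot_start_decays_with_tau(self, ff):
        # closed-form oracle: with no forces, T obeys dT/dt = (T0 - T)/tau
        topo, state = gas_state(ff, n=4, seed=8)
        for i in range(4):
            state.pos[i] += np.array([200.0 * i, 0.0, 0.0])  # non-interacting
        rng = np.random.default_rng(1)
        state.vel[:] = rng.normal(size=(4, 1, 3)) * 0.3  # rigid translation only
        t0 = md.temperature(state.vel, topo)
        cfg = md.MDConfig(temperature=t0 / 2.0, tau_t=0.1, thermostat=True)
        traj = md.run_simulation(topo, cfg, 150, state, sample_stride=1)
        t = np.array(traj.temperature)
        assert np.all(np.diff(t) <= 1e-9)  # monotone decay
        expected = cfg.temperature + (t0 - cfg.temperature) * np.exp(
            -np.array(traj.time) / cfg.tau_t
        )
        assert np.allclose(t, expected, rtol=0.05)

    def test_volume_constant_without_barostat(self, ff, topo8, dense_state):
        state, _ = dense_state
        state = state.copy()
        md.assign_velocities(state, topo8, 300.0, seed=4)
        cfg = md.MDConfig(thermostat=True, barostat=False)
        v0 = state.box**3
        md.run_simulation(topo8, cfg, 20, state, sample_stride=20)
        assert state.box**3 == v0


class TestEngineModelConsistency:
    def test_single_molecule_gas_no_field_zero_potential(self, ff):
        topo, state = gas_state(ff)
        cfg = md.MDConfig(thermostat=False)
        traj = md.run_simulation(topo, cfg, 10, state, sample_stride=1)
        assert np.allclose(traj.u_potential, 0.0, atol=1e-12)

    def test_total_dipole_vector_sum_in_field(self, ff):
        # closed form: |mu| = sqrt(mu_s^2 + 2 mu_s mu_i cos(theta) + mu_i^2)
        # for a static dipole at angle theta to the field axis
        topo, state = gas_state(ff)
        e_z = 50.0
        cfg = md.MDConfig(e_field_z=e_z, scf_tol=1e-12)
        md.scf_cos(state, topo, cfg)
        _, rep = md.compute_forces(state, topo, cfg)
        mu_s_vec = md._molecular_dipoles(
            md.SystemState(state.pos, state.vel, np.zeros((1, 3)), state.box, pbc=False), ff
        )[0]
        mu_s = np.linalg.norm(mu_s_vec)
        mu_i = ff.pol.alpha_iso * e_z / F_ELEC
        cos_t = mu_s_vec[2] / mu_s
        expected = np.sqrt(mu_s**2 + 2 * mu_s * mu_i * cos_t + mu_i**2)
        from coswater.constants import DEBYE_E_NM

        assert rep.mean_dipole == pytest.approx(expected / DEBYE_E_NM, rel=1e-9)

    def test_selfpol_energy_two_routes(self, ff, topo8, dense_state):
        # spring accumulator vs f_elec sum(mu_ind^2)/(2 alpha)
        state, cfg = dense_state
        state = state.copy()
        md.scf_cos(state, topo8, cfg)
        _, rep = md.compute_forces(state, topo8, cfg)
        mu_ind = ff.pol.q_COS * state.cos_disp
        expected = F_ELEC * (mu_ind**2).sum() / (2.0 * ff.pol.alpha_iso)
        assert rep.u_selfpol == pytest.approx(expected, rel=1e-12)

    def test_induced_dipole_matches_alpha_times_field(self, ff):
        # weak uniform field: mu_induced = alpha E / f_elec after dynamics
        topo, state = gas_state(ff)
        e_z = 2.0
        cfg = md.MDConfig(e_field_z=e_z, thermostat=False, scf_tol=1e-10)
        md.run_simulation(topo, cfg, 20, state, sample_stride=20)
        mu_ind_z = ff.pol.q_COS * state.cos_disp[0, 2]
        assert mu_ind_z == pytest.approx(ff.pol.alpha_iso * e_z / F_ELEC, rel=1e-8)
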