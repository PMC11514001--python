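"""Potential assembly, force consistency, optimisation, dynamics and scans."""

import numpy as np
import pytest

import dimergpr as dg
from dimergpr.engine import (
    MASSES,
    OraclePotential,
    ThermostatSettings,
    kinetic_temperature,
    maxwell_boltzmann_velocities,
)
from dimergpr.oracle import hydrogen_bonded_guess

from conftest import random_rigid_motion


def _fd4_forces(potential, g, h=3e-4):
    """4th-order central finite-difference force oracle."""
    out = np.zeros((6, 3))
    for i in range(6):
        for c in range(3):
            es = []
            for m in (2, 1, -1, -2):
                p = g.positions.copy()
                p[i, c] += m * h
                es.append(potential.total_energy(dg.DimerGeometry(p)))
            out[i, c] = -(-es[0] + 8 * es[1] - 8 * es[2] + es[3]) / (12 * h)
    return out


class TestDimerPotential:
    def test_requires_six_models_covering_all_atoms(self, small_potential):
        with pytest.raises(ValueError, match="six"):
            dg.DimerPotential(small_potential.atomic_models[:5])
        with pytest.raises(ValueError, match="cover"):
            dg.DimerPotential(small_potential.atomic_models[:5]
                              + (small_potential.atomic_models[0],))

    def test_total_is_exact_sum_of_atomic_predictions(self, small_potential,
                                                      small_labeled):
        g = small_labeled[300].geometry
        atomic = small_potential.atomic_energies(g)
        assert small_potential.total_energy(g) == pytest.approx(
            float(atomic.sum()), abs=1e-12)

    def test_energy_invariant_forces_equivariant_under_rigid_motion(
            self, small_potential, small_labeled, rng):
        g = small_labeled[301].geometry
        e0 = small_potential.total_energy(g)
        f0 = small_potential.forces(g)
        for _ in range(25):
            R, t = random_rigid_motion(rng)
            moved = g.transformed(R, t)
            assert abs(small_potential.total_energy(moved) - e0) < 1e-8
            assert np.abs(small_potential.forces(moved) - f0 @ R.T).max() < 1e-8

    def test_interpolates_training_total_at_training_point(self, small_potential,
                                                           small_labeled):
        lg = small_labeled[0]  # a training geometry
        pred = small_potential.total_energy(lg.geometry)
        assert pred == pytest.approx(lg.total_energy, abs=0.5)


class TestForces:
    def test_forces_match_finite_difference_gradient(self, small_potential,
                                                     small_labeled):
        # the single most important consistency check: the chain rule
        # through all six feature Jacobians against a numerical gradient
        for lg in small_labeled[300:315]:
            F = small_potential.forces(lg.geometry)
            fd = _fd4_forces(small_potential, lg.geometry)
            assert np.abs(F - fd).max() < 1e-5

    def test_net_force_and_torque_vanish(self, small_potential, small_labeled):
        for lg in small_labeled[300:320]:
            F = small_potential.forces(lg.geometry)
            assert np.abs(F.sum(0)).max() < 1e-8
            pos = lg.geometry.positions
            torque = np.cross(pos - pos.mean(0), F).sum(0)
            assert np.abs(torque).max() < 1e-8


class TestOptimization:
    def test_zero_steps_at_stationary_point(self, oracle_spec, surrogate_minimum):
        g_min, _ = surrogate_minimum
        res = dg.optimize_geometry(OraclePotential(oracle_spec), g_min, fmax=1.0)
        assert res.converged and res.n_steps == 0

    def test_damped_descent_reaches_surrogate_minimum(self, oracle_spec,
                                                      surrogate_minimum):
        g_min, e_min = surrogate_minimum
        start = hydrogen_bonded_guess(5.0, oracle_spec)
        res = dg.optimize_geometry(OraclePotential(oracle_spec), start,
                                   fmax=0.05, max_steps=30000)
        assert res.converged
        assert dg.kabsch_rmsd(dg.StructurePair(g_min, res.final_geometry)) <= 0.1
        assert res.energy_trace[-1] == pytest.approx(e_min, abs=4.184)

    def test_doubling_step_limit_leaves_converged_result_unchanged(
            self, oracle_spec):
        start = hydrogen_bonded_guess(3.4, oracle_spec)
        pot = OraclePotential(oracle_spec)
        r1 = dg.optimize_geometry(pot, start, fmax=0.5, max_steps=15000)
        r2 = dg.optimize_geometry(pot, start, fmax=0.5, max_steps=30000)
        assert r1.converged
        np.testing.assert_array_equal(r1.final_geometry.positions,
                                      r2.final_geometry.positions)

    def test_lbfgs_mode_agrees_with_damped_mode(self, oracle_spec,
                                                surrogate_minimum):
        g_min, e_min = surrogate_minimum
        start = hydrogen_bonded_guess(3.2, oracle_spec)
        res = dg.optimize_geometry(OraclePotential(oracle_spec), start,
                                   fmax=0.05, method="lbfgs")
        assert res.converged
        assert res.energy_trace[-1] == pytest.approx(e_min, abs=0.5)


class TestNVT:
    def test_free_flight_when_potential_is_flat(self):
        class Flat:
            def total_energy(self, g):
                return 1.5

            def forces(self, g):
                return np.zeros((6, 3))

        start = hydrogen_bonded_guess(3.0)
        v0 = maxwell_boltzmann_velocities(200.0, np.random.default_rng(1))
        traj = dg.run_nvt(Flat(), start, temperature=200.0, dt=1.0, n_steps=50,
                          thermostat=ThermostatSettings(enabled=False),
                          initial_velocities=v0)
        # velocities constant, positions linear in time
        np.testing.assert_allclose(traj.frames[-1].velocities, v0, atol=1e-12)
        np.testing.assert_allclose(traj.frames[-1].positions,
                                   start.positions + 50.0 * v0, atol=1e-9)

    def test_energy_conservation_without_thermostat(self, oracle_spec,
                                                    surrogate_minimum):
        # symplectic check with exact analytic forces: the secular trend of
        # E_pot + E_kin stays tiny; the bounded oscillation scales as dt^2
        g_min, _ = surrogate_minimum
        traj = dg.run_nvt(OraclePotential(oracle_spec), g_min, temperature=298.0,
                          dt=0.5, n_steps=10000,
                          thermostat=ThermostatSettings(enabled=False),
                          seed=5, sample_every=10)
        assert traj.energy_drift() < 0.1

    def test_thermostat_holds_target_temperature(self, oracle_spec,
                                                 surrogate_minimum):
        g_min, _ = surrogate_minimum
        traj = dg.run_nvt(OraclePotential(oracle_spec), g_min, temperature=298.0,
                          dt=1.0, n_steps=10000, seed=6, sample_every=10)
        mean_t = traj.temperatures[len(traj.frames) // 5:].mean()
        assert abs(mean_t - 298.0) / 298.0 < 0.10

    def test_reproducible_from_seed(self, oracle_spec, surrogate_minimum):
        g_min, _ = surrogate_minimum
        kw = dict(temperature=298.0, dt=1.0, n_steps=50, seed=12)
        t1 = dg.run_nvt(OraclePotential(oracle_spec), g_min, **kw)
        t2 = dg.run_nvt(OraclePotential(oracle_spec), g_min, **kw)
        np.testing.assert_array_equal(t1.frames[-1].positions,
                                      t2.frames[-1].positions)

    def test_initial_velocities_have_no_drift_and_exact_temperature(self):
        rng = np.random.default_rng(0)
        v = maxwell_boltzmann_velocities(298.0, rng)
        assert np.abs((MASSES[:, None] * v).sum(0)).max() < 1e-12
        assert kinetic_temperature(v) == pytest.approx(298.0, rel=1e-12)

    def test_scalar_log_and_xyz_outputs(self, tmp_path, oracle_spec,
                                        surrogate_minimum):
        g_min, _ = surrogate_minimum
        traj = dg.run_nvt(OraclePotential(oracle_spec), g_min, n_steps=5, seed=1)
        traj.write_xyz(tmp_path / "t.xyz")
        traj.write_scalars(tmp_path / "t.tsv")
        assert len(dg.read_xyz(tmp_path / "t.xyz")) == len(traj)
        lines = (tmp_path / "t.tsv").read_text().splitlines()
        assert lines[0].split("\t") == ["time_fs", "energy_kj_mol", "temperature_k"]
        assert len(lines) == len(traj) + 1


class TestScan:
    def test_single_point_profile_equals_total_energy(self, oracle_spec,
                                                      surrogate_minimum):
        g_min, e_min = surrogate_minimum
        pot = OraclePotential(oracle_spec)
        r0 = dg.min_separation(g_min, "OO")
        prof = dg.scan_coordinate(pot, g_min, r0, r0)
        assert len(prof.distances) == 1
        assert prof.energies[0] == pytest.approx(e_min, abs=1e-9)

    def test_scan_moves_only_molecule_b_along_axis(self, oracle_spec,
                                                   surrogate_minimum):
        g_min, _ = surrogate_minimum
        pot = OraclePotential(oracle_spec)
        prof = dg.scan_coordinate(pot, g_min, 2.4, 5.0, 0.2,
                                  reference=OraclePotential(oracle_spec))
        np.testing.assert_allclose(prof.energies, prof.reference_energies)
        assert prof.distances[0] == pytest.approx(2.4)
        assert np.all(np.diff(prof.distances) > 0)

    def test_contact_guard(self, oracle_spec, surrogate_minimum):
        g_min, _ = surrogate_minimum
        with pytest.raises(ValueError, match="contact"):
            dg.scan_coordinate(OraclePotential(oracle_spec), g_min, 0.8, 1.2, 0.2)
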