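"""Minimization, Langevin/NVE integration and the weak-coupling barostat."""

import numpy as np
import pytest

from lipobrush import engine
from lipobrush.dynamics import (
    Integrator, IntegratorConfig, MinimizerConfig, init_velocities,
    kinetic_energy, minimize, run, step_langevin, step_nve, temperature,
)
from lipobrush.system import SimState
from lipobrush.units import FORCE_TO_ACC, KB

from conftest import make_topology


class TestMinimizer:
    def test_already_minimal_dimer(self, tables):
        top = make_topology(2, bonds=[(0, 1, 5.212, 7.17)])
        state = SimState.from_positions(
            [[10.0, 10, 10], [15.212, 10, 10]], [60.0, 60, 60])
        out, report = minimize(state, top, tables)
        assert report.iterations <= 2
        assert np.allclose(out.positions, state.positions, atol=1e-12)

    def test_stretched_dimer_converges_to_r0(self, tables):
        r0 = 5.212
        top = make_topology(2, bonds=[(0, 1, r0, 7.17)])
        state = SimState.from_positions(
            [[10.0, 10, 10], [10.0 + r0 + 1.0, 10, 10]], [60.0, 60, 60])
        out, report = minimize(
            state, top, tables, MinimizerConfig(e_stop=1e-14, f_stop=1e-10))
        r = np.linalg.norm(out.positions[1] - out.positions[0])
        assert abs(r - r0) < 1e-3
        assert report.final_energy <= report.initial_energy

    def test_lj_cluster_monotone_descent(self, tables):
        rng = np.random.default_rng(3)
        n = 100
        top = make_topology(n)  # neutral C1 beads
        state = SimState.from_positions(rng.uniform(0, 30, (n, 3)) + 10,
                                        [70.0, 70, 70])
        out, report = minimize(state, top, tables,
                               MinimizerConfig(max_iter=300))
        trace = np.array(report.energy_trace)
        assert (np.diff(trace) <= 1e-9).all()
        assert report.final_energy < report.initial_energy

    def test_overlap_at_entry_aborts(self, tables):
        top = make_topology(2)
        state = SimState.from_positions(
            [[10.0, 10, 10], [10.0 + 1e-9, 10, 10]], [60.0, 60, 60])
        with pytest.raises(RuntimeError,
                           match="non-finite|overlap|unusable"):
            minimize(state, top, tables)


class TestLangevin:
    def test_zero_temperature_friction_decay(self, tables):
        """Free particle at T = 0: speed decays by exp(-dt/damp) per step."""
        top = make_topology(1)
        state = SimState.from_positions([[30.0, 30, 30]], [60.0, 60, 60])
        v0 = 0.01
        state.velocities[0] = [v0, 0, 0]
        cfg = IntegratorConfig(dt=10.0, t_target=0.0, damp=100.0, seed=1)
        step_langevin(state, top, tables, cfg, n_steps=5)
        expected = v0 * np.exp(-5 * 10.0 / 100.0)
        assert state.velocities[0, 0] == pytest.approx(expected, rel=1e-12)

    def test_temperature_recovery_and_maxwell_speeds(self, tables):
        """Ideal Langevin gas equilibrates to 300 K with MB speeds."""
        from scipy import stats

        n = 300
        top = make_topology(n)
        rng = np.random.default_rng(5)
        # dilute enough that interactions are negligible
        state = SimState.from_positions(rng.uniform(0, 400, (n, 3)),
                                        [400.0, 400.0, 400.0])
        cfg = IntegratorConfig(dt=10.0, t_target=300.0, damp=100.0, seed=9)
        it = Integrator(top, tables, cfg, thermostat=True)
        temps = []
        vsq = []
        for k in range(400):
            it.step(state)
            if k >= 100:
                temps.append(temperature(state, top))
                vsq.append((state.velocities**2).sum(axis=1).copy())
        t_mean = np.mean(temps)
        assert abs(t_mean - 300.0) / 300.0 < 0.03
        # chi-square on speed-squared against the 3-dof gamma distribution
        v2 = np.concatenate(vsq[::50])
        scale = KB * 300.0 * FORCE_TO_ACC / 72.0  # kT/m in (A/fs)^2
        q = np.quantile(v2 / scale, np.linspace(0.1, 0.9, 9))
        ref = stats.chi2.ppf(np.linspace(0.1, 0.9, 9), df=3)
        assert np.abs(q - ref).max() / ref.max() < 0.1

    def test_same_seed_identical_trajectories(self, tables, random_cluster):
        top, state = random_cluster
        cfg = IntegratorConfig(seed=42)
        s1 = state.copy()
        s2 = state.copy()
        step_langevin(s1, top, tables, cfg, n_steps=20)
        step_langevin(s2, top, tables, cfg, n_steps=20)
        assert np.array_equal(s1.positions, s2.positions)
        assert np.array_equal(s1.velocities, s2.velocities)


class TestNVE:
    def test_isolated_bead_straight_line(self, tables):
        top = make_topology(1)
        state = SimState.from_positions([[5.0, 5, 5]], [100.0, 100, 100])
        state.velocities[0] = [1e-3, 2e-3, 0.0]
        step_nve(state, top, tables, IntegratorConfig(dt=10.0), n_steps=50)
        assert state.unwrapped()[0] == pytest.approx(
            [5.0 + 1e-3 * 500, 5.0 + 2e-3 * 500, 5.0], rel=1e-12)

    def test_harmonic_dimer_period(self, tables):
        """Oscillation period matches 2 pi sqrt(mu / (2 Kb)) within 0.1%."""
        kb, r0, m = 7.17, 5.212, 72.0
        top = make_topology(2, bonds=[(0, 1, r0, kb)])
        state = SimState.from_positions(
            [[30.0, 30, 30], [30.0 + r0 + 0.2, 30, 30]], [80.0, 80, 80])
        mu = m / 2.0
        # V = Kb dr^2 -> omega^2 = 2 Kb / mu (with unit conversion)
        omega = np.sqrt(2 * kb * FORCE_TO_ACC / mu)
        period = 2 * np.pi / omega
        cfg = IntegratorConfig(dt=1.0)
        it = Integrator(top, tables, cfg, thermostat=False)
        seps = []
        n_steps = int(3 * period)
        for _ in range(n_steps):
            it.step(state)
            seps.append(np.linalg.norm(state.positions[1] -
                                       state.positions[0]))
        seps = np.array(seps) - r0
        # measure the period from zero crossings of the elongation
        crossings = np.flatnonzero(np.diff(np.sign(seps)) != 0)
        measured = 2 * np.mean(np.diff(crossings))
        assert abs(measured - period) / period < 1e-3

    def test_energy_conservation_membrane_patch(self, tables):
        """|dE| / <KE> stays below 1e-4 over 10^4 NVE steps at dt = 10 fs
        on an equilibrated bilayer patch."""
        from lipobrush.builder import BuildConfig, build_system
        from lipobrush.dynamics import step_langevin

        cfg = BuildConfig(nx=3, ny=3, x_p=0.0, n_p=45, gap=3.0,
                          outer_gap=2.0, water_mode="implicit", seed=55)
        top, state = build_system(cfg, tables)
        state, _ = minimize(state, top, tables,
                            MinimizerConfig(max_iter=300))
        rng = np.random.default_rng(56)
        init_velocities(state, top, 300.0, rng)
        step_langevin(state, top, tables,
                      IntegratorConfig(dt=10.0, seed=57), n_steps=2000)
        it = Integrator(top, tables, IntegratorConfig(dt=10.0),
                        thermostat=False)
        e0 = it.engine.compute(state)[0].total + kinetic_energy(state, top)
        kes = []
        for _ in range(10_000):
            it.step(state)
            kes.append(kinetic_energy(state, top))
        e1 = it.engine.compute(state)[0].total + kinetic_energy(state, top)
        assert abs(e1 - e0) / np.mean(kes) < 1e-4

    def test_momentum_conserved_to_machine_precision(self, tables,
                                                     random_cluster):
        top, state = random_cluster
        rng = np.random.default_rng(23)
        init_velocities(state, top, 300.0, rng)
        p0 = (top.mass[:, None] * state.velocities).sum(axis=0)
        step_nve(state, top, tables, IntegratorConfig(dt=5.0), n_steps=200)
        p1 = (top.mass[:, None] * state.velocities).sum(axis=0)
        assert np.abs(p1 - p0).max() < 1e-12

    def test_time_reversibility(self, tables, random_cluster):
        """Forward n steps, negate velocities, forward n steps returns the
        start to 1e-8 A (velocity Verlet is symplectic/time-reversible)."""
        top, state = random_cluster
        rng = np.random.default_rng(29)
        init_velocities(state, top, 200.0, rng)
        start = state.unwrapped().copy()
        cfg = IntegratorConfig(dt=2.0)
        step_nve(state, top, tables, cfg, n_steps=50)
        state.velocities *= -1.0
        step_nve(state, top, tables, cfg, n_steps=50)
        assert np.abs(state.unwrapped() - start).max() < 1e-8


class TestBarostat:
    def test_no_rescale_at_target_pressure(self, tables):
        """An ideal gas prepared exactly at P = NkT/V stays unscaled in the
        mean (mu fluctuates only with the kinetic pressure noise)."""
        n = 200
        top = make_topology(n)
        rng = np.random.default_rng(31)
        # choose V such that NkT/V = 1 atm exactly, beads non-interacting
        from lipobrush.units import PRESS_TO_ATM

        vol = n * KB * 300.0 / (1.0 / PRESS_TO_ATM)
        lbox = vol ** (1.0 / 3.0)
        state = SimState.from_positions(rng.uniform(0, lbox, (n, 3)),
                                        [lbox] * 3)
        cfg = IntegratorConfig(dt=10.0, barostat_mode="isotropic", seed=37)
        it = Integrator(top, tables, cfg, thermostat=True, barostat=True)
        v0 = state.volume()
        for _ in range(300):
            it.step(state)
        assert abs(state.volume() / v0 - 1.0) < 0.05

    def test_ideal_gas_expands_toward_target(self, tables):
        """2x over-compressed ideal gas expands monotonically toward the
        PV = NkT volume."""
        n = 200
        top = make_topology(n)
        rng = np.random.default_rng(41)
        from lipobrush.units import PRESS_TO_ATM

        v_eq = n * KB * 300.0 / (1.0 / PRESS_TO_ATM)
        lbox = (v_eq / 2.0) ** (1.0 / 3.0)  # half the equilibrium volume
        state = SimState.from_positions(rng.uniform(0, lbox, (n, 3)),
                                        [lbox] * 3)
        cfg = IntegratorConfig(dt=10.0, barostat_mode="isotropic", seed=43,
                               max_strain=2e-3)
        it = Integrator(top, tables, cfg, thermostat=True, barostat=True)
        vols = [state.volume()]
        for _ in range(600):
            it.step(state)
            vols.append(state.volume())
        vols = np.array(vols)
        # overwhelmingly expanding, and closer to v_eq than at the start
        assert (np.diff(vols) > 0).mean() > 0.9
        assert abs(vols[-1] - v_eq) < abs(vols[0] - v_eq)

    def test_strain_cap(self, tables):
        n = 20
        top = make_topology(n)
        rng = np.random.default_rng(47)
        state = SimState.from_positions(rng.uniform(0, 20, (n, 3)),
                                        [20.0, 20, 20])
        cfg = IntegratorConfig(dt=10.0, barostat_mode="isotropic", seed=51)
        it = Integrator(top, tables, cfg, thermostat=True, barostat=True)
        for _ in range(20):
            b0 = state.box.copy()
            it.step(state)
            assert np.abs(state.box / b0 - 1.0).max() <= cfg.max_strain + 1e-12


class TestRunProtocol:
    def test_zero_steps_single_frame(self, tables, random_cluster):
        top, state = random_cluster
        _, traj = run(state, top, tables, "nvt_production", 0,
                      dump_every=10, cfg=IntegratorConfig(seed=3))
        assert len(traj) == 1

    def test_thermo_log_length(self, tables, random_cluster):
        top, state = random_cluster
        _, traj = run(state, top, tables, "nvt_production", 100,
                      dump_every=20, cfg=IntegratorConfig(seed=3))
        assert len(traj.thermo) == 1 + 100 // 20
        table = traj.thermo_table()
        for col in ("time", "T", "P", "E_pot", "E_kin", "Lx", "Lz"):
            assert col in table.columns

    def test_unknown_protocol_rejected(self, tables, random_cluster):
        top, state = random_cluster
        with pytest.raises(ValueError, match="unknown protocol"):
            run(state, top, tables, "npt_vacuum", 10)
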