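"""Total energy, analytic forces and neighbor-list consistency."""

import numpy as np
import pytest

from lipobrush import engine
from lipobrush._kernels import brute_pair_list
from lipobrush.system import ANGLE_COS2, ANGLE_HARMONIC, SimState

from conftest import make_topology


def rotation_matrix(axis, angle):
    axis = np.asarray(axis, dtype=float)
    axis /= np.linalg.norm(axis)
    a = np.cos(angle / 2)
    b, c, d = -axis * np.sin(angle / 2)
    return np.array([
        [a*a+b*b-c*c-d*d, 2*(b*c+a*d), 2*(b*d-a*c)],
        [2*(b*c-a*d), a*a+c*c-b*b-d*d, 2*(c*d+a*b)],
        [2*(b*d+a*c), 2*(c*d-a*b), a*a+d*d-b*b-c*c],
    ])


class TestForcesMatchGradients:
    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_random_cluster_forces(self, tables, seed):
        """Analytic forces equal central finite differences for random
        configurations exercising every term type."""
        from lipobrush.builder import _Assembler, build_chitosan

        rng = np.random.default_rng(seed)
        tpl = build_chitosan(4, 1.0, tables)
        asm = _Assembler(tables)
        coords = tpl.coords + rng.normal(0.0, 0.4, size=tpl.coords.shape)
        asm.add_molecule(tpl, coords + 20.0, "chitosan")
        for _ in range(4):
            asm.add_bead("Cl", -1.0, rng.uniform(14.0, 40.0, 3), "ion")
        top, state = asm.finish(np.array([55.0, 55.0, 60.0]))
        f = engine.forces(state, top, tables)
        fn = engine.numerical_forces(state, top, tables)
        scale = np.abs(fn).max()
        assert np.abs(f - fn).max() / scale < 1e-5

    @pytest.mark.parametrize("style,theta0,k", [
        (ANGLE_COS2, np.radians(120.0), 5.97),
        (ANGLE_HARMONIC, np.radians(123.76), 107.553),
    ])
    def test_angle_term_gradient(self, tables, style, theta0, k):
        rng = np.random.default_rng(11)
        top = make_topology(3, angles=[(0, 1, 2, style, theta0, k)])
        state = SimState.from_positions(rng.uniform(20, 30, (3, 3)),
                                        [50.0, 50.0, 50.0])
        f = engine.forces(state, top, tables)
        fn = engine.numerical_forces(state, top, tables)
        assert np.abs(f - fn).max() / max(np.abs(fn).max(), 1e-12) < 1e-5

    def test_dihedral_gradient(self, tables):
        rng = np.random.default_rng(13)
        top = make_topology(
            4, dihedrals=[(0, 1, 2, 3, np.radians(-28.59), 2.39006, 3)]
        )
        state = SimState.from_positions(rng.uniform(20, 28, (4, 3)),
                                        [50.0, 50.0, 50.0])
        f = engine.forces(state, top, tables)
        fn = engine.numerical_forces(state, top, tables)
        assert np.abs(f - fn).max() / np.abs(fn).max() < 1e-5

    def test_bonded_dimer_harmonic_gradient(self, tables):
        kb, r0, delta = 2.98, 4.7, 0.6
        top = make_topology(2, bonds=[(0, 1, r0, kb)])
        pos = np.array([[20.0, 20, 20], [20.0 + r0 + delta, 20, 20]])
        state = SimState.from_positions(pos, [60.0, 60, 60])
        f = engine.forces(state, top, tables)
        # V = Kb (r - r0)^2 -> |F| = 2 Kb delta, equal and opposite
        assert f[0, 0] == pytest.approx(2 * kb * delta)
        assert np.allclose(f[0], -f[1])

    def test_isolated_bead_zero_force(self, tables):
        top = make_topology(1)
        state = SimState.from_positions([[10.0, 10, 10]], [40.0, 40, 40])
        assert np.allclose(engine.forces(state, top, tables), 0.0)


class TestEnergyInvariance:
    def test_translation_and_rotation_invariance(self, tables,
                                                 random_cluster):
        top, state = random_cluster
        big = np.array([200.0, 200.0, 200.0])  # avoid periodic images
        pos = state.positions.copy()
        e0 = engine.total_energy(
            SimState.from_positions(pos + 40.0, big), top, tables).total
        e_tr = engine.total_energy(
            SimState.from_positions(pos + 53.7, big), top, tables).total
        rot = rotation_matrix([1.0, 2.0, 0.5], 1.1)
        center = pos.mean(axis=0)
        pos_rot = (pos - center) @ rot.T + 90.0
        e_rot = engine.total_energy(
            SimState.from_positions(pos_rot, big), top, tables).total
        assert e_tr == pytest.approx(e0, rel=1e-10)
        assert e_rot == pytest.approx(e0, rel=1e-8)

    def test_two_neutral_beads_beyond_cutoff(self, tables):
        top = make_topology(2)  # two C1 beads
        state = SimState.from_positions(
            [[10.0, 10, 10], [35.0, 10, 10]], [60.0, 60, 60])
        assert engine.total_energy(state, top, tables).total == 0.0

    def test_bonded_dimer_at_r0_excluded_from_pairs(self, tables):
        """Bonded (1-2) neighbors contribute no LJ/Coulomb energy."""
        top = make_topology(2, bonds=[(0, 1, 5.212, 7.17)])
        state = SimState.from_positions(
            [[10.0, 10, 10], [15.212, 10, 10]], [60.0, 60, 60])
        bd = engine.total_energy(state, top, tables)
        assert bd.bond == pytest.approx(0.0, abs=1e-20)
        assert bd.lj == 0.0 and bd.coulomb == 0.0

    def test_matches_brute_force_all_pairs(self, tables):
        """Cell-list energies (energy-shift style) equal a direct O(N^2)
        double-loop sum over minimum images."""
        rng = np.random.default_rng(21)
        n = 60
        species = rng.integers(0, 9, n)
        charges = np.array(
            [tables.species[name].charge
             for name in np.array(
                 ["Q0", "Qa", "Na", "C1", "MW", "R1", "R2", "R3p", "Cl"]
             )[species]], dtype=float)
        charges -= charges.mean()  # neutrality for topology validation
        top = make_topology(n, species=species, charges=charges)
        # dense box so that the cell path is exercised
        state = SimState.from_positions(rng.uniform(0, 42, (n, 3)),
                                        [42.0, 42.0, 42.0])
        eng = engine.ForceEngine(top, tables, pair_style="shift")
        bd, _, _ = eng.compute(state)
        # independent oracle: explicit double loop over minimum images
        sig, eps = tables.pair_matrices()
        rc = tables.cutoff
        sc6 = (sig / rc) ** 6
        shift = 4 * eps * (sc6**2 - sc6)
        e_lj = e_c = 0.0
        box = state.box
        for i in range(n):
            for j in range(i + 1, n):
                d = state.positions[i] - state.positions[j]
                d -= np.rint(d / box) * box
                r = np.linalg.norm(d)
                if r >= rc:
                    continue
                s6 = (sig[species[i], species[j]] / r) ** 6
                e_lj += (4 * eps[species[i], species[j]] * (s6**2 - s6)
                         - shift[species[i], species[j]])
                qq = charges[i] * charges[j]
                if qq:
                    c = 332.06371 / 15.0 * qq
                    e_c += c * (1 / r - 1 / rc + (r - rc) / rc**2)
        assert bd.lj == pytest.approx(e_lj, rel=1e-10)
        assert bd.coulomb == pytest.approx(e_c, rel=1e-10)

    def test_switch_style_tail_behavior(self, tables):
        """Force-switched nonbonded: energy and force vanish at the
        cutoff, and the plain 12-6 force acts below the inner radius."""
        top = make_topology(2)
        eng = engine.ForceEngine(top, tables, pair_style="switch")
        sig = tables.pair("C1", "C1").sigma
        eps = tables.pair("C1", "C1").epsilon

        def at(r):
            state = SimState.from_positions(
                [[10.0, 25, 25], [10.0 + r, 25, 25]], [60.0, 60, 60])
            bd, f, _ = eng.compute(state)
            return bd.lj, f[0, 0]

        e_rc, f_rc = at(eng.cutoff - 1e-7)
        assert abs(e_rc) < 1e-10 and abs(f_rc) < 1e-10
        # below r_inner the force equals the unmodified LJ force
        r = 6.0
        _, f6 = at(r)
        s6 = (sig / r) ** 6
        f_exact = 24 * eps * (2 * s6**2 - s6) / r
        assert f6 == pytest.approx(-f_exact, rel=1e-12)

    def test_cell_list_equals_brute_list(self, tables, random_cluster):
        top, state = random_cluster
        from lipobrush._kernels import build_pair_list

        excl = top.exclusions()
        bi, bj = brute_pair_list(state.positions, state.box, 14.0, excl)
        ci, cj = build_pair_list(state.positions, state.box, 14.0, excl)
        brute = {(int(a), int(b)) for a, b in zip(bi, bj)}
        cell = {tuple(sorted((int(a), int(b)))) for a, b in zip(ci, cj)}
        assert brute == cell


class TestExclusions:
    def test_lipid_chain_excludes_bonded_neighbors_only(self, tables):
        top = make_topology(3, bonds=[(0, 1, 4.7, 2.98), (1, 2, 4.7, 2.98)])
        excl = top.exclusions()
        assert set(excl[0]) - {-1} == {1}
        assert set(excl[1]) - {-1} == {0, 2}

    def test_chitosan_excludes_second_neighbors(self, tables,
                                                random_cluster):
        """Within a chitosan chain 1-3 pairs are excluded: the printed
        side-bead geometry sits inside the LJ core."""
        top, _ = random_cluster
        excl = top.exclusions()
        # bead 0 = R2 of unit 0: bonded to R1(0)=1, R3(0)=2, R2(1)=3 and
        # 1-3 coupled to R1(1)=4, R3(1)=5, R2(2)=6
        assert {1, 2, 3, 4, 5, 6} <= set(excl[0]) - {-1}

    def test_overlap_detection(self, tables):
        top = make_topology(2)
        state = SimState.from_positions(
            [[10.0, 10, 10], [11.0, 10, 10]], [60.0, 60, 60])
        eng = engine.ForceEngine(top, tables)
        with pytest.raises(engine.OverlapError):
            eng.compute(state, check_overlap=True)
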