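"""Total energy/force evaluation over a system with neighbor lists.

The :class:`ForceEngine` binds a topology to the parameter tables, keeps a
Verlet pair list (cell-binned, 2 A skin) and evaluates all interaction
terms.  ``total_energy``/``forces`` are the functional entry points used in
tests and scripts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _kernels
from .forcefield import SPECIES_ORDER, ForceFieldTables
from .system import ANGLE_COS2, SimState, Topology
from .units import COULOMB


class OverlapError(RuntimeError):
    """Two nonbonded beads closer than the hard-core threshold."""


@dataclass
class EnergyBreakdown:
    lj: float
    coulomb: float
    bond: float
    angle: float
    dihedral: float

    @property
    def total(self) -> float:
        return self.lj + self.coulomb + self.bond + self.angle + self.dihedral

    def as_dict(self) -> dict:
        return {
            "E_lj": self.lj, "E_coul": self.coulomb, "E_bond": self.bond,
            "E_angle": self.angle, "E_dihedral": self.dihedral,
            "E_pot": self.total,
        }


class ForceEngine:
    """Evaluates energies, forces and the diagonal virial for one system."""

    def __init__(
        self,
        topology: Topology,
        tables: ForceFieldTables,
        skin: float = 2.0,
        pair_style: str = "switch",
        r_inner: float = 9.0,
    ):
        """``pair_style`` selects the nonbonded tail treatment:

        * ``"switch"`` (default): GROMACS-style force switching, LJ from
          ``r_inner`` to the cutoff and Coulomb from zero - the convention
          Martini membrane simulations use, which this model's printed
          parameters were tuned against;
        * ``"shift"``: plain energy-shifted LJ with shifted-force Coulomb.
        """
        if pair_style not in ("switch", "shift"):
            raise ValueError("pair_style must be 'switch' or 'shift'")
        self.top = topology
        self.tables = tables
        self.cutoff = tables.cutoff
        self.skin = skin
        self.pair_style = pair_style
        self.r_inner = r_inner
        self.ke_over_eps = COULOMB / tables.dielectric

        sig, eps = tables.pair_matrices()
        self.sigma_mat = sig
        self.eps_mat = eps
        sc6 = (sig / self.cutoff) ** 6
        self.eshift_mat = 4.0 * eps * (sc6 * sc6 - sc6)
        self.c12_mat = 4.0 * eps * sig**12
        self.c6_mat = 4.0 * eps * sig**6
        self.excl = topology.exclusions()
        self.types = topology.species.astype(np.int64)
        self.charges = topology.charge.astype(np.float64)

        self._pairs: tuple[np.ndarray, np.ndarray] | None = None
        self._ref_box: np.ndarray | None = None

    # -- neighbor list ----------------------------------------------------
    def _needs_rebuild(self, state: SimState) -> bool:
        if self._pairs is None:
            return True
        # barostat rescales are affine: scale the reference accordingly so
        # only genuine bead motion counts toward the skin criterion
        scale = state.box / self._ref_box
        disp = state.unwrapped() - self._ref_unwrapped * scale
        # minimum-image so boundary wrapping does not register as a jump
        disp -= np.rint(disp / state.box) * state.box
        max_disp = float(np.abs(disp).max()) if len(disp) else 0.0
        # shrinking boxes tighten distances; spend part of the skin on that
        shrink = float((1.0 - scale.min()) * state.box.max())
        return max_disp + max(shrink, 0.0) > 0.5 * self.skin

    def _rebuild(self, state: SimState) -> None:
        state.wrap()
        ii, jj = _kernels.build_pair_list(
            state.positions, state.box, self.cutoff + self.skin, self.excl
        )
        self._pairs = (ii, jj)
        self._ref_unwrapped = state.unwrapped().copy()
        self._ref_box = state.box.copy()

    def n_pairs(self) -> int:
        return 0 if self._pairs is None else len(self._pairs[0])

    # -- evaluation -------------------------------------------------------
    def compute(
        self, state: SimState, check_overlap: bool = False,
        overlap_frac: float = 0.7,
    ) -> tuple[EnergyBreakdown, np.ndarray, np.ndarray]:
        """Energies, forces (N,3) and diagonal virial (3,) for ``state``.

        With ``check_overlap`` the evaluation raises :class:`OverlapError`
        when any nonbonded pair sits below ``overlap_frac`` of the smallest
        LJ diameter."""
        if self._needs_rebuild(state):
            self._rebuild(state)
        top = self.top
        forces = np.zeros_like(state.positions)
        virial = np.zeros(3)
        ii, jj = self._pairs
        if self.pair_style == "switch":
            e_lj, e_c, min_r2 = _kernels.pair_energy_forces_switch(
                state.positions, state.box, ii, jj, self.types,
                self.c12_mat, self.c6_mat, self.charges, self.ke_over_eps,
                self.r_inner, self.cutoff, forces, virial,
            )
        else:
            e_lj, e_c, min_r2 = _kernels.pair_energy_forces(
                state.positions, state.box, ii, jj, self.types,
                self.sigma_mat, self.eps_mat, self.eshift_mat,
                self.charges, self.ke_over_eps, self.cutoff, forces, virial,
            )
        if check_overlap and len(ii):
            rmin = overlap_frac * float(self.sigma_mat.min())
            if min_r2 < rmin * rmin:
                raise OverlapError(
                    f"nonbonded beads at r = {np.sqrt(min_r2):.3f} A "
                    f"(< {overlap_frac} sigma = {rmin:.3f} A)"
                )
        e_b = _kernels.bond_energy_forces(
            state.positions, state.box, top.bonds, top.bond_r0, top.bond_k,
            forces, virial,
        ) if len(top.bonds) else 0.0
        e_a = _kernels.angle_energy_forces(
            state.positions, state.box, top.angles, top.angle_style,
            top.angle_theta0, top.angle_k, forces, virial,
        ) if len(top.angles) else 0.0
        e_d = _kernels.dihedral_energy_forces(
            state.positions, state.box, top.dihedrals, top.dihedral_phi0,
            top.dihedral_k, top.dihedral_n, forces, virial,
        ) if len(top.dihedrals) else 0.0
        return EnergyBreakdown(e_lj, e_c, e_b, e_a, e_d), forces, virial


def total_energy(
    state: SimState, topology: Topology, tables: ForceFieldTables
) -> EnergyBreakdown:
    """Per-term potential-energy breakdown of a configuration."""
    eng = ForceEngine(topology, tables)
    breakdown, _, _ = eng.compute(state)
    return breakdown


def forces(
    state: SimState, topology: Topology, tables: ForceFieldTables
) -> np.ndarray:
    """Analytic forces, kcal/(mol A), one row per bead."""
    eng = ForceEngine(topology, tables)
    _, f, _ = eng.compute(state)
    return f


def numerical_forces(
    state: SimState, topology: Topology, tables: ForceFieldTables,
    h: float = 1.0e-4,
) -> np.ndarray:
    """Central finite differences of the total energy (test oracle)."""
    eng = ForceEngine(topology, tables)
    f = np.zeros_like(state.positions)
    s = state.copy()
    for i in range(state.n_beads):
        for a in range(3):
            orig = s.positions[i, a]
            s.positions[i, a] = orig + h
            ep = eng.compute(s)[0].total
            s.positions[i, a] = orig - h
            em = eng.compute(s)[0].total
            s.positions[i, a] = orig
            f[i, a] = -(ep - em) / (2.0 * h)
    return f
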