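"""Shared fixtures: parameter tables, small assembled systems and helpers."""

from __future__ import annotations

import numpy as np
import pytest

from lipobrush.builder import _Assembler, build_chitosan
from lipobrush.forcefield import load_tables
from lipobrush.system import ANGLE_COS2, ANGLE_HARMONIC, SimState, Topology


@pytest.fixture(scope="session")
def tables():
    return load_tables()


def make_topology(
    n: int,
    bonds=(),
    angles=(),
    dihedrals=(),
    charges=None,
    species=None,
    mass: float = 72.0,
) -> Topology:
    """Minimal topology from explicit term lists (test helper).

    ``bonds``: (i, j, r0, Kb); ``angles``: (i, j, k, style, theta0_rad, K);
    ``dihedrals``: (i, j, k, l, phi0_rad, K, n).
    """
    return Topology(
        species=(np.full(n, 3, dtype=np.int64) if species is None
                 else np.asarray(species, dtype=np.int64)),
        charge=(np.zeros(n) if charges is None
                else np.asarray(charges, dtype=float)),
        mass=np.full(n, mass),
        mol_id=np.zeros(n, dtype=np.int64),
        group=np.zeros(n, dtype=np.int64),
        leaflet=np.full(n, -1, dtype=np.int64),
        bonds=np.array([b[:2] for b in bonds], dtype=np.int64).reshape(-1, 2),
        bond_r0=np.array([b[2] for b in bonds], dtype=float),
        bond_k=np.array([b[3] for b in bonds], dtype=float),
        angles=np.array([a[:3] for a in angles], dtype=np.int64
                        ).reshape(-1, 3),
        angle_style=np.array([a[3] for a in angles], dtype=np.int64),
        angle_theta0=np.array([a[4] for a in angles], dtype=float),
        angle_k=np.array([a[5] for a in angles], dtype=float),
        dihedrals=np.array([d[:4] for d in dihedrals], dtype=np.int64
                           ).reshape(-1, 4),
        dihedral_phi0=np.array([d[4] for d in dihedrals], dtype=float),
        dihedral_k=np.array([d[5] for d in dihedrals], dtype=float),
        dihedral_n=np.array([d[6] for d in dihedrals], dtype=np.int64),
    )


@pytest.fixture()
def random_cluster(tables):
    """A small chitosan fragment plus ions: every term type is exercised."""
    rng = np.random.default_rng(7)
    tpl = build_chitosan(5, 1.0, tables)
    asm = _Assembler(tables)
    coords = tpl.coords + rng.normal(0.0, 0.35, size=tpl.coords.shape)
    asm.add_molecule(tpl, coords + 20.0, "chitosan")
    for _ in range(5):
        asm.add_bead("Cl", -1.0, rng.uniform(12.0, 40.0, 3), "ion")
    return asm.finish(np.array([55.0, 55.0, 60.0]))
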