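"""Construction of opposed DPPC bilayers with grafted chitosan chains.

The builder emulates the production geometry of the study at configurable
desk scale: two flat bilayers normal to z, their facing ("inner") leaflets
decorated with DPPC-chitosan lipo-polyelectrolytes at grafting molar
fraction ``X_p``, one Cl- counterion per protonated chitosan unit placed in
the inter-membrane gap, and optional explicit coarse-grained water (MW
beads, 4:1 mapping).  Lipids start on a jittered lattice at the configured
area per lipid (0.49 nm^2 by default); chains start roughly extended along
the membrane normal with small random kinks and fold back when they would
leave the gap.  Everything is deterministic under a fixed seed.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial import cKDTree

from .forcefield import SPECIES_INDEX, ForceFieldTables, load_tables
from .system import ANGLE_COS2, ANGLE_HARMONIC, GROUPS, SimState, Topology

#: bulk coarse-grained water density, one 4:1 MW bead per 0.12 nm^3
WATER_VOL_A3 = 120.0

#: the printed bond/angle constants follow the GROMACS convention
#: V = (K/2) x^2, the native form of the parameter set this model descends
#: from; assembled systems therefore carry K/2 against the plain K x^2
#: kernels.  (The scalar term-energy helpers evaluate the printed form.)
BONDED_PREFACTOR = 0.5


@dataclass
class BuildConfig:
    """Parameters of one opposed-bilayer build."""

    nx: int = 15                    # lipid grid, x
    ny: int = 14                    # lipid grid, y
    x_p: float = 0.005              # grafting molar fraction
    n_p: int = 45                   # degree of polymerization
    area_per_lipid: float = 0.49    # nm^2 (initial)
    gap: float = 8.0                # nm between the opposed head planes
    outer_gap: float = 2.0          # nm across the periodic boundary
    water_mode: str = "implicit"    # "explicit" | "shell" | "implicit"
    shell_thickness: float = 1.2    # nm, hydration slab ("shell" mode)
    protonated_fraction: float = 1.0
    graft_both_leaflets: bool = False  # also graft the outer leaflets
    seed: int = 2025

    def __post_init__(self) -> None:
        if not 0.0 <= self.x_p <= 1.0:
            raise ValueError("x_p must be in [0, 1]")
        if self.n_p < 1:
            raise ValueError("n_p must be >= 1")
        if self.water_mode not in ("explicit", "shell", "implicit"):
            raise ValueError(
                "water_mode must be 'explicit', 'shell' or 'implicit'"
            )
        if not 0.0 <= self.protonated_fraction <= 1.0:
            raise ValueError("protonated_fraction must be in [0, 1]")

    @property
    def lipids_per_leaflet(self) -> int:
        return self.nx * self.ny

    @property
    def chains_per_leaflet(self) -> int:
        return int(round(self.x_p * self.lipids_per_leaflet))


@dataclass
class MoleculeTemplate:
    """One molecule: ordered species, internal terms, canonical coordinates."""

    name: str
    species: list[str]
    charges: list[float]
    coords: np.ndarray                      # (n, 3) A, canonical orientation
    bonds: list[tuple[int, int, float, float]]             # i, j, r0, Kb
    angles: list[tuple[int, int, int, int, float, float]]  # i,j,k, style, th0(rad), K
    dihedrals: list[tuple[int, int, int, int, float, float, int]]

    @property
    def n_beads(self) -> int:
        return len(self.species)


def build_dppc(tables: ForceFieldTables | None = None) -> MoleculeTemplate:
    """12-bead DPPC: choline Q0, phosphate Qa, two glycerol Na, two 4-bead
    C1 tails.  Canonical coordinates put the head bead at the origin with
    tails extending toward -z."""
    t = tables or load_tables()
    # bead order: Q0, Qa, GL1, GL2, tail A (4 x C1), tail B (4 x C1)
    species = ["Q0", "Qa", "Na", "Na"] + ["C1"] * 8
    charges = [1.0, -1.0] + [0.0] * 10
    coords = np.array([
        [0.0, 0.0, 0.0],      # Q0
        [0.0, 0.0, -4.5],     # Qa
        [0.0, 0.0, -8.5],     # GL1
        [2.6, 2.6, -8.5],     # GL2
        [0.0, 0.0, -12.5], [0.0, 0.0, -16.5],
        [0.0, 0.0, -20.5], [0.0, 0.0, -24.5],
        [2.6, 2.6, -12.5], [2.6, 2.6, -16.5],
        [2.6, 2.6, -20.5], [2.6, 2.6, -24.5],
    ])
    bond_pairs = [
        (0, 1, "Q0", "Qa"), (1, 2, "Qa", "Na"), (2, 3, "Na", "Na"),
        (2, 4, "Na", "C1"), (4, 5, "C1", "C1"), (5, 6, "C1", "C1"),
        (6, 7, "C1", "C1"),
        (3, 8, "Na", "C1"), (8, 9, "C1", "C1"), (9, 10, "C1", "C1"),
        (10, 11, "C1", "C1"),
    ]
    bonds = []
    for i, j, a, b in bond_pairs:
        bt = t.bond(a, b)
        bonds.append((i, j, bt.r0, BONDED_PREFACTOR * bt.Kb))
    angle_triplets = [
        (1, 2, 3, "Qa", "Na", "Na"),
        (2, 4, 5, "Na", "C1", "C1"), (3, 8, 9, "Na", "C1", "C1"),
        (4, 5, 6, "C1", "C1", "C1"), (5, 6, 7, "C1", "C1", "C1"),
        (8, 9, 10, "C1", "C1", "C1"), (9, 10, 11, "C1", "C1", "C1"),
    ]
    angles = []
    for i, j, k, a, b, c in angle_triplets:
        at = t.angle(a, b, c)
        angles.append((i, j, k, ANGLE_COS2, math.radians(at.theta0),
                       BONDED_PREFACTOR * at.Ka1))
    return MoleculeTemplate(
        "DPPC", species, charges, coords, bonds, angles, []
    )


def build_chitosan(
    n_p: int,
    protonated_fraction: float = 1.0,
    tables: ForceFieldTables | None = None,
    rng: np.random.Generator | None = None,
) -> MoleculeTemplate:
    """Chitosan chain of ``n_p`` repeat units (R1, R2, R3+ per unit).

    The R2 beads form the backbone (n_p - 1 R2-R2 links); R1 and R3+ hang
    off each backbone bead.  At ionization fraction f < 1, a deterministic
    (or rng-chosen) subset of round(f*n_p) units keeps the +1 charge; the
    rest keep R3+ nonbonded parameters but zero charge.  Canonical
    coordinates extend the backbone along +z.
    """
    if n_p < 1:
        raise ValueError("n_p must be >= 1")
    t = tables or load_tables()
    species: list[str] = []
    charges: list[float] = []
    coords = np.zeros((3 * n_p, 3))
    n_charged = int(round(protonated_fraction * n_p))
    if rng is None:
        charged_units = set(range(n_charged))
    else:
        charged_units = set(
            rng.choice(n_p, size=n_charged, replace=False).tolist()
        )
    golden = math.radians(137.507764)
    bb = t.bond("R2", "R2")
    b_r1 = t.bond("R1", "R2")
    b_r3 = t.bond("R2", "R3p")
    for u in range(n_p):
        psi = golden * u
        e1 = np.array([math.cos(psi), math.sin(psi), 0.0])
        zb = bb.r0 * u
        species += ["R2", "R1", "R3p"]
        charges += [0.0, 0.0, 1.0 if u in charged_units else 0.0]
        coords[3 * u] = [0.0, 0.0, zb]
        coords[3 * u + 1] = np.array([0.0, 0.0, zb]) + b_r1.r0 * e1
        coords[3 * u + 2] = np.array([0.0, 0.0, zb]) - b_r3.r0 * e1
    bonds = []
    for u in range(n_p):
        bonds.append((3 * u, 3 * u + 1, b_r1.r0,
                      BONDED_PREFACTOR * b_r1.Kb))
        bonds.append((3 * u, 3 * u + 2, b_r3.r0,
                      BONDED_PREFACTOR * b_r3.Kb))
        if u + 1 < n_p:
            bonds.append((3 * u, 3 * (u + 1), bb.r0,
                          BONDED_PREFACTOR * bb.Kb))

    def harm(labels):
        at = t.angle(*labels)
        return ANGLE_HARMONIC, math.radians(at.theta0), BONDED_PREFACTOR * at.Ka2

    angles = []
    for u in range(n_p):
        st, th, k = harm([("R1", 0), ("R2", 0), ("R3p", 0)])
        angles.append((3 * u + 1, 3 * u, 3 * u + 2, st, th, k))
        if u + 1 < n_p:
            st, th, k = harm([("R2", 0), ("R2", 1), ("R1", 1)])
            angles.append((3 * u, 3 * (u + 1), 3 * (u + 1) + 1, st, th, k))
            st, th, k = harm([("R1", 0), ("R2", 0), ("R2", 1)])
            angles.append((3 * u + 1, 3 * u, 3 * (u + 1), st, th, k))
            st, th, k = harm([("R3p", 0), ("R2", 0), ("R2", 1)])
            angles.append((3 * u + 2, 3 * u, 3 * (u + 1), st, th, k))
            st, th, k = harm([("R3p", 1), ("R2", 1), ("R2", 0)])
            angles.append((3 * (u + 1) + 2, 3 * (u + 1), 3 * u, st, th, k))
        if u + 2 < n_p:
            st, th, k = harm([("R2", 0), ("R2", 1), ("R2", 2)])
            angles.append((3 * u, 3 * (u + 1), 3 * (u + 2), st, th, k))
    dihedrals = []
    for u in range(n_p - 1):
        for quad, idx in (
            ((("R1", 0), ("R2", 0), ("R2", 1), ("R1", 1)),
             (3 * u + 1, 3 * u, 3 * (u + 1), 3 * (u + 1) + 1)),
            ((("R1", 0), ("R2", 0), ("R2", 1), ("R3p", 1)),
             (3 * u + 1, 3 * u, 3 * (u + 1), 3 * (u + 1) + 2)),
            ((("R3p", 0), ("R2", 0), ("R2", 1), ("R1", 1)),
             (3 * u + 2, 3 * u, 3 * (u + 1), 3 * (u + 1) + 1)),
        ):
            dt = t.dihedral(*quad)
            dihedrals.append(
                (*idx, math.radians(dt.phi0), dt.Ki, dt.ni)
            )
    return MoleculeTemplate(
        f"chitosan{n_p}", species, charges, coords, bonds, angles, dihedrals
    )


# -------------------------------------------------------------------------
# system assembly
# -------------------------------------------------------------------------

class _Assembler:
    """Accumulates molecules into flat topology arrays."""

    def __init__(self, tables: ForceFieldTables):
        self.tables = tables
        self.species: list[int] = []
        self.charge: list[float] = []
        self.mass: list[float] = []
        self.mol_id: list[int] = []
        self.group: list[int] = []
        self.leaflet: list[int] = []
        self.positions: list[np.ndarray] = []
        self.bonds: list[tuple] = []
        self.angles: list[tuple] = []
        self.dihedrals: list[tuple] = []
        self.next_mol = 0

    def add_molecule(
        self, tpl: MoleculeTemplate, coords: np.ndarray, group: str,
        leaflet: int = -1, mol_id: int | None = None,
    ) -> int:
        if mol_id is None:
            mol_id = self.next_mol
            self.next_mol += 1
        off = len(self.species)
        masses = self.tables.masses()
        for s, q in zip(tpl.species, tpl.charges):
            self.species.append(SPECIES_INDEX[s])
            self.charge.append(q)
            self.mass.append(masses[SPECIES_INDEX[s]])
            self.mol_id.append(mol_id)
            self.group.append(GROUPS[group])
            self.leaflet.append(leaflet)
        self.positions.append(np.asarray(coords, dtype=float))
        for i, j, r0, kb in tpl.bonds:
            self.bonds.append((off + i, off + j, r0, kb))
        for i, j, k, st, th, ka in tpl.angles:
            self.angles.append((off + i, off + j, off + k, st, th, ka))
        for i, j, k, l, ph, kd, nd in tpl.dihedrals:
            self.dihedrals.append(
                (off + i, off + j, off + k, off + l, ph, kd, nd)
            )
        return off

    def add_bead(
        self, species: str, charge: float, pos, group: str
    ) -> int:
        off = len(self.species)
        idx = SPECIES_INDEX[species]
        self.species.append(idx)
        self.charge.append(charge)
        self.mass.append(self.tables.masses()[idx])
        self.mol_id.append(self.next_mol)
        self.next_mol += 1
        self.group.append(GROUPS[group])
        self.leaflet.append(-1)
        self.positions.append(np.asarray(pos, dtype=float).reshape(1, 3))
        return off

    def add_bond(self, i: int, j: int, r0: float, kb: float) -> None:
        self.bonds.append((i, j, r0, kb))

    def finish(self, box: np.ndarray) -> tuple[Topology, SimState]:
        pos = np.vstack(self.positions) if self.positions else np.zeros((0, 3))
        bonds = np.array([(i, j) for i, j, *_ in self.bonds], dtype=np.int64
                         ).reshape(-1, 2)
        top = Topology(
            species=np.array(self.species, dtype=np.int64),
            charge=np.array(self.charge),
            mass=np.array(self.mass),
            mol_id=np.array(self.mol_id, dtype=np.int64),
            group=np.array(self.group, dtype=np.int64),
            leaflet=np.array(self.leaflet, dtype=np.int64),
            bonds=bonds,
            bond_r0=np.array([b[2] for b in self.bonds]),
            bond_k=np.array([b[3] for b in self.bonds]),
            angles=np.array([a[:3] for a in self.angles], dtype=np.int64
                            ).reshape(-1, 3),
            angle_style=np.array([a[3] for a in self.angles], dtype=np.int64),
            angle_theta0=np.array([a[4] for a in self.angles]),
            angle_k=np.array([a[5] for a in self.angles]),
            dihedrals=np.array([d[:4] for d in self.dihedrals], dtype=np.int64
                               ).reshape(-1, 4),
            dihedral_phi0=np.array([d[4] for d in self.dihedrals]),
            dihedral_k=np.array([d[5] for d in self.dihedrals]),
            dihedral_n=np.array([d[6] for d in self.dihedrals], dtype=np.int64),
        )
        top.validate()
        state = SimState.from_positions(pos, box)
        return top, state


def _chain_backbone_walk(
    start: np.ndarray, direction: float, n_p: int, zlo: float, zhi: float,
    spacing: float, rng: np.random.Generator,
    avoid: np.ndarray | None = None,
    box: np.ndarray | None = None,
) -> np.ndarray:
    """Backbone bead positions: mostly-straight walk along the membrane
    normal with small random kinks, folding back at the gap margins.

    Candidate beads keep 8.5 A from non-adjacent beads of the same chain
    and 8.0 A from previously placed chains (``avoid``) so that the side
    beads, which extend up to 2.5 A laterally, stay clear of the hard-core
    overlap threshold."""
    pts = np.zeros((n_p, 3))
    p = start.copy()
    d = direction
    pts[0] = p

    def clearance(c: np.ndarray, u: int) -> float:
        out = np.inf
        if u >= 3:
            out = min(out, float(
                np.min(np.linalg.norm(pts[: u - 2] - c, axis=1))
            ))
        if avoid is not None and len(avoid):
            d = avoid - c
            if box is not None:
                d -= np.rint(d / box) * box
            out = min(out, 0.5 + float(np.min(np.linalg.norm(d, axis=1))))
        return out

    turn_left = 0       # remaining steps of a hairpin turn
    turn_dir = np.zeros(2)
    for u in range(1, n_p):
        if turn_left > 0:
            # arc turn: rotate the step from +-z to -+z in 45 deg increments
            # (keeps every step length = spacing, i.e. the bond length)
            k = 4 - turn_left
            theta = math.radians(45.0 * (k + 1))
            step = spacing * np.array([
                turn_dir[0] * math.sin(theta), turn_dir[1] * math.sin(theta),
                d * math.cos(theta),
            ])
            turn_left -= 1
            if turn_left == 0:
                d = -d
            p = p + step
            p[2] = min(max(p[2], zlo - 2.0), zhi + 2.0)
            pts[u] = p
            continue
        best, best_score = None, -np.inf
        for _ in range(120):
            lat = rng.normal(0.0, 0.8, size=2)
            dz = d * math.sqrt(max(spacing**2 - lat @ lat, 1.0))
            cand = p + np.array([lat[0], lat[1], dz])
            if not zlo <= cand[2] <= zhi:
                # start a smooth hairpin: 4 arc steps back into the gap
                turn_left = 4
                turn_dir = rng.normal(0.0, 1.0, size=2)
                turn_dir /= max(np.linalg.norm(turn_dir), 1e-9)
                theta = math.radians(45.0)
                cand = p + spacing * np.array([
                    turn_dir[0] * math.sin(theta),
                    turn_dir[1] * math.sin(theta),
                    d * math.cos(theta),
                ])
                turn_left -= 1
                best, best_score = cand, 0.0
                break
            score = clearance(cand, u)
            if score > best_score:
                best, best_score = cand, score
            if score >= 9.0:
                break
        p = best
        pts[u] = p
    return pts


def _place_chain(
    tpl: MoleculeTemplate, graft_point: np.ndarray, direction: float,
    zlo: float, zhi: float, rng: np.random.Generator,
    avoid: np.ndarray | None = None,
    box: np.ndarray | None = None,
) -> np.ndarray:
    n_p = tpl.n_beads // 3
    spacing = 5.212
    start = graft_point + np.array([0.0, 0.0, direction * 5.0])
    bb = _chain_backbone_walk(start, direction, n_p, zlo, zhi, spacing, rng,
                              avoid, box)
    coords = np.zeros((3 * n_p, 3))
    golden = math.radians(137.507764)
    phase = rng.uniform(0.0, 2.0 * math.pi)
    for u in range(n_p):
        psi = golden * u + phase
        e1 = np.array([math.cos(psi), math.sin(psi), 0.0])
        coords[3 * u] = bb[u]
        coords[3 * u + 1] = bb[u] + 2.494 * e1
        coords[3 * u + 2] = bb[u] - 1.934 * e1
    return coords


def build_system(
    config: BuildConfig, tables: ForceFieldTables | None = None
) -> tuple[Topology, SimState]:
    """Assemble the opposed-bilayer system described by ``config``.

    Layout along z (angstrom): outer_gap/2 | bilayer 1 | gap | bilayer 2 |
    outer_gap/2, periodic.  Leaflets are numbered 0 (bottom, outer), 1
    (inner), 2 (inner), 3 (top, outer); chains are grafted on the facing
    leaflets 1 and 2 (and 0/3 too when ``graft_both_leaflets``).
    """
    t = tables or load_tables()
    rng = np.random.default_rng(config.seed)
    asm = _Assembler(t)

    a_l = config.area_per_lipid * 100.0  # A^2
    pitch = math.sqrt(a_l)
    lx = config.nx * pitch
    ly = config.ny * pitch
    gap = config.gap * 10.0
    outer = config.outer_gap * 10.0
    half_bilayer = 26.5  # head plane to tail-end plane of one leaflet
    bilayer_thick = 2 * half_bilayer
    lz = 2 * bilayer_thick + gap + outer
    box = np.array([lx, ly, lz])

    zc1 = outer / 2.0 + half_bilayer            # bilayer-1 center
    zc2 = zc1 + bilayer_thick + gap             # bilayer-2 center
    gap_zlo = zc1 + half_bilayer                # inner head plane, bilayer 1
    gap_zhi = zc2 - half_bilayer

    dppc = build_dppc(t)
    n_leaf = config.lipids_per_leaflet
    n_chains = config.chains_per_leaflet
    if config.x_p > 0 and n_chains == 0:
        warnings.warn(
            f"X_p = {config.x_p} rounds to zero chains for "
            f"{n_leaf} lipids per leaflet; need at least "
            f"{math.ceil(0.5 / config.x_p)} lipids per leaflet",
            stacklevel=2,
        )

    # leaflet -> (bilayer center, head-plane sign)
    leaf_geometry = {
        0: (zc1, -1.0), 1: (zc1, +1.0), 2: (zc2, -1.0), 3: (zc2, +1.0),
    }
    grafted_leaflets = [1, 2] if not config.graft_both_leaflets else [0, 1, 2, 3]
    graft_rows = {
        lf: rng.choice(n_leaf, size=n_chains, replace=False)
        for lf in grafted_leaflets
    }

    head_offsets = {}  # (leaflet, row) -> Q0 position for grafting
    for lf in range(4):
        zc, sgn = leaf_geometry[lf]
        # half-pitch stagger between apposed leaflets
        shift = 0.5 * pitch if lf in (1, 2) else 0.0
        for row in range(n_leaf):
            ix, iy = divmod(row, config.ny)
            x0 = (ix + 0.5) * pitch + shift
            y0 = (iy + 0.5) * pitch + shift
            jitter = rng.uniform(-0.3, 0.3, size=2)
            base = np.array([x0 + jitter[0], y0 + jitter[1],
                             zc + sgn * half_bilayer])
            # canonical tails point -z: keep for the upper leaflet (tails
            # toward the bilayer center), mirror in z for the lower one
            coords = dppc.coords * np.array([1.0, 1.0, sgn])
            coords = coords + base
            asm.add_molecule(dppc, coords, "lipid", leaflet=lf)
            head_offsets[(lf, row)] = base

    # chains + their grafting bonds
    bb = t.bond("R2", "R2")
    chain_tpl = build_chitosan(config.n_p, config.protonated_fraction, t, rng)
    chain_charge = sum(chain_tpl.charges)
    n_ions_total = 0
    chain_beads_so_far: list[np.ndarray] = []
    for lf in grafted_leaflets:
        zc, sgn = leaf_geometry[lf]
        direction = +1.0 if sgn > 0 else -1.0
        if lf in (1, 2):
            zlo, zhi = gap_zlo + 4.0, gap_zhi - 4.0
        else:
            # outer leaflets graft into the periodic outer gap
            zlo, zhi = -1e9, 1e9
        for row in graft_rows[lf]:
            head = head_offsets[(lf, row)]
            avoid = (np.vstack(chain_beads_so_far)
                     if chain_beads_so_far else None)
            coords = _place_chain(chain_tpl, head, direction, zlo, zhi, rng,
                                  avoid, box)
            chain_beads_so_far.append(coords)
            off = asm.add_molecule(chain_tpl, coords, "chitosan")
            # graft: lipid head Q0 to first backbone R2, R2-R2 parameters
            lipid_off = (lf * n_leaf + row) * dppc.n_beads
            asm.add_bond(lipid_off, off, bb.r0, BONDED_PREFACTOR * bb.Kb)
            n_ions_total += int(round(chain_charge))

    # counterions in the inner gap
    placed = np.vstack(asm.positions) if asm.positions else np.zeros((0, 3))
    ion_positions = _scatter_beads(
        n_ions_total, box, gap_zlo + 2.0, gap_zhi - 2.0,
        placed, min_dist=4.0, rng=rng,
    )
    for p in ion_positions:
        asm.add_bead("Cl", -1.0, p, "ion")

    # water at bulk CG density: "explicit" fills both gaps, "shell" lays
    # hydration slabs against each head plane (leaving the chain/ion
    # region between the slabs open so the gap can relax under pressure)
    if config.water_mode != "implicit":
        shell = config.shell_thickness * 10.0
        if config.water_mode == "explicit":
            regions = [(gap_zlo + 1.0, gap_zhi - 1.0)]
        else:
            inner_mid = 0.5 * (gap_zlo + gap_zhi)
            regions = [
                (gap_zlo + 1.0, min(gap_zlo + 1.0 + shell, inner_mid)),
                (max(gap_zhi - 1.0 - shell, inner_mid), gap_zhi - 1.0),
            ]
        # the outer gap (hydrating the outer leaflets) is always filled
        regions.append((zc2 + half_bilayer + 1.0,
                        zc2 + half_bilayer + outer - 1.0))
        placed = np.vstack(asm.positions)
        for zlo, zhi in regions:
            if zhi <= zlo:
                continue
            water = _water_lattice(box, zlo, zhi, placed, rng)
            for p in water:
                asm.add_bead("MW", 0.0, p, "water")
            placed = np.vstack(asm.positions)

    top, state = asm.finish(box)
    _relax_overlaps(top, state, t)
    _check_overlaps(top, state, t)
    return top, state


def _relax_overlaps(
    top: Topology, state: SimState, tables: ForceFieldTables,
    max_iter: int = 400,
) -> None:
    """Push residual hard-core contacts apart before the dynamics stages.

    Chain, ion and water beads closer than 0.7 sigma to any nonbonded
    neighbor are displaced along the pair axis; lipid beads stay on their
    lattice.  Purely geometric (no forces) - the energy minimizer does the
    physical relaxation afterwards."""
    sig, _ = tables.pair_matrices()
    movable = top.group != GROUPS["lipid"]
    excl = top.exclusions()
    thresh_max = 0.7 * sig.max()
    cap = 0.35  # A per bead per sweep, keeps bonded neighbors together

    def bond_project() -> None:
        # pull stretched/compressed bonds back toward r0 (within 10%)
        for _ in range(30):
            d = state.positions[top.bonds[:, 0]] - state.positions[top.bonds[:, 1]]
            d -= np.rint(d / state.box) * state.box
            r = np.linalg.norm(d, axis=1)
            dev = (r - top.bond_r0) / top.bond_r0
            bad = np.abs(dev) > 0.10
            if not bad.any():
                return
            for k in np.flatnonzero(bad):
                i, j = top.bonds[k]
                target = top.bond_r0[k] * (1.08 if dev[k] > 0 else 0.92)
                corr = (r[k] - target) / r[k] * d[k]
                mi, mj = movable[i], movable[j]
                if mi and mj:
                    state.positions[i] -= 0.5 * corr
                    state.positions[j] += 0.5 * corr
                elif mi:
                    state.positions[i] -= corr
                elif mj:
                    state.positions[j] += corr

    for _ in range(max_iter):
        state.wrap()
        tree = cKDTree(state.positions, boxsize=state.box)
        pairs = tree.query_pairs(thresh_max, output_type="ndarray")
        moved = False
        shift = np.zeros_like(state.positions)
        for i, j in pairs:
            if j in excl[i]:
                continue
            lim = 0.7 * sig[top.species[i], top.species[j]]
            d = state.positions[i] - state.positions[j]
            d -= np.rint(d / state.box) * state.box
            r = float(np.linalg.norm(d))
            if r >= lim:
                continue
            if r < 1e-6:
                d = np.array([lim, 0.0, 0.0])
                r = lim
            push = min(lim - r + 0.05, cap) * d / r
            if movable[i] and movable[j]:
                shift[i] += 0.5 * push
                shift[j] -= 0.5 * push
            elif movable[i]:
                shift[i] += push
            elif movable[j]:
                shift[j] -= push
            else:
                continue
            moved = True
        if moved:
            state.positions += shift
        bond_project()
        if not moved:
            return


def _scatter_beads(
    n: int, box: np.ndarray, zlo: float, zhi: float,
    existing: np.ndarray, min_dist: float, rng: np.random.Generator,
) -> np.ndarray:
    """Uniform random placement with a hard minimum distance (rejection),
    periodic in all box dimensions."""
    tree = (cKDTree(np.mod(existing, box), boxsize=box)
            if len(existing) else None)
    pts: list[np.ndarray] = []
    for k in range(n):
        for _ in range(2000):
            cand = np.array([
                rng.uniform(0, box[0]), rng.uniform(0, box[1]),
                rng.uniform(zlo, zhi),
            ])
            if tree is not None:
                if tree.query(cand, k=1)[0] < min_dist:
                    continue
            if pts:
                d = np.array(pts) - cand
                d -= np.rint(d / box) * box
                if np.linalg.norm(d, axis=1).min() < min_dist:
                    continue
            pts.append(cand)
            break
        else:
            raise RuntimeError(
                f"could not place bead {k + 1}/{n} in the gap; "
                "gap too small or too crowded"
            )
    return np.array(pts).reshape(n, 3)


def _water_lattice(
    box: np.ndarray, zlo: float, zhi: float,
    existing: np.ndarray, rng: np.random.Generator,
) -> np.ndarray:
    a = WATER_VOL_A3 ** (1.0 / 3.0)  # 4.93 A
    lx, ly = box[0], box[1]
    nx = max(1, int(lx / a))
    ny = max(1, int(ly / a))
    nz = max(1, int((zhi - zlo) / a))
    xs = (np.arange(nx) + 0.5) * (lx / nx)
    ys = (np.arange(ny) + 0.5) * (ly / ny)
    zs = zlo + (np.arange(nz) + 0.5) * ((zhi - zlo) / nz)
    grid = np.array(np.meshgrid(xs, ys, zs, indexing="ij")).reshape(3, -1).T
    grid = grid + rng.uniform(-0.5, 0.5, size=grid.shape)
    grid = np.mod(grid, box)
    if len(existing):
        tree = cKDTree(np.mod(existing, box), boxsize=box)
        d, _ = tree.query(grid, k=1)
        grid = grid[d > 4.0]
    return grid


def _check_overlaps(
    top: Topology, state: SimState, tables: ForceFieldTables
) -> None:
    """Abort on nonbonded beads closer than 0.7 sigma after placement."""
    sig, _ = tables.pair_matrices()
    thresh = 0.7 * sig.max()
    tree = cKDTree(state.positions, boxsize=state.box)
    pairs = tree.query_pairs(thresh, output_type="ndarray")
    if not len(pairs):
        return
    excl = top.exclusions()
    d = state.positions[pairs[:, 0]] - state.positions[pairs[:, 1]]
    d -= np.rint(d / state.box) * state.box
    dist = np.linalg.norm(d, axis=1)
    for (i, j), r in zip(pairs, dist):
        if j in excl[i]:
            continue
        lim = 0.7 * sig[top.species[i], top.species[j]]
        if r < lim:
            raise RuntimeError(
                f"overlap after placement: beads {i} and {j} at "
                f"r = {r:.3f} A < 0.7 sigma = {lim:.3f} A"
            )


# -------------------------------------------------------------------------
# presets
# -------------------------------------------------------------------------

#: theoretical layer heights (nm) used to size the gaps: a sqrt(n_p) for the
#: mushroom regime, n_p a (a^2 X_p / A_l)^(1/3) for critic/brush at A_l = 0.7
_PRESETS = {
    "mushroom": dict(nx=15, ny=14, x_p=0.005, gap=8.0, seed=20250),
    "critic": dict(nx=15, ny=14, x_p=0.014, gap=9.0, seed=20251),
    "brush": dict(nx=10, ny=10, x_p=0.1, gap=17.0, seed=20252),
}


def scaled_preset(regime: str) -> BuildConfig:
    """Desk-scale build configuration for one grafting regime.

    The grafting fractions are the study conditions (X_p = 0.005 / 0.014 /
    0.1, n_p = 45, initial area per lipid 0.49 nm^2); patch sizes are
    desk-scale stand-ins for the full production system, with the gap sized
    to ~2.5x the theoretical layer height and scaled solvent: hydration
    slabs against every head plane rather than a fully flooded gap, so the
    inter-membrane distance can relax under the barostat.
    """
    if regime not in _PRESETS:
        raise ValueError(f"unknown regime {regime!r}; "
                         f"choose from {sorted(_PRESETS)}")
    p = _PRESETS[regime]
    return BuildConfig(
        nx=p["nx"], ny=p["ny"], x_p=p["x_p"], n_p=45,
        area_per_lipid=0.49, gap=p["gap"], outer_gap=2.0,
        water_mode="shell", seed=p["seed"],
    )
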