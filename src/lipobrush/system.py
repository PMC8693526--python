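"""In-memory containers: topology, simulation state and trajectories.

Everything is stored as flat numpy arrays so the numba kernels can consume
them directly.  Species are encoded as integers over
:data:`lipobrush.forcefield.SPECIES_ORDER`; groups partition the beads into
lipid / chitosan / ion / water.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .forcefield import SPECIES_ORDER, SPECIES_INDEX

GROUPS = {"lipid": 0, "chitosan": 1, "ion": 2, "water": 3}
GROUP_NAMES = {v: k for k, v in GROUPS.items()}

# angle styles in the flat arrays
ANGLE_COS2 = 0
ANGLE_HARMONIC = 1


@dataclass
class Topology:
    """Beads, connectivity and term parameters of one simulated system.

    ``leaflet`` is -1 for non-lipid beads; lipid beads carry the index of
    their leaflet (0, 1 for the lower bilayer; 2, 3 for the upper bilayer;
    odd/even = inner/outer follows the builder's documented layout).
    """

    species: np.ndarray          # (N,) int64, index into SPECIES_ORDER
    charge: np.ndarray           # (N,) float64, e
    mass: np.ndarray             # (N,) float64, Da
    mol_id: np.ndarray           # (N,) int64
    group: np.ndarray            # (N,) int64, GROUPS encoding
    leaflet: np.ndarray          # (N,) int64, -1 for non-lipid

    bonds: np.ndarray            # (NB, 2) int64
    bond_r0: np.ndarray          # (NB,) A
    bond_k: np.ndarray           # (NB,) kcal/(mol A^2)

    angles: np.ndarray           # (NA, 3) int64
    angle_style: np.ndarray      # (NA,) int64
    angle_theta0: np.ndarray     # (NA,) rad
    angle_k: np.ndarray          # (NA,)

    dihedrals: np.ndarray        # (ND, 4) int64
    dihedral_phi0: np.ndarray    # (ND,) rad
    dihedral_k: np.ndarray       # (ND,) kcal/mol
    dihedral_n: np.ndarray       # (ND,) int64

    _excl: np.ndarray | None = field(default=None, repr=False)

    @property
    def n_beads(self) -> int:
        return len(self.species)

    def species_names(self) -> list[str]:
        return [SPECIES_ORDER[i] for i in self.species]

    def group_mask(self, name: str) -> np.ndarray:
        return self.group == GROUPS[name]

    def species_mask(self, name: str) -> np.ndarray:
        return self.species == SPECIES_INDEX[name]

    def total_charge(self) -> float:
        return float(self.charge.sum())

    def validate(self) -> None:
        n = self.n_beads
        for arr, width in ((self.bonds, 2), (self.angles, 3), (self.dihedrals, 4)):
            if len(arr) and (arr.min() < 0 or arr.max() >= n):
                raise ValueError("topology references nonexistent beads")
            if len(arr) and arr.shape[1] != width:
                raise ValueError("malformed term index list")
        if abs(self.total_charge()) > 1e-9:
            raise ValueError(f"system is not neutral: q = {self.total_charge()}")

    def exclusions(self, max_neighbors: int = 16) -> np.ndarray:
        """(N, M) padded array of excluded nonbonded neighbors (-1 pad).

        Directly bonded (1-2) pairs are always excluded, the standard
        convention for this class of coarse-grained model; without the
        second-neighbor LJ the lipid head would fold onto the glycerol
        beads, since no bending term spans the choline.  Within chitosan
        chains second (1-3) neighbors are excluded as well: the printed
        repeat-unit geometry (side-bead bonds of 1.9-2.5 A at the printed
        angles) places 1-3 pairs well inside the LJ core, so they must not
        interact nonbondedly.
        """
        if self._excl is not None:
            return self._excl
        n = self.n_beads
        chito = GROUPS["chitosan"]
        adj: list[set[int]] = [set() for _ in range(n)]
        for i, j in self.bonds:
            adj[i].add(int(j))
            adj[j].add(int(i))
        excl_sets: list[set[int]] = [set(a) for a in adj]
        for i in range(n):
            if self.group[i] != chito:
                continue
            for j in adj[i]:
                for k in adj[j]:
                    if k != i and self.group[k] == chito:
                        excl_sets[i].add(k)
                        excl_sets[k].add(i)
        m = max((len(s) for s in excl_sets), default=1)
        m = max(m, 1)
        if m > max_neighbors:
            raise ValueError(f"exclusion list overflow ({m} neighbors)")
        out = np.full((n, m), -1, dtype=np.int64)
        for i, s in enumerate(excl_sets):
            for k, j in enumerate(sorted(s)):
                out[i, k] = j
        self._excl = out
        return out


@dataclass
class SimState:
    """Positions (wrapped, with image counts), velocities, box and time."""

    positions: np.ndarray   # (N, 3) A, wrapped into [0, L)
    velocities: np.ndarray  # (N, 3) A/fs
    box: np.ndarray         # (3,) A
    images: np.ndarray      # (N, 3) int64 periodic image counts
    time: float = 0.0       # fs

    @classmethod
    def from_positions(cls, positions: np.ndarray, box) -> "SimState":
        pos = np.asarray(positions, dtype=float).copy()
        box = np.asarray(box, dtype=float).copy()
        images = np.floor(pos / box).astype(np.int64)
        pos -= images * box
        return cls(
            positions=pos,
            velocities=np.zeros_like(pos),
            box=box,
            images=images,
            time=0.0,
        )

    @property
    def n_beads(self) -> int:
        return len(self.positions)

    def unwrapped(self) -> np.ndarray:
        return self.positions + self.images * self.box

    def wrap(self) -> None:
        shift = np.floor(self.positions / self.box).astype(np.int64)
        self.positions -= shift * self.box
        self.images += shift

    def copy(self) -> "SimState":
        return SimState(
            self.positions.copy(), self.velocities.copy(),
            self.box.copy(), self.images.copy(), self.time,
        )

    def volume(self) -> float:
        return float(np.prod(self.box))


@dataclass
class Frame:
    """One stored trajectory frame (wrapped coordinates + image counts)."""

    time: float             # fs
    step: int
    box: np.ndarray         # (3,) A
    positions: np.ndarray   # (N, 3) A wrapped
    images: np.ndarray | None  # (N, 3) int or None (unwrap unavailable)
    extras: dict | None = None  # unknown trajectory columns, passed through

    def unwrapped(self) -> np.ndarray:
        if self.images is None:
            raise ValueError(
                "frame carries no image flags: unwrapping required but "
                "unavailable; re-dump with image counts"
            )
        return self.positions + self.images * self.box


@dataclass
class Trajectory:
    """A time-ordered list of frames plus the thermodynamic log."""

    frames: list[Frame] = field(default_factory=list)
    thermo: list[dict] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.frames)

    def __getitem__(self, i: int) -> Frame:
        return self.frames[i]

    def times(self) -> np.ndarray:
        return np.array([f.time for f in self.frames])

    def boxes(self) -> np.ndarray:
        return np.array([f.box for f in self.frames])

    def thermo_table(self):
        import pandas as pd

        return pd.DataFrame(self.thermo)
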