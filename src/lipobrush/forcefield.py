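"""Coarse-grained force field: parameter tables, mixing rules and term energies.

The interaction model is a Martini-style coarse-grained force field:

* nonbonded 12-6 Lennard-Jones, energy-shifted to zero at the cutoff,
* screened Coulomb between the charged beads (Q0+, Qa-, R3p+, Cl-) with a
  uniform relative dielectric of 15, shifted-force tapered at the cutoff,
* harmonic bonds ``V = Kb (r - r0)^2`` (no 1/2 prefactor),
* cosine-squared angles for the lipid and harmonic (radian) angles for the
  chitosan backbone,
* a single-term Fourier dihedral ``V = Ki [1 + cos(ni phi - phi0)]`` for
  chitosan backbone torsions.

All printed parameters live in ``data/martini_chitosan.toml``; every pair of
species without a printed row resolves through Lorentz-Berthelot mixing
(arithmetic sigma, geometric epsilon).  A printed entry always overrides a
mixed one.
"""

from __future__ import annotations

import hashlib
import math
import tomllib
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np

from .units import COULOMB

SPECIES_ORDER: tuple[str, ...] = (
    "Q0", "Qa", "Na", "C1", "MW", "R1", "R2", "R3p", "Cl",
)
SPECIES_INDEX: Mapping[str, int] = {s: i for i, s in enumerate(SPECIES_ORDER)}

#: canonical data file shipped with the package
DEFAULT_TABLE_RESOURCE = "martini_chitosan.toml"

_ALIASES = {"BR0": ("R2", 0), "R3": ("R3p", 0), "Cl-": ("Cl", 0)}


class ForceFieldError(ValueError):
    """Raised for inconsistent or missing force-field entries."""


@dataclass(frozen=True)
class BeadSpecies:
    """A coarse-grained bead type (~4 heavy atoms per bead)."""

    name: str
    mass: float  # Da
    charge: int  # elementary charges

    def __post_init__(self) -> None:
        if self.mass <= 0:
            raise ForceFieldError(f"species {self.name}: mass must be > 0")
        if self.charge not in (-1, 0, 1):
            raise ForceFieldError(
                f"species {self.name}: charge must be -1, 0 or +1"
            )


@dataclass(frozen=True)
class PairCoefficients:
    """Lennard-Jones coefficients for an unordered species pair."""

    species: tuple[str, str]
    sigma: float    # A
    epsilon: float  # kcal/mol
    source: str = "printed"  # "printed" | "mixed"

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ForceFieldError(f"pair {self.species}: sigma must be > 0")
        if self.epsilon < 0:
            raise ForceFieldError(f"pair {self.species}: epsilon must be >= 0")


@dataclass(frozen=True)
class BondTerm:
    species: tuple[str, str]
    r0: float  # A
    Kb: float  # kcal/(mol A^2)

    def __post_init__(self) -> None:
        if self.r0 <= 0 or self.Kb <= 0:
            raise ForceFieldError(f"bond {self.species}: r0 and Kb must be > 0")


@dataclass(frozen=True)
class AngleTermCosSq:
    """V = Ka1 (cos(theta) - cos(theta0))^2 ; lipid triplets."""

    species: tuple[str, str, str]
    theta0: float  # degrees
    Ka1: float     # kcal/mol

    def __post_init__(self) -> None:
        if not 0.0 < self.theta0 <= 180.0:
            raise ForceFieldError(f"angle {self.species}: theta0 out of range")


@dataclass(frozen=True)
class AngleTermHarmonic:
    """V = Ka2 (theta - theta0)^2 with theta in radians; chitosan triplets.

    Species labels carry repeat-unit offsets, e.g. ``(("R2", 0), ("R2", 1),
    ("R1", 1))`` for a backbone-backbone-side-bead angle spanning two units.
    """

    species: tuple[tuple[str, int], ...]
    theta0: float  # degrees
    Ka2: float     # kcal/(mol rad^2)

    def __post_init__(self) -> None:
        if not 0.0 < self.theta0 <= 180.0:
            raise ForceFieldError(f"angle {self.species}: theta0 out of range")


@dataclass(frozen=True)
class DihedralTermFourier:
    """V = Ki [1 + cos(ni phi - phi0)]; chitosan backbone torsions."""

    species: tuple[tuple[str, int], ...]
    phi0: float  # degrees
    Ki: float    # kcal/mol
    ni: int

    def __post_init__(self) -> None:
        if self.ni < 1:
            raise ForceFieldError(f"dihedral {self.species}: ni must be >= 1")


def _canon_pair(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a <= b else (b, a)


def _canon_tagged(seq: Sequence[tuple[str, int]]) -> tuple[tuple[str, int], ...]:
    """Canonical orientation + zero-based unit offsets for tagged tuples."""
    def norm(t: Sequence[tuple[str, int]]) -> tuple[tuple[str, int], ...]:
        lo = min(off for _, off in t)
        return tuple((sp, off - lo) for sp, off in t)

    fwd = norm(seq)
    rev = norm(tuple(reversed(seq)))
    return min(fwd, rev)


def _parse_tagged(label: str) -> tuple[str, int]:
    if label in _ALIASES:
        return _ALIASES[label]
    if ":" in label:
        sp, off = label.split(":")
        return sp, int(off)
    return label, 0


def mix_pair(
    sigma_i: float, sigma_j: float, eps_i: float, eps_j: float,
    species: tuple[str, str] = ("?", "?"),
) -> PairCoefficients:
    """Lorentz-Berthelot combination: arithmetic sigma, geometric epsilon."""
    if min(sigma_i, sigma_j) <= 0 or min(eps_i, eps_j) < 0:
        raise ForceFieldError("mix_pair: inputs must be positive")
    return PairCoefficients(
        species=_canon_pair(*species),
        sigma=0.5 * (sigma_i + sigma_j),
        epsilon=math.sqrt(eps_i * eps_j),
        source="mixed",
    )


@dataclass
class ForceFieldTables:
    """All interaction terms of the coarse-grained model.

    ``pair``/``bond``/``angle``/``dihedral`` look terms up by species
    label(s); unprinted LJ pairs fall back to Lorentz-Berthelot mixing from
    the self terms.
    """

    species: dict[str, BeadSpecies]
    pairs: dict[tuple[str, str], PairCoefficients]
    bonds: dict[tuple[str, str], BondTerm]
    angles_cos2: dict[tuple[str, str, str], AngleTermCosSq]
    angles_harmonic: dict[tuple[tuple[str, int], ...], AngleTermHarmonic]
    dihedrals: dict[tuple[tuple[str, int], ...], DihedralTermFourier]
    cutoff: float = 12.0       # A
    dielectric: float = 15.0   # relative
    checksum: str = ""
    _mixed_cache: dict = field(default_factory=dict, repr=False)

    # -- lookups ----------------------------------------------------------
    def pair(self, a: str, b: str) -> PairCoefficients:
        key = _canon_pair(a, b)
        if key in self.pairs:
            return self.pairs[key]
        if key in self._mixed_cache:
            return self._mixed_cache[key]
        try:
            pa = self.pairs[(a, a)]
            pb = self.pairs[(b, b)]
        except KeyError as exc:
            raise ForceFieldError(
                f"pair {a}-{b}: no printed entry and self terms missing, "
                "cannot mix"
            ) from exc
        mixed = mix_pair(pa.sigma, pb.sigma, pa.epsilon, pb.epsilon, (a, b))
        self._mixed_cache[key] = mixed
        return mixed

    def bond(self, a: str, b: str) -> BondTerm:
        key = _canon_pair(a, b)
        try:
            return self.bonds[key]
        except KeyError as exc:
            raise ForceFieldError(f"no bond term for {a}-{b}") from exc

    def angle(self, *labels) -> AngleTermCosSq | AngleTermHarmonic:
        """Look up an angle term.

        Plain species strings address the lipid cosine-squared table;
        ``(species, unit_offset)`` tuples (or "R2:1"-style strings) address
        the chitosan harmonic table.
        """
        tagged = [
            _parse_tagged(x) if isinstance(x, str) else tuple(x) for x in labels
        ]
        if all(sp in ("R1", "R2", "R3p") for sp, _ in tagged):
            key = _canon_tagged(tagged)
            if key in self.angles_harmonic:
                return self.angles_harmonic[key]
        names = tuple(sp for sp, _ in tagged)
        for cand in (names, names[::-1]):
            if cand in self.angles_cos2:
                return self.angles_cos2[cand]
        raise ForceFieldError(f"no angle term for {labels}")

    def dihedral(self, *labels) -> DihedralTermFourier:
        tagged = [
            _parse_tagged(x) if isinstance(x, str) else tuple(x) for x in labels
        ]
        key = _canon_tagged(tagged)
        try:
            return self.dihedrals[key]
        except KeyError as exc:
            raise ForceFieldError(f"no dihedral term for {labels}") from exc

    # -- validation -------------------------------------------------------
    def validate_coverage(self, species_names: Iterable[str]) -> list[str]:
        """Report species pairs that resolve to neither a printed nor a
        mixable entry.  An empty list means full coverage."""
        missing = []
        names = sorted(set(species_names))
        for i, a in enumerate(names):
            for b in names[i:]:
                try:
                    self.pair(a, b)
                except ForceFieldError:
                    missing.append(f"{a}-{b}")
        return missing

    # -- dense matrices for the simulation kernels ------------------------
    def pair_matrices(self) -> tuple[np.ndarray, np.ndarray]:
        """(sigma, epsilon) as dense (S, S) arrays over SPECIES_ORDER."""
        n = len(SPECIES_ORDER)
        sig = np.zeros((n, n))
        eps = np.zeros((n, n))
        for i, a in enumerate(SPECIES_ORDER):
            for j, b in enumerate(SPECIES_ORDER):
                pc = self.pair(a, b)
                sig[i, j] = pc.sigma
                eps[i, j] = pc.epsilon
        return sig, eps

    def charges(self) -> np.ndarray:
        return np.array(
            [self.species[s].charge for s in SPECIES_ORDER], dtype=float
        )

    def masses(self) -> np.ndarray:
        return np.array(
            [self.species[s].mass for s in SPECIES_ORDER], dtype=float
        )


# -------------------------------------------------------------------------
# loading
# -------------------------------------------------------------------------

def _canonical_serialization(doc: dict) -> str:
    """Stable text form of all parameter rows, used for the checksum."""
    lines: list[str] = []
    for sp in doc.get("species", []):
        lines.append(f"species|{sp['name']}|{sp['mass']:.6f}|{sp['charge']}")
    for row in doc.get("pairs", []):
        for a, b in row["species"]:
            pa, pb = _canon_pair(a, b)
            lines.append(
                f"pair|{pa}|{pb}|{row['sigma']:.6f}|{row['epsilon']:.6f}"
            )
    for row in doc.get("bonds", []):
        a, b = _canon_pair(*row["species"])
        lines.append(f"bond|{a}|{b}|{row['r0']:.6f}|{row['Kb']:.6f}")
    for row in doc.get("angles_cos2", []):
        names = tuple(row["species"])
        names = min(names, names[::-1])
        lines.append(
            f"angle1|{'|'.join(names)}|{row['theta0']:.6f}|{row['Ka1']:.6f}"
        )
    for row in doc.get("angles_harmonic", []):
        key = _canon_tagged([_parse_tagged(x) for x in row["species"]])
        tag = "|".join(f"{sp}:{off}" for sp, off in key)
        lines.append(f"angle2|{tag}|{row['theta0']:.6f}|{row['Ka2']:.6f}")
    for row in doc.get("dihedrals", []):
        key = _canon_tagged([_parse_tagged(x) for x in row["species"]])
        tag = "|".join(f"{sp}:{off}" for sp, off in key)
        lines.append(
            f"dihedral|{tag}|{row['phi0']:.6f}|{row['Ki']:.6f}|{row['ni']}"
        )
    return "\n".join(sorted(lines)) + "\n"


def table_checksum(doc: dict) -> str:
    return hashlib.sha256(_canonical_serialization(doc).encode()).hexdigest()


def load_tables(
    path: str | None = None, verify_checksum: bool = True
) -> ForceFieldTables:
    """Load the parameter tables from TOML (packaged file by default).

    Raises :class:`ForceFieldError` on duplicate rows with conflicting
    values, and (optionally) on a checksum mismatch against the embedded
    integrity record.
    """
    if path is None:
        src = resources.files("lipobrush.data").joinpath(DEFAULT_TABLE_RESOURCE)
        doc = tomllib.loads(src.read_text())
    else:
        with open(path, "rb") as fh:
            doc = tomllib.load(fh)

    digest = table_checksum(doc)
    embedded = doc.get("integrity", {}).get("sha256", "")
    if verify_checksum and embedded not in ("", "PLACEHOLDER") and embedded != digest:
        raise ForceFieldError(
            f"parameter-table checksum mismatch: file says {embedded[:12]}..., "
            f"rows hash to {digest[:12]}..."
        )

    species = {}
    for sp in doc["species"]:
        if sp["name"] in species:
            raise ForceFieldError(f"duplicate species {sp['name']}")
        species[sp["name"]] = BeadSpecies(sp["name"], sp["mass"], sp["charge"])

    pairs: dict[tuple[str, str], PairCoefficients] = {}
    for row in doc["pairs"]:
        for a, b in row["species"]:
            key = _canon_pair(a, b)
            pc = PairCoefficients(key, row["sigma"], row["epsilon"], "printed")
            if key in pairs and (
                pairs[key].sigma != pc.sigma or pairs[key].epsilon != pc.epsilon
            ):
                raise ForceFieldError(
                    f"conflicting pair rows for {key}: "
                    f"{pairs[key].sigma}/{pairs[key].epsilon} vs "
                    f"{pc.sigma}/{pc.epsilon}"
                )
            pairs[key] = pc

    bonds: dict[tuple[str, str], BondTerm] = {}
    for row in doc["bonds"]:
        key = _canon_pair(*row["species"])
        bt = BondTerm(key, row["r0"], row["Kb"])
        if key in bonds and bonds[key] != bt:
            raise ForceFieldError(
                f"conflicting bond rows for {key}: {bonds[key]} vs {bt}"
            )
        bonds[key] = bt

    angles_cos2 = {}
    for row in doc["angles_cos2"]:
        names = tuple(row["species"])
        key = min(names, names[::-1])
        term = AngleTermCosSq(key, row["theta0"], row["Ka1"])
        if key in angles_cos2 and angles_cos2[key] != term:
            raise ForceFieldError(f"conflicting angle rows for {key}")
        angles_cos2[key] = term

    angles_harmonic = {}
    for row in doc["angles_harmonic"]:
        key = _canon_tagged([_parse_tagged(x) for x in row["species"]])
        term = AngleTermHarmonic(key, row["theta0"], row["Ka2"])
        if key in angles_harmonic and angles_harmonic[key] != term:
            raise ForceFieldError(f"conflicting angle rows for {key}")
        angles_harmonic[key] = term

    dihedrals = {}
    for row in doc["dihedrals"]:
        key = _canon_tagged([_parse_tagged(x) for x in row["species"]])
        term = DihedralTermFourier(key, row["phi0"], row["Ki"], row["ni"])
        if key in dihedrals and dihedrals[key] != term:
            raise ForceFieldError(f"conflicting dihedral rows for {key}")
        dihedrals[key] = term

    return ForceFieldTables(
        species=species,
        pairs=pairs,
        bonds=bonds,
        angles_cos2=angles_cos2,
        angles_harmonic=angles_harmonic,
        dihedrals=dihedrals,
        cutoff=float(doc.get("cutoff", 12.0)),
        dielectric=float(doc.get("dielectric", 15.0)),
        checksum=digest,
    )


# -------------------------------------------------------------------------
# scalar term energies (the reference forms; the simulation kernels in
# _kernels.py implement the same expressions over arrays)
# -------------------------------------------------------------------------

def lj_energy(
    r: float, pair: PairCoefficients, cutoff: float = math.inf
) -> float:
    """12-6 Lennard-Jones, energy-shifted to zero at the cutoff."""
    if r <= 0:
        raise ValueError("lj_energy: overlapping beads (r <= 0)")
    if r >= cutoff:
        return 0.0
    s6 = (pair.sigma / r) ** 6
    e = 4.0 * pair.epsilon * (s6 * s6 - s6)
    if math.isfinite(cutoff):
        sc6 = (pair.sigma / cutoff) ** 6
        e -= 4.0 * pair.epsilon * (sc6 * sc6 - sc6)
    return e


def coulomb_energy(
    r: float, qi: float, qj: float, dielectric: float = 15.0,
    cutoff: float = math.inf,
) -> float:
    """Screened Coulomb with shifted-force taper at the cutoff.

    V(r) = (k_e qi qj / eps_r) (1/r - 1/rc + (r - rc)/rc^2); both V and its
    derivative vanish at r = rc.  With cutoff = inf this is the bare
    screened Coulomb energy.
    """
    if r <= 0:
        raise ValueError("coulomb_energy: overlapping beads (r <= 0)")
    if qi == 0.0 or qj == 0.0 or r >= cutoff:
        return 0.0
    c = COULOMB * qi * qj / dielectric
    if math.isfinite(cutoff):
        return c * (1.0 / r - 1.0 / cutoff + (r - cutoff) / cutoff**2)
    return c / r


def bond_energy(r: float, term: BondTerm) -> float:
    """Harmonic bond V = Kb (r - r0)^2 (as printed: no 1/2 prefactor)."""
    return term.Kb * (r - term.r0) ** 2


def angle_energy(
    theta: float, term: AngleTermCosSq | AngleTermHarmonic
) -> float:
    """Angle energy; ``theta`` in radians.

    Cosine-squared form for lipid triplets, harmonic (radian) form for
    chitosan triplets.
    """
    theta0 = math.radians(term.theta0)
    if isinstance(term, AngleTermCosSq):
        return term.Ka1 * (math.cos(theta) - math.cos(theta0)) ** 2
    if isinstance(term, AngleTermHarmonic):
        return term.Ka2 * (theta - theta0) ** 2
    raise ForceFieldError(f"unknown angle term type {type(term)!r}")


def dihedral_energy(phi: float, term: DihedralTermFourier) -> float:
    """Fourier dihedral V = Ki [1 + cos(ni phi - phi0)]; ``phi`` in radians."""
    return term.Ki * (1.0 + math.cos(term.ni * phi - math.radians(term.phi0)))
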