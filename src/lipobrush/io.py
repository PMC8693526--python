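"""File formats: LAMMPS-dump and extended-XYZ trajectories, LAMMPS-data
configurations, thermo CSV, and JSON state checkpoints.

All formats are plain text.  Trajectory round-trips preserve coordinates to
the printed precision (1e-6 A) and periodic image flags; unknown dump
columns are carried through opaquely.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .forcefield import SPECIES_ORDER
from .system import Frame, GROUP_NAMES, SimState, Topology, Trajectory

DIALECTS = ("lammps-dump", "extended-xyz")


class TrajectoryFormatError(ValueError):
    """Malformed trajectory file; the message names the offending line."""


# -------------------------------------------------------------------------
# LAMMPS dump
# -------------------------------------------------------------------------

def _write_dump_frame(fh, frame: Frame, types: np.ndarray) -> None:
    n = len(frame.positions)
    fh.write("ITEM: TIMESTEP\n%d\n" % frame.step)
    fh.write("ITEM: NUMBER OF ATOMS\n%d\n" % n)
    fh.write("ITEM: BOX BOUNDS pp pp pp\n")
    for d in range(3):
        fh.write("0.0 %.6f\n" % frame.box[d])
    if frame.images is not None:
        fh.write("ITEM: ATOMS id type x y z ix iy iz\n")
        for i in range(n):
            x, y, z = frame.positions[i]
            ix, iy, iz = frame.images[i]
            fh.write(
                "%d %d %.6f %.6f %.6f %d %d %d\n"
                % (i + 1, types[i] + 1, x, y, z, ix, iy, iz)
            )
    else:
        fh.write("ITEM: ATOMS id type x y z\n")
        for i in range(n):
            x, y, z = frame.positions[i]
            fh.write("%d %d %.6f %.6f %.6f\n" % (i + 1, types[i] + 1, x, y, z))


def _read_dump(path: Path) -> tuple[Trajectory, np.ndarray | None]:
    traj = Trajectory()
    types = None
    lines = path.read_text().splitlines()
    k = 0
    nline = len(lines)
    while k < nline:
        if not lines[k].startswith("ITEM: TIMESTEP"):
            raise TrajectoryFormatError(
                f"{path}:{k + 1}: expected ITEM: TIMESTEP"
            )
        step = int(lines[k + 1])
        if not lines[k + 2].startswith("ITEM: NUMBER OF ATOMS"):
            raise TrajectoryFormatError(
                f"{path}:{k + 3}: expected ITEM: NUMBER OF ATOMS"
            )
        n = int(lines[k + 3])
        if not lines[k + 4].startswith("ITEM: BOX BOUNDS"):
            raise TrajectoryFormatError(
                f"{path}:{k + 5}: expected ITEM: BOX BOUNDS"
            )
        box = np.zeros(3)
        for d in range(3):
            lo, hi = lines[k + 5 + d].split()[:2]
            box[d] = float(hi) - float(lo)
        hdr = lines[k + 8]
        if not hdr.startswith("ITEM: ATOMS"):
            raise TrajectoryFormatError(f"{path}:{k + 9}: expected ITEM: ATOMS")
        cols = hdr.split()[2:]
        need = {"id", "x", "y", "z"}
        if not need <= set(cols):
            raise TrajectoryFormatError(
                f"{path}:{k + 9}: dump must provide columns {sorted(need)}"
            )
        has_img = {"ix", "iy", "iz"} <= set(cols)
        ci = {c: cols.index(c) for c in cols}
        pos = np.zeros((n, 3))
        img = np.zeros((n, 3), dtype=np.int64) if has_img else None
        tp = np.zeros(n, dtype=np.int64)
        extras = {c: np.zeros(n) for c in cols
                  if c not in {"id", "type", "x", "y", "z", "ix", "iy", "iz"}}
        for a in range(n):
            parts = lines[k + 9 + a].split()
            if len(parts) != len(cols):
                raise TrajectoryFormatError(
                    f"{path}:{k + 10 + a}: expected {len(cols)} columns"
                )
            idx = int(parts[ci["id"]]) - 1
            pos[idx] = [float(parts[ci[c]]) for c in ("x", "y", "z")]
            if "type" in ci:
                tp[idx] = int(parts[ci["type"]]) - 1
            if has_img:
                img[idx] = [int(parts[ci[c]]) for c in ("ix", "iy", "iz")]
            for c, arr in extras.items():
                arr[idx] = float(parts[ci[c]])
        frame = Frame(time=float(step), step=step, box=box,
                      positions=pos, images=img)
        frame.extras = extras or None
        traj.frames.append(frame)
        types = tp
        k += 9 + n
    return traj, types


# -------------------------------------------------------------------------
# extended XYZ
# -------------------------------------------------------------------------

def _write_xyz_frame(
    fh, frame: Frame, species: list[str], groups: list[str] | None
) -> None:
    n = len(frame.positions)
    props = "species:S:1:pos:R:3"
    if frame.images is not None:
        props += ":image:I:3"
    if groups is not None:
        props += ":group:S:1"
    lat = "%.6f 0.0 0.0 0.0 %.6f 0.0 0.0 0.0 %.6f" % tuple(frame.box)
    fh.write("%d\n" % n)
    fh.write(
        'Lattice="%s" Properties=%s Time=%.6f Step=%d\n'
        % (lat, props, frame.time, frame.step)
    )
    for i in range(n):
        parts = [species[i]] + ["%.6f" % v for v in frame.positions[i]]
        if frame.images is not None:
            parts += [str(int(v)) for v in frame.images[i]]
        if groups is not None:
            parts.append(groups[i])
        fh.write(" ".join(parts) + "\n")


def _read_xyz(path: Path) -> tuple[Trajectory, list[str] | None]:
    traj = Trajectory()
    species = None
    lines = path.read_text().splitlines()
    k = 0
    while k < len(lines):
        if not lines[k].strip():
            k += 1
            continue
        try:
            n = int(lines[k].strip())
        except ValueError as exc:
            raise TrajectoryFormatError(
                f"{path}:{k + 1}: expected atom count"
            ) from exc
        comment = lines[k + 1]
        box = np.zeros(3)
        if 'Lattice="' in comment:
            lat = comment.split('Lattice="')[1].split('"')[0].split()
            box = np.array([float(lat[0]), float(lat[4]), float(lat[8])])
        props = ""
        if "Properties=" in comment:
            props = comment.split("Properties=")[1].split()[0]
        fields = props.split(":")
        has_img = "image" in fields
        has_group = "group" in fields
        t = 0.0
        step = len(traj.frames)
        for tok in comment.split():
            if tok.startswith("Time="):
                t = float(tok[5:])
            elif tok.startswith("Step="):
                step = int(tok[5:])
        pos = np.zeros((n, 3))
        img = np.zeros((n, 3), dtype=np.int64) if has_img else None
        sp = []
        for a in range(n):
            parts = lines[k + 2 + a].split()
            sp.append(parts[0])
            pos[a] = [float(v) for v in parts[1:4]]
            if has_img:
                img[a] = [int(v) for v in parts[4:7]]
        traj.frames.append(
            Frame(time=t, step=step, box=box, positions=pos, images=img)
        )
        species = sp
        k += 2 + n
    return traj, species


# -------------------------------------------------------------------------
# public API
# -------------------------------------------------------------------------

def write_trajectory(
    traj: Trajectory,
    path: str | Path,
    dialect: str = "lammps-dump",
    topology: Topology | None = None,
) -> None:
    """Write all frames in the requested dialect.

    The LAMMPS dump stores 1-based numeric types (species index + 1);
    extended XYZ stores species labels and, when a topology is supplied,
    group labels.
    """
    if dialect not in DIALECTS:
        raise ValueError(f"dialect must be one of {DIALECTS}")
    path = Path(path)
    with open(path, "w") as fh:
        if dialect == "lammps-dump":
            types = (topology.species if topology is not None
                     else np.zeros(len(traj.frames[0].positions), dtype=int))
            for frame in traj.frames:
                _write_dump_frame(fh, frame, types)
        else:
            if topology is not None:
                species = topology.species_names()
                groups = [GROUP_NAMES[g] for g in topology.group]
            else:
                n = len(traj.frames[0].positions)
                species, groups = ["X"] * n, None
            for frame in traj.frames:
                _write_xyz_frame(fh, frame, species, groups)


def read_trajectory(
    path: str | Path, dialect: str | None = None
) -> tuple[Trajectory, object]:
    """Read a trajectory; returns (trajectory, species info).

    Species info is a 0-based numeric type array for dumps and a label list
    for extended XYZ.  The dialect is sniffed from the first line when not
    given."""
    path = Path(path)
    if dialect is None:
        first = path.read_text(encoding="utf-8").split("\n", 1)[0]
        dialect = "lammps-dump" if first.startswith("ITEM:") else "extended-xyz"
    if dialect == "lammps-dump":
        return _read_dump(path)
    if dialect == "extended-xyz":
        return _read_xyz(path)
    raise ValueError(f"dialect must be one of {DIALECTS}")


def write_lammps_data(
    topology: Topology, state: SimState, path: str | Path,
    header_comment: str = "",
) -> None:
    """Initial configuration in LAMMPS-data dialect (full atom style).

    Bond/angle/dihedral types enumerate the distinct parameter tuples; the
    parameters themselves are recorded in commented coeff sections since
    the model mixes two angle styles."""
    top = topology
    path = Path(path)

    def type_map(params: list[tuple]) -> tuple[dict, list[int]]:
        uniq: dict[tuple, int] = {}
        ids = []
        for p in params:
            if p not in uniq:
                uniq[p] = len(uniq) + 1
            ids.append(uniq[p])
        return uniq, ids

    bond_params = [
        (top.bond_r0[i], top.bond_k[i]) for i in range(len(top.bonds))
    ]
    angle_params = [
        (top.angle_style[i], top.angle_theta0[i], top.angle_k[i])
        for i in range(len(top.angles))
    ]
    dih_params = [
        (top.dihedral_phi0[i], top.dihedral_k[i], top.dihedral_n[i])
        for i in range(len(top.dihedrals))
    ]
    bond_types, bond_ids = type_map(bond_params)
    angle_types, angle_ids = type_map(angle_params)
    dih_types, dih_ids = type_map(dih_params)

    with open(path, "w") as fh:
        fh.write(f"# {header_comment}\n\n")
        fh.write(f"{top.n_beads} atoms\n")
        fh.write(f"{len(top.bonds)} bonds\n")
        fh.write(f"{len(top.angles)} angles\n")
        fh.write(f"{len(top.dihedrals)} dihedrals\n\n")
        fh.write(f"{len(SPECIES_ORDER)} atom types\n")
        fh.write(f"{max(len(bond_types), 1)} bond types\n")
        fh.write(f"{max(len(angle_types), 1)} angle types\n")
        fh.write(f"{max(len(dih_types), 1)} dihedral types\n\n")
        for d, name in enumerate("xyz"):
            fh.write(f"0.0 {state.box[d]:.6f} {name}lo {name}hi\n")
        fh.write("\nMasses\n\n")
        masses = {}
        for i in range(top.n_beads):
            masses[int(top.species[i]) + 1] = top.mass[i]
        for t in range(1, len(SPECIES_ORDER) + 1):
            fh.write(f"{t} {masses.get(t, 72.0):.4f}  # {SPECIES_ORDER[t-1]}\n")
        fh.write("\n# Bond Coeffs (Kb r0): ")
        fh.write("; ".join(f"{i} {k:.4f} {r0:.4f}"
                           for (r0, k), i in bond_types.items()) + "\n")
        fh.write("# Angle Coeffs (style theta0_rad K): ")
        fh.write("; ".join(f"{i} {s} {t0:.4f} {k:.4f}"
                           for (s, t0, k), i in angle_types.items()) + "\n")
        fh.write("# Dihedral Coeffs (phi0_rad K n): ")
        fh.write("; ".join(f"{i} {p0:.4f} {k:.4f} {n}"
                           for (p0, k, n), i in dih_types.items()) + "\n")
        fh.write("\nAtoms  # full\n\n")
        for i in range(top.n_beads):
            x, y, z = state.positions[i]
            fh.write(
                f"{i+1} {top.mol_id[i]+1} {top.species[i]+1} "
                f"{top.charge[i]:.1f} {x:.6f} {y:.6f} {z:.6f}\n"
            )
        if len(top.bonds):
            fh.write("\nBonds\n\n")
            for n, (i, j) in enumerate(top.bonds):
                fh.write(f"{n+1} {bond_ids[n]} {i+1} {j+1}\n")
        if len(top.angles):
            fh.write("\nAngles\n\n")
            for n, (i, j, k) in enumerate(top.angles):
                fh.write(f"{n+1} {angle_ids[n]} {i+1} {j+1} {k+1}\n")
        if len(top.dihedrals):
            fh.write("\nDihedrals\n\n")
            for n, (i, j, k, l) in enumerate(top.dihedrals):
                fh.write(f"{n+1} {dih_ids[n]} {i+1} {j+1} {k+1} {l+1}\n")


def write_thermo_csv(traj: Trajectory, path: str | Path) -> None:
    traj.thermo_table().to_csv(path, index=False)


def save_state(state: SimState, path: str | Path, meta: dict | None = None
               ) -> None:
    """JSON text checkpoint (positions, velocities, images, box, time)."""
    doc = {
        "meta": meta or {},
        "time": state.time,
        "box": state.box.tolist(),
        "positions": np.round(state.positions, 8).tolist(),
        "velocities": np.round(state.velocities, 10).tolist(),
        "images": state.images.tolist(),
    }
    Path(path).write_text(json.dumps(doc))


def load_state(path: str | Path) -> tuple[SimState, dict]:
    doc = json.loads(Path(path).read_text())
    state = SimState(
        positions=np.array(doc["positions"]),
        velocities=np.array(doc["velocities"]),
        box=np.array(doc["box"]),
        images=np.array(doc["images"], dtype=np.int64),
        time=float(doc["time"]),
    )
    return state, doc.get("meta", {})
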