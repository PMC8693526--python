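"""Energy minimization and time integration.

The protocols mirror the study workflow: minimize the as-built
configuration, equilibrate with a Langevin thermostat coupled to a
weak-coupling (Berendsen-style) barostat at 300 K / 1 atm, then produce
with the Langevin thermostat over a velocity-Verlet (NVE) core.  The
barostat can couple the lateral (xy) and normal (z) box dimensions to the
corresponding pressure components separately, which membrane runs need so
that the area per lipid can relax independently of the inter-membrane gap.

The Langevin step is BAOAB-ordered velocity Verlet: half kick, half drift,
exact Ornstein-Uhlenbeck velocity refresh at the target temperature, half
drift, half kick.  With zero friction and zero noise it reduces to plain
velocity Verlet and is time-reversible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .engine import EnergyBreakdown, ForceEngine
from .forcefield import ForceFieldTables
from .system import Frame, SimState, Topology, Trajectory
from .units import FORCE_TO_ACC, KB, MVV_TO_ENERGY, PRESS_TO_ATM


@dataclass
class IntegratorConfig:
    """Time-integration parameters (real units)."""

    dt: float = 10.0           # fs
    t_target: float = 300.0    # K
    damp: float = 100.0        # fs (Langevin damping time)
    p_target: float = 1.0      # atm
    barostat_mode: str = "xy-z"    # "xy-z" | "isotropic" | "none"
    tau_p: float = 500.0       # fs, barostat coupling time
    # weak-coupling gain: deliberately larger than a physical liquid
    # compressibility so that desk-scale patches with partly open gaps
    # relax within the affordable step counts
    compressibility: float = 2.0e-3  # atm^-1
    max_strain: float = 5.0e-4  # per-step cap on |mu - 1|
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dt <= 0 or self.damp <= 0:
            raise ValueError("dt and damp must be > 0")
        if self.barostat_mode not in ("xy-z", "isotropic", "none"):
            raise ValueError("barostat_mode must be xy-z, isotropic or none")


@dataclass
class MinimizerConfig:
    e_stop: float = 1.0e-7     # relative energy change
    f_stop: float = 1.0e-8     # kcal/(mol A), force-vector norm
    max_iter: int = 100_000
    max_step: float = 0.5      # A, per-coordinate displacement cap

    def __post_init__(self) -> None:
        if min(self.e_stop, self.f_stop) <= 0:
            raise ValueError("tolerances must be > 0")


@dataclass
class MinimizeReport:
    iterations: int
    converged_by: str          # "energy" | "force" | "max_iter"
    initial_energy: float
    final_energy: float
    final_force_norm: float
    energy_trace: list = field(default_factory=list)


def minimize(
    state: SimState,
    topology: Topology,
    tables: ForceFieldTables,
    cfg: MinimizerConfig | None = None,
    engine: ForceEngine | None = None,
) -> tuple[SimState, MinimizeReport]:
    """Steepest descent with backtracking line search.

    Accepted steps never increase the energy.  Terminates when the relative
    energy change drops below ``e_stop``, the global force norm below
    ``f_stop``, or at the iteration cap.
    """
    cfg = cfg or MinimizerConfig()
    eng = engine or ForceEngine(topology, tables)
    s = state.copy()
    # entry guard: non-finite energy or an essentially coincident pair
    # (which the pair kernel would otherwise skip silently)
    try:
        breakdown, f, _ = eng.compute(s, check_overlap=True,
                                      overlap_frac=0.05)
    except Exception as exc:
        raise RuntimeError(
            f"unusable configuration at minimizer entry: {exc}"
        ) from exc
    e = breakdown.total
    if not math.isfinite(e):
        raise RuntimeError("non-finite energy at minimizer entry")
    e0 = e
    trace = [e]
    alpha = 0.05  # initial step along the normalized force direction
    converged_by = "max_iter"
    it = 0
    for it in range(1, cfg.max_iter + 1):
        fnorm = float(np.linalg.norm(f))
        if fnorm < cfg.f_stop:
            converged_by = "force"
            break
        fmax = float(np.abs(f).max())
        step = f * min(alpha, cfg.max_step / max(fmax, 1e-300))
        accepted = False
        for _ in range(30):
            cand = s.copy()
            cand.positions = s.positions + step
            cand.wrap()
            bd, fc, _ = eng.compute(cand)
            if bd.total <= e:
                accepted = True
                break
            step *= 0.5
        if not accepted:
            converged_by = "energy"
            break
        de = e - bd.total
        s, f, e = cand, fc, bd.total
        trace.append(e)
        alpha = min(alpha * 1.1, 1.0)
        if de < cfg.e_stop * max(abs(e), 1e-300):
            converged_by = "energy"
            break
    return s, MinimizeReport(
        iterations=it,
        converged_by=converged_by,
        initial_energy=e0,
        final_energy=e,
        final_force_norm=float(np.linalg.norm(f)),
        energy_trace=trace,
    )


# -------------------------------------------------------------------------
# integrators
# -------------------------------------------------------------------------

def init_velocities(
    state: SimState, topology: Topology, t_target: float,
    rng: np.random.Generator,
) -> None:
    """Maxwell-Boltzmann draw at ``t_target`` with net momentum zeroed."""
    m = topology.mass[:, None]
    sigma = np.sqrt(KB * t_target * FORCE_TO_ACC / m)
    v = rng.normal(size=state.positions.shape) * sigma
    v -= (m * v).sum(axis=0) / m.sum()
    state.velocities = v


def kinetic_energy(state: SimState, topology: Topology) -> float:
    return 0.5 * MVV_TO_ENERGY * float(
        (topology.mass[:, None] * state.velocities**2).sum()
    )


def temperature(state: SimState, topology: Topology) -> float:
    ndof = 3 * state.n_beads
    return 2.0 * kinetic_energy(state, topology) / (ndof * KB)


def pressure_tensor_diag(
    state: SimState, topology: Topology, virial: np.ndarray
) -> np.ndarray:
    """Diagonal of the virial pressure tensor, atm."""
    v = state.volume()
    kin = MVV_TO_ENERGY * (
        topology.mass[:, None] * state.velocities**2
    ).sum(axis=0)
    return (kin + virial) / v * PRESS_TO_ATM


class Integrator:
    """Stateful stepper shared by the Langevin and NVE protocols."""

    def __init__(
        self,
        topology: Topology,
        tables: ForceFieldTables,
        cfg: IntegratorConfig,
        thermostat: bool = True,
        barostat: bool = False,
    ):
        self.top = topology
        self.cfg = cfg
        self.engine = ForceEngine(topology, tables)
        self.thermostat = thermostat
        self.barostat = barostat and cfg.barostat_mode != "none"
        self.rng = np.random.default_rng(cfg.seed)
        self._forces: np.ndarray | None = None
        self._virial: np.ndarray | None = None
        self._breakdown: EnergyBreakdown | None = None
        m = topology.mass[:, None]
        self._inv_m = FORCE_TO_ACC / m
        gamma = 1.0 / cfg.damp
        self._ou_c1 = math.exp(-gamma * cfg.dt)
        self._ou_c2 = math.sqrt(1.0 - self._ou_c1**2)
        self._v_sigma = np.sqrt(KB * cfg.t_target * FORCE_TO_ACC / m)

    def _ensure_forces(self, state: SimState) -> None:
        if self._forces is None:
            self._breakdown, self._forces, self._virial = self.engine.compute(
                state
            )

    def step(self, state: SimState) -> SimState:
        """One BAOAB step (O-step skipped when the thermostat is off)."""
        cfg = self.cfg
        dt = cfg.dt
        self._ensure_forces(state)
        v = state.velocities + 0.5 * dt * self._forces * self._inv_m
        state.positions += 0.5 * dt * v
        if self.thermostat:
            noise = self.rng.normal(size=v.shape)
            v = self._ou_c1 * v + self._ou_c2 * self._v_sigma * noise
        state.positions += 0.5 * dt * v
        state.wrap()
        self._breakdown, self._forces, self._virial = self.engine.compute(state)
        state.velocities = v + 0.5 * dt * self._forces * self._inv_m
        state.time += dt
        if self.barostat:
            self._apply_barostat(state)
        return state

    def _apply_barostat(self, state: SimState) -> None:
        cfg = self.cfg
        p_diag = pressure_tensor_diag(state, self.top, self._virial)
        rate = cfg.dt * cfg.compressibility / cfg.tau_p
        lo, hi = 1.0 - cfg.max_strain, 1.0 + cfg.max_strain
        if cfg.barostat_mode == "isotropic":
            p = float(p_diag.mean())
            mu = np.clip(1.0 - rate / 3.0 * (cfg.p_target - p), lo, hi)
            scale = np.array([mu, mu, mu])
        else:  # xy-z split: lateral and normal couple to their own P
            p_lat = float(0.5 * (p_diag[0] + p_diag[1]))
            p_norm = float(p_diag[2])
            mu_l = np.clip(1.0 - rate / 3.0 * (cfg.p_target - p_lat), lo, hi)
            mu_z = np.clip(1.0 - rate / 3.0 * (cfg.p_target - p_norm), lo, hi)
            scale = np.array([mu_l, mu_l, mu_z])
        new_box = state.box * scale
        if (new_box <= 0).any():
            raise RuntimeError("barostat drove a box length negative")
        state.positions *= scale
        state.box = new_box

    def thermo(self, state: SimState) -> dict:
        self._ensure_forces(state)
        bd = self._breakdown
        p_diag = pressure_tensor_diag(state, self.top, self._virial)
        return {
            "time": state.time,
            "T": temperature(state, self.top),
            "P": float(p_diag.mean()),
            "Pxx": float(p_diag[0]), "Pyy": float(p_diag[1]),
            "Pzz": float(p_diag[2]),
            "E_kin": kinetic_energy(state, self.top),
            "Lx": float(state.box[0]), "Ly": float(state.box[1]),
            "Lz": float(state.box[2]),
            **bd.as_dict(),
        }


def step_langevin(
    state: SimState, topology: Topology, tables: ForceFieldTables,
    cfg: IntegratorConfig, n_steps: int = 1,
) -> SimState:
    """Convenience wrapper: ``n_steps`` Langevin (NVT) steps."""
    it = Integrator(topology, tables, cfg, thermostat=True, barostat=False)
    for _ in range(n_steps):
        it.step(state)
    return state


def step_nve(
    state: SimState, topology: Topology, tables: ForceFieldTables,
    cfg: IntegratorConfig, n_steps: int = 1,
) -> SimState:
    """Convenience wrapper: ``n_steps`` plain velocity-Verlet (NVE) steps."""
    it = Integrator(topology, tables, cfg, thermostat=False, barostat=False)
    for _ in range(n_steps):
        it.step(state)
    return state


def step_barostat(
    state: SimState, topology: Topology, tables: ForceFieldTables,
    cfg: IntegratorConfig,
) -> SimState:
    """Apply one weak-coupling barostat rescale to ``state`` in place.

    Computes the instantaneous virial pressure and rescales box and
    coordinates toward ``cfg.p_target`` (isotropic or xy-z split per
    ``cfg.barostat_mode``), capped at ``cfg.max_strain`` per call."""
    it = Integrator(topology, tables, cfg, thermostat=False, barostat=True)
    it._ensure_forces(state)
    it._apply_barostat(state)
    return state


PROTOCOLS = ("minimize", "npt_equilibrate", "nvt_production", "nve")


def run(
    state: SimState,
    topology: Topology,
    tables: ForceFieldTables,
    protocol: str,
    n_steps: int,
    dump_every: int = 100,
    cfg: IntegratorConfig | None = None,
    min_cfg: MinimizerConfig | None = None,
) -> tuple[SimState, Trajectory]:
    """Run one protocol stage, emitting frames every ``dump_every`` steps.

    Frames store wrapped coordinates plus periodic image counts so
    downstream analysis can unwrap; the thermo log gains one row per dump
    (including the initial state, so ``1 + n_steps // dump_every`` rows).
    """
    if protocol not in PROTOCOLS:
        raise ValueError(f"unknown protocol {protocol!r}")
    traj = Trajectory()
    if protocol == "minimize":
        s, report = minimize(state, topology, tables, min_cfg)
        traj.frames.append(
            Frame(s.time, 0, s.box.copy(), s.positions.copy(), s.images.copy())
        )
        traj.thermo.append({
            "time": s.time, "E_pot": report.final_energy,
            "iterations": report.iterations,
            "converged_by": report.converged_by,
        })
        return s, traj
    cfg = cfg or IntegratorConfig()
    it = Integrator(
        topology, tables, cfg,
        thermostat=protocol in ("npt_equilibrate", "nvt_production"),
        barostat=protocol == "npt_equilibrate",
    )

    def dump(step: int) -> None:
        traj.frames.append(Frame(
            state.time, step, state.box.copy(),
            state.positions.copy(), state.images.copy(),
        ))
        row = it.thermo(state)
        row["step"] = step
        traj.thermo.append(row)
        if not np.isfinite(row["E_pot"]):
            raise RuntimeError(
                f"non-finite energy at step {step}; last good frame kept"
            )

    dump(0)
    for step in range(1, n_steps + 1):
        it.step(state)
        if step % dump_every == 0:
            dump(step)
    return state, traj


def box_z_plateaued(traj: Trajectory, window_frac: float = 0.2,
                    tol: float = 0.01) -> bool:
    """True when the running mean of box-z over the trailing window varies
    by less than ``tol`` (relative): the membrane-membrane distance has
    stopped drifting."""
    lz = np.array([row["Lz"] for row in traj.thermo if "Lz" in row])
    if len(lz) < 10:
        return False
    nwin = max(int(len(lz) * window_frac), 5)
    tail = lz[-nwin:]
    return float(tail.max() - tail.min()) / float(tail.mean()) < tol
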