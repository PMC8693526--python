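"""Closed-form and semi-analytic models of the grafted-chain layer and of
bead diffusion.

Chain-conformation theory
-------------------------
A grafted chain of ``n_p`` Kuhn segments of length ``a`` is a mushroom at
low grafting fraction, with layer height the ideal-chain RMS end-to-end
length R0 = a sqrt(n_p).  At high grafting fraction the chains stretch into
a brush; minimizing the one-dimensional mean-field free energy

    F/kT = 3 R^2 / (2 n_p a^2) + 3 a^3 n_p^2 X_p / (A_l R)

over the layer height R gives R = n_p a (a^2 X_p / A_l)^(1/3).  The
mushroom-brush crossover happens where neighboring mushrooms start to
overlap, X_p* ~ A_l / (pi R0^2).  For a strongly charged chain (f = 1) with
condensed counterions there is no Pincus (electrostatic-stretching) regime;
the osmotic-brush limit is R ~ a n_p.  The scaling-regime heights carry
unit prefactors and are flagged as proportionalities, not absolute
predictions.

Diffusion theory
----------------
The generalized Langevin equation with memory kernel kappa(t) gives the
velocity autocorrelation C(t) via

    dC/dt = -gamma C(t) - int_0^t kappa(t - s) C(s) ds,   C(0) = 3 kT / m,

and MSD(t) = 2 int_0^t (t - s) C(s) ds.  With kappa = 0 this is ordinary
Langevin dynamics, MSD = (6 kT / m gamma)(t - (1 - e^{-gamma t})/gamma); a
power-law kernel window produces an intermediate subdiffusive regime
between the ballistic and normal ones.  The Rouse model gives the monomer
MSD ~ t^(1/2) below the chain relaxation time and normal diffusion above.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable

import numpy as np

from .observables import MSDSeries
from .units import COULOMB, FORCE_TO_ACC, KB


@dataclass
class BrushParams:
    n_p: int = 45
    a: float = 0.47        # Kuhn length, nm
    x_p: float = 0.1       # grafting molar fraction
    a_l: float = 0.7       # area per lipid, nm^2
    f: float = 1.0         # ionization fraction
    l_b: float = 3.71      # Bjerrum length, nm (eps_r = 15, 300 K)

    def __post_init__(self) -> None:
        if min(self.n_p, self.a, self.a_l, self.l_b) <= 0:
            raise ValueError("BrushParams fields must be positive")
        if not 0.0 <= self.f <= 1.0:
            raise ValueError("f must lie in [0, 1]")


def bjerrum_length(dielectric: float = 15.0, t: float = 300.0) -> float:
    """Distance at which two elementary charges interact with kT, nm."""
    return COULOMB / (dielectric * KB * t) / 10.0


def r0_ideal(n_p: int, a: float = 0.47) -> float:
    """Ideal (freely jointed) chain RMS end-to-end length a sqrt(n_p), nm.

    This is the mushroom-regime layer-height estimate."""
    if n_p < 1:
        raise ValueError("n_p must be >= 1")
    return a * math.sqrt(n_p)


def brush_height_mean_field(
    n_p: int, a: float = 0.47, x_p: float = 0.1, a_l: float = 0.7
) -> float:
    """Equilibrium brush height R = n_p a (a^2 X_p / A_l)^(1/3), nm."""
    if x_p <= 0:
        raise ValueError("x_p must be > 0 in the brush regime")
    return n_p * a * (a * a * x_p / a_l) ** (1.0 / 3.0)


def mean_field_free_energy(r: float, params: BrushParams) -> float:
    """Mean-field free energy of a grafted chain at layer height r, in kT.

    Elastic stretching 3 r^2 / (2 n_p a^2) plus binary monomer repulsion
    3 a^3 n_p^2 X_p / (A_l r); the analytic minimizer coincides with
    :func:`brush_height_mean_field`."""
    if r <= 0:
        raise ValueError("r must be > 0")
    p = params
    elastic = 3.0 * r * r / (2.0 * p.n_p * p.a * p.a)
    interaction = 3.0 * p.a**3 * p.n_p**2 * p.x_p / (p.a_l * r)
    return elastic + interaction


def critical_molar_fraction(
    n_p: int, a: float = 0.47, a_l: float = 0.62,
    geometry_factor: float = 1.0,
) -> float:
    """Mushroom-brush crossover X_p* = factor * A_l / (pi R0^2)."""
    r0 = r0_ideal(n_p, a)
    return geometry_factor * a_l / (math.pi * r0 * r0)


def classify_regime(
    x_p: float, n_p: int = 45, a: float = 0.47, a_l: float = 0.62,
    geometry_factor: float = 0.70, band: float = 0.30,
) -> str:
    """Map a grafting fraction to mushroom / critic / brush.

    The crossover estimate carries an O(1) geometric prefactor; the default
    factor 0.70 places the crossover at X_p* ~ 0.014 for n_p = 45 chains on
    a fluid membrane (A_l = 0.62 nm^2).  A +-``band`` window around X_p* is
    labelled critic."""
    x_c = critical_molar_fraction(n_p, a, a_l, geometry_factor)
    if x_p < (1.0 - band) * x_c:
        return "mushroom"
    if x_p > (1.0 + band) * x_c:
        return "brush"
    return "critic"


@dataclass
class ScalingHeights:
    """Scaling-only layer heights (unit prefactors, proportionalities)."""

    osmotic: float            # nm, R ~ a n_p
    pincus: float             # nm, electrostatic-stretching balance
    pincus_applicable: bool   # False for f = 1 (condensed counterions)
    note: str = "scaling-only: unit prefactors, not absolute predictions"


def scaling_heights(params: BrushParams) -> ScalingHeights:
    """Osmotic-brush and Pincus-regime heights from the scaling balances.

    Osmotic: counterion osmotic pressure vs chain elasticity, R ~ a n_p
    (independent of X_p).  Pincus: bare electrostatic stretching vs the
    good-solvent (nu = 3/5) elastic term, R ~ a n_p (l_B/a)^(2/7) f^(4/7);
    inapplicable for the strongly charged chain (f = 1), where counterion
    condensation removes the regime."""
    p = params
    osmotic = p.a * p.n_p
    pincus = (
        p.a * p.n_p * (p.l_b / p.a) ** (2.0 / 7.0) * p.f ** (4.0 / 7.0)
        if p.f > 0 else 0.0
    )
    return ScalingHeights(
        osmotic=osmotic, pincus=pincus, pincus_applicable=p.f < 1.0,
    )


def expansion_virial(
    x_p: float, n_p: int = 45, m_f: float = 1.5, coefficient: float = 1.0
) -> float:
    """Parametric membrane-expansion estimate (A_l - A_l0)/A_l0.

    Virial treatment of the lateral pressure exerted by the grafted chains:
    expansion = coefficient * X_p * n_p^m_f, with the critical exponent
    m_f selectable between the scaling and mean-field variants and the
    coefficient absorbing the (system-specific) membrane elastic response.
    Monotone increasing in X_p and zero without grafting."""
    if m_f <= 0 or x_p < 0:
        raise ValueError("m_f must be > 0 and x_p >= 0")
    return coefficient * x_p * n_p**m_f


def calibrate_expansion_coefficient(
    x_p_ref: float, expansion_ref: float, n_p: int = 45, m_f: float = 1.5
) -> float:
    """Coefficient such that expansion_virial reproduces one reference point."""
    return expansion_ref / (x_p_ref * n_p**m_f)


# -------------------------------------------------------------------------
# GLE / memory-kernel and Rouse MSD models
# -------------------------------------------------------------------------

@dataclass
class GLEParams:
    m: float = 72.0        # bead mass, Da
    t: float = 300.0       # K
    gamma: float = 0.01    # fs^-1 relaxation rate
    b: float = 0.0         # kernel amplitude (dimensionless)
    tau1: float = 1.0e5    # fs, subdiffusive -> normal crossover
    tau2: float = 1.0e3    # fs, onset of subdiffusion
    tau3: float = 1.0e2    # fs, ballistic -> subdiffusive crossover
    alpha: float = 0.5     # subdiffusion exponent

    def __post_init__(self) -> None:
        if not self.tau3 < self.tau2 < self.tau1:
            raise ValueError("require tau3 < tau2 < tau1")
        if not 0.0 < self.alpha <= 1.0:
            raise ValueError("alpha must be in (0, 1]")


def power_law_kernel(params: GLEParams) -> Callable[[np.ndarray], np.ndarray]:
    """Memory kernel: power-law t^(alpha-1) window between tau3 and tau1.

    kappa(t) = B gamma^2 (t/tau2)^(alpha-1) (1 - e^{-t/tau3}) e^{-t/tau1};
    the delta (instantaneous friction) part is carried by gamma in the GLE
    solver itself.  B = 0 switches the retarded friction off entirely."""
    p = params

    def kappa(t: np.ndarray) -> np.ndarray:
        t = np.maximum(np.asarray(t, dtype=float), 1.0e-12)
        return (
            p.b * p.gamma**2 * (t / p.tau2) ** (p.alpha - 1.0)
            * (1.0 - np.exp(-t / p.tau3)) * np.exp(-t / p.tau1)
        )

    return kappa


def gle_msd(
    params: GLEParams,
    kernel: Callable[[np.ndarray], np.ndarray] | None = None,
    t_grid: np.ndarray | None = None,
    n_internal: int = 20000,
) -> MSDSeries:
    """Numerical MSD from the memory-kernel GLE (Volterra scheme).

    Solves the VACF equation with an exponential integrator for the
    instantaneous-friction part (exact when the kernel vanishes) and
    trapezoidal quadrature for the memory integral, then integrates twice
    for the MSD and interpolates onto ``t_grid``.
    """
    p = params
    if t_grid is None:
        t_grid = np.logspace(0, 5, 200)
    t_grid = np.asarray(t_grid, dtype=float)
    if not np.all(np.diff(t_grid) > 0):
        raise ValueError("t_grid must be strictly increasing")
    if kernel is None:
        kernel = power_law_kernel(p)
    t_max = float(t_grid[-1])
    h = t_max / n_internal
    if p.gamma * h > 50.0:
        raise ValueError("step too large vs gamma; refine n_internal")
    tt = np.arange(n_internal + 1) * h
    c0 = 3.0 * KB * p.t * FORCE_TO_ACC / p.m  # (A/fs)^2
    c = np.zeros(n_internal + 1)
    c[0] = c0
    kvals = kernel(tt)
    kvals[0] = 0.0  # delta part is carried by gamma
    decay = math.exp(-p.gamma * h)
    has_memory = bool(np.any(kvals != 0.0))
    # trapezoidal Volterra scheme with exact integration of the gamma part:
    # C_{n+1} = e^{-gh} C_n - (h/2)[e^{-gh} I_n + I_{n+1}], where
    # I_m = int_0^{t_m} kappa(t_m - s) C(s) ds (trapezoid; the unknown
    # C_{n+1} enters I_{n+1} with weight kappa(0) = 0)
    i_prev = 0.0
    for n in range(n_internal):
        if has_memory:
            w = kvals[n + 1 :: -1] * c[: n + 2]
            i_next = h * (0.5 * (w[0] + w[-1]) + w[1:-1].sum())
        else:
            i_next = 0.0
        c[n + 1] = decay * c[n] - 0.5 * h * (decay * i_prev + i_next)
        i_prev = i_next
        if not math.isfinite(c[n + 1]) or abs(c[n + 1]) > 1.0e3 * c0:
            raise ValueError(
                "non-convergent quadrature: internal step too large for "
                "this kernel/gamma; increase n_internal or shrink t_grid"
            )
    # MSD = 2 int_0^t (t - s) C(s) ds computed as a double cumulative
    # integral; Simpson keeps the short-time (ballistic) branch accurate
    from scipy.integrate import cumulative_simpson

    a1 = cumulative_simpson(c, x=tt, initial=0.0)
    msd_int = 2.0 * cumulative_simpson(a1, x=tt, initial=0.0)
    # interpolate MSD/t^2, which is smooth on the kernel/friction time
    # scales rather than on the scale of t itself (keeps the short-time
    # ballistic branch accurate on log-spaced request grids)
    q = np.empty_like(msd_int)
    q[0] = c0  # lim t->0 MSD/t^2 = C(0)
    q[1:] = msd_int[1:] / tt[1:] ** 2
    out = np.interp(t_grid, tt, q) * t_grid**2
    return MSDSeries(lag=t_grid, msd=out, dims=3, n_origins=0, group="gle")


def langevin_msd_closed_form(
    t: np.ndarray, m: float = 72.0, temp: float = 300.0, gamma: float = 0.01
) -> np.ndarray:
    """MSD(t) = (6 kT / m gamma)(t - (1 - e^{-gamma t})/gamma), A^2."""
    t = np.asarray(t, dtype=float)
    pref = 6.0 * KB * temp * FORCE_TO_ACC / (m * gamma)
    return pref * (t - (1.0 - np.exp(-gamma * t)) / gamma)


@dataclass
class RouseParams:
    k: float               # entropic spring constant, kcal/(mol A^2)
    xi: float              # friction coefficient, Da/fs
    tau: float             # crossover time, fs
    d: int = 3             # dimensionality
    dcoef: float = 1.0e-6  # long-time diffusion coefficient, A^2/fs

    def __post_init__(self) -> None:
        if min(self.k, self.xi, self.tau, self.dcoef) <= 0 or self.d < 1:
            raise ValueError("RouseParams fields must be positive")

    @classmethod
    def from_temperature(
        cls, sigma: float = 4.7, temp: float = 300.0, xi: float = 0.72,
        tau: float = 1.0e5, d: int = 3,
    ) -> "RouseParams":
        """k = 3 kT / sigma^2 entropic spring; D = kT/xi (A^2/fs with xi in
        Da/fs after the unit conversion)."""
        k = 3.0 * KB * temp / sigma**2
        dcoef = KB * temp * FORCE_TO_ACC / xi
        return cls(k=k, xi=xi, tau=tau, d=d, dcoef=dcoef)


def rouse_msd(params: RouseParams, t_grid: np.ndarray) -> MSDSeries:
    """Piecewise Rouse monomer MSD: ~ t^(1/2) below the chain relaxation
    time tau, normal diffusion 2 d D t above, continuous at tau."""
    t = np.asarray(t_grid, dtype=float)
    if np.any(t <= 0):
        raise ValueError("t_grid must be positive")
    p = params
    amp = 2.0 * p.d * p.dcoef * math.sqrt(p.tau)  # continuity at tau
    out = np.where(t < p.tau, amp * np.sqrt(t), 2.0 * p.d * p.dcoef * t)
    return MSDSeries(lag=t, msd=out, dims=p.d, n_origins=0, group="rouse")
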