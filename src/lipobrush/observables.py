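"""Structural and dynamic observables measured on trajectories.

Implements the measurements used to characterize the grafted-bilayer
system: z-density profiles and the thicknesses derived from them (chitosan
layer L_DM, bilayer head-head thickness D_B, hydrocarbon FWHM thickness
D_HH), area per lipid and membrane expansion, radial distribution
functions, and multiple-time-origin mean-square displacements with
piecewise power-law fits yielding the anomalous exponent alpha and the
generalized diffusion coefficient D_alpha.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .system import Trajectory
from .units import CM2_PER_A2, FS_PER_S


# -------------------------------------------------------------------------
# density profiles and thicknesses
# -------------------------------------------------------------------------

@dataclass
class DensityProfile:
    """Frame-averaged number density along z, centered on the box midplane."""

    z: np.ndarray          # bin centers, nm (z = 0 is the box midplane)
    density: np.ndarray    # nm^-3
    bin_width: float       # nm
    frames: int
    area: float            # mean lateral area, nm^2

    def reduced(self) -> np.ndarray:
        """Density normalized to a maximum of one."""
        m = self.density.max()
        return self.density / m if m > 0 else self.density

    def integral(self) -> float:
        """Mean bead count: integral of density x bin x area."""
        return float(self.density.sum() * self.bin_width * self.area)


def density_profile(
    traj: Trajectory, mask: np.ndarray, bin_width: float = 0.1,
) -> DensityProfile:
    """Histogram of the masked beads' z coordinates, averaged over frames.

    z is measured from the box midplane (wrapped into [-Lz/2, Lz/2)); the
    density is in beads/nm^3 so that integral x area recovers the group
    size.
    """
    if len(traj) == 0:
        raise ValueError("empty trajectory")
    if not mask.any():
        raise ValueError("empty bead group")
    lz_max = max(float(f.box[2]) for f in traj.frames) / 10.0  # nm
    nbins = max(int(np.ceil(lz_max / bin_width)), 1)
    edges = (np.arange(nbins + 1) - nbins / 2.0) * bin_width
    counts = np.zeros(nbins)
    areas = []
    for f in traj.frames:
        lz = float(f.box[2]) / 10.0
        # measure z from the box midplane, wrapped into [-Lz/2, Lz/2)
        z = f.positions[mask, 2] / 10.0
        z = np.mod(z, lz) - lz / 2.0
        h, _ = np.histogram(z, bins=edges)
        counts += h
        areas.append(float(f.box[0] * f.box[1]) / 100.0)
    area = float(np.mean(areas))
    density = counts / (len(traj) * bin_width * area)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return DensityProfile(centers, density, bin_width, len(traj), area)


def _refine_peak(z: np.ndarray, y: np.ndarray, i: int) -> float:
    """Quadratic (three-point) refinement of a local maximum position."""
    if i == 0 or i == len(y) - 1:
        return float(z[i])
    denom = y[i - 1] - 2.0 * y[i] + y[i + 1]
    if denom >= 0:
        return float(z[i])
    delta = 0.5 * (y[i - 1] - y[i + 1]) / denom
    return float(z[i] + delta * (z[1] - z[0]))


def find_peaks(
    profile: DensityProfile, min_height_frac: float = 0.2
) -> list[tuple[float, float]]:
    """(position, height) of local maxima above a fraction of the global max."""
    y = profile.density
    z = profile.z
    thresh = min_height_frac * y.max()
    out = []
    for i in range(1, len(y) - 1):
        if y[i] >= y[i - 1] and y[i] > y[i + 1] and y[i] >= thresh:
            out.append((_refine_peak(z, y, i), float(y[i])))
    return out


@dataclass
class LayerThickness:
    gap_half: float            # nm, L_DM = d/2 from the facing head planes
    extent: float | None       # nm, grafting plane to 5% density threshold
    grafting_planes: tuple[float, float]  # nm, inner head-peak positions


def chitosan_layer(
    chitosan_profile: DensityProfile,
    qa_profile: DensityProfile,
    threshold: float = 0.05,
) -> LayerThickness:
    """Chitosan layer thickness from an opposed-bilayer density profile.

    ``gap_half``: half the distance d between the two grafting-surface
    planes, taken as the phosphate (Qa) density peaks facing the midplane.
    ``extent``: mean distance from each grafting plane to where the
    chitosan density first falls below ``threshold`` of its maximum,
    marching toward the midplane and beyond.
    """
    peaks = find_peaks(qa_profile)
    below = [(p, h) for p, h in peaks if p < 0]
    above = [(p, h) for p, h in peaks if p > 0]
    if not below or not above:
        raise ValueError("cannot identify the two grafting planes")
    z_lo = max(below, key=lambda t: t[1])[0]  # strongest peak per side
    z_hi = max(above, key=lambda t: t[1])[0]
    gap_half = 0.5 * (z_hi - z_lo)

    y = chitosan_profile.density
    z = chitosan_profile.z
    extent = None
    if y.max() > 0:
        level = threshold * y.max()
        mid = 0.5 * (z_lo + z_hi)
        ext = []
        # march from each grafting plane toward the midplane; the extent is
        # the distance to the last above-threshold bin before the density
        # first drops below the level (capped at the midplane: when the
        # two layers meet, each extends to gap_half)
        for zp, zstop, direction in ((z_lo, mid, 1), (z_hi, mid, -1)):
            sel = (direction * (z - zp) > 0) & (direction * (z - zstop) < 0)
            zi, yi = z[sel], y[sel]
            order = np.argsort(direction * (zi - zp))
            started = False
            last = None
            for k in order:
                if yi[k] >= level:
                    started = True
                    last = zi[k]
                elif started:
                    break
            if last is not None:
                ext.append(abs(last - zp))
        if ext:
            extent = float(np.mean(ext))
    return LayerThickness(float(gap_half), extent, (float(z_lo), float(z_hi)))


def bilayer_thickness(q0_profile: DensityProfile) -> float:
    """Head-head bilayer thickness D_B: distance between the two Q0
    density maxima (quadratic peak refinement), nm.

    The profile must cover a single bilayer (select one bilayer's Q0 beads
    before histogramming)."""
    peaks = find_peaks(q0_profile)
    if len(peaks) < 2:
        raise ValueError("need two resolvable Q0 peaks")
    peaks.sort(key=lambda p: -p[1])
    (z1, _), (z2, _) = peaks[:2]
    return abs(z2 - z1)


def hydrocarbon_thickness(c1_profile: DensityProfile) -> float:
    """Hydrocarbon thickness D_HH: FWHM of the (merged) tail-bead peak, nm."""
    y = c1_profile.density
    z = c1_profile.z
    imax = int(np.argmax(y))
    half = 0.5 * y[imax]

    def cross(side: int) -> float:
        i = imax
        while 0 < i < len(y) - 1 and y[i] > half:
            i += side
        if y[i] > half:
            raise ValueError("hydrocarbon peak cannot be bracketed")
        # linear interpolation between bins i and i-side
        y0, y1 = y[i - side], y[i]
        z0, z1 = z[i - side], z[i]
        return z0 + (half - y0) * (z1 - z0) / (y1 - y0)

    return abs(cross(+1) - cross(-1))


def area_per_lipid(box, n_lipids_per_leaflet: int) -> float:
    """A_l = Lx Ly / (lipids per leaflet), nm^2 (box in angstrom)."""
    return float(box[0] * box[1]) / 100.0 / n_lipids_per_leaflet


def expansion(a_l: float, a_l0: float) -> float:
    """Relative membrane expansion (A_l - A_l0) / A_l0."""
    return (a_l - a_l0) / a_l0


# -------------------------------------------------------------------------
# radial distribution function
# -------------------------------------------------------------------------

@dataclass
class RDFCurve:
    r: np.ndarray         # bin centers, A
    g: np.ndarray         # dimensionless
    dr: float
    r_max: float
    n_frames: int

    def first_peak(self) -> tuple[float, float]:
        """Position and height of the first local maximum above g = 1."""
        y = self.g
        for i in range(1, len(y) - 1):
            if y[i] >= y[i - 1] and y[i] > y[i + 1] and y[i] > 1.0:
                return _refine_peak(self.r, y, i), float(y[i])
        i = int(np.argmax(y))
        return float(self.r[i]), float(y[i])


def rdf(
    traj: Trajectory,
    mask_a: np.ndarray,
    mask_b: np.ndarray | None = None,
    dr: float = 0.2,
    r_max: float = 12.0,
    every: int = 1,
) -> RDFCurve:
    """Radial distribution function g(r) with minimum-image convention and
    ideal-gas normalization rho = N/V.

    Intra-molecular (bonded) pairs are deliberately included: the bonded
    4.7-5.2 A shell is part of the measured local structure.  ``r_max``
    must not exceed half the smallest box length.
    """
    mask_b = mask_a if mask_b is None else mask_b
    same = mask_b is mask_a or bool(np.array_equal(mask_a, mask_b))
    frames = traj.frames[::every]
    if not frames:
        raise ValueError("empty trajectory")
    box0 = frames[0].box
    if r_max > 0.5 * float(min(box0)):
        raise ValueError("r_max exceeds half the smallest box length")
    nbins = int(np.ceil(r_max / dr))
    edges = np.arange(nbins + 1) * dr
    hist = np.zeros(nbins)
    norm = 0.0
    for f in frames:
        vol = float(np.prod(f.box))
        pos = np.mod(f.positions, f.box)
        if same:
            pa = pos[mask_a]
            tree = cKDTree(pa, boxsize=f.box)
            pairs = tree.query_pairs(r_max, output_type="ndarray")
            if len(pairs):
                d = pa[pairs[:, 0]] - pa[pairs[:, 1]]
                d -= np.rint(d / f.box) * f.box
                r = np.linalg.norm(d, axis=1)
                h, _ = np.histogram(r, bins=edges)
                hist += h
            n = len(pa)
            norm += n * (n - 1) / 2.0 / vol
        else:
            pa, pb = pos[mask_a], pos[mask_b]
            tree = cKDTree(pb, boxsize=f.box)
            for i, p in enumerate(pa):
                idx = tree.query_ball_point(p, r_max)
                if not idx:
                    continue
                d = pb[idx] - p
                d -= np.rint(d / f.box) * f.box
                r = np.linalg.norm(d, axis=1)
                r = r[r > 1e-9]  # drop self if the groups overlap
                h, _ = np.histogram(r, bins=edges)
                hist += h
            norm += len(pa) * len(pb) / vol
    shell = 4.0 / 3.0 * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
    ideal = shell * norm
    g = np.divide(hist, ideal, out=np.zeros_like(hist), where=ideal > 0)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return RDFCurve(centers, g, dr, r_max, len(frames))


# -------------------------------------------------------------------------
# mean-square displacement and diffusion
# -------------------------------------------------------------------------

@dataclass
class MSDSeries:
    lag: np.ndarray        # fs
    msd: np.ndarray        # A^2
    dims: int              # 2 (xy) or 3
    n_origins: int
    group: str = ""


def msd(
    traj: Trajectory,
    mask: np.ndarray,
    dims: int = 3,
    mol_ids: np.ndarray | None = None,
    max_lag_frac: float = 0.9,
) -> MSDSeries:
    """Multiple-time-origin MSD of a bead group (or molecule centers).

    ``dims = 2`` ignores the z component (lateral lipid diffusion);
    ``dims = 3`` is the full displacement.  When ``mol_ids`` is given the
    MSD is computed over molecular centers of mass (equal bead masses
    assumed within the selection).  Requires frames with image flags
    (unwrapped coordinates).
    """
    if len(traj) < 2:
        raise ValueError("need at least two frames")
    coords = np.array([f.unwrapped()[mask] for f in traj.frames])
    if mol_ids is not None:
        ids = mol_ids[mask] if len(mol_ids) != coords.shape[1] else mol_ids
        uniq = np.unique(ids)
        com = np.zeros((coords.shape[0], len(uniq), 3))
        for k, u in enumerate(uniq):
            com[:, k] = coords[:, ids == u].mean(axis=1)
        coords = com
    if dims == 2:
        coords = coords[:, :, :2]
    times = traj.times()
    nt = len(times)
    max_lag = max(int(nt * max_lag_frac), 1)
    lags = np.arange(max_lag + 1)
    out = np.zeros(len(lags))
    for k in lags[1:]:
        disp = coords[k:] - coords[:-k]
        out[k] = float((disp**2).sum(axis=2).mean())
    dt = float(times[1] - times[0])
    return MSDSeries(lags * dt, out, dims, n_origins=nt - 1)


@dataclass
class DiffusionFit:
    window: tuple[float, float]   # fs
    alpha: float
    d_alpha: float                # cm^2 s^-alpha
    r_squared: float
    n_points: int


def fit_diffusion(
    series: MSDSeries, windows: list[tuple[float, float]]
) -> list[DiffusionFit]:
    """Power-law fits MSD ~ t^alpha per lag window.

    alpha is the least-squares slope in log10-log10 space; the generalized
    diffusion coefficient D_alpha = MSD / (2 d t^alpha), averaged over the
    window, converted from A^2/fs^alpha to cm^2 s^-alpha.
    """
    fits = []
    prev_end = -np.inf
    for t_lo, t_hi in windows:
        if t_lo < prev_end:
            raise ValueError("fit windows must not overlap")
        prev_end = t_hi
        sel = (series.lag >= t_lo) & (series.lag <= t_hi) & (series.lag > 0)
        sel &= series.msd > 0
        if sel.sum() < 5:
            raise ValueError(
                f"window [{t_lo}, {t_hi}] fs holds fewer than 5 points"
            )
        lt = np.log10(series.lag[sel])
        lm = np.log10(series.msd[sel])
        slope, intercept = np.polyfit(lt, lm, 1)
        pred = slope * lt + intercept
        ss_res = float(((lm - pred) ** 2).sum())
        ss_tot = float(((lm - lm.mean()) ** 2).sum())
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
        alpha = float(slope)
        d_alpha = float(np.mean(
            series.msd[sel] / (2.0 * series.dims * series.lag[sel] ** alpha)
        ))
        d_alpha *= CM2_PER_A2 * FS_PER_S**alpha
        fits.append(DiffusionFit(
            (float(t_lo), float(t_hi)), alpha, d_alpha, r2, int(sel.sum())
        ))
    return fits
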