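"""Density profiles, thicknesses, RDF, MSD and diffusion fits."""

import numpy as np
import pytest

from lipobrush.observables import (
    DensityProfile, MSDSeries, area_per_lipid, bilayer_thickness,
    chitosan_layer, density_profile, expansion, fit_diffusion,
    hydrocarbon_thickness, msd, rdf,
)
from lipobrush.system import Frame, Trajectory


def make_traj(list_of_positions, box, with_images=True, dt=100.0):
    traj = Trajectory()
    box = np.asarray(box, dtype=float)
    for k, pos in enumerate(list_of_positions):
        pos = np.asarray(pos, dtype=float)
        images = np.floor(pos / box).astype(np.int64)
        traj.frames.append(Frame(
            time=k * dt, step=k, box=box.copy(),
            positions=pos - images * box,
            images=images if with_images else None,
        ))
    return traj


def gaussian_profile(centers, sigma, lz=30.0, bins=300, weight=1.0):
    z = (np.arange(bins) + 0.5) * (lz / bins) - lz / 2
    y = np.zeros_like(z)
    for c in np.atleast_1d(centers):
        y += weight * np.exp(-0.5 * ((z - c) / sigma) ** 2)
    return DensityProfile(z, y, lz / bins, 1, 100.0)


class TestDensityProfile:
    def test_uniform_gas_flat(self):
        rng = np.random.default_rng(1)
        box = [50.0, 50.0, 80.0]
        frames = [rng.uniform(0, box, (4000, 3)) for _ in range(10)]
        traj = make_traj(frames, box)
        prof = density_profile(traj, np.ones(4000, dtype=bool), 0.4)
        mean = prof.density.mean()
        assert prof.density.std() / mean < 0.15
        rho = 4000 / (5.0 * 5.0 * 8.0)  # nm^-3
        assert mean == pytest.approx(rho, rel=0.05)

    def test_mass_conservation(self):
        rng = np.random.default_rng(2)
        box = [40.0, 40.0, 60.0]
        traj = make_traj([rng.uniform(0, box, (500, 3))], box)
        prof = density_profile(traj, np.ones(500, dtype=bool), 0.1)
        assert prof.integral() == pytest.approx(500.0, rel=1e-9)

    def test_two_slab_fixture(self):
        """Constructed two-slab input shows rectangular peaks in place."""
        rng = np.random.default_rng(3)
        box = np.array([30.0, 30.0, 100.0])
        n = 3000
        z1 = rng.uniform(20.0, 30.0, n // 2)   # abs slabs at 20-30, 70-80 A
        z2 = rng.uniform(70.0, 80.0, n // 2)
        pos = np.zeros((n, 3))
        pos[:, 0] = rng.uniform(0, 30, n)
        pos[:, 1] = rng.uniform(0, 30, n)
        pos[:, 2] = np.concatenate([z1, z2])
        traj = make_traj([pos], box)
        prof = density_profile(traj, np.ones(n, dtype=bool), 0.2)
        # slabs in midplane coordinates: [-3, -2] and [2, 3] nm
        inside = ((prof.z > -2.9) & (prof.z < -2.1)) | (
            (prof.z > 2.1) & (prof.z < 2.9))
        outside = (prof.z < -3.3) | ((prof.z > -1.7) & (prof.z < 1.7)) | (
            prof.z > 3.3)
        assert prof.density[inside].min() > 0
        assert prof.density[outside].max() == 0

    def test_empty_group_rejected(self):
        traj = make_traj([np.ones((5, 3))], [10.0, 10, 10])
        with pytest.raises(ValueError, match="empty bead group"):
            density_profile(traj, np.zeros(5, dtype=bool))


class TestThicknesses:
    def test_gap_half_from_synthetic_planes(self):
        qa = gaussian_profile([-5.0, 5.0], 0.15)
        ch = gaussian_profile([0.0], 2.0)
        layer = chitosan_layer(ch, qa)
        assert layer.gap_half == pytest.approx(5.0, abs=0.05)

    def test_extent_full_gap_occupancy(self):
        """Layers meeting at the midplane: extent equals gap_half."""
        qa = gaussian_profile([-5.0, 5.0], 0.15)
        z = qa.z
        y = np.where(np.abs(z) < 4.99, 1.0, 0.0)
        ch = DensityProfile(z, y, qa.bin_width, 1, 100.0)
        layer = chitosan_layer(ch, qa)
        assert layer.extent == pytest.approx(5.0, abs=0.3)

    def test_extent_two_separated_layers(self):
        """Two layers hugging their grafting planes: extent is each
        layer's own reach, not the full gap."""
        qa = gaussian_profile([-5.0, 5.0], 0.15)
        z = qa.z
        y = np.where((np.abs(z) > 2.0) & (np.abs(z) < 5.0), 1.0, 0.0)
        ch = DensityProfile(z, y, qa.bin_width, 1, 100.0)
        layer = chitosan_layer(ch, qa)
        assert layer.extent == pytest.approx(3.0, abs=0.3)

    def test_unidentifiable_planes(self):
        qa = gaussian_profile([3.0], 0.2)   # single peak only
        ch = gaussian_profile([0.0], 1.0)
        with pytest.raises(ValueError, match="grafting planes"):
            chitosan_layer(ch, qa)

    def test_bilayer_thickness_two_gaussians(self):
        prof = gaussian_profile([-2.05, 2.05], 0.3)
        assert bilayer_thickness(prof) == pytest.approx(4.1, abs=0.02)

    def test_bilayer_thickness_bin_insensitive(self):
        for bins in (300, 400, 600):
            prof = gaussian_profile([-2.05, 2.05], 0.3, bins=bins)
            assert bilayer_thickness(prof) == pytest.approx(4.1, abs=0.02)

    def test_fwhm_gaussian(self):
        prof = gaussian_profile([0.0], 1.0)
        assert hydrocarbon_thickness(prof) == pytest.approx(2.3548, abs=0.02)

    def test_fwhm_rectangle(self):
        z = np.linspace(-10, 10, 400)
        y = np.where(np.abs(z) < 1.5, 1.0, 0.0)
        prof = DensityProfile(z, y, z[1] - z[0], 1, 100.0)
        assert hydrocarbon_thickness(prof) == pytest.approx(3.0, abs=0.1)


class TestArea:
    def test_arithmetic(self):
        assert area_per_lipid([108.5, 108.5, 200.0], 196) == pytest.approx(
            0.6005, abs=1e-3)

    def test_expansion(self):
        assert expansion(0.66, 0.6) == pytest.approx(0.1)
        assert expansion(0.6, 0.6) == 0.0


class TestRDF:
    def test_ideal_gas_unity(self):
        rng = np.random.default_rng(5)
        box = [40.0, 40.0, 40.0]
        frames = [rng.uniform(0, 40.0, (600, 3)) for _ in range(20)]
        traj = make_traj(frames, box)
        curve = rdf(traj, np.ones(600, dtype=bool), dr=0.5, r_max=15.0)
        tail = curve.g[curve.r > 4.0]
        assert np.abs(tail - 1.0).max() < 0.15

    def test_fixed_pair_spike(self):
        box = [40.0, 40.0, 40.0]
        pos = np.array([[10.0, 10, 10], [16.0, 10, 10]])
        traj = make_traj([pos], box)
        curve = rdf(traj, np.ones(2, dtype=bool), dr=0.2, r_max=10.0)
        k = int(np.argmax(curve.g))
        assert abs(curve.r[k] - 6.0) <= 0.2
        assert (curve.g > 0).sum() == 1

    def test_simple_cubic_lattice_shells(self):
        """A perfect cubic crystal shows its analytic neighbor shells."""
        a = 5.0
        grid = np.array(np.meshgrid(*[np.arange(8)] * 3,
                                    indexing="ij")).reshape(3, -1).T * a
        box = [40.0, 40.0, 40.0]
        traj = make_traj([grid + 2.5], box)
        curve = rdf(traj, np.ones(len(grid), dtype=bool), dr=0.1, r_max=14.0)
        peaks = curve.r[curve.g > 1.0]
        # shells at a, a sqrt2, a sqrt3, 2a ...
        for shell in (a, a * np.sqrt(2), a * np.sqrt(3), 2 * a):
            assert np.min(np.abs(peaks - shell)) < 0.15

    def test_r_max_beyond_half_box_rejected(self):
        traj = make_traj([np.ones((4, 3)) * 5], [20.0, 20, 20])
        with pytest.raises(ValueError, match="half the smallest box"):
            rdf(traj, np.ones(4, dtype=bool), r_max=11.0)


class TestMSD:
    def test_stationary_zero(self):
        pos = np.ones((5, 3)) * 8.0
        traj = make_traj([pos] * 10, [20.0, 20, 20])
        series = msd(traj, np.ones(5, dtype=bool))
        assert np.allclose(series.msd, 0.0)

    def test_ballistic_law(self):
        """Constant velocity: MSD = (v t)^2, across periodic wrapping."""
        v = np.array([0.03, 0.0, 0.01])
        frames = [np.array([[5.0, 5, 5] + v * (100.0 * k)])
                  for k in range(30)]
        traj = make_traj(frames, [20.0, 20, 20])
        series = msd(traj, np.ones(1, dtype=bool), dims=3)
        expected = (np.linalg.norm(v) * series.lag) ** 2
        assert np.allclose(series.msd, expected, rtol=1e-10)

    def test_dims2_ignores_z(self):
        v = np.array([0.0, 0.0, 0.05])
        frames = [np.array([[5.0, 5, 5] + v * (100.0 * k)])
                  for k in range(20)]
        traj = make_traj(frames, [20.0, 20, 20])
        series = msd(traj, np.ones(1, dtype=bool), dims=2)
        assert np.allclose(series.msd, 0.0)

    def test_multi_origin_equals_single_origin_for_linear_motion(self):
        v = np.array([0.02, -0.01, 0.0])
        frames = [np.array([[5.0, 5, 5] + v * (100.0 * k)])
                  for k in range(25)]
        traj = make_traj(frames, [30.0, 30, 30])
        series = msd(traj, np.ones(1, dtype=bool), dims=3)
        start = frames[0][0]
        single = np.array([
            ((frames[k][0] - start) ** 2).sum()
            for k in range(len(series.lag))
        ])
        assert np.allclose(series.msd, single, rtol=1e-9)

    def test_wrapped_only_trajectory_rejected(self):
        frames = [np.ones((3, 3)) * k for k in range(5)]
        traj = make_traj(frames, [20.0, 20, 20], with_images=False)
        with pytest.raises(ValueError, match="unwrap"):
            msd(traj, np.ones(3, dtype=bool))

    def test_free_langevin_gas_long_time_slope(self, tables):
        """Long-time MSD slope of a free Langevin gas is 2 d kT/(m gamma)."""
        from lipobrush.dynamics import Integrator, IntegratorConfig
        from lipobrush.units import FORCE_TO_ACC, KB
        from conftest import make_topology

        n = 400
        top = make_topology(n)
        rng = np.random.default_rng(8)
        state_pos = rng.uniform(0, 600, (n, 3))
        from lipobrush.system import SimState

        state = SimState.from_positions(state_pos, [600.0] * 3)
        cfg = IntegratorConfig(dt=10.0, t_target=300.0, damp=100.0, seed=12)
        it = Integrator(top, tables, cfg, thermostat=True)
        traj = Trajectory()
        for k in range(600):
            it.step(state)
            if k % 10 == 0:
                traj.frames.append(Frame(state.time, k, state.box.copy(),
                                         state.positions.copy(),
                                         state.images.copy()))
        series = msd(traj, np.ones(n, dtype=bool), dims=3)
        d_expected = KB * 300.0 * FORCE_TO_ACC / (72.0 * 0.01)  # kT/(m gamma)
        sel = series.lag > 2000.0  # >> damp
        slope = np.polyfit(series.lag[sel], series.msd[sel], 1)[0]
        assert slope == pytest.approx(6.0 * d_expected, rel=0.15)


class TestDiffusionFit:
    def test_exact_normal_diffusion(self):
        t = np.linspace(0.0, 1e6, 200)
        d_cm2 = 1e-6
        d_a2fs = d_cm2 / 0.1  # cm^2/s -> A^2/fs
        series = MSDSeries(t, 6 * d_a2fs * t, dims=3, n_origins=1)
        fit = fit_diffusion(series, [(1e4, 1e6)])[0]
        assert fit.alpha == pytest.approx(1.0, abs=1e-9)
        assert fit.d_alpha == pytest.approx(1e-6, rel=1e-6)

    @pytest.mark.parametrize("alpha", [0.3, 0.6, 1.0])
    def test_power_law_recovery_three_digits(self, alpha):
        t = np.logspace(2, 6, 300)
        series = MSDSeries(t, 0.37 * t**alpha, dims=3, n_origins=1)
        fit = fit_diffusion(series, [(1e2, 1e6)])[0]
        assert fit.alpha == pytest.approx(alpha, abs=5e-4)
        d_expected = 0.37 / 6.0 * 1e-16 * (1e15) ** alpha
        assert fit.d_alpha == pytest.approx(d_expected, rel=1e-3)

    def test_overlapping_windows_rejected(self):
        t = np.linspace(0, 1e4, 50)
        series = MSDSeries(t, t + 1.0, dims=3, n_origins=1)
        with pytest.raises(ValueError, match="overlap"):
            fit_diffusion(series, [(0, 5e3), (4e3, 1e4)])

    def test_sparse_window_rejected(self):
        t = np.linspace(0, 1e4, 50)
        series = MSDSeries(t, t + 1.0, dims=3, n_origins=1)
        with pytest.raises(ValueError, match="fewer than 5"):
            fit_diffusion(series, [(9.9e3, 1e4)])
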