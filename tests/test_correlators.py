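"""Density correlators: SISF, radial van Hove, MSD, g(r), peak-height curve."""

import numpy as np
import pytest

from conftest import per_particle_se
from hydroshell import (
    GeneratorConfig,
    Trajectory,
    compute_msd,
    compute_rdf,
    compute_sisf,
    compute_svhf,
    generate,
    select_hydration_shell,
    svhf_peak_height_curve,
)
from hydroshell.correlators import log_lag_grid
from hydroshell.trajectory import TrajectoryUsageError


class TestSisf:
    def test_static_particles_give_unity(self, static_traj):
        c = compute_sisf(static_traj.unwrapped(), Q=22.5)
        assert np.allclose(c.values, 1.0)

    def test_free_diffusion_matches_gaussian_decay(self, free_traj):
        D, Q = 0.01, 2.0
        cont = free_traj.unwrapped()
        lags = np.array([1.0, 5.0, 20.0])
        c = compute_sisf(cont, Q=Q, lag_grid=lags, origin_stride=3, max_origins=500)
        for i, lag in enumerate(lags):
            lf = int(round(lag / 0.1))
            origins = np.arange(0, cont.n_frames - lf, 3)[:500]
            d = cont.coords[origins + lf] - cont.coords[origins]
            kern = np.sinc(Q * np.linalg.norm(d, axis=-1) / np.pi)
            se = per_particle_se(kern)
            assert abs(c.values[i] - np.exp(-(Q**2) * D * lag)) <= 3 * se

    def test_caged_plateau_matches_gaussian_confinement(self, caged_traj):
        sigma, Q = 0.0224, 22.5
        c = compute_sisf(
            caged_traj.unwrapped(), Q=Q, lag_grid=np.array([100.0]),
            origin_stride=5, max_origins=400,
        )
        assert c.values[0] == pytest.approx(np.exp(-(Q * sigma) ** 2), rel=0.01)

    def test_wrapped_input_rejected(self, free_traj):
        with pytest.raises(TrajectoryUsageError, match="continuous"):
            compute_sisf(free_traj, Q=1.0)

    def test_lag_grid_must_snap_to_frames(self, free_traj):
        with pytest.raises(TrajectoryUsageError, match="multiples"):
            compute_sisf(free_traj.unwrapped(), Q=1.0, lag_grid=np.array([0.1234]))


class TestMsd:
    def test_free_diffusion_is_6dt(self, free_traj):
        D = 0.01
        cont = free_traj.unwrapped()
        lags = np.array([1.0, 10.0, 50.0])
        c = compute_msd(cont, lag_grid=lags, origin_stride=3, max_origins=500)
        for i, lag in enumerate(lags):
            lf = int(round(lag / 0.1))
            origins = np.arange(0, cont.n_frames - lf, 3)[:500]
            d = cont.coords[origins + lf] - cont.coords[origins]
            sq = np.sum(d * d, axis=-1)
            assert abs(c.values[i] - 6 * D * lag) <= 3 * per_particle_se(sq)

    def test_lag_grid_excludes_zero(self, free_traj):
        c = compute_msd(free_traj.unwrapped())
        assert c.lags[0] > 0

    def test_counts_recorded_per_lag(self, free_traj):
        c = compute_msd(free_traj.unwrapped(), origin_stride=10, max_origins=50)
        assert np.all(c.counts > 0)


class TestSvhf:
    def test_density_normalizes_to_one(self, free_traj):
        d = compute_svhf(free_traj.unwrapped(), lag=5.0, bin_width=0.02, r_max=3.0)
        assert np.sum(d.density) * d.bin_width == pytest.approx(1.0, abs=1e-6)

    def test_normalization_survives_bin_refinement(self, free_traj):
        cont = free_traj.unwrapped()
        coarse = compute_svhf(cont, lag=5.0, bin_width=0.04, r_max=3.0)
        fine = compute_svhf(cont, lag=5.0, bin_width=0.02, r_max=3.0)
        assert np.sum(fine.density) * fine.bin_width == pytest.approx(1.0, abs=1e-6)
        assert abs(coarse.peak_position() - fine.peak_position()) <= 0.04

    def test_free_diffusion_mode_at_2_sqrt_dt(self, free_traj):
        D, lag = 0.01, 10.0
        d = compute_svhf(free_traj.unwrapped(), lag=lag, bin_width=0.02, r_max=3.0)
        assert d.refined_peak_position() == pytest.approx(2 * np.sqrt(D * lag), abs=0.02)

    def test_overflow_warning_names_fraction(self, free_traj):
        with pytest.warns(UserWarning, match="beyond r_max"):
            compute_svhf(free_traj.unwrapped(), lag=50.0, bin_width=0.02, r_max=0.5)

    def test_origin_stride_invariance(self, free_traj):
        cont = free_traj.unwrapped()
        a = compute_svhf(cont, lag=5.0, bin_width=0.05, r_max=3.0, origin_stride=1)
        b = compute_svhf(cont, lag=5.0, bin_width=0.05, r_max=3.0, origin_stride=2)
        # halving the origins changes the density far less than its own scale
        assert np.max(np.abs(a.density - b.density)) < 0.1 * a.peak_height()


class TestMembershipConventions:
    def _tiny(self):
        # one protein at the centre; one water drifting out of the shell
        L = 5.0
        n_frames = 4
        coords = np.zeros((n_frames, 2, 3))
        coords[:, 0] = [2.5, 2.5, 2.5]
        for f, dist in enumerate([0.3, 0.45, 0.55, 0.75]):
            coords[f, 1] = [2.5 + dist, 2.5, 2.5]
        classes = np.array(["protein", "water-oxygen"], dtype=object)
        return Trajectory(coords, np.arange(n_frames) * 1.0, L, classes)

    @pytest.mark.parametrize(
        "convention,expected_counts",
        [("origin", 3), ("both_ends", 2), ("continuous", 2)],
    )
    def test_admitted_pairs_per_convention(self, convention, expected_counts):
        traj = self._tiny()
        m = select_hydration_shell(traj, cutoff=0.6, convention=convention)
        cont = traj.unwrapped()
        c = compute_msd(cont, membership=m, lag_grid=np.array([1.0]))
        # member at frames 0,1,2 (distances 0.3,0.45,0.6) but not 3 (0.75);
        # origin: origins 0,1,2; both_ends/continuous: origins 0,1
        assert c.counts[0] == expected_counts

    def test_all_gap_lags_reported_as_nan(self):
        traj = self._tiny()
        m = select_hydration_shell(traj, cutoff=0.2)  # never a member
        with pytest.warns(UserWarning, match="no admitted pairs"):
            c = compute_msd(traj.unwrapped(), membership=m, lag_grid=np.array([1.0]))
        assert c.counts[0] == 0 and np.isnan(c.values[0])


class TestRdf:
    def test_ideal_gas_is_flat(self):
        rng = np.random.default_rng(3)
        L = 5.0
        coords = rng.uniform(0, L, (2, 600, 3))
        traj = Trajectory(coords, np.array([0.0, 1.0]), L,
                          np.full(600, "water-oxygen", dtype=object))
        rdf = compute_rdf(traj, "water-oxygen", bin_width=0.05)
        inner = rdf.g[(rdf.bin_centres > 0.5) & (rdf.bin_centres < 2.4)]
        assert np.mean(inner) == pytest.approx(1.0, abs=0.05)

    def test_two_particles_occupy_single_bin(self):
        L = 5.0
        coords = np.array([[[1.0, 1.0, 1.0], [1.0, 1.0, 1.8]]])
        traj = Trajectory(coords, np.array([0.0]), L,
                          np.full(2, "water-oxygen", dtype=object))
        rdf = compute_rdf(traj, "water-oxygen", bin_width=0.05)
        occupied = np.flatnonzero(rdf.g > 0)
        assert occupied.size == 1
        assert rdf.bin_centres[occupied[0]] == pytest.approx(0.8, abs=0.05)

    def test_cubic_lattice_first_peak_at_spacing(self):
        a, n = 0.5, 6
        grid = np.stack(np.meshgrid(*[np.arange(n) * a] * 3), -1).reshape(-1, 3)
        L = n * a
        traj = Trajectory(grid[None], np.array([0.0]), L,
                          np.full(grid.shape[0], "water-oxygen", dtype=object))
        rdf = compute_rdf(traj, "water-oxygen", bin_width=0.02, r_max=1.4)
        first = np.flatnonzero(rdf.g > 0)[0]
        assert rdf.bin_centres[first] == pytest.approx(a, abs=0.02)

    def test_r_max_beyond_half_box_rejected(self, free_traj):
        with pytest.raises(TrajectoryUsageError, match="half the box"):
            compute_rdf(free_traj, "water-oxygen", r_max=3.0)


class TestPeakHeightCurve:
    def test_static_particles_constant(self, static_traj):
        c = svhf_peak_height_curve(static_traj.unwrapped(), bin_width=0.01, r_max=1.0)
        assert np.allclose(c.values, c.values[0])

    def test_free_diffusion_decays(self, free_traj):
        c = svhf_peak_height_curve(
            free_traj.unwrapped(), bin_width=0.02, r_max=4.0, origin_stride=5
        )
        # statistically decreasing: no step rises appreciably, strong net decay
        assert np.all(np.diff(c.values) < 0.02 * c.values[:-1])
        assert c.values[-1] < 0.2 * c.values[0]

    def test_caged_curve_holds_a_plateau(self, caged_traj):
        from hydroshell import detect_plateaus

        c = svhf_peak_height_curve(
            caged_traj.unwrapped(), bin_width=0.005, r_max=0.5, origin_stride=5
        )
        regions = detect_plateaus(c)
        assert regions, "no plateau found in the caged peak-height curve"


class TestLagGrid:
    def test_log_grid_snaps_to_frames_and_deduplicates(self):
        lags = log_lag_grid(10_000, 0.1)
        frames = lags / 0.1
        assert np.allclose(frames, np.round(frames))
        assert np.all(np.diff(lags) > 0)
        assert lags[0] == pytest.approx(0.1)
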