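"""Caging/hopping signatures: peaks, shoulders, plateaus, exponents."""

import dataclasses

import numpy as np
import pytest

from hydroshell import (
    GeneratorConfig,
    Trajectory,
    cage_radius_from_sisf_plateau,
    compute_msd,
    compute_sisf,
    compute_svhf,
    detect_peaks_and_shoulders,
    detect_plateaus,
    fit_subdiffusion_exponent,
    generate,
    localization_length_from_msd_plateau,
    svhf_peak_height_curve,
)
from hydroshell.correlators import (
    CorrelationFunction,
    RadialDisplacementDistribution,
    RadialDistribution,
)
from hydroshell.features import FeatureError, align_shoulders_to_shells


def maxwell_density(r, scale):
    """Radial density of an isotropic Gaussian displacement (per-coord sd scale)."""
    return np.sqrt(2 / np.pi) * r**2 / scale**3 * np.exp(-(r**2) / (2 * scale**2))


def analytic_mixture(bin_width=0.02, r_max=4.0):
    edges = np.arange(0.0, r_max + bin_width, bin_width)
    r = 0.5 * (edges[:-1] + edges[1:])
    rho = 0.7 * maxwell_density(r, 0.3 / np.sqrt(2)) + 0.3 * maxwell_density(
        r, 2.5 / np.sqrt(2)
    )
    rho /= rho.sum() * bin_width
    return RadialDisplacementDistribution(1.0, edges, rho, 10**6)


class TestPeaksAndShoulders:
    def test_two_population_mixture_gives_two_features(self):
        prof = detect_peaks_and_shoulders(analytic_mixture())
        pos = sorted(f.position for f in prof.features)
        assert len(pos) == 2
        assert pos[0] == pytest.approx(0.3, abs=0.02)
        assert pos[1] == pytest.approx(2.5, abs=0.02)

    @pytest.mark.parametrize("seed", range(8))
    def test_free_diffusion_yields_single_main_peak(self, seed):
        cfg = GeneratorConfig(300, 0.1, 1200, 5.0, seed, "free_diffusion", {"D": 0.01})
        d = compute_svhf(
            generate(cfg).unwrapped(), lag=10.0, bin_width=0.02, r_max=3.0,
            origin_stride=5,
        )
        prof = detect_peaks_and_shoulders(d)
        assert [f.kind for f in prof.features] == ["main_peak"]

    def test_hop_features_near_shell_distances(self, hopping_traj):
        d = compute_svhf(
            hopping_traj.unwrapped(), lag=350.0, bin_width=0.01, r_max=2.0,
            origin_stride=5,
        )
        prof = detect_peaks_and_shoulders(d)
        pos = [f.position for f in prof.features if f.kind != "main_peak"]
        for target in (0.29, 0.45):
            assert min(abs(p - target) for p in pos) <= 0.01

    def test_invariant_under_uniform_rescaling(self):
        d = analytic_mixture()
        scaled = dataclasses.replace(d, density=3.0 * d.density)
        a = detect_peaks_and_shoulders(d)
        b = detect_peaks_and_shoulders(scaled)
        assert a.positions().tolist() == b.positions().tolist()

    def test_positions_stable_under_bin_halving(self):
        coarse = detect_peaks_and_shoulders(analytic_mixture(bin_width=0.04))
        fine = detect_peaks_and_shoulders(analytic_mixture(bin_width=0.02))
        for pc in coarse.positions():
            assert np.min(np.abs(fine.positions() - pc)) <= 0.04

    def test_all_zero_density_rejected(self):
        edges = np.arange(0.0, 1.0, 0.02)
        zero = RadialDisplacementDistribution(1.0, edges, np.zeros(edges.size - 1), 0)
        with pytest.raises(FeatureError):
            detect_peaks_and_shoulders(zero)


class TestShellAlignment:
    def _rdf_with_shells(self, shells=(0.29, 0.45, 0.67)):
        edges = np.arange(0.0, 2.0, 0.01)
        r = 0.5 * (edges[:-1] + edges[1:])
        g = np.ones(r.size)
        for s in shells:
            g += 1.5 * np.exp(-((r - s) ** 2) / (2 * 0.02**2))
        return RadialDistribution(edges, g)

    def test_hop_features_match_shell_positions(self, hopping_traj):
        d = compute_svhf(
            hopping_traj.unwrapped(), lag=350.0, bin_width=0.01, r_max=2.0,
            origin_stride=5,
        )
        prof = detect_peaks_and_shoulders(d)
        report = align_shoulders_to_shells(prof, self._rdf_with_shells(), tolerance=0.05)
        matched_pos = sorted(p for _, p in report.matched)
        assert len(report.matched) >= 2
        assert all(abs(f.position - p) <= 0.05 for f, p in report.matched)
        assert any(abs(p - s) <= 0.01 for p in matched_pos for s in (0.29, 0.45))

    def test_free_diffusion_gives_empty_report(self, free_traj):
        d = compute_svhf(free_traj.unwrapped(), lag=10.0, bin_width=0.02, r_max=3.0,
                         origin_stride=5)
        prof = detect_peaks_and_shoulders(d)
        report = align_shoulders_to_shells(prof, self._rdf_with_shells())
        assert report.matched == [] and report.unmatched == []

    def test_beyond_shell_feature_flagged_unmatched(self):
        # a 2.5 nm displacement feature against a structureless g(r) ~ 1
        edges = np.arange(0.0, 4.0, 0.02)
        flat = RadialDistribution(edges, np.ones(edges.size - 1))
        prof = detect_peaks_and_shoulders(analytic_mixture())
        report = align_shoulders_to_shells(prof, flat, tolerance=0.05)
        assert any(f.position == pytest.approx(2.5, abs=0.05) for f in report.unmatched)


class TestPlateaus:
    def test_caged_msd_plateau_at_6_sigma_squared(self, caged_traj):
        msd = compute_msd(caged_traj.unwrapped(), origin_stride=5, max_origins=400)
        regions = detect_plateaus(msd)
        assert len(regions) == 1
        assert regions[0].level == pytest.approx(6 * 0.0224**2, rel=0.05)

    def test_pure_power_law_has_no_plateau(self):
        t = np.logspace(-1, 3, 50)
        curve = CorrelationFunction(t, 0.01 * t**0.66, np.full(t.size, 100), "msd")
        assert detect_plateaus(curve) == []

    def test_nonpositive_values_rejected(self):
        t = np.logspace(-1, 1, 30)
        curve = CorrelationFunction(t, np.linspace(-1, 1, 30), np.full(30, 5), "msd")
        with pytest.raises(FeatureError):
            detect_plateaus(curve)

    def test_peak_height_and_msd_plateaus_share_a_time_window(self, caged_traj):
        cont = caged_traj.unwrapped()
        msd_regions = detect_plateaus(
            compute_msd(cont, origin_stride=5, max_origins=400)
        )
        peak_regions = detect_plateaus(
            svhf_peak_height_curve(cont, bin_width=0.005, r_max=0.5, origin_stride=5)
        )
        assert msd_regions and peak_regions
        assert any(
            a.overlaps(b) for a in msd_regions for b in peak_regions
        )


class TestLocalizationLengths:
    @pytest.mark.parametrize(
        "level,expected", [(0.003, 0.055), (0.6, 0.77), (0.3, 0.55), (0.0, 0.0)]
    )
    def test_linear_trapping_distance(self, level, expected):
        assert localization_length_from_msd_plateau(level) == pytest.approx(
            expected, abs=5e-3
        )

    def test_negative_level_rejected(self):
        with pytest.raises(FeatureError):
            localization_length_from_msd_plateau(-0.1)

    def test_sisf_and_msd_lengths_differ_by_sqrt_two(self, caged_traj):
        """For an ideal Gaussian cage the SISF plateau gives a = sqrt(3) sigma
        while sqrt(MSD plateau) = sqrt(6) sigma: the two localization lengths
        sit on the same ~0.05 nm scale but differ by exactly sqrt(2)."""
        cont = caged_traj.unwrapped()
        sisf = compute_sisf(cont, Q=22.5, lag_grid=np.array([100.0]),
                            origin_stride=5, max_origins=300)
        a_sisf = cage_radius_from_sisf_plateau(float(sisf.values[0]), 22.5)
        msd = compute_msd(cont, origin_stride=5, max_origins=300)
        level = detect_plateaus(msd)[0].level
        a_msd = localization_length_from_msd_plateau(level)
        assert a_msd / a_sisf == pytest.approx(np.sqrt(2), rel=0.05)
        assert 0.02 < a_sisf < 0.1 and 0.02 < a_msd < 0.1


class TestSubdiffusion:
    def test_diffusive_limit_has_unit_exponent(self, free_traj):
        msd = compute_msd(free_traj.unwrapped(), origin_stride=5, max_origins=400)
        fit = fit_subdiffusion_exponent(msd, window=(1.0, 50.0))
        assert fit.delta == pytest.approx(1.0, abs=0.05)

    def test_ballistic_limit_has_exponent_two(self):
        rng = np.random.default_rng(6)
        v = rng.standard_normal((200, 3)) * 0.01
        times = np.arange(500) * 0.1
        coords = times[:, None, None] * v[None] + 2.5
        traj = Trajectory(coords, times, 5.0,
                          np.full(200, "water-oxygen", dtype=object), wrapped=False)
        msd = compute_msd(traj, origin_stride=7, max_origins=200)
        fit = fit_subdiffusion_exponent(msd, window=(0.1, 20.0))
        assert fit.delta == pytest.approx(2.0, abs=0.02)

    def test_short_window_rejected(self, free_traj):
        msd = compute_msd(free_traj.unwrapped(), origin_stride=10, max_origins=100)
        with pytest.raises(FeatureError, match="half a decade"):
            fit_subdiffusion_exponent(msd, window=(10.0, 20.0))
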