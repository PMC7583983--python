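"""Three-term relaxation model, fits, temperature laws and crossovers."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hydroshell import (
    RelaxationParams,
    TemperatureSeries,
    cage_radius_from_sisf_plateau,
    detect_crossover,
    fit_relaxation,
    fit_temperature_law,
    generate_tau_table,
    model_eval,
)
from hydroshell.correlators import CorrelationFunction
from hydroshell.relaxation import RelaxationError
from hydroshell.synthetic import KB_KJ_PER_MOL_K, tau_arrhenius


def make_curve(params, t, noise=0.0, seed=0):
    y = model_eval(params, t)
    if noise:
        rng = np.random.default_rng(seed)
        y = y * (1 + noise * rng.standard_normal(t.size))
    return CorrelationFunction(t, y, np.full(t.size, 1000), "sisf")


valid_params = st.builds(
    RelaxationParams,
    tau_s=st.floats(0.05, 0.5),
    f_alpha=st.floats(0.1, 0.6),
    tau_alpha=st.floats(1.0, 1e3),
    beta_alpha=st.floats(0.3, 1.0),
    f_long=st.floats(0.0, 0.35),
    tau_long=st.floats(1e3, 1e6),
    beta_long=st.floats(0.3, 1.0),
)


class TestModelEval:
    def test_unity_at_time_zero(self):
        p = RelaxationParams(0.2, 0.5, 100.0, 0.8, 0.3, 5000.0, 0.6)
        assert model_eval(p, 0.0) == 1.0

    def test_single_stretched_term_at_its_own_timescale(self):
        for beta in (0.4, 0.7, 1.0):
            p = RelaxationParams(0.2, 1.0, 50.0, beta, 0.0, 1e5, 0.8)
            assert model_eval(p, 50.0) == pytest.approx(np.exp(-1), abs=1e-12)

    def test_matches_term_by_term_arithmetic(self):
        p = RelaxationParams(0.2, 0.5, 100.0, 0.8, 0.4, 5000.0, 0.6)
        t = 100.0
        expected = (
            (1 - 0.5 - 0.4) * np.exp(-((t / 0.2) ** 2))
            + 0.5 * np.exp(-((t / 100.0) ** 0.8))
            + 0.4 * np.exp(-((t / 5000.0) ** 0.6))
        )
        assert model_eval(p, t) == pytest.approx(expected, rel=1e-14)

    @pytest.mark.parametrize(
        "bad",
        [
            RelaxationParams(-1.0, 0.5, 100.0, 0.8, 0.3, 5000.0, 0.6),
            RelaxationParams(0.2, 0.5, 100.0, 1.5, 0.3, 5000.0, 0.6),
            RelaxationParams(0.2, 0.7, 100.0, 0.8, 0.5, 5000.0, 0.6),
        ],
    )
    def test_invalid_parameters_rejected(self, bad):
        with pytest.raises(RelaxationError):
            model_eval(bad, 1.0)

    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(valid_params)
    def test_monotone_non_increasing(self, p):
        if p.f_alpha + p.f_long > 1:
            return
        t = np.logspace(-3, 7, 300)
        y = model_eval(p, t)
        assert np.all(np.diff(y) <= 1e-12)


class TestFitRelaxation:
    def test_recovery_within_three_stderr(self):
        true = RelaxationParams(0.2, 0.5, 100.0, 0.8, 0.3, 10000.0, 0.6)
        t = np.logspace(-2, 5.6, 100)
        res = fit_relaxation(make_curve(true, t, noise=0.005, seed=1))
        assert res.converged
        for name in ("tau_alpha", "tau_long", "f_alpha", "f_long"):
            est, se = getattr(res.params, name), res.stderr[name]
            assert abs(est - getattr(true, name)) <= 3 * se, name

    def test_two_term_truth_drives_f_long_to_zero(self):
        true = RelaxationParams(0.2, 0.8, 100.0, 0.8, 0.0, 1e6, 0.8)
        t = np.logspace(-2, 4, 80)
        res = fit_relaxation(make_curve(true, t, noise=0.005, seed=5))
        assert res.converged
        assert res.params.f_long <= 3 * max(res.stderr["f_long"], 1e-3)

    def test_bulk_variant_pins_f_long(self):
        true = RelaxationParams(0.2, 0.8, 100.0, 0.8, 0.0, 1e6, 0.8)
        t = np.logspace(-2, 4, 80)
        res = fit_relaxation(make_curve(true, t, noise=0.005, seed=5),
                             variant="bulk_two_term")
        assert res.converged
        assert res.params.f_long == 0.0
        assert res.params.f_alpha == pytest.approx(0.8, abs=0.02)
        assert res.params.tau_alpha == pytest.approx(100.0, rel=0.05)

    def test_constant_curve_flagged_not_reported(self):
        t = np.logspace(-2, 4, 60)
        res = fit_relaxation(
            CorrelationFunction(t, np.ones(t.size), np.full(t.size, 10), "sisf")
        )
        assert not res.converged
        assert res.params is None

    def test_non_sisf_curve_rejected(self):
        t = np.logspace(-1, 2, 30)
        msd = CorrelationFunction(t, t.copy(), np.full(t.size, 10), "msd")
        with pytest.raises(RelaxationError):
            fit_relaxation(msd)


class TestTemperatureLaws:
    def test_noiseless_arrhenius_is_exact(self):
        T = np.arange(200.0, 301.0, 5.0)
        s = generate_tau_table("arrhenius", {"EA": 61.9, "tau0": 1e-8}, T)
        fit = fit_temperature_law(s, "arrhenius")
        assert fit.EA == pytest.approx(61.9, rel=1e-10)

    def test_noiseless_power_law_recovered_within_one_percent(self):
        T = np.arange(215.0, 301.0, 5.0)
        s = generate_tau_table("power_law", {"TC": 199.0, "gamma": 2.68, "tau0": 50.0}, T)
        fit = fit_temperature_law(s, "power_law")
        assert fit.TC == pytest.approx(199.0, rel=0.01)
        assert fit.gamma == pytest.approx(2.68, rel=0.01)

    def test_temperature_independent_tau_gives_zero_ea(self):
        s = TemperatureSeries(np.array([300.0, 280.0, 260.0]), np.full(3, 7.5))
        fit = fit_temperature_law(s, "arrhenius")
        assert fit.EA == pytest.approx(0.0, abs=1e-10)

    def test_too_few_points_rejected(self):
        s = TemperatureSeries(np.array([300.0, 280.0]), np.array([1.0, 2.0]))
        with pytest.raises(RelaxationError, match="3 points"):
            fit_temperature_law(s, "arrhenius")


def fragile_to_strong_series(T_join=215.0, step=5.0):
    """Power law above the join, Arrhenius below, continuous at the join."""
    T = np.arange(200.0, 301.0, step)
    tau_join = 50.0 * (T_join - 199.0) ** -2.68
    tau0 = tau_join / np.exp(61.9 / (KB_KJ_PER_MOL_K * T_join))
    tau = np.where(
        T >= T_join,
        50.0 * (T - 199.0) ** -2.68,
        tau_arrhenius(T, 61.9, tau0),
    )
    return TemperatureSeries(T, tau)


def strong_to_strong_series(T_join=240.0, step=5.0):
    T = np.arange(200.0, 301.0, step)
    tau_join = tau_arrhenius(T_join, 26.6, 1e-3)
    tau0_lo = tau_join / np.exp(39.3 / (KB_KJ_PER_MOL_K * T_join))
    tau = np.where(
        T >= T_join,
        tau_arrhenius(T, 26.6, 1e-3),
        tau_arrhenius(T, 39.3, tau0_lo),
    )
    return TemperatureSeries(T, tau)


class TestCrossoverDetection:
    def test_fragile_to_strong_at_215(self):
        xo = detect_crossover(fragile_to_strong_series(), ("power_law", "arrhenius"))
        assert xo.kind == "fragile_to_strong"
        assert xo.T_cross == pytest.approx(215.0, abs=5.0)

    def test_strong_to_strong_at_240(self):
        xo = detect_crossover(strong_to_strong_series(), ("arrhenius", "arrhenius"))
        assert xo.kind == "strong_to_strong"
        assert xo.T_cross == pytest.approx(240.0, abs=5.0)
        assert xo.law_high.EA == pytest.approx(26.6, rel=0.05)
        assert xo.law_low.EA == pytest.approx(39.3, rel=0.05)

    def test_single_law_data_reports_no_crossover(self):
        T = np.arange(200.0, 301.0, 5.0)
        s = generate_tau_table("arrhenius", {"EA": 45.0, "tau0": 1e-6}, T)
        xo = detect_crossover(s, ("arrhenius", "arrhenius"))
        assert xo.kind == "no_crossover"

    def test_branch_fits_use_disjoint_subsets(self):
        xo = detect_crossover(strong_to_strong_series(), ("arrhenius", "arrhenius"))
        assert xo.law_high.fit_range[0] > xo.law_low.fit_range[1]

    def test_too_few_points_rejected(self):
        s = TemperatureSeries(np.array([300.0, 280.0, 260.0, 240.0]),
                              np.array([1.0, 2.0, 4.0, 9.0]))
        with pytest.raises(RelaxationError):
            detect_crossover(s, ("arrhenius", "arrhenius"), min_branch_points=3)


class TestCageRadius:
    def test_printed_operating_point(self):
        assert cage_radius_from_sisf_plateau(0.7, 22.5) == pytest.approx(0.046, abs=5e-4)

    def test_vanishes_as_plateau_approaches_unity(self):
        assert cage_radius_from_sisf_plateau(1 - 1e-12, 22.5) < 1e-6

    def test_formula_inversion_round_trip(self):
        a, Q = 0.1, 10.0
        phi = np.exp(-(Q**2) * a**2 / 3)
        assert cage_radius_from_sisf_plateau(phi, Q) == pytest.approx(a, rel=1e-12)

    @pytest.mark.parametrize("phi", [0.0, 1.0, -0.5, 1.5])
    def test_plateau_outside_unit_interval_rejected(self, phi):
        with pytest.raises(RelaxationError):
            cage_radius_from_sisf_plateau(phi, 22.5)
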