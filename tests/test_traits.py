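"""Trait extraction: growth rate, lag, yield, productivity, Pirt fit."""

import numpy as np
import pytest

import labferm as lf
from labferm.simulate import InitialConditions, Trajectory
from labferm.traits import (
    DegenerateCurveError,
    InsufficientDataError,
    UndefinedYieldError,
    growth_yield,
    lag_time,
    pirt_fit,
    productivity,
    specific_growth_rate,
)

P = lf.get_preset("bulgaricus").params


def synthetic_trajectory(times, X, S=None, A=None, Q=None, init=None):
    """Hand-built trajectory for closed-form trait checks (synthetic stand-in,
    not a model solution)."""
    times = np.asarray(times, dtype=float)
    X = np.asarray(X, dtype=float)
    n = times.size
    if init is None:
        init = InitialConditions(S0=30.0, Q0=0.6, X0=float(X[0]), A0=0.0)
    S = np.full(n, init.S0) if S is None else np.asarray(S, dtype=float)
    A = np.zeros(n) if A is None else np.asarray(A, dtype=float)
    Q = np.full(n, init.Q0) if Q is None else np.asarray(Q, dtype=float)
    return Trajectory(times=times, S=S, Q=Q, X=X, A=A, params=P, init=init,
                      meta={"integrator": "synthetic", "dt": times[1] - times[0]})


class TestSpecificGrowthRate:
    def test_exact_exponential(self):
        t = np.arange(0, 10, 0.01)
        traj = synthetic_trajectory(t, 0.02 * np.exp(0.4 * t))
        assert specific_growth_rate(traj) == pytest.approx(0.4, abs=1e-6)

    def test_constant_biomass_gives_zero(self):
        t = np.arange(0, 10, 0.01)
        traj = synthetic_trajectory(t, np.full(t.size, 0.5))
        assert specific_growth_rate(traj) == pytest.approx(0.0, abs=1e-12)

    def test_invariant_to_biomass_rescaling(self, bulgaricus_traj):
        mu = specific_growth_rate(bulgaricus_traj)
        scaled = Trajectory(
            times=bulgaricus_traj.times, S=bulgaricus_traj.S,
            Q=bulgaricus_traj.Q, X=37.0 * bulgaricus_traj.X,
            A=bulgaricus_traj.A, params=bulgaricus_traj.params,
            init=bulgaricus_traj.init, meta=bulgaricus_traj.meta,
        )
        assert specific_growth_rate(scaled) == pytest.approx(mu, rel=1e-12)

    def test_uninhibited_limit_recovers_mu_max(self):
        # no substrate/product inhibition, S held high by a huge biomass yield
        p = P.replace(K_Q=1e12, K_I=1e12, alpha=0.0, beta=0.0,
                      gamma_XS=1e6, gamma_AS=1.0)
        init = InitialConditions(S0=800.0, Q0=0.6, X0=0.02)
        traj = lf.simulate(p, init, t_end=40.0)
        expected = p.mu_max * init.S0 / (p.K_S + init.S0)
        assert specific_growth_rate(traj) == pytest.approx(expected, rel=0.01)

    def test_too_short_trajectory_rejected(self):
        t = np.arange(5) * 0.01
        traj = synthetic_trajectory(t, 0.02 * np.exp(0.4 * t))
        with pytest.raises(InsufficientDataError):
            specific_growth_rate(traj)


class TestLagTime:
    def test_tangent_matches_baranyi_closed_form(self):
        # K_Q, K_I -> inf and S >> K_S: lag = ln(1 + 1/Q0)/mu_max
        for Q0 in (0.2, 0.6, 1.0, 2.0):
            p = P.replace(K_Q=1e12, K_I=1e12, alpha=0.0, beta=0.0,
                          gamma_XS=1e6, gamma_AS=1.0, mu_max=0.5)
            init = InitialConditions(S0=800.0, Q0=Q0, X0=0.02)
            traj = lf.simulate(p, init, t_end=50.0)
            expected = np.log(1.0 + 1.0 / Q0) / p.mu_max
            assert lag_time(traj, "tangent") == pytest.approx(expected, rel=0.05)

    def test_tangent_lag_vanishes_for_pure_exponential(self):
        t = np.arange(0, 10, 0.01)
        traj = synthetic_trajectory(t, 0.02 * np.exp(0.4 * t))
        assert lag_time(traj, "tangent") == pytest.approx(0.0, abs=0.05)

    def test_derivative_peak_is_time_of_fastest_growth(self, bulgaricus_traj):
        lag = lag_time(bulgaricus_traj, "derivative-peak")
        dX = np.gradient(bulgaricus_traj.X, bulgaricus_traj.times)
        assert lag == pytest.approx(bulgaricus_traj.times[np.argmax(dX)], abs=0.05)

    def test_degenerate_curve_rejected(self):
        t = np.arange(0, 1, 0.01)
        traj = synthetic_trajectory(t, np.full(t.size, 0.5))
        with pytest.raises(DegenerateCurveError):
            lag_time(traj, "derivative-peak")
        with pytest.raises(DegenerateCurveError):
            lag_time(traj, "tangent")

    def test_unknown_method_rejected(self, bulgaricus_traj):
        with pytest.raises(ValueError):
            lag_time(bulgaricus_traj, "nonsense")


class TestGrowthYield:
    def test_all_substrate_to_biomass_when_no_product(self):
        p = P.replace(alpha=0.0, beta=0.0)
        init = InitialConditions(S0=10.0, Q0=0.6, X0=0.02)
        traj = lf.simulate(p, init, t_end=100.0)
        assert growth_yield(traj) == pytest.approx(p.gamma_XS, rel=1e-6)

    def test_product_formation_lowers_yield(self, bulgaricus_traj):
        Y = growth_yield(bulgaricus_traj)
        assert 0.0 < Y < P.gamma_XS

    def test_stronger_product_inhibition_lowers_yield(self):
        # smaller K_I slows growth; with beta > 0 more substrate goes to
        # maintenance production, lowering the observed yield
        init = InitialConditions(S0=26.0, Q0=0.6, X0=0.02)
        Y = {}
        for K_I in (46.0, 12.0):
            traj = lf.simulate_to_stationarity(P.replace(K_I=K_I), init)
            Y[K_I] = growth_yield(traj)
        assert Y[12.0] < Y[46.0]

    def test_no_consumption_rejected(self):
        t = np.arange(0, 1, 0.01)
        traj = synthetic_trajectory(t, np.full(t.size, 0.5))
        with pytest.raises(UndefinedYieldError):
            growth_yield(traj)


class TestProductivity:
    def test_linear_accumulation_is_flat(self):
        t = np.arange(0, 10, 0.01)
        c = 1.7
        traj = synthetic_trajectory(t, np.full(t.size, 0.5), A=c * t)
        series = productivity(traj)
        assert np.allclose(series.values, c)

    def test_constant_product_gives_zero(self):
        t = np.arange(0, 10, 0.01)
        traj = synthetic_trajectory(t, np.full(t.size, 0.5),
                                    A=np.zeros(t.size))
        assert np.allclose(productivity(traj).values, 0.0)

    def test_saturating_product_peaks_interior_then_decays(self, bulgaricus_traj):
        series = productivity(bulgaricus_traj)
        assert 0.0 < series.t_max < bulgaricus_traj.times[-1]
        assert series.values[-1] < series.p_max

    def test_cutoff_productivity_interpolated(self, bulgaricus_traj):
        tr = lf.extract_traits(bulgaricus_traj, cutoff_time=12.0)
        expected = float(np.interp(
            12.0, tr.productivity_series.times, tr.productivity_series.values
        ))
        assert tr.final_productivity == pytest.approx(expected)


class TestPirtFit:
    def test_hand_checked_line(self):
        # three points on 1/Y = 1 + 1/mu: slope m = 1, intercept 1/YG = 1
        mu = np.array([1.0, 0.5, 1 / 3])
        Y = 1.0 / (1.0 + 1.0 / mu)
        fit = pirt_fit(mu, Y)
        assert fit.m == pytest.approx(1.0)
        assert fit.YG_inv == pytest.approx(1.0)

    def test_flat_relation_has_zero_maintenance(self):
        mu = np.array([0.1, 0.2, 0.4, 0.8])
        fit = pirt_fit(mu, np.full(4, 0.25))
        assert fit.m == pytest.approx(0.0, abs=1e-12)
        assert 1.0 / fit.YG_inv == pytest.approx(0.25)

    def test_local_slopes_exposed_in_x_order(self):
        mu = np.array([1.0, 0.5, 0.25])
        Y = 1.0 / np.array([2.0, 3.0, 5.0])
        fit = pirt_fit(mu, Y)
        assert fit.local_slopes == pytest.approx([1.0, 1.0])

    def test_degenerate_points_rejected(self):
        with pytest.raises(ValueError):
            pirt_fit([0.5, 0.5, 0.5], [0.2, 0.2, 0.2])
        with pytest.raises(ValueError):
            pirt_fit([0.5, 0.4], [0.2, 0.21])
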