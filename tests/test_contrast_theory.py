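"""Contrast laws, flow sensitivity, g2 estimation and tau_c fitting."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import speckle_precision as sp
from speckle_precision.contrast_theory import G2Curve, _bracket
from speckle_precision.errors import DomainError, FitError, ParameterError

P = sp.ModelParams
REGIMES = list(sp.Regime)

# Closed-form brackets evaluated independently at 20 significant digits
# (symbolic computation), K = sqrt(bracket):
EXACT_K = [
    # (regime, rho, x, K)
    (sp.Regime.MO_SU, 1.0, 0.5, 0.85776388496070679648),
    (sp.Regime.MU, 1.0, 0.5, 0.70290912841026955171),
    (sp.Regime.SO, 1.0, 0.5, 0.96141047592043870632),
    (sp.Regime.MO_SU, 0.6, 2.0, 0.75385984886235988219),
    (sp.Regime.MU, 0.8, 2.0, 0.60847462223524757492),
    (sp.Regime.SO, 1.0, 2.0, 0.70827911692432535838),
]


class TestContrastK:
    @pytest.mark.parametrize("regime,rho,x,expected", EXACT_K)
    def test_matches_high_precision_evaluation(self, regime, rho, x, expected):
        tc = 10.0
        out = sp.contrast_K(x * tc, P(rho=rho, tau_c=tc), regime)
        assert out == pytest.approx(expected, rel=1e-12)

    @pytest.mark.parametrize("regime", REGIMES)
    def test_zero_exposure_limit(self, regime):
        """x -> 0: the bracket sums to (rho + (1-rho))^2 = 1, K -> sqrt(beta)+C."""
        params = P(beta=0.7, rho=0.6, C=0.02, tau_c=20.0)
        assert sp.contrast_K(0.0, params, regime) == pytest.approx(
            np.sqrt(0.7) + 0.02, abs=1e-12
        )
        assert sp.contrast_K(1e-6, params, regime) == pytest.approx(
            np.sqrt(0.7) + 0.02, abs=1e-4
        )

    @pytest.mark.parametrize("regime", REGIMES)
    @given(x=st.floats(min_value=1e-8, max_value=1e3), beta=st.floats(0.1, 1.0),
           c=st.floats(0, 0.1))
    def test_static_only_is_flat(self, regime, x, beta, c):
        """rho = 0: no dynamic scattering, K = sqrt(beta) + C at every x."""
        params = P(beta=beta, rho=0.0, C=c, tau_c=1.0)
        assert sp.contrast_K(x, params, regime) == pytest.approx(
            np.sqrt(beta) + c, rel=1e-12
        )

    @pytest.mark.parametrize("regime", REGIMES)
    def test_strictly_decreasing_in_x(self, regime):
        xs = np.geomspace(1e-4, 1e3, 300)
        k = sp.contrast_K(xs * 5.0, P(tau_c=5.0), regime)
        assert np.all(np.diff(k) < 0)

    @pytest.mark.parametrize("regime", REGIMES)
    def test_series_joins_closed_form_continuously(self, regime):
        """The small-x Taylor switch at x=1e-3 must not introduce a jump."""
        x = 1e-3
        below = _bracket(x * (1 - 1e-12), 1.0, regime)  # series branch
        above = _bracket(x * (1 + 1e-12), 1.0, regime)  # closed form
        assert below == pytest.approx(above, rel=1e-5)

    def test_regime_curves_distinct_and_smooth(self):
        xs = np.geomspace(0.1, 100, 200)
        curves = {
            r: sp.contrast_K(xs * 2.0, P(tau_c=2.0), r) for r in REGIMES
        }
        for r1 in REGIMES:
            d2 = np.diff(np.log(curves[r1]), 2)
            assert np.all(np.abs(d2) < 0.1)  # smooth on the log grid
            for r2 in REGIMES:
                if r1 is not r2:
                    assert np.max(np.abs(curves[r1] - curves[r2])) > 0.01

    def test_invalid_tau_c_rejected(self):
        with pytest.raises(DomainError):
            P(tau_c=-1.0)


class TestSensitivity:
    def test_absolute_independent_of_offset(self):
        a = sp.absolute_sensitivity(50.0, P(C=0.0, tau_c=20.0), sp.Regime.MO_SU)
        b = sp.absolute_sensitivity(50.0, P(C=0.3, tau_c=20.0), sp.Regime.MO_SU)
        assert a == pytest.approx(b, rel=1e-9)

    def test_fast_flow_limit_vanishes(self):
        assert sp.absolute_sensitivity(
            10.0, P(tau_c=1e-4), sp.Regime.MO_SU
        ) == pytest.approx(0.0, abs=1e-6)

    def test_small_x_absolute_approaches_t_over_3(self):
        """MO_SU, K ~ 1 - x/3 at small x, so |dK/dv| -> T/3."""
        T, tc = 0.01, 100.0
        s_a = sp.absolute_sensitivity(T, P(tau_c=tc), sp.Regime.MO_SU)
        assert s_a == pytest.approx(T / 3.0, rel=1e-2)

    def test_richardson_step_stability(self):
        """Central difference agrees with a 10x finer step to < 0.1%."""
        from speckle_precision import contrast_theory as ct

        T, params = 30.0, P(tau_c=20.0)
        coarse = sp.absolute_sensitivity(T, params, sp.Regime.SO)
        original = ct._REL_STEP
        try:
            ct._REL_STEP = original / 10.0
            fine = sp.absolute_sensitivity(T, params, sp.Regime.SO)
        finally:
            ct._REL_STEP = original
        assert coarse == pytest.approx(fine, rel=1e-3)

    def test_relative_vanishes_at_zero_exposure(self):
        assert sp.relative_sensitivity(
            1e-4 * 20.0, P(tau_c=20.0), sp.Regime.MO_SU
        ) < 1e-3

    def test_relative_asymptote_one_half(self):
        """MO_SU with beta=1, rho=1, C=0: K ~ x^(-1/2), S_r -> 1/2."""
        s_r = sp.relative_sensitivity(1e5 * 20.0, P(tau_c=20.0), sp.Regime.MO_SU)
        assert s_r == pytest.approx(0.5, abs=1e-3)

    def test_offset_creates_interior_peak(self):
        """C > 0: S_r rises, peaks, then falls off with exposure."""
        xs = np.geomspace(0.1, 1e3, 120)
        sr = np.array([
            sp.relative_sensitivity(x * 20.0, P(C=0.01, tau_c=20.0),
                                    sp.Regime.MO_SU)
            for x in xs
        ])
        peak = int(np.argmax(sr))
        assert 0 < peak < len(xs) - 1
        assert sr[-1] < sr[peak] * 0.9


class TestOptimalExposure:
    def test_saturating_case_flags_boundary(self):
        res = sp.optimal_exposure(P(tau_c=20.0), sp.Regime.MO_SU)
        assert res.on_boundary

    def test_offset_case_interior_maximum(self):
        res = sp.optimal_exposure(P(C=0.01, tau_c=20.0), sp.Regime.MO_SU)
        assert not res.on_boundary
        assert 1.0 < res.x_star < 100.0
        assert res.T_star == pytest.approx(res.x_star * 20.0)

    def test_result_within_range(self):
        rng = (0.5, 50.0)
        res = sp.optimal_exposure(P(C=0.01, tau_c=20.0), sp.Regime.MU, x_range=rng)
        assert rng[0] <= res.x_star <= rng[1]


class TestG2:
    def test_time_constant_stack_is_unity(self):
        frames = np.tile(np.random.default_rng(0).uniform(1, 2, (8, 8)), (50, 1, 1))
        curve = sp.g2_autocorrelation(
            sp.FrameStack(frames=frames, dt=1.0), max_lag=5
        )
        np.testing.assert_allclose(curve.values, 1.0, atol=1e-12)

    def test_independent_speckle_zero_lag_siegert(self):
        """Fully developed independent frames: g2(0) ~ 2, g2(lag>0) ~ 1."""
        stack = sp.fast_speckle((48, 48), 2.0, 400, seed=1)
        stack.dt = 1.0  # independent frames; lags beyond 0 are decorrelated
        curve = sp.g2_autocorrelation(stack, max_lag=3)
        assert curve.values[0] == pytest.approx(2.0, abs=0.1)
        np.testing.assert_allclose(curve.values[1:], 1.0, atol=0.05)

    def test_short_stack_rejected(self):
        stack = sp.FrameStack(frames=np.ones((20, 4, 4)), dt=1.0)
        with pytest.raises(ParameterError):
            sp.g2_autocorrelation(stack, max_lag=10)


class TestFitTauC:
    G1 = {
        sp.Regime.SO: lambda t, tc: np.exp(-((t / tc) ** 2)),
        sp.Regime.MO_SU: lambda t, tc: np.exp(-t / tc),
        sp.Regime.MU: lambda t, tc: np.exp(-np.sqrt(t / tc)),
    }

    @pytest.mark.parametrize("regime", REGIMES)
    @pytest.mark.parametrize("tau_c", [10.0, 20.0, 100.0])
    def test_recovery_on_exact_curves(self, regime, tau_c):
        lags = np.linspace(0, 12 * tau_c, 400)
        vals = 1 + self.G1[regime](lags, tau_c) ** 2
        res = sp.fit_tau_c(G2Curve(lags=lags, values=vals), regime, beta=1.0)
        assert res.tau_c == pytest.approx(tau_c, rel=0.05)

    def test_free_beta_recovery(self):
        lags = np.linspace(0, 200, 300)
        vals = 1 + 0.5 * np.exp(-2 * (lags / 20.0) ** 2)
        res = sp.fit_tau_c(G2Curve(lags=lags, values=vals), sp.Regime.SO)
        assert res.beta == pytest.approx(0.5, rel=0.02)
        assert res.tau_c == pytest.approx(20.0, rel=0.02)

    def test_non_decaying_curve_raises(self):
        lags = np.arange(20.0)
        vals = np.full(20, 1.9)
        with pytest.raises(FitError):
            sp.fit_tau_c(G2Curve(lags=lags, values=vals), sp.Regime.SO)
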