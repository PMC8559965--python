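"""Unit tests of the hybrid right-hand side, indicators and the closed-form
intracellular equilibrium."""

import numpy as np
import pytest

from crccsim import (apoptosis_indicator, constant_protocol, csc_indicator,
                     default_parameters, full_rhs, intracellular_equilibrium,
                     simulate)
from crccsim.model import DegenerateStateError
from crccsim.parameters import STATE_NAMES


def independent_rhs(y, t, p, T_clamped, A_clamped):
    """Literal term-by-term transcription of the governing equations,
    written independently of the packaged right-hand side."""
    F, B, X, C, S, L, A, T = y
    i_apop = 1.0 if (B < p.th_B and X > p.th_X) else 0.0
    i_s = 1.0 if p.csc_window[0] < t <= p.csc_window[1] else 0.0
    return np.array([
        p.lambda_F + p.lambda_2 * L - p.mu_F * F,
        p.lambda_B + p.lambda_3 * F + p.k5 * p.k4**2 / (p.k4**2 + p.delta * T**2) - p.mu_B * B,
        p.lambda_X + p.k7 * p.k6**2 / (p.k6**2 + p.gamma * B**2) - p.mu_X * X,
        p.r * C * (1 - C / p.K) + p.lambda_1 * S - p.mu_C * (p.alpha / B) * C * i_apop,
        p.beta * T * i_s,
        p.lambda_L + p.k3 * S / (p.k1 + p.k2 * A) - p.mu_L * L,
        0.0,
        0.0,
    ])


class TestFullRhs:
    def test_sources_off_leaves_pure_decay(self, params):
        """With all sources and feedback strengths off, only B decays toward
        the autocatalytic supply k5."""
        p = params.replace(lambda_F=0, lambda_B=0, lambda_X=0, lambda_2=0,
                           lambda_3=0, delta=0, gamma=0, k7=0, lambda_L=0,
                           k3=0, lambda_1=0, beta=0, r=0)
        proto = constant_protocol(0.0, 0.0, 40)
        y = np.zeros(8)
        y[STATE_NAMES.index("B")] = 1.0
        dy = full_rhs(y, 0.0, p, proto)
        assert dy[STATE_NAMES.index("B")] == pytest.approx(p.k5 - p.mu_B)
        assert np.all(dy[[0, 2, 3, 4, 5, 6, 7]] == 0.0)

    def test_logistic_fixed_point_at_capacity(self, params):
        """dC/dt vanishes at C = K when there is no CSC seeding or killing."""
        proto = constant_protocol(0.0, 0.0, 40)
        y = np.array([1.0, 10.0, 1.0, params.K, 0.0, 1.0, 0.0, 0.0])
        dy = full_rhs(y, 0.0, params, proto)
        assert dy[STATE_NAMES.index("C")] == pytest.approx(0.0, abs=1e-14)

    def test_matches_independent_formula_evaluation(self, params):
        """The packaged derivative equals a hand evaluation of the governing
        equations on a mid-simulation state of the TZB-alone arm."""
        proto = constant_protocol(1.0, 0.0, 40)
        sim = simulate(params, proto, t_span=(0.0, 240.0))
        y = np.array([sim.at(240.0)[n] for n in STATE_NAMES])
        got = full_rhs(y, 240.0, params, proto)
        want = independent_rhs(y, 240.0, params, 1.0, 0.0)
        np.testing.assert_allclose(got, want, rtol=1e-12, atol=1e-15)

    def test_negative_state_rejected(self, params):
        proto = constant_protocol(0.0, 0.0, 40)
        y = np.zeros(8)
        y[0] = -0.1
        with pytest.raises(ValueError, match="negative"):
            full_rhs(y, 0.0, params, proto)

    def test_zero_bcl2_with_killing_is_degenerate(self, params):
        proto = constant_protocol(0.0, 0.0, 40)
        # B = 0 < th_B and X = 9 > th_X puts the state in the kill regime
        y = np.array([0.0, 0.0, 9.0, 0.5, 0.0, 0.0, 0.0, 0.0])
        with pytest.raises(DegenerateStateError):
            full_rhs(y, 0.0, params, proto)


class TestIndicators:
    @pytest.mark.parametrize("B,X,expected", [
        (7.9, 8.1, 1),   # inside the apoptotic region
        (9.0, 9.0, 0),   # Bcl-2 above threshold
        (8.0, 8.0, 0),   # boundary: strict inequalities
        (7.9, 8.0, 0),
    ])
    def test_apoptosis_indicator_thresholds(self, params, B, X, expected):
        assert apoptosis_indicator(B, X, params) == expected

    @pytest.mark.parametrize("t_days,expected", [
        (22.0, 1),   # inside the activation window
        (20.0, 0),   # left endpoint excluded
        (25.0, 1),   # right endpoint included
        (26.0, 0),
    ])
    def test_csc_indicator_window(self, params, t_days, expected):
        assert csc_indicator(t_days * 24.0, params) == expected


class TestIntracellularEquilibrium:
    def test_decoupled_limit(self, params):
        """With IL-6 coupling and both inhibitions off the cascade reduces to
        simple source/decay ratios."""
        p = params.replace(lambda_2=0.0, delta=0.0, gamma=0.0)
        eq = intracellular_equilibrium(p, S=0.25, A=0.0, T=1.0)
        F = p.lambda_F / p.mu_F
        assert eq.F_star == pytest.approx(F)
        assert eq.B_star == pytest.approx(
            (p.lambda_B + p.lambda_3 * F + p.k5) / p.mu_B)
        assert eq.X_star == pytest.approx((p.lambda_X + p.k7) / p.mu_X)

    def test_saturating_tzb_removes_autocatalytic_bcl2(self, params):
        """As T grows without bound the drug fully suppresses the
        autocatalytic Bcl-2 term."""
        eq = intracellular_equilibrium(params, S=0.25, A=0.0, T=1e9)
        floor = (params.lambda_B + params.lambda_3 * eq.F_star) / params.mu_B
        assert eq.B_star == pytest.approx(floor, rel=1e-6)

    def test_agrees_with_long_time_integration(self, params):
        """Closed-form cascade equilibrium equals the long-time limit of the
        ODE system at the baseline working point."""
        S, A, T = 0.25, 0.0, 0.5
        eq = intracellular_equilibrium(params, S=S, A=A, T=T)
        p = params.replace(beta=0.0)  # hold S fixed for the subsystem check
        proto = constant_protocol(T, A, horizon_days=100)
        sim = simulate(p, proto,
                       init=[0, 5, 0, 0.01, S, 0, A, T],
                       rtol=1e-10, atol=1e-12)
        final = sim.final_state
        for name, want in [("L", eq.L_star), ("F", eq.F_star),
                           ("B", eq.B_star), ("X", eq.X_star)]:
            assert final[name] == pytest.approx(want, rel=1e-6)

    def test_monotone_dose_response(self, params):
        """B* is non-increasing and X* non-decreasing in the TZB dose, and
        X* is a decreasing function of B*."""
        T_grid = np.linspace(0, 6, 25)
        eqs = [intracellular_equilibrium(params, S=0.25, A=5.0, T=t)
               for t in T_grid]
        B = np.array([e.B_star for e in eqs])
        X = np.array([e.X_star for e in eqs])
        assert np.all(np.diff(B) <= 1e-12)
        assert np.all(np.diff(X) >= -1e-12)

    def test_feedback_knockouts(self, params):
        """delta = 0 makes B* dose-independent; k2 = 0 makes L* independent
        of the ATV level."""
        p0 = params.replace(delta=0.0)
        b = {t: intracellular_equilibrium(p0, T=t).B_star for t in (0, 1, 6)}
        assert len({round(v, 12) for v in b.values()}) == 1
        p1 = params.replace(k2=0.0)
        l = {a: intracellular_equilibrium(p1, A=a).L_star for a in (0, 5, 40)}
        assert len({round(v, 12) for v in l.values()}) == 1

    def test_cascade_is_locally_stable(self, params):
        """All equilibria of the feed-forward cascade are stable: the
        Jacobian is triangular with the negated decay rates on the
        diagonal."""
        for T in (0.0, 0.5, 4.0):
            eq = intracellular_equilibrium(params, S=1.0, A=5.0, T=T)
            assert eq.stability == "stable"
            re = sorted(ev.real for ev in eq.eigenvalues)
            assert re == pytest.approx(sorted(
                [-params.mu_L, -params.mu_F, -params.mu_B, -params.mu_X]))

    def test_nonpositive_decay_rejected(self, params):
        bad = params.replace()
        object.__setattr__(bad, "mu_L", 0.0)  # bypass constructor check
        with pytest.raises(ValueError):
            intracellular_equilibrium(bad)


class TestNonnegativity:
    def test_trajectories_stay_nonnegative_under_random_parameters(
            self, params, rng):
        """From nonnegative initial data the dynamics preserve
        nonnegativity of every component (random parameter sweep)."""
        scale_fields = ("lambda_F", "lambda_B", "lambda_X", "lambda_2",
                        "lambda_3", "k5", "k7", "delta", "gamma", "r",
                        "lambda_1", "beta", "lambda_L", "k2", "k3", "mu_C")
        proto = constant_protocol(1.0, 5.0, horizon_days=4)
        for _ in range(12):
            mult = {f: getattr(params, f) * rng.uniform(0.3, 3.0)
                    for f in scale_fields}
            p = params.replace(**mult)
            init = rng.uniform(0.0, 5.0, size=8)
            init[7] = 1.0  # clamped T
            init[6] = 5.0  # clamped A
            sim = simulate(p, proto, t_span=(0.0, 96.0), init=init,
                           rtol=1e-8, atol=1e-10)
            assert sim.states.min() >= -1e-8
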