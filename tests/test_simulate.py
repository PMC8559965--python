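"""Integration engine: breakpoints, event handling, convergence, and the
qualitative arm narratives."""

import numpy as np
import pytest

from crccsim import (HOURS_PER_DAY, constant_protocol, event_times,
                     initial_state, periodic_protocol, simulate)
from crccsim.model import full_rhs
from crccsim.parameters import STATE_NAMES


class TestEventTimes:
    def test_control_protocol_breakpoints(self, params):
        proto = constant_protocol(0.0, 0.0, horizon_days=40)
        pts = event_times(proto, params, (0.0, 960.0))
        np.testing.assert_allclose(pts, [0.0, 480.0, 600.0, 960.0])

    def test_periodic_protocol_window_edges(self, params):
        proto = periodic_protocol("ATV", dose=2.0, period_days=4,
                                  duration_days=1.0, n_injections=10,
                                  horizon_days=41)
        pts = event_times(proto, params, (0.0, proto.horizon))
        # 20 window edges + span ends + 2 CSC endpoints, minus coincidences:
        # t=0 doubles as the first window start, the day-20 CSC onset as the
        # 6th window start (480 h), the day-25 offset as a window end (600 h)
        assert pts[0] == 0.0 and pts[-1] == proto.horizon
        assert len(pts) == 21
        assert 480.0 in pts and 600.0 in pts

    def test_coincident_edges_deduplicated(self, params):
        proto = periodic_protocol("ATV", dose=1.0, period_days=20,
                                  duration_days=5.0, n_injections=2,
                                  horizon_days=40)
        pts = event_times(proto, params, (0.0, 960.0))
        assert len(pts) == len(np.unique(np.round(pts, 6)))


class TestSimulate:
    def test_zero_dynamics_stay_zero(self, params):
        p = params.replace(lambda_F=0, lambda_B=0, lambda_X=0, lambda_L=0,
                           k5=0, k7=0, r=0, lambda_1=0, beta=0)
        proto = constant_protocol(0.0, 0.0, horizon_days=10)
        sim = simulate(p, proto, init=np.zeros(8))
        assert np.allclose(sim.states, 0.0, atol=1e-12)

    def test_tolerance_refinement_converges(self, params):
        """Halving the tolerances changes the combination-arm final state by
        less than 1e-6 relative."""
        proto = constant_protocol(1.0, 5.0, horizon_days=40)
        a = simulate(params, proto, rtol=1e-8, atol=1e-10)
        b = simulate(params, proto, rtol=1e-10, atol=1e-12)
        ya, yb = a.states[:, -1], b.states[:, -1]
        scale = np.maximum(np.abs(yb), 1e-6)
        assert np.max(np.abs(ya - yb) / scale) < 1e-6

    def test_event_splitting_matches_fixed_step_rk4(self, params):
        """Event-split integration agrees with a brute-force fixed-step RK4
        oracle on a smooth 5-day stretch of the combination arm."""
        proto = constant_protocol(1.0, 5.0, horizon_days=40)
        ref = simulate(params, proto, t_span=(0.0, 240.0))
        y0 = ref.states[:, -1]  # day 10: inside the apoptotic phase
        sim = simulate(params, proto, t_span=(240.0, 360.0), init=y0)

        dt = 0.01
        y = y0.copy()
        t = 240.0
        f = lambda tt, yy: full_rhs(yy, tt, params, proto, validate=False)
        for _ in range(int(120.0 / dt)):
            k1 = f(t, y)
            k2 = f(t + dt / 2, y + dt / 2 * k1)
            k3 = f(t + dt / 2, y + dt / 2 * k2)
            k4 = f(t + dt, y + dt * k3)
            y = y + dt / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
            t += dt
        scale = np.maximum(np.abs(y), 1e-8)
        assert np.max(np.abs(sim.states[:, -1] - y) / scale) < 1e-4

    def test_naive_switching_agrees_on_smooth_arm(self, params):
        """Per-evaluation indicator handling and event location give the
        same trajectories when crossings are simple."""
        proto = constant_protocol(1.0, 5.0, horizon_days=30)
        ev = simulate(params, proto, switching="events")
        nv = simulate(params, proto, switching="naive")
        for name in ("B", "X", "L", "F"):
            np.testing.assert_allclose(ev.state(name), nv.state(name),
                                       rtol=1e-6, atol=1e-8)
        assert nv.final_state["C"] == pytest.approx(ev.final_state["C"],
                                                    rel=1e-3)

    def test_csc_density_is_monotone_and_window_limited(self, params):
        """S is non-decreasing and constant outside the activation window."""
        proto = constant_protocol(1.0, 0.0, horizon_days=40)
        sim = simulate(params, proto)
        S = sim.state("S")
        assert np.all(np.diff(S) >= -1e-12)
        before = sim.times <= params.csc_window[0]
        after = sim.times >= params.csc_window[1]
        assert np.ptp(S[before]) < 1e-10
        assert np.ptp(S[after]) < 1e-10

    def test_state_continuity_across_events(self, params):
        """The trajectory has no jumps at breakpoints (only derivative
        switches): adjacent 1-h grid values differ by O(rate * dt)."""
        proto = periodic_protocol("ATV", dose=2.0, period_days=4,
                                  duration_days=1.0, n_injections=10,
                                  horizon_days=41, other_clamped_level=1.0)
        sim = simulate(params, proto)
        jumps = np.abs(np.diff(sim.states, axis=1))
        assert jumps.max() < 60.0  # bounded by max |dA/dt| * 1 h

    def test_indicator_traces_are_binary(self, params):
        proto = constant_protocol(1.0, 0.0, horizon_days=40)
        sim = simulate(params, proto)
        assert set(np.unique(sim.i_apop)) <= {0, 1}
        assert set(np.unique(sim.i_s)) <= {0, 1}

    def test_negative_initial_state_rejected(self, params):
        proto = constant_protocol(0.0, 0.0, horizon_days=10)
        bad = initial_state(params, proto)
        bad[3] = -0.01
        with pytest.raises(ValueError):
            simulate(params, proto, init=bad)


class TestArmNarratives:
    def test_control_arm_settles_in_antiapoptotic_region(self, params):
        """Without treatment the intracellular state converges into the
        anti-apoptotic region (B above, X below threshold)."""
        sim = simulate(params, constant_protocol(0.0, 0.0, horizon_days=40))
        final = sim.final_state
        assert final["B"] > params.th_B
        assert final["X"] < params.th_X
        assert sim.i_apop.sum() == 0  # never enters the apoptotic region

    def test_tzb_arm_switches_from_apoptotic_to_resistant(self, params):
        """TZB alone kills initially (apoptotic indicator on), then the CSC
        window raises IL-6 and the system switches permanently back."""
        sim = simulate(params, constant_protocol(1.0, 0.0, horizon_days=40))
        segs = sim.apop_segments
        on = [(t0, t1) for t0, t1, v in segs if v == 1]
        assert len(on) == 1, "single contiguous apoptotic interval"
        t_on, t_off = on[0]
        assert t_on < params.csc_window[0]          # starts pre-window
        assert params.csc_window[0] < t_off < params.csc_window[1] + 48.0
        assert sim.i_apop[-1] == 0                  # resistant at horizon

    def test_combination_arm_sustains_apoptosis(self, params):
        sim = simulate(params, constant_protocol(1.0, 5.0, horizon_days=40))
        assert sim.i_apop[-1] == 1
        assert sim.final_state["C"] < 0.05
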