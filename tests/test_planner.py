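"""Feed-calculator machinery: target rates, enzyme dosing, closed-loop plans."""

import numpy as np
import pytest

from enzfeed import (
    ExperimentDesign,
    ReleaseParameters,
    ReleaseState,
    SetpointSchedule,
    enzyme_addition,
    plan_feed,
    stock_volume,
    target_rate,
    target_release_profile,
)
from enzfeed.planner import InfeasibleFeedError


class TestTargetRate:
    def test_difference_quotient(self):
        assert target_rate(2.0, 3.0, 0.5) == pytest.approx(2.0)

    def test_flat_target_zero_rate(self):
        assert target_rate(4.0, 4.0, 1.0) == 0.0

    def test_decreasing_target_negative(self):
        # release cannot be reversed; the caller clamps
        assert target_rate(5.0, 4.0, 1.0) == -1.0


class TestTargetReleaseProfile:
    def test_zero_growth_zero_rate(self):
        sched = SetpointSchedule(phases=[(0.0, 0.0)], horizon=6.0)
        prof = target_release_profile(3.0, sched)
        assert prof(0.0) == 0.0 and prof(5.0) == 0.0

    def test_direct_evaluation_at_phase_start(self):
        sched = SetpointSchedule(phases=[(0.0, 0.2)], horizon=6.0)
        prof = target_release_profile(3.0, sched, Y_XS=0.5)
        assert prof(0.0) == pytest.approx(1.2)

    def test_yield_proportionality(self):
        sched = SetpointSchedule(phases=[(0.0, 0.15)], horizon=6.0)
        p1 = target_release_profile(3.0, sched, Y_XS=0.5)
        p2 = target_release_profile(3.0, sched, Y_XS=1.0)
        for t in (0.0, 2.0, 5.0):
            assert p1(t) == pytest.approx(2.0 * p2(t))

    def test_phases_chain_continuously(self):
        sched = SetpointSchedule(phases=[(0.0, 0.2), (6.0, 0.1)], horizon=10.0)
        prof = target_release_profile(3.0, sched, Y_XS=0.5)
        # biomass carried over: just after the switch the rate reflects
        # X(6h) = 3*exp(1.2) with the new mu
        X6 = 3.0 * np.exp(0.2 * 6.0)
        assert prof(6.0) == pytest.approx((0.1 / 0.5) * X6, rel=1e-9)


class TestEnzymeAddition:
    def test_hand_evaluated_dose(self):
        p = ReleaseParameters()
        s = ReleaseState(P=0.0, S=40.0, WS=0.464, E=0.0, V=0.010)
        e_add = enzyme_addition(s, p, r_target=1.0)
        assert e_add == pytest.approx(14.22, rel=1e-3)

    def test_target_already_met_returns_zero(self):
        p = ReleaseParameters()
        s = ReleaseState(P=0.0, S=40.0, WS=0.464, E=50.0, V=0.010)
        assert enzyme_addition(s, p, r_target=0.1) == 0.0

    def test_no_substrate_is_infeasible(self):
        p = ReleaseParameters()
        s = ReleaseState(P=5.0, S=0.0, WS=0.0, E=0.0, V=0.010)
        with pytest.raises(InfeasibleFeedError):
            enzyme_addition(s, p, r_target=1.0)

    def test_dose_linear_in_rate_gap(self):
        p = ReleaseParameters()
        s = ReleaseState(P=0.0, S=40.0, WS=0.464, E=0.0, V=0.010)
        assert enzyme_addition(s, p, 2.0) == pytest.approx(2 * enzyme_addition(s, p, 1.0))


class TestStockVolume:
    def test_dilution_aware_inversion(self):
        s = ReleaseState(P=0.0, S=40.0, WS=0.464, E=0.0, V=0.010)
        v = stock_volume(s, E_add=14.22, E_stock=3000.0)
        assert v == pytest.approx(4.76e-5, rel=1e-3)

    def test_mixing_reproduces_target_exactly(self):
        from enzfeed import BolusEvent, apply_bolus

        s = ReleaseState(P=1.0, S=30.0, WS=0.5, E=5.0, V=0.011)
        e_add = 12.0
        v = stock_volume(s, e_add, 3000.0)
        out = apply_bolus(
            s, BolusEvent(0.0, "enzyme", v, 3000.0), stock_ws=0.464
        )
        assert out.E == pytest.approx(s.E + e_add, rel=1e-12)

    def test_zero_addition_zero_volume(self):
        s = ReleaseState(P=0.0, S=40.0, WS=0.5, E=0.0, V=0.010)
        assert stock_volume(s, 0.0, 3000.0) == 0.0

    def test_unreachable_stock_rejected(self):
        s = ReleaseState(P=0.0, S=40.0, WS=0.5, E=2990.0, V=0.010)
        with pytest.raises(InfeasibleFeedError):
            stock_volume(s, 20.0, 3000.0)


def _released_per_interval(plan, grid, dt, nu=1.111):
    """Reaction-released glucose per interval from the glucose mass ledger.

    Boluses add no glucose, evaporation removes none, so the increase of
    P*V over an interval is exactly the integrated release.
    """
    traj = plan.trajectory
    P = np.interp(grid, traj.times, traj.P)
    V = np.interp(grid, traj.times, traj.V)
    Pn = np.interp(grid + dt, traj.times, traj.P)
    Vn = np.interp(grid + dt, traj.times, traj.V)
    return (Pn * Vn - P * V) / (V * dt)


@pytest.fixture
def feed_design():
    return ExperimentDesign(
        initial_state=ReleaseState(P=0.0, S=40.0, WS=0.464, E=0.0, V=0.010),
        horizon=12.0,
        experiment_id="feed",
    )


class TestPlanFeed:
    def test_constant_rate_tracking_within_two_percent(self, feed_design):
        p = ReleaseParameters(r_evap=0.0)
        plan = plan_feed(feed_design, p, rate_profile=lambda t: 1.0,
                         schedule=SetpointSchedule(phases=[(0.0, 0.0)], horizon=6.0))
        dt = 1.0 / 6.0
        grid = plan.table["time_h"].to_numpy()
        realized = _released_per_interval(plan, grid, dt)
        # approximation regime of the difference-quotient dosing rule
        traj = plan.trajectory
        rs_over_s = 1.0 / np.interp(grid, traj.times, traj.S)
        assert np.all(rs_over_s * dt < 0.01)
        assert np.max(np.abs(realized - 1.0)) < 0.02

    def test_zero_setpoint_no_enzyme(self, feed_design):
        p = ReleaseParameters()
        sched = SetpointSchedule(phases=[(0.0, 0.0)], horizon=6.0)
        plan = plan_feed(feed_design, p, schedule=sched, X0=3.0)
        assert plan.table["E_add_UL"].sum() == 0.0

    def test_exponential_schedule_well_formed(self, feed_design):
        p = ReleaseParameters()
        sched = SetpointSchedule(phases=[(0.0, 0.21), (6.0, 0.11)], horizon=10.0,
                                 induction_time=6.0)
        plan = plan_feed(feed_design, p, schedule=sched, X0=3.0)
        assert (plan.table["E_add_UL"] >= 0.0).all()
        # dextrin maintenance every grid step
        assert (plan.table["dextrin_stock_uL"] == 40.0).all()
        assert len(plan.table) == 60

    def test_cumulative_error_does_not_accumulate(self, feed_design):
        """Replanning from the integrated state each interval keeps the
        cumulative release near the cumulative target."""
        p = ReleaseParameters(r_evap=0.0)
        target = 0.8
        plan = plan_feed(feed_design, p, rate_profile=lambda t: target,
                         schedule=SetpointSchedule(phases=[(0.0, 0.0)], horizon=8.0))
        dt = 1.0 / 6.0
        grid = plan.table["time_h"].to_numpy()
        realized = _released_per_interval(plan, grid, dt)
        per_interval_worst = np.max(np.abs(realized - target)) * dt
        n = np.arange(1, grid.size + 1)
        cumulative_dev = np.abs(np.cumsum(realized - target) * dt)
        # bounded by a small multiple of the worst single interval, not ~ n
        assert np.all(cumulative_dev <= 3.0 * per_interval_worst + 1e-9)

    def test_plan_reproducible(self, feed_design):
        p = ReleaseParameters()
        sched = SetpointSchedule(phases=[(0.0, 0.15)], horizon=6.0)
        a = plan_feed(feed_design, p, schedule=sched, X0=3.0)
        b = plan_feed(feed_design, p, schedule=sched, X0=3.0)
        assert a.table.equals(b.table)

    def test_substrate_exhaustion_raises_with_time(self):
        design = ExperimentDesign(
            initial_state=ReleaseState(P=0.0, S=0.5, WS=1.0, E=0.0, V=0.010),
            horizon=6.0,
        )
        p = ReleaseParameters()
        with pytest.raises(InfeasibleFeedError, match="t="):
            plan_feed(design, p, rate_profile=lambda t: 5.0,
                      schedule=SetpointSchedule(phases=[(0.0, 0.0)], horizon=6.0),
                      dextrin_volume=0.0)

    def test_glucose_target_mode_tracks_concentration(self, feed_design):
        p = ReleaseParameters(r_evap=0.0)
        plan = plan_feed(
            feed_design, p,
            glucose_target=lambda t: 0.5 * t,
            schedule=SetpointSchedule(phases=[(0.0, 0.0)], horizon=6.0),
            dextrin_volume=0.0,
        )
        traj = plan.trajectory
        P_end = np.interp(6.0, traj.times, traj.P)
        assert P_end == pytest.approx(3.0, rel=0.02)

    def test_shooting_refinement_not_worse(self, feed_design):
        p = ReleaseParameters(r_evap=0.0)
        sched = SetpointSchedule(phases=[(0.0, 0.0)], horizon=2.0)
        base = plan_feed(feed_design, p, rate_profile=lambda t: 1.0, schedule=sched,
                         dextrin_volume=0.0)
        shot = plan_feed(feed_design, p, rate_profile=lambda t: 1.0, schedule=sched,
                         dextrin_volume=0.0, shooting=True)
        dt = 1.0 / 6.0
        g = base.table["time_h"].to_numpy()
        dev_base = np.abs(_released_per_interval(base, g, dt) - 1.0).max()
        dev_shot = np.abs(_released_per_interval(shot, g, dt) - 1.0).max()
        assert dev_shot <= dev_base + 1e-6

    def test_cumulated_plan_preserves_totals(self, feed_design):
        p = ReleaseParameters()
        sched = SetpointSchedule(phases=[(0.0, 0.15)], horizon=6.0)
        plan = plan_feed(feed_design, p, schedule=sched, X0=3.0)
        merged = plan.cumulated(window=0.5)
        assert merged.table["enzyme_stock_uL"].sum() == pytest.approx(
            plan.table["enzyme_stock_uL"].sum()
        )
        assert merged.table["dextrin_stock_uL"].sum() == pytest.approx(
            plan.table["dextrin_stock_uL"].sum()
        )
        assert len(merged.table) < len(plan.table)
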