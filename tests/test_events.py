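"""Bolus mixing, sampling and piecewise event-driven integration."""

import numpy as np
import pytest

from enzfeed import (
    BolusEvent,
    ExperimentDesign,
    ReleaseParameters,
    ReleaseState,
    SampleEvent,
    apply_bolus,
    apply_sample,
    simulate,
)

from conftest import glucose_equivalent_mass


class TestApplyBolus:
    def test_enzyme_stock_mixing(self):
        s = ReleaseState(P=0.0, S=0.0, WS=0.0, E=0.0, V=0.010)
        ev = BolusEvent(time=1.0, species="enzyme", volume_added=5.0e-5,
                        stock_concentration=3000.0)
        out = apply_bolus(s, ev)
        assert out.V == pytest.approx(0.01005)
        assert out.E == pytest.approx(14.925, rel=1e-3)

    def test_dextrin_added_with_fresh_stock_composition(self):
        s = ReleaseState(P=0.0, S=40.0, WS=0.3, E=0.0, V=0.010)
        ev = BolusEvent(time=0.0, species="dextrin", volume_added=4.0e-5,
                        stock_concentration=150.0)
        out = apply_bolus(s, ev, stock_ws=0.464)
        assert out.S == pytest.approx((0.4 + 0.006) / 0.01004, rel=1e-6)
        assert out.SS == pytest.approx((0.12 + 0.464 * 0.006) / 0.01004, rel=1e-6)

    def test_water_is_pure_dilution(self):
        s = ReleaseState(P=8.0, S=20.0, WS=0.4, E=12.0, V=0.010)
        ev = BolusEvent(time=0.0, species="water", volume_added=1.0e-3)
        out = apply_bolus(s, ev)
        f = 0.010 / 0.011
        assert out.P == pytest.approx(8.0 * f)
        assert out.S == pytest.approx(20.0 * f)
        assert out.E == pytest.approx(12.0 * f)
        assert out.WS == pytest.approx(0.4)  # dilution keeps the proportion

    def test_dextrin_without_stock_ws_rejected(self):
        s = ReleaseState(P=0.0, S=10.0, WS=0.5, E=0.0, V=0.010)
        ev = BolusEvent(time=0.0, species="dextrin", volume_added=4.0e-5)
        with pytest.raises(ValueError, match="stock_ws"):
            apply_bolus(s, ev)

    def test_mass_balance_exact(self):
        s = ReleaseState(P=2.0, S=30.0, WS=0.5, E=5.0, V=0.011)
        ev = BolusEvent(time=0.0, species="glucose", volume_added=1.0e-4,
                        stock_concentration=600.0)
        out = apply_bolus(s, ev)
        assert out.P * out.V == pytest.approx(s.P * s.V + 600.0 * 1.0e-4)
        assert out.S * out.V == pytest.approx(s.S * s.V)


class TestApplySample:
    def test_volume_drops_concentrations_unchanged(self):
        s = ReleaseState(P=3.0, S=25.0, WS=0.6, E=8.0, V=0.010)
        out = apply_sample(s, SampleEvent(time=0.0, volume_removed=2.0e-4))
        assert out.V == pytest.approx(0.0098)
        assert (out.P, out.S, out.WS, out.E) == (s.P, s.S, s.WS, s.E)

    def test_consecutive_samples_commute_with_combined(self):
        s = ReleaseState(P=3.0, S=25.0, WS=0.6, E=8.0, V=0.010)
        two = apply_sample(apply_sample(s, SampleEvent(0.0, 1e-4)), SampleEvent(0.0, 1e-4))
        one = apply_sample(s, SampleEvent(0.0, 2e-4))
        assert two.V == pytest.approx(one.V, rel=1e-14)
        assert (two.P, two.S, two.WS, two.E) == (one.P, one.S, one.WS, one.E)

    def test_overdraw_rejected(self):
        s = ReleaseState(P=0.0, S=0.0, WS=0.0, E=0.0, V=0.010)
        with pytest.raises(ValueError):
            apply_sample(s, SampleEvent(time=0.0, volume_removed=0.011))


class TestSimulate:
    def test_no_enzyme_no_evaporation_all_constant(self):
        p = ReleaseParameters(r_evap=0.0)
        d = ExperimentDesign(
            initial_state=ReleaseState(P=5.0, S=20.0, WS=0.5, E=0.0, V=0.01),
            horizon=10.0,
        )
        traj = simulate(d, p)
        np.testing.assert_allclose(traj.P, 5.0, rtol=1e-10)
        np.testing.assert_allclose(traj.S, 20.0, rtol=1e-10)
        np.testing.assert_allclose(traj.E, 0.0, atol=1e-12)

    def test_zero_order_release_increment(self):
        """WS0=1, S0=30 >> K, 1 h: deltaP ~ nu*k_s*E."""
        p = ReleaseParameters(k_s=0.134, k_r=0.0, r_evap=0.0)
        d = ExperimentDesign(
            initial_state=ReleaseState(P=0.0, S=30.0, WS=1.0, E=10.0, V=0.01),
            horizon=1.0,
        )
        traj = simulate(d, p, t_eval=[0.0, 1.0])
        assert traj.P[-1] == pytest.approx(1.489, rel=2e-3)

    def test_empty_event_list_matches_single_shot(self, params):
        s = ReleaseState(P=0.0, S=30.0, WS=0.464, E=15.0, V=0.011)
        t_eval = np.linspace(0.0, 30.0, 31)
        a = simulate(ExperimentDesign(initial_state=s, horizon=30.0), params, t_eval=t_eval)
        from scipy.integrate import solve_ivp
        from enzfeed.kinetics import ModelVariant, rhs_vector
        sol = solve_ivp(rhs_vector, (0, 30), s.as_vector(), method="LSODA",
                        t_eval=t_eval, rtol=1e-8, atol=1e-10,
                        args=(params, ModelVariant.TWO_SUBSTRATE))
        np.testing.assert_allclose(a.states[:, 0], np.maximum(sol.y[0], 0), rtol=1e-9, atol=1e-10)

    def test_conservation_across_30h_with_additions(self, params):
        """V*(P/nu + S) changes only by the added stock masses."""
        events = [
            BolusEvent(0.0, "enzyme", 4e-5, 3000.0),
            BolusEvent(6.0, "dextrin", 4e-4, 150.0),
            BolusEvent(6.0, "glucose", 1e-4, 600.0),
        ]
        d = ExperimentDesign(
            initial_state=ReleaseState(P=3.75, S=15.0, WS=0.464, E=0.0, V=0.011),
            horizon=30.0, events=events,
        )
        traj = simulate(d, params)
        m = glucose_equivalent_mass(traj, params.nu)
        added = 150.0 * 4e-4 + 600.0 * 1e-4 / 1.111
        assert m[-1] - m[0] == pytest.approx(added, rel=1e-6)

    def test_event_times_on_output_grid(self, params):
        d = ExperimentDesign(
            initial_state=ReleaseState(P=0.0, S=30.0, WS=0.464, E=0.0, V=0.011),
            horizon=10.0,
            events=[BolusEvent(2.5, "enzyme", 4e-5, 3000.0)],
        )
        traj = simulate(d, params, t_eval=[0.0, 5.0, 10.0])
        assert 2.5 in traj.times
        # post-event state on the grid
        assert traj.state_at(2.5).E > 0.0

    def test_same_time_boluses_apply_in_listed_order_and_conserve_mass(self, params):
        s = ReleaseState(P=0.0, S=10.0, WS=0.464, E=0.0, V=0.010)
        ev1 = BolusEvent(1.0, "glucose", 1e-4, 600.0)
        ev2 = BolusEvent(1.0, "dextrin", 2e-4, 150.0)
        d12 = ExperimentDesign(initial_state=s, horizon=2.0, events=[ev1, ev2])
        d21 = ExperimentDesign(initial_state=s, horizon=2.0, events=[ev2, ev1])
        p0 = params.replace(k_s=1e-9, k_r=0.0, r_evap=0.0)  # inert: mixing only
        a = simulate(d12, p0, t_eval=[0.0, 2.0])
        b = simulate(d21, p0, t_eval=[0.0, 2.0])
        for col in ("P", "S", "E", "V"):
            assert getattr(a, col)[-1] == pytest.approx(getattr(b, col)[-1], rel=1e-12)

    def test_per_species_mass_ledger(self, params):
        """Final mass - initial mass = added stock + integrated reaction - samples."""
        d = ExperimentDesign(
            initial_state=ReleaseState(P=0.0, S=30.0, WS=0.464, E=0.0, V=0.011),
            horizon=12.0,
            events=[
                BolusEvent(0.0, "enzyme", 4e-5, 3000.0),
                SampleEvent(4.0, 2e-4),
                BolusEvent(6.0, "dextrin", 4e-4, 150.0),
                SampleEvent(8.0, 2e-4),
            ],
        )
        traj = simulate(d, params, dense_step=0.05)
        # enzyme ledger: only addition, sampling and evaporation-concentration
        E_mass = traj.E * traj.V
        # sampled enzyme mass: concentration at sample times x 200 uL
        e4 = traj.state_at(4.0).E  # post-sample concentration (unchanged by sampling)
        e8 = traj.state_at(8.0).E
        expected = 3000.0 * 4e-5 - 2e-4 * (e4 + e8)
        assert E_mass[-1] == pytest.approx(expected, rel=1e-6)
        # glucose-equivalent ledger including removal
        m = glucose_equivalent_mass(traj, params.nu)
        s4 = traj.state_at(4.0)
        s8 = traj.state_at(8.0)
        removed = 2e-4 * ((s4.P / params.nu + s4.S) + (s8.P / params.nu + s8.S))
        assert m[-1] - m[0] == pytest.approx(150.0 * 4e-4 - removed, rel=1e-6)


class TestDesignValidation:
    def test_events_beyond_horizon_rejected(self):
        with pytest.raises(ValueError, match="horizon"):
            ExperimentDesign(
                initial_state=ReleaseState(P=0, S=1, WS=0.5, E=0, V=0.01),
                horizon=5.0,
                events=[BolusEvent(6.0, "water", 1e-5)],
            )

    def test_events_sorted_on_construction(self):
        d = ExperimentDesign(
            initial_state=ReleaseState(P=0, S=1, WS=0.5, E=0, V=0.01),
            horizon=10.0,
            events=[BolusEvent(5.0, "water", 1e-5), BolusEvent(1.0, "water", 1e-5)],
        )
        assert [e.time for e in d.events] == [1.0, 5.0]
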