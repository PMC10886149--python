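"""Model-based feed planning: enzyme doses that realize a target release.

The liquid handler acts on a fixed temporal grid (default every 10 min).
For each grid time the planner compares the target glucose release rate
with the model's current release rate and, if the model falls short,
computes the enzyme concentration increment that closes the gap:

    E_add = (r_target - r_now) * (S + K) / (nu * (kS*SS + kR*SR))

clamped at zero because hydrolysis cannot be reversed — the release rate
can only be raised by adding enzyme, never lowered. Between grid times the
full ODE system is integrated, so approximation errors of one interval do
not carry into the next. Dextrin maintenance boluses keep the substrate
concentration high so the rate stays enzyme-controlled.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .events import BolusEvent, ExperimentDesign, Trajectory, simulate
from .kinetics import ModelVariant, ReleaseParameters, ReleaseState, release_rates

__all__ = [
    "SetpointSchedule",
    "FeedPlan",
    "target_rate",
    "target_release_profile",
    "enzyme_addition",
    "stock_volume",
    "plan_feed",
    "InfeasibleFeedError",
]


class InfeasibleFeedError(RuntimeError):
    """No admissible addition can realize the requested rate."""


@dataclass
class SetpointSchedule:
    """Growth-rate setpoints over the feeding phase.

    ``phases`` is an ordered list of ``(start_time_h, mu_set_per_h)``;
    typically one exponential phase before induction and a reduced one
    after. Times are hours from feed start.
    """

    phases: list[tuple[float, float]]
    horizon: float
    dt: float = 1.0 / 6.0
    induction_time: float | None = None

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("grid interval dt must be > 0")
        if not self.phases:
            raise ValueError("schedule needs at least one phase")
        starts = [t for t, _ in self.phases]
        if starts != sorted(starts) or len(set(starts)) != len(starts):
            raise ValueError("phase start times must be strictly increasing")
        if any(mu < 0 for _, mu in self.phases):
            raise ValueError("mu_set must be >= 0")

    def mu_at(self, t: float) -> float:
        mu = self.phases[0][1]
        for t0, m in self.phases:
            if t >= t0 - 1e-12:
                mu = m
        return mu

    def grid(self) -> np.ndarray:
        n = int(round(self.horizon / self.dt))
        return np.arange(n) * self.dt


@dataclass
class FeedPlan:
    """Grid-timed enzyme/dextrin additions plus the predicted trajectory."""

    table: pd.DataFrame
    trajectory: Trajectory | None = None

    COLUMNS = ("time_h", "r_target", "E_add_UL", "enzyme_stock_uL", "dextrin_stock_uL")

    def __post_init__(self) -> None:
        missing = [c for c in self.COLUMNS if c not in self.table.columns]
        if missing:
            raise ValueError(f"feed plan lacks columns {missing}")
        if (self.table["E_add_UL"] < 0).any():
            raise ValueError("planned enzyme additions must be >= 0")

    def to_events(
        self,
        enzyme_stock: float = 3000.0,
        dextrin_stock: float = 150.0,
        t_offset: float = 0.0,
    ) -> list[BolusEvent]:
        events = []
        for row in self.table.itertuples():
            if row.enzyme_stock_uL > 0:
                events.append(
                    BolusEvent(
                        time=row.time_h + t_offset,
                        species="enzyme",
                        volume_added=row.enzyme_stock_uL * 1e-6,
                        stock_concentration=enzyme_stock,
                    )
                )
            if row.dextrin_stock_uL > 0:
                events.append(
                    BolusEvent(
                        time=row.time_h + t_offset,
                        species="dextrin",
                        volume_added=row.dextrin_stock_uL * 1e-6,
                        stock_concentration=dextrin_stock,
                    )
                )
        return events

    def cumulated(self, window: float) -> "FeedPlan":
        """Merge additions closer than ``window`` hours, for manual pipetting."""
        df = self.table.copy()
        bins = (df["time_h"] / window).astype(int)
        agg = df.groupby(bins).agg(
            time_h=("time_h", "first"),
            r_target=("r_target", "mean"),
            E_add_UL=("E_add_UL", "sum"),
            enzyme_stock_uL=("enzyme_stock_uL", "sum"),
            dextrin_stock_uL=("dextrin_stock_uL", "sum"),
        )
        return FeedPlan(agg.reset_index(drop=True), trajectory=self.trajectory)

    def to_csv(self, path, **kwargs) -> None:
        self.table.to_csv(path, sep="\t", index=False, **kwargs)


def target_rate(P_now: float, P_target_next: float, dt: float) -> float:
    """Average release rate [g/(L h)] needed to reach the next glucose target.

    Negative values (target below the current concentration) are returned
    as-is; the caller clamps, since release cannot be reversed.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    return (P_target_next - P_now) / dt


def target_release_profile(
    X0: float,
    schedule: SetpointSchedule,
    Y_XS: float = 0.5,
) -> Callable[[float], float]:
    """Exponential fed-batch release-rate profile r_target(t) [g/(L h)].

    Within a phase of specific growth rate ``mu`` starting at ``t0`` with
    biomass ``X_phase``, glucose-limited growth at yield ``Y_XS`` [g/g]
    demands r(t) = (mu / Y_XS) * X_phase * exp(mu (t - t0)); the biomass is
    carried over at phase boundaries so the profile chains continuously.
    """
    if X0 <= 0 or Y_XS <= 0:
        raise ValueError("X0 and Y_XS must be > 0")
    starts = [t for t, _ in schedule.phases]
    mus = [m for _, m in schedule.phases]
    X_at_start = [X0]
    for i in range(1, len(starts)):
        X_at_start.append(X_at_start[-1] * math.exp(mus[i - 1] * (starts[i] - starts[i - 1])))

    def profile(t: float) -> float:
        i = 0
        for j, t0 in enumerate(starts):
            if t >= t0 - 1e-12:
                i = j
        mu = mus[i]
        return (mu / Y_XS) * X_at_start[i] * math.exp(mu * (t - starts[i]))

    return profile


def biomass_growth_factor(schedule: SetpointSchedule) -> Callable[[float], float]:
    """Chained exponential growth factor X(t)/X(0) over the schedule phases."""
    starts = [t for t, _ in schedule.phases]
    mus = [m for _, m in schedule.phases]
    factors = [1.0]
    for i in range(1, len(starts)):
        factors.append(factors[-1] * math.exp(mus[i - 1] * (starts[i] - starts[i - 1])))

    def factor(t: float) -> float:
        i = 0
        for j, t0 in enumerate(starts):
            if t >= t0 - 1e-12:
                i = j
        return factors[i] * math.exp(mus[i] * (t - starts[i]))

    return factor


def _rate_gradient(state: ReleaseState, params: ReleaseParameters) -> float:
    """d(release rate)/dE at the current composition: nu*(kS*SS+kR*SR)/(S+K)."""
    return params.nu * (params.k_s * state.SS + params.k_r * state.SR) / (state.S + params.K)


def enzyme_addition(
    state: ReleaseState,
    params: ReleaseParameters,
    r_target: float,
) -> float:
    """Enzyme increment [U/L] raising the model release rate to ``r_target``.

    Uses the reaction term only (dilution and evaporation excluded): with
    the current composition the glucose rate is linear in E, so

        E_add = (r_target - r_now) * (S + K) / (nu * (kS*SS + kR*SR)),

    returned as 0 whenever the current rate already meets the target.
    """
    if not math.isfinite(r_target):
        raise ValueError("r_target must be finite")
    rS, rR = release_rates(state, params)
    r_now = params.nu * (rS + rR)
    if r_now >= r_target:
        return 0.0
    grad = _rate_gradient(state, params)
    if grad <= 0.0:
        raise InfeasibleFeedError(
            f"no hydrolyzable substrate (S={state.S} g/L): cannot reach "
            f"r_target={r_target} g/(L h) with any enzyme amount"
        )
    return (r_target - r_now) / grad


def stock_volume(state: ReleaseState, E_add: float, E_stock: float = 3000.0) -> float:
    """Stock volume [L] whose mixing raises E by exactly ``E_add`` U/L.

    Inverts the bolus dilution rule: v = V*(E_target - E)/(E_stock - E_target)
    with E_target = E + E_add, so that the post-mixing concentration equals
    E_target despite the dilution of the vessel contents.
    """
    if E_add < 0:
        raise ValueError("E_add must be >= 0")
    if E_add == 0.0:
        return 0.0
    E_target = state.E + E_add
    if E_target >= E_stock:
        raise InfeasibleFeedError(
            f"target enzyme concentration {E_target} U/L is unreachable with a "
            f"{E_stock} U/L stock"
        )
    return state.V * (E_target - state.E) / (E_stock - E_target)


def _segment_design(state: ReleaseState, t0: float, t1: float, template: ExperimentDesign) -> ExperimentDesign:
    return ExperimentDesign(
        initial_state=state,
        horizon=t1 - t0,
        events=[],
        rtol=template.rtol,
        atol=template.atol,
        experiment_id=template.experiment_id,
    )


def plan_feed(
    design: ExperimentDesign,
    params: ReleaseParameters,
    schedule: SetpointSchedule | None = None,
    rate_profile: Callable[[float], float] | None = None,
    glucose_target: Callable[[float], float] | None = None,
    X0: float | None = None,
    Y_XS: float = 0.5,
    enzyme_stock: float = 3000.0,
    dextrin_stock: float = 150.0,
    dextrin_volume: float = 4.0e-5,
    dextrin_period: float = 1.0 / 6.0,
    shooting: bool = False,
    variant: ModelVariant = ModelVariant.TWO_SUBSTRATE,
) -> FeedPlan:
    """Closed-loop (over the model) construction of a feed plan.

    The target rate comes from one of three sources, checked in order:
    ``rate_profile`` (explicit r_target(t)), ``glucose_target`` (explicit
    P_target(t), differenced per interval), or ``schedule`` + ``X0``
    (exponential growth profile via :func:`target_release_profile`).

    At each grid time the model is integrated up to that time, the enzyme
    increment and pipetted stock volume are computed, the boluses (enzyme
    plus the periodic dextrin maintenance bolus, default 40 uL of 150 g/L
    stock every 10 min; ``dextrin_volume=0`` disables it) are inserted, and
    the loop continues. With ``shooting=True`` each closed-form dose is
    refined by minimizing the squared end-of-interval glucose error.
    """
    growth_mass_target = None
    if rate_profile is None and glucose_target is None:
        if schedule is None or X0 is None:
            raise ValueError("provide rate_profile, glucose_target, or schedule with X0")
        # cultivation mode: target the biomass *mass* trajectory
        # Xm(t) = X0*V0*exp(chained mu phases). Growth rate means mass
        # doubling; a concentration target would conflate growth with the
        # dilution caused by the feed boluses themselves.
        growth = biomass_growth_factor(schedule)
        V0 = design.initial_state.V
        growth_mass_target = lambda t: X0 * V0 * growth(t)
    dt = schedule.dt if schedule is not None else dextrin_period
    horizon = schedule.horizon if schedule is not None else design.horizon
    if horizon > design.horizon + 1e-9:
        raise ValueError("schedule horizon exceeds the design horizon")

    n = int(round(horizon / dt))
    grid = np.arange(n) * dt

    state = design.initial_state
    rows = []
    times_all: list[np.ndarray] = []
    states_all: list[np.ndarray] = []
    t_prev = 0.0
    dex_elapsed = dextrin_period  # first maintenance bolus at t=0
    glucose_mass0 = state.P * state.V
    target_mass = 0.0  # cumulative target release [g]

    for i, ti in enumerate(grid):
        if ti > t_prev + 1e-12:
            seg = simulate(_segment_design(state, t_prev, ti, design), params, variant)
            times_all.append(t_prev + seg.times[:-1])
            states_all.append(seg.states[:-1])
            state = ReleaseState.from_vector(seg.states[-1])
            t_prev = ti

        # substrate maintenance first, so the dose is computed on the state
        # the enzyme actually meets
        dex_elapsed += dt if i else 0.0
        v_dex = 0.0
        if dextrin_volume > 0 and dex_elapsed >= dextrin_period - 1e-12:
            v_dex = dextrin_volume
            state = _mix(state, v_dex, dextrin_stock, "dextrin", params)
            dex_elapsed = 0.0

        released_mass = state.P * state.V - glucose_mass0
        if growth_mass_target is not None:
            # cumulative release must cover the biomass-mass increment at
            # yield Y_XS; differencing against the *released-so-far* mass
            # gives the catch-up property of the difference-quotient rule
            need = (growth_mass_target(ti + dt) - growth_mass_target(0.0)) / Y_XS
            r_t = max((need - released_mass) / (state.V * dt), 0.0)
        elif rate_profile is not None:
            # track the cumulative release so that an interval's shortfall
            # raises the next interval's issued rate (and vice versa):
            # errors correct instead of accumulating.
            # nominal rate: interval average (difference-quotient construction)
            r_nom = max(0.5 * (rate_profile(ti) + rate_profile(ti + dt)), 0.0)
            deficit = target_mass - released_mass
            r_t = max(r_nom + deficit / (state.V * dt), 0.0)
            target_mass += r_nom * state.V * dt
        else:
            r_t = max(target_rate(state.P, glucose_target(ti + dt), dt), 0.0)

        try:
            e_add = enzyme_addition(state, params, r_t)
            if shooting and r_t > 0:
                e_add = _refine_by_shooting(state, params, variant, r_t, dt, e_add, design)
            v_enz = stock_volume(state, e_add, enzyme_stock)
        except InfeasibleFeedError as err:
            raise InfeasibleFeedError(f"at t={ti:.3f} h: {err}") from err

        if v_enz > 0:
            state = _mix(state, v_enz, enzyme_stock, "enzyme", params)

        rows.append(
            {
                "time_h": ti,
                "r_target": r_t,
                "E_add_UL": e_add,
                "enzyme_stock_uL": v_enz * 1e6,
                "dextrin_stock_uL": v_dex * 1e6,
            }
        )

    if horizon > t_prev + 1e-12:
        seg = simulate(_segment_design(state, t_prev, horizon, design), params, variant)
        times_all.append(t_prev + seg.times)
        states_all.append(seg.states)

    times = np.concatenate(times_all)
    states = np.vstack(states_all)
    keep = np.append(np.diff(times) > 0, True)
    traj = Trajectory(times=times[keep], states=states[keep], event_times=grid,
                      experiment_id=design.experiment_id)
    return FeedPlan(pd.DataFrame(rows), trajectory=traj)


def _mix(state: ReleaseState, volume: float, stock: float, species: str,
         params: ReleaseParameters) -> ReleaseState:
    from .events import apply_bolus

    ev = BolusEvent(time=0.0, species=species, volume_added=volume, stock_concentration=stock)
    return apply_bolus(state, ev, stock_ws=params.ws0)


def _refine_by_shooting(
    state: ReleaseState,
    params: ReleaseParameters,
    variant: ModelVariant,
    r_target: float,
    dt: float,
    e_add0: float,
    template: ExperimentDesign,
) -> float:
    """Minimize the squared end-of-interval glucose error over E_add."""
    P_goal = state.P + r_target * dt

    def cost(e_add: float) -> float:
        s = ReleaseState(state.P, state.S, state.WS, state.E + max(e_add, 0.0), state.V)
        seg = simulate(_segment_design(s, 0.0, dt, template), params, variant)
        return (seg.states[-1, 0] - P_goal) ** 2

    hi = max(2.0 * e_add0, 1e-6)
    res = minimize_scalar(cost, bounds=(0.0, hi), method="bounded",
                          options={"xatol": 1e-6})
    return float(res.x) if res.fun <= cost(e_add0) else e_add0
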