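"""Macro-kinetic E. coli growth coupled to the enzymatic glucose release.

The release model feeds dissolved glucose into a standard aerobic
macro-kinetic description of E. coli fed-batch physiology: Monod glucose
uptake, acetate overflow above a critical specific uptake rate, acetate
re-consumption when uptake capacity is spare, an oxygen balance mapping
volumetric uptake to dissolved oxygen tension (DOT) through kLa, and
first-order recombinant product formation after induction with a reduced
uptake capacity (metabolic load). The structure is the common textbook
family for this organism; every coefficient is configurable and the
defaults are illustrative, not measured values.

State vector: [P, S, WS, E, V, X, A, DOT, Prod] — the first five entries
are exactly the release-model state, so with X = 0 the system reduces to
the cell-free release dynamics.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .events import (
    BolusEvent,
    Event,
    ExperimentDesign,
    SampleEvent,
    SimulationError,
    apply_bolus,
    apply_sample,
)
from .kinetics import ModelVariant, ReleaseParameters, ReleaseState, ZERO_SUBSTRATE_EPS, _denominator
from .planner import FeedPlan

__all__ = [
    "CultureState",
    "GrowthParameters",
    "CultureTrajectory",
    "growth_rhs",
    "simulate_cultivation",
    "observed_mu",
    "biomass_from_base",
    "OD600_TO_BIOMASS",
]

#: OD600-to-biomass conversion factor [g/L per OD unit].
OD600_TO_BIOMASS = 0.37


@dataclass
class CultureState(ReleaseState):
    """Release-model state extended with the culture observables.

    X : biomass [g/L]; A : acetate [g/L]; DOT : dissolved oxygen tension
    [% air saturation]; Prod : recombinant product [g/L].
    """

    X: float = 0.0
    A: float = 0.0
    DOT: float = 100.0
    Prod: float = 0.0

    def __post_init__(self) -> None:
        super().__post_init__()
        if self.X < 0 or self.A < 0 or self.Prod < 0:
            raise ValueError("X, A and Prod must be >= 0")
        if not 0.0 <= self.DOT <= 100.0:
            raise ValueError(f"DOT must lie in [0, 100], got {self.DOT}")

    def as_vector(self) -> list[float]:
        return [self.P, self.S, self.WS, self.E, self.V, self.X, self.A, self.DOT, self.Prod]

    @classmethod
    def from_vector(cls, y) -> "CultureState":
        P, S, WS, E, V, X, A, DOT, Prod = (float(v) for v in y)
        return cls(
            P=max(P, 0.0), S=max(S, 0.0), WS=min(max(WS, 0.0), 1.0), E=max(E, 0.0), V=V,
            X=max(X, 0.0), A=max(A, 0.0), DOT=min(max(DOT, 0.0), 100.0), Prod=max(Prod, 0.0),
        )

    def release_view(self) -> ReleaseState:
        return ReleaseState(P=self.P, S=self.S, WS=self.WS, E=self.E, V=self.V)


@dataclass
class GrowthParameters:
    """Coefficients of the macro-kinetic growth model (illustrative defaults).

    qS_max : maximal specific glucose uptake [g/(g h)]; with Y_XS it caps
        growth at mu_max ~ Y_XS * qS_max.
    K_s : glucose affinity [g/L].
    Y_XS : biomass yield on glucose [g/g].
    qS_crit : critical specific uptake above which overflow sets in [g/(g h)].
    Y_AS : acetate yield on overflow glucose flux [g/g].
    qA_max, K_a : acetate re-uptake capacity [g/(g h)] and affinity [g/L].
    Y_XA : biomass yield on acetate [g/g].
    Y_OS : oxygen demand per oxidized glucose [g O2 / g].
    kLa : volumetric oxygen transfer coefficient [1/h].
    DOT_star : DOT in equilibrium with the gas phase [%].
    c_o2_sat : dissolved O2 at 100% DOT [g/L].
    induction_uptake_factor : multiplier on qS_max after induction
        (metabolic load), in (0, 1].
    q_prod : specific product formation rate after induction [g/(g h)].
    mu_max : reference maximal growth rate [1/h] (documentation value).
    """

    qS_max: float = 1.4
    K_s: float = 0.05
    Y_XS: float = 0.5
    qS_crit: float = 0.7
    Y_AS: float = 0.4
    qA_max: float = 0.1
    K_a: float = 0.1
    Y_XA: float = 0.3
    Y_OS: float = 0.6
    kLa: float = 400.0
    DOT_star: float = 100.0
    c_o2_sat: float = 0.0075
    induction_uptake_factor: float = 0.45
    q_prod: float = 0.03
    mu_max: float = 0.7

    def __post_init__(self) -> None:
        for name in (
            "qS_max", "K_s", "Y_XS", "qS_crit", "Y_AS", "qA_max", "K_a",
            "Y_XA", "Y_OS", "kLa", "DOT_star", "c_o2_sat", "q_prod", "mu_max",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 < self.induction_uptake_factor <= 1.0:
            raise ValueError("induction_uptake_factor must lie in (0, 1]")


def growth_rhs(
    state: CultureState,
    gp: GrowthParameters,
    rp: ReleaseParameters,
    induced: bool = False,
    variant: ModelVariant = ModelVariant.TWO_SUBSTRATE,
) -> tuple[float, ...]:
    """Time derivatives of the coupled release + growth system."""
    y = state.as_vector()
    return tuple(_culture_rhs(0.0, np.asarray(y), rp, gp, variant, induced))


def _culture_rhs(t, y, rp: ReleaseParameters, gp: GrowthParameters,
                 variant: ModelVariant, induced: bool):
    P = y[0] if y[0] > 0 else 0.0
    S = y[1] if y[1] > 0 else 0.0
    WS = min(max(y[2], 0.0), 1.0)
    E = y[3] if y[3] > 0 else 0.0
    V = y[4]
    X = y[5] if y[5] > 0 else 0.0
    A = y[6] if y[6] > 0 else 0.0
    DOT = min(max(y[7], 0.0), 100.0)

    denom = _denominator(S, P, rp, variant)
    rS = rp.k_s * E * WS * S / denom
    rR = rp.k_r * E * (1.0 - WS) * S / denom

    qS_cap = gp.qS_max * (gp.induction_uptake_factor if induced else 1.0)
    qS = qS_cap * P / (P + gp.K_s)
    qS_ox = min(qS, gp.qS_crit)
    qS_of = qS - qS_ox
    # acetate re-uptake only with spare oxidative capacity
    spare = max(gp.qS_crit - qS_ox, 0.0) / gp.qS_crit if gp.qS_crit > 0 else 0.0
    qA = gp.qA_max * A / (A + gp.K_a) * spare
    mu = gp.Y_XS * qS_ox + gp.Y_XA * qA
    q_o2 = gp.Y_OS * (qS_ox + qA)

    dV = -rp.r_evap
    dil = dV / V

    dP = rp.nu * (rS + rR) - qS * X - dil * P
    dS = -(rS + rR) - dil * S
    dWS = (-rS + WS * (rS + rR)) / S if S > ZERO_SUBSTRATE_EPS else 0.0
    dE = -dil * E
    dX = mu * X - dil * X
    dA = (gp.Y_AS * qS_of - qA) * X - dil * A
    our = q_o2 * X  # g O2 / (L h)
    dDOT = gp.kLa * (gp.DOT_star - DOT) - our * 100.0 / gp.c_o2_sat
    if DOT <= 0.0 and dDOT < 0.0:
        dDOT = 0.0
    dProd = (gp.q_prod * X if induced else 0.0)
    return [dP, dS, dWS, dE, dV, dX, dA, dDOT, dProd]


@dataclass
class CultureTrajectory:
    """Grid of simulated culture states, columns per CultureState vector."""

    times: np.ndarray
    states: np.ndarray
    event_times: np.ndarray = field(default_factory=lambda: np.empty(0))
    experiment_id: str = ""

    _COLS = ("P", "S", "WS", "E", "V", "X", "A", "DOT", "Prod")

    def __getattr__(self, name):
        try:
            idx = CultureTrajectory._COLS.index(name)
        except ValueError:
            raise AttributeError(name) from None
        return self.states[:, idx]

    def to_frame(self):
        import pandas as pd

        P, S, WS, E, V, X, A, DOT, Prod = (self.states[:, j] for j in range(9))
        return pd.DataFrame(
            {
                "time_h": self.times,
                "P_gL": P, "S_gL": S, "WS": WS, "SS_gL": WS * S,
                "SR_gL": (1.0 - WS) * S, "E_UL": E, "V_L": V,
                "X_gL": X, "A_gL": A, "DOT_pct": DOT, "Prod_gL": Prod,
            }
        )


def _apply_culture_event(state: CultureState, event: Event, rp: ReleaseParameters) -> CultureState:
    """Boluses dilute the culture observables exactly like the release species."""
    if isinstance(event, SampleEvent):
        base = apply_sample(state.release_view(), event)
        return replace(state, V=base.V)
    base = apply_bolus(state.release_view(), event, stock_ws=rp.ws0)
    f = state.V / base.V
    return CultureState(
        P=base.P, S=base.S, WS=base.WS, E=base.E, V=base.V,
        X=state.X * f, A=state.A * f, DOT=state.DOT, Prod=state.Prod * f,
    )


def simulate_cultivation(
    design: ExperimentDesign,
    rp: ReleaseParameters,
    gp: GrowthParameters,
    plan: FeedPlan | None = None,
    induction_time: float | None = None,
    initial_state: CultureState | None = None,
    plan_t_offset: float = 0.0,
    variant: ModelVariant = ModelVariant.TWO_SUBSTRATE,
    dense_step: float = 0.05,
) -> CultureTrajectory:
    """Piecewise integration of the coupled system under a feed plan.

    Events come from the design plus (optionally) the plan's boluses shifted
    by ``plan_t_offset`` (feed-phase-relative times to process time). The
    induction time splits the integration into a pre- and post-induction
    regime with the induced parameter set.
    """
    if initial_state is None:
        base = design.initial_state
        initial_state = CultureState(P=base.P, S=base.S, WS=base.WS, E=base.E, V=base.V)
    events: list[Event] = list(design.events)
    if plan is not None:
        events += [e for e in plan.to_events(t_offset=plan_t_offset) if e.time <= design.horizon]
    events.sort(key=lambda e: e.time)

    breakpoints = sorted({e.time for e in events} | ({induction_time} if induction_time is not None else set()))
    breakpoints = [b for b in breakpoints if 0.0 < b < design.horizon]
    segments = []
    prev = 0.0
    for b in breakpoints:
        segments.append((prev, b))
        prev = b
    segments.append((prev, design.horizon))

    grid = np.unique(np.concatenate([
        np.arange(0.0, design.horizon + 1e-12, dense_step),
        [design.horizon],
        [e.time for e in events],
    ]))

    y = np.asarray(initial_state.as_vector(), dtype=float)
    ei = 0
    while ei < len(events) and events[ei].time == 0.0:
        y = np.asarray(_apply_culture_event(CultureState.from_vector(y), events[ei], rp).as_vector())
        ei += 1

    times_out = [0.0]
    states_out = [y.copy()]

    for t0, t1 in segments:
        induced = induction_time is not None and t0 >= induction_time - 1e-12
        seg_eval = grid[(grid > t0 + 1e-12) & (grid <= t1 + 1e-12)]
        if seg_eval.size == 0 or seg_eval[-1] < t1 - 1e-12:
            seg_eval = np.append(seg_eval, t1)
        sol = solve_ivp(
            _culture_rhs, (t0, t1), y, method="LSODA", t_eval=seg_eval,
            rtol=design.rtol, atol=design.atol, args=(rp, gp, variant, induced),
        )
        if not sol.success:
            raise SimulationError(f"cultivation integration failed on [{t0:.4g}, {t1:.4g}] h: {sol.message}")
        for tk, yk in zip(sol.t, sol.y.T):
            yk = yk.copy()
            yk[[0, 1, 3, 5, 6, 8]] = np.maximum(yk[[0, 1, 3, 5, 6, 8]], 0.0)
            yk[2] = min(max(yk[2], 0.0), 1.0)
            yk[7] = min(max(yk[7], 0.0), 100.0)
            if tk < t1 - 1e-12:
                times_out.append(tk)
                states_out.append(yk)
        y = sol.y[:, -1].copy()
        y[[0, 1, 3, 5, 6, 8]] = np.maximum(y[[0, 1, 3, 5, 6, 8]], 0.0)
        y[2] = min(max(y[2], 0.0), 1.0)
        y[7] = min(max(y[7], 0.0), 100.0)
        while ei < len(events) and abs(events[ei].time - t1) <= 1e-12:
            y = np.asarray(_apply_culture_event(CultureState.from_vector(y), events[ei], rp).as_vector())
            ei += 1
        times_out.append(t1)
        states_out.append(y.copy())

    times = np.asarray(times_out)
    states = np.vstack(states_out)
    keep = np.append(np.diff(times) > 0, True)
    return CultureTrajectory(
        times=times[keep], states=states[keep],
        event_times=np.asarray([e.time for e in events]),
        experiment_id=design.experiment_id,
    )


def observed_mu(times: Sequence[float], biomass: Sequence[float],
                window: tuple[float, float] | None = None) -> float:
    """Specific growth rate [1/h]: slope of the least-squares line ln X vs t."""
    t = np.asarray(times, dtype=float)
    x = np.asarray(biomass, dtype=float)
    if window is not None:
        m = (t >= window[0]) & (t <= window[1])
        t, x = t[m], x[m]
    if t.size < 3:
        raise ValueError("need at least 3 points in the window")
    if np.any(x <= 0):
        raise ValueError("biomass must be positive throughout the window")
    slope = np.polyfit(t, np.log(x), 1)[0]
    return float(slope)


def biomass_from_base(
    base_events: Sequence[BolusEvent],
    volume: float,
    molarity: float = 7.0,
    nitrogen_to_biomass: float = 8.0,
) -> "np.ndarray":
    """Biomass increment estimate [g/L] from the cumulative ammonia dosed.

    Growing cells consume ammonia as nitrogen source; the pH controller
    replaces it, so the base ledger mirrors biomass formation. Each base
    bolus of ``v`` L at ``molarity`` mol/L contributes
    v * molarity * 14.007 g N, converted with ``nitrogen_to_biomass``
    [g biomass / g N] and referenced to the culture ``volume``.

    Returns the cumulative estimate per event, in event order.
    """
    if volume <= 0:
        raise ValueError("volume must be > 0")
    n_mass = np.array([e.volume_added * molarity * 14.007 for e in base_events])
    return np.cumsum(n_mass) * nitrogen_to_biomass / volume


def od600_to_biomass(od: float | np.ndarray, factor: float = OD600_TO_BIOMASS):
    """Convert OD600 readings to biomass [g/L] (invertible linear map)."""
    return np.asarray(od, dtype=float) * factor


def biomass_to_od600(x: float | np.ndarray, factor: float = OD600_TO_BIOMASS):
    return np.asarray(x, dtype=float) / factor
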