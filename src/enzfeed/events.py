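"""Piecewise ODE integration between discrete liquid-handling events.

Additions of dextrin, glucose, enzyme and pH-control reagents, as well as
samplings, are instantaneous boluses in a well-mixed ~10 mL vessel. At each
event the integration is stopped, the volume-dependent states are
recomputed from an ideal-mixing mass balance, and the integration is
restarted from the new state.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .kinetics import ModelVariant, ReleaseParameters, ReleaseState, rhs_vector

__all__ = [
    "BolusEvent",
    "SampleEvent",
    "ExperimentDesign",
    "Trajectory",
    "apply_bolus",
    "apply_sample",
    "simulate",
    "DEFAULT_STOCKS",
    "SimulationError",
]

#: Default stock concentrations of the liquid-handling station
#: (enzyme [U/L], dextrin and glucose [g/L]; pH reagents and water carry
#: no modeled species).
DEFAULT_STOCKS: dict[str, float] = {
    "enzyme": 3000.0,
    "dextrin": 150.0,
    "glucose": 600.0,
    "base": 0.0,
    "acid": 0.0,
    "water": 0.0,
}

_SPECIES = tuple(DEFAULT_STOCKS)


class SimulationError(RuntimeError):
    """Integration failure, annotated with the failing time span."""


@dataclass(frozen=True)
class BolusEvent:
    """Instantaneous addition of ``volume_added`` L of a stock solution."""

    time: float
    species: str
    volume_added: float
    stock_concentration: float | None = None

    def __post_init__(self) -> None:
        if self.time < 0:
            raise ValueError(f"event time must be >= 0, got {self.time}")
        if self.species not in _SPECIES:
            raise ValueError(f"unknown species {self.species!r}; expected one of {_SPECIES}")
        if self.volume_added <= 0:
            raise ValueError(f"volume_added must be > 0, got {self.volume_added}")
        if self.stock_concentration is not None and self.stock_concentration < 0:
            raise ValueError("stock_concentration must be >= 0")

    @property
    def stock(self) -> float:
        if self.stock_concentration is None:
            return DEFAULT_STOCKS[self.species]
        return self.stock_concentration


@dataclass(frozen=True)
class SampleEvent:
    """Well-mixed removal of ``volume_removed`` L (an at-line sample)."""

    time: float
    volume_removed: float

    def __post_init__(self) -> None:
        if self.time < 0:
            raise ValueError(f"event time must be >= 0, got {self.time}")
        if self.volume_removed <= 0:
            raise ValueError(f"volume_removed must be > 0, got {self.volume_removed}")


Event = BolusEvent | SampleEvent


@dataclass
class ExperimentDesign:
    """Initial state, time-ordered event list and horizon of one experiment."""

    initial_state: ReleaseState
    horizon: float
    events: list[Event] = field(default_factory=list)
    rtol: float = 1e-8
    atol: float = 1e-10
    experiment_id: str = ""

    def __post_init__(self) -> None:
        if self.horizon <= 0:
            raise ValueError(f"horizon must be > 0, got {self.horizon}")
        self.events = sorted(self.events, key=lambda e: e.time)
        for e in self.events:
            if e.time > self.horizon:
                raise ValueError(
                    f"event at t={e.time} h lies beyond the horizon {self.horizon} h"
                )

    def with_events(self, extra: Sequence[Event]) -> "ExperimentDesign":
        return replace(self, events=list(self.events) + list(extra))


@dataclass
class Trajectory:
    """Solution grid of one simulated experiment.

    ``states`` has one row per time, columns (P, S, WS, E, V). Event times
    appear once with the post-event state.
    """

    times: np.ndarray
    states: np.ndarray
    event_times: np.ndarray = field(default_factory=lambda: np.empty(0))
    experiment_id: str = ""

    _COLS = ("P", "S", "WS", "E", "V")

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.states = np.asarray(self.states, dtype=float)
        if self.states.shape != (self.times.size, 5):
            raise ValueError("states must be (n_times, 5)")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")

    def __getattr__(self, name):
        try:
            idx = Trajectory._COLS.index(name)
        except ValueError:
            raise AttributeError(name) from None
        return self.states[:, idx]

    def state_at(self, t: float) -> ReleaseState:
        """State at grid time ``t`` (must be on the grid)."""
        idx = np.searchsorted(self.times, t)
        if idx >= self.times.size or not np.isclose(self.times[idx], t, atol=1e-9):
            raise KeyError(f"t={t} is not on the trajectory grid")
        return ReleaseState.from_vector(self.states[idx])

    def interp(self, t) -> np.ndarray:
        """Linear interpolation of the state columns at times ``t``."""
        t = np.atleast_1d(np.asarray(t, dtype=float))
        return np.column_stack([np.interp(t, self.times, self.states[:, j]) for j in range(5)])

    def to_frame(self) -> pd.DataFrame:
        """Tidy export: time_h, P_gL, S_gL, WS, SS_gL, SR_gL, E_UL, V_L."""
        P, S, WS, E, V = (self.states[:, j] for j in range(5))
        return pd.DataFrame(
            {
                "time_h": self.times,
                "P_gL": P,
                "S_gL": S,
                "WS": WS,
                "SS_gL": WS * S,
                "SR_gL": (1.0 - WS) * S,
                "E_UL": E,
                "V_L": V,
            }
        )


def apply_bolus(
    state: ReleaseState, event: BolusEvent, stock_ws: float | None = None
) -> ReleaseState:
    """Ideal-mixing update of all concentrations for one bolus addition.

    Every concentration is diluted by V/V'; the added species additionally
    receives the stock mass. Added dextrin is split into the two pools with
    susceptible fraction ``stock_ws`` (the fresh-stock composition), so the
    pool balance is

        SS' = (SS*V + stock_ws * D_stock * v) / V',   WS' = SS'/S'.
    """
    v = event.volume_added
    V_new = state.V + v
    f = state.V / V_new
    P, S, E = state.P * f, state.S * f, state.E * f
    SS = state.SS * f
    add = event.stock * v / V_new
    if event.species == "glucose":
        P += add
    elif event.species == "enzyme":
        E += add
    elif event.species == "dextrin":
        if stock_ws is None:
            raise ValueError("dextrin bolus requires the stock susceptible fraction stock_ws")
        S += add
        SS += stock_ws * add
    WS = SS / S if S > 0 else state.WS
    return ReleaseState(P=P, S=S, WS=min(max(WS, 0.0), 1.0), E=E, V=V_new)


def apply_sample(state: ReleaseState, event: SampleEvent) -> ReleaseState:
    """Remove a well-mixed sample: volume drops, concentrations unchanged."""
    if event.volume_removed >= state.V:
        raise ValueError(
            f"cannot remove {event.volume_removed} L from a {state.V} L vessel"
        )
    return replace(state, V=state.V - event.volume_removed)


def apply_event(state: ReleaseState, event: Event, params: ReleaseParameters) -> ReleaseState:
    if isinstance(event, BolusEvent):
        return apply_bolus(state, event, stock_ws=params.ws0)
    return apply_sample(state, event)


def simulate(
    design: ExperimentDesign,
    params: ReleaseParameters,
    variant: ModelVariant = ModelVariant.TWO_SUBSTRATE,
    t_eval: Sequence[float] | None = None,
    dense_step: float = 0.25,
) -> Trajectory:
    """Integrate the release ODEs piecewise across the design's events.

    The horizon is cut into segments at the event times; each segment is
    solved with a stiff-capable adaptive integrator (LSODA) at the design's
    tolerances, the event's mixing rule is applied, and integration
    restarts. The output grid is ``t_eval`` if given (event times are
    inserted), otherwise a uniform grid of spacing ``dense_step`` plus all
    event times.
    """
    events = sorted(design.events, key=lambda e: e.time)
    event_times = np.array([e.time for e in events])

    if t_eval is None:
        grid = np.arange(0.0, design.horizon + 1e-12, dense_step)
        if grid[-1] < design.horizon:
            grid = np.append(grid, design.horizon)
    else:
        grid = np.asarray(sorted(set(float(t) for t in t_eval)))
        if grid.size and (grid[0] < 0 or grid[-1] > design.horizon):
            raise ValueError("t_eval outside [0, horizon]")
    grid = np.unique(np.concatenate([grid, event_times, [0.0, design.horizon]]))

    times_out: list[float] = []
    states_out: list[np.ndarray] = []

    def _clip(y: np.ndarray) -> np.ndarray:
        y = y.copy()
        y[:4] = np.maximum(y[:4], 0.0)
        y[2] = min(y[2], 1.0)
        return y

    y = np.asarray(design.initial_state.as_vector(), dtype=float)
    t_now = 0.0
    times_out.append(0.0)
    states_out.append(y.copy())

    # breakpoints: each distinct event time once; same-time events apply in order
    breakpoints = sorted(set(event_times.tolist()))
    segments = []
    prev = 0.0
    for bt in breakpoints:
        if bt > prev:
            segments.append((prev, bt))
        prev = max(prev, bt)
    if prev < design.horizon:
        segments.append((prev, design.horizon))

    ei = 0  # event cursor
    # events at t=0 apply before any integration
    while ei < len(events) and events[ei].time == 0.0:
        y = np.asarray(apply_event(ReleaseState.from_vector(y), events[ei], params).as_vector())
        ei += 1
    states_out[-1] = y.copy()

    for t0, t1 in segments:
        seg_eval = grid[(grid > t0 + 1e-12) & (grid <= t1 + 1e-12)]
        if seg_eval.size == 0 or seg_eval[-1] < t1 - 1e-12:
            seg_eval = np.append(seg_eval, t1)
        sol = solve_ivp(
            rhs_vector,
            (t0, t1),
            y,
            method="LSODA",
            t_eval=seg_eval,
            rtol=design.rtol,
            atol=design.atol,
            args=(params, variant),
        )
        if not sol.success:
            raise SimulationError(
                f"integration failed on [{t0:.4g}, {t1:.4g}] h"
                + (f" of experiment {design.experiment_id!r}" if design.experiment_id else "")
                + f": {sol.message}"
            )
        for tk, yk in zip(sol.t, sol.y.T):
            yk = _clip(yk)
            if tk < t1 - 1e-12:
                times_out.append(tk)
                states_out.append(yk)
        y = _clip(sol.y[:, -1])
        t_now = t1
        # apply all events scheduled at this breakpoint, in listed order
        while ei < len(events) and abs(events[ei].time - t1) <= 1e-12:
            y = np.asarray(
                apply_event(ReleaseState.from_vector(y), events[ei], params).as_vector()
            )
            ei += 1
        times_out.append(t_now)
        states_out.append(y.copy())

    times = np.asarray(times_out)
    states = np.vstack(states_out)
    # collapse duplicate times keeping the last (post-event) state
    keep = np.append(np.diff(times) > 0, True)
    return Trajectory(
        times=times[keep],
        states=states[keep],
        event_times=event_times,
        experiment_id=design.experiment_id,
    )
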