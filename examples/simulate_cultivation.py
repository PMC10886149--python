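"""Simulate an E. coli fed-batch cultivation under an enzymatic feed plan.

A feed plan is built for mu_set = 0.124 1/h and applied to the coupled
release + growth model. The realized growth rate is estimated from the
slope of ln(biomass mass) — in a fed vessel the concentration series also
carries the dilution of the feed boluses, so mass is the clean readout.
"""

import numpy as np

from enzfeed import (
    CultureState,
    ExperimentDesign,
    GrowthParameters,
    ReleaseParameters,
    ReleaseState,
    SetpointSchedule,
    observed_mu,
    plan_feed,
    simulate_cultivation,
)

mu_set, X0 = 0.124, 3.0
rp = ReleaseParameters()
gp = GrowthParameters()

design = ExperimentDesign(
    initial_state=ReleaseState(P=0.05, S=40.0, WS=rp.ws0, E=0.0, V=0.010),
    horizon=6.0,
)
schedule = SetpointSchedule(phases=[(0.0, mu_set)], horizon=6.0)
plan = plan_feed(design, rp, schedule=schedule, X0=X0, Y_XS=gp.Y_XS)

start = CultureState(P=0.05, S=40.0, WS=rp.ws0, E=0.0, V=0.010, X=X0)
traj = simulate_cultivation(design, rp, gp, plan=plan, initial_state=start)

mask = traj.times >= 0.5
mu_real = observed_mu(traj.times[mask], (traj.X * traj.V)[mask])
frame = traj.to_frame()

print(f"setpoint mu              : {mu_set:.3f} 1/h")
print(f"realized mu (mass-based) : {mu_real:.3f} 1/h "
      f"({100 * abs(mu_real - mu_set) / mu_set:.1f}% off)")
print(f"biomass 0 -> 6 h         : {X0:.2f} -> {frame.X_gL.iloc[-1]:.2f} g/L")
print(f"glucose stays limiting   : max P during feed = "
      f"{np.max(frame.P_gL.iloc[5:]):.3f} g/L")
print(f"DOT drifts smoothly down : {frame.DOT_pct.iloc[10]:.0f}% -> "
      f"{frame.DOT_pct.iloc[-1]:.0f}% (no feast/famine oscillation)")
print()
print("Glucose is consumed as fast as it is released, so the culture grows")
print("exponentially at the setpoint while glucose itself stays near zero --")
print("the defining signature of a substrate-limited fed-batch.")
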