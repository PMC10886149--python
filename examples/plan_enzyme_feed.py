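"""Compute an enzyme feed plan for an exponential growth schedule.

The planner doses glucoamylase on a 10-minute grid so that the model's
glucose release follows the demand of a culture growing at mu = 0.21 1/h
for 6 h, then 0.11 1/h after induction (with 40 uL dextrin maintenance
boluses every interval). This is the "feed calculator": the printed table
is what a liquid handler — or a patient human with a pipette — executes.
"""

from enzfeed import (
    ExperimentDesign,
    ReleaseParameters,
    ReleaseState,
    SetpointSchedule,
    plan_feed,
)

params = ReleaseParameters()
design = ExperimentDesign(
    initial_state=ReleaseState(P=0.0, S=40.0, WS=params.ws0, E=0.0, V=0.010),
    horizon=10.0,
)
schedule = SetpointSchedule(
    phases=[(0.0, 0.21), (6.0, 0.11)], horizon=10.0, induction_time=6.0
)

plan = plan_feed(design, params, schedule=schedule, X0=3.0, Y_XS=0.5)

print("first feeding hour (10-min grid):")
print(plan.table.head(6).to_string(index=False, float_format=lambda x: f"{x:.3f}"))
print("...")
print(f"\ntotal enzyme stock pipetted : {plan.table.enzyme_stock_uL.sum():7.1f} uL")
print(f"total dextrin stock pipetted: {plan.table.dextrin_stock_uL.sum():7.1f} uL")
merged = plan.cumulated(window=0.5)
print(f"\nfor manual pipetting, additions can be cumulated to 30-min slots:"
      f" {len(plan.table)} -> {len(merged.table)} actions.")
print("E_add_UL is the enzyme concentration increment each dose realizes;")
print("after the induction switch the target rate halves, so dosing pauses")
print("until the (irreversible) release decays down to the new setpoint.")
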