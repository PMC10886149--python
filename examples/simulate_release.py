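"""Simulate one cell-free glucose-release experiment.

Builds a mini-bioreactor run (30 g/L dextrin, 20 U/L glucoamylase added at
t=0, a dextrin top-up at 6 h) and integrates the two-pool hydrolysis model
over 30 h.
"""

from enzfeed import (
    BolusEvent,
    ExperimentDesign,
    ReleaseParameters,
    ReleaseState,
    max_release,
    simulate,
)

params = ReleaseParameters()  # fitted kinetics: k_s=0.134, k_r=0.00212, ws0=0.464

design = ExperimentDesign(
    initial_state=ReleaseState(P=0.0, S=30.0, WS=params.ws0, E=0.0, V=0.011),
    horizon=30.0,
    events=[
        BolusEvent(time=0.0, species="enzyme", volume_added=7.38e-5,
                   stock_concentration=3000.0),
        BolusEvent(time=6.0, species="dextrin", volume_added=4.0e-4,
                   stock_concentration=150.0),
    ],
    experiment_id="demo",
)

traj = simulate(design, params)
final = traj.to_frame().iloc[-1]

print(f"glucose released after 30 h : {final.P_gL:6.2f} g/L")
print(f"dextrin remaining           : {final.S_gL:6.2f} g/L "
      f"(susceptible {final.SS_gL:.2f}, resistant {final.SR_gL:.2f})")
print(f"theoretical yield of 30 g/L : {max_release(30.0):6.2f} g/L")
print()
print("The release starts fast while the susceptible pool lasts, then slows:")
print("after 30 h roughly half the dextrin is hydrolyzed and the remainder")
print("is dominated by the resistant fraction (k_s is ~60x k_r).")
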