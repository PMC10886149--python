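import numpy as np
import pytest

from enzfeed import (
    BolusEvent,
    ExperimentDesign,
    ModelVariant,
    ReleaseParameters,
    ReleaseState,
)

TRUTH = {"k_s": 0.134, "k_r": 0.00212, "ws0": 0.464}


@pytest.fixture
def params() -> ReleaseParameters:
    """Fitted release kinetics (K fixed at 0.001 g/L)."""
    return ReleaseParameters()


@pytest.fixture
def params_noevap() -> ReleaseParameters:
    return ReleaseParameters(r_evap=0.0)


@pytest.fixture
def state() -> ReleaseState:
    """A representative mid-hydrolysis vessel state."""
    return ReleaseState(P=0.0, S=40.0, WS=0.464, E=10.0, V=0.011)


@pytest.fixture
def simple_design() -> ExperimentDesign:
    """Single enzyme addition at t=0, no further events, 30 h horizon."""
    return ExperimentDesign(
        initial_state=ReleaseState(P=0.0, S=30.0, WS=0.464, E=0.0, V=0.011),
        horizon=30.0,
        events=[
            BolusEvent(time=0.0, species="enzyme", volume_added=3.68e-5,
                       stock_concentration=3000.0)
        ],
        experiment_id="fixture",
    )


def glucose_equivalent_mass(traj, nu: float = 1.111) -> np.ndarray:
    """V*(P/nu + S): conserved along bolus-free trajectories."""
    return traj.V * (traj.P / nu + traj.S)
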