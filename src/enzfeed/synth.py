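"""Synthetic experiment designs and noisy measurements.

Emulates the two kinds of campaign the release model is calibrated and
validated on, without requiring any external data:

* a cell-free model-calibration campaign of 24 stirred mini-bioreactor
  runs spanning initial dextrin (15/30 g/L), glucose (0-15 g/L) and enzyme
  (10/20 U/L) levels, with mid-run dextrin/glucose pulses at ~6 h to probe
  substrate and product inhibition;
* two fed-batch validation campaigns (enzymatic feed at several exponential
  growth-rate setpoints, bolus-fed controls and cell-free controls), each
  condition in triplicate.

Measurements are simulated glucose concentrations plus additive Gaussian
noise truncated at zero.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .estimation import MeasurementSet
from .events import BolusEvent, ExperimentDesign, SampleEvent, Trajectory
from .kinetics import ReleaseState

__all__ = [
    "NoiseModel",
    "FedBatchCondition",
    "dataset1_designs",
    "dataset23_designs",
    "generate_measurements",
    "dataset1_measurements",
    "DATASET1_LEVELS",
]

#: Factor levels of the cell-free calibration campaign.
DATASET1_LEVELS = {
    "D0": (15.0, 30.0),
    "G0": (0.0, 3.75, 7.5, 15.0),
    "E0": (10.0, 20.0),
    "Dadd": (0.0, 5.25, 10.5),
    "Gadd": (0.0, 3.75, 7.5),
}

_DEXTRIN_STOCK = 150.0
_GLUCOSE_STOCK = 600.0
_ADDITION_TIME = 6.0
_V0_CELLFREE = 0.011  # L
_V0_FEDBATCH = 0.010  # L
_SAMPLE_VOLUME = 2.0e-4  # L


@dataclass
class NoiseModel:
    """Additive Gaussian measurement noise, truncated at zero."""

    sigma: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def _addition_volume(V: float, delta_conc: float, stock: float) -> float:
    """Stock volume giving a post-mixing concentration increment delta_conc."""
    if delta_conc >= stock:
        raise ValueError("increment exceeds the stock concentration")
    return V * delta_conc / (stock - delta_conc)


def dataset1_designs(
    horizon: float = 30.0,
    sample_every: float = 2.0,
    with_sampling: bool = False,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> list[ExperimentDesign]:
    """The 24 cell-free release designs of the calibration campaign.

    The 16-run full factorial over (D0, G0, E0) runs without mid-run
    additions; 8 further runs cycle deterministically through the 8
    non-zero (Dadd, Gadd) combinations, applied at 6 h. Initial volume
    11 mL; enzyme is added at t = 0 from the 3000 U/L stock.
    """
    factorial = list(itertools.product(
        DATASET1_LEVELS["D0"], DATASET1_LEVELS["G0"], DATASET1_LEVELS["E0"]
    ))
    addition_combos = [
        (d, g)
        for d in DATASET1_LEVELS["Dadd"]
        for g in DATASET1_LEVELS["Gadd"]
        if not (d == 0.0 and g == 0.0)
    ]
    runs = [(D0, G0, E0, 0.0, 0.0) for D0, G0, E0 in factorial]
    for i, (dadd, gadd) in enumerate(addition_combos):
        D0, G0, E0 = factorial[(2 * i) % len(factorial)]
        runs.append((D0, G0, E0, dadd, gadd))

    designs = []
    for idx, (D0, G0, E0, dadd, gadd) in enumerate(runs, start=1):
        events: list = [
            BolusEvent(
                time=0.0,
                species="enzyme",
                volume_added=_addition_volume(_V0_CELLFREE, E0, 3000.0),
                stock_concentration=3000.0,
            )
        ]
        if dadd > 0:
            events.append(BolusEvent(
                time=_ADDITION_TIME, species="dextrin",
                volume_added=_addition_volume(_V0_CELLFREE, dadd, _DEXTRIN_STOCK),
                stock_concentration=_DEXTRIN_STOCK,
            ))
        if gadd > 0:
            events.append(BolusEvent(
                time=_ADDITION_TIME, species="glucose",
                volume_added=_addition_volume(_V0_CELLFREE, gadd, _GLUCOSE_STOCK),
                stock_concentration=_GLUCOSE_STOCK,
            ))
        if with_sampling:
            for ts in np.arange(sample_every, horizon + 1e-9, sample_every):
                events.append(SampleEvent(time=float(ts), volume_removed=_SAMPLE_VOLUME))
        designs.append(ExperimentDesign(
            initial_state=ReleaseState(P=G0, S=D0, WS=0.464, E=0.0, V=_V0_CELLFREE),
            horizon=horizon,
            events=events,
            rtol=rtol,
            atol=atol,
            experiment_id=f"ds1_run{idx:02d}",
        ))
    return designs


@dataclass
class FedBatchCondition:
    """One row of the fed-batch validation design table."""

    condition: int
    dataset: int
    feed_method: str  # "bolus", "enzymatic", "enzymatic_two_additions"
    mu_set_pre: float
    mu_set_post: float
    G0: float
    D0: float
    cells: bool
    replicate: int = 1

    @property
    def cell_free(self) -> bool:
        return not self.cells

    @property
    def experiment_id(self) -> str:
        return f"ds{self.dataset}_c{self.condition:02d}_r{self.replicate}"

    def design(self, horizon: float = 20.0, rtol: float = 1e-8, atol: float = 1e-10) -> ExperimentDesign:
        return ExperimentDesign(
            initial_state=ReleaseState(P=self.G0, S=self.D0, WS=0.464, E=0.0, V=_V0_FEDBATCH),
            horizon=horizon,
            events=[],
            rtol=rtol,
            atol=atol,
            experiment_id=self.experiment_id,
        )


_DATASET2_ROWS = [
    # condition, feed_method, mu_pre, mu_post, G0, D0, cells
    (1, "bolus", 0.18, 0.09, 5.0, 2.0, True),
    (2, "bolus", 0.21, 0.11, 5.0, 2.0, True),
    (3, "enzymatic", 0.18, 0.09, 5.0, 40.0, True),
    (4, "enzymatic", 0.21, 0.11, 5.0, 40.0, True),
    (5, "enzymatic_two_additions", 0.18, 0.09, 5.0, 40.0, True),
    (6, "enzymatic_two_additions", 0.21, 0.11, 5.0, 40.0, True),
    (7, "enzymatic", 0.18, 0.09, 0.0, 40.0, False),
    (8, "enzymatic", 0.21, 0.11, 0.0, 40.0, False),
]

_DATASET3_ROWS = [
    (9, "enzymatic", 0.14, 0.07, 5.0, 40.0, True),
    (10, "enzymatic", 0.21, 0.11, 5.0, 40.0, True),
    (11, "enzymatic_two_additions", 0.25, 0.12, 5.0, 80.0, True),
    (12, "enzymatic", 0.14, 0.07, 0.0, 40.0, False),
    (13, "enzymatic", 0.21, 0.11, 0.0, 40.0, False),
]


def dataset23_designs(which: int, replicates: int = 3) -> list[FedBatchCondition]:
    """Triplicated fed-batch validation conditions (campaign 2 or 3)."""
    if which not in (2, 3):
        raise ValueError("which must be 2 or 3")
    rows = _DATASET2_ROWS if which == 2 else _DATASET3_ROWS
    out = []
    for cond, method, mu_pre, mu_post, G0, D0, cells in rows:
        for rep in range(1, replicates + 1):
            out.append(FedBatchCondition(
                condition=cond, dataset=which, feed_method=method,
                mu_set_pre=mu_pre, mu_set_post=mu_post,
                G0=G0, D0=D0, cells=cells, replicate=rep,
            ))
    return out


def generate_measurements(
    trajectory: Trajectory,
    sample_times,
    noise: NoiseModel | None = None,
    rng: np.random.Generator | None = None,
) -> MeasurementSet:
    """Noisy glucose observations of a simulated trajectory.

    observed = max(0, simulated + N(0, sigma)); reproducible per seed. An
    explicit ``rng`` may be passed to draw several experiments from one
    seeded stream.
    """
    noise = noise if noise is not None else NoiseModel()
    t = np.asarray(list(sample_times), dtype=float)
    if t.size and (t.min() < trajectory.times[0] - 1e-9 or t.max() > trajectory.times[-1] + 1e-9):
        raise ValueError("sampling times outside the trajectory span")
    sim_P = trajectory.interp(t)[:, 0]
    rng = rng if rng is not None else noise.rng()
    obs = sim_P + rng.normal(0.0, noise.sigma, size=sim_P.shape) if noise.sigma > 0 else sim_P.copy()
    obs = np.maximum(obs, 0.0)
    return MeasurementSet(pd.DataFrame({
        "experiment_id": trajectory.experiment_id or "exp",
        "time_h": t,
        "glucose_gL": obs,
        "sd": noise.sigma if noise.sigma > 0 else np.nan,
    }))


def dataset1_measurements(
    designs: list[ExperimentDesign],
    params,
    noise: NoiseModel | None = None,
    sample_every: float = 2.0,
    variant=None,
) -> MeasurementSet:
    """Simulate every design and sample noisy glucose on a uniform grid."""
    from .events import simulate
    from .kinetics import ModelVariant

    noise = noise if noise is not None else NoiseModel()
    variant = variant if variant is not None else ModelVariant.TWO_SUBSTRATE
    rng = noise.rng()
    sets = []
    for d in designs:
        times = np.arange(0.0, d.horizon + 1e-9, sample_every)
        traj = simulate(d, params, variant, t_eval=times)
        sets.append(generate_measurements(traj, times, noise=noise, rng=rng))
    return MeasurementSet(pd.concat([s.data for s in sets], ignore_index=True))
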