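"""Multi-experiment parameter estimation and model-variant comparison.

All experiments of a campaign are fitted simultaneously: one parameter
vector must explain every glucose time series. The objective is the plain
residual sum of squares (RSS) on glucose, minimized globally by seeded
differential evolution (population 20, up to 200 generations) and polished
locally by bounded nonlinear least squares. Variants are ranked by RSS.
"""

from __future__ import annotations

from dataclasses import dataclass, replace as dc_replace
from typing import Sequence

import lmfit
import numpy as np
import pandas as pd
from scipy.optimize import differential_evolution

from .events import ExperimentDesign, simulate
from .kinetics import ModelVariant, ReleaseParameters

__all__ = [
    "MeasurementSet",
    "FitResult",
    "rss",
    "fit_local",
    "fit_global",
    "compare_variants",
    "free_parameters",
    "DEFAULT_BOUNDS",
]

#: Default estimation bounds, spanning the literature by orders of magnitude.
DEFAULT_BOUNDS: dict[str, tuple[float, float]] = {
    "k_s": (1e-5, 1.0),
    "k_r": (1e-5, 1.0),
    "k_single": (1e-5, 1.0),
    "ws0": (0.0, 1.0),
    "Ki_P": (0.1, 1000.0),
    "Ki_S": (0.1, 1000.0),
}


def free_parameters(variant: ModelVariant) -> list[str]:
    """Free parameters of a variant (K stays fixed at its configured value)."""
    names = ["k_s", "k_r", "ws0"] if variant.two_substrate else ["k_single"]
    if variant.product_inhibition:
        names.append("Ki_P")
    if variant.substrate_inhibition:
        names.append("Ki_S")
    return names


@dataclass
class MeasurementSet:
    """Observed glucose concentrations, one row per (experiment, time).

    Backed by a DataFrame with columns ``experiment_id``, ``time_h``,
    ``glucose_gL`` and optional ``sd``.
    """

    data: pd.DataFrame

    REQUIRED = ("experiment_id", "time_h", "glucose_gL")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.data.columns]
        if missing:
            raise ValueError(f"measurement table lacks columns {missing}")
        if (self.data["glucose_gL"] < 0).any():
            raise ValueError("observed glucose must be >= 0")
        if "sd" not in self.data.columns:
            self.data = self.data.assign(sd=np.nan)
        self.data = self.data.sort_values(["experiment_id", "time_h"]).reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.data)

    def experiments(self) -> list[str]:
        return list(dict.fromkeys(self.data["experiment_id"]))

    def for_experiment(self, experiment_id: str) -> pd.DataFrame:
        return self.data[self.data["experiment_id"] == experiment_id]

    def merged(self, other: "MeasurementSet") -> "MeasurementSet":
        return MeasurementSet(pd.concat([self.data, other.data], ignore_index=True))

    def to_csv(self, path, **kwargs) -> None:
        self.data.to_csv(path, sep="\t", index=False, **kwargs)

    @classmethod
    def from_csv(cls, path) -> "MeasurementSet":
        return cls(pd.read_csv(path, sep="\t", comment="#"))


@dataclass
class FitResult:
    """Outcome of one estimation run."""

    variant: ModelVariant
    params: ReleaseParameters
    estimates: dict[str, float]
    stderr: dict[str, float | None]
    rss: float
    n_obs: int
    n_eval: int = 0
    seed: int | None = None
    success: bool = True
    message: str = ""

    def to_dict(self) -> dict:
        return {
            "variant": self.variant.value,
            "estimates": self.estimates,
            "stderr": self.stderr,
            "rss": self.rss,
            "n_obs": self.n_obs,
            "n_eval": self.n_eval,
            "seed": self.seed,
            "success": self.success,
            "message": self.message,
        }


def _with_trial_ws0(design: ExperimentDesign, params: ReleaseParameters) -> ExperimentDesign:
    """Start each experiment from fresh dextrin of the trial composition.

    ws0 is the initial susceptible fraction: it is simultaneously the
    initial condition WS(0) of every calibration experiment and the
    composition of added dextrin stock, so a trial value must override the
    design's starting WS.
    """
    if design.initial_state.S <= 0:
        return design
    state = dc_replace(design.initial_state, WS=params.ws0)
    return dc_replace(design, initial_state=state)


def _residuals(
    params: ReleaseParameters,
    designs: Sequence[ExperimentDesign],
    data: MeasurementSet,
    variant: ModelVariant,
    weighted: bool = False,
) -> np.ndarray:
    by_id = {d.experiment_id: d for d in designs}
    out: list[np.ndarray] = []
    for exp_id in data.experiments():
        if exp_id not in by_id:
            raise KeyError(f"no design for experiment {exp_id!r}")
        obs = data.for_experiment(exp_id)
        t_obs = obs["time_h"].to_numpy()
        design = by_id[exp_id]
        if variant.two_substrate:
            design = _with_trial_ws0(design, params)
        try:
            traj = simulate(design, params, variant, t_eval=t_obs)
        except Exception as err:
            raise RuntimeError(f"simulation failed for experiment {exp_id!r}") from err
        sim_P = traj.interp(t_obs)[:, 0]
        res = sim_P - obs["glucose_gL"].to_numpy()
        if weighted:
            sd = obs["sd"].to_numpy()
            res = np.where(np.isfinite(sd) & (sd > 0), res / sd, res)
        out.append(res)
    return np.concatenate(out)


def rss(
    params: ReleaseParameters,
    designs: Sequence[ExperimentDesign],
    data: MeasurementSet,
    variant: ModelVariant = ModelVariant.TWO_SUBSTRATE,
) -> float:
    """Residual sum of squared errors of simulated vs observed glucose."""
    r = _residuals(params, designs, data, variant)
    return float(np.dot(r, r))


def _apply(base: ReleaseParameters, names: Sequence[str], values: Sequence[float]) -> ReleaseParameters:
    return base.replace(**dict(zip(names, (float(v) for v in values))))


def canonicalize(params: ReleaseParameters) -> ReleaseParameters:
    """Resolve the two-pool label-swap symmetry.

    Swapping (k_s, k_r) while replacing ws0 by 1 - ws0 leaves the
    two-substrate model invariant, so the likelihood has two mirror optima.
    The convention is that the susceptible pool is the fast one: k_s >= k_r.
    """
    if params.k_r > params.k_s:
        return params.replace(k_s=params.k_r, k_r=params.k_s, ws0=1.0 - params.ws0)
    return params


def fit_local(
    start: ReleaseParameters,
    designs: Sequence[ExperimentDesign],
    data: MeasurementSet,
    variant: ModelVariant = ModelVariant.TWO_SUBSTRATE,
    free: Sequence[str] | None = None,
    bounds: dict[str, tuple[float, float]] | None = None,
    weighted: bool = False,
) -> FitResult:
    """Bounded nonlinear least squares from ``start`` (lmfit ``least_squares``).

    Standard deviations are the linearized (Jacobian-based) values at the
    optimum; ``None`` where the covariance is unavailable.
    """
    free = list(free) if free is not None else free_parameters(variant)
    bnds = dict(DEFAULT_BOUNDS)
    if bounds:
        bnds.update(bounds)

    lm = lmfit.Parameters()
    for name in free:
        lo, hi = bnds[name]
        v0 = getattr(start, name)
        if v0 is None:
            v0 = np.sqrt(lo * hi) if lo > 0 else 0.5 * (lo + hi)
        if not lo <= v0 <= hi:
            raise ValueError(f"start value {name}={v0} outside bounds {lo, hi}")
        lm.add(name, value=v0, min=lo, max=hi)

    def objective(p: lmfit.Parameters) -> np.ndarray:
        trial = _apply(start, free, [p[n].value for n in free])
        return _residuals(trial, designs, data, variant, weighted=weighted)

    minim = lmfit.Minimizer(objective, lm)
    res = minim.minimize(method="least_squares")
    estimates = {n: float(res.params[n].value) for n in free}
    stderr = {
        n: (float(res.params[n].stderr) if res.params[n].stderr is not None else None)
        for n in free
    }
    if {"k_s", "k_r", "ws0"} <= set(free) and estimates["k_r"] > estimates["k_s"]:
        # report the canonical (k_s >= k_r) member of the label-swap pair
        estimates["k_s"], estimates["k_r"] = estimates["k_r"], estimates["k_s"]
        stderr["k_s"], stderr["k_r"] = stderr["k_r"], stderr["k_s"]
        estimates["ws0"] = 1.0 - estimates["ws0"]
    best = _apply(start, free, [estimates[n] for n in free])
    return FitResult(
        variant=variant,
        params=best,
        estimates=estimates,
        stderr=stderr,
        rss=rss(best, designs, data, variant),
        n_obs=len(data),
        n_eval=int(res.nfev),
        success=bool(res.success),
        message=str(getattr(res, "message", "")),
    )


def fit_global(
    designs: Sequence[ExperimentDesign],
    data: MeasurementSet,
    variant: ModelVariant = ModelVariant.TWO_SUBSTRATE,
    bounds: dict[str, tuple[float, float]] | None = None,
    base: ReleaseParameters | None = None,
    population: int = 20,
    generations: int = 200,
    seed: int = 0,
    polish: bool = True,
) -> FitResult:
    """Seeded differential evolution over the bounds, then a local polish.

    The DE stage explores the full box (population ``population`` for up to
    ``generations`` generations, self-adaptive dithered mutation); the best
    member then seeds :func:`fit_local`. Deterministic for a given seed.
    """
    free = free_parameters(variant)
    bnds = dict(DEFAULT_BOUNDS)
    if bounds:
        bnds.update(bounds)
    box = [bnds[n] for n in free]
    base = base if base is not None else ReleaseParameters()

    ordered = variant.two_substrate and "k_s" in free and "k_r" in free
    i_ks = free.index("k_s") if ordered else -1
    i_kr = free.index("k_r") if ordered else -1

    def objective(x: np.ndarray) -> float:
        # identifiability convention k_s >= k_r: the mirror half of the box
        # holds the label-swapped duplicate of every optimum; penalizing it
        # keeps the population in one basin
        if ordered and x[i_kr] > x[i_ks]:
            return 1e6 * (1.0 + x[i_kr] - x[i_ks])
        trial = _apply(base, free, x)
        try:
            r = _residuals(trial, designs, data, variant)
        except RuntimeError:
            return 1e12
        return float(np.dot(r, r))

    de = differential_evolution(
        objective,
        bounds=box,
        popsize=population,
        maxiter=generations,
        seed=seed,
        mutation=(0.5, 1.0),
        recombination=0.7,
        init="latinhypercube",
        polish=False,
        updating="immediate",
    )
    start = _apply(base, free, de.x)
    if polish:
        result = fit_local(start, designs, data, variant, free=free, bounds=bnds)
        result.n_eval += int(de.nfev)
        result.seed = seed
        return result
    return FitResult(
        variant=variant,
        params=start,
        estimates={n: float(v) for n, v in zip(free, de.x)},
        stderr={n: None for n in free},
        rss=float(de.fun),
        n_obs=len(data),
        n_eval=int(de.nfev),
        seed=seed,
        success=bool(de.success),
        message=str(de.message),
    )


#: Table ordering used for variant-comparison reports.
VARIANT_ORDER = [
    ModelVariant.SIMPLE_MM,
    ModelVariant.SIMPLE_MM_PI,
    ModelVariant.SIMPLE_MM_SI,
    ModelVariant.SIMPLE_MM_PI_SI,
    ModelVariant.TWO_SUBSTRATE,
    ModelVariant.TWO_SUBSTRATE_PI,
    ModelVariant.TWO_SUBSTRATE_PI_SI,
]


def compare_variants(
    designs: Sequence[ExperimentDesign],
    data: MeasurementSet,
    variants: Sequence[ModelVariant] = tuple(VARIANT_ORDER),
    seed: int = 0,
    population: int = 20,
    generations: int = 200,
    base: ReleaseParameters | None = None,
) -> pd.DataFrame:
    """Fit each variant (global + local) and tabulate RSS and estimates.

    Per-variant failures are recorded in the ``error`` column rather than
    aborting the comparison. Rows follow the canonical family ordering.
    """
    rows = []
    order = {v: i for i, v in enumerate(VARIANT_ORDER)}
    for variant in sorted(variants, key=lambda v: order.get(v, 99)):
        row: dict = {"variant": variant.value}
        try:
            fit = fit_global(
                designs, data, variant,
                base=base, population=population, generations=generations, seed=seed,
            )
            row["rss"] = fit.rss
            row["error"] = ""
            for n, v in fit.estimates.items():
                row[n] = v
        except Exception as err:  # per-variant failure is not fatal
            row["rss"] = np.nan
            row["error"] = f"{type(err).__name__}: {err}"
        rows.append(row)
    return pd.DataFrame(rows)
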