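"""Config and tabular file IO.

Configs are YAML (or JSON, a YAML subset) with flat key-value blocks;
tables are tab-separated text. Every table written here carries a comment
header recording the config hash and seed so a run can be reproduced from
its outputs.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
import pandas as pd
import yaml

from .events import BolusEvent, ExperimentDesign, SampleEvent
from .kinetics import ReleaseParameters, ReleaseState
from .planner import SetpointSchedule

__all__ = [
    "load_config",
    "dump_config",
    "config_hash",
    "params_from_config",
    "design_from_config",
    "design_to_config",
    "schedule_from_config",
    "write_table",
    "read_table",
]


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"config {path} must be a mapping, got {type(cfg).__name__}")
    return cfg


def dump_config(cfg: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)


def config_hash(cfg: dict) -> str:
    """Stable short hash of a config mapping."""
    blob = json.dumps(cfg, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def params_from_config(cfg: dict) -> ReleaseParameters:
    known = {
        "k_s", "k_r", "K", "ws0", "nu", "r_evap", "k_single", "Ki_P", "Ki_S",
    }
    unknown = set(cfg) - known
    if unknown:
        raise ValueError(f"unknown parameter keys: {sorted(unknown)}")
    return ReleaseParameters(**cfg)


def _event_from_config(e: dict):
    if "volume_removed" in e:
        return SampleEvent(time=float(e["time"]), volume_removed=float(e["volume_removed"]))
    return BolusEvent(
        time=float(e["time"]),
        species=str(e["species"]),
        volume_added=float(e["volume_added"]),
        stock_concentration=(
            float(e["stock_concentration"]) if "stock_concentration" in e else None
        ),
    )


def design_from_config(cfg: dict) -> ExperimentDesign:
    st = cfg["initial_state"]
    state = ReleaseState(
        P=float(st.get("P", 0.0)),
        S=float(st.get("S", 0.0)),
        WS=float(st.get("WS", 0.0)),
        E=float(st.get("E", 0.0)),
        V=float(st["V"]),
    )
    return ExperimentDesign(
        initial_state=state,
        horizon=float(cfg["horizon"]),
        events=[_event_from_config(e) for e in cfg.get("events", [])],
        rtol=float(cfg.get("rtol", 1e-8)),
        atol=float(cfg.get("atol", 1e-10)),
        experiment_id=str(cfg.get("experiment_id", "")),
    )


def design_to_config(design: ExperimentDesign) -> dict:
    s = design.initial_state
    events = []
    for e in design.events:
        if isinstance(e, SampleEvent):
            events.append({"time": e.time, "volume_removed": e.volume_removed})
        else:
            ev = {"time": e.time, "species": e.species, "volume_added": e.volume_added}
            if e.stock_concentration is not None:
                ev["stock_concentration"] = e.stock_concentration
            events.append(ev)
    return {
        "experiment_id": design.experiment_id,
        "initial_state": {"P": s.P, "S": s.S, "WS": s.WS, "E": s.E, "V": s.V},
        "horizon": design.horizon,
        "rtol": design.rtol,
        "atol": design.atol,
        "events": events,
    }


def schedule_from_config(cfg: dict) -> SetpointSchedule:
    return SetpointSchedule(
        phases=[(float(t), float(mu)) for t, mu in cfg["phases"]],
        horizon=float(cfg["horizon"]),
        dt=float(cfg.get("dt", 1.0 / 6.0)),
        induction_time=(
            float(cfg["induction_time"]) if cfg.get("induction_time") is not None else None
        ),
    )


def write_table(df: pd.DataFrame, path, cfg: dict | None = None, seed: int | None = None) -> None:
    """Tab-separated export with a reproducibility comment header."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        if cfg is not None:
            fh.write(f"# config_hash: {config_hash(cfg)}\n")
        if seed is not None:
            fh.write(f"# seed: {seed}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")
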