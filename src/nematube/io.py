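"""Configuration and file-format plumbing (YAML config, CSV schemas,
JSON reports).  CSV files are comma-separated UTF-8 with a mandatory
header; units are encoded in the column names."""
from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .params import (ModelParams, NoiseSpec, PressureProtocol,
                     ParameterError, step_protocol)
from .order import AngleSet
from .stiffness import StressStrainCurve
from .tube import Trajectory

__all__ = ["RunConfig", "load_config", "write_trajectory", "read_angles",
           "read_ramp", "write_report"]

_KNOWN_BLOCKS = {"params", "protocol", "noise", "io", "seed", "log_level"}


class RunConfig:
    """Validated run configuration: parameter, protocol and noise blocks
    plus seed and io paths.  Unknown keys are rejected."""

    def __init__(self, params: ModelParams, protocol: PressureProtocol,
                 noise: NoiseSpec, io: Optional[dict] = None, seed: int = 0,
                 log_level: str = "INFO"):
        self.params = params
        self.protocol = protocol
        self.noise = noise
        self.io = io or {}
        self.seed = int(seed)
        self.log_level = log_level

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        unknown = set(d) - _KNOWN_BLOCKS
        if unknown:
            raise ParameterError(f"unknown config keys: {sorted(unknown)}")
        params = ModelParams(**d.get("params", {}))
        proto = d.get("protocol", {})
        if proto:
            protocol = PressureProtocol(
                segments=tuple(tuple(seg) for seg in proto["segments"]),
                ramp_duration=proto.get("ramp_duration_h", 1 / 60),
            )
        else:
            protocol = step_protocol()
        noise = NoiseSpec(**d.get("noise", {}))
        return cls(params, protocol, noise, d.get("io"),
                   d.get("seed", 0), d.get("log_level", "INFO"))

    def digest(self) -> str:
        blob = json.dumps({
            "params": self.params.to_dict(),
            "protocol": {"segments": list(self.protocol.segments),
                         "ramp_duration_h": self.protocol.ramp_duration},
            "noise": asdict(self.noise),
            "seed": self.seed,
        }, sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def load_config(path) -> RunConfig:
    with open(path) as fh:
        d = yaml.safe_load(fh) or {}
    if not isinstance(d, dict):
        raise ParameterError("config must be a YAML mapping")
    return RunConfig.from_dict(d)


def write_trajectory(traj: Trajectory, path) -> None:
    traj.to_frame().to_csv(path, index=False)


def read_angles(path, label: Optional[str] = None,
                time_h: Optional[float] = None) -> AngleSet:
    """Read an angle-sample CSV (columns: angle_deg[,weight,label,time_h])."""
    df = pd.read_csv(path)
    if "angle_deg" not in df.columns:
        raise ParameterError(f"{path}: missing angle_deg column")
    if label is not None and "label" in df.columns:
        df = df[df["label"] == label]
    if time_h is not None and "time_h" in df.columns:
        df = df[np.isclose(df["time_h"], time_h)]
    w = df["weight"].to_numpy() if "weight" in df.columns else None
    lab = label or (df["label"].iloc[0] if "label" in df.columns and len(df)
                    else "actin")
    return AngleSet(df["angle_deg"].to_numpy(), weights=w, label=lab)


def read_ramp(path, D0_ref: float = 125e-6) -> StressStrainCurve:
    """Read a pressure-diameter ramp CSV (columns: dP_Pa, D_m)."""
    df = pd.read_csv(path)
    for col in ("dP_Pa", "D_m"):
        if col not in df.columns:
            raise ParameterError(f"{path}: missing {col} column")
    return StressStrainCurve(df["dP_Pa"].to_numpy(), df["D_m"].to_numpy(),
                             D0_ref=D0_ref)


def write_report(obj: dict, path) -> None:
    def default(o):
        if isinstance(o, (np.floating, np.integer, np.bool_)):
            return o.item()
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(type(o))
    Path(path).write_text(json.dumps(obj, indent=2, default=default) + "\n")
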