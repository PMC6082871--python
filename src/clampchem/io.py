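"""Trajectory and result serialization.

Trajectories are stored as a TSV (columns time_s, force_pN, extension_nm)
plus a JSON sidecar holding the protocol, compound, seed and ground-truth
events; both are diff-friendly and round-trip at full float precision.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .core import ForceProtocol, ProtocolSegment, load_compound_table
from .detect import StepEvent
from .simulate import Trajectory

__all__ = ["write_trajectory", "read_trajectory", "RunManifest", "sidecar_path"]

_COLUMNS = ["time_s", "force_pN", "extension_nm"]


def sidecar_path(path: str | Path) -> Path:
    return Path(path).with_suffix(".json")


def write_trajectory(trajectory: Trajectory, path: str | Path) -> Path:
    """Write TSV + JSON sidecar; returns the TSV path."""
    path = Path(path)
    df = pd.DataFrame(
        {
            "time_s": trajectory.time_s,
            "force_pN": trajectory.force_pN,
            "extension_nm": trajectory.extension_nm,
        }
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")
    sidecar = {
        "compound_name": trajectory.compound_name,
        "seed": int(trajectory.seed),
        "sample_rate_Hz": trajectory.sample_rate_Hz,
        "feedback_tau_s": trajectory.feedback_tau_s,
        "trajectory_id": trajectory.trajectory_id,
        "protocol": [dataclasses.asdict(s) for s in trajectory.protocol.segments],
        "true_events": [dataclasses.asdict(e) for e in trajectory.true_events],
        "units": {"time_s": "s", "force_pN": "pN", "extension_nm": "nm"},
    }
    sidecar_path(path).write_text(json.dumps(sidecar, indent=1))
    return path


def read_trajectory(path: str | Path, validate_compound: bool = True) -> Trajectory:
    """Read a TSV + sidecar trajectory back; inverse of :func:`write_trajectory`."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    missing = [c for c in _COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trajectory TSV {path} is missing column(s): {', '.join(missing)}")
    t = df["time_s"].to_numpy()
    if t.size > 1:
        dt = np.diff(t)
        if np.any(dt <= 0) or np.ptp(dt) > 1e-9 * np.median(dt) + 1e-12:
            raise ValueError("non-uniform sampling in trajectory TSV")
    side = sidecar_path(path)
    if not side.exists():
        raise FileNotFoundError(f"missing JSON sidecar {side}")
    meta = json.loads(side.read_text())
    if validate_compound and meta["compound_name"] not in load_compound_table():
        raise ValueError(
            f"unknown compound {meta['compound_name']!r}: not in the packaged "
            "compound parameter table"
        )
    protocol = ForceProtocol(tuple(ProtocolSegment(**s) for s in meta["protocol"]))
    events = [StepEvent(**e) for e in meta["true_events"]]
    return Trajectory(
        time_s=t,
        force_pN=df["force_pN"].to_numpy(),
        extension_nm=df["extension_nm"].to_numpy(),
        true_events=events,
        protocol=protocol,
        compound_name=meta["compound_name"],
        seed=meta["seed"],
        sample_rate_Hz=meta["sample_rate_Hz"],
        feedback_tau_s=meta["feedback_tau_s"],
        trajectory_id=meta.get("trajectory_id", ""),
    )


@dataclass(frozen=True)
class RunManifest:
    """Reproducibility record of one CLI run: config digest, seed, outputs."""

    config_hash: str
    seed: int
    stage_outputs: dict[str, str]
    tool_version: str = __version__

    @staticmethod
    def hash_config(config: dict) -> str:
        return hashlib.sha256(json.dumps(config, sort_keys=True).encode()).hexdigest()

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=1, sort_keys=True))

    @staticmethod
    def read(path: str | Path) -> "RunManifest":
        return RunManifest(**json.loads(Path(path).read_text()))
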