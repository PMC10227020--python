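"""Configuration files, trajectory tables, and run provenance.

* Config: YAML mapping 1:1 to :class:`~stressfiber.params.Parameters`
  (unknown keys rejected; defaults filled).
* Trajectory: TSV observable table plus a JSON sidecar manifest carrying
  the config, seed, code version and a config hash, so any run is a pure
  function of (config, seed).
* Snapshots: versioned JSON state dumps (see :mod:`stressfiber.state`).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Tuple

import pandas as pd
import yaml

from . import __version__
from .params import Parameters
from .protocol import PullSpec, Trajectory

__all__ = [
    "RunManifest",
    "config_hash",
    "load_config",
    "save_config",
    "write_trajectory",
    "read_trajectory",
]

TRAJECTORY_FORMAT_VERSION = 1


def config_hash(params: Parameters) -> str:
    canon = json.dumps(params.to_dict(), sort_keys=True)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    code_version: str
    t_start: float
    t_end: float
    replicate: int = 0
    outputs: Tuple[str, ...] = ()


def load_config(path) -> Tuple[Parameters, Optional[PullSpec], dict]:
    """Read a YAML config into (Parameters, optional PullSpec, run settings).

    Top-level keys: ``parameters`` (required), ``pull`` (optional:
    d_pull/n_steps/duration/t_pull), ``run`` (optional: t_end, replicates,
    output prefix...).  Unknown parameter keys raise with the key name.
    """
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    if "parameters" not in doc:
        raise ValueError(f"config {path} missing the 'parameters' section")
    params = Parameters.from_dict(doc["parameters"] or {})
    pull = None
    if "pull" in doc and doc["pull"] is not None:
        pull = PullSpec(**doc["pull"])
    run_settings = doc.get("run", {}) or {}
    return params, pull, run_settings


def save_config(params: Parameters, path, pull: Optional[PullSpec] = None,
                run_settings: Optional[dict] = None) -> None:
    doc = {"parameters": params.to_dict()}
    if pull is not None:
        doc["pull"] = {
            "d_pull": pull.d_pull, "n_steps": pull.n_steps,
            "duration": pull.duration, "t_pull": pull.t_pull,
        }
    if run_settings:
        doc["run"] = dict(run_settings)
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=True)


# ----------------------------------------------------------------------
def write_trajectory(traj: Trajectory, prefix) -> Tuple[Path, Path]:
    """Write ``<prefix>.tsv`` (observable table) + ``<prefix>.json`` manifest."""
    prefix = Path(prefix)
    tsv = prefix.with_suffix(".tsv")
    meta = prefix.with_suffix(".json")
    df = traj.to_dataframe()
    df.to_csv(tsv, sep="\t", index=False)
    manifest = {
        "format_version": TRAJECTORY_FORMAT_VERSION,
        "config_hash": config_hash(traj.params),
        "seed": traj.seed,
        "code_version": __version__,
        "n_frames": int(len(df)),
        "t_start": float(df["t"].iloc[0]) if len(df) else 0.0,
        "t_end": float(df["t"].iloc[-1]) if len(df) else 0.0,
        "events": traj.events,
        "parameters": traj.params.to_dict(),
    }
    with open(meta, "w") as fh:
        json.dump(manifest, fh, indent=1)
    return tsv, meta


def read_trajectory(prefix) -> Trajectory:
    prefix = Path(prefix)
    tsv = prefix.with_suffix(".tsv")
    meta = prefix.with_suffix(".json")
    try:
        with open(meta) as fh:
            manifest = json.load(fh)
    except json.JSONDecodeError as err:
        raise ValueError(f"corrupt trajectory manifest {meta}: {err}")
    if manifest.get("format_version") != TRAJECTORY_FORMAT_VERSION:
        raise ValueError(
            f"trajectory format version {manifest.get('format_version')!r} "
            f"not supported (expected {TRAJECTORY_FORMAT_VERSION})"
        )
    try:
        df = pd.read_csv(tsv, sep="\t")
    except pd.errors.EmptyDataError:
        df = pd.DataFrame()
    if len(df) != manifest["n_frames"]:
        raise ValueError(
            f"trajectory table {tsv} is truncated: "
            f"{len(df)} rows, manifest says {manifest['n_frames']}"
        )
    params = Parameters.from_dict(manifest["parameters"])
    traj = Trajectory(params, manifest["seed"], rows=df.to_dict("records"),
                      events=manifest.get("events", 0))
    return traj
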