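"""Configuration loading, snapshot files, reports, and run manifests.

Field snapshots are stored in a chunked HDF5 container (one group per
frame holding Qn, Qm, u, rho) with the parameter set, schedule and seed
as attributes. Human-facing outputs are CSV and JSON with deterministic
ordering, so re-running on the same inputs is byte-identical.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from .lp9 import LP9Config
from .params import (
    MICRONS_PER_LU,
    MINUTES_PER_STEP,
    ModelParams,
    RunConfig,
    lp9_params,
    mdck_params,
)
from .simulate import Trajectory
from .synth import SynthConfig


# ---------------------------------------------------------------------------
# configuration

def _build(cls, section: dict, name: str, defaults: dict | None = None):
    allowed = {f.name for f in dataclasses.fields(cls)}
    kwargs = dict(defaults or {})
    for key, value in section.items():
        if key not in allowed:
            raise ValueError(f"unknown key '{name}.{key}'")
        if isinstance(value, str):
            raise ValueError(f"malformed numeric value for '{name}.{key}': {value!r}")
        kwargs[key] = value
    try:
        return cls(**kwargs)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"invalid section '{name}': {exc}") from exc


def load_config(path: str | Path) -> dict:
    """Load and validate a YAML run configuration.

    Top-level keys: ``scenario`` ("mdck" | "lp9"), ``params``
    (:class:`ModelParams` fields), ``run`` (:class:`RunConfig`),
    ``synth`` (:class:`SynthConfig`), ``lp9`` (:class:`LP9Config` fields
    except ``params``). Unknown keys are rejected with the offending key
    named. An empty file yields the all-defaults MDCK configuration.
    Defaults are the MDCK parameter set, or the LP-9 set when
    ``scenario: lp9``.
    """
    path = Path(path)
    raw = yaml.safe_load(path.read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError("config root must be a mapping")
    known = {"scenario", "params", "run", "synth", "lp9"}
    for key in raw:
        if key not in known:
            raise ValueError(f"unknown key '{key}'")
    scenario = raw.get("scenario", "mdck")
    if scenario not in ("mdck", "lp9"):
        raise ValueError(f"unknown scenario {scenario!r}")

    base = lp9_params() if scenario == "lp9" else mdck_params()
    params = _build(ModelParams, raw.get("params", {}), "params", base.to_dict())
    run_defaults = {"scenario": scenario}
    run = _build(RunConfig, raw.get("run", {}), "run", run_defaults)
    synth = _build(SynthConfig, raw.get("synth", {}), "synth")
    lp9_section = dict(raw.get("lp9", {}))
    lp9_section.pop("params", None)
    lp9 = _build(LP9Config, lp9_section, "lp9", {"params": lp9_params()})
    return {
        "scenario": scenario,
        "params": params,
        "run": run,
        "synth": synth,
        "lp9": lp9,
    }


# ---------------------------------------------------------------------------
# manifests

def config_hash(config: dict) -> str:
    """Stable SHA-256 over a JSON-canonicalised configuration dict."""
    def canon(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return canon(dataclasses.asdict(obj))
        if isinstance(obj, dict):
            return {k: canon(v) for k, v in sorted(obj.items())}
        if isinstance(obj, (list, tuple)):
            return [canon(v) for v in obj]
        if isinstance(obj, (np.floating, np.integer)):
            return obj.item()
        return obj

    blob = json.dumps(canon(config), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()


def write_manifest(
    out_dir: str | Path,
    config: dict,
    seeds: dict,
    inputs: list[str] | None = None,
    outputs: list[str] | None = None,
) -> Path:
    """Write the run manifest tying outputs to config, seeds and units."""
    from . import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "config_hash": config_hash(config),
        "seeds": seeds,
        "code_version": __version__,
        "inputs": inputs or [],
        "outputs": outputs or [],
        "unit_calibration": {
            "microns_per_lu": MICRONS_PER_LU,
            "minutes_per_step": MINUTES_PER_STEP,
        },
    }
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return path


# ---------------------------------------------------------------------------
# snapshots

def save_trajectory(traj: Trajectory, path: str | Path) -> None:
    """Store a trajectory as chunked HDF5, one group per frame."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with h5py.File(path, "w") as fh:
        fh.attrs["steps"] = traj.steps
        if traj.config is not None:
            fh.attrs["config"] = json.dumps(traj.config.to_dict(), sort_keys=True)
        if traj.params is not None:
            fh.attrs["params"] = json.dumps(traj.params.to_dict(), sort_keys=True)
        fh.attrs["meta"] = json.dumps(traj.meta, sort_keys=True)
        for i in range(traj.n_frames):
            g = fh.create_group(f"frame_{i:05d}")
            g.attrs["step"] = int(traj.steps[i])
            for name in ("qn_xx", "qn_xy", "qm_xx", "qm_xy", "ux", "uy", "rho"):
                g.create_dataset(
                    name, data=getattr(traj, name)[i], compression="gzip", shuffle=True
                )


def load_trajectory(path: str | Path) -> Trajectory:
    with h5py.File(path, "r") as fh:
        steps = np.asarray(fh.attrs["steps"])
        names = ("qn_xx", "qn_xy", "qm_xx", "qm_xy", "ux", "uy", "rho")
        frames = sorted(k for k in fh if k.startswith("frame_"))
        stacks = {
            n: np.stack([fh[f][n][()] for f in frames]) for n in names
        }
        meta = json.loads(fh.attrs.get("meta", "{}"))
    return Trajectory(steps=steps, config=None, params=None, meta=meta, **stacks)


# ---------------------------------------------------------------------------
# reports

def write_report(summary: dict, out_dir: str | Path, curves: dict | None = None) -> Path:
    """Write the analysis summary JSON plus any correlation-curve CSVs.

    ``summary`` values may be numbers, lists or None (undefined statistics
    such as colocalization with zero defects stay null, never 0).
    ``curves`` maps file stems to DataFrames written as CSV. Ordering is
    deterministic so repeated runs produce byte-identical reports.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    def jsonify(v):
        if isinstance(v, (np.floating, np.integer)):
            return v.item()
        if isinstance(v, np.ndarray):
            return v.tolist()
        if isinstance(v, dict):
            return {k: jsonify(x) for k, x in sorted(v.items())}
        if isinstance(v, (list, tuple)):
            return [jsonify(x) for x in v]
        return v

    path = out_dir / "summary.json"
    path.write_text(json.dumps(jsonify(summary), indent=2, sort_keys=True) + "\n")
    for stem, frame in (curves or {}).items():
        if not isinstance(frame, pd.DataFrame):
            frame = pd.DataFrame(frame)
        frame.to_csv(out_dir / f"{stem}.csv", index=False, float_format="%.10g")
    return path


def read_cell_table(path: str | Path) -> pd.DataFrame:
    """Read a per-cell CSV (x_um, y_um, angle_deg, aspect_ratio, sxx, sxy, syy)."""
    df = pd.read_csv(path)
    required = {"x_um", "y_um", "angle_deg", "aspect_ratio"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return df
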