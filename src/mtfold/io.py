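"""Trajectory files and run configuration.

Trajectories travel as tab-separated text with header columns
``time_s force_pN height_nm`` and an optional ``true_state`` column
(N/U labels), plus a JSON sidecar ``<file>.meta.json`` for metadata.
Gzip-compressed files are accepted transparently.  Run configurations
are JSON or YAML and are validated before any stage executes; a seed is
mandatory.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .simulate import STATE_LABELS, Trajectory

__all__ = [
    "TrajectoryParseError",
    "ConfigError",
    "read_trajectory",
    "write_trajectory",
    "load_config",
    "validate_config",
]

_REQUIRED = ("time_s", "force_pN", "height_nm")


class TrajectoryParseError(ValueError):
    """A trajectory file violates the expected format."""


class ConfigError(ValueError):
    """A run configuration fails schema validation."""


def _sidecar(path: Path) -> Path:
    return Path(str(path) + ".meta.json")


def write_trajectory(traj: Trajectory, path) -> Path:
    """Write a trajectory as TSV (+ JSON metadata sidecar)."""
    path = Path(path)
    cols = {"time_s": traj.time, "force_pN": traj.force,
            "height_nm": traj.height}
    if traj.true_state is not None:
        cols["true_state"] = STATE_LABELS[traj.true_state]
    pd.DataFrame(cols).to_csv(path, sep="\t", index=False)
    if traj.metadata:
        _sidecar(path).write_text(json.dumps(traj.metadata, default=str,
                                             indent=1))
    return path


def read_trajectory(path) -> Trajectory:
    """Read a TSV trajectory, validating columns and uniform sampling."""
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", compression="infer")
    except Exception as exc:
        raise TrajectoryParseError(f"cannot parse {path}: {exc}") from exc
    missing = [c for c in _REQUIRED if c not in df.columns]
    if missing:
        raise TrajectoryParseError(
            f"{path}: missing required column(s) {missing}; "
            f"found {list(df.columns)}")
    t = df["time_s"].to_numpy(dtype=float)
    if len(t) < 2:
        raise TrajectoryParseError(f"{path}: need at least 2 samples")
    dt = np.diff(t)
    if np.any(dt <= 0):
        raise TrajectoryParseError(f"{path}: time must be strictly increasing")
    if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-12):
        raise TrajectoryParseError(f"{path}: mixed sampling interval "
                                   f"(min {dt.min():.3g}, max {dt.max():.3g})")
    state = None
    if "true_state" in df.columns:
        labels = df["true_state"].astype(str).to_numpy()
        bad = set(np.unique(labels)) - {"N", "U"}
        if bad:
            raise TrajectoryParseError(f"{path}: unknown state labels {bad}")
        state = (labels == "U").astype(np.int8)
    meta = {}
    sc = _sidecar(path)
    if sc.exists():
        meta = json.loads(sc.read_text())
    return Trajectory(time=t, force=df["force_pN"].to_numpy(dtype=float),
                      height=df["height_nm"].to_numpy(dtype=float),
                      true_state=state, metadata=meta)


# ----------------------------------------------------------------------
# run configuration

_KNOWN_TOP = {"seed", "constructs", "elasticity", "equilibrium", "ramp",
              "jump", "analysis", "output"}


def load_config(path) -> dict:
    """Load and validate a JSON or YAML run configuration."""
    path = Path(path)
    text = path.read_text()
    if path.suffix in (".yaml", ".yml"):
        import yaml

        cfg = yaml.safe_load(text)
    else:
        cfg = json.loads(text)
    validate_config(cfg)
    return cfg


def validate_config(cfg: dict) -> None:
    if not isinstance(cfg, dict):
        raise ConfigError("configuration must be a mapping")
    if "seed" not in cfg or not isinstance(cfg["seed"], int):
        raise ConfigError("configuration requires an integer 'seed'")
    unknown = set(cfg) - _KNOWN_TOP
    if unknown:
        raise ConfigError(f"unknown configuration keys: {sorted(unknown)}")
    constructs = cfg.get("constructs", ["LE-CSP-GS"])
    if not isinstance(constructs, list) or not constructs:
        raise ConfigError("'constructs' must be a non-empty list")
    for block, keys in (("equilibrium", {"forces", "duration_s",
                                         "sampling_rate", "noise_sigma"}),
                        ("ramp", {"n_traces", "start", "end", "rate",
                                  "round_trip", "sampling_rate",
                                  "noise_sigma"}),
                        ("jump", {"forces", "hold_s", "n_traces",
                                  "sampling_rate", "noise_sigma"}),
                        ("analysis", {"smooth_window", "threshold_sigma",
                                      "n_bootstrap", "hold_force"})):
        sub = cfg.get(block)
        if sub is None:
            continue
        if not isinstance(sub, dict):
            raise ConfigError(f"'{block}' must be a mapping")
        extra = set(sub) - keys
        if extra:
            raise ConfigError(f"unknown keys in '{block}': {sorted(extra)}")
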