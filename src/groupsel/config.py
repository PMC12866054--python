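"""Configuration parsing, validation, presets and result serialization.

Run configurations are flat key-value mappings (YAML or JSON) validated
against the model parameter ranges before any run.  Presets encode the
parameter sets of the reference experiments; the *_small variants are
desk-scale versions (coarser grids, fewer replicates) of sweeps whose
full grids are not desk scale.
"""

from __future__ import annotations

import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__ as _pkg_version
from .experiments import InitSpec, ReplicateSet
from .model import MODES, ModelParams

__all__ = ["ExperimentConfig", "parse_config", "PRESETS", "export_replicates", "write_manifest"]

_KEYS = {
    "command": str,
    "mode": str,
    "K": int,
    "K_g": int,
    "mu": float,
    "a": float,
    "b": float,
    "N_g_A": int,
    "N_g_B": int,
    "N_g": int,
    "heterogeneous": bool,
    "T": int,
    "M": int,
    "seed": int,
    "out": str,
    "log_level": str,
}

_DEFAULTS = {
    "command": "simulate",
    "mode": "neutral",
    "a": 0.0,
    "b": 1.0,
    "N_g_A": 0,
    "N_g_B": 0,
    "N_g": 0,
    "heterogeneous": False,
    "M": 1,
    "seed": 0,
    "out": "runs",
    "log_level": "info",
}


@dataclass
class ExperimentConfig:
    """Validated run configuration."""

    command: str
    params: ModelParams
    init_spec: InitSpec
    T: int
    M: int
    seed: int
    out: str
    log_level: str = "info"
    raw: dict = field(default_factory=dict, repr=False)


def _validate(mapping: dict) -> dict:
    cfg = dict(_DEFAULTS)
    for key, value in mapping.items():
        if key not in _KEYS:
            raise ValueError(f"unknown configuration key {key!r}")
        try:
            cfg[key] = _KEYS[key](value)
        except (TypeError, ValueError):
            raise ValueError(f"key {key!r} expects a {_KEYS[key].__name__}, got {value!r}")
    for required in ("K", "K_g", "mu", "T"):
        if required not in cfg:
            raise ValueError(f"missing required configuration key {required!r}")
    return cfg


def parse_config(path: str | Path | None = None, **overrides) -> ExperimentConfig:
    """Load and validate a configuration; keyword overrides beat file values.

    Raises ValueError naming the offending key and admissible range, e.g.
    b outside [1, 4] or a outside [0, 1].
    """
    mapping: dict = {}
    if path is not None:
        text = Path(path).read_text()
        loaded = yaml.safe_load(text)  # YAML is a superset of JSON
        if not isinstance(loaded, dict):
            raise ValueError(f"config file {path} must contain a key-value mapping")
        mapping.update(loaded)
    mapping.update({k: v for k, v in overrides.items() if v is not None})
    cfg = _validate(mapping)
    params = ModelParams(
        K=cfg["K"], K_g=cfg["K_g"], mu=cfg["mu"], a=cfg["a"], b=cfg["b"], mode=cfg["mode"]
    )
    if cfg["heterogeneous"]:
        n_g = cfg["N_g"] or (cfg["N_g_A"] + cfg["N_g_B"])
        init_spec = InitSpec("heterogeneous", N_g=n_g)
    else:
        init_spec = InitSpec("homogeneous", N_gA=cfg["N_g_A"], N_gB=cfg["N_g_B"])
    return ExperimentConfig(
        command=cfg["command"],
        params=params,
        init_spec=init_spec,
        T=cfg["T"],
        M=cfg["M"],
        seed=cfg["seed"],
        out=cfg["out"],
        log_level=cfg["log_level"],
        raw=cfg,
    )


#: Parameter sets of the reference experiments.  Grid-based entries carry
#: axis definitions consumed by the CLI sweep command.
PRESETS: dict[str, dict] = {
    # neutral survival phase diagram: mu vs K, N_g = 50, b = 1
    "neutral-phase": dict(mode="neutral", b=1.0, N_g_A=0, N_g_B=50, K_g=200, T=1000, M=50,
                  axis1=("mu", list(np.round(np.arange(0.0, 1.0001, 0.01), 4))),
                  axis2=("K", list(range(10, 101)))),
    "neutral-phase-small": dict(mode="neutral", b=1.0, N_g_A=0, N_g_B=50, K_g=200, T=1000, M=10,
                        axis1=("mu", list(np.round(np.arange(0.0, 1.0001, 0.05), 4))),
                        axis2=("K", list(range(10, 101, 5)))),
    # relative-fitness (a, b) landscape, homogeneous init
    "relative-landscape": dict(mode="relative", K=10, K_g=70, mu=0.7, N_g_A=10, N_g_B=10, T=3000, M=50,
                  axis1=("a", list(np.round(np.arange(0.0, 1.0, 0.033), 4))),
                  axis2=("b", list(np.round(np.arange(1.0, 4.0001, 0.1), 4)))),
    "relative-landscape-small": dict(mode="relative", K=10, K_g=70, mu=0.7, N_g_A=10, N_g_B=10,
                        T=3000, M=10,
                        axis1=("a", list(np.round(np.arange(0.0, 1.0, 0.165), 4))),
                        axis2=("b", list(np.round(np.arange(1.0, 4.0001, 0.5), 4)))),
    # heterogeneous-init composition landscape
    "relative-hetero": dict(mode="relative", K=10, K_g=70, mu=0.7, N_g=20, heterogeneous=True,
                  T=5000, M=50,
                  axis1=("a", list(np.round(np.arange(0.0, 1.0, 0.033), 4))),
                  axis2=("b", list(np.round(np.arange(1.0, 4.0001, 0.1), 4)))),
    # (N_g, K) landscape at fixed a, b
    "size-landscape": dict(mode="relative", mu=0.7, a=0.4, b=4.0, K_g=150, T=5000, M=50,
                  axis1=("N_g", list(range(20, 41))),
                  axis2=("K", list(range(10, 31)))),
    # resource-limited extinction trajectories
    "collapse": dict(mode="relative", K=20, K_g=45, mu=0.5, a=0.75, b=4.0,
                 N_g_A=15, N_g_B=15, T=5000, M=50),
    # absolute-fitness (a, b) landscape
    "absolute-landscape": dict(mode="absolute", K=10, K_g=70, mu=0.7, N_g_A=10, N_g_B=10, T=3000, M=50,
                  axis1=("a", list(np.round(np.arange(0.0, 1.0, 0.033), 4))),
                  axis2=("b", list(np.round(np.arange(1.0, 4.0001, 0.1), 4)))),
    # biofilm reference constants (protocol chosen by CLI subcommand)
    "biofilm-constants": dict(),
}


def export_replicates(reps: ReplicateSet, T: int, out_dir: str | Path) -> tuple[Path, Path]:
    """Write tidy trajectory CSV and JSON outcome summary; returns both paths."""
    from .experiments import mean_statistic, outcome_S, theta_mean

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    frames = []
    for alpha, run in enumerate(reps.results):
        frames.append(
            pd.DataFrame(
                {
                    "replicate": alpha,
                    "t": run.times,
                    "n_groups": run.n_groups,
                    "n_groups_allA": run.n_groups_allA,
                    "total_A": run.total_A,
                    "total_B": run.total_B,
                }
            )
        )
    csv_path = out / "trajectories.csv"
    pd.concat(frames, ignore_index=True).to_csv(csv_path, index=False)
    summary = {
        "outcomes": [r.outcome for r in reps.results],
        "final_t": [r.final_t for r in reps.results],
        "S": [outcome_S(r, T) for r in reps.results],
        "theta": theta_mean(reps, T),
        "mean_S": mean_statistic(reps, T, "S"),
    }
    json_path = out / "summary.json"
    json_path.write_text(json.dumps(summary, indent=2))
    return csv_path, json_path


def write_manifest(out_dir: str | Path, cfg: dict, seeds: list[int], wall_time: float) -> Path:
    """Record parameters, seeds, package version and wall time for replay."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "package": "groupsel",
        "version": _pkg_version,
        "config": {k: v for k, v in cfg.items() if not k.startswith("axis")},
        "seeds": seeds,
        "wall_time_s": wall_time,
        "written": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    path = Path(out) / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, default=str))
    return path
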