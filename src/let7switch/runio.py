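"""Config parsing and CSV/JSON writers for the command-line tools.

Configs are YAML or JSON with an explicit ``mode`` (``dimensionless`` or
``dimensional``); parameter keys must match the chosen mode exactly and
mixing modes is an error.  Partial parameter sets are allowed in a config
(commands supply the rest through flags).  All tables are written as
headered CSV with deterministic row order and 12 significant digits.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .dynamics import Trajectory
from .equilibria import BifurcationBranch, SteadyState
from .model_core import DimensionalParams, DimensionlessParams
from .phase_classifier import PhaseDiagram

__all__ = [
    "ConfigError",
    "RunConfig",
    "load_config",
    "write_branch_csv",
    "write_folds_csv",
    "write_phase_csv",
    "write_traj_csv",
    "write_steady_csv",
    "read_traj_csv",
]

logger = logging.getLogger("let7switch")

FLOAT_FMT = "%.12g"

DIMENSIONLESS_KEYS = ("alpha", "gamma", "gamma1", "gamma2", "gamma3", "epsilon")
DIMENSIONAL_KEYS = ("alpha_M", "alpha_P", "beta_M", "beta_P",
                    "kappa_P", "Gamma1", "Gamma2", "Gamma3")
SETTING_KEYS = ("seed", "t_end", "dt", "burn_in", "alpha_max",
                "noise_mean", "noise_variance", "redraw_interval",
                "clip_at_zero", "n_traj", "obs_noise_sd", "n_obs",
                "out", "log_level")


class ConfigError(ValueError):
    """Invalid run configuration (unknown key, bad value, mixed modes)."""


@dataclass
class RunConfig:
    mode: str                               # "dimensionless" | "dimensional"
    params: dict[str, float]                # possibly partial parameter set
    settings: dict = field(default_factory=dict)
    log_level: str = "INFO"

    def dimensionless_params(self, **overrides: float) -> DimensionlessParams:
        """Assemble full DimensionlessParams from config plus overrides."""
        if self.mode != "dimensionless":
            raise ConfigError("config is in dimensional mode")
        merged = {**self.params, **{k: v for k, v in overrides.items()
                                    if v is not None}}
        missing = [k for k in DIMENSIONLESS_KEYS if k not in merged]
        if missing:
            raise ConfigError(f"missing parameter keys: {missing}")
        return DimensionlessParams(**{k: float(merged[k])
                                      for k in DIMENSIONLESS_KEYS})

    def dimensional_params(self) -> DimensionalParams:
        if self.mode != "dimensional":
            raise ConfigError("config is in dimensionless mode")
        missing = [k for k in DIMENSIONAL_KEYS if k not in self.params]
        if missing:
            raise ConfigError(f"missing parameter keys: {missing}")
        return DimensionalParams(**{k: float(self.params[k])
                                    for k in DIMENSIONAL_KEYS})

    def to_yaml(self) -> str:
        return yaml.safe_dump({"mode": self.mode, **self.params,
                               **self.settings, "log_level": self.log_level},
                              sort_keys=True)


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML/JSON run config.

    Errors name the offending key; unknown keys are rejected, as is mixing
    dimensional and dimensionless parameter names.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    text = path.read_text()
    raw = yaml.safe_load(text) if path.suffix in (".yaml", ".yml") \
        else json.loads(text)
    if raw is None:
        raise ConfigError(
            "empty config: requires 'mode' and parameter keys "
            f"({DIMENSIONLESS_KEYS} or {DIMENSIONAL_KEYS})")
    if not isinstance(raw, dict):
        raise ConfigError(f"config must be a mapping, got {type(raw).__name__}")

    dimless = {k: v for k, v in raw.items() if k in DIMENSIONLESS_KEYS}
    dimful = {k: v for k, v in raw.items() if k in DIMENSIONAL_KEYS}
    if dimless and dimful:
        raise ConfigError(
            f"mixed parameter modes: dimensionless keys {sorted(dimless)} "
            f"with dimensional keys {sorted(dimful)}")

    mode = raw.get("mode")
    if mode is None:
        if dimless and not dimful:
            mode = "dimensionless"
        elif dimful:
            mode = "dimensional"
        else:
            raise ConfigError(
                "config has no 'mode' and no recognizable parameter keys; "
                f"required: mode plus {DIMENSIONLESS_KEYS} or {DIMENSIONAL_KEYS}")
    if mode not in ("dimensionless", "dimensional"):
        raise ConfigError(f"mode must be dimensionless or dimensional, got {mode!r}")
    if mode == "dimensionless" and dimful:
        raise ConfigError(f"dimensional keys {sorted(dimful)} in dimensionless mode")
    if mode == "dimensional" and dimless:
        raise ConfigError(f"dimensionless keys {sorted(dimless)} in dimensional mode")

    params = dimless if mode == "dimensionless" else dimful
    for k, v in params.items():
        if not isinstance(v, (int, float)) or isinstance(v, bool):
            raise ConfigError(f"parameter {k!r} must be numeric, got {v!r}")

    settings = {k: v for k, v in raw.items() if k in SETTING_KEYS}
    known = set(params) | set(settings) | {"mode"}
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")

    log_level = str(settings.pop("log_level", "INFO"))
    cfg = RunConfig(mode=mode, params={k: float(v) for k, v in params.items()},
                    settings=settings, log_level=log_level)
    logger.info("loaded config %s: %s", path, cfg)
    return cfg


def _write_df(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format=FLOAT_FMT)
    return path


def write_steady_csv(states: list[SteadyState], path: str | Path) -> Path:
    df = pd.DataFrame(
        [(s.psi_s, s.phi_s, s.eigenvalues[0].real, s.eigenvalues[1].real,
          s.stability) for s in states],
        columns=["psi_s", "phi_s", "re_eig1", "re_eig2", "stability"],
    )
    return _write_df(df, path)


def write_branch_csv(branch: BifurcationBranch, path: str | Path) -> Path:
    df = pd.DataFrame({
        "psi": branch.psi_grid,
        "alpha": branch.alpha_values,
        "stability": branch.stability,
    }).sort_values("psi", kind="stable")
    return _write_df(df, path)


def write_folds_csv(branch: BifurcationBranch, path: str | Path) -> Path:
    df = pd.DataFrame(
        [(f.psi_fold, f.alpha_fold, f.kind) for f in branch.folds],
        columns=["psi_fold", "alpha_fold", "kind"],
    )
    return _write_df(df, path)


def write_phase_csv(diagram: PhaseDiagram, path: str | Path) -> Path:
    return _write_df(diagram.to_dataframe(), path)


def write_traj_csv(traj: Trajectory, path: str | Path) -> Path:
    df = pd.DataFrame({
        "tau": traj.tau,
        "phi": traj.phi,
        "psi": traj.psi,
        "alpha": traj.alpha_trace,
    })
    return _write_df(df, path)


def read_traj_csv(path: str | Path) -> Trajectory:
    df = pd.read_csv(path)
    return Trajectory(tau=df["tau"].to_numpy(), phi=df["phi"].to_numpy(),
                      psi=df["psi"].to_numpy(),
                      alpha_trace=df["alpha"].to_numpy(),
                      meta={"source": str(path)})
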