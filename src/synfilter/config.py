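"""Run configuration, seeding and tabular serialisation.

Configs are flat YAML/JSON mappings; unknown keys are rejected and missing
keys are filled from per-experiment defaults (benchmark experiments use the
tracking-task hyperparameters, plasticity experiments the protocol ones).
Every result written by :func:`write_results` gets a JSON sidecar embedding
the full config, its hash and the package version, so a run can be
reproduced bit-identically from the sidecar alone.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__all__ = ["RunConfig", "load_config", "write_results", "EXPERIMENTS"]

# per-experiment default hyperparameters; keys not listed fall back to the
# dataclass defaults below
EXPERIMENTS: dict[str, dict] = {
    "benchmark_mse": {"g0": 20.0, "beta": 0.1, "dt": 1e-3, "tau_ou": 20.0},
    "sweep_eta": {"g0": 20.0, "beta": 0.1, "dt": 1e-3, "tau_ou": 20.0},
    "stdp": {"g0": 1.0, "beta": 1.0, "dt": 1e-4, "tau_ou": 1e4,
             "sigma2_bias": 2.0, "d": 2},
    "hetero": {"g0": 1.0, "beta": 1.0, "dt": 1e-5, "tau_ou": 1e4,
               "sigma2_bias": 1.0, "d": 3},
    "validate_adf": {"d": 1, "beta": 0.5, "g0": 20.0, "dt": 1e-3,
                     "tau_ou": 2.0},
}


@dataclass
class RunConfig:
    """Flat bag of every hyperparameter a run may need."""

    experiment: str = "benchmark_mse"
    # model / task
    d: int = 16
    rho: float = 40.0
    g0: float = 20.0
    beta: float = 0.1
    eta: float = 1.0
    tau_m: float = 0.025
    tau_ou: float = 20.0
    tau_ou_bias: float = 0.025
    sigma2_ou: float = 1.0
    sigma2_bias: float = 2.0
    mu_bias: float = 1.0
    variant: str = "full"
    block_size: int = 8
    input_mode: str = "homogeneous"
    tau_block: float = 1.0
    double_beta: bool = True
    preconditioned: bool = True
    # sweep / protocol grids
    param: str = "beta"
    grid: list = field(default_factory=list)
    n_delays: int = 200
    delay_max: float = 0.125
    # integration and averaging
    dt: float = 1e-3
    n_epochs: int = 16
    burn_in_epochs: int = 8
    n_particles: int = 10_000
    T: float = 5.0
    # bookkeeping
    seed: int = 0
    outdir: str = "results"

    def __post_init__(self) -> None:
        if self.experiment not in EXPERIMENTS:
            raise ValueError(
                f"unknown experiment {self.experiment!r}; "
                f"choose from {sorted(EXPERIMENTS)}"
            )
        for key in ("dt", "tau_m", "tau_ou", "tau_ou_bias", "tau_block",
                    "sigma2_ou", "sigma2_bias", "g0", "T"):
            if getattr(self, key) <= 0:
                raise ValueError(f"config field {key!r} must be > 0")
        for key in ("beta", "rho", "delay_max"):
            if getattr(self, key) < 0:
                raise ValueError(f"config field {key!r} must be >= 0")
        for key in ("d", "block_size", "n_delays", "n_epochs", "n_particles"):
            if getattr(self, key) < 1:
                raise ValueError(f"config field {key!r} must be >= 1")

    # -- serialisation -----------------------------------------------------
    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        names = {f.name for f in dataclasses.fields(cls)}
        unknown = sorted(set(data) - names)
        if unknown:
            raise ValueError(f"unknown config keys: {', '.join(unknown)}")
        experiment = data.get("experiment", "benchmark_mse")
        merged = dict(EXPERIMENTS.get(experiment, {}))
        merged.update(data)
        return cls(**merged)

    def save(self, path: str | Path) -> None:
        path = Path(path)
        text = (
            json.dumps(self.to_dict(), indent=2)
            if path.suffix == ".json"
            else yaml.safe_dump(self.to_dict(), sort_keys=True)
        )
        path.write_text(text)

    def hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]

    def delay_grid(self) -> np.ndarray:
        return np.linspace(-self.delay_max, self.delay_max, self.n_delays)


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML or JSON run configuration."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    text = path.read_text()
    # yaml 1.1 resolvers miss floats like "2e-05"; JSON files get json.loads
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ValueError(f"config root must be a mapping, got {type(data).__name__}")
    return RunConfig.from_dict(data)


def write_results(
    result,
    path: str | Path,
    config: RunConfig | dict | None = None,
) -> tuple[Path, Path]:
    """Write a tidy CSV plus a JSON sidecar; returns (csv_path, json_path).

    ``result`` may be a DataFrame or any result object with ``to_frame()``
    (STDPCurve, MSEResult, HeteroResult, TutorSession).
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    frame = result if isinstance(result, pd.DataFrame) else result.to_frame()
    csv_path = path.with_suffix(".csv")
    try:
        frame.to_csv(csv_path, index=False)
    except OSError as exc:
        raise OSError(f"failed writing results to {csv_path}: {exc}") from exc

    from . import __version__

    sidecar: dict = {"software_version": __version__}
    if config is not None:
        cfg = config.to_dict() if isinstance(config, RunConfig) else dict(config)
        sidecar["config"] = cfg
        if isinstance(config, RunConfig):
            sidecar["config_hash"] = config.hash()
            sidecar["seed"] = config.seed
    meta = getattr(result, "meta", None)
    if meta:
        sidecar["meta"] = _jsonable(meta)
    json_path = path.with_suffix(".json")
    json_path.write_text(json.dumps(sidecar, indent=2))
    return csv_path, json_path


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating, np.bool_)):
        return obj.item()
    return obj
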