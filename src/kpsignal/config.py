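"""Run configuration: strict JSON/YAML schema for pipeline stages."""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, fields
from pathlib import Path

import yaml

__all__ = ["RunConfig"]

SCHEMA_VERSION = 1


@dataclass
class RunConfig:
    """Resolved stage parameters; unknown keys are rejected on load.

    The full resolved config is embedded in output sidecar JSON so every
    run is reproducible from (config, seed).
    """

    schema_version: int = SCHEMA_VERSION
    bins: int = 10                      # MI histogram bins per axis
    k: float = 4.0                      # spike threshold multiplier (MADs)
    min_separation: float = 30.0        # spike peak spacing, seconds
    epsilon: float = 0.1                # Hebbian learning rate
    seed: int = 0
    quantization_step: float = 0.0      # mV, 0 = off
    duration: float = 3600.0            # synthetic recording length, seconds
    fs: float = 1.0                     # samples per second
    n_channels: int = 2
    noise_std: float = 5.0              # mV
    coupling: list | None = None        # [[i, j, rho], ...]
    spike_model: str = "none"           # none | kombucha | proteinoid

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        data = (json.loads(text) if path.suffix.lower() == ".json"
                else yaml.safe_load(text)) or {}
        if not isinstance(data, dict):
            raise ValueError(f"{path}: config must be a mapping")
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(
                f"{path}: unknown config keys {sorted(unknown)}; "
                f"valid keys: {sorted(known)}"
            )
        return cls(**data)

    def to_dict(self) -> dict:
        return asdict(self)
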