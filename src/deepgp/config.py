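"""Run configuration: one flat key set shared by the library and the CLI.

Loaded from a YAML/JSON key-value file with command-line overrides; unknown
keys are rejected so typos fail loudly instead of silently using defaults.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import yaml


@dataclasses.dataclass
class RunConfig:
    # feature construction
    top_k: int = 5
    window_bp: int = 0
    log_transform: bool = False
    restrict_eqtl: bool = True
    # graph embedding
    gcn_mode: str = "trained"  # {"trained", "fixed", "off"}
    gcn_layers: int = 1
    gcn_activation: str = "relu"
    # classifier
    arch_preset: str = "A"
    lr: float = 1e-3
    epochs: int = 100
    batch_size: int = 32
    # evaluation
    k_folds: int = 10
    n_repeats: int = 1
    threshold: float = 0.5
    # randomness
    seed: int = 0
    threads: int = 1

    def __post_init__(self) -> None:
        if self.gcn_mode not in ("trained", "fixed", "off"):
            raise ValueError(f"invalid gcn_mode {self.gcn_mode!r}")
        if self.gcn_activation not in ("relu", "identity"):
            raise ValueError(f"invalid gcn_activation {self.gcn_activation!r}")
        if not 0.0 <= self.threshold <= 1.0:
            raise ValueError("threshold must lie in [0, 1]")
        if self.top_k < 1 or self.k_folds < 2 or self.n_repeats < 1:
            raise ValueError("top_k >= 1, k_folds >= 2, n_repeats >= 1 required")

    @classmethod
    def field_names(cls) -> set[str]:
        return {f.name for f in dataclasses.fields(cls)}

    @classmethod
    def from_dict(cls, values: dict) -> "RunConfig":
        unknown = set(values) - cls.field_names()
        if unknown:
            raise ValueError(
                f"unknown config key(s): {', '.join(sorted(unknown))}"
            )
        return cls(**values)

    @classmethod
    def from_file(cls, path: str | Path, overrides: dict | None = None) -> "RunConfig":
        values = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(values, dict):
            raise ValueError(f"{path}: config file must be a key-value mapping")
        if overrides:
            values.update(overrides)
        return cls.from_dict(values)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def digest(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def parse_override(text: str):
    """Parse a ``key=value`` override; values go through YAML scalar rules."""
    if "=" not in text:
        raise ValueError(f"override {text!r} is not of the form key=value")
    key, raw = text.split("=", 1)
    return key.strip(), yaml.safe_load(raw)
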