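"""Run configuration: YAML/JSON parameter blocks with strict key checking."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

__all__ = ["RunConfig"]

_KNOWN_BLOCKS = ("meniscus", "qc", "profile", "confluency", "cellcycle", "synth")
_KNOWN_SCALARS = ("seed", "output_dir", "log_level")


@dataclass
class RunConfig:
    """Module parameter blocks plus the master seed and output location.

    Unknown top-level keys are rejected so that typos fail loudly.  Every
    run should persist its resolved configuration next to its outputs
    (:meth:`dump`).
    """

    meniscus: dict = field(default_factory=dict)
    qc: dict = field(default_factory=dict)
    profile: dict = field(default_factory=dict)
    confluency: dict = field(default_factory=dict)
    cellcycle: dict = field(default_factory=dict)
    synth: dict = field(default_factory=dict)
    seed: int = 0
    output_dir: str = "."
    log_level: str = "INFO"

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        data = data or {}
        unknown = set(data) - set(_KNOWN_BLOCKS) - set(_KNOWN_SCALARS)
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        return cls(**data)

    def dump(self, path: str | Path) -> None:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text(yaml.safe_dump(vars(self), sort_keys=True))
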