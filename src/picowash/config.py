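"""Run configuration, validation and provenance records.

Every CLI stage writes a ``provenance.json`` beside its outputs holding
the resolved configuration, seed, software version and SHA-256
checksums of the inputs — enough to re-run the stage bit-identically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path
from typing import Any

import yaml

from . import __version__

COMMANDS = ("simulate", "reconstruct", "calibrate", "mapdf", "quantify", "designcheck")


@dataclasses.dataclass
class RunConfig:
    """One validated pipeline-stage invocation."""

    command: str
    paths: dict[str, str] = dataclasses.field(default_factory=dict)
    parameters: dict[str, Any] = dataclasses.field(default_factory=dict)
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.command not in COMMANDS:
            raise ValueError(f"unknown command {self.command!r}; expected one of {COMMANDS}")

    def validate_inputs(self) -> None:
        for role, path in self.paths.items():
            if role == "out":
                continue
            p = Path(path)
            if not p.exists():
                raise FileNotFoundError(f"input path for {role!r} does not exist: {p}")


def load_config(path: str | Path) -> dict[str, Any]:
    """Load a YAML or JSON configuration mapping."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        data = json.loads(text)
    else:
        data = yaml.safe_load(text)
    if data is None:
        return {}
    if not isinstance(data, dict):
        raise ValueError(f"configuration file {path} must hold a mapping at the top level")
    return data


def _sha256(path: Path) -> str:
    digest = hashlib.sha256()
    with open(path, "rb") as handle:
        for chunk in iter(lambda: handle.read(1 << 20), b""):
            digest.update(chunk)
    return digest.hexdigest()


def write_provenance(
    out_dir: str | Path,
    config: RunConfig,
) -> Path:
    """Write the machine-readable provenance record for one stage run."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    inputs = {
        role: {"path": str(p), "sha256": _sha256(Path(p))}
        for role, p in config.paths.items()
        if role != "out" and Path(p).is_file()
    }
    record = {
        "command": config.command,
        "parameters": config.parameters,
        "paths": {k: str(v) for k, v in config.paths.items() if k != "out"},
        "seed": config.seed,
        "software_version": __version__,
        "input_checksums": inputs,
    }
    path = out_dir / "provenance.json"
    path.write_text(json.dumps(record, indent=1, sort_keys=True))
    return path
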