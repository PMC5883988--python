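"""Configuration loading and run provenance.

Every CLI command records a ``RunManifest``: the command, its resolved
options, seeds, timestamps, and SHA-256 digests of every input and
output file, so deterministic stages can be re-verified bit-for-bit.
"""

from __future__ import annotations

import hashlib
import json
import platform
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import yaml

__all__ = ["RunManifest", "load_config", "file_digest"]


def file_digest(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def load_config(path: str | Path) -> dict:
    """Load a YAML or JSON config file into a dict."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        return json.loads(text)
    loaded = yaml.safe_load(text)
    if not isinstance(loaded, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return loaded


@dataclass
class RunManifest:
    command: str
    config: dict = field(default_factory=dict)
    seeds: dict = field(default_factory=dict)
    inputs: dict = field(default_factory=dict)
    outputs: dict = field(default_factory=dict)
    started: str = ""
    finished: str = ""

    def __post_init__(self) -> None:
        if not self.started:
            self.started = datetime.now(timezone.utc).isoformat()

    def add_input(self, path: str | Path) -> None:
        self.inputs[str(path)] = file_digest(path)

    def add_output(self, path: str | Path) -> None:
        self.outputs[str(path)] = file_digest(path)

    def finalize(self) -> None:
        self.finished = datetime.now(timezone.utc).isoformat()

    def to_dict(self) -> dict:
        from . import __version__
        return {
            "command": self.command,
            "package_version": __version__,
            "python": platform.python_version(),
            "config": self.config,
            "seeds": self.seeds,
            "inputs": self.inputs,
            "outputs": self.outputs,
            "started": self.started,
            "finished": self.finished,
        }

    def write(self, path: str | Path) -> None:
        self.finalize()
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True))
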