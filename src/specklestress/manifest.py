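"""Run manifests: reproducibility metadata written next to every output."""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from datetime import datetime, timezone
from pathlib import Path

from . import __version__

__all__ = ["RunManifest", "config_hash"]


def config_hash(config: dict) -> str:
    """Stable digest of a configuration mapping (key order independent)."""
    canonical = json.dumps(config, sort_keys=True, default=str)
    return hashlib.sha256(canonical.encode()).hexdigest()[:16]


@dataclass
class RunManifest:
    command: str
    seed: int
    config: dict = field(default_factory=dict)
    input_paths: list[str] = field(default_factory=list)
    output_paths: list[str] = field(default_factory=list)

    def write(self, path: str | Path) -> Path:
        path = Path(path)
        payload = {
            "command": self.command,
            "config_hash": config_hash(self.config),
            "config": self.config,
            "seed": self.seed,
            "input_paths": self.input_paths,
            "output_paths": self.output_paths,
            "tool_version": __version__,
            "timestamp": datetime.now(timezone.utc).isoformat(),
        }
        path.write_text(json.dumps(payload, indent=2, default=str) + "\n")
        return path
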