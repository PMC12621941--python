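"""Run manifests: every CLI run records exactly what produced its outputs."""

from __future__ import annotations

import dataclasses
import datetime
import hashlib
import json
import platform
from pathlib import Path
from typing import Any


def _checksum(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as f:
        for chunk in iter(lambda: f.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclasses.dataclass
class RunManifest:
    """Snapshot of a CLI run: effective config, seeds, input checksums."""

    command: str
    config: dict[str, Any]
    seeds: dict[str, int]
    inputs: dict[str, str] = dataclasses.field(default_factory=dict)
    outputs: list[str] = dataclasses.field(default_factory=list)
    status: str = "ok"
    failure_stage: str | None = None
    package_version: str = ""
    timestamp: str = ""

    def __post_init__(self):
        if not self.package_version:
            from . import __version__
            self.package_version = __version__
        if not self.timestamp:
            self.timestamp = datetime.datetime.now(
                datetime.timezone.utc).isoformat()

    def add_input(self, path) -> None:
        p = Path(path)
        self.inputs[str(p)] = _checksum(p)

    def write(self, directory) -> Path:
        out = Path(directory) / "manifest.json"
        payload = dataclasses.asdict(self)
        payload["platform"] = platform.platform()
        out.write_text(json.dumps(payload, indent=2, sort_keys=True))
        return out
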