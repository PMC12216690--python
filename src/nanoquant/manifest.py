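"""Ground-truth manifests written alongside every synthetic dataset.

A manifest records the generator name, the full configuration it ran with,
and the per-object truth needed to predict the output of each analysis
operation without re-running the simulation (true t_lag and tau, grain
classes and volumes, lifetimes and fractions, band fractions, ...).
Serialization is plain JSON; numpy scalars/arrays are converted to native
Python types so the round trip is lossless.
"""
from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np


def _jsonify(obj: Any) -> Any:
    if isinstance(obj, (np.floating, np.integer, np.bool_)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, dict):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonify(dataclasses.asdict(obj))
    return obj


@dataclass
class GroundTruthManifest:
    generator: str
    config: dict = field(default_factory=dict)
    truth: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "generator": self.generator,
            "config": _jsonify(self.config),
            "truth": _jsonify(self.truth),
        }

    def to_json(self, **kwargs: Any) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, **kwargs)

    @classmethod
    def from_json(cls, text: str) -> "GroundTruthManifest":
        d = json.loads(text)
        return cls(generator=d["generator"], config=d["config"], truth=d["truth"])

    def save(self, path: str | Path) -> Path:
        """Write the sidecar ``<name>.truth.json`` next to a dataset."""
        path = Path(path)
        if not path.name.endswith(".truth.json"):
            path = path.with_suffix(path.suffix + ".truth.json") if path.suffix else path.with_name(path.name + ".truth.json")
        path.write_text(self.to_json(indent=2))
        return path

    @classmethod
    def load(cls, path: str | Path) -> "GroundTruthManifest":
        return cls.from_json(Path(path).read_text())
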