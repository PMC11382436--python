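"""Run configuration and deterministic seed fan-out for the pipeline."""
from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["RunConfig", "stage_seed"]

_STAGES = ("cohort", "rotations", "observers", "session1", "session2")


@dataclass
class RunConfig:
    """End-to-end pipeline parameters.

    A single master seed is fanned out to per-stage seeds through a fixed
    derivation (:func:`stage_seed`), so each stage is independently
    reproducible.  A serialized copy of the configuration is written into
    every output directory.
    """

    n_wrists: int = 30
    seed: int = 0
    spacing: float = 0.4
    pixel_spacing: float = 0.4
    rotation_range: tuple[float, float] = (1.0, 10.0)
    n_uninstructed: int = 7
    n_instructed: int = 6
    outlier_threshold: float = 20.0

    def __post_init__(self) -> None:
        if self.n_wrists < 1:
            raise ValueError("n_wrists must be >= 1")
        if not 0.2 <= self.spacing <= 1.0:
            raise ValueError("spacing must be in [0.2, 1.0] mm")
        lo, hi = self.rotation_range
        if not 0 <= lo < hi:
            raise ValueError("rotation_range must satisfy 0 <= lo < hi")
        if self.n_uninstructed < 1 or self.n_instructed < 1:
            raise ValueError("observer counts must be >= 1")

    def stage_seed(self, stage: str) -> int:
        return stage_seed(self.seed, stage)

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=list)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    def write(self, directory: str | Path) -> Path:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        path = directory / "run_config.json"
        payload = asdict(self)
        payload["rotation_range"] = list(self.rotation_range)
        payload["config_hash"] = self.config_hash()
        path.write_text(json.dumps(payload, indent=1, sort_keys=True))
        return path

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        d = json.loads(Path(path).read_text())
        d.pop("config_hash", None)
        d["rotation_range"] = tuple(d.get("rotation_range", (1.0, 10.0)))
        return cls(**d)


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2^31 derived from the master seed."""
    if stage not in _STAGES:
        raise ValueError(f"unknown stage {stage!r}; expected one of {_STAGES}")
    h = hashlib.sha256(f"{int(master_seed)}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)
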