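"""Run configuration: YAML file + CLI overrides, serialized into provenance."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml


@dataclass
class RunConfig:
    """All pipeline settings; every output carries this in its provenance."""

    structures: str = ""
    kinetics: str = ""
    output_dir: str = "koffgrid_out"
    # grid / field
    spacing: float = 0.5  # A
    margin: float = 5.0  # A
    cutoff: float = 8.0  # A
    shift: bool = False
    probe_table: str | None = None
    # modeling
    p_enter: float = 0.05
    p_remove: float = 0.10
    ncomp_grid: tuple[int, ...] = (1, 2, 3)
    cv_scheme: str = "5-fold"
    koff_floor: float | None = None
    train_fraction: float = 35 / 52
    max_vars: int | None = 9
    parsimony_tol: float = 0.05
    # validation
    n_reps: int = 1000
    n_perms: int = 500
    # randomness
    seed: int = 0

    def __post_init__(self) -> None:
        if self.spacing <= 0 or self.margin < 0 or self.cutoff <= 0:
            raise ValueError("grid settings out of range")
        if not (0 < self.p_enter < 1 and 0 < self.p_remove < 1):
            raise ValueError("entry/removal probabilities must be in (0, 1)")
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must be in (0, 1)")
        if self.n_reps < 1 or self.n_perms < 0:
            raise ValueError("repetition counts out of range")
        self.ncomp_grid = tuple(int(v) for v in self.ncomp_grid)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    def provenance(self, tool_version: str) -> dict:
        return {
            "tool": "koffgrid",
            "version": tool_version,
            "config_hash": self.config_hash(),
            "seed": self.seed,
            "config": self.to_dict(),
        }

    @classmethod
    def load(cls, path: str | Path | None = None, **overrides) -> "RunConfig":
        """Build a config with precedence CLI overrides > file > defaults."""
        values: dict = {}
        if path is not None:
            values.update(yaml.safe_load(Path(path).read_text()) or {})
        values.update({k: v for k, v in overrides.items() if v is not None})
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(values) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**values)
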