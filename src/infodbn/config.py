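"""Run configuration: one seed, one set of knobs, serialized with every run."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .errors import ParameterError


@dataclass
class RunConfig:
    """All tunables of a pipeline run; every stochastic step derives its seed here."""

    seed: int = 0
    # synthetic panel shape
    p: int = 12
    n_feedback: int = 8
    n_unidirectional: int = 10
    n_states: int = 10
    counties_per_state: int = 20
    n_weeks: int = 100
    # imputation
    imputation_method: str = "ewma"
    ewma_k: int = 4
    min_observed: int = 5
    max_missing: float = 0.30
    # learning
    w_grid: tuple = (1, 2, 4, 8, 16, 32, 64, 128)
    split_week: int = 52
    ratio_floor: float = 0.999
    penalty_unit: str = "half_log_n"
    # averaging
    B: int = 500
    subsample_fraction: float = 0.75
    threshold_override: float | None = None
    # inference
    n_sim: int = 100_000
    quartiles: str = "simulated"
    # output
    output_dir: str = "infodbn_run"

    def __post_init__(self):
        if self.seed < 0:
            raise ParameterError("seed must be nonnegative")
        self.w_grid = tuple(self.w_grid)

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["w_grid"] = list(d["w_grid"])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ParameterError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def spawn_seed(self, stage: str) -> int:
        """Deterministic per-stage sub-seed derived from the run seed."""
        import zlib

        return (self.seed * 1_000_003 + zlib.crc32(stage.encode())) % (2**31 - 1)
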