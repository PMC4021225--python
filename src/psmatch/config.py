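"""Run configuration: YAML-loadable, strictly validated, round-trippable.

A dumped effective-config file reloads to an identical run; unknown keys are
rejected rather than ignored so typos never silently fall back to defaults.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from .scoring import ION_TYPE_NAMES, SearchConfig


@dataclass
class RunConfig:
    """Everything a search run needs beyond its input/output paths."""

    precursor_tol_da: float = 3.0
    fragment_tol_da: float = 0.5
    ion_types: list[str] = field(default_factory=lambda: list(ION_TYPE_NAMES))
    offset_mode: str = "exact"
    score_mode: str = "count"
    # enzyme / digestion settings
    max_missed: int = 2
    min_len: int = 6
    max_len: int = 50
    mass_min: float = 500.0
    mass_max: float = 5000.0
    # execution
    mode: str = "serial"  # serial | mc | dc
    workers: int = 1
    nodes: int = 1
    chunks: int = 1
    retry_limit: int = 1
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.precursor_tol_da <= 0 or self.fragment_tol_da <= 0:
            raise ValueError("tolerances must be positive")
        for name in ("workers", "nodes", "chunks"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be at least 1")
        if self.mode not in ("serial", "mc", "dc"):
            raise ValueError(f"invalid mode {self.mode!r}")
        if self.mass_min >= self.mass_max:
            raise ValueError("mass_min must be below mass_max")
        SearchConfig(**self.search_kwargs())  # validates ion/offset/score opts

    def search_kwargs(self) -> dict:
        return {
            "precursor_tol_da": self.precursor_tol_da,
            "fragment_tol_da": self.fragment_tol_da,
            "ion_types": tuple(self.ion_types),
            "offset_mode": self.offset_mode,
            "score_mode": self.score_mode,
        }

    def search_config(self) -> SearchConfig:
        return SearchConfig(**self.search_kwargs())

    def digestion_kwargs(self) -> dict:
        return {
            "max_missed": self.max_missed,
            "min_len": self.min_len,
            "max_len": self.max_len,
            "mass_bounds": (self.mass_min, self.mass_max),
        }

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))
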