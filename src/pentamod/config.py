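"""Run configuration shared by the CLI and the pipeline orchestration."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .errors import InvalidParameterError
from .spectrum import MAX_K

#: The eleven frequency targets spanning zero, low, medium and high proteomic
#: frequencies: the never-expressed set, singletons, the distribution mode
#: (50), the median frequency (341), and the long tail up to 2500.
DEFAULT_FREQUENCY_TARGETS = (0, 1, 4, 5, 50, 100, 341, 500, 1000, 1368, 2500)


@dataclass
class RunConfig:
    k: int = 5
    frequency_targets: tuple[int, ...] = DEFAULT_FREQUENCY_TARGETS
    scale_files: dict[str, str] = field(default_factory=dict)
    usage_table: str | None = None
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if not 1 <= self.k <= MAX_K:
            raise InvalidParameterError(f"k must be in [1, {MAX_K}], got {self.k}")
        if len(set(self.frequency_targets)) != len(self.frequency_targets):
            raise InvalidParameterError(
                f"frequency targets must be distinct: {list(self.frequency_targets)}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "frequency_targets" in raw:
            raw["frequency_targets"] = tuple(raw["frequency_targets"])
        return cls(**raw)
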