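"""Run configuration: validated, hashable, and serialisable to JSON."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

from pydantic import BaseModel, Field, ValidationError

from .errors import ConfigurationError


class ScheduleConfig(BaseModel):
    """Interleaved acquisition timing (seconds; samples/s for burst_rate)."""

    fret_period: float = 10.0
    fret_exposure: float = 0.1
    burst_rate: float = 1000.0
    burst_duration: float = 2.0
    total_duration: float = 120.0
    burst_offset: float = 0.1


class PathsConfig(BaseModel):
    """Input files: CFP/YFP/mask plus one Vm and Ca stack per burst."""

    cfp: str
    yfp: str
    mask: str
    vm: list[str] = Field(default_factory=list)
    ca: list[str] = Field(default_factory=list)
    rois: str | None = None


class RunConfig(BaseModel):
    """Everything a full pipeline run needs; hashed into every output CSV."""

    schedule: ScheduleConfig = Field(default_factory=ScheduleConfig)
    paths: PathsConfig
    baseline_window: tuple[int, int] = (0, 1)
    polarity: dict[str, int] = Field(default_factory=lambda: {"vm": -1, "ca": 1})
    tophat_window_ms: float | None = None
    yfp_floor: float = 0.0
    n_beats: int = 10
    seed: int = 0
    stimulus_onset: float = 0.0

    def config_hash(self) -> str:
        """SHA-256 of the canonical JSON form (first 16 hex digits)."""
        canon = json.dumps(self.model_dump(mode="json"), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]

    def check_paths(self) -> None:
        """Verify every referenced input file exists; name the missing channel."""
        named = [("cfp", self.paths.cfp), ("yfp", self.paths.yfp), ("mask", self.paths.mask)]
        named += [("vm", p) for p in self.paths.vm]
        named += [("ca", p) for p in self.paths.ca]
        if self.paths.rois:
            named.append(("rois", self.paths.rois))
        for channel, p in named:
            if not Path(p).exists():
                raise ConfigurationError(f"missing {channel} input: {p}")


def load_config(path) -> RunConfig:
    """Load and schema-validate a JSON run config."""
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"config not found: {path}")
    try:
        return RunConfig.model_validate_json(path.read_text())
    except ValidationError as exc:
        raise ConfigurationError(f"invalid config {path}: {exc}") from exc


def config_schema() -> dict:
    """Published JSON schema for :class:`RunConfig`."""
    return RunConfig.model_json_schema()
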