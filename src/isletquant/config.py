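"""Run configuration: one YAML-backed record covering every tunable knob."""
from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .errors import ParameterError
from .imgio import DEFAULT_CHANNEL_MAP, _validate_channel_map
from .scoring import ScoringConfig


@dataclass
class RunConfig:
    """Pipeline-wide configuration with CLI-flag overrides.

    Every default mirrors a documented design choice of the owning
    module, so the adjustable assumptions are user-visible in one place.
    Round-trips losslessly through its YAML representation.
    """

    channel_map: dict = field(default_factory=lambda: dict(DEFAULT_CHANNEL_MAP))
    histogram_bins: int = 256
    min_radius: float = 3.0
    max_radius: float = 8.0
    patch_radius: float | None = None
    denominator: str = "islet"
    target_channel: str = "target488"
    pixel_size: float | None = None
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        _validate_channel_map(self.channel_map)
        # delegate numeric-range checks to ScoringConfig
        self.scoring()
        if self.log_level.upper() not in ("DEBUG", "INFO", "WARNING", "ERROR"):
            raise ParameterError(f"unknown log level {self.log_level!r}")
        if int(self.seed) != self.seed or not 0 <= self.seed < 2**31:
            raise ParameterError("seed must be an integer in [0, 2^31)")

    def scoring(self) -> ScoringConfig:
        return ScoringConfig(
            histogram_bins=self.histogram_bins,
            min_radius=self.min_radius,
            max_radius=self.max_radius,
            patch_radius=self.patch_radius,
            denominator=self.denominator,
            target_channel=self.target_channel,
            pixel_size=self.pixel_size,
        )

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ParameterError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)
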