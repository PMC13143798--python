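"""Run-time configuration: defaults, YAML loading, CLI override merging."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Any

import yaml

from .errors import ConfigError

DEFAULT_COLUMNS = {"t": "t_ms", "flow": "flow_lpm", "pco2": "pco2_mmhg"}


@dataclass
class PipelineConfig:
    """Options shared by the processing stages.

    Attributes
    ----------
    dt_ms:
        Nominal sampling interval of the record in milliseconds.
    invert_flow:
        Flip the sign of the flow channel on read.  The toolkit convention is
        positive flow = expiration; set this if the recording uses the
        opposite polarity.
    patm_mmhg:
        Atmospheric pressure used to convert a CO2 partial pressure into a
        gas-volume fraction.
    deadband_lpm:
        Half-width of the hysteresis band around zero flow used by the
        breath segmenter.
    min_phase_ms:
        Minimum duration a new flow direction must persist before a phase
        change is accepted.
    apnea_ms:
        A sub-deadband stretch longer than this terminates the current cycle
        instead of extending its expiration.
    slope3_window:
        (lo, hi) expired-volume fractions delimiting the phase III fit.
    columns:
        CSV column-name remapping for the three channels.
    """

    dt_ms: int = 10
    invert_flow: bool = False
    patm_mmhg: float = 760.0
    deadband_lpm: float = 0.5
    min_phase_ms: float = 150.0
    apnea_ms: float = 2000.0
    slope3_window: tuple[float, float] = (0.40, 0.80)
    columns: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_COLUMNS))

    def __post_init__(self) -> None:
        if self.dt_ms <= 0:
            raise ConfigError(f"dt_ms must be positive, got {self.dt_ms}")
        if self.patm_mmhg <= 0:
            raise ConfigError(f"patm_mmhg must be positive, got {self.patm_mmhg}")
        if self.deadband_lpm < 0:
            raise ConfigError(f"deadband_lpm must be >= 0, got {self.deadband_lpm}")
        if self.min_phase_ms < self.dt_ms:
            raise ConfigError(
                f"min_phase_ms ({self.min_phase_ms}) must be >= dt_ms ({self.dt_ms})"
            )
        lo, hi = self.slope3_window
        if not (0.0 < lo < hi < 1.0):
            raise ConfigError(
                f"slope3_window must satisfy 0 < lo < hi < 1, got {self.slope3_window}"
            )

    @classmethod
    def from_mapping(cls, mapping: dict[str, Any]) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = sorted(set(mapping) - known)
        if unknown:
            raise ConfigError(f"unknown configuration key(s): {', '.join(unknown)}")
        kwargs = dict(mapping)
        if "slope3_window" in kwargs:
            kwargs["slope3_window"] = tuple(kwargs["slope3_window"])
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ConfigError(f"config file {path!r} must contain a mapping")
        return cls.from_mapping(data)

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["slope3_window"] = list(self.slope3_window)
        return d
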