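"""Analysis configuration: defaults, validation, YAML round trip."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import yaml

from .core import BIN_WIDTH_RANGE
from .evoked import DEFAULT_EPOCHS


class ConfigError(ValueError):
    pass


@dataclass
class AnalysisConfig:
    """Pipeline-level parameters; every field is validated against its allowed
    range at load time."""

    bin_rate_hz: float = 50.0  # 30-50 Hz
    pupil_lag_s: float = 0.75  # pupil leads spikes by this much
    blink_sd: float = 6.0
    excision_s: float = 6.0
    response_window: tuple[float, float] = (0.2, 0.15)  # after onset / after offset
    epochs: dict = field(default_factory=lambda: {k: tuple(v) for k, v in DEFAULT_EPOCHS.items()})
    alpha: float = 0.05
    cv_folds: int = 20
    block_size: int = 20
    min_sustained_rate: float = 1.0  # units below this in every phase are excluded
    analysis_window: tuple[float, float] = (-0.5, 1.5)
    seed: int = 0

    @property
    def bin_width(self) -> float:
        return 1.0 / self.bin_rate_hz

    def validate(self) -> "AnalysisConfig":
        if not 30.0 <= self.bin_rate_hz <= 50.0:
            raise ConfigError("bin_rate_hz must lie in [30, 50]")
        if not BIN_WIDTH_RANGE[0] - 1e-9 <= self.bin_width <= BIN_WIDTH_RANGE[1] + 1e-9:
            raise ConfigError("bin width outside allowed range")
        if self.pupil_lag_s < 0:
            raise ConfigError("pupil_lag_s must be non-negative")
        if self.blink_sd <= 0 or self.excision_s <= 0:
            raise ConfigError("blink parameters must be positive")
        if not 0 < self.alpha < 1:
            raise ConfigError("alpha must lie in (0, 1)")
        if self.cv_folds < 1 or self.block_size < 1:
            raise ConfigError("cv_folds and block_size must be positive integers")
        for name, (lo, hi) in self.epochs.items():
            if hi <= lo:
                raise ConfigError(f"epoch {name} must have positive length")
        return self

    def to_yaml(self, path: str) -> None:
        d = asdict(self)
        d["response_window"] = list(self.response_window)
        d["analysis_window"] = list(self.analysis_window)
        d["epochs"] = {k: list(v) for k, v in self.epochs.items()}
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str) -> "AnalysisConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        if "response_window" in d:
            d["response_window"] = tuple(d["response_window"])
        if "analysis_window" in d:
            d["analysis_window"] = tuple(d["analysis_window"])
        if "epochs" in d:
            d["epochs"] = {k: tuple(v) for k, v in d["epochs"].items()}
        return cls(**d).validate()
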