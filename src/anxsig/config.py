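"""Run configuration: every numeric setting of the analysis in one
serializable, round-trippable object."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .preprocess import DEFAULT_FILTERS
from .synth import EEG_BANDS, NATIVE_RATES


@dataclass
class RunConfig:
    """Defaults encode the study's stated settings: 30 s / 5 s epoching at
    a common 100 Hz rate over 300 s recordings, the per-modality filter
    cutoffs, the five EEG bands, and alpha = 0.05."""

    n_participants: int = 17
    duration_s: float = 300.0
    seed: int = 0
    target_fs: float = 100.0
    window_s: float = 30.0
    step_s: float = 5.0
    alpha: float = 0.05
    native_rates: dict = field(default_factory=lambda: dict(NATIVE_RATES))
    bands: dict = field(default_factory=lambda: {
        b: list(v) for b, v in EEG_BANDS.items()})
    filters: dict = field(default_factory=lambda: {
        k: v.to_dict() for k, v in DEFAULT_FILTERS.items()})

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(**data)
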