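"""Declarative pipeline configuration.

Defaults follow the canonical analysis settings: k scanned over 2..24
with 100 maximum iterations per k and the final fit re-run at 1000
iterations; the representative-track margin is 10% of the subdivision
s.d.; the diversity moving-average window is 3 hours. All randomness
flows from the seeds recorded here. The config round-trips losslessly
through YAML.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .classifier import ClassifierSpec


@dataclass
class PipelineConfig:
    seed: int = 0
    # synthetic inputs
    n_tracks: int = 500_000
    n_events: int = 2_000_000
    invalid_frac: float = 0.1
    n_people: int = 2000
    n_participants: int = 176
    rating_effects: dict[str, float] = field(
        default_factory=lambda: {
            "morning": 4.0,
            "afternoon": -4.0,
            "evening": 0.0,
            "night": -5.0,
            "late_night": 11.0,
        }
    )
    rating_noise_sd: float = 20.0
    rating_missing_frac: float = 0.05
    # clustering
    k_range: tuple[int, int] = (2, 24)
    restarts: int = 20
    scan_max_iter: int = 100
    fit_max_iter: int = 1000
    # preference
    margin: float = 0.10
    # diversity
    diversity_window: int = 3
    # classifier overrides
    classifier: ClassifierSpec = field(default_factory=ClassifierSpec)

    def to_yaml(self) -> str:
        d = asdict(self)
        d["k_range"] = list(self.k_range)
        d["classifier"]["hidden"] = list(self.classifier.hidden)
        return yaml.safe_dump(d, sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "PipelineConfig":
        d = yaml.safe_load(text) or {}
        if "classifier" in d:
            c = d["classifier"]
            if "hidden" in c:
                c["hidden"] = tuple(c["hidden"])
            d["classifier"] = ClassifierSpec(**c)
        if "k_range" in d:
            d["k_range"] = tuple(d["k_range"])
        return cls(**d)

    @classmethod
    def load(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_yaml(Path(path).read_text())

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_yaml())
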