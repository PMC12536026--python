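"""Run configuration shared by the CLI and the end-to-end pipeline."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

# The nine marker/clinical correlation pairs examined within the ALS group.
DEFAULT_CORRELATION_FAMILY: tuple[tuple[str, str], ...] = (
    ("alps_index", "cpv_fraction_pct"),
    ("alps_index", "coupling_index"),
    ("alps_index", "progression_rate"),
    ("alps_index", "alsfrs_r"),
    ("coupling_index", "progression_rate"),
    ("coupling_index", "alsfrs_r"),
    ("cpv_fraction_pct", "progression_rate"),
    ("cpv_fraction_pct", "alsfrs_r"),
    ("alsfrs_r", "progression_rate"),
)


@dataclass(frozen=True)
class RunConfig:
    """Defaults mirror the acquisition/analysis settings of the study
    cohort: TR 2 s, 10 discarded volumes, 0.01-0.1 Hz band, +/-10 s lag
    grid with the coupling index at +4 s, 10,000 permutations, 1,000
    bootstrap repetitions."""

    tr: float = 2.0
    n_volumes: int = 240
    n_discard: int = 10
    passband: tuple[float, float] = (0.01, 0.1)
    max_lag: float = 10.0
    index_lag: float = 4.0
    n_perm: int = 10_000
    n_boot: int = 1_000
    normality_alpha: float = 0.05
    signal_coupling_strength: float = 0.9
    correlation_family: tuple[tuple[str, str], ...] = DEFAULT_CORRELATION_FAMILY
    seed: int = 0

    def __post_init__(self) -> None:
        low, high = self.passband
        if not (0 < low < high < 0.5 / self.tr):
            raise ValueError("passband must lie inside (0, Nyquist)")
        if self.n_discard >= self.n_volumes:
            raise ValueError("n_discard must be smaller than n_volumes")
        if self.index_lag > self.max_lag:
            raise ValueError("index_lag must be within the lag range")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["passband"] = list(self.passband)
        d["correlation_family"] = [list(p) for p in self.correlation_family]
        return d

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "passband" in raw:
            raw["passband"] = tuple(raw["passband"])
        if "correlation_family" in raw:
            raw["correlation_family"] = tuple(tuple(p) for p in raw["correlation_family"])
        return cls(**raw)
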