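"""Pipeline configuration with the protocol's default parameter values."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml


@dataclass
class PipelineConfig:
    """Parameters of the analysis pipeline.

    Defaults follow the capture protocol: a fourth-order 5 Hz low-pass
    Butterworth filter (applied zero-phase), five equidistant evaluation
    points per fitted curve, four capture instants per stationary trial,
    four extracted cycles per dynamic trial analyzed at 0/25/50/75/100 %
    of each half-cycle.
    """

    filter_cutoff_hz: float = 5.0
    filter_order: int = 4
    n_eval_points: int = 5
    n_static_captures: int = 4
    n_cycles_extracted: int = 4
    phase_percentages: tuple[int, ...] = (0, 25, 50, 75, 100)
    max_gap_frames: int = 24
    seed: int = 0

    # cycle / hold detection
    prominence_frac: float = 0.25
    static_tolerance_deg: float = 2.0
    drop_first_cycle: bool = True

    # geometry conventions
    ml_definition: str = "side_midpoints"  # or "tip"
    shared_eval_range: bool = True
    collinearity_tol_mm: float = 1e-6

    def __post_init__(self) -> None:
        self.phase_percentages = tuple(int(p) for p in self.phase_percentages)
        if self.filter_order < 1:
            raise ValueError("filter_order must be >= 1")
        if self.filter_cutoff_hz <= 0:
            raise ValueError("filter_cutoff_hz must be positive")
        if self.n_eval_points < 2:
            raise ValueError("n_eval_points must be >= 2")
        if self.ml_definition not in ("side_midpoints", "tip"):
            raise ValueError(f"unknown ml_definition {self.ml_definition!r}")
        if any(not 0 <= p <= 100 for p in self.phase_percentages):
            raise ValueError("phase percentages must lie in [0, 100]")

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        data["phase_percentages"] = list(self.phase_percentages)
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)
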