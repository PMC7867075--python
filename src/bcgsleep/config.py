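"""Pipeline configuration: every tunable constant, YAML in/out.

Defaults are the method's printed operating point: 0.1-Hz high-pass,
1-10-Hz band-pass, 0.325-s smoothing, 0.365-s minimum peak interval,
2-Hz tachogram, 7-s despike window, 30-s epochs and a 2 x 10 x 10
hyperparameter grid.  Any deviation must be explicit in the config.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, fields
from pathlib import Path

import yaml

from .types import ParameterError


@dataclass
class PipelineConfig:
    # preprocess
    highpass_hz: float = 0.1
    band_hz: tuple[float, float] = (1.0, 10.0)
    ma_window_s: float = 0.325
    # bcg_beats
    min_peak_interval_s: float = 0.365
    tachogram_fs: float = 2.0
    despike_window_s: float = 7.0
    max_gap_s: float = 2.0
    # features
    epoch_len_s: float = 30.0
    fs_mode: str = "density"  # "density" or "sum" scaling of the FS feature
    hrv_spectrum: str = "power"  # "power" or "amplitude" band ratios
    # staging grid
    criteria: tuple[str, ...] = ("gini", "entropy")
    max_depth: tuple[int, int] = (1, 10)
    n_trees: tuple[int, int] = (1, 10)
    paper_faithful: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.band_hz, list):
            self.band_hz = tuple(self.band_hz)
        if isinstance(self.criteria, list):
            self.criteria = tuple(self.criteria)
        if isinstance(self.max_depth, list):
            self.max_depth = tuple(self.max_depth)
        if isinstance(self.n_trees, list):
            self.n_trees = tuple(self.n_trees)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ParameterError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)
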