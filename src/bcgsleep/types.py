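"""Domain containers shared across the pipeline.

All signal containers carry SI units: acceleration in m/s**2, time in
seconds, sampling rates in Hz.  Sleep is scored in fixed 30-s epochs with
the four-class alphabet WAKE / REM / LIGHT / DEEP (LIGHT = AASM N1+N2,
DEEP = N3).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

EPOCH_LEN_S = 30.0

STAGES = ("WAKE", "REM", "LIGHT", "DEEP")
SLEEP_STAGES = ("REM", "LIGHT", "DEEP")

#: AASM scoring aliases accepted on input, normalised to the 4-class alphabet.
STAGE_ALIASES = {
    "WAKE": "WAKE", "W": "WAKE", "WK": "WAKE",
    "REM": "REM", "R": "REM",
    "LIGHT": "LIGHT", "N1": "LIGHT", "N2": "LIGHT", "L": "LIGHT",
    "DEEP": "DEEP", "N3": "DEEP", "D": "DEEP",
}

#: Feature manifest of the wake/sleep (step-1) classifier.
FIRST_STEP_FEATURES = ("AGM", "VGM", "FS", "AJJI", "VJJI")
#: Base (unstandardised) features from which step-2 inputs are derived.
BASE_FEATURES = ("AGM", "VGM", "FS", "AJJI", "VJJI", "HF/TF", "HF/LF")
#: Feature manifest of the REM/LIGHT/DEEP (step-2) classifier.
SECOND_STEP_FEATURES = (
    "SAGM", "SVGM", "SFS", "SAJJI", "SVJJI", "SHF/TF", "SHF/LF", "SET", "HRT",
)


class FormatError(ValueError):
    """Malformed on-disk artifact (missing column, duplicate name, ...)."""


class RateError(ValueError):
    """Time axis inconsistent with the declared sampling rate."""


class LabelError(ValueError):
    """Sleep-stage label outside the accepted alphabet."""


class ParameterError(ValueError):
    """Invalid processing parameter (cutoff past Nyquist, ...)."""


@dataclass
class Recording:
    """Raw 3-axis head acceleration at a fixed sampling rate.

    Axes are the sensor frame; gravity is present in the raw data and is
    removed by the high-pass/band-pass stages downstream.
    """

    subject_id: str
    night_id: str
    fs: float
    ax: np.ndarray
    ay: np.ndarray
    az: np.ndarray
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.ax = np.asarray(self.ax, dtype=float)
        self.ay = np.asarray(self.ay, dtype=float)
        self.az = np.asarray(self.az, dtype=float)
        if self.fs <= 0:
            raise ParameterError(f"sampling rate must be positive, got {self.fs}")
        if not (len(self.ax) == len(self.ay) == len(self.az)):
            raise FormatError("axis series must have identical length")
        if len(self.ax) < 1:
            raise FormatError("recording must contain at least one sample")
        for name, arr in (("ax", self.ax), ("ay", self.ay), ("az", self.az)):
            if not np.all(np.isfinite(arr)):
                raise FormatError(f"non-finite samples in {name}")

    def __len__(self) -> int:
        return len(self.ax)

    @property
    def duration_s(self) -> float:
        return len(self.ax) / self.fs

    @property
    def n_epochs(self) -> int:
        """Number of complete 30-s epochs; a trailing partial epoch is dropped."""
        return int(len(self.ax) // round(EPOCH_LEN_S * self.fs))

    def axes(self) -> np.ndarray:
        """Return the (n, 3) axis matrix."""
        return np.column_stack([self.ax, self.ay, self.az])


@dataclass
class Hypnogram:
    """Ordered 30-s epoch stage labels in the 4-class alphabet."""

    stages: list[str]
    epoch_len: float = EPOCH_LEN_S

    def __post_init__(self) -> None:
        if self.epoch_len != EPOCH_LEN_S:
            raise ParameterError("epoch length is fixed at 30 s")
        self.stages = [str(s) for s in self.stages]
        for s in self.stages:
            if s not in STAGES:
                raise LabelError(f"unknown stage label {s!r}")

    def __len__(self) -> int:
        return len(self.stages)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.stages, dtype=object)

    def sleep_mask(self) -> np.ndarray:
        """Boolean mask of epochs scored as any sleep stage (not WAKE)."""
        return np.asarray([s != "WAKE" for s in self.stages])


@dataclass
class FusedSignal:
    """One-axis RMS-fused acceleration envelope (nonnegative by construction)."""

    fs: float
    values: np.ndarray
    branch: str  # "movement" or "bcg"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.branch not in ("movement", "bcg"):
            raise ParameterError(f"unknown branch {self.branch!r}")

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class BeatSeries:
    """Detected J-wave fiducials: strictly increasing times and peak amplitudes."""

    times: np.ndarray
    amplitudes: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.amplitudes = np.asarray(self.amplitudes, dtype=float)
        if len(self.times) != len(self.amplitudes):
            raise FormatError("times and amplitudes must have equal length")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise FormatError("beat times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.times)


#: Tachogram sample quality flags.
QUALITY_OK = 0
QUALITY_INTERP = 1  # interpolated across a movement-induced detection gap


@dataclass
class Tachogram:
    """Beat-interval series resampled on a uniform grid (default 2 Hz).

    ``jji[i]`` is the interpolated J-J interval at time
    ``t_start + i / fs``.  ``quality`` marks samples where the spline
    bridged a detection dropout.
    """

    fs: float
    t_start: float
    jji: np.ndarray
    quality: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.jji = np.asarray(self.jji, dtype=float)
        if self.quality is None:
            self.quality = np.zeros(len(self.jji), dtype=np.int8)
        else:
            self.quality = np.asarray(self.quality, dtype=np.int8)
        if len(self.quality) != len(self.jji):
            raise FormatError("quality flags must match the interval series")

    def __len__(self) -> int:
        return len(self.jji)

    def times(self) -> np.ndarray:
        return self.t_start + np.arange(len(self.jji)) / self.fs


def make_feature_table(
    subject_id: str,
    night_id: str,
    columns: dict[str, np.ndarray],
) -> pd.DataFrame:
    """Assemble a per-epoch feature table.

    The canonical in-memory form is a DataFrame with identity columns
    ``subject_id``, ``night_id``, ``epoch`` followed by named feature
    columns.  Feature names must be unique.
    """
    names = list(columns)
    if len(set(names)) != len(names):
        raise FormatError("duplicate feature names")
    lengths = {len(np.asarray(v)) for v in columns.values()}
    if len(lengths) > 1:
        raise FormatError("feature columns must have equal length")
    n = lengths.pop() if lengths else 0
    out = pd.DataFrame(
        {
            "subject_id": [subject_id] * n,
            "night_id": [night_id] * n,
            "epoch": np.arange(n, dtype=int),
        }
    )
    for name, vals in columns.items():
        out[name] = np.asarray(vals)
    return out
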