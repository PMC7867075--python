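"""On-disk formats: recording CSV, hypnogram TSV, feature-table CSV.

The canonical recording format is a CSV with header ``t,ax,ay,az`` in SI
units (seconds, m/s^2).  Hypnograms are one stage label per line (or TSV
``epoch_index<TAB>stage``); AASM aliases (W, R, N1, N2, N3) are accepted
and normalised to WAKE/REM/LIGHT/DEEP.  Feature tables round-trip through
CSV losslessly within float text precision.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .types import (
    FormatError,
    Hypnogram,
    LabelError,
    RateError,
    Recording,
    STAGE_ALIASES,
)

log = logging.getLogger(__name__)

RATE_TOLERANCE = 0.01  # fractional deviation of any sample spacing

_TIME_NAMES = ("t", "time", "time_s", "timestamp")
_AXIS_NAMES = ("ax", "ay", "az")


def read_recording(
    path: str | Path,
    fs_hint: float | None = None,
    subject_id: str = "",
    night_id: str = "",
) -> Recording:
    """Read a 3-axis acceleration CSV and validate its time grid.

    The sample spacing must be uniform within 1%; the rate must agree with
    ``fs_hint`` (when given) within the same tolerance.  A non-monotone
    time column is rejected.
    """
    df = pd.read_csv(path)
    cols = {c.strip().lower(): c for c in df.columns}
    tcol = next((cols[n] for n in _TIME_NAMES if n in cols), None)
    if tcol is None:
        raise FormatError(f"{path}: no time column (expected one of {_TIME_NAMES})")
    missing = [n for n in _AXIS_NAMES if n not in cols]
    if missing:
        raise FormatError(f"{path}: missing axis column(s) {missing}")
    t = df[tcol].to_numpy(dtype=float)
    if len(t) < 2:
        raise FormatError(f"{path}: need at least 2 samples")
    dt = np.diff(t)
    if np.any(dt <= 0):
        raise RateError(f"{path}: time column not strictly increasing")
    dt0 = float(np.median(dt))
    if np.any(np.abs(dt - dt0) > RATE_TOLERANCE * dt0):
        raise RateError(f"{path}: non-uniform sampling beyond {RATE_TOLERANCE:.0%}")
    fs = 1.0 / dt0
    if fs_hint is not None and abs(fs - fs_hint) > RATE_TOLERANCE * fs_hint:
        raise RateError(f"{path}: rate {fs:.3f} Hz disagrees with hint {fs_hint} Hz")
    return Recording(
        subject_id=subject_id,
        night_id=night_id,
        fs=fs_hint if fs_hint is not None else fs,
        ax=df[cols["ax"]].to_numpy(dtype=float),
        ay=df[cols["ay"]].to_numpy(dtype=float),
        az=df[cols["az"]].to_numpy(dtype=float),
        t0=float(t[0]),
    )


def write_recording(rec: Recording, path: str | Path) -> None:
    t = rec.t0 + np.arange(len(rec)) / rec.fs
    pd.DataFrame({"t": t, "ax": rec.ax, "ay": rec.ay, "az": rec.az}).to_csv(
        path, index=False, float_format="%.9g"
    )


def read_hypnogram(path: str | Path) -> Hypnogram:
    """Read a hypnogram: one label per line, or TSV ``epoch_index<TAB>stage``."""
    stages: list[str] = []
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        token = parts[-1].strip().upper()
        if token in ("STAGE", "LABEL"):  # tolerated header
            continue
        if token not in STAGE_ALIASES:
            raise LabelError(f"{path}: unknown stage label {token!r}")
        stages.append(STAGE_ALIASES[token])
    return Hypnogram(stages=stages)


def write_hypnogram(hyp: Hypnogram, path: str | Path) -> None:
    Path(path).write_text("".join(f"{s}\n" for s in hyp.stages))


def write_feature_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write a per-epoch feature table to CSV (full float precision)."""
    names = list(table.columns)
    if len(set(names)) != len(names):
        raise FormatError("duplicate feature names")
    table.to_csv(path, index=False, float_format="%.17g")


def read_feature_table(path: str | Path) -> pd.DataFrame:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(",")
    if len(set(header)) != len(header):
        raise FormatError(f"{path}: duplicate feature names in header")
    df = pd.read_csv(path)
    if "epoch" in df.columns:
        df["epoch"] = df["epoch"].astype(int)
    return df


def align_recording_hypnogram(
    n_feature_epochs: int, hyp: Hypnogram
) -> tuple[int, Hypnogram]:
    """Truncate to the shorter of the feature epochs and the hypnogram.

    The two can disagree when the recording ends mid-epoch or scoring
    stopped early; truncation is lossy but explicit (a warning is logged).
    """
    n = min(n_feature_epochs, len(hyp))
    if n != n_feature_epochs or n != len(hyp):
        log.warning(
            "length mismatch: %d feature epochs vs %d scored epochs; using %d",
            n_feature_epochs,
            len(hyp),
            n,
        )
    return n, Hypnogram(stages=hyp.stages[:n])
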