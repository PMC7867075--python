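"""Filtering and 3-axis -> 1-axis RMS fusion.

Two branches share this module: the gross-movement branch (0.1 Hz
high-pass, then RMS fusion) and the ballistocardiogram branch (1-10 Hz
band-pass, RMS fusion, 0.325-s moving average).  Filters are 4th-order
Butterworth applied forward-backward (zero phase), so peak times are not
shifted relative to the 30-s stage epochs.
"""

from __future__ import annotations

import numpy as np
from scipy import signal as sps

from .types import FusedSignal, ParameterError, Recording

FILTER_ORDER = 4


def _sosfiltfilt(sos: np.ndarray, x: np.ndarray) -> np.ndarray:
    return sps.sosfiltfilt(sos, x)


def highpass_filter(rec: Recording, cutoff: float = 0.1) -> Recording:
    """High-pass each axis, removing DC (gravity) and slow drift."""
    nyq = rec.fs / 2.0
    if not 0 < cutoff < nyq:
        raise ParameterError(f"high-pass cutoff {cutoff} Hz outside (0, {nyq}) Hz")
    sos = sps.butter(FILTER_ORDER, cutoff, btype="highpass", fs=rec.fs, output="sos")
    return Recording(
        subject_id=rec.subject_id,
        night_id=rec.night_id,
        fs=rec.fs,
        ax=_sosfiltfilt(sos, rec.ax),
        ay=_sosfiltfilt(sos, rec.ay),
        az=_sosfiltfilt(sos, rec.az),
        t0=rec.t0,
    )


def bandpass_filter(rec: Recording, lo: float = 1.0, hi: float = 10.0) -> Recording:
    """Band-pass each axis; suppresses DC, drift and respiration (~0.25 Hz)."""
    nyq = rec.fs / 2.0
    if not 0 < lo < hi < nyq:
        raise ParameterError(f"band ({lo}, {hi}) Hz invalid for fs {rec.fs} Hz")
    sos = sps.butter(FILTER_ORDER, [lo, hi], btype="bandpass", fs=rec.fs, output="sos")
    return Recording(
        subject_id=rec.subject_id,
        night_id=rec.night_id,
        fs=rec.fs,
        ax=_sosfiltfilt(sos, rec.ax),
        ay=_sosfiltfilt(sos, rec.ay),
        az=_sosfiltfilt(sos, rec.az),
        t0=rec.t0,
    )


def rms_fuse(rec: Recording, branch: str = "movement") -> FusedSignal:
    """Fuse the three axes into one by the per-sample RMS.

    ``sqrt((ax^2 + ay^2 + az^2) / 3)`` is invariant under any fixed
    orthonormal rotation of the sensor frame, which removes the influence
    of sensor mounting orientation and sleep posture.
    """
    vals = np.sqrt((rec.ax**2 + rec.ay**2 + rec.az**2) / 3.0)
    return FusedSignal(fs=rec.fs, values=vals, branch=branch)


def moving_average(sig: FusedSignal, window: float = 0.325) -> FusedSignal:
    """Centered moving mean with an odd kernel; edges use shrinking windows.

    At 200 Hz the default 0.325-s window gives a 65-sample kernel.  The
    shrinking-window edges keep the output unbiased near the boundaries
    (a constant input maps to the same constant everywhere).
    """
    if window <= 0:
        raise ParameterError("moving-average window must be positive")
    k = int(round(window * sig.fs))
    if k < 1:
        raise ParameterError("window shorter than one sample")
    if k % 2 == 0:
        k += 1
    if k == 1:
        return FusedSignal(fs=sig.fs, values=sig.values.copy(), branch=sig.branch)
    half = k // 2
    x = sig.values
    csum = np.concatenate([[0.0], np.cumsum(x)])
    n = len(x)
    idx = np.arange(n)
    lo = np.maximum(idx - half, 0)
    hi = np.minimum(idx + half, n - 1)
    out = (csum[hi + 1] - csum[lo]) / (hi - lo + 1)
    return FusedSignal(fs=sig.fs, values=out, branch=sig.branch)


def movement_branch(rec: Recording, highpass_hz: float = 0.1) -> FusedSignal:
    """Gross-movement envelope: high-pass then RMS fusion."""
    return rms_fuse(highpass_filter(rec, highpass_hz), branch="movement")


def bcg_branch(
    rec: Recording,
    band_hz: tuple[float, float] = (1.0, 10.0),
    ma_window_s: float = 0.325,
) -> FusedSignal:
    """Ballistocardiogram envelope: band-pass, RMS fusion, moving average."""
    fused = rms_fuse(bandpass_filter(rec, *band_hz), branch="bcg")
    return moving_average(fused, ma_window_s)
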