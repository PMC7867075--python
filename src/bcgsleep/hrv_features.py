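"""Epoch-level heart-rate-variability features from the JJI tachogram.

AJJI/VJJI are the mean and population variance of the 2-Hz tachogram in
each 30-s epoch (60 samples).  HF/LF band powers come from a 60-point
DFT of the mean-removed epoch: LF 0.04-0.15 Hz, HF 0.15-0.4 Hz, TF their
union, so TF = HF + LF holds exactly by bin partition.  VLF is not
computed spectrally - at 2 Hz and 30-s epochs the resolution is too
coarse - its information enters through AJJI instead.
"""

from __future__ import annotations

import numpy as np

from .types import EPOCH_LEN_S, QUALITY_OK, Tachogram

LF_BAND = (0.04, 0.15)  # inclusive lower, exclusive upper
HF_BAND = (0.15, 0.4)  # inclusive both ends
#: Minimum count of ok-quality samples for an epoch's AJJI/VJJI to be valid.
MIN_OK_SAMPLES = 30


def _epoch_slices(
    tach: Tachogram, n_epochs: int, epoch_len: float
) -> list[tuple[int, int]]:
    """Index range [i0, i1) of tachogram samples inside each epoch."""
    out = []
    n = len(tach)
    for e in range(n_epochs):
        lo_t, hi_t = e * epoch_len, (e + 1) * epoch_len
        i0 = int(np.ceil((lo_t - tach.t_start) * tach.fs - 1e-9))
        i1 = int(np.ceil((hi_t - tach.t_start) * tach.fs - 1e-9))
        out.append((min(max(i0, 0), n), min(max(i1, 0), n)))
    return out


def ajji_vjji(
    tach: Tachogram,
    n_epochs: int,
    epoch_len: float = EPOCH_LEN_S,
    min_ok: int = MIN_OK_SAMPLES,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-epoch tachogram mean (AJJI) and population variance (VJJI).

    Epochs with fewer than ``min_ok`` ok-quality samples are returned as
    NaN with ``missing=True``; callers impute them with the recording
    median (see :func:`impute_missing`).
    """
    ajji = np.full(n_epochs, np.nan)
    vjji = np.full(n_epochs, np.nan)
    missing = np.ones(n_epochs, dtype=bool)
    for e, (i0, i1) in enumerate(_epoch_slices(tach, n_epochs, epoch_len)):
        if i1 <= i0:
            continue
        seg = tach.jji[i0:i1]
        n_ok = int(np.count_nonzero(tach.quality[i0:i1] == QUALITY_OK))
        if n_ok < min_ok:
            continue
        ajji[e] = seg.mean()
        vjji[e] = seg.var()  # population variance
        missing[e] = False
    return ajji, vjji, missing


def band_powers(
    tach: Tachogram,
    n_epochs: int,
    epoch_len: float = EPOCH_LEN_S,
) -> dict[str, np.ndarray]:
    """Per-epoch HF/LF/TF band powers and the HF/TF, HF/LF ratios.

    Power is the squared one-sided DFT amplitude summed over band bins
    (bin centers at multiples of 1/epoch_len; LF takes
    0.04 <= f < 0.15 Hz, HF takes 0.15 <= f <= 0.4 Hz).  Epochs without
    full tachogram coverage, or with zero denominator, give NaN ratios.
    """
    spe = int(round(epoch_len * tach.fs))
    freqs = np.fft.rfftfreq(spe, d=1.0 / tach.fs)
    lf_bins = (freqs >= LF_BAND[0] - 1e-12) & (freqs < LF_BAND[1] - 1e-12)
    hf_bins = (freqs >= HF_BAND[0] - 1e-12) & (freqs <= HF_BAND[1] + 1e-12)
    out = {
        k: np.full(n_epochs, np.nan) for k in ("HF", "LF", "TF", "HF/TF", "HF/LF")
    }
    for e, (i0, i1) in enumerate(_epoch_slices(tach, n_epochs, epoch_len)):
        if i1 - i0 != spe:
            continue  # partial coverage: no spectral estimate for this epoch
        seg = tach.jji[i0:i1]
        x = seg - seg.mean()
        amps = np.abs(np.fft.rfft(x)) / spe
        amps[1:] *= 2.0
        if spe % 2 == 0:
            amps[-1] /= 2.0
        power = amps**2
        hf = float(power[hf_bins].sum())
        lf = float(power[lf_bins].sum())
        out["HF"][e], out["LF"][e], out["TF"][e] = hf, lf, hf + lf
        if hf + lf > 0:
            out["HF/TF"][e] = hf / (hf + lf)
        if lf > 0:
            out["HF/LF"][e] = hf / lf
    return out


def impute_missing(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Replace NaN entries by the median of the finite ones.

    Returns ``(imputed, was_missing)``.  An all-NaN input is filled with
    zeros (no information available at all).
    """
    values = np.asarray(values, dtype=float)
    missing = ~np.isfinite(values)
    out = values.copy()
    if missing.all():
        out[:] = 0.0
    elif missing.any():
        out[missing] = np.median(values[~missing])
    return out, missing
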