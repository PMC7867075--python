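"""Epoch-level gross-movement features: AGM, VGM and the full spectrum FS.

AGM/VGM are the mean and population variance of the fused movement
envelope inside each 30-s epoch.  FS is the total one-sided amplitude
spectrum of the mean-removed epoch, scaled by the bin width so it reads
as an amplitude density in (m/s^2)/Hz.
"""

from __future__ import annotations

import numpy as np

from .types import EPOCH_LEN_S, FusedSignal, ParameterError


def _epoch_matrix(sig: FusedSignal, epoch_len: float) -> np.ndarray:
    """Reshape to (n_epochs, samples_per_epoch), dropping a trailing partial epoch."""
    spe = int(round(epoch_len * sig.fs))
    if spe < 1:
        raise ParameterError("epoch shorter than one sample")
    n = len(sig.values) // spe
    return sig.values[: n * spe].reshape(n, spe)


def agm_vgm(
    sig: FusedSignal, epoch_len: float = EPOCH_LEN_S
) -> tuple[np.ndarray, np.ndarray]:
    """Per-epoch mean (AGM) and population variance (VGM) of the envelope."""
    m = _epoch_matrix(sig, epoch_len)
    return m.mean(axis=1), m.var(axis=1)  # ddof=0: population variance


def epoch_amplitude_spectrum(
    sig: FusedSignal, epoch_len: float = EPOCH_LEN_S
) -> tuple[np.ndarray, np.ndarray]:
    """One-sided amplitude spectrum of each mean-removed epoch.

    Returns ``(freqs, amps)`` where ``amps[e, k]`` is the amplitude of a
    real sinusoid at ``freqs[k]`` (DC bin excluded).  For interior bins the
    amplitude is ``2|X_k|/N``; the Nyquist bin (when N is even) is
    ``|X_k|/N``.  With this scaling a mean-removed epoch satisfies
    ``var(x) = sum(interior amps^2)/2 + amp_nyquist^2`` (Parseval).
    """
    m = _epoch_matrix(sig, epoch_len)
    n = m.shape[1]
    x = m - m.mean(axis=1, keepdims=True)
    spec = np.fft.rfft(x, axis=1)
    amps = np.abs(spec) / n
    amps[:, 1:] *= 2.0
    if n % 2 == 0:
        amps[:, -1] /= 2.0  # Nyquist bin is not doubled
    freqs = np.fft.rfftfreq(n, d=1.0 / sig.fs)
    return freqs[1:], amps[:, 1:]


def full_spectrum(
    sig: FusedSignal, epoch_len: float = EPOCH_LEN_S, mode: str = "density"
) -> np.ndarray:
    """Per-epoch total spectrum FS over all bins 0 < f <= Nyquist.

    ``mode="density"`` (default) divides the amplitude sum by the bin
    width 1/epoch_len so FS carries (m/s^2)/Hz; ``mode="sum"`` returns the
    plain amplitude sum in m/s^2.
    """
    _, amps = epoch_amplitude_spectrum(sig, epoch_len)
    total = amps.sum(axis=1)
    if mode == "density":
        return total * epoch_len  # / (1/epoch_len) bin width
    if mode == "sum":
        return total
    raise ParameterError(f"unknown FS mode {mode!r}")
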