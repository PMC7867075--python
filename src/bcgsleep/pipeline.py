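"""End-to-end feature extraction: raw recording -> per-epoch feature table.

Chains the two preprocessing branches, J-peak/tachogram extraction and
the epoch feature computations, and imputes JJI features for epochs where
beat detection failed (movement) with the recording median, flagged in
the ``jji_missing`` column.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from . import bcg_beats, hrv_features, movement_features, preprocess
from .config import PipelineConfig
from .types import BeatSeries, Recording, Tachogram, make_feature_table

log = logging.getLogger(__name__)


def extract_features(
    rec: Recording, cfg: PipelineConfig | None = None
) -> pd.DataFrame:
    """Compute the base per-epoch feature table of a recording.

    Columns: AGM, VGM, FS (gross-movement branch), AJJI, VJJI, HF/TF,
    HF/LF (ballistocardiogram branch) and the ``jji_missing`` flag.
    """
    table, _, _ = extract_features_debug(rec, cfg)
    return table


def extract_features_debug(
    rec: Recording, cfg: PipelineConfig | None = None
) -> tuple[pd.DataFrame, BeatSeries, Tachogram]:
    """As :func:`extract_features`, also returning beats and tachogram."""
    cfg = cfg or PipelineConfig()
    n_epochs = int(len(rec) // round(cfg.epoch_len_s * rec.fs))

    move = preprocess.movement_branch(rec, cfg.highpass_hz)
    agm, vgm = movement_features.agm_vgm(move, cfg.epoch_len_s)
    fs_feat = movement_features.full_spectrum(move, cfg.epoch_len_s, cfg.fs_mode)

    bcg = preprocess.bcg_branch(rec, cfg.band_hz, cfg.ma_window_s)
    beats, tach = bcg_beats.extract_tachogram(
        bcg,
        min_interval=cfg.min_peak_interval_s,
        fs_out=cfg.tachogram_fs,
        despike_window=cfg.despike_window_s,
        max_gap_s=cfg.max_gap_s,
    )
    ajji, vjji, _ = hrv_features.ajji_vjji(tach, n_epochs, cfg.epoch_len_s)
    bands = hrv_features.band_powers(tach, n_epochs, cfg.epoch_len_s)
    hftf, hflf = bands["HF/TF"], bands["HF/LF"]
    if cfg.hrv_spectrum == "amplitude":
        # amplitude-spectrum ratios: sqrt of per-bin power before summing is
        # not recoverable from the sums; recompute from sqrt of band powers
        hf, lf = np.sqrt(bands["HF"]), np.sqrt(bands["LF"])
        with np.errstate(invalid="ignore", divide="ignore"):
            hftf = np.where(hf + lf > 0, hf / (hf + lf), np.nan)
            hflf = np.where(lf > 0, hf / lf, np.nan)

    ajji_i, miss_a = hrv_features.impute_missing(ajji)
    vjji_i, miss_v = hrv_features.impute_missing(vjji)
    hftf_i, miss_r1 = hrv_features.impute_missing(hftf)
    hflf_i, miss_r2 = hrv_features.impute_missing(hflf)
    missing = miss_a | miss_v | miss_r1 | miss_r2
    if missing.any():
        log.info(
            "%s/%s: imputed JJI features in %d of %d epochs",
            rec.subject_id,
            rec.night_id,
            int(missing.sum()),
            n_epochs,
        )
    table = make_feature_table(
        rec.subject_id,
        rec.night_id,
        {
            "AGM": agm,
            "VGM": vgm,
            "FS": fs_feat,
            "AJJI": ajji_i,
            "VJJI": vjji_i,
            "HF/TF": hftf_i,
            "HF/LF": hflf_i,
            "jji_missing": missing,
        },
    )
    return table, beats, tach
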