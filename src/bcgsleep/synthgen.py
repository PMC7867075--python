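"""Synthetic overnight head-acceleration recordings with ground truth.

The generator emulates the statistical structure the staging method
relies on:

* a semi-Markov hypnogram with explicit bout dwells, deep sleep biased
  to the first half of the night and REM to the second half;
* stage-dependent RR dynamics: per-stage mean interval, respiratory
  (~0.25 Hz) and low-frequency (~0.1 Hz) sinusoidal modulation, and
  per-beat Gaussian jitter that is largest in REM;
* a ballistocardiogram rendered as a damped-sinusoid template (~7 Hz)
  placed at each beat on the dominant (vertical) axis, bounded by the
  ~0.98 m/s^2 head-BCG amplitude range;
* gross-movement bursts (band-limited noise much larger than the BCG)
  Poisson-placed with stage-dependent rates, densest in WAKE;
* respiration, sensor white noise, a fixed random mounting rotation and
  the gravity offset.

All randomness flows from a single seed; the same config and seed give a
bit-identical recording.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .types import EPOCH_LEN_S, Hypnogram, ParameterError, Recording

EPOCHS_PER_HOUR = int(3600 / EPOCH_LEN_S)

#: Head-BCG amplitude bound (m/s^2) motivated by the sensor operating range.
BCG_AMP_BOUND = 0.98


@dataclass
class SynthConfig:
    """Generator parameters; defaults define the study conditions."""

    seed: int = 0
    fs: float = 200.0
    duration_h: float = 8.0
    # hypnogram (dwells in 30-s epochs; geometric with the given mean)
    sleep_latency_epochs: float = 16.0  # ~8 min to first sleep
    dwell_epochs: dict = field(
        default_factory=lambda: {"WAKE": 6.0, "REM": 12.0, "LIGHT": 24.0, "DEEP": 18.0}
    )
    # exit weights from LIGHT: DEEP decays, REM grows across the night
    deep_weight: tuple[float, float] = (0.60, 0.05)  # w(u) = a*(1-u) + b
    rem_weight: tuple[float, float] = (0.10, 0.45)  # w(u) = a + b*u
    wake_weight: float = 0.27
    force_wake: bool = False  # all-WAKE transition weights (diagnostics)
    # RR-interval model (s); HF at 0.25 Hz, LF at 0.1 Hz
    rr_mean: dict = field(
        default_factory=lambda: {"WAKE": 0.95, "REM": 1.00, "LIGHT": 1.05, "DEEP": 1.12}
    )
    rr_hf_amp: dict = field(
        default_factory=lambda: {"WAKE": 0.010, "REM": 0.010, "LIGHT": 0.020, "DEEP": 0.030}
    )
    rr_lf_amp: dict = field(
        default_factory=lambda: {"WAKE": 0.040, "REM": 0.050, "LIGHT": 0.030, "DEEP": 0.015}
    )
    rr_jitter_sd: dict = field(
        default_factory=lambda: {"WAKE": 0.040, "REM": 0.050, "LIGHT": 0.015, "DEEP": 0.008}
    )
    hf_freq: float = 0.25
    lf_freq: float = 0.10
    rr_min: float = 0.4
    # BCG template: damped sinusoid
    bcg_center_hz: float = 7.0
    bcg_decay_s: float = 0.08
    bcg_amp: float = 0.15  # peak m/s^2, must stay <= BCG_AMP_BOUND
    # respiration and noise
    resp_amp: float = 0.02
    resp_freq: float = 0.25
    noise_sd: float = 0.01
    # gross-movement bursts
    movement_rate_per_min: dict = field(
        default_factory=lambda: {"WAKE": 4.0, "REM": 0.10, "LIGHT": 0.05, "DEEP": 0.01}
    )
    movement_amp: float = 1.0
    movement_duration_s: float = 2.0
    # sensor mounting: None -> random small rotation from the seed
    rotation_deg: float | None = None
    max_rotation_deg: float = 20.0
    gravity: float = 9.80665

    def __post_init__(self) -> None:
        if self.bcg_amp > BCG_AMP_BOUND:
            raise ParameterError(
                f"BCG amplitude {self.bcg_amp} exceeds the {BCG_AMP_BOUND} m/s^2 bound"
            )
        for d in (self.rr_mean, self.rr_hf_amp, self.rr_lf_amp, self.rr_jitter_sd,
                  self.dwell_epochs, self.movement_rate_per_min):
            if any(v < 0 for v in d.values()):
                raise ParameterError("rates and amplitudes must be nonnegative")


@dataclass
class GroundTruth:
    """What the generator knows: stages, true beats, movement bursts."""

    hypnogram: Hypnogram
    beat_times: np.ndarray
    bursts: list[tuple[float, float]]  # (start, end) in s


def _geometric_dwell(rng: np.random.Generator, mean_epochs: float) -> int:
    if mean_epochs <= 1:
        return 1
    return int(rng.geometric(1.0 / mean_epochs))


def sample_hypnogram(cfg: SynthConfig, rng: np.random.Generator | None = None) -> Hypnogram:
    """Semi-Markov stage sequence with a night-time DEEP->REM drift.

    The night starts WAKE and enters LIGHT after a geometric sleep
    latency.  LIGHT exits to DEEP, REM or WAKE with weights evaluated at
    the elapsed-night fraction u: the DEEP weight decreases with u and
    the REM weight increases, so deep sleep concentrates early and REM
    late.  DEEP/REM/WAKE bouts return to LIGHT.
    """
    if cfg.duration_h < 1:
        raise ParameterError("need at least 1 h")
    rng = rng or np.random.default_rng(cfg.seed)
    n = int(round(cfg.duration_h * EPOCHS_PER_HOUR))
    stages: list[str] = []
    if cfg.force_wake:
        return Hypnogram(stages=["WAKE"] * n)
    latency = min(_geometric_dwell(rng, cfg.sleep_latency_epochs), n)
    stages.extend(["WAKE"] * latency)
    current = "LIGHT"
    while len(stages) < n:
        dwell = _geometric_dwell(rng, cfg.dwell_epochs[current])
        stages.extend([current] * dwell)
        if current == "LIGHT":
            u = min(len(stages) / n, 1.0)
            w = np.array([
                cfg.deep_weight[0] * (1.0 - u) + cfg.deep_weight[1],
                cfg.rem_weight[0] + cfg.rem_weight[1] * u,
                cfg.wake_weight,
            ])
            current = ["DEEP", "REM", "WAKE"][rng.choice(3, p=w / w.sum())]
        else:
            current = "LIGHT"
    return Hypnogram(stages=stages[:n])


def sample_beats(
    hyp: Hypnogram, cfg: SynthConfig, rng: np.random.Generator | None = None
) -> np.ndarray:
    """True beat times by integrating the stage-dependent RR process.

    RR(t) = mean(stage) + HF*sin(2*pi*0.25*t) + LF*sin(2*pi*0.1*t + phi)
    + jitter(stage), clipped at ``rr_min``.
    """
    if len(hyp) == 0:
        raise ParameterError("empty hypnogram")
    rng = rng or np.random.default_rng(cfg.seed)
    duration = len(hyp) * hyp.epoch_len
    phi = rng.uniform(0, 2 * np.pi)
    times = []
    t = float(rng.uniform(0.0, 0.5))  # first beat shortly after start
    n_ep = len(hyp)
    while t < duration:
        stage = hyp.stages[min(int(t // hyp.epoch_len), n_ep - 1)]
        rr = (
            cfg.rr_mean[stage]
            + cfg.rr_hf_amp[stage] * np.sin(2 * np.pi * cfg.hf_freq * t)
            + cfg.rr_lf_amp[stage] * np.sin(2 * np.pi * cfg.lf_freq * t + phi)
            + cfg.rr_jitter_sd[stage] * rng.standard_normal()
        )
        rr = max(rr, cfg.rr_min)
        times.append(t)
        t += rr
    return np.asarray(times)


def _bcg_template(cfg: SynthConfig) -> np.ndarray:
    """Damped sinusoid normalised to the configured peak amplitude."""
    length = int(round(6 * cfg.bcg_decay_s * cfg.fs))
    t = np.arange(length) / cfg.fs
    tpl = np.exp(-t / cfg.bcg_decay_s) * np.sin(2 * np.pi * cfg.bcg_center_hz * t)
    peak = np.max(np.abs(tpl))
    return tpl * (cfg.bcg_amp / peak)


def _rotation_matrix(cfg: SynthConfig, rng: np.random.Generator) -> np.ndarray:
    """Mounting rotation: given tilt angle about a random axis, or random tilt."""
    if cfg.rotation_deg is not None:
        angle = np.deg2rad(cfg.rotation_deg)
        axis = np.array([1.0, 0.0, 0.0])
        _ = rng.normal(size=3)  # keep the stream layout stable across configs
    else:
        angle = np.deg2rad(rng.uniform(0, cfg.max_rotation_deg))
        axis = rng.normal(size=3)
        axis /= np.linalg.norm(axis)
    ux, uy, uz = axis
    c, s = np.cos(angle), np.sin(angle)
    K = np.array([[0, -uz, uy], [uz, 0, -ux], [-uy, ux, 0]])
    return np.eye(3) + s * K + (1 - c) * (K @ K)


def render_recording(
    hyp: Hypnogram,
    beats: np.ndarray,
    cfg: SynthConfig,
    rng: np.random.Generator | None = None,
    subject_id: str = "synthetic",
    night_id: str = "n1",
) -> tuple[Recording, GroundTruth]:
    """Render the 3-axis acceleration of a night at 200 Hz."""
    rng = rng or np.random.default_rng(cfg.seed)
    fs = cfg.fs
    n = int(round(len(hyp) * hyp.epoch_len * fs))
    axes = np.zeros((3, n))

    # ballistocardiogram on the vertical axis
    tpl = _bcg_template(cfg)
    for tb in beats:
        i = int(round(tb * fs))
        j = min(i + len(tpl), n)
        if i < n:
            axes[2, i:j] += tpl[: j - i]

    # respiration (survives the 0.1-Hz high-pass, removed by the 1-10-Hz band)
    t = np.arange(n) / fs
    axes[2] += cfg.resp_amp * np.sin(2 * np.pi * cfg.resp_freq * t + rng.uniform(0, 2 * np.pi))

    # gross-movement bursts, Poisson per epoch with stage-dependent rates
    bursts: list[tuple[float, float]] = []
    dur = cfg.movement_duration_s
    blen = int(round(dur * fs))
    window = np.hanning(blen)
    for e, stage in enumerate(hyp.stages):
        rate = cfg.movement_rate_per_min[stage] * (hyp.epoch_len / 60.0)
        for _ in range(rng.poisson(rate)):
            start = e * hyp.epoch_len + rng.uniform(0, hyp.epoch_len - dur)
            i = int(round(start * fs))
            j = min(i + blen, n)
            for ax in range(3):
                raw = rng.standard_normal(blen)
                smooth = np.convolve(raw, np.ones(5) / 5, mode="same")
                axes[ax, i:j] += cfg.movement_amp * (window * smooth)[: j - i]
            bursts.append((start, start + dur))

    # sensor noise
    if cfg.noise_sd > 0:
        for ax in range(3):
            axes[ax] += cfg.noise_sd * rng.standard_normal(n)

    # mounting rotation, then gravity along the sensor's rotated vertical
    R = _rotation_matrix(cfg, rng)
    axes += np.array([0.0, 0.0, cfg.gravity])[:, None]
    axes = R @ axes

    rec = Recording(
        subject_id=subject_id, night_id=night_id, fs=fs,
        ax=axes[0], ay=axes[1], az=axes[2],
    )
    truth = GroundTruth(hypnogram=hyp, beat_times=np.asarray(beats), bursts=bursts)
    return rec, truth


def generate_recording(
    cfg: SynthConfig,
    subject_id: str = "synthetic",
    night_id: str = "n1",
) -> tuple[Recording, GroundTruth]:
    """One seeded night: hypnogram, beats and rendered acceleration."""
    rng = np.random.default_rng(cfg.seed)
    hyp = sample_hypnogram(cfg, rng)
    beats = sample_beats(hyp, cfg, rng)
    return render_recording(hyp, beats, cfg, rng, subject_id, night_id)


def generate_feature_dataset(
    n_subjects: int,
    n_nights: int = 2,
    cfg: SynthConfig | None = None,
    seed: int = 0,
    pipeline_cfg=None,
):
    """Generate a multi-subject dataset and extract features night by night.

    Raw recordings are discarded after feature extraction to keep memory
    bounded.  Returns ``(tables, truths, ground_truths)`` where ``truths``
    are the hypnograms aligned to each feature table.
    """
    from .pipeline import extract_features  # local import to avoid a cycle

    base = cfg or SynthConfig()
    ss = np.random.SeedSequence(seed)
    seeds = ss.generate_state(n_subjects * n_nights)
    tables, truths, gts = [], [], []
    k = 0
    for s in range(n_subjects):
        for night in range(n_nights):
            # keep derived seeds below 2**31 for portability
            ncfg = replace(base, seed=int(seeds[k]) % (2**31))
            k += 1
            rec, gt = generate_recording(
                ncfg, subject_id=f"S{s + 1:02d}", night_id=f"night{night + 2}"
            )
            table = extract_features(rec, pipeline_cfg)
            n_ep = len(table)
            tables.append(table)
            truths.append(Hypnogram(stages=gt.hypnogram.stages[:n_ep]))
            gts.append(gt)
            del rec
    return tables, truths, gts
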