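# Methods

`bcgsleep` estimates four sleep states — WAKE, REM, LIGHT (N1+N2), DEEP
(N3) — from a single head-mounted 3-axis accelerometer sampled at 200 Hz.
Two kinds of information are read off the same sensor: gross head
movement (turning over, fidgeting, concentrated around WAKE) and the
ballistocardiogram (BCG), the millimetre-scale recoil of the head at each
heartbeat, whose J wave serves as a per-beat fiducial analogous to the
ECG R wave. This note records the model, the numerical choices, the
synthetic-data design and the known limitations.

## Signal chains

All scoring is in fixed, non-overlapping 30-s epochs, 0-based and
half-open `[30k, 30(k+1))` from the start of the recording; a trailing
partial epoch is dropped. When a recording and its scored hypnogram
disagree in length, both are truncated to the shorter with a logged
warning.

**Movement branch.** Each axis is high-passed at 0.1 Hz to remove
gravity and drift, then the three axes are fused to one by the per-sample
RMS `sqrt((ax²+ay²+az²)/3)`. The RMS is invariant under any orthonormal
rotation of the sensor frame, which removes mounting orientation and
posture from the analysis (a tested property). Per epoch:

* **AGM** — mean of the fused envelope (m/s²);
* **VGM** — population variance (divisor N) of the envelope ((m/s²)²);
* **FS** — "full spectrum": the one-sided amplitude spectrum of the
  mean-removed 6000-sample epoch, summed over all bins 0 < f ≤ Nyquist
  and divided by the bin width (1/30 Hz), read as an amplitude density in
  (m/s²)/Hz. Mean removal keeps FS from duplicating AGM; no window taper
  is applied (rectangular), and a plain amplitude-sum variant is
  config-switchable (`fs_mode`).

**BCG branch.** Axes are band-passed 1–10 Hz (removes DC, drift and
respiration at ~0.25 Hz), RMS-fused, and smoothed with a centered
0.325-s moving average (65 samples at 200 Hz; kernel length forced odd so
peak positions are unbiased; edges use shrinking windows). Filters are
4th-order Butterworth applied forward–backward (zero phase), so feature
timing is not shifted against the epoch grid; the filter family and order
are config-visible choices, since only the cutoffs are prescribed by the
method.

**J-peak detection.** Local maxima of the smoothed envelope with
(a) a minimum separation of 0.365 s (cardiac refractory period plus
envelope width; the taller peak wins a conflict) and (b) prominence of at
least 20% of the envelope's dynamic range (90th percentile minus median).
The prominence floor is needed because a pure minimum-separation rule
admits every noise ripple between beats. A correction pass then removes
residual over-detections: any inter-peak interval more than 50% *below*
its running 5-interval median deletes the weaker of its two bounding
peaks, and intervals are re-derived until stable. The rule is
deliberately one-sided — deleting a peak cannot shorten a too-*long*
interval, so detection gaps under movement are left alone and surface
downstream as quality flags.

**Tachogram.** J-J intervals (JJI) are timestamped at the later beat
(causal convention), interpolated with a natural cubic spline, and
evaluated on the uniform 2-Hz grid of multiples of 0.5 s inside the
support (no extrapolation); the grid therefore aligns exactly with epoch
boundaries. Samples bridging a support gap wider than `max_gap_s`
(default 2 s — the signature of a movement-induced detection dropout) are
flagged `interpolated-over-movement`. Fewer than 4 support points yield a
flagged constant fill at the mean interval. A 7-s running median (15
samples, shrinking edges) despikes the result. The ~0.1–0.3-s lag of the
BCG J wave behind the cardiac ejection is not corrected: it is constant
on the scale of a night and cancels in interval differences.

Per epoch (60 tachogram samples):

* **AJJI / VJJI** — mean and population variance of the tachogram.
  Epochs with fewer than 30 ok-flagged samples are marked missing and
  imputed with the recording median (flagged in `jji_missing`). AJJI
  doubles as a proxy for very-low-frequency heart-rate information, which
  cannot be estimated spectrally at 2 Hz and 30-s windows.
* **HF, LF, TF and the ratios HF/TF, HF/LF** — band powers from a
  60-point DFT of the mean-removed epoch (squared one-sided amplitudes).
  Bin centers lie at multiples of 1/30 Hz; LF takes 0.04 ≤ f < 0.15 Hz,
  HF takes 0.15 ≤ f ≤ 0.4 Hz, and TF is their union, so **TF = HF + LF
  holds exactly** by bin partition (tested to 1e-12). Power rather than
  amplitude spectra are used (conventional HRV practice;
  config-switchable).

## Two-step classifier

Step 1 labels every epoch WAKE vs SLEEP from (AGM, VGM, FS, AJJI, VJJI)
with a random forest. Step 2 assigns REM/LIGHT/DEEP within SLEEP from
nine features: the seven continuous features (the five above plus HF/TF,
HF/LF) z-scored per recording using mean and population SD computed over
*SLEEP* epochs only (so the normalisation does not depend on how much
WAKE a night contains; WAKE values are far larger and would dominate),
plus two features derived from the step-1 output:

* **SET** (sleep elapsed time): `0.5·(k − k_onset)` minutes after the
  first SLEEP epoch, 0 before — deep sleep concentrates early in the
  night and REM late, so elapsed time is informative;
* **HRT** (head rest time): `0.5·(k − k_move)` minutes since the most
  recent epoch that was either scored WAKE or exceeded the per-recording
  movement threshold θ = median + 3·MAD of SLEEP-epoch AGM (raw median
  absolute deviation, no consistency scaling); 0 when none precedes.
  Body movement subsides roughly ten minutes before deep sleep, which is
  the signal this feature encodes. HRT is the one feature whose published
  definition is ambiguous; the movement-reset reading implemented here is
  a deliberate design choice.

At training time the WAKE/SLEEP conditioning for standardisation, SET
and HRT comes from the reference hypnogram (the only conditioning
available); at inference it comes from the step-1 predictions. A feature
constant across SLEEP rows (SD = 0) is set to 0 with a warning; fewer
than 2 SLEEP epochs is an error.

Merged output: WAKE exactly where step 1 said WAKE; REM/LIGHT/DEEP from
step 2 elsewhere. Per-class probabilities follow the chain rule
P(WAKE) = p₁ and P(stage) = (1 − p₁)·P(stage | SLEEP); the step-2 forest
is evaluated on every epoch so that scores (needed for ROC) are defined
on WAKE-called epochs too, while labels honour the two-step gate.

**Hyperparameters.** Split criterion {gini, entropy}, tree depth 1–10
and tree count 1–10 (200 candidates per step) are chosen by grid search
maximising the macro F-score of predictions pooled across
leave-one-subject-out folds; all other forest settings are scikit-learn
defaults, recorded in the model bundle together with the seed. Ties go to
the smaller depth, then fewer trees, then gini (simplest-model
preference, deterministic). By default the search runs *inside each
training pool* (nested, leak-free); a `paper_faithful` switch instead
selects once on all subjects, reproducing the common but leaky variant of
the procedure. Same seed and inputs give bit-identical predictions.

## Evaluation

Folds are subjects: every night of the held-out subject is the test set.
Reported per fold: per-class precision/recall/F (F = 2PR/(P+R)) and
accuracy; pooled: a 4×4 confusion matrix oriented rows = estimated,
columns = correct. ROC is one-vs-rest per class from the merged scores,
vertically averaged over folds on a fixed 101-point FPR grid; AUC is the
fold-average. Values are kept at full precision internally and rounded
to one decimal only for display.

Feature tests: step-1 features use a Wilcoxon signed-rank test on 20
randomly drawn epochs per class (WAKE vs SLEEP); step-2 features use a
Friedman test across REM/LIGHT/DEEP followed, on rejection at 5%, by
pairwise Wilcoxon tests with Bonferroni ×3. Sampling is seeded;
comparisons with too few epochs are skipped with a notice.

`summary_stats` implements the reporting conventions of the study tables:
arithmetic mean, population SD (divisor n — the printed SDs reproduce
only with this convention), and pooled stage percentages
100·Σstage/Σall per night.

## Synthetic-night generator

No public recordings exist for this sensor placement, so the package
carries a seeded generator that embodies the statistical structure the
method assumes. Defaults are calibrated once, from published magnitudes
and general sleep physiology, and define the study conditions for all
tests:

* **Hypnogram** — semi-Markov bouts (geometric dwells; means: WAKE 6,
  LIGHT 24, DEEP 18, REM 12 epochs; initial sleep latency ~8 min). LIGHT
  exits to DEEP/REM/WAKE with weights evaluated at the elapsed-night
  fraction u: DEEP weight 0.60·(1−u)+0.05, REM weight 0.10+0.45·u, WAKE
  0.27. Long-run proportions ≈ 6/11/65/17% (WAKE/REM/LIGHT/DEEP) with a
  LIGHT plurality and the first-half-DEEP / second-half-REM drift,
  matching scored-night reference rates.
* **RR process** — per-stage mean interval (WAKE 0.95, REM 1.00, LIGHT
  1.05, DEEP 1.12 s), sinusoidal HF (0.25 Hz) and LF (0.10 Hz)
  modulation whose amplitudes shift toward HF with depth, and per-beat
  Gaussian jitter largest in REM (0.05 s) — giving the VJJI-high-in-REM
  and HF-ratio-high-in-DEEP signatures. Intervals are clipped at 0.4 s.
* **BCG** — a damped sinusoid (7 Hz center, 80 ms decay) at each beat on
  the vertical axis, peak 0.15 m/s². The amplitude must stay under the
  0.98 m/s² head-BCG bound; 0.15 m/s² sits in the mid range of head-BCG
  amplitudes and gives an in-band SNR comfortably above the ≥6 dB regime
  the detection gates assume.
* **Artifacts** — respiration sinusoid (0.02 m/s² at 0.25 Hz), white
  sensor noise (SD 0.01 m/s²), and gross-movement bursts: 2-s
  Hann-windowed smoothed-noise bursts of 1.0 m/s² on all axes,
  Poisson-placed per epoch at stage-dependent rates (WAKE 4/min, REM
  0.1, LIGHT 0.05, DEEP 0.01/min). A random mounting rotation (up to
  20°) and gravity on the rotated vertical complete the render.

What the generator does *not* emulate: real I-J-K BCG morphology and its
beat-to-beat amplitude variability, posture changes that re-orient the
sensor mid-night, apnea events, non-stationary noise, and scorer
disagreement in the reference hypnograms. Synthetic benchmark results
therefore demonstrate that the pipeline recovers the structure it is
built for — they say nothing quantitative about accuracy on human
recordings, and published human-data figures are not comparable targets.
On the synthetic benchmark the stage structure is much cleaner than in
human data, and the classifier scores accordingly higher.

## Problem sizes and determinism

The shipped benchmark uses 5 subjects × 2 nights × 8 h (9600 epochs,
~276 000 beats) with the full 2×10×10 grid searched nested per fold;
smaller cohorts and shorter nights appear in unit tests and examples.
All randomness flows from explicit seeds (generator configs, forest
`random_state`, sampling in the significance tests); repeated runs are
bit-identical, and derived seeds are kept below 2³¹.

## Known limitations

* Beat detection degrades inside gross-movement bursts by design; the
  pipeline copes through despiking, quality flags and median imputation
  rather than recovering those beats.
* The spectral HRV ratios are computed from 30-s windows at 2 Hz — a
  resolution of 1/30 Hz — so the LF band holds only three bins; the
  ratios are correspondingly coarse.
* With very little detected sleep on a night (fewer than 2
  predicted-SLEEP epochs) step 2 cannot standardise; the prediction
  falls back to step-1 labels with prior-weighted sleep scores.
* The two-step design propagates step-1 errors into step-2 features
  (SET, HRT and the standardisation all condition on the WAKE/SLEEP
  call); this mirrors the method and is not mitigated.
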