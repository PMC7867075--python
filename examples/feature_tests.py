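"""Stage-difference significance tests for the epoch features.

Step-1 features are compared WAKE vs SLEEP with a Wilcoxon signed-rank
test on randomly drawn epochs; step-2 features are compared across
REM/LIGHT/DEEP with a Friedman test followed by Bonferroni-corrected
pairwise Wilcoxon tests.
"""

from bcgsleep import SynthConfig, feature_significance, generate_feature_dataset

tables, truths, _ = generate_feature_dataset(
    3, 1, SynthConfig(duration_h=6.0), seed=9
)
report = feature_significance(tables, truths, n_per_stage=20, seed=9)
with_p = report.dropna(subset=["p"]).copy()
with_p["p"] = with_p["p"].map(lambda v: f"{v:.2e}")
print(with_p.to_string(index=False))

# Movement features (AGM/VGM/FS) separate WAKE from SLEEP sharply; among
# sleep stages the JJI-derived features and SET/HRT carry the signal,
# mirroring why the classifier needs both branches.
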