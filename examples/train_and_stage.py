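"""Train the two-step stager and stage an unseen subject's night.

Step 1 calls each epoch WAKE or SLEEP; step 2 assigns REM/LIGHT/DEEP
within SLEEP using features standardised over the predicted-SLEEP epochs
plus the elapsed-sleep-time (SET) and head-rest-time (HRT) features.
"""

import numpy as np

from bcgsleep import HyperGrid, SynthConfig, fit, generate_feature_dataset, predict

# 4 training subjects + 1 held-out, one 4-h night each (small for speed)
tables, truths, _ = generate_feature_dataset(
    5, 1, SynthConfig(duration_h=4.0), seed=3
)
train_t, train_h = tables[:4], truths[:4]
test_t, test_h = tables[4], truths[4]

grid = HyperGrid(criteria=("gini",), depths=(3, 5, 7), n_trees=(5, 10))
model = fit(train_t, train_h, grid=grid, seed=0)
print(f"chosen hyperparameters: step1 {model.hyper1}, step2 {model.hyper2}")

labels, scores = predict(model, test_t)
truth = test_h.as_array()
print(f"held-out accuracy: {np.mean(labels == truth):.3f}")
print("first 20 epochs (predicted / true):")
for k in range(20):
    mark = "" if labels[k] == truth[k] else "  <-- miss"
    print(f"  epoch {k:3d}  {labels[k]:<6} / {truth[k]:<6}{mark}")

# The per-class scores are probabilities: P(WAKE) from step 1 and
# (1 - P(WAKE)) * P(stage | SLEEP) from step 2; rows sum to 1.
print("\nscore row sums:", np.unique(scores.sum(axis=1).round(9)))
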