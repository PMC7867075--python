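"""Two-step sleep staging with random forests.

Step 1 separates WAKE from SLEEP on the raw epoch features (AGM, VGM,
FS, AJJI, VJJI).  Step 2 assigns REM/LIGHT/DEEP within SLEEP using
features standardised over the SLEEP epochs of each recording (so the
standardisation does not depend on how much WAKE a night contains) plus
two features derived from the step-1 output: sleep elapsed time (SET)
and head rest time (HRT).

Hyperparameters (split criterion, tree depth 1-10, number of trees 1-10)
are chosen by grid search maximising the macro F-score under
leave-one-subject-out cross-validation.  By default the search runs
inside each training pool (nested, leak-free); ``paper_faithful`` callers
may select once on the full dataset instead.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from pathlib import Path

import joblib
import numpy as np
import pandas as pd
import yaml
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import f1_score

from .types import (
    EPOCH_LEN_S,
    FIRST_STEP_FEATURES,
    BASE_FEATURES,
    SECOND_STEP_FEATURES,
    SLEEP_STAGES,
    Hypnogram,
    ParameterError,
)

log = logging.getLogger(__name__)

EPOCH_MIN = EPOCH_LEN_S / 60.0  # epoch length in minutes


class StandardizationError(ValueError):
    """Too few SLEEP epochs to compute standardisation statistics."""


class ManifestError(KeyError):
    """Feature table does not match the trained model's feature manifest."""


@dataclass(frozen=True)
class HyperGrid:
    """Random-forest hyperparameter search space."""

    criteria: tuple[str, ...] = ("gini", "entropy")
    depths: tuple[int, ...] = tuple(range(1, 11))
    n_trees: tuple[int, ...] = tuple(range(1, 11))

    def combos(self) -> list[tuple[str, int, int]]:
        """Candidate (criterion, depth, n_trees) triples.

        Ordered so that earlier combos win F-score ties: smaller depth,
        then fewer trees, then gini before entropy.
        """
        order = sorted(
            itertools.product(self.criteria, self.depths, self.n_trees),
            key=lambda c: (c[1], c[2], c[0] != "gini"),
        )
        return order

    @classmethod
    def from_ranges(
        cls,
        criteria: tuple[str, ...] = ("gini", "entropy"),
        depth: tuple[int, int] = (1, 10),
        trees: tuple[int, int] = (1, 10),
    ) -> "HyperGrid":
        return cls(
            criteria=tuple(criteria),
            depths=tuple(range(depth[0], depth[1] + 1)),
            n_trees=tuple(range(trees[0], trees[1] + 1)),
        )


def standardize_sleep(
    table: pd.DataFrame,
    sleep_mask: np.ndarray,
    features: tuple[str, ...] = BASE_FEATURES,
) -> pd.DataFrame:
    """Z-score features per recording using SLEEP-epoch statistics.

    Mean and population SD are computed over SLEEP rows only; the z-score
    is applied to every row (callers subset as needed).  Output columns
    carry an S prefix.  A feature constant across SLEEP rows (SD = 0) is
    set to 0 with a warning.
    """
    sleep_mask = np.asarray(sleep_mask, dtype=bool)
    if sleep_mask.sum() < 2:
        raise StandardizationError(
            f"need >= 2 SLEEP epochs to standardise, got {int(sleep_mask.sum())}"
        )
    out = {}
    for name in features:
        if name not in table.columns:
            raise ManifestError(f"missing feature column {name!r}")
        vals = table[name].to_numpy(dtype=float)
        ref = vals[sleep_mask]
        mu, sd = float(ref.mean()), float(ref.std())  # population SD
        if sd == 0.0:
            log.warning("feature %s constant over SLEEP epochs; z-score set to 0", name)
            out["S" + name] = np.zeros(len(vals))
        else:
            out["S" + name] = (vals - mu) / sd
    return pd.DataFrame(out, index=table.index)


def sleep_elapsed_time(sleep_mask: np.ndarray) -> np.ndarray:
    """Minutes since the first SLEEP epoch; 0 before sleep onset.

    SET(k) = 0.5 * (k - k_onset) for k >= k_onset; all zeros (with a
    warning) when no epoch is scored SLEEP.
    """
    sleep_mask = np.asarray(sleep_mask, dtype=bool)
    k = np.arange(len(sleep_mask))
    onset_candidates = np.flatnonzero(sleep_mask)
    if len(onset_candidates) == 0:
        log.warning("no SLEEP epoch: SET is all zeros")
        return np.zeros(len(sleep_mask))
    onset = onset_candidates[0]
    return np.where(k >= onset, (k - onset) * EPOCH_MIN, 0.0)


def movement_threshold(agm: np.ndarray, sleep_mask: np.ndarray) -> float:
    """Per-recording gross-movement threshold: median + 3*MAD of SLEEP AGM.

    MAD is the raw median absolute deviation (no consistency scaling).
    """
    ref = np.asarray(agm, dtype=float)[np.asarray(sleep_mask, dtype=bool)]
    if len(ref) == 0:
        ref = np.asarray(agm, dtype=float)
    med = float(np.median(ref))
    mad = float(np.median(np.abs(ref - med)))
    return med + 3.0 * mad


def head_rest_time(
    agm: np.ndarray,
    sleep_mask: np.ndarray,
    theta: float | None = None,
) -> np.ndarray:
    """Minutes since the head last moved.

    HRT(k) = 0.5 * (k - k_move), where k_move is the most recent epoch at
    or before k that either exceeded the movement threshold (AGM > theta)
    or was scored WAKE; 0 when no such epoch precedes k.
    """
    agm = np.asarray(agm, dtype=float)
    sleep_mask = np.asarray(sleep_mask, dtype=bool)
    if theta is None:
        theta = movement_threshold(agm, sleep_mask)
    event = (agm > theta) | ~sleep_mask
    hrt = np.empty(len(agm))
    k_move = -1
    for k in range(len(agm)):
        if event[k]:
            k_move = k
        hrt[k] = (k - k_move) * EPOCH_MIN if k_move >= 0 else 0.0
    return hrt


def build_step2_features(
    table: pd.DataFrame, sleep_mask: np.ndarray
) -> pd.DataFrame:
    """Step-2 feature block for one recording, conditioned on a WAKE/SLEEP call.

    ``sleep_mask`` is the step-1 output (truth labels at training time,
    predictions at inference).  Standardised columns are valid for every
    row; SET/HRT derive from the mask.
    """
    std = standardize_sleep(table, sleep_mask)
    std["SET"] = sleep_elapsed_time(sleep_mask)
    std["HRT"] = head_rest_time(table["AGM"].to_numpy(), sleep_mask)
    return std[list(SECOND_STEP_FEATURES)]


@dataclass
class TrainedStager:
    """Fitted two-step model plus everything needed to reproduce it."""

    step1: RandomForestClassifier
    step2: RandomForestClassifier
    hyper1: dict
    hyper2: dict
    seed: int
    step1_features: tuple[str, ...] = FIRST_STEP_FEATURES
    step2_features: tuple[str, ...] = SECOND_STEP_FEATURES
    sleep_priors: dict[str, float] = field(default_factory=dict)
    search_log1: list = field(default_factory=list, repr=False)
    search_log2: list = field(default_factory=list, repr=False)

    def save(self, path: str | Path) -> None:
        """Serialise to a bundle directory (YAML metadata + forests)."""
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        meta = {
            "hyper1": self.hyper1,
            "hyper2": self.hyper2,
            "seed": self.seed,
            "step1_features": list(self.step1_features),
            "step2_features": list(self.step2_features),
            "sleep_priors": self.sleep_priors,
            "forest_defaults": "scikit-learn RandomForestClassifier defaults "
            "except criterion/max_depth/n_estimators/random_state",
        }
        (path / "meta.yaml").write_text(yaml.safe_dump(meta, sort_keys=False))
        joblib.dump(self.step1, path / "step1.joblib")
        joblib.dump(self.step2, path / "step2.joblib")

    @classmethod
    def load(cls, path: str | Path) -> "TrainedStager":
        path = Path(path)
        meta = yaml.safe_load((path / "meta.yaml").read_text())
        return cls(
            step1=joblib.load(path / "step1.joblib"),
            step2=joblib.load(path / "step2.joblib"),
            hyper1=meta["hyper1"],
            hyper2=meta["hyper2"],
            seed=meta["seed"],
            step1_features=tuple(meta["step1_features"]),
            step2_features=tuple(meta["step2_features"]),
            sleep_priors=meta.get("sleep_priors", {}),
        )


def _forest(criterion: str, depth: int, trees: int, seed: int) -> RandomForestClassifier:
    return RandomForestClassifier(
        criterion=criterion,
        max_depth=depth,
        n_estimators=trees,
        random_state=seed,
    )


def grid_search(
    X: np.ndarray,
    y: np.ndarray,
    groups: np.ndarray,
    grid: HyperGrid,
    seed: int,
) -> tuple[dict, list]:
    """Leave-one-subject-out grid search maximising pooled macro F-score.

    Returns the winning hyperparameters and the full search log
    (one entry per candidate).  Ties go to the earlier candidate in
    :meth:`HyperGrid.combos` order (smaller depth, fewer trees, gini).
    """
    uniq = np.unique(groups)
    if len(uniq) < 2:
        raise ParameterError("grid search needs >= 2 subjects")
    folds = [(groups != g, groups == g) for g in uniq]
    classes = np.unique(y)
    best, best_score, search_log = None, -np.inf, []
    for criterion, depth, trees in grid.combos():
        pred = np.empty(len(y), dtype=object)
        for train_mask, test_mask in folds:
            clf = _forest(criterion, depth, trees, seed)
            clf.fit(X[train_mask], y[train_mask])
            pred[test_mask] = clf.predict(X[test_mask])
        score = f1_score(y, pred.astype(str), labels=classes, average="macro")
        search_log.append(
            {"criterion": criterion, "depth": depth, "trees": trees, "macro_f": score}
        )
        if score > best_score:
            best_score = score
            best = {"criterion": criterion, "max_depth": depth, "n_trees": trees}
    return best, search_log


def _pool(
    tables: list[pd.DataFrame], truths: list[Hypnogram]
) -> tuple[pd.DataFrame, np.ndarray, np.ndarray]:
    """Concatenate recordings; returns (table, stage labels, subject groups)."""
    if len(tables) != len(truths):
        raise ParameterError("one hypnogram per feature table required")
    parts, labels, groups = [], [], []
    for table, truth in zip(tables, truths):
        n = min(len(table), len(truth))
        parts.append(table.iloc[:n])
        labels.append(truth.as_array()[:n])
        groups.append(table["subject_id"].to_numpy()[:n])
    return (
        pd.concat(parts, ignore_index=True),
        np.concatenate(labels),
        np.concatenate(groups),
    )


def fit(
    tables: list[pd.DataFrame],
    truths: list[Hypnogram],
    grid: HyperGrid | None = None,
    seed: int = 0,
    hyper1: dict | None = None,
    hyper2: dict | None = None,
) -> TrainedStager:
    """Train the two-step stager on a pool of recordings.

    Hyperparameters for each step come from a leave-one-subject-out grid
    search on the pool (or are supplied directly via ``hyper1``/
    ``hyper2``, e.g. by a paper-faithful outer procedure).  Step 2 is
    trained on truth-SLEEP epochs with per-recording standardisation over
    truth-SLEEP rows and SET/HRT derived from the truth WAKE/SLEEP mask.
    """
    grid = grid or HyperGrid()
    pooled, stages, groups = _pool(tables, truths)
    y1 = np.where(stages == "WAKE", "WAKE", "SLEEP")
    if len(np.unique(y1)) < 2:
        raise ParameterError("training pool contains a single WAKE/SLEEP class")
    X1 = pooled[list(FIRST_STEP_FEATURES)].to_numpy(dtype=float)

    # step-2 design: per-recording conditioning on the truth mask
    x2_parts, y2_parts, g2_parts = [], [], []
    for table, truth in zip(tables, truths):
        n = min(len(table), len(truth))
        sub = table.iloc[:n].reset_index(drop=True)
        mask = truth.sleep_mask()[:n]
        feats = build_step2_features(sub, mask)
        x2_parts.append(feats.loc[mask])
        y2_parts.append(truth.as_array()[:n][mask])
        g2_parts.append(sub["subject_id"].to_numpy()[mask])
    X2 = pd.concat(x2_parts, ignore_index=True).to_numpy(dtype=float)
    y2 = np.concatenate(y2_parts)
    g2 = np.concatenate(g2_parts)
    if len(np.unique(y2)) < 2:
        raise ParameterError("training pool contains a single sleep stage")

    log1, log2 = [], []
    combos = grid.combos()
    if len(combos) == 1:
        # degenerate grid: nothing to search
        only = {"criterion": combos[0][0], "max_depth": combos[0][1],
                "n_trees": combos[0][2]}
        hyper1 = hyper1 or dict(only)
        hyper2 = hyper2 or dict(only)
    if hyper1 is None:
        hyper1, log1 = grid_search(X1, y1, groups, grid, seed)
    if hyper2 is None:
        hyper2, log2 = grid_search(X2, y2, g2, grid, seed)

    clf1 = _forest(hyper1["criterion"], hyper1["max_depth"], hyper1["n_trees"], seed)
    clf1.fit(X1, y1)
    clf2 = _forest(hyper2["criterion"], hyper2["max_depth"], hyper2["n_trees"], seed)
    clf2.fit(X2, y2)
    priors = {s: float(np.mean(y2 == s)) for s in SLEEP_STAGES}
    return TrainedStager(
        step1=clf1,
        step2=clf2,
        hyper1=hyper1,
        hyper2=hyper2,
        seed=seed,
        sleep_priors=priors,
        search_log1=log1,
        search_log2=log2,
    )


def predict(
    model: TrainedStager, table: pd.DataFrame
) -> tuple[np.ndarray, pd.DataFrame]:
    """Stage one recording: merged 4-class labels and per-class scores.

    Step 1 labels every epoch WAKE/SLEEP; step-2 features are then built
    from the *predicted* mask (standardisation over predicted-SLEEP rows,
    SET, HRT) and the sleep forest assigns REM/LIGHT/DEEP within SLEEP.
    Scores follow the chain rule: P(WAKE) = p1, P(stage) = (1-p1) *
    P(stage | SLEEP); step-2 probabilities are evaluated on every epoch so
    the scores are defined for WAKE-called epochs too.  The merged labels
    honour the gate: WAKE exactly where step 1 said WAKE.
    """
    for name in model.step1_features:
        if name not in table.columns:
            raise ManifestError(f"missing feature column {name!r}")
    X1 = table[list(model.step1_features)].to_numpy(dtype=float)
    wake_col = list(model.step1.classes_).index("WAKE")
    p_wake = model.step1.predict_proba(X1)[:, wake_col]
    step1_labels = model.step1.predict(X1)
    sleep_mask = step1_labels == "SLEEP"

    n = len(table)
    scores = pd.DataFrame(
        {"WAKE": p_wake, "REM": 0.0, "LIGHT": 0.0, "DEEP": 0.0}, index=table.index
    )
    labels = np.array(step1_labels, dtype=object)
    if sleep_mask.sum() >= 2:
        feats = build_step2_features(table, sleep_mask)
        X2 = feats.to_numpy(dtype=float)
        p2 = model.step2.predict_proba(X2)
        cls2 = list(model.step2.classes_)
        for s in SLEEP_STAGES:
            if s in cls2:
                scores[s] = (1.0 - p_wake) * p2[:, cls2.index(s)]
        pred2 = model.step2.predict(X2)
        labels[sleep_mask] = pred2[sleep_mask]
    else:
        # degenerate night: (almost) no sleep called; spread the residual
        # probability mass by the training priors and keep step-1 labels
        for s in SLEEP_STAGES:
            scores[s] = (1.0 - p_wake) * model.sleep_priors.get(s, 1 / 3)
        labels[sleep_mask] = max(
            model.sleep_priors, default="LIGHT", key=model.sleep_priors.get
        ) if model.sleep_priors else "LIGHT"
    # normalise away float round-off; rows already sum to ~1 by construction
    total = scores.sum(axis=1).to_numpy()
    scores = scores.div(np.where(total > 0, total, 1.0), axis=0)
    assert len(labels) == n
    return labels, scores
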