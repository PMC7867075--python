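"""Leave-one-subject-out evaluation, metrics, ROC/AUC and feature tests.

Folds are subjects: every night of the held-out subject forms the test
set and the remaining subjects the training pool.  The pooled confusion
matrix is oriented rows = estimated, columns = correct.  ROC curves are
one-vs-rest per class, vertically averaged over folds on a fixed
101-point false-positive-rate grid.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import auc as _auc
from sklearn.metrics import roc_curve

from . import staging
from .types import STAGES, SLEEP_STAGES, Hypnogram, ParameterError

log = logging.getLogger(__name__)

FPR_GRID = np.linspace(0.0, 1.0, 101)


def _quiet_stat(fn, *args, **kwargs):
    """Run a scipy test suppressing degenerate-input RuntimeWarnings.

    Ties or zero spread yield NaN p-values, which downstream logic already
    treats as "not significant"; the warnings are just noise.
    """
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return fn(*args, **kwargs)


def metrics_from_confusion(M: np.ndarray, labels: tuple[str, ...] = STAGES) -> dict:
    """Per-class precision/recall/F plus accuracy from a confusion matrix.

    ``M[i, j]`` counts epochs estimated ``labels[i]`` whose correct stage
    is ``labels[j]``.  Precision of class c is TP / row-sum, recall is
    TP / column-sum, F = 2PR/(P+R); undefined ratios (empty row/column or
    P+R = 0) are reported as 0.
    """
    M = np.asarray(M)
    if M.ndim != 2 or M.shape[0] != M.shape[1] or M.shape[0] != len(labels):
        raise ParameterError("confusion matrix shape does not match labels")
    if np.any(M < 0):
        raise ParameterError("confusion matrix entries must be nonnegative")
    total = M.sum()
    if total == 0:
        raise ParameterError("empty confusion matrix")
    out: dict = {"accuracy": float(np.trace(M) / total)}
    f_scores = []
    for i, name in enumerate(labels):
        tp = M[i, i]
        est, correct = M[i, :].sum(), M[:, i].sum()
        p = float(tp / est) if est > 0 else 0.0
        r = float(tp / correct) if correct > 0 else 0.0
        f = 2 * p * r / (p + r) if (p + r) > 0 else 0.0
        out[f"{name}_precision"], out[f"{name}_recall"], out[f"{name}_f"] = p, r, f
        f_scores.append(f)
    out["macro_f"] = float(np.mean(f_scores))
    return out


def confusion_matrix(
    predicted: np.ndarray, correct: np.ndarray, labels: tuple[str, ...] = STAGES
) -> np.ndarray:
    """Counts with rows = estimated stage, columns = correct stage."""
    idx = {name: i for i, name in enumerate(labels)}
    M = np.zeros((len(labels), len(labels)), dtype=int)
    for p, c in zip(predicted, correct):
        M[idx[p], idx[c]] += 1
    return M


@dataclass
class EvalReport:
    """Fold-wise metrics, pooled confusion matrix and averaged ROC."""

    fold_metrics: pd.DataFrame  # one row per fold (held-out subject)
    confusion: pd.DataFrame  # rows = estimated, columns = correct
    roc_curves: dict[str, pd.DataFrame]  # class -> (fpr, mean tpr)
    auc: dict[str, float]  # class -> fold-averaged AUC
    auc_per_fold: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def summary(self) -> pd.DataFrame:
        """Mean and SD (population) of every metric across folds."""
        num = self.fold_metrics.drop(columns=["subject"])
        return pd.DataFrame(
            {"mean": num.mean(), "sd": num.std(ddof=0)}
        )

    def save(self, outdir) -> None:
        from pathlib import Path

        import yaml

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.fold_metrics.to_csv(outdir / "fold_metrics.csv", index=False)
        self.confusion.to_csv(outdir / "confusion_matrix.csv")
        for name, df in self.roc_curves.items():
            df.to_csv(outdir / f"roc_{name.lower()}.csv", index=False)
        (outdir / "report.yaml").write_text(
            yaml.safe_dump(
                {
                    "auc": {k: float(v) for k, v in self.auc.items()},
                    "mean_metrics": {
                        k: float(v) for k, v in self.summary()["mean"].items()
                    },
                },
                sort_keys=False,
            )
        )


def _fold_roc(
    truth: np.ndarray, scores: pd.DataFrame
) -> tuple[dict[str, np.ndarray], dict[str, float]]:
    """One-vs-rest ROC per class for one fold; skips one-class folds."""
    tprs, aucs = {}, {}
    for name in STAGES:
        y = (truth == name).astype(int)
        if y.min() == y.max():
            continue
        fpr, tpr, _ = roc_curve(y, scores[name].to_numpy())
        tprs[name] = np.interp(FPR_GRID, fpr, tpr)
        aucs[name] = float(_auc(fpr, tpr))
    return tprs, aucs


def loso_evaluate(
    tables: list[pd.DataFrame],
    truths: list[Hypnogram],
    grid: staging.HyperGrid | None = None,
    seed: int = 0,
    paper_faithful: bool = False,
) -> EvalReport:
    """Leave-one-subject-out evaluation of the full two-step pipeline.

    With ``paper_faithful=True`` hyperparameters are selected once by grid
    search over all subjects (the printed procedure, which leaks the test
    subject into the selection); the default re-runs the search inside
    each training pool.
    """
    grid = grid or staging.HyperGrid()
    subjects = [t["subject_id"].iloc[0] for t in tables]
    uniq = sorted(set(subjects))
    if len(uniq) < 2:
        raise ParameterError("leave-one-subject-out needs >= 2 subjects")

    hyper1 = hyper2 = None
    if paper_faithful:
        model_all = staging.fit(tables, truths, grid=grid, seed=seed)
        hyper1, hyper2 = model_all.hyper1, model_all.hyper2

    rows, tpr_acc, auc_acc = [], {s: [] for s in STAGES}, {s: [] for s in STAGES}
    auc_rows = []
    pooled_M = np.zeros((4, 4), dtype=int)
    for held in uniq:
        train_idx = [i for i, s in enumerate(subjects) if s != held]
        test_idx = [i for i, s in enumerate(subjects) if s == held]
        model = staging.fit(
            [tables[i] for i in train_idx],
            [truths[i] for i in train_idx],
            grid=grid,
            seed=seed,
            hyper1=hyper1,
            hyper2=hyper2,
        )
        preds, scores, truth_all = [], [], []
        for i in test_idx:
            n = min(len(tables[i]), len(truths[i]))
            labels, sc = staging.predict(model, tables[i].iloc[:n])
            preds.append(labels[:n])
            scores.append(sc.iloc[:n])
            truth_all.append(truths[i].as_array()[:n])
        pred = np.concatenate(preds)
        truth = np.concatenate(truth_all)
        score = pd.concat(scores, ignore_index=True)

        M = confusion_matrix(pred, truth)
        pooled_M += M
        row = {"subject": held, "n_epochs": int(M.sum())}
        row.update(metrics_from_confusion(M))
        rows.append(row)
        tprs, aucs = _fold_roc(truth, score)
        for name, v in tprs.items():
            tpr_acc[name].append(v)
        for name, v in aucs.items():
            auc_acc[name].append(v)
        auc_rows.append({"subject": held, **aucs})

    roc_curves = {
        name: pd.DataFrame({"fpr": FPR_GRID, "tpr": np.mean(vals, axis=0)})
        for name, vals in tpr_acc.items()
        if vals
    }
    auc_mean = {name: float(np.mean(v)) for name, v in auc_acc.items() if v}
    return EvalReport(
        fold_metrics=pd.DataFrame(rows),
        confusion=pd.DataFrame(pooled_M, index=list(STAGES), columns=list(STAGES)),
        roc_curves=roc_curves,
        auc=auc_mean,
        auc_per_fold=pd.DataFrame(auc_rows),
    )


def feature_significance(
    tables: list[pd.DataFrame],
    truths: list[Hypnogram],
    n_per_stage: int = 20,
    seed: int = 0,
) -> pd.DataFrame:
    """Stage-difference tests on randomly drawn epochs.

    Step-1 features: Wilcoxon signed-rank on ``n_per_stage`` randomly
    paired WAKE vs SLEEP epochs.  Step-2 features (built from truth
    masks): Friedman across REM/LIGHT/DEEP, then pairwise Wilcoxon with
    Bonferroni (x3) when the Friedman test rejects at 5%.  Comparisons
    with too few epochs are skipped with a notice row.
    """
    rng = np.random.default_rng(seed)
    pooled, stages, _ = staging._pool(tables, truths)
    rows = []

    def draw(mask: np.ndarray) -> np.ndarray | None:
        idx = np.flatnonzero(mask)
        if len(idx) < n_per_stage:
            return None
        return rng.choice(idx, size=n_per_stage, replace=False)

    wake_idx = draw(stages == "WAKE")
    sleep_idx = draw(stages != "WAKE")
    for name in staging.FIRST_STEP_FEATURES:
        if wake_idx is None or sleep_idx is None:
            rows.append({"step": 1, "feature": name, "comparison": "WAKE-SLEEP",
                         "p": np.nan, "significant": False, "note": "insufficient epochs"})
            continue
        vals = pooled[name].to_numpy(dtype=float)
        stat = _quiet_stat(stats.wilcoxon, vals[wake_idx], vals[sleep_idx])
        rows.append({"step": 1, "feature": name, "comparison": "WAKE-SLEEP",
                     "p": float(stat.pvalue), "significant": stat.pvalue < 0.05,
                     "note": ""})

    # step-2 features conditioned on the truth WAKE/SLEEP mask
    feat_parts, stage_parts = [], []
    for table, truth in zip(tables, truths):
        n = min(len(table), len(truth))
        sub = table.iloc[:n].reset_index(drop=True)
        mask = truth.sleep_mask()[:n]
        feat_parts.append(staging.build_step2_features(sub, mask))
        stage_parts.append(truth.as_array()[:n])
    feats2 = pd.concat(feat_parts, ignore_index=True)
    stages2 = np.concatenate(stage_parts)
    draws = {s: draw(stages2 == s) for s in SLEEP_STAGES}
    pairs = [("REM", "LIGHT"), ("REM", "DEEP"), ("LIGHT", "DEEP")]
    for name in staging.SECOND_STEP_FEATURES:
        if any(draws[s] is None for s in SLEEP_STAGES):
            rows.append({"step": 2, "feature": name, "comparison": "Friedman",
                         "p": np.nan, "significant": False, "note": "insufficient epochs"})
            continue
        vals = feats2[name].to_numpy(dtype=float)
        samples = [vals[draws[s]] for s in SLEEP_STAGES]
        fried = _quiet_stat(stats.friedmanchisquare, *samples)
        rows.append({"step": 2, "feature": name, "comparison": "Friedman",
                     "p": float(fried.pvalue), "significant": fried.pvalue < 0.05,
                     "note": ""})
        if fried.pvalue < 0.05:
            for a, b in pairs:
                w = _quiet_stat(stats.wilcoxon, vals[draws[a]], vals[draws[b]])
                p_adj = min(float(w.pvalue) * len(pairs), 1.0)
                rows.append({"step": 2, "feature": name, "comparison": f"{a}-{b}",
                             "p": p_adj, "significant": p_adj < 0.05,
                             "note": "Bonferroni x3"})
    return pd.DataFrame(rows)


def summary_stats(values) -> tuple[float, float]:
    """Arithmetic mean and population SD (divisor n) of a numeric list."""
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise ParameterError("empty value list")
    return float(arr.mean()), float(arr.std(ddof=0))


def stage_rates(stage_epochs: dict[str, list[float]]) -> dict[str, float]:
    """Pooled stage percentages: 100 * sum(stage epochs) / sum(all epochs)."""
    totals = {k: float(np.sum(v)) for k, v in stage_epochs.items()}
    grand = sum(totals.values())
    if grand <= 0:
        raise ParameterError("no epochs")
    return {k: 100.0 * v / grand for k, v in totals.items()}
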