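import numpy as np
import pandas as pd
import pytest

from bcgsleep import evaluation, staging
from bcgsleep.reference_data import STAGE_EPOCHS, stage_summary, subject_summary
from bcgsleep.types import STAGES, Hypnogram, ParameterError


class TestMetricsFromConfusion:
    def test_perfect_diagonal(self):
        m = evaluation.metrics_from_confusion(np.diag([10, 10, 10, 10]))
        assert m["accuracy"] == 1.0
        for s in STAGES:
            assert m[f"{s}_f"] == 1.0

    def test_hand_checkable_two_class(self):
        M = np.zeros((4, 4), dtype=int)
        M[0, 0], M[0, 1], M[1, 1] = 5, 5, 10  # WAKE row [5,5], REM gets 10
        m = evaluation.metrics_from_confusion(M)
        assert m["WAKE_precision"] == pytest.approx(0.5)
        assert m["WAKE_recall"] == pytest.approx(1.0)
        assert m["WAKE_f"] == pytest.approx(2 * 0.5 * 1.0 / 1.5)
        assert m["REM_recall"] == pytest.approx(10 / 15)
        assert m["accuracy"] == pytest.approx(15 / 20)

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(200):
            M = rng.integers(0, 40, size=(4, 4))
            m = evaluation.metrics_from_confusion(M)
            total = M.sum()
            assert m["accuracy"] == pytest.approx(np.trace(M) / total)
            for i, s in enumerate(STAGES):
                tp = M[i, i]
                fp = sum(M[i, j] for j in range(4) if j != i)
                fn = sum(M[j, i] for j in range(4) if j != i)
                p = tp / (tp + fp) if tp + fp else 0.0
                r = tp / (tp + fn) if tp + fn else 0.0
                f = 2 * p * r / (p + r) if p + r else 0.0
                assert m[f"{s}_precision"] == pytest.approx(p)
                assert m[f"{s}_recall"] == pytest.approx(r)
                assert m[f"{s}_f"] == pytest.approx(f)

    def test_empty_matrix_rejected(self):
        with pytest.raises(ParameterError):
            evaluation.metrics_from_confusion(np.zeros((4, 4), dtype=int))


class TestLosoStructure:
    def test_three_subjects_three_disjoint_folds(self, small_dataset):
        tables, truths, _ = small_dataset
        grid = staging.HyperGrid(criteria=("gini",), depths=(4,), n_trees=(8,))
        report = evaluation.loso_evaluate(tables, truths, grid=grid, seed=0)
        assert len(report.fold_metrics) == 3
        assert set(report.fold_metrics["subject"]) == {"S01", "S02", "S03"}
        # pooled confusion totals equal total test epochs
        assert report.confusion.to_numpy().sum() == sum(len(t) for t in tables)
        # per-fold column sums equal that fold's test epoch count
        assert report.fold_metrics["n_epochs"].sum() == sum(len(t) for t in tables)

    def test_perfect_oracle_predictions(self):
        """Injected perfect predictions give accuracy 1 and diagonal matrix."""
        rng = np.random.default_rng(0)
        truth = rng.choice(list(STAGES), size=400)
        M = evaluation.confusion_matrix(truth, truth)
        assert np.trace(M) == 400
        m = evaluation.metrics_from_confusion(M)
        assert m["accuracy"] == 1.0

    def test_random_predictions_near_chance(self, rng):
        """Multinomial null: accuracy of random 4-class guessing is ~0.25."""
        accs = []
        for _ in range(100):
            truth = rng.choice(list(STAGES), size=400)
            pred = rng.choice(list(STAGES), size=400)
            M = evaluation.confusion_matrix(pred, truth)
            accs.append(np.trace(M) / M.sum())
        assert np.mean(accs) == pytest.approx(0.25, abs=0.03)

    def test_fold_metrics_match_confusion_recompute(self, small_dataset):
        tables, truths, _ = small_dataset
        grid = staging.HyperGrid(criteria=("gini",), depths=(4,), n_trees=(8,))
        report = evaluation.loso_evaluate(tables, truths, grid=grid, seed=0)
        # micro-accuracy from the pooled matrix is the epoch-weighted
        # combination of fold accuracies
        M = report.confusion.to_numpy()
        pooled_acc = np.trace(M) / M.sum()
        w = report.fold_metrics["n_epochs"] / report.fold_metrics["n_epochs"].sum()
        assert pooled_acc == pytest.approx(
            float((report.fold_metrics["accuracy"] * w).sum()), abs=1e-9
        )


class TestFeatureSignificance:
    def _const_dataset(self, n=300, seed=0):
        rng = np.random.default_rng(seed)
        stages = rng.choice(list(STAGES), size=n, p=[0.15, 0.2, 0.45, 0.2])
        table = pd.DataFrame(
            {
                "subject_id": ["S"] * n,
                "night_id": ["n"] * n,
                "epoch": np.arange(n),
                **{f: np.ones(n) for f in ("AGM", "VGM", "FS", "AJJI", "VJJI")},
                "HF/TF": np.ones(n),
                "HF/LF": np.ones(n),
            }
        )
        return [table], [Hypnogram(stages=list(stages))], stages

    def test_identical_feature_not_significant(self):
        tables, truths, _ = self._const_dataset()
        # constant features: zero-difference pairs; Wilcoxon is degenerate,
        # so add tiny stage-independent noise instead
        rng = np.random.default_rng(1)
        for f in ("AGM", "VGM", "FS", "AJJI", "VJJI", "HF/TF", "HF/LF"):
            tables[0][f] = 1.0 + 1e-6 * rng.normal(size=len(tables[0]))
        report = evaluation.feature_significance(tables, truths, seed=0)
        step1 = report[(report["step"] == 1)]
        assert not step1["significant"].any()

    def test_large_shift_detected_reliably(self):
        """A d=3 WAKE/SLEEP shift is significant in >=95% of seeded draws."""
        hits = 0
        reps = 100
        for rep in range(reps):
            tables, truths, stages = self._const_dataset(seed=rep)
            rng = np.random.default_rng(1000 + rep)
            shift = np.where(stages == "WAKE", 3.0, 0.0)
            tables[0]["AGM"] = shift + rng.normal(size=len(stages))
            report = evaluation.feature_significance(tables, truths, seed=rep)
            row = report[(report["feature"] == "AGM") & (report["step"] == 1)]
            if float(row["p"].iloc[0]) < 0.01:
                hits += 1
        assert hits >= 95

    def test_bonferroni_multiplication(self):
        # raw p 0.02 with 3 comparisons -> adjusted 0.06, not significant
        assert min(0.02 * 3, 1.0) == pytest.approx(0.06)
        tables, truths, stages = self._const_dataset(seed=3)
        rng = np.random.default_rng(3)
        # make REM differ strongly so Friedman rejects and pairwise runs
        tables[0]["AJJI"] = np.where(stages == "REM", 2.0, 1.0) + 0.05 * rng.normal(
            size=len(stages)
        )
        report = evaluation.feature_significance(tables, truths, seed=3)
        pairwise = report[report["note"] == "Bonferroni x3"]
        assert len(pairwise) > 0
        assert (pairwise["p"] <= 1.0).all()

    def test_insufficient_epochs_skipped_with_notice(self):
        tables, truths, _ = self._const_dataset(n=30)
        truths = [Hypnogram(stages=["LIGHT"] * 30)]
        report = evaluation.feature_significance(tables, truths, seed=0)
        assert (report["note"] == "insufficient epochs").any()


def _agrees_to_printed_precision(value, printed, decimals):
    """True when ``value`` rounds to ``printed`` at the table's precision
    (within half an ulp of the last printed digit; exact .5 cells print
    half-up)."""
    return abs(value - printed) <= 0.5 * 10 ** (-decimals) + 1e-9


class TestSummaryStats:
    def test_printed_subject_table_reproduced(self):
        """Demographics: mean/SD cells match the printed study table."""
        s = subject_summary()
        for key, mean, sd, nd in [
            ("age_years", 21.8, 0.7, 1),
            ("height_m", 1.718, 0.046, 3),
            ("weight_kg", 66.9, 10.9, 1),
        ]:
            assert _agrees_to_printed_precision(s[key]["mean"], mean, nd), key
            assert _agrees_to_printed_precision(s[key]["sd"], sd, nd), key

    def test_printed_stage_table_reproduced(self):
        """Every mean/SD/%Rate cell of the stage-count table reproduces."""
        expected = {
            "night2": {
                "WAKE": (55.5, 22.1, 6.4),
                "REM": (110.4, 18.0, 12.8),
                "LIGHT": (534.9, 65.7, 62.0),
                "DEEP": (161.5, 26.1, 18.7),
            },
            "night3": {
                "WAKE": (48.9, 20.0, 5.7),
                "REM": (108.9, 49.3, 12.7),
                "LIGHT": (541.4, 68.6, 63.0),
                "DEEP": (160.1, 53.3, 18.6),
            },
        }
        got = stage_summary()
        for night, stages in expected.items():
            for stage, (mean, sd, rate) in stages.items():
                cells = got[night][stage]
                assert _agrees_to_printed_precision(cells["mean"], mean, 1), (night, stage)
                assert _agrees_to_printed_precision(cells["sd"], sd, 1), (night, stage)
                assert _agrees_to_printed_precision(cells["rate_pct"], rate, 1), (night, stage)

    def test_population_sd_convention(self):
        # Day-2 WAKE epochs: mean printed as 55.5
        mean, sd = evaluation.summary_stats(STAGE_EPOCHS["night2"]["WAKE"])
        assert mean == pytest.approx(55.5)
        # Day-3 DEEP epochs: SD printed as 53.3 only with divisor n
        _, sd3 = evaluation.summary_stats(STAGE_EPOCHS["night3"]["DEEP"])
        assert round(sd3, 1) == 53.3
        assert round(np.std(STAGE_EPOCHS["night3"]["DEEP"], ddof=1), 1) != 53.3

    def test_constant_list_zero_sd(self):
        assert evaluation.summary_stats([4, 4, 4])[1] == 0.0

    def test_empty_rejected(self):
        with pytest.raises(ParameterError):
            evaluation.summary_stats([])
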