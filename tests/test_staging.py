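import numpy as np
import pandas as pd
import pytest

from bcgsleep import staging
from bcgsleep.types import (
    BASE_FEATURES,
    FIRST_STEP_FEATURES,
    Hypnogram,
    ParameterError,
)


def _table(n, subject="S01", night="n2", rng=None, agm=None):
    rng = rng or np.random.default_rng(0)
    data = {
        "subject_id": [subject] * n,
        "night_id": [night] * n,
        "epoch": np.arange(n),
    }
    for name in BASE_FEATURES:
        data[name] = rng.random(n)
    if agm is not None:
        data["AGM"] = np.asarray(agm, dtype=float)
    return pd.DataFrame(data)


class TestStandardizeSleep:
    def test_two_point_z_score(self):
        t = _table(4)
        t["AGM"] = [9.0, 1.0, 3.0, 9.0]
        sleep = np.array([False, True, True, False])
        out = staging.standardize_sleep(t, sleep, features=("AGM",))
        np.testing.assert_allclose(out["SAGM"][sleep], [-1.0, 1.0])

    def test_constant_feature_zeroed(self):
        t = _table(4)
        t["VGM"] = 1.0
        out = staging.standardize_sleep(t, np.array([True] * 4), features=("VGM",))
        np.testing.assert_array_equal(out["SVGM"], 0.0)

    def test_moments_over_sleep_rows(self, rng):
        t = _table(200, rng=rng)
        sleep = rng.random(200) < 0.8
        out = staging.standardize_sleep(t, sleep)
        for name in BASE_FEATURES:
            col = out["S" + name].to_numpy()[sleep]
            assert col.mean() == pytest.approx(0.0, abs=1e-9)
            assert col.var() == pytest.approx(1.0, abs=1e-9)

    def test_too_few_sleep_epochs_rejected(self):
        with pytest.raises(staging.StandardizationError):
            staging.standardize_sleep(_table(5), np.array([True] + [False] * 4))


class TestSleepElapsedTime:
    def test_onset_formula(self):
        mask = np.zeros(130, dtype=bool)
        mask[0:] = True
        set_min = staging.sleep_elapsed_time(mask)
        assert set_min[120] == pytest.approx(60.0)
        assert set_min[0] == 0.0

    def test_before_onset_zero(self, rng):
        onset = 10
        mask = np.arange(50) >= onset
        set_min = staging.sleep_elapsed_time(mask)
        assert (set_min[:onset] == 0).all()
        for m in rng.integers(0, 39, size=10):
            assert set_min[onset + m] == pytest.approx(0.5 * m)

    def test_no_sleep_all_zero(self):
        assert (staging.sleep_elapsed_time(np.zeros(20, bool)) == 0).all()


class TestHeadRestTime:
    def test_ten_minutes_after_movement(self):
        agm = np.zeros(30)
        agm[5] = 10.0
        hrt = staging.head_rest_time(agm, np.ones(30, bool), theta=1.0)
        assert hrt[25] == pytest.approx(10.0)

    def test_movement_in_current_epoch_zero(self):
        agm = np.zeros(10)
        agm[7] = 5.0
        hrt = staging.head_rest_time(agm, np.ones(10, bool), theta=1.0)
        assert hrt[7] == 0.0

    def test_matches_scanback_oracle(self, rng):
        n = 200
        agm = rng.random(n)
        sleep = rng.random(n) < 0.9
        theta = 0.8
        hrt = staging.head_rest_time(agm, sleep, theta=theta)
        for k in rng.integers(0, n, size=25):
            k_move = -1
            for j in range(int(k), -1, -1):
                if agm[j] > theta or not sleep[j]:
                    k_move = j
                    break
            expected = 0.5 * (k - k_move) if k_move >= 0 else 0.0
            assert hrt[k] == pytest.approx(expected)

    def test_wake_epoch_resets(self):
        agm = np.zeros(20)
        sleep = np.ones(20, bool)
        sleep[4] = False
        hrt = staging.head_rest_time(agm, sleep, theta=1.0)
        assert hrt[10] == pytest.approx(0.5 * 6)


def _separable_dataset(n_subjects=3, n_epochs=120, seed=0):
    """WAKE has AGM >> SLEEP AGM; stages among SLEEP driven by AJJI."""
    rng = np.random.default_rng(seed)
    tables, truths = [], []
    stages_pool = ["WAKE", "REM", "LIGHT", "DEEP"]
    means = {"WAKE": 0.2, "REM": 0.01, "LIGHT": 0.011, "DEEP": 0.009}
    ajji = {"WAKE": 0.95, "REM": 1.0, "LIGHT": 1.05, "DEEP": 1.12}
    for s in range(n_subjects):
        stages = rng.choice(stages_pool, size=n_epochs, p=[0.1, 0.15, 0.55, 0.2])
        t = _table(n_epochs, subject=f"S{s}", rng=rng)
        t["AGM"] = [means[x] + 0.001 * rng.normal() for x in stages]
        t["AJJI"] = [ajji[x] + 0.005 * rng.normal() for x in stages]
        t["VJJI"] = [
            (0.02 if x == "REM" else 0.005) * (1 + 0.1 * rng.normal()) for x in stages
        ]
        tables.append(t)
        truths.append(Hypnogram(stages=list(stages)))
    return tables, truths


SMALL_GRID = staging.HyperGrid(criteria=("gini",), depths=(2, 4), n_trees=(5,))


class TestFit:
    def test_separable_step1_perfect_on_training_pool(self):
        tables, truths = _separable_dataset()
        model = staging.fit(tables, truths, grid=SMALL_GRID, seed=0)
        pooled, stages, _ = staging._pool(tables, truths)
        X1 = pooled[list(FIRST_STEP_FEATURES)].to_numpy()
        pred = model.step1.predict(X1)
        truth1 = np.where(stages == "WAKE", "WAKE", "SLEEP")
        assert (pred == truth1).mean() == 1.0

    def test_shuffled_labels_yield_chance_cv_score(self):
        """Permutation null: macro F under label shuffling stays near chance."""
        rng = np.random.default_rng(1)
        tables, truths = _separable_dataset(n_subjects=4, n_epochs=80)
        pooled, stages, groups = staging._pool(tables, truths)
        X = pooled[list(FIRST_STEP_FEATURES)].to_numpy()
        y = np.where(stages == "WAKE", "WAKE", "SLEEP")
        scores = []
        for _ in range(10):
            y_shuf = rng.permutation(y)
            best, log = staging.grid_search(
                X, y_shuf, groups, staging.HyperGrid(("gini",), (3,), (5,)), seed=0
            )
            scores.append(log[0]["macro_f"])
        assert np.mean(scores) <= 0.6

    def test_grid_cardinality_logged(self):
        tables, truths = _separable_dataset(n_subjects=2, n_epochs=60)
        grid = staging.HyperGrid()  # 2 x 10 x 10
        assert len(grid.combos()) == 200
        model = staging.fit(tables, truths, grid=grid, seed=0)
        assert len(model.search_log1) == 200
        assert len(model.search_log2) == 200

    def test_single_class_rejected(self):
        tables, truths = _separable_dataset(n_subjects=2)
        all_wake = [Hypnogram(stages=["WAKE"] * len(t)) for t in truths]
        with pytest.raises(ParameterError):
            staging.fit(tables, all_wake, grid=SMALL_GRID, seed=0)

    def test_tie_break_prefers_simpler_model(self):
        combos = staging.HyperGrid().combos()
        assert combos[0] == ("gini", 1, 1)
        assert combos[1] == ("entropy", 1, 1)
        assert combos[2] == ("gini", 1, 2)


@pytest.fixture(scope="module")
def model_and_data():
    tables, truths = _separable_dataset()
    model = staging.fit(tables, truths, grid=SMALL_GRID, seed=0)
    test_tables, test_truths = _separable_dataset(seed=99)
    return model, test_tables[0], test_truths[0]


class TestPredict:
    def test_wake_gate_consistency(self, model_and_data):
        model, table, _ = model_and_data
        labels, scores = staging.predict(model, table)
        X1 = table[list(FIRST_STEP_FEATURES)].to_numpy()
        step1 = model.step1.predict(X1)
        np.testing.assert_array_equal(labels == "WAKE", step1 == "WAKE")

    def test_scores_sum_to_one(self, model_and_data):
        model, table, _ = model_and_data
        _, scores = staging.predict(model, table)
        np.testing.assert_allclose(scores.sum(axis=1), 1.0, atol=1e-9)

    def test_deterministic(self, model_and_data):
        model, table, _ = model_and_data
        l1, s1 = staging.predict(model, table)
        l2, s2 = staging.predict(model, table)
        np.testing.assert_array_equal(l1, l2)
        pd.testing.assert_frame_equal(s1, s2)

    def test_missing_feature_rejected(self, model_and_data):
        model, table, _ = model_and_data
        with pytest.raises(staging.ManifestError):
            staging.predict(model, table.drop(columns=["AGM"]))

    def test_accuracy_beats_majority_baseline(self, model_and_data):
        model, table, truth = model_and_data
        labels, _ = staging.predict(model, table)
        stages = truth.as_array()
        majority = max(set(stages), key=list(stages).count)
        assert (labels == stages).mean() > (stages == majority).mean()


class TestBundle:
    def test_save_load_identical_predictions(self, tmp_path):
        tables, truths = _separable_dataset()
        model = staging.fit(tables, truths, grid=SMALL_GRID, seed=0)
        model.save(tmp_path / "bundle")
        back = staging.TrainedStager.load(tmp_path / "bundle")
        assert back.hyper1 == model.hyper1 and back.seed == model.seed
        l1, s1 = staging.predict(model, tables[0])
        l2, s2 = staging.predict(back, tables[0])
        np.testing.assert_array_equal(l1, l2)
        pd.testing.assert_frame_equal(s1, s2)
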