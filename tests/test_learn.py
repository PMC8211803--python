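"""Metrics, scaling, under-sampling, CV harness and the final predictor."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import confusion_matrix

from metalsite import learn as L
from metalsite.fixtures import make_feature_table


def oracle_metrics(y_true, y_pred):
    """Independent confusion-matrix oracle via sklearn."""
    tn, fp, fn, tp = confusion_matrix(y_true, y_pred,
                                      labels=[0, 1]).ravel()
    acc = (tp + tn) / len(y_true)
    prec = tp / (tp + fp) if tp + fp else 0.0
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = ((tp * tn - fp * fn) / np.sqrt(denom)) if denom else 0.0
    return acc, prec, mcc


class TestScore:
    def test_agrees_with_confusion_matrix_oracle(self):
        rng = np.random.default_rng(123)
        for _ in range(1000):
            n = rng.integers(2, 40)
            yt = rng.integers(0, 2, n)
            yp = rng.integers(0, 2, n)
            m = L.score(yt, yp)
            acc, prec, mcc = oracle_metrics(yt, yp)
            assert m.accuracy == pytest.approx(acc)
            assert m.precision == pytest.approx(prec)
            assert m.mcc == pytest.approx(mcc)

    def test_constant_predictor_mcc_zero(self):
        yt = np.array([1] * 24 + [0] * 76)
        assert L.score(yt, np.zeros(100, int)).mcc == 0.0
        assert L.score(yt, np.ones(100, int)).mcc == 0.0

    def test_all_negative_on_24pct_positive_gives_76pct_accuracy(self):
        yt = np.array([1] * 240 + [0] * 760)
        m = L.score(yt, np.zeros(1000, int))
        assert m.accuracy == pytest.approx(0.76)
        assert m.recall == 0.0 and m.true_negative_rate == 1.0

    def test_perfect_prediction(self):
        yt = np.array([1, 0, 1, 0, 1])
        m = L.score(yt, yt)
        assert m.mcc == 1.0 and m.precision == 1.0 and m.recall == 1.0

    def test_balanced_confusion_closed_form(self):
        # (TP, TN, FP, FN) = (1, 1, 1, 1)
        m = L.score([1, 0, 0, 1], [1, 1, 0, 0])
        assert m.mcc == 0.0 and m.accuracy == 0.5

    def test_multi_score_is_mean_of_three(self):
        m = L.score([1, 0, 1, 1], [1, 0, 0, 1])
        assert m.multi_score == pytest.approx(
            (m.accuracy + m.mcc + m.jaccard) / 3)

    def test_empty_vectors_rejected(self):
        with pytest.raises(ValueError):
            L.score([], [])


class TestRobustScale:
    def test_quantile_mapping(self):
        fit = pd.DataFrame({"x": [-1.0, -1.0, 0.0, 1.0, 1.0]})
        out = L.robust_scale(fit, pd.DataFrame({"x": [2.0]}))
        assert out["x"].iloc[0] == pytest.approx(1.0)

    def test_constant_feature_maps_to_zero(self):
        fit = pd.DataFrame({"x": [3.0] * 10})
        out = L.robust_scale(fit)
        assert np.allclose(out["x"], 0.0)

    def test_values_outside_fit_range_not_clipped(self):
        fit = pd.DataFrame({"x": np.linspace(0, 1, 50)})
        out = L.robust_scale(fit, pd.DataFrame({"x": [100.0]}))
        assert out["x"].iloc[0] > 10


class TestUndersample:
    def _data(self, n_pos, n_neg):
        table = pd.DataFrame({"x": np.arange(n_pos + n_neg, dtype=float)})
        labels = np.array([1] * n_pos + [0] * n_neg)
        return table, labels

    def test_three_to_one_ratio(self):
        table, labels = self._data(100, 900)
        xt, yt = L.undersample(table, labels, seed=0)
        assert (yt == 1).sum() == 100 and (yt == 0).sum() == 300

    def test_fewer_negatives_all_kept(self):
        table, labels = self._data(100, 200)
        xt, yt = L.undersample(table, labels, seed=0)
        assert len(yt) == 300

    def test_same_seed_identical_sample(self):
        table, labels = self._data(50, 500)
        a = L.undersample(table, labels, seed=11)[0]
        b = L.undersample(table, labels, seed=11)[0]
        pd.testing.assert_frame_equal(a, b)
        c = L.undersample(table, labels, seed=12)[0]
        assert not a.equals(c)

    def test_zero_positives_rejected(self):
        table, labels = self._data(0, 10)
        with pytest.raises(ValueError):
            L.undersample(table, labels)


class _ConstantEstimator:
    def __init__(self, value):
        self.value = value

    def predict(self, x):
        return np.full(len(x), self.value)


def _stub_bundle(member_values, n_features=2):
    cols = [f"f{i}" for i in range(n_features)]
    table = pd.DataFrame(np.zeros((4, n_features)), columns=cols)
    return L.ModelBundle(
        algorithm="stub", params={}, feature_names=cols,
        scaler=L.fit_scaler(table),
        members=[_ConstantEstimator(v) for v in member_values],
        member_seeds=list(range(len(member_values))))


class TestPredict:
    def test_average_exactly_half_is_enzymatic(self):
        bundle = _stub_bundle([1, 1, 1, 1, 1, 0, 0, 0, 0, 0])
        x = pd.DataFrame(np.zeros((3, 2)), columns=["f0", "f1"])
        labels, scores = L.predict(bundle, x)
        assert np.all(scores == 0.5)
        assert np.all(labels == 1)

    def test_unanimous_members(self):
        x = pd.DataFrame(np.zeros((2, 2)), columns=["f0", "f1"])
        labels, scores = L.predict(_stub_bundle([0] * 10), x)
        assert np.all(labels == 0) and np.all(scores == 0.0)
        labels, scores = L.predict(_stub_bundle([1] * 10), x)
        assert np.all(labels == 1) and np.all(scores == 1.0)

    def test_schema_mismatch_names_columns(self):
        bundle = _stub_bundle([1] * 10)
        bad = pd.DataFrame(np.zeros((2, 2)), columns=["f0", "other"])
        with pytest.raises(L.SchemaMismatchError) as err:
            L.predict(bundle, bad)
        assert "f1" in str(err.value) and "other" in str(err.value)


@pytest.fixture(scope="module")
def data():
    return make_feature_table(n_pos=60, n_neg=180, n_features=8,
                              effect_size=5.0, seed=2)


class TestTrainBundle:

    def test_bundle_has_ten_members_and_predicts(self, data):
        x, y = data
        bundle = L.train_bundle(x, y, seed=0)
        assert len(bundle.members) == 10
        labels, scores = L.predict(bundle, x)
        assert L.score(y, labels).mcc > 0.9

    def test_training_is_reproducible(self, data):
        x, y = data
        b1 = L.train_bundle(x, y, seed=5)
        b2 = L.train_bundle(x, y, seed=5)
        _, s1 = L.predict(b1, x)
        _, s2 = L.predict(b2, x)
        assert np.array_equal(s1, s2)

    def test_importance_scale_and_ranking(self, data):
        x, y = data
        for seed in range(5):
            bundle = L.train_bundle(x, y, seed=seed,
                                    params={"n_estimators": 30})
            imp = L.feature_importance(bundle)
            assert imp["importance"].between(0, 100).all()
            assert imp.iloc[0]["feature"] == "f00"   # informative column

    def test_single_member_max_importance_is_100(self, data):
        x, y = data
        bundle = L.train_bundle(x, y, n_members=1, seed=1)
        imp = L.feature_importance(bundle)
        assert imp["importance"].max() == pytest.approx(100.0)


class TestNestedCV:
    def test_scaler_never_sees_test_folds(self, monkeypatch):
        x, y = make_feature_table(n_pos=30, n_neg=90, n_features=4,
                                  effect_size=3.0, seed=4)
        seen_sizes = []
        original = L.fit_scaler

        def recording_fit(table):
            seen_sizes.append(len(table))
            return original(table)

        monkeypatch.setattr(L, "fit_scaler", recording_fit)
        L.nested_cv(x, y, algorithms=("logistic_regression",),
                    scorers=("accuracy",), n_repetitions=1, seed=0)
        assert seen_sizes
        assert all(n < len(x) for n in seen_sizes)

    def test_single_grid_point_selected_on_all_folds(self):
        x, y = make_feature_table(n_pos=30, n_neg=90, n_features=4,
                                  effect_size=4.0, seed=5)
        roster = L.algorithm_roster(0)

        def tiny_roster(seed=0):
            est, _ = roster["logistic_regression"]
            return {"logistic_regression": (est, {"C": [1.0]})}

        import unittest.mock as mock
        with mock.patch.object(L, "algorithm_roster", tiny_roster):
            results = L.nested_cv(x, y, algorithms=("logistic_regression",),
                                  scorers=("mcc",), n_repetitions=2, seed=0)
        r = results[0]
        assert r.best_params_count == 7        # chosen on all 7 folds
        assert len(r.params_per_fold) == 7
        assert len(r.fold_metrics) == 7 * 2
        assert r.mean.mcc > 0.7
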