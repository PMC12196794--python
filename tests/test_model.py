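import numpy as np
import pandas as pd
import pytest

from longlie import (EnsembleModel, NormalizationModel, cross_validate_candidates,
                     evaluate, fit_ensemble, split_dataset, train_ensemble)
from longlie.model import CandidateSpec, SelectionReport, default_candidates
from longlie.windows import feature_columns


def toy_dataset(n_per_class=40, n_features=200, separation=6.0, seed=0):
    """Linearly separable two-class table in the dataset layout."""
    rng = np.random.default_rng(seed)
    x0 = rng.normal(0.0, 1.0, size=(n_per_class, n_features))
    x1 = rng.normal(separation, 1.0, size=(n_per_class, n_features))
    df = pd.DataFrame(np.vstack([x0, x1]), columns=feature_columns())
    df["label"] = ["adl"] * n_per_class + ["fall"] * n_per_class
    df["source"] = [f"s:{i}" for i in range(2 * n_per_class)]
    return df


class _StubClassifier:
    def __init__(self, proba_row):
        self.proba_row = np.asarray(proba_row, dtype=float)

    def predict_proba(self, x):
        return np.tile(self.proba_row, (len(x), 1))


def stub_ensemble(rows):
    n = 200
    norm = NormalizationModel(mean=np.zeros(n), sd=np.ones(n),
                              columns=tuple(feature_columns()))
    members = {f"m{i}": _StubClassifier(r) for i, r in enumerate(rows)}
    return EnsembleModel(members=members, classes=np.array(["adl", "fall"]),
                         normalization=norm)


class TestSoftVoting:
    def test_probability_averaging(self):
        model = stub_ensemble([[0.9, 0.1], [0.6, 0.4], [0.7, 0.3]])
        p = model.predict_proba(np.zeros(200))
        assert p[0] == pytest.approx([2.2 / 3, 0.8 / 3])
        assert p.sum() == pytest.approx(1.0, abs=1e-9)

    def test_unanimous_members(self):
        model = stub_ensemble([[1, 0], [1, 0], [1, 0]])
        assert model.predict_proba(np.zeros(200))[0] == pytest.approx([1.0, 0.0])

    def test_symmetric_members_tie(self):
        model = stub_ensemble([[1, 0], [0, 1], [0.5, 0.5]])
        p = model.predict_proba(np.zeros(200))
        assert p[0] == pytest.approx([0.5, 0.5])
        # exact tie resolves to the lowest-index class
        assert model.predict(np.zeros(200))[0] == "adl"

    def test_argmax_prediction(self):
        model = stub_ensemble([[0.1, 0.9], [0.2, 0.8], [0.3, 0.7]])
        assert model.predict(np.zeros(200))[0] == "fall"

    def test_dimension_mismatch_rejected(self):
        model = stub_ensemble([[0.5, 0.5]])
        with pytest.raises(ValueError, match="features"):
            model.predict_proba(np.zeros(7))


class TestSelection:
    def test_separable_data_all_perfect_tiebreak_by_name(self):
        report = cross_validate_candidates(toy_dataset(), k=3, seed=0)
        assert (report.metrics["f1_mean"] == 1.0).all()
        assert report.ranking == sorted(report.ranking)
        assert report.selected == sorted(m.name for m in default_candidates())[:3]

    def test_fixed_seed_reproducible(self):
        ds = toy_dataset(separation=0.8, seed=3)
        a = cross_validate_candidates(ds, k=3, seed=9)
        b = cross_validate_candidates(ds, k=3, seed=9)
        pd.testing.assert_frame_equal(a.metrics, b.metrics)
        assert a.selected == b.selected

    def test_too_few_examples_per_class_rejected(self):
        ds = toy_dataset(n_per_class=3)
        with pytest.raises(ValueError, match="k examples"):
            cross_validate_candidates(ds, k=5, seed=0)

    def test_selection_must_have_three(self):
        with pytest.raises(ValueError, match="three"):
            SelectionReport(metrics=pd.DataFrame(), ranking=["knn"],
                            selected=["knn"])


class TestFitAndEvaluate:
    @pytest.fixture(scope="class")
    def fitted(self):
        ds = toy_dataset(seed=1)
        sel = cross_validate_candidates(ds, k=3, seed=42)
        return ds, fit_ensemble(ds, sel, seed=42)

    def test_three_members_and_manifest(self, fitted):
        _, model = fitted
        assert len(model.members) == 3
        assert model.manifest["members"] == list(model.members)

    def test_deterministic_predictions(self, fitted):
        ds, _ = fitted
        sel = cross_validate_candidates(ds, k=3, seed=42)
        m1 = fit_ensemble(ds, sel, seed=42)
        m2 = fit_ensemble(ds, sel, seed=42)
        probe = np.linspace(-1, 7, 200)
        assert np.array_equal(m1.predict_proba(probe), m2.predict_proba(probe))

    def test_single_class_training_rejected(self, fitted):
        ds, _ = fitted
        sel = cross_validate_candidates(ds, k=3, seed=42)
        one = ds[ds["label"] == "fall"].reset_index(drop=True)
        with pytest.raises(ValueError, match="both classes"):
            fit_ensemble(one, sel, seed=42)

    def test_perfect_predictions_all_metrics_one(self, fitted):
        ds, model = fitted
        rep = evaluate(model, ds)
        assert (rep.accuracy, rep.precision, rep.recall, rep.specificity,
                rep.f1, rep.auc) == (1.0, 1.0, 1.0, 1.0, 1.0, 1.0)

    def test_metrics_recomputable_from_confusion(self, fitted):
        ds, model = fitted
        rep = evaluate(model, ds)
        c = rep.confusion
        n = sum(c.values())
        assert n == len(ds)
        assert rep.accuracy == pytest.approx((c["tp"] + c["tn"]) / n)
        assert rep.specificity == pytest.approx(c["tn"] / (c["tn"] + c["fp"]))

    def test_one_class_test_set_rejected(self, fitted):
        ds, model = fitted
        with pytest.raises(ValueError, match="both classes"):
            evaluate(model, ds[ds["label"] == "adl"])

    def test_metric_arithmetic_from_known_confusion(self):
        # TP=50, FN=0, TN=49, FP=1 by construction
        rows = [[0.1, 0.9]] * 50 + [[0.9, 0.1]] * 49 + [[0.1, 0.9]]
        labels = ["fall"] * 50 + ["adl"] * 50

        class _Varying:
            def __init__(self, rows):
                self.rows = np.asarray(rows, dtype=float)

            def predict_proba(self, x):
                return self.rows

        norm = NormalizationModel(mean=np.zeros(200), sd=np.ones(200))
        model = EnsembleModel(members={"m": _Varying(rows)},
                              classes=np.array(["adl", "fall"]),
                              normalization=norm)
        ds = pd.DataFrame(np.zeros((100, 200)), columns=feature_columns())
        ds["label"] = labels
        ds["source"] = "s"
        rep = evaluate(model, ds)
        assert rep.accuracy == pytest.approx(0.99)
        assert rep.recall == pytest.approx(1.0)
        assert rep.specificity == pytest.approx(0.98)

    def test_probability_rows_sum_to_one(self, fitted):
        ds, model = fitted
        x = ds[[c for c in ds.columns if c.startswith("f_")]].to_numpy()
        p = model.predict_proba(x)
        assert np.abs(p.sum(axis=1) - 1.0).max() < 1e-9

    def test_persistence_round_trip(self, fitted, tmp_path):
        ds, model = fitted
        path = tmp_path / "model.joblib"
        model.save(path)
        back = EnsembleModel.load(path)
        probe = np.linspace(-1, 7, 200)
        assert np.array_equal(back.predict_proba(probe),
                              model.predict_proba(probe))
        assert back.manifest == model.manifest


class TestCoinFlipAUC:
    def test_random_scores_give_half_auc(self):
        # rank-statistic AUC should hover at 0.5 for label-independent scores
        rng = np.random.default_rng(0)
        aucs = []
        for _ in range(20):
            model = stub_ensemble([[0.5, 0.5]])
            ds = toy_dataset(n_per_class=50, separation=0.0,
                             seed=int(rng.integers(1 << 30)))

            class _Rand:
                def predict_proba(self, x, rng=rng):
                    p = rng.uniform(size=len(x))
                    return np.column_stack([1 - p, p])

            model.members = {"r": _Rand()}
            rep = evaluate(model, ds)
            aucs.append(rep.auc)
        assert abs(np.mean(aucs) - 0.5) < 0.05


def test_train_ensemble_end_to_end_split():
    ds = toy_dataset(n_per_class=30, separation=4.0, seed=2)
    train, test = split_dataset(ds, 0.25, 7)
    assert set(train["label"]) == {"adl", "fall"}
    model, selection = train_ensemble(train, k=3, seed=7)
    rep = evaluate(model, test)
    assert rep.accuracy == 1.0
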