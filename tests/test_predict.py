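"""Dataset assembly, model training, cross-validation and the
multi-label / binary evaluation metrics."""

import numpy as np
import pytest

from rtstress import predict, synth
from rtstress._seqmodels import AttentionNet, RecurrentNet


@pytest.fixture(scope="module")
def cohort_cases():
    return synth.generate_cohort(
        synth.CohortConfig(n_patients=60, days_per_patient=(4, 4), seed=5)
    )


@pytest.fixture(scope="module")
def dataset(cohort_cases):
    return predict.build_dataset(cohort_cases, 8)


class TestBuildDataset:
    @pytest.mark.parametrize(
        "dtype,width", [(1, 7), (2, 8), (3, 8), (4, 8), (5, 9), (6, 9),
                        (7, 9), (8, 10)],
    )
    def test_widths(self, cohort_cases, dtype, width):
        ds = predict.build_dataset(cohort_cases, dtype)
        assert ds.X.shape[1] == width

    def test_column_order_deterministic(self, dataset):
        assert dataset.columns[:7] == tuple(
            f"before_{k}" for k in
            ("hr", "sdnn", "rmssd", "pnn50", "hf", "lf_hf", "tp")
        )
        assert dataset.columns[7:] == ("age", "sex", "day")

    def test_sex_encoded_binary(self, dataset):
        sex_col = dataset.X[:, dataset.columns.index("sex")]
        assert set(np.unique(sex_col)) <= {0.0, 1.0}

    def test_bad_type_rejected(self, cohort_cases):
        with pytest.raises(ValueError):
            predict.build_dataset(cohort_cases, 9)


class TestSequenceModels:
    @pytest.mark.parametrize("cls,kw", [
        (RecurrentNet, {"hidden": 3}), (AttentionNet, {"dim": 3}),
    ])
    def test_gradients_match_numerical(self, cls, kw):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(5, 4))
        Y = rng.integers(0, 2, (5, 3)).astype(float)
        m = cls(n_outputs=3, seed=1, **kw)
        if isinstance(m, AttentionNet):
            m._T = 4
            params = m._init_params(np.random.default_rng(1), 4)
        else:
            params = m._init_params(np.random.default_rng(1))
        _, grads = m.loss_and_grads(X, Y, params)
        eps = 1e-6
        for key, arr in params.items():
            it = np.nditer(arr, flags=["multi_index"])
            for _ in it:
                idx = it.multi_index
                old = arr[idx]
                arr[idx] = old + eps
                lp = m.loss_and_grads(X, Y, params)[0]
                arr[idx] = old - eps
                lm = m.loss_and_grads(X, Y, params)[0]
                arr[idx] = old
                num = (lp - lm) / (2 * eps)
                assert num == pytest.approx(grads[key][idx], rel=1e-4, abs=1e-7)

    def test_rnn_learns_separable_labels(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(150, 7))
        Y = (X > 0).astype(int)
        m = RecurrentNet(seed=0).fit(X, Y)
        assert (m.predict(X) == Y).mean() > 0.9

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(40, 7))
        Y = rng.integers(0, 2, (40, 7))
        p1 = RecurrentNet(seed=9, epochs=50).fit(X, Y).predict(X)
        p2 = RecurrentNet(seed=9, epochs=50).fit(X, Y).predict(X)
        np.testing.assert_array_equal(p1, p2)


class TestFitPredict:
    def test_leakage_fixture_perfect_emr(self):
        # copying the targets into the input columns makes the task
        # trivial: a held-out tree must reach EMR 1 (combinations recur,
        # so every held-out combination is seen in training)
        rng = np.random.default_rng(0)
        combos = rng.integers(0, 2, (8, 7))
        Y = combos[rng.integers(0, 8, 160)]
        groups = np.array([f"P{i}" for i in range(160)])
        leaky = predict.PredictionDataset(
            1, Y.astype(float), Y, groups, tuple(f"c{i}" for i in range(7))
        )
        pred = predict.fit_predict(leaky, "tree", seed=0, k=5, grouped=False)
        rep = predict.evaluate_multilabel(pred, Y)
        assert rep.emr == 1.0

    def test_shuffled_targets_near_chance(self, dataset):
        rng = np.random.default_rng(1)
        Ysh = dataset.Y[rng.permutation(dataset.n)]
        shuffled = predict.PredictionDataset(
            8, dataset.X, Ysh, dataset.groups, dataset.columns
        )
        pred = predict.fit_predict(shuffled, "forest", seed=0, k=5,
                                   grouped=False)
        # per-label accuracy should track the label base rate p (a
        # constant-predicting model attains max(p, 1-p)); allow 3 SE
        for j in range(7):
            p = Ysh[:, j].mean()
            base = max(p, 1 - p)
            acc = (pred[:, j] == Ysh[:, j]).mean()
            se = np.sqrt(base * (1 - base) / dataset.n)
            assert acc <= base + 3 * se + 0.02

    def test_same_seed_identical_predictions(self, dataset):
        a = predict.fit_predict(dataset, "forest", seed=3, k=5)
        b = predict.fit_predict(dataset, "forest", seed=3, k=5)
        np.testing.assert_array_equal(a, b)

    @pytest.mark.parametrize("model", ["svm", "rnn", "attention"])
    def test_all_model_families_run(self, dataset, model):
        sub = predict.PredictionDataset(
            8, dataset.X[:60], dataset.Y[:60], dataset.groups[:60],
            dataset.columns,
        )
        pred = predict.fit_predict(sub, model, seed=0, k=3, grouped=False)
        assert pred.shape == (60, 7)
        assert set(np.unique(pred)) <= {0, 1}


class TestCrossvalidate:
    def test_fold_sizes_123_cases(self):
        cases = synth.generate_cohort(
            synth.CohortConfig(n_patients=41, days_per_patient=(3, 3), seed=9)
        )[:123]
        ds = predict.build_dataset(cases, 1)
        folds = predict._fold_indices(ds, 10, seed=0, grouped=False)
        assert sorted({len(te) for _, te in folds}) == [12, 13]
        assert sum(len(te) for _, te in folds) == 123

    def test_grouped_folds_never_split_patients(self, dataset):
        folds = predict._fold_indices(dataset, 10, seed=0, grouped=True)
        for train_idx, test_idx in folds:
            assert not (
                set(dataset.groups[train_idx]) & set(dataset.groups[test_idx])
            )

    def test_k_exceeding_n_rejected(self, dataset):
        with pytest.raises(ValueError):
            predict._fold_indices(dataset, dataset.n + 1, 0, grouped=False)

    def test_leave_one_out_equivalence(self):
        cases = synth.generate_cohort(
            synth.CohortConfig(n_patients=12, days_per_patient=(1, 1), seed=2)
        )
        ds = predict.build_dataset(cases, 1)
        folds = predict._fold_indices(ds, ds.n, seed=0, grouped=False)
        assert all(len(te) == 1 for _, te in folds)

    def test_report_shapes_and_bounds(self, dataset):
        rep, binary = predict.crossvalidate(dataset, "tree", k=5, seed=0)
        assert len(rep.per_fold) == 5
        assert 0.0 <= rep.emr <= rep.accuracy <= 1.0
        assert 0.0 <= binary.accuracy <= 1.0


class TestEvaluateMultilabel:
    def test_perfect_predictions(self):
        Y = np.eye(7, dtype=int)[:3]
        rep = predict.evaluate_multilabel(Y, Y)
        assert (rep.emr, rep.accuracy, rep.recall, rep.precision, rep.f1) == (
            1.0, 1.0, 1.0, 1.0, 1.0
        )

    def test_half_right_emr(self):
        t = np.array([[1, 0, 1, 0, 1, 0, 1], [1, 1, 1, 1, 1, 1, 1]])
        p = np.array([[1, 0, 1, 0, 1, 0, 1], [0, 0, 0, 0, 0, 0, 0]])
        assert predict.evaluate_multilabel(p, t).emr == 0.5

    def test_three_case_hand_worked_fixture(self):
        # case A: true {0,1}, pred {0,1}     -> J=1, P=1, R=1, F1=1
        # case B: true {0,1,2}, pred {0,3}   -> J=1/4, P=1/2, R=1/3, F1=2/5
        # case C: true {}, pred {4}          -> J=0, P=0, R=0, F1=0
        t = np.zeros((3, 7), dtype=int)
        p = np.zeros((3, 7), dtype=int)
        t[0, [0, 1]] = 1; p[0, [0, 1]] = 1
        t[1, [0, 1, 2]] = 1; p[1, [0, 3]] = 1
        p[2, 4] = 1
        rep = predict.evaluate_multilabel(p, t)
        assert rep.emr == pytest.approx(1 / 3)
        assert rep.accuracy == pytest.approx((1 + 0.25 + 0) / 3)
        assert rep.precision == pytest.approx((1 + 0.5 + 0) / 3)
        assert rep.recall == pytest.approx((1 + 1 / 3 + 0) / 3)
        assert rep.f1 == pytest.approx((1 + 0.4 + 0) / 3)
        # micro from pooled confusion counts: TP=3, FP=2, FN=2, TN=14
        assert rep.micro["precision"] == pytest.approx(3 / 5)
        assert rep.micro["recall"] == pytest.approx(3 / 5)
        assert rep.micro["accuracy"] == pytest.approx(17 / 21)

    def test_emr_bounded_by_accuracy_random(self):
        rng = np.random.default_rng(6)
        for _ in range(50):
            t = rng.integers(0, 2, (20, 7))
            p = rng.integers(0, 2, (20, 7))
            rep = predict.evaluate_multilabel(p, t)
            assert rep.emr <= rep.accuracy + 1e-12

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            predict.evaluate_multilabel(np.zeros((2, 7)), np.zeros((3, 7)))


class TestEvaluateBinary:
    def test_eleven_of_thirteen_correct(self):
        # 13 cases; truth: 5 stressed (5 true labels), 8 not (3 true);
        # two errors: one stressed case predicted 3 shifts, one
        # non-stressed predicted 5
        t = np.zeros((13, 7), dtype=int)
        p = np.zeros((13, 7), dtype=int)
        t[:5, :5] = 1; t[5:, :3] = 1
        p[:5, :5] = 1; p[5:, :3] = 1
        p[0, :] = 0; p[0, :3] = 1      # stressed -> predicted no
        p[5, :5] = 1                   # non-stressed -> predicted yes
        rep = predict.evaluate_binary(p, t)
        assert round(rep.accuracy, 3) == 0.846

    def test_all_yes_recall_one(self):
        t = np.ones((5, 7), dtype=int)
        p = np.ones((5, 7), dtype=int)
        assert predict.evaluate_binary(p, t).recall == 1.0

    def test_no_positive_predictions_zero_precision_with_warning(self):
        t = np.ones((4, 7), dtype=int)
        p = np.zeros((4, 7), dtype=int)
        with pytest.warns(UserWarning, match="precision"):
            rep = predict.evaluate_binary(p, t)
        assert rep.precision == 0.0


def test_deterministic_dependence_emr_grows_with_n():
    """When during-labels are a deterministic function of the inputs,
    the tree ensemble's held-out EMR approaches 1 as n grows."""
    emrs = []
    for n_patients, seed in ((30, 0), (120, 0)):
        cases = synth.generate_cohort(
            synth.CohortConfig(n_patients=n_patients, days_per_patient=(3, 3),
                               seed=seed)
        )
        ds = predict.build_dataset(cases, 1)
        med = np.median(ds.X, axis=0)
        Ydet = (ds.X > med).astype(int)
        det = predict.PredictionDataset(1, ds.X, Ydet, ds.groups, ds.columns)
        pred = predict.fit_predict(det, "forest", seed=1, k=5, grouped=False)
        emrs.append(predict.evaluate_multilabel(pred, Ydet).emr)
    assert emrs[1] > emrs[0]
    assert emrs[1] > 0.9
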