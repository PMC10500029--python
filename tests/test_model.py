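import math

import numpy as np
import pytest

import nichecnn as nc
from nichecnn.neighborhoods import MultiCellInput


def make_model(W, b=None, pooling="max", task="regression", head_w=None, head_b=0.0):
    W = np.atleast_2d(np.asarray(W, float))
    F, M = W.shape
    return nc.TrainedModel(
        filter_weights=W,
        filter_biases=np.zeros(F) if b is None else np.asarray(b, float),
        pooling=pooling,
        head_weights=np.ones(F) if head_w is None else np.asarray(head_w, float),
        head_bias=np.asarray(head_b, float),
        task=task,
        classes=None,
        feature_names=None,
    )


def mci(matrix, label="c"):
    matrix = np.asarray(matrix, float)
    return MultiCellInput(
        matrix=matrix,
        member_cell_ids=np.arange(len(matrix)),
        anchor_cell_id=None,
        image_id="img",
        sample_id="s",
        label=label,
    )


class TestForward:
    def test_hand_evaluated_relu_max_pool(self):
        # one filter w=(1,0), b=0, max pooling, identity head:
        # cells (2,5) and (3,1) respond 2 and 3; max pool -> 3
        m = make_model([[1.0, 0.0]])
        assert nc.forward(m, mci([[2, 5], [3, 1]])) == 3.0

    def test_relu_clips_negative_activations(self):
        m = make_model([[1.0, 0.0]])
        assert nc.forward(m, mci([[-2, 5], [-3, 1]])) == 0.0

    def test_zero_weights_give_head_bias(self):
        m = make_model(np.zeros((2, 3)), head_w=[0.0, 0.0], head_b=1.25)
        rng = np.random.default_rng(0)
        for _ in range(5):
            assert nc.forward(m, mci(rng.normal(size=(6, 3)))) == 1.25

    def test_dimension_mismatch_raises(self):
        m = make_model([[1.0, 0.0]])
        with pytest.raises(ValueError, match="features"):
            nc.forward(m, mci(np.zeros((4, 3))))

    @pytest.mark.parametrize("pooling", ["mean", "max"])
    def test_permutation_invariance_is_exact(self, pooling):
        rng = np.random.default_rng(42)
        for _ in range(20):
            F, K, M = rng.integers(1, 6), int(rng.integers(2, 30)), 5
            m = make_model(rng.normal(size=(F, M)), b=rng.normal(size=F),
                           pooling=pooling, head_w=rng.normal(size=F))
            X = rng.normal(size=(K, M))
            base = m.forward_matrix(X)
            for _ in range(10):
                perm = rng.permutation(K)
                assert m.forward_matrix(X[perm]) == base  # bitwise

    def test_classification_outputs_probabilities(self):
        m = nc.TrainedModel(
            filter_weights=np.ones((2, 3)), filter_biases=np.zeros(2),
            pooling="mean", head_weights=np.ones((2, 3)), head_bias=np.zeros(3),
            task="classification", classes=["a", "b", "c"], feature_names=None,
        )
        out = nc.forward(m, mci(np.ones((4, 3))))
        assert out.shape == (3,) and np.isclose(out.sum(), 1.0)


class TestFilterResponse:
    def test_dot_product(self):
        m = make_model([[1.0, 2.0]])
        assert nc.filter_response(m, np.array([3.0, 4.0]), 0) == 11.0

    def test_zero_vector(self):
        m = make_model(np.random.default_rng(1).normal(size=(3, 4)))
        for f in range(3):
            assert nc.filter_response(m, np.zeros(4), f) == 0.0

    def test_matches_matrix_product_oracle(self):
        rng = np.random.default_rng(2)
        W = rng.normal(size=(4, 6))
        m = make_model(W)
        X = rng.normal(size=(100, 6))
        oracle = X @ W.T
        for f in range(4):
            got = np.array([nc.filter_response(m, x, f) for x in X])
            assert np.allclose(got, oracle[:, f], rtol=0, atol=1e-12)

    def test_index_out_of_range(self):
        m = make_model([[1.0, 0.0]])
        with pytest.raises(IndexError):
            nc.filter_response(m, np.zeros(2), 1)

    def test_positive_scaling_preserves_selection_partition(self):
        rng = np.random.default_rng(3)
        w = rng.normal(size=6)
        X = rng.normal(size=(200, 6))
        r = X @ w
        for c in (0.1, 3.7):
            rc = X @ (c * w)
            assert np.allclose(rc, c * r)
            assert np.array_equal(rc > 0, r > 0)


class TestRegressionMetrics:
    def test_perfect_prediction(self):
        out = nc.regression_metrics([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert out == {"r2": 1.0, "rmse": 0.0}

    def test_hand_example(self):
        out = nc.regression_metrics([1, 2, 3], [1, 2, 4])
        assert math.isclose(out["r2"], 0.5)
        assert math.isclose(out["rmse"], math.sqrt(1 / 3))

    def test_mean_predictor_gives_zero_r2(self):
        y = np.array([2.0, 4.0, 9.0])
        out = nc.regression_metrics(y, np.full(3, y.mean()))
        assert math.isclose(out["r2"], 0.0)

    def test_constant_y_r2_undefined_rmse_returned(self):
        out = nc.regression_metrics([2.0, 2.0], [1.0, 3.0])
        assert out["r2"] is None and math.isclose(out["rmse"], 1.0)

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError):
            nc.regression_metrics([1.0], [1.0, 2.0])


def planted_two_class_inputs(n_per_class=60, k=10, m=4, shift=3.0, seed=0):
    """Class 'pos' neighborhoods carry 3 cells shifted on marker 0."""
    rng = np.random.default_rng(seed)
    inputs = []
    for label, shifted in (("pos", True), ("neg", False)):
        for i in range(n_per_class):
            X = rng.normal(size=(k, m))
            if shifted:
                X[:3, 0] += shift
            sample = f"{label}{i % 6}"
            inputs.append(
                MultiCellInput(
                    matrix=X, member_cell_ids=np.arange(k),
                    anchor_cell_id=None, image_id=sample, sample_id=sample,
                    label=label,
                )
            )
    return inputs


class TestTrain:
    def test_recovers_planted_separable_classes(self):
        inputs = planted_two_class_inputs(n_per_class=80)
        split = nc.SplitAssignment(frozenset(), 0.25, seed=1)
        model, report = nc.train(inputs, split, n_trials=8, seed=2, max_epochs=40)
        assert model.val_score > 0.9
        # the best filter weights favor the discriminative marker
        f = int(np.argmax(np.abs(model.filter_weights).sum(axis=1) > 0))
        w = model.filter_weights[np.argmax(np.abs(model.filter_weights[:, 0]))]
        assert abs(w[0]) > np.abs(w[1:]).max()

    def test_permuted_labels_score_at_chance(self):
        rng = np.random.default_rng(3)
        inputs = planted_two_class_inputs(seed=4)
        labels = [i.label for i in inputs]
        rng.shuffle(labels)
        for inp, lab in zip(inputs, labels):
            inp.label = lab
        # hold out some samples entirely to score on untouched data
        split = nc.SplitAssignment(frozenset({"pos5", "neg5"}), 0.25, seed=5)
        model, report = nc.train(inputs, split, n_trials=3, seed=6, max_epochs=20)
        n_test = 20
        # binomial noise around 1/2: allow 3.5 sigma
        assert abs(report.test_score - 0.5) < 3.5 * math.sqrt(0.25 / n_test)

    def test_seeded_determinism(self):
        inputs = planted_two_class_inputs(seed=7)
        split = nc.SplitAssignment(frozenset(), 0.2, seed=8)
        m1, r1 = nc.train(inputs, split, n_trials=4, seed=9, max_epochs=10)
        m2, r2 = nc.train(inputs, split, n_trials=4, seed=9, max_epochs=10)
        assert m1.hyperparams == m2.hyperparams
        assert m1.val_score == m2.val_score
        assert np.array_equal(m1.filter_weights, m2.filter_weights)

    def test_single_class_rejected(self):
        inputs = [i for i in planted_two_class_inputs() if i.label == "pos"]
        split = nc.SplitAssignment(frozenset(), 0.2, seed=0)
        with pytest.raises(ValueError, match="classes"):
            nc.train(inputs, split, n_trials=1, seed=0)

    def test_zero_variance_regression_rejected(self):
        inputs = planted_two_class_inputs()
        for i in inputs:
            i.label = 1.0
        split = nc.SplitAssignment(frozenset(), 0.2, seed=0)
        with pytest.raises(ValueError, match="variance"):
            nc.train(inputs, split, task="regression", n_trials=1, seed=0)

    def test_regression_learns_linear_signal(self):
        rng = np.random.default_rng(10)
        inputs = []
        for i in range(150):
            X = rng.normal(size=(8, 3))
            label = X[:, 1].mean() + 0.05 * rng.normal()
            sample = f"s{i % 5}"
            inputs.append(
                MultiCellInput(matrix=X, member_cell_ids=np.arange(8),
                               anchor_cell_id=None, image_id=sample,
                               sample_id=sample, label=label)
            )
        split = nc.SplitAssignment(frozenset(), 0.25, seed=11)
        model, report = nc.train(inputs, split, task="regression",
                                 n_trials=6, seed=12, max_epochs=40)
        assert model.n_filters == 2
        assert model.val_score > 0.5
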