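import math
import warnings

import numpy as np
import pytest

from veinsemble.ensemble import (
    TrainConfig,
    ensemble_weights,
    evaluate,
    featurize_samples,
    neg_weight,
    pos_weight,
    predict,
    shared_epochs,
    speed_alpha,
    step_epochs,
    train_basic,
    train_full,
    train_shared,
)
from tests.conftest import TEST_INPUT_SHAPE


def sigmoid(x: float) -> float:
    return 1.0 / (1.0 + math.exp(-x))


class TestSharedEpochs:
    @pytest.mark.parametrize(
        "st,p,expected",
        [
            (1.0, 8, 3),       # 2*floor(2)-1
            (0.3, 8, 0),       # raw -1 clamps to 0
            (0.64, 20, 5),     # 2*floor(3.2)-1
            (0.5, 8, 1),
            (0.99, 4, 0),      # floor(0.99) = 0 -> raw -1 -> 0
            (1.0, 4, 1),
        ],
    )
    def test_values(self, st, p, expected):
        assert shared_epochs(st, p) == expected

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            shared_epochs(0.0, 8)
        with pytest.raises(ValueError):
            shared_epochs(1.2, 8)
        with pytest.raises(ValueError):
            shared_epochs(0.5, 0)


class TestSpeedAlpha:
    def test_zero_loss_is_half(self):
        assert speed_alpha(0.0) == pytest.approx(0.5)

    def test_unit_loss(self):
        assert speed_alpha(1.0) == pytest.approx(1.0 / (1.0 + math.exp(-1.0)), rel=1e-12)

    def test_large_loss_saturates(self):
        assert speed_alpha(10.0) == pytest.approx(0.9999546021312976, rel=1e-9)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            speed_alpha(-0.1)


class TestStepEpochs:
    @pytest.mark.parametrize(
        "alpha,p,expected",
        [(0.5, 10, 5), (0.6, 1, 1), (0.7311, 10, 7), (1.0, 4, 4), (0.51, 2, 1)],
    )
    def test_values(self, alpha, p, expected):
        assert step_epochs(alpha, p) == expected

    def test_bad_alpha_rejected(self):
        with pytest.raises(ValueError):
            step_epochs(0.0, 4)
        with pytest.raises(ValueError):
            step_epochs(1.5, 4)


class TestVoteWeights:
    def test_equal_scores_uniform(self):
        e = pos_weight([0.5] * 6)
        np.testing.assert_allclose(e, 1.0 / 6.0)

    def test_pos_weight_hand_computed(self):
        e = pos_weight([0.9, 0.1])
        s = sigmoid(0.9) + sigmoid(0.1)
        np.testing.assert_allclose(e, [sigmoid(0.9) / s, sigmoid(0.1) / s], rtol=1e-12)

    def test_neg_weight_hand_computed(self):
        e = neg_weight([2.0, 0.5])
        s = sigmoid(2.0) + sigmoid(0.5)
        np.testing.assert_allclose(e, [sigmoid(2.0) / s, sigmoid(0.5) / s], rtol=1e-12)

    def test_sums_to_one(self, rng):
        scores = rng.random(6)
        losses = rng.random(6) * 3
        assert pos_weight(scores).sum() == pytest.approx(1.0)
        assert neg_weight(losses).sum() == pytest.approx(1.0)

    def test_validation(self):
        with pytest.raises(ValueError):
            pos_weight([])
        with pytest.raises(ValueError):
            pos_weight([1.5])
        with pytest.raises(ValueError):
            neg_weight([-1.0])

    def test_single_gated_gets_all_weight(self):
        scores = [0.9, 0.2, 0.3]
        e_plus = pos_weight(scores)
        e_minus = neg_weight([1.0, 1.0, 1.0])
        w, gate = ensemble_weights(e_plus, e_minus, scores)
        assert gate.tolist() == [True, False, False]
        np.testing.assert_allclose(w, [1.0, 0.0, 0.0])

    def test_all_gated_equal_diffs_uniform(self):
        k = 4
        e_plus = np.full(k, 0.25)
        e_minus = np.full(k, 0.25)
        w, gate = ensemble_weights(e_plus, e_minus, [0.9] * k)
        assert gate.all()
        np.testing.assert_allclose(w, 0.25)

    def test_mixed_case_hand_computed(self):
        scores = [0.9, 0.6, 0.2]
        losses = [0.5, 1.5, 2.5]
        e_plus = pos_weight(scores)
        e_minus = neg_weight(losses)
        w, gate = ensemble_weights(e_plus, e_minus, scores)
        assert gate.tolist() == [True, True, False]
        d0 = abs(e_plus[0] - e_minus[0])
        d1 = abs(e_plus[1] - e_minus[1])
        np.testing.assert_allclose(w, [d0 / (d0 + d1), d1 / (d0 + d1), 0.0])
        assert w.sum() == pytest.approx(1.0)

    def test_no_gated_falls_back_uniform_with_warning(self):
        scores = [0.1, 0.2, 0.3]
        with pytest.warns(UserWarning, match="fallback|uniform"):
            w, gate = ensemble_weights(
                pos_weight(scores), neg_weight([1, 1, 1]), scores
            )
        assert not gate.any()
        np.testing.assert_allclose(w, 1.0 / 3.0)


class TestTrainConfig:
    def test_inconsistent_total_rejected(self):
        with pytest.raises(ValueError, match="total_epochs"):
            TrainConfig(k_steps=3, p_epochs=4, total_epochs=10)

    def test_consistent_total_accepted(self):
        cfg = TrainConfig(k_steps=3, p_epochs=4, total_epochs=12)
        assert cfg.total_epochs == 12


@pytest.fixture(scope="module")
def tiny_cfg():
    return TrainConfig(
        k_steps=2, p_epochs=2, lr=0.02, seed=0, input_shape=TEST_INPUT_SHAPE
    )


@pytest.fixture(scope="module")
def basic_model(ds4_features, tiny_cfg):
    tr, _ = ds4_features
    return train_basic(tr, tiny_cfg)


class TestTrainBasic:
    def test_history_lengths(self, basic_model, tiny_cfg):
        for state in basic_model.classifiers:
            assert len(state.loss_history) == tiny_cfg.k_steps
            assert len(state.score_history) == tiny_cfg.k_steps
            assert len(state.epochs_history) == tiny_cfg.k_steps

    def test_schedule_conservation(self, basic_model, tiny_cfg):
        # basic regime: every classifier runs exactly R = K * P own epochs
        total = tiny_cfg.k_steps * tiny_cfg.p_epochs
        for state in basic_model.classifiers:
            assert sum(state.epochs_history) == total

    def test_weight_conservation_each_step(self, basic_model):
        for entry in basic_model.weight_history:
            assert np.isclose(sum(entry["e_plus"]), 1.0)
            assert np.isclose(sum(entry["e_minus"]), 1.0)
            assert np.isclose(sum(entry["w"]), 1.0)

    def test_rejects_multiple_samples_per_class(self, ds4, tiny_cfg):
        with pytest.raises(ValueError, match="single-sample"):
            train_basic(
                featurize_samples(
                    [s for s in ds4.samples if s.session == 1],
                    input_shape=TEST_INPUT_SHAPE,
                ),
                tiny_cfg,
            )

    def test_deterministic(self, ds4_features, tiny_cfg, basic_model):
        tr, _ = ds4_features
        again = train_basic(tr, tiny_cfg)
        np.testing.assert_array_equal(again.weights, basic_model.weights)
        for a, b in zip(again.classifiers, basic_model.classifiers):
            assert a.loss_history == b.loss_history


class TestTrainShared:
    def test_ec_table_matches_similarity(self, ds4_features, tiny_cfg):
        tr, _ = ds4_features
        model = train_shared(tr, tiny_cfg)
        assert model.similarity is not None
        for (i, j), ec in model.ec_table.items():
            assert ec == shared_epochs(model.similarity.pair(i, j), tiny_cfg.p_epochs)

    def test_degenerates_to_basic_when_no_sharing(self, ds4_features, basic_model):
        # P = 2 makes Ec = 0 for every St < 1, so shared == basic
        tr, _ = ds4_features
        cfg = TrainConfig(
            k_steps=2, p_epochs=2, lr=0.02, seed=0, input_shape=TEST_INPUT_SHAPE
        )
        model = train_shared(tr, cfg)
        assert all(ec == 0 for ec in model.ec_table.values())
        np.testing.assert_array_equal(model.weights, basic_model.weights)
        for a, b in zip(model.classifiers, basic_model.classifiers):
            assert a.loss_history == b.loss_history


class TestTrainFull:
    def test_first_step_runs_p_epochs(self, ds4_features, tiny_cfg):
        tr, _ = ds4_features
        model = train_full(tr, tiny_cfg)
        for state in model.classifiers:
            assert state.epochs_history[0] == tiny_cfg.p_epochs

    def test_epoch_counts_follow_loss(self, ds4_features):
        tr, _ = ds4_features
        cfg = TrainConfig(
            k_steps=3, p_epochs=8, lr=0.02, seed=0, input_shape=TEST_INPUT_SHAPE
        )
        model = train_full(tr, cfg)
        for state in model.classifiers:
            for u in range(1, cfg.k_steps):
                expected = step_epochs(
                    speed_alpha(state.loss_history[u - 1]), cfg.p_epochs
                )
                assert state.epochs_history[u] == expected


class TestPredictEvaluate:
    def test_combined_probabilities_sum_to_one(self, basic_model, ds4_features):
        _, te = ds4_features
        sample_img = (te.stack[0, 0] * 255).astype(np.uint8)
        label, probs = predict(basic_model, sample_img)
        assert probs.shape == (4,)
        assert probs.sum() == pytest.approx(1.0, abs=1e-6)
        assert label == probs.argmax()

    def test_single_gated_classifier_matches_weak(self, basic_model, ds4_features):
        _, te = ds4_features
        model = basic_model
        saved_w, saved_gate = model.weights, model.gate
        try:
            model.weights = np.array([0.0, 0.0, 0.0, 0.0, 1.0, 0.0])
            model.gate = model.weights > 0
            result = evaluate(model, te)
            weak = model.classifiers[4].predict_proba(te.stack[4]).argmax(axis=1)
            np.testing.assert_array_equal(
                result.records["predicted_class"].to_numpy(), weak
            )
        finally:
            model.weights, model.gate = saved_w, saved_gate

    def test_accuracy_permutation_invariant(self, basic_model, ds4_features):
        _, te = ds4_features
        acc = evaluate(basic_model, te).accuracy
        rng = np.random.default_rng(0)
        perm = rng.permutation(te.labels.size)
        from veinsemble.ensemble import FeatureData

        shuffled = FeatureData(
            stack=te.stack[:, perm],
            labels=te.labels[perm],
            map_sets=[te.map_sets[i] for i in perm],
            paths=[te.paths[i] for i in perm],
        )
        assert evaluate(basic_model, shuffled).accuracy == pytest.approx(acc)

    def test_label_shuffle_near_chance(self, basic_model, ds4_features):
        _, te = ds4_features
        from veinsemble.ensemble import FeatureData

        accs = []
        for s in range(10):
            rng = np.random.default_rng(s)
            shuffled = FeatureData(
                stack=te.stack,
                labels=rng.permutation(te.labels),
                map_sets=te.map_sets,
                paths=te.paths,
            )
            accs.append(evaluate(basic_model, shuffled).accuracy)
        assert abs(np.mean(accs) - 0.25) < 0.2

    def test_empty_test_set_rejected(self, basic_model, ds4_features):
        _, te = ds4_features
        from veinsemble.ensemble import FeatureData

        empty = FeatureData(
            stack=te.stack[:, :0], labels=te.labels[:0], map_sets=[], paths=[]
        )
        with pytest.raises(ValueError):
            evaluate(basic_model, empty)
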