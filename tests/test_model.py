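"""Pair-tensor assembly, the cross-entropy loss, and CNN training behavior."""

import math

import numpy as np
import pytest

import deepgp
from deepgp import io, model
from deepgp.model import (
    ARCH_PRESETS,
    TrainConfig,
    assemble_pair_tensor,
    bce_loss,
    build_cnn,
    train_cnn,
)


def identity_similarity(d=5):
    return io.DiseaseSimilarity([f"d{i}" for i in range(d)], np.eye(d))


class TestPairTensor:
    def test_three_channels_of_panel_shape(self):
        sim = identity_similarity()
        t = assemble_pair_tensor(np.random.default_rng(0).random((2, 5, 5)), sim, "d2")
        assert t.shape == (3, 5, 5)

    def test_similarity_channel_rows_all_equal(self):
        sim = io.DiseaseSimilarity(
            ["a", "b", "c"],
            np.array([[1, 0.3, 0.2], [0.3, 1, 0.1], [0.2, 0.1, 1.0]]),
        )
        t = assemble_pair_tensor(np.ones((2, 3, 3)) * 0.5, sim, "b")
        assert (t[2] == t[2][0]).all()
        np.testing.assert_allclose(t[2][0], [0.3, 1.0, 0.1])

    def test_identity_similarity_marks_target_column(self):
        sim = identity_similarity()
        t = assemble_pair_tensor(np.ones((2, 5, 5)), sim, "d3")
        expected = np.zeros((5, 5))
        expected[:, 3] = 1.0
        np.testing.assert_array_equal(t[2], expected)

    def test_non_square_panel_rejected(self):
        sim = identity_similarity(4)
        with pytest.raises(io.ValidationError, match="D == K"):
            assemble_pair_tensor(np.ones((2, 4, 5)), sim, "d0")

    def test_unknown_disease_rejected(self):
        with pytest.raises(KeyError, match="dX"):
            assemble_pair_tensor(np.ones((2, 5, 5)), identity_similarity(), "dX")

    def test_symmetrization_idempotence(self):
        # channel 2 depends only on the target row, already symmetric
        S = np.array([[1, 0.4], [0.4, 1.0]])
        sim = io.DiseaseSimilarity(["a", "b"], S)
        sim_sym = io.DiseaseSimilarity(["a", "b"], (S + S.T) / 2)
        g = np.ones((2, 2, 2))
        np.testing.assert_array_equal(
            assemble_pair_tensor(g, sim, "a"), assemble_pair_tensor(g, sim_sym, "a")
        )


class TestBceLoss:
    def test_half_prediction_gives_log_two(self):
        assert bce_loss([0.5], [1]) == pytest.approx(math.log(2), abs=1e-12)
        assert bce_loss([0.5], [0]) == pytest.approx(math.log(2), abs=1e-12)

    def test_symmetry_under_label_flip(self):
        assert bce_loss([0.9], [1]) == pytest.approx(bce_loss([0.1], [0]), abs=1e-12)

    def test_length_mismatch_rejected(self):
        with pytest.raises(io.ValidationError):
            bce_loss([0.5, 0.5], [1])

    def test_minimized_at_label_and_convex_on_grid(self):
        grid = np.linspace(0.01, 0.99, 99)
        for y in (0.0, 1.0):
            vals = np.array([bce_loss([p], [y]) for p in grid])
            assert vals.argmin() == (len(grid) - 1 if y == 1.0 else 0)
            # strict convexity: positive second differences
            assert (np.diff(vals, 2) > 0).all()

    def test_mean_reduction_batch_invariance(self):
        assert bce_loss([0.3, 0.3], [1, 1]) == pytest.approx(
            bce_loss([0.3], [1]), abs=1e-12
        )


class TestBuildCnn:
    def test_output_is_scalar_probability(self):
        m = build_cnn("A", seed=0)
        p = m.predict(np.random.default_rng(1).random((1, 3, 5, 5)))
        assert p.shape == (1,) and 0.0 < p[0] < 1.0

    def test_same_seed_identical_initial_weights(self):
        w1 = build_cnn("A", seed=42).get_weights()
        w2 = build_cnn("A", seed=42).get_weights()
        for a, b in zip(w1, w2):
            np.testing.assert_array_equal(a, b)

    def test_different_seed_different_weights(self):
        w1 = build_cnn("A", seed=1).get_weights()
        w2 = build_cnn("A", seed=2).get_weights()
        assert any((a != b).any() for a, b in zip(w1, w2))

    def test_activation_closed_forms(self):
        from deepgp.nn import sigmoid

        assert np.tanh(0.0) == 0.0
        assert sigmoid(np.array([0.0]))[0] == 0.5
        np.testing.assert_allclose(
            sigmoid(np.array([-2.0, 3.0])),
            1 / (1 + np.exp([2.0, -3.0])),
            atol=1e-15,
        )

    @pytest.mark.parametrize("preset", sorted(ARCH_PRESETS))
    def test_all_presets_build_and_score(self, preset):
        m = build_cnn(preset, seed=3)
        p = m.predict(np.random.default_rng(4).random((7, 3, 5, 5)))
        assert p.shape == (7,) and ((p > 0) & (p < 1)).all()

    def test_unknown_preset_rejected(self):
        with pytest.raises(io.ValidationError, match="preset"):
            build_cnn("Z", seed=0)


def separable_pairs(n=50, seed=0):
    """Planted toy: positives carry small p-values in their disease row."""
    rng = np.random.default_rng(seed)
    sim = identity_similarity()
    tensors, labels = [], []
    for i in range(n):
        label = i % 2
        block = 1.0 - rng.random((2, 5, 5))
        d = int(rng.integers(5))
        if label:
            block[:, d, :] = rng.random((2, 5)) * 0.01
        tensors.append(assemble_pair_tensor(block, sim, f"d{d}"))
        labels.append(label)
    return np.array(tensors), np.array(labels, dtype=float)


class TestTraining:
    def test_overfits_separable_pairs(self):
        tensors, labels = separable_pairs()
        m = build_cnn("A", seed=0)
        history = train_cnn(m, tensors, labels, TrainConfig(epochs=200, seed=0))
        assert history[-1] < 0.05

    def test_loss_decreases_from_initialization(self):
        tensors, labels = separable_pairs(seed=5)
        m = build_cnn("A", seed=1)
        history = train_cnn(m, tensors, labels, TrainConfig(epochs=30, seed=1))
        assert history[-1] < history[0]

    def test_zero_epochs_leaves_model_at_initialization(self):
        tensors, labels = separable_pairs()
        m = build_cnn("A", seed=7)
        before = m.get_weights()
        train_cnn(m, tensors, labels, TrainConfig(epochs=0, seed=7))
        for a, b in zip(before, m.get_weights()):
            np.testing.assert_array_equal(a, b)

    def test_training_is_deterministic_given_seed(self):
        tensors, labels = separable_pairs()
        h1 = train_cnn(
            build_cnn("A", seed=3), tensors, labels, TrainConfig(epochs=20, seed=3)
        )
        h2 = train_cnn(
            build_cnn("A", seed=3), tensors, labels, TrainConfig(epochs=20, seed=3)
        )
        assert h1 == h2

    def test_single_class_training_rejected(self):
        tensors, _ = separable_pairs(n=10)
        with pytest.raises(io.ValidationError, match="both classes"):
            train_cnn(build_cnn("A", 0), tensors, np.ones(10), TrainConfig())


class TestScoring:
    def test_scores_stay_in_unit_interval(self):
        tensors, labels = separable_pairs()
        m = build_cnn("A", seed=0)
        train_cnn(m, tensors, labels, TrainConfig(epochs=5, seed=0))
        wild = np.random.default_rng(8).standard_normal((40, 3, 5, 5)) * 50
        p = m.predict(wild)
        assert ((p >= 0) & (p <= 1)).all()

    def test_repeat_scoring_identical(self):
        tensors, labels = separable_pairs()
        m = build_cnn("B", seed=0)
        train_cnn(m, tensors, labels, TrainConfig(epochs=5, seed=0))
        np.testing.assert_array_equal(m.predict(tensors[:3]), m.predict(tensors[:3]))

    def test_positives_outscore_negatives_on_planted_toy(self):
        tensors, labels = separable_pairs(n=80, seed=2)
        m = build_cnn("A", seed=2)
        train_cnn(m, tensors, labels, TrainConfig(epochs=60, seed=2))
        p = m.predict(tensors)
        assert p[labels == 1].mean() > p[labels == 0].mean()

    def test_shape_mismatch_rejected(self):
        m = build_cnn("A", seed=0)
        with pytest.raises(io.ValidationError, match="input"):
            m.predict(np.ones((1, 3, 4, 4)))


class TestJointPipelineModel:
    def test_joint_gcn_cnn_fit_separates_planted_bundle(self, toy_bundle):
        rc = deepgp.RunConfig(epochs=40, seed=5)
        inputs = deepgp.prepare_inputs(toy_bundle.tables(), rc)
        ds = deepgp.build_labeled_dataset(
            inputs.gene_ids, inputs.disease_ids, inputs.positives, seed=5
        )
        m = deepgp.DeepGP(inputs, rc).fit(ds.pairs, ds.labels, seed=5)
        assert m.loss_history[-1] < m.loss_history[0]
        scores = m.score_pairs(ds.pairs)["score"].to_numpy()
        assert scores[ds.labels == 1].mean() > scores[ds.labels == 0].mean()

    def test_checkpoint_round_trip_reproduces_scores(self, toy_bundle, tmp_path):
        rc = deepgp.RunConfig(epochs=3, seed=5)
        inputs = deepgp.prepare_inputs(toy_bundle.tables(), rc)
        ds = deepgp.build_labeled_dataset(
            inputs.gene_ids, inputs.disease_ids, inputs.positives, seed=5
        )
        m = deepgp.DeepGP(inputs, rc).fit(ds.pairs, ds.labels, seed=5)
        path = tmp_path / "model.npz"
        m.save(path)
        m2 = deepgp.DeepGP.load(path)
        np.testing.assert_allclose(
            m.score_pairs(ds.pairs)["score"],
            m2.score_pairs(ds.pairs)["score"],
            atol=1e-12,
        )
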