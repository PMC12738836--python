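"""Interpretability: attention aggregation, saliency, perturbation importance."""

import numpy as np
import pytest

from plastleader.encoding import CHANNELS, encode
from plastleader.interpret import (PositionProfile, cnn_attention, group_profile,
                                   group_saliency, interpolate_to_length,
                                   lstm_attention, moving_average,
                                   perturbation_importance, saliency)
from plastleader.model import ForwardTrace
from plastleader.nn import autograd as ag
from plastleader.nn.layers import Module
from plastleader.sequences import LeaderSequence


def _trace(conv_features=None, attention=None, n=1):
    zeros = np.zeros((n, 2))
    return ForwardTrace(logits=zeros, probabilities=zeros,
                        conv_features=conv_features, attention=attention,
                        context=zeros)


class TestCnnAttention:
    def test_mean_absolute_activation_over_channels(self):
        F = np.zeros((1, 4, 2))
        F[0, 1] = [3.0, -3.0]  # |3| and |-3| average to 3
        profiles = cnn_attention(_trace(conv_features=F))
        assert profiles[0].values[1] == pytest.approx(3.0)
        assert profiles[0].values[0] == 0.0

    def test_all_zero_features_give_a_zero_profile(self):
        profiles = cnn_attention(_trace(conv_features=np.zeros((2, 5, 3))))
        assert all(np.all(p.values == 0) for p in profiles)

    def test_constant_features_are_an_interpolation_fixed_point(self):
        F = np.full((1, 10, 4), 1.7)
        profiles = cnn_attention(_trace(conv_features=F), length=30)
        np.testing.assert_allclose(profiles[0].values, 1.7, atol=1e-12)
        assert len(profiles[0]) == 30


class TestLstmAttention:
    def test_uniform_attention_gives_constant_one_over_length(self):
        T = 8
        alpha = np.full((1, 2, T, T), 1.0 / T)
        profiles = lstm_attention(_trace(attention=alpha))
        np.testing.assert_allclose(profiles[0].values, 1.0 / T, atol=1e-12)

    def test_received_attention_matches_loop_oracle_on_a_toy_matrix(self):
        # all rows attend position 0: position 0 receives everything
        alpha = np.zeros((1, 1, 4, 4))
        alpha[0, 0, :, 0] = 1.0
        profiles = lstm_attention(_trace(attention=alpha))
        # two-line loop oracle: average of alpha[j, i] over query rows j
        oracle = [sum(alpha[0, 0, j, i] for j in range(4)) / 4 for i in range(4)]
        np.testing.assert_allclose(profiles[0].values, oracle, atol=1e-12)
        assert profiles[0].values[0] == 1.0

    def test_random_stochastic_matrix_matches_loop_oracle(self, rng):
        raw = rng.random((2, 3, 6, 6))
        alpha = raw / raw.sum(axis=-1, keepdims=True)
        profiles = lstm_attention(_trace(attention=alpha, n=2))
        head_avg = alpha.mean(axis=1)
        for n, p in enumerate(profiles):
            oracle = [head_avg[n, :, i].sum() / 6 for i in range(6)]
            np.testing.assert_allclose(p.values, oracle, atol=1e-12)

    def test_unnormalised_rows_are_rejected(self):
        alpha = np.full((1, 1, 3, 3), 0.5)
        with pytest.raises(ValueError, match="normalised"):
            lstm_attention(_trace(attention=alpha))

    def test_single_position_sequence(self):
        alpha = np.ones((1, 4, 1, 1))
        profiles = lstm_attention(_trace(attention=alpha))
        np.testing.assert_array_equal(profiles[0].values, [1.0])


class TestGroupAggregation:
    def _profiles(self, arrays, kind="saliency"):
        return [PositionProfile(a, kind=kind) for a in arrays]

    def test_identical_profiles_aggregate_to_themselves(self, rng):
        v = rng.random(10)
        groups = group_profile(self._profiles([v] * 5), ["c"] * 5)
        np.testing.assert_allclose(groups["c"].values, v, atol=1e-12)
        assert groups["c"].n_aggregated == 5

    def test_mean_of_zero_and_two_is_one(self):
        groups = group_profile(self._profiles([np.zeros(6), np.full(6, 2.0)]),
                               ["c", "c"])
        np.testing.assert_array_equal(groups["c"].values, np.ones(6))

    def test_matches_column_mean_oracle_to_machine_precision(self, rng):
        arrays = [rng.random(20) for _ in range(50)]
        labels = [("x" if i % 2 else "y") for i in range(50)]
        groups = group_profile(self._profiles(arrays), labels)
        for label in ("x", "y"):
            members = np.stack([a for a, l in zip(arrays, labels) if l == label])
            oracle = members.mean(axis=0)
            assert np.abs(groups[label].values - oracle).max() < 1e-12

    def test_mixed_kinds_are_rejected(self):
        p1 = PositionProfile(np.zeros(4), kind="saliency")
        p2 = PositionProfile(np.zeros(4), kind="importance")
        with pytest.raises(ValueError, match="mixed"):
            group_profile([p1, p2], ["a", "b"])


class _LinearScorer(Module):
    """Toy scorer: logits = flattened input @ W; analytic gradients known."""

    def __init__(self, weights):
        super().__init__()
        self.weights = ag.Tensor(weights.astype(np.float32), requires_grad=True)

    def __call__(self, x):
        flat = ag.reshape(x, (x.shape[0], -1))
        return ag.matmul(flat, self.weights)


class TestSaliency:
    def test_linear_scorer_saliency_equals_channel_summed_absolute_weights(self, rng):
        L = 7
        W = rng.normal(size=(L * 5, 2)).astype(np.float32)
        model = _LinearScorer(W)
        data = np.zeros((3, L, 5), dtype=np.float32)
        data[:, :, 0] = 1.0
        pred = (data.reshape(3, -1) @ W).argmax(axis=1)
        profiles = saliency(model, data)
        for p, c in zip(profiles, pred):
            expected = np.abs(W[:, c]).reshape(L, 5).sum(axis=1)
            np.testing.assert_allclose(p.values, expected, atol=1e-6)

    def test_input_ignoring_model_has_zero_saliency(self, tiny_config):
        from plastleader.model import build_model
        model = build_model(tiny_config)
        # cut every path from input to output at the first convolution
        model.conv1.weight.data[:] = 0.0
        model.conv1.bias.data[:] = 0.0
        model.res1.weight.data[:] = 0.0
        model.res1.bias.data[:] = 0.0
        data = np.zeros((2, tiny_config.seq_length, 5), dtype=np.float32)
        data[:, :, 0] = 1.0
        profiles = saliency(model, data)
        for p in profiles:
            np.testing.assert_allclose(p.values, 0.0, atol=1e-7)

    def test_saliency_is_equivariant_to_batch_order(self, rng):
        W = rng.normal(size=(5 * 5, 2))
        model = _LinearScorer(W)
        data = rng.random((4, 5, 5)).astype(np.float32)
        perm = [2, 0, 3, 1]
        p1 = saliency(model, data)
        p2 = saliency(model, data[perm])
        for i, j in enumerate(perm):
            np.testing.assert_allclose(p2[i].values, p1[j].values, atol=1e-7)

    def test_group_saliency_single_member_classes(self, rng):
        arrays = [rng.random(8), rng.random(8)]
        per_sample = [PositionProfile(a, kind="saliency") for a in arrays]
        groups = group_saliency(per_sample, ["a", "b"])
        np.testing.assert_allclose(groups["a"].values, arrays[0], atol=1e-12)
        np.testing.assert_allclose(groups["b"].values, arrays[1], atol=1e-12)


class TestMovingAverage:
    def test_matches_loop_oracle_with_shrinking_edges(self, rng):
        v = rng.random(50)
        for window in (3, 7, 10):
            got = moving_average(v, window)
            half = window // 2
            oracle = np.array([
                v[max(i - half, 0):min(i + half + 1, len(v))].mean()
                for i in range(len(v))
            ])
            assert np.abs(got - oracle).max() < 1e-9

    def test_window_one_is_identity(self, rng):
        v = rng.random(20)
        np.testing.assert_array_equal(moving_average(v, 1), v)


class _ConstantModel:
    """Always predicts class 0 — mutations can never change its output."""

    def predict(self, data, batch_size=256):
        return np.zeros(len(data), dtype=np.int64)


class _MotifOracleModel:
    """Predicts class 1 iff AGGAGG occurs within the proximal 20 nt."""

    def predict(self, data, batch_size=256):
        out = np.zeros(len(data), dtype=np.int64)
        for n, row in enumerate(data):
            seq = "".join(CHANNELS[c] for c in row.argmax(axis=1))
            if "AGGAGG" in seq[-20:]:
                out[n] = 1
        return out


def _encode_strings(seqs, labels):
    leaders = [LeaderSequence(id=f"s{i}", sequence=s, label=l)
               for i, (s, l) in enumerate(zip(seqs, labels))]
    return encode(leaders, len(seqs[0]))


class TestPerturbationImportance:
    def test_constant_model_has_identically_zero_importance(self):
        batch = _encode_strings(["A" * 30] * 8, ["x"] * 8)
        profiles = perturbation_importance(_ConstantModel(), batch,
                                           window_sizes=(1, 4), seed=0)
        for p in profiles.values():
            np.testing.assert_array_equal(p.values, 0.0)
            np.testing.assert_array_equal(p.metadata["raw"], 0.0)

    def test_oracle_classifier_importance_matches_enumeration(self):
        """20-nt toys, motif at a fixed position, k=1: a mutation inside the
        motif destroys classification unless the drawn base equals the
        original. Exhaustive enumeration over the 4 replacement draws gives
        expected importance 3/4 per motif position; Monte-Carlo estimate must
        agree within four binomial standard errors."""
        n, reps = 50, 8
        seqs = ["T" * 10 + "AGGAGG" + "T" * 4] * n  # motif at indices 10..15
        batch = _encode_strings(seqs, ["motif"] * n)
        batch.labels[:] = 1  # oracle model calls these class 1
        profiles = perturbation_importance(
            _MotifOracleModel(), batch, window_sizes=(1,), coarse_step=1,
            refine_threshold=2.0, n_random=reps, seed=3)
        raw = profiles[1].metadata["raw"]
        exact = 0.75  # 3 of 4 enumerated draws destroy the motif base
        se = np.sqrt(exact * (1 - exact) / (n * reps))
        for i in range(10, 16):
            assert abs(raw[i] - exact) < 4 * se
        # windows fully outside the decision-relevant region
        for i in range(0, 10):
            assert raw[i] == 0.0

    def test_importance_lies_in_the_valid_range(self, rng):
        seqs = ["T" * 10 + "AGGAGG" + "T" * 4] * 20
        batch = _encode_strings(seqs, ["motif"] * 20)
        batch.labels[:] = rng.integers(0, 2, 20)  # half the labels are wrong
        profiles = perturbation_importance(_MotifOracleModel(), batch,
                                           window_sizes=(1, 4), coarse_step=2,
                                           seed=1)
        for p in profiles.values():
            assert np.all(p.metadata["raw"] >= -1.0)
            assert np.all(p.metadata["raw"] <= 1.0)

    def test_oversized_window_and_empty_dataset_raise(self):
        batch = _encode_strings(["A" * 10] * 2, ["x"] * 2)
        with pytest.raises(ValueError):
            perturbation_importance(_ConstantModel(), batch, window_sizes=(11,))
        empty = batch.subset([])
        with pytest.raises(ValueError):
            perturbation_importance(_ConstantModel(), empty, window_sizes=(1,))


def test_interpolation_preserves_endpoints_and_length(rng):
    v = rng.random(10)
    out = interpolate_to_length(v, 37)
    assert len(out) == 37
    assert out[0] == pytest.approx(v[0]) and out[-1] == pytest.approx(v[-1])
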