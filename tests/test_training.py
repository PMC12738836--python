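"""Splitting, cross-validation, the metric suite and the training loop."""

from dataclasses import replace

import numpy as np
import pytest

from plastleader.encoding import encode
from plastleader.model import ModelConfig, build_model
from plastleader.sequences import LeaderSequence
from plastleader.training import (MetricsReport, TrainConfig, evaluate,
                                  kfold_indices, metrics_from_scores,
                                  run_cv_experiment, stratified_split, train,
                                  truncation_experiment)
from plastleader.synthetic import SyntheticSpec, MotifPlan, generate_dataset

import metric_oracles
from conftest import random_leader_strings


def _batch(n_a, n_b, length=20, seed=0):
    seqs = random_leader_strings(n_a + n_b, length, 0.7, seed)
    leaders = [LeaderSequence(id=f"s{i}", sequence=s,
                              label="a" if i < n_a else "b")
               for i, s in enumerate(seqs)]
    return encode(leaders, length)


class TestStratifiedSplit:
    def test_balanced_counts(self):
        tr, te = stratified_split(_batch(100, 100), 0.2, seed=0)
        assert np.bincount(tr.labels).tolist() == [80, 80]
        assert np.bincount(te.labels).tolist() == [20, 20]

    def test_deterministic_and_disjoint(self):
        batch = _batch(50, 50)
        tr1, te1 = stratified_split(batch, 0.2, seed=5)
        tr2, te2 = stratified_split(batch, 0.2, seed=5)
        assert tr1.ids == tr2.ids and te1.ids == te2.ids
        assert not set(tr1.ids) & set(te1.ids)
        assert set(tr1.ids) | set(te1.ids) == set(batch.ids)

    def test_imbalanced_proportions_preserved_within_one(self):
        tr, te = stratified_split(_batch(150, 50), 0.2, seed=1)
        counts = np.bincount(te.labels)
        assert abs(counts[0] - 30) <= 1 and abs(counts[1] - 10) <= 1


class TestKfold:
    def test_folds_partition_the_data(self):
        labels = np.repeat([0, 1], 100)
        folds = kfold_indices(labels, 5, seed=2)
        all_idx = np.concatenate(folds)
        assert len(all_idx) == 200 and len(set(all_idx)) == 200

    def test_each_fold_is_stratified(self):
        labels = np.repeat([0, 1], 100)
        for fold in kfold_indices(labels, 5, seed=3):
            counts = np.bincount(labels[fold], minlength=2)
            assert counts.tolist() == [20, 20]

    def test_stratification_against_brute_force_counter(self):
        rng = np.random.default_rng(4)
        labels = rng.integers(0, 2, 83)
        expected = np.bincount(labels)
        for fold in kfold_indices(labels, 4, seed=4):
            counts = np.bincount(labels[fold], minlength=2)
            for c in (0, 1):
                assert abs(counts[c] - expected[c] / 4) <= 1

    def test_k_larger_than_class_raises(self):
        with pytest.raises(ValueError):
            kfold_indices(np.array([0, 0, 1, 1, 1]), 3, seed=0)


class TestMetrics:
    def test_perfect_predictions(self):
        y = np.repeat([0, 1], 25)
        probs = np.stack([1.0 - y, y.astype(float)], axis=1)
        rep = metrics_from_scores(y, probs)
        assert rep.accuracy == 1.0 and rep.mcc == 1.0 and rep.roc_auc == 1.0

    def test_degenerate_all_one_class_predictor(self):
        y = np.repeat([0, 1], 25)
        probs = np.tile([0.4, 0.6], (50, 1))  # always predicts class 1
        rep = metrics_from_scores(y, probs)
        assert rep.accuracy == 0.5 and rep.mcc == 0.0

    def test_single_class_test_set_is_flagged(self):
        y = np.zeros(10, dtype=int)
        probs = np.tile([0.7, 0.3], (10, 1))
        rep = metrics_from_scores(y, probs)
        assert rep.roc_auc is None and "undefined" in rep.notes

    def test_metric_suite_matches_from_formula_oracles(self):
        rng = np.random.default_rng(99)
        y = rng.integers(0, 2, 500)
        scores = np.round(rng.random(500), 3)  # rounding forces score ties
        probs = np.stack([1 - scores, scores], axis=1)
        rep = metrics_from_scores(y, probs)
        y_pred = (scores > 0.5).astype(int)
        assert abs(rep.mcc - metric_oracles.mcc_from_counts(y, y_pred)) < 1e-9
        assert abs(rep.f1_weighted - metric_oracles.weighted_f1(y, y_pred)) < 1e-9
        assert abs(rep.roc_auc - metric_oracles.auc_pairwise(y, scores)) < 1e-9
        assert abs(rep.average_precision
                   - metric_oracles.average_precision_step(y, scores)) < 1e-9
        np.testing.assert_array_equal(rep.confusion,
                                      metric_oracles.confusion(y, y_pred))


@pytest.fixture(scope="module")
def separable_setup():
    """Small separable two-motif dataset and a tiny architecture."""
    spec = SyntheticSpec(
        n_per_class=200, length=60, at_fraction=0.7,
        class_motifs={"a": [MotifPlan("AGGAGG", (-30, -1), 1.0)],
                      "b": [MotifPlan("CCTCCT", (-30, -1), 1.0)]},
        forbidden_motifs={"a": [("CCTCCT", (-30, -1))],
                          "b": [("AGGAGG", (-30, -1))]},
        oligo_tract_rate=0.5, seed=13,
    )
    batch = encode(generate_dataset(spec).leaders, 60)
    config = ModelConfig(seq_length=60, conv_channels=16,
                         channel_attention_reduction=4, lstm_hidden=16,
                         attention_heads=2, fc_sizes=(16, 24), seed=1)
    return batch, config


class TestTrainLoop:
    def test_zero_epochs_leaves_the_model_at_initialisation(self, separable_setup):
        batch, config = separable_setup
        tr, te = stratified_split(batch, 0.2, seed=0)
        model = build_model(config)
        before = {k: v.copy() for k, v in model.state_dict().items()}
        history = train(model, tr, te, TrainConfig(epochs=0, seed=0))
        assert history == []
        after = model.state_dict()
        assert all(np.array_equal(before[k], after[k]) for k in before)

    def test_training_is_deterministic_under_seed(self, separable_setup):
        batch, config = separable_setup
        tr, va = stratified_split(batch, 0.2, seed=0)
        tc = TrainConfig(epochs=2, seed=42)
        m1, m2 = build_model(config), build_model(config)
        h1 = train(m1, tr, va, tc)
        h2 = train(m2, tr, va, tc)
        assert h1 == h2
        s1, s2 = m1.state_dict(), m2.state_dict()
        assert all(np.array_equal(s1[k], s2[k]) for k in s1)

    def test_separable_motifs_reach_high_validation_accuracy(self, separable_setup):
        batch, config = separable_setup
        tr, va = stratified_split(batch, 0.2, seed=0)
        model = build_model(config)
        history = train(model, tr, va, TrainConfig(epochs=10, batch_size=16, seed=0))
        assert max(h.val_accuracy for h in history) >= 0.95

    def test_seed_sweep_accuracy_dispersion_is_small(self, separable_setup):
        batch, config = separable_setup
        tr, va = stratified_split(batch, 0.2, seed=0)
        accs = []
        for seed in (0, 1, 2):
            model = build_model(replace(config, seed=seed))
            train(model, tr, va, TrainConfig(epochs=10, batch_size=16, seed=seed))
            accs.append(evaluate(model, va).accuracy)
        assert max(accs) - min(accs) < 0.05

    def test_empty_sets_raise(self, separable_setup):
        batch, config = separable_setup
        with pytest.raises(ValueError):
            train(build_model(config), batch.subset([]), batch,
                  TrainConfig(epochs=1))


class TestCvExperiment:
    def test_report_has_one_entry_per_fold_and_no_leakage(self, separable_setup):
        batch, config = separable_setup
        tc = TrainConfig(epochs=1, cv_folds=2, seed=0)
        result = run_cv_experiment(batch, config, tc)
        assert len(result.fold_reports) == 2
        total = sum(r.n for r in result.fold_reports)
        assert total == len(batch)  # folds partition the data

    def test_aggregation_matches_hand_computed_mean_and_sd(self, separable_setup):
        batch, config = separable_setup
        tc = TrainConfig(epochs=1, cv_folds=3, seed=1)
        result = run_cv_experiment(batch, config, tc)
        accs = [r.accuracy for r in result.fold_reports]
        assert result.summary.loc["accuracy", "mean"] == pytest.approx(np.mean(accs))
        assert result.summary.loc["accuracy", "sd"] == pytest.approx(
            np.std(accs, ddof=1))


class TestTruncationExperiment:
    def test_remove_zero_yields_identical_reports(self, separable_setup):
        batch, config = separable_setup
        spec = SyntheticSpec(
            n_per_class=60, length=60, at_fraction=0.7,
            class_motifs={"a": [MotifPlan("AGGAGG", (-30, -1), 1.0)], "b": []},
            forbidden_motifs={"b": [("AGGAGG", (-30, -1))]}, seed=8)
        leaders = generate_dataset(spec).leaders
        tc = TrainConfig(epochs=1, seed=0)
        result = truncation_experiment(leaders, config, tc, remove=0)
        assert result.full_report.accuracy == result.truncated_report.accuracy
        np.testing.assert_array_equal(result.full_report.confusion,
                                      result.truncated_report.confusion)

    def test_table_reports_both_arms_and_sd_breakdown(self, separable_setup):
        _, config = separable_setup
        spec = SyntheticSpec(
            n_per_class=60, length=60, at_fraction=0.7,
            class_motifs={"a": [MotifPlan("AGGAGG", (-20, -1), 1.0)], "b": []},
            forbidden_motifs={"b": [("AGGAGG", (-20, -1))]}, seed=9)
        leaders = generate_dataset(spec).leaders
        tc = TrainConfig(epochs=1, seed=0)
        result = truncation_experiment(leaders, config, tc, remove=10)
        table = result.table
        assert set(table["inputs"]) == {"full", "truncated"}
        assert set(table["class"]) == {"a", "b"}
        assert (table["misclassified_with_sd"]
                + table["misclassified_without_sd"]).equals(
                    table["misclassified_total"])
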