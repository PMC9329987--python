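import numpy as np
import pytest
from sklearn.metrics import f1_score, matthews_corrcoef, roc_auc_score

import oracles
from circloc import (
    DescriptorConfig,
    GeneratorSpec,
    ModelConfig,
    auroc_ova,
    confusion_matrix,
    cross_validate,
    grid_search,
    metrics,
    sample_dataset,
    train_predict,
)
from circloc.modeling_eval import ModelConfigError

SCHEMA_AB = ("Exosome", "Cytosol")


class TestConfusionMatrix:
    def test_perfect_prediction_is_diagonal(self):
        cm = confusion_matrix(["a", "a", "b", "b"], ["a", "a", "b", "b"], ("a", "b"))
        np.testing.assert_array_equal(cm.counts, [[2, 0], [0, 2]])

    def test_ovr_tallies_from_hand_count(self):
        cm = confusion_matrix(["a", "a", "b", "b"], ["a", "b", "b", "b"], ("a", "b"))
        t = cm.tallies("a")
        assert (t.tp, t.fn, t.tn, t.fp) == (1, 1, 2, 0)

    def test_empty_inputs_rejected(self):
        with pytest.raises(ValueError):
            confusion_matrix([], [], ("a",))

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="length"):
            confusion_matrix(["a"], ["a", "b"], ("a", "b"))

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError, match="zzz"):
            confusion_matrix(["zzz"], ["zzz"], ("a", "b"))


class TestMetrics:
    def test_perfect_prediction(self):
        cm = confusion_matrix(["a", "b"] * 3, ["a", "b"] * 3, ("a", "b"))
        report = metrics(cm)
        assert (report.accuracy, report.specificity_macro) == (1.0, 1.0)
        assert (report.f1_macro, report.mcc_macro) == (1.0, 1.0)

    def test_mcc_from_hand_tallies(self):
        # class-a OvR tallies TP=2, TN=2, FP=1, FN=1 -> MCC = 1/3 (both classes
        # symmetric here, so the macro equals the per-class value)
        cm = confusion_matrix(
            ["a", "a", "a", "b", "b", "b"], ["a", "a", "b", "b", "b", "a"], ("a", "b")
        )
        assert metrics(cm).mcc_macro == pytest.approx(1 / 3)

    def test_three_of_four_accuracy(self):
        cm = confusion_matrix(["a", "a", "b", "b"], ["a", "a", "b", "a"], ("a", "b"))
        assert metrics(cm).accuracy == 0.75

    def test_undefined_ratios_flagged_and_zeroed(self):
        # class b never predicted and never true-negative-free: precision undefined
        cm = confusion_matrix(["a", "b"], ["a", "a"], ("a", "b"))
        report = metrics(cm)
        assert "b" in report.undefined_classes

    def test_matches_brute_force_on_random_labels(self, rng):
        labels = ("a", "b", "c")
        for _ in range(100):
            true = [labels[i] for i in rng.integers(0, 3, size=30)]
            pred = [labels[i] for i in rng.integers(0, 3, size=30)]
            report = metrics(confusion_matrix(true, pred, labels))
            expected = oracles.naive_macro_metrics(true, pred)
            assert report.accuracy == pytest.approx(expected["accuracy"])
            assert report.specificity_macro == pytest.approx(expected["specificity_macro"])
            assert report.f1_macro == pytest.approx(expected["f1_macro"])
            assert report.mcc_macro == pytest.approx(expected["mcc_macro"])
            assert -1.0 <= report.mcc_macro <= 1.0

    def test_f1_and_per_class_mcc_agree_with_sklearn(self, rng):
        labels = ("a", "b", "c")
        true = [labels[i] for i in rng.integers(0, 3, size=60)]
        pred = [labels[i] for i in rng.integers(0, 3, size=60)]
        report = metrics(confusion_matrix(true, pred, labels))
        assert report.f1_macro == pytest.approx(
            f1_score(true, pred, labels=list(labels), average="macro", zero_division=0)
        )
        per_class_mcc = [
            matthews_corrcoef([t == c for t in true], [p == c for p in pred])
            for c in labels
        ]
        assert report.mcc_macro == pytest.approx(np.mean(per_class_mcc))

    def test_mcc_is_one_iff_diagonal(self):
        diagonal = confusion_matrix(["a", "b", "c"], ["a", "b", "c"], ("a", "b", "c"))
        assert metrics(diagonal).mcc_macro == 1.0
        off = confusion_matrix(["a", "b", "c"], ["a", "c", "b"], ("a", "b", "c"))
        assert metrics(off).mcc_macro < 1.0


class TestAuroc:
    def test_perfect_separation(self):
        truth = ["a", "a", "b", "b"]
        scores = np.array([[0.9, 0.1], [0.8, 0.2], [0.1, 0.9], [0.2, 0.8]])
        _, macro = auroc_ova(truth, scores, ("a", "b"))
        assert macro == 1.0

    def test_constant_scores_are_chance(self):
        truth = ["a", "a", "b"]
        scores = np.full((3, 2), 0.5)
        per_class, macro = auroc_ova(truth, scores, ("a", "b"))
        assert per_class == {"a": 0.5, "b": 0.5}
        assert macro == 0.5

    def test_small_example_matches_pair_counting(self):
        truth = ["a", "a", "b"]
        scores = np.array([[0.9, 0.1], [0.4, 0.6], [0.6, 0.4]])
        per_class, _ = auroc_ova(truth, scores, ("a", "b"))
        # one concordant pair (0.9 > 0.6), one discordant (0.4 < 0.6)
        assert per_class["a"] == oracles.naive_auroc([0.9, 0.4], [0.6]) == 0.5

    def test_matches_pair_oracle_and_sklearn_on_random_scores(self, rng):
        for _ in range(50):
            truth = ["a" if u < 0.4 else "b" for u in rng.random(25)]
            if len(set(truth)) < 2:
                continue
            col = rng.random(25)
            scores = np.column_stack([col, 1 - col])
            per_class, _ = auroc_ova(truth, scores, ("a", "b"))
            pos = [s for t, s in zip(truth, col) if t == "a"]
            neg = [s for t, s in zip(truth, col) if t == "b"]
            assert per_class["a"] == pytest.approx(oracles.naive_auroc(pos, neg))
            assert per_class["a"] == pytest.approx(
                roc_auc_score([t == "a" for t in truth], col)
            )

    def test_invariant_under_monotone_transform(self, rng):
        truth = ["a" if u < 0.5 else "b" for u in rng.random(30)]
        col = rng.random(30)
        scores = np.column_stack([col, 1 - col])
        warped = np.column_stack([np.exp(3 * col), 1 - col])
        a1, _ = auroc_ova(truth, scores, ("a", "b"))
        a2, _ = auroc_ova(truth, warped, ("a", "b"))
        assert a1["a"] == pytest.approx(a2["a"])

    def test_absent_class_skipped_with_warning(self):
        truth = ["a", "a"]
        scores = np.array([[1.0, 0.0], [1.0, 0.0]])
        with pytest.warns(UserWarning):
            per_class, _ = auroc_ova(truth, scores, ("a", "b"))
        assert "b" not in per_class

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shape"):
            auroc_ova(["a", "b"], np.zeros((2, 3)), ("a", "b"))


class TestTrainPredict:
    @pytest.mark.parametrize(
        "model_id", ["random_forest", "xgboost", "adaboost", "svm", "naive_bayes"]
    )
    def test_scores_row_stochastic_and_deterministic(self, model_id, tiny_records):
        config = DescriptorConfig("kmer", k=2)
        model = ModelConfig(model_id)
        test_seqs = [r.sequence for r in tiny_records[:6]]
        labels1, scores1 = train_predict(
            tiny_records, test_seqs, config, model, seed=1, schema=SCHEMA_AB
        )
        labels2, scores2 = train_predict(
            tiny_records, test_seqs, config, model, seed=1, schema=SCHEMA_AB
        )
        np.testing.assert_allclose(scores1.sum(axis=1), 1.0, atol=1e-9)
        assert labels1 == labels2
        np.testing.assert_array_equal(scores1, scores2)
        assert set(labels1) <= set(SCHEMA_AB)

    def test_training_accuracy_at_least_held_out(self, tiny_records):
        config = DescriptorConfig("kmer", k=2)
        model = ModelConfig("random_forest")
        train, held_out = tiny_records[:16], tiny_records[16:]
        train_pred, _ = train_predict(
            train, [r.sequence for r in train], config, model, schema=SCHEMA_AB
        )
        held_pred, _ = train_predict(
            train, [r.sequence for r in held_out], config, model, schema=SCHEMA_AB
        )
        acc_train = np.mean([p == r.locality for p, r in zip(train_pred, train)])
        acc_held = np.mean([p == r.locality for p, r in zip(held_pred, held_out)])
        assert acc_train >= acc_held

    def test_single_class_training_rejected(self, tiny_records):
        one_class = [r for r in tiny_records if r.locality == "Exosome"]
        with pytest.raises(ValueError, match="two classes"):
            train_predict(
                one_class,
                [one_class[0].sequence],
                DescriptorConfig("zcurve"),
                ModelConfig("naive_bayes"),
                schema=SCHEMA_AB,
            )


class TestCrossValidate:
    def test_folds_partition_dataset(self, tiny_records):
        result = cross_validate(
            tiny_records, DescriptorConfig("kmer", k=2), ModelConfig("naive_bayes"),
            folds=4, seed=0, schema=SCHEMA_AB,
        )
        assert len(result.fold_assignment) == len(tiny_records)
        assert set(result.fold_assignment) == set(range(4))

    def test_same_seed_reproduces_folds_and_metrics(self, tiny_records):
        args = (DescriptorConfig("kmer", k=2), ModelConfig("random_forest"))
        r1 = cross_validate(tiny_records, *args, folds=4, seed=9, schema=SCHEMA_AB)
        r2 = cross_validate(tiny_records, *args, folds=4, seed=9, schema=SCHEMA_AB)
        np.testing.assert_array_equal(r1.fold_assignment, r2.fold_assignment)
        assert r1.mean_report.accuracy == r2.mean_report.accuracy

    def test_shuffled_input_order_gives_identical_mean_metrics(self, tiny_records, rng):
        shuffled = list(tiny_records)
        rng.shuffle(shuffled)
        args = (DescriptorConfig("kmer", k=2), ModelConfig("naive_bayes"))
        r1 = cross_validate(tiny_records, *args, folds=4, seed=3, schema=SCHEMA_AB)
        r2 = cross_validate(shuffled, *args, folds=4, seed=3, schema=SCHEMA_AB)
        assert r1.mean_report.as_dict() == r2.mean_report.as_dict()

    def test_small_class_downgrades_folds_with_warning(self, tiny_records):
        subset = tiny_records[:8] + [r for r in tiny_records if r.locality == "Cytosol"][:3]
        with pytest.warns(UserWarning, match="downgrading"):
            result = cross_validate(
                subset, DescriptorConfig("zcurve"), ModelConfig("naive_bayes"),
                folds=10, seed=0, schema=SCHEMA_AB,
            )
        assert result.n_folds < 10

    def test_tiny_class_is_an_error(self, tiny_records):
        exosome = [r for r in tiny_records if r.locality == "Exosome"]
        subset = exosome[:4] + [r for r in tiny_records if r.locality == "Cytosol"][:1]
        with pytest.raises(ValueError, match="at least 2"):
            cross_validate(
                subset, DescriptorConfig("zcurve"), ModelConfig("naive_bayes"),
                schema=SCHEMA_AB,
            )


class TestGridSearch:
    def test_singleton_grids_return_that_configuration(self, tiny_records):
        featurizer = DescriptorConfig("kmer", k=2)
        model = ModelConfig.make("random_forest", n_estimators=20)
        result = grid_search(
            tiny_records, [featurizer], [model], folds=3, seed=0, schema=SCHEMA_AB
        )
        assert result.best_featurizer == featurizer
        assert result.best_model == model

    def test_leaderboard_is_exhaustive_and_best_dominates(self, tiny_records):
        featurizers = [DescriptorConfig("kmer", k=2), DescriptorConfig("zcurve")]
        models = [
            ModelConfig.make("naive_bayes", var_smoothing=1e-9),
            ModelConfig.make("random_forest", n_estimators=20),
        ]
        result = grid_search(
            tiny_records, featurizers, models, folds=3, seed=0, schema=SCHEMA_AB
        )
        assert len(result.leaderboard) == 4
        best_acc = result.best_result.mean_report.accuracy
        assert all(best_acc >= r.mean_report.accuracy for _, _, r in result.leaderboard)

    def test_out_of_bounds_grid_rejected(self, tiny_records):
        with pytest.raises(ModelConfigError, match="n_estimators"):
            grid_search(
                tiny_records,
                [DescriptorConfig("zcurve")],
                [ModelConfig.make("random_forest", n_estimators=500)],
                folds=2, schema=SCHEMA_AB,
            )
        with pytest.raises(ModelConfigError, match="k outside"):
            grid_search(
                tiny_records,
                [DescriptorConfig("kmer", k=6)],
                [ModelConfig("naive_bayes")],
                folds=2, schema=SCHEMA_AB,
            )
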