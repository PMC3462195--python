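"""SVM training, scoring, AUROC, nested CV, interpretation, selection."""

import numpy as np
import pandas as pd
import pytest

from secprod.features import assemble_features
from secprod.model_eval import (
    TrainedModel,
    WeightVector,
    auroc,
    compare_weight_vectors,
    correlate_weights_with_property,
    decision_scores,
    extract_weight_vector,
    forward_feature_selection,
    load_model,
    nested_cv,
    normalize_contributions,
    save_model,
    train_linear_svm,
    transfer_evaluate,
)
from secprod.synthetic_data import labels_vector


def _random_problem(seed=0, n=40, p=5, separation=2.0):
    rng = np.random.default_rng(seed)
    y = np.array([1] * (n // 2) + [-1] * (n // 2))
    X = rng.normal(size=(n, p))
    X[:, 0] += separation * y
    return pd.DataFrame(X, columns=[f"x{i}" for i in range(p)]), y


class TestTrainLinearSvm:
    def test_symmetric_1d_problem(self):
        X = pd.DataFrame({"x": [1.0, 1.2, 0.8, -1.0, -1.2, -0.8]})
        y = np.array([1, 1, 1, -1, -1, -1])
        model = train_linear_svm(X, y, C=1.0)
        w = extract_weight_vector(model)
        assert w["x"] > 0
        assert abs(model.bias) < 1e-6

    def test_kernel_expansion_equals_explicit_weights(self):
        X, y = _random_problem(seed=1)
        model = train_linear_svm(X, y, C=1.0)
        w = extract_weight_vector(model)
        X_test, _ = _random_problem(seed=2, n=20)
        expansion = decision_scores(model, X_test)
        explicit = X_test.values @ w.values.values + model.bias
        assert np.allclose(expansion, explicit, atol=1e-6)

    def test_duplicated_training_set_same_decision_function(self):
        X, y = _random_problem(seed=3)
        m1 = train_linear_svm(X, y)
        X2 = pd.concat([X, X], ignore_index=True)
        m2 = train_linear_svm(X2, np.concatenate([y, y]))
        probe, _ = _random_problem(seed=4, n=10)
        assert np.allclose(
            decision_scores(m1, probe), decision_scores(m2, probe), atol=1e-4
        )

    def test_single_class_rejected(self):
        X, _ = _random_problem()
        with pytest.raises(ValueError):
            train_linear_svm(X, np.ones(len(X), dtype=int))

    def test_support_vector_on_margin(self):
        # separable data: KKT conditions put the margin support vectors at
        # decision score +-1
        X = pd.DataFrame({"x": [2.0, 3.0, -2.0, -3.0]})
        y = np.array([1, 1, -1, -1])
        model = train_linear_svm(X, y, C=100.0)
        scores = decision_scores(model, X)
        assert np.isclose(np.abs(scores).min(), 1.0, atol=1e-3)


class TestDecisionScores:
    def test_column_mismatch_listed(self):
        X, y = _random_problem()
        model = train_linear_svm(X, y)
        bad = X.rename(columns={"x0": "other"})
        with pytest.raises(ValueError, match="x0"):
            decision_scores(model, bad)

    def test_empty_matrix(self):
        X, y = _random_problem()
        model = train_linear_svm(X, y)
        assert decision_scores(model, X.iloc[:0]).shape == (0,)

    def test_linearity(self):
        X, y = _random_problem()
        model = train_linear_svm(X, y)
        s1 = decision_scores(model, X) - model.bias
        s2 = decision_scores(model, 2 * X) - model.bias
        assert np.allclose(s2, 2 * s1, atol=1e-8)

    def test_json_roundtrip(self, tmp_path):
        X, y = _random_problem()
        model = train_linear_svm(X, y)
        path = tmp_path / "model.json"
        save_model(model, path)
        loaded = load_model(path)
        assert np.allclose(decision_scores(loaded, X), decision_scores(model, X))


class TestAuroc:
    def test_perfect_and_random(self):
        labels = [1, 1, -1, -1]
        assert auroc([4, 3, 2, 1], labels) == 1.0
        assert auroc([1, 1, 1, 1], labels) == 0.5

    def test_negation_symmetry(self):
        rng = np.random.default_rng(0)
        scores = rng.normal(size=30)
        labels = rng.choice([1, -1], size=30)
        assert auroc(-scores, labels) == pytest.approx(1 - auroc(scores, labels))

    def test_matches_sklearn(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(1)
        scores = rng.normal(size=50)
        scores[::5] = scores[0]  # inject ties
        labels = rng.choice([1, -1], size=50)
        assert auroc(scores, labels) == pytest.approx(
            roc_auc_score(labels, scores)
        )

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(2)
        scores = rng.normal(size=40)
        labels = rng.choice([1, -1], size=40)
        assert auroc(np.exp(scores), labels) == pytest.approx(auroc(scores, labels))

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            auroc([1, 2], [1, 1])


class TestNestedCv:
    def test_deterministic_and_partitioning(self, small_dataset):
        records, annotations = small_dataset
        X = assemble_features(records, annotations, "f2")
        y = labels_vector(records)
        r1 = nested_cv(X, y, outer_folds=5, inner_folds=3, seed=3,
                       C_grid=(0.1, 1.0, 10.0))
        r2 = nested_cv(X, y, outer_folds=5, inner_folds=3, seed=3,
                       C_grid=(0.1, 1.0, 10.0))
        assert r1.fold_aurocs == r2.fold_aurocs
        assert np.array_equal(r1.fold_assignments, r2.fold_assignments)
        # every record tested exactly once, folds stratified
        assert len(r1.fold_assignments) == len(y)
        for fold in range(5):
            mask = r1.fold_assignments == fold
            assert mask.sum() == len(y) // 5
            assert (y[mask] == 1).sum() == mask.sum() // 2
        assert r1.mean_auroc == pytest.approx(np.mean(r1.fold_aurocs))

    def test_separable_synthetic_high_auroc(self, medium_dataset):
        records, annotations = medium_dataset
        X = assemble_features(records, annotations, "f2")
        y = labels_vector(records)
        result = nested_cv(X, y, outer_folds=5, inner_folds=5, seed=0,
                           C_grid=(0.1, 1.0, 10.0))
        assert result.mean_auroc >= 0.95

    def test_permuted_labels_near_chance(self, medium_dataset):
        records, annotations = medium_dataset
        X = assemble_features(records, annotations, "f2")
        y = labels_vector(records)
        rng = np.random.default_rng(0)
        y_perm = rng.permutation(y)
        result = nested_cv(X, y_perm, outer_folds=5, inner_folds=5, seed=0,
                           C_grid=(0.1, 1.0, 10.0))
        assert 0.35 <= result.mean_auroc <= 0.65

    def test_too_few_examples_suggests_fewer_folds(self):
        X, y = _random_problem(n=10)
        with pytest.raises(ValueError, match="folds"):
            nested_cv(X, y, outer_folds=10)


class TestWeightInterpretation:
    def test_empty_model_zero_vector(self):
        model = TrainedModel(
            support_coeffs=np.empty(0),
            support_features=np.empty((0, 3)),
            bias=0.0,
            C=1.0,
            column_names=("a", "b", "c"),
        )
        w = extract_weight_vector(model)
        assert (w.values == 0).all()

    def test_planted_signs_recovered(self, medium_dataset):
        records, annotations = medium_dataset
        X = assemble_features(records, annotations, "f2")
        y = labels_vector(records)
        w = extract_weight_vector(train_linear_svm(X, y, C=1.0))
        assert w["comp:Y"] > 0
        assert w["comp:N"] > 0
        assert w["comp:K"] < 0
        assert w["comp:M"] < 0

    def test_normalize(self):
        w = WeightVector(pd.Series({"a": 2.0, "b": -4.0}))
        n = normalize_contributions(w)
        assert n["a"] == pytest.approx(0.5)
        assert n["b"] == pytest.approx(-1.0)
        again = normalize_contributions(n)
        assert np.allclose(again.values.values, n.values.values)
        neg = normalize_contributions(WeightVector(pd.Series({"a": -3.0})))
        assert neg["a"] == -1.0
        with pytest.raises(ValueError):
            normalize_contributions(WeightVector(pd.Series({"a": 0.0})))

    def test_compare_weight_vectors(self):
        w = WeightVector(pd.Series({"a": 1.0, "b": 2.0, "c": -1.0}))
        assert compare_weight_vectors(w, w) == pytest.approx(1.0)
        neg = WeightVector(-w.values)
        assert compare_weight_vectors(w, neg) == pytest.approx(-1.0)
        other = WeightVector(pd.Series({"a": 1.0, "z": 2.0, "c": -1.0}))
        with pytest.raises(ValueError):
            compare_weight_vectors(w, other)

    def test_property_correlation(self):
        w = WeightVector(pd.Series({"A": 1.0, "C": 2.0, "D": -1.0, "E": 0.5}))
        prop = {k: float(v) for k, v in w.values.items()}
        r, _ = correlate_weights_with_property(w, prop)
        assert r == pytest.approx(1.0)
        r, _ = correlate_weights_with_property(w, {k: -v for k, v in prop.items()})
        assert r == pytest.approx(-1.0)
        with pytest.raises(ValueError):
            correlate_weights_with_property(w, {"A": 1.0, "C": 2.0})

    def test_property_exclusion_list(self):
        w = WeightVector(pd.Series({"A": 1.0, "C": 2.0, "D": 3.0, "F": -50.0}))
        prop = {"A": 1.0, "C": 2.0, "D": 3.0, "F": 100.0}
        r_with, _ = correlate_weights_with_property(w, prop)
        r_without, _ = correlate_weights_with_property(w, prop, exclude=("F",))
        assert r_without > r_with
        assert r_without == pytest.approx(1.0)


class TestForwardSelection:
    def _planted(self, seed=0):
        rng = np.random.default_rng(seed)
        n = 60
        y = np.array([1] * (n // 2) + [-1] * (n // 2))
        X = pd.DataFrame(
            {
                "signal": y * 3.0 + rng.normal(0, 0.1, n),
                "noise1": rng.normal(size=n),
                "noise2": rng.normal(size=n),
            }
        )
        return X, y

    def test_perfect_feature_selected_first_then_stops(self):
        X, y = self._planted()
        result = forward_feature_selection(
            X, y, ["noise1", "signal", "noise2"], folds=5, seed=0
        )
        assert result.selected[0] == "signal"
        assert result.scores[0] == 1.0
        # nothing can beat a perfect score; ties extend, drops stop — either
        # way "signal" must lead and the trajectory never decreases
        assert list(result.scores) == sorted(result.scores)

    def test_deterministic(self):
        X, y = self._planted(seed=1)
        r1 = forward_feature_selection(X, y, list(X.columns), folds=5, seed=2)
        r2 = forward_feature_selection(X, y, list(X.columns), folds=5, seed=2)
        assert r1.selected == r2.selected
        assert r1.scores == r2.scores

    def test_empty_candidates_rejected(self):
        X, y = self._planted()
        with pytest.raises(ValueError):
            forward_feature_selection(X, y, [], folds=5)


class TestTransferEvaluate:
    def test_resubstitution_is_optimistic(self, small_dataset):
        records, annotations = small_dataset
        X = assemble_features(records, annotations, "f2")
        y = labels_vector(records)
        from secprod.model_eval import select_C

        _, inner = select_C(X, y, (0.1, 1.0, 10.0), folds=5, seed=0)
        result = transfer_evaluate(X, y, X, y, (0.1, 1.0, 10.0), folds=5, seed=0)
        assert result.auroc >= inner

    def test_generalizes_across_independent_draws(self, medium_dataset):
        from secprod.synthetic_data import EffectConfig, generate_proteins

        records, annotations = medium_dataset
        X_tr = assemble_features(records, annotations, "f2")
        y_tr = labels_vector(records)
        recs2, ann2 = generate_proteins(100, 100, EffectConfig(), seed=99)
        X_te = assemble_features(recs2, ann2, "f2")
        y_te = labels_vector(recs2)
        result = transfer_evaluate(X_tr, y_tr, X_te, y_te, (0.1, 1.0, 10.0),
                                   folds=5, seed=0)
        assert result.auroc >= 0.9

    def test_flipped_labels_symmetry(self, small_dataset):
        records, annotations = small_dataset
        X = assemble_features(records, annotations, "f2")
        y = labels_vector(records)
        r = transfer_evaluate(X, y, X, y, (1.0,), folds=5, seed=0)
        r_flip = transfer_evaluate(X, y, X, -y, (1.0,), folds=5, seed=0)
        assert r_flip.auroc == pytest.approx(1 - r.auroc)

    def test_column_mismatch_rejected(self, small_dataset):
        records, annotations = small_dataset
        X = assemble_features(records, annotations, "f2")
        y = labels_vector(records)
        with pytest.raises(ValueError):
            transfer_evaluate(X, y, X.iloc[:, :5], y, (1.0,), folds=5)
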