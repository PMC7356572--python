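import itertools

import numpy as np
import pytest

from hsiderm.classification import (
    ClassifierKind,
    GAConfig,
    HyperparameterSet,
    ParamSpec,
    default_search_space,
    ga_optimize,
    predict,
    train_classifier,
)
from hsiderm.labeling import LabeledSpectraSet
from hsiderm.metrics import roc_auc


def _separable_set(n_per_class=20, bands=8, seed=0, patients=("A", "B", "C", "D")):
    """Two lesion classes separated by a clean spectral offset."""
    rng = np.random.default_rng(seed)
    benign = rng.normal(0.3, 0.02, (n_per_class, bands))
    malignant = rng.normal(0.7, 0.02, (n_per_class, bands))
    spectra = np.vstack([benign, malignant])
    classes = np.array(["benign"] * n_per_class + ["malignant"] * n_per_class, dtype=object)
    n = 2 * n_per_class
    return LabeledSpectraSet(
        spectra=spectra,
        classes=classes,
        patient_id=np.array([patients[i % len(patients)] for i in range(n)], dtype=object),
        image_id=np.array([f"I{i}" for i in range(n)], dtype=object),
        wavelengths_nm=np.linspace(450, 950, bands),
    )


class TestTrainPredict:
    def test_linear_svm_separates_separable_set(self):
        train = _separable_set()
        model = train_classifier(train, HyperparameterSet(classifier="svm_linear"), seed=0)
        labels, scores = predict(model, train.spectra)
        assert list(labels) == list(train.classes)
        y = train.classes == "malignant"
        assert scores[y].min() > 0.5 and scores[~y].max() < 0.5

    def test_single_tree_rf_memorizes_two_samples(self):
        train = _separable_set(n_per_class=1)
        model = train_classifier(
            train, HyperparameterSet(classifier="rf", n_trees=1), seed=0
        )
        labels, _ = predict(model, train.spectra)
        assert list(labels) == list(train.classes)

    @pytest.mark.parametrize("kind", [k.value for k in ClassifierKind])
    def test_deterministic_given_seed(self, kind):
        train = _separable_set()
        runs = []
        for _ in range(2):
            model = train_classifier(train, HyperparameterSet(classifier=kind), seed=5)
            runs.append(predict(model, train.spectra)[1])
        np.testing.assert_array_equal(runs[0], runs[1])

    def test_single_class_training_rejected(self):
        train = _separable_set()
        only_benign = train.subset(train.classes == "benign")
        with pytest.raises(ValueError):
            train_classifier(only_benign, HyperparameterSet(classifier="svm_linear"))

    def test_feature_mismatch_rejected(self):
        model = train_classifier(_separable_set(), HyperparameterSet(classifier="svm_linear"))
        with pytest.raises(ValueError):
            predict(model, np.zeros((3, 5)))

    def test_empty_matrix_gives_empty_output(self):
        model = train_classifier(_separable_set(), HyperparameterSet(classifier="svm_linear"))
        labels, scores = predict(model, np.empty((0, 8)))
        assert labels.size == 0 and scores.size == 0

    def test_duplicated_row_gives_identical_outputs(self):
        model = train_classifier(_separable_set(), HyperparameterSet(classifier="rf", n_trees=15))
        row = _separable_set().spectra[3]
        _, scores = predict(model, np.vstack([row, row]))
        assert scores[0] == scores[1]

    def test_scores_in_unit_interval(self):
        train = _separable_set()
        for kind in ClassifierKind:
            model = train_classifier(train, HyperparameterSet(classifier=kind), seed=0)
            _, scores = predict(model, train.spectra)
            assert scores.min() >= 0.0 and scores.max() <= 1.0


class TestHyperparameterSet:
    def test_invalid_values_rejected(self):
        with pytest.raises(ValueError):
            HyperparameterSet(classifier="svm_linear", C=-1)
        with pytest.raises(ValueError):
            HyperparameterSet(classifier="rf", n_trees=0)
        with pytest.raises(ValueError):
            HyperparameterSet(classifier="ann", neurons=(1, 1, 1))

    def test_search_spaces_cover_published_optima(self):
        # tuned values of the order C~94, gamma~8.4, slope~-9.5, cf~-14.2,
        # n_trees~3, neurons~443 must be inside the default bounds
        space = {p.name: p for p in default_search_space(ClassifierKind.SVM_RBF)}
        assert space["C"].low <= 94.07 <= space["C"].high
        assert space["gamma"].low <= 8.43 <= space["gamma"].high
        space = {p.name: p for p in default_search_space(ClassifierKind.SVM_SIGMOID)}
        assert space["slope"].low <= -9.53 <= space["slope"].high
        assert space["intercept"].low <= -14.22 <= space["intercept"].high
        space = {p.name: p for p in default_search_space(ClassifierKind.ANN)}
        assert space["neurons_2"].low <= 443 <= space["neurons_2"].high


def _noisy_split(seed=3):
    """Harder two-class problem so AUC varies with hyperparameters."""
    rng = np.random.default_rng(seed)

    def block(mean, n, patients):
        spectra = rng.normal(mean, 0.25, (n, 6))
        classes = np.array(
            ["benign" if mean < 0.5 else "malignant"] * n, dtype=object
        )
        return spectra, classes, np.array(
            [patients[i % len(patients)] for i in range(n)], dtype=object
        )

    def build(patients):
        sb, cb, pb = block(0.35, 30, patients)
        sm, cm, pm = block(0.6, 30, patients)
        spectra = np.vstack([sb, sm])
        return LabeledSpectraSet(
            spectra=spectra,
            classes=np.concatenate([cb, cm]),
            patient_id=np.concatenate([pb, pm]),
            image_id=np.array([f"I{i}" for i in range(60)], dtype=object),
            wavelengths_nm=np.linspace(450, 950, 6),
        )

    return build(("A", "B")), build(("C", "D"))


class TestGaOptimize:
    def test_collapsed_space_returns_that_point(self):
        train, val = _noisy_split()
        cfg = GAConfig(
            population=4,
            generations=2,
            seed=0,
            bounds=(ParamSpec("n_trees", 7, 7, integer=True),),
        )
        best, _ = ga_optimize(ClassifierKind.RF, train, val, cfg)
        assert best.n_trees == 7

    def test_matches_exhaustive_search_on_enumerable_space(self):
        train, val = _noisy_split()
        space = ParamSpec("n_trees", 1, 8, integer=True)
        # independent oracle: brute-force every n_trees value
        y_val = (val.classes == "malignant").astype(int)
        oracle = {}
        for n_trees in range(1, 9):
            hp = HyperparameterSet(classifier="rf", n_trees=n_trees)
            model = train_classifier(train, hp, seed=7)
            _, scores = predict(model, val.spectra)
            oracle[n_trees] = roc_auc(scores, y_val)
        best_auc = max(oracle.values())

        cfg = GAConfig(population=10, generations=6, seed=7, bounds=(space,))
        ga_best, ga_auc = ga_optimize(ClassifierKind.RF, train, val, cfg)
        assert ga_auc == pytest.approx(best_auc, abs=1e-12)
        assert oracle[ga_best.n_trees] == pytest.approx(best_auc, abs=1e-12)

    def test_result_at_least_default_auc(self):
        train, val = _noisy_split(seed=9)
        y_val = (val.classes == "malignant").astype(int)
        default_model = train_classifier(
            train, HyperparameterSet(classifier="svm_rbf"), seed=2
        )
        _, default_scores = predict(default_model, val.spectra)
        default_auc = roc_auc(default_scores, y_val)
        cfg = GAConfig(population=6, generations=2, seed=2)
        _, ga_auc = ga_optimize(ClassifierKind.SVM_RBF, train, val, cfg)
        assert ga_auc >= default_auc - 1e-12

    def test_deterministic_given_seed(self):
        train, val = _noisy_split()
        cfg = GAConfig(
            population=6, generations=2, seed=4,
            bounds=(ParamSpec("n_trees", 1, 10, integer=True),),
        )
        a = ga_optimize(ClassifierKind.RF, train, val, cfg)
        b = ga_optimize(ClassifierKind.RF, train, val, cfg)
        assert a == b

    def test_shared_patients_rejected(self):
        train, _ = _noisy_split()
        with pytest.raises(ValueError, match="share patients"):
            ga_optimize(ClassifierKind.RF, train, train, GAConfig(population=4, generations=1))
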