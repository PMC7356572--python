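"""Supervised benign/malignant pixel classifiers and GA hyperparameter tuning.

Five classifier families are supported — SVM with linear, RBF or sigmoid
kernel, random forest, and a four-hidden-layer feed-forward neural
network — all producing a per-pixel malignancy score in [0, 1].

Hyperparameters are tuned with a real-coded genetic algorithm that
maximizes the ROC AUC of a model trained on the training set and scored
on a patient-disjoint validation set.  The GA uses tournament selection
(size 3), blend crossover, Gaussian mutation clipped to the search
bounds, elitism, and injects the default hyperparameters into the
initial population, so the tuned result can never score below the
default on the same validation set.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC


class _PlattSVC:
    """SVC wrapper with Platt-style probability calibration: a logistic
    model fitted on the training decision values maps margins to [0, 1]."""

    def __init__(self, svc: SVC):
        self.svc = svc

    def fit(self, X, y):
        self.svc.fit(X, y)
        margins = self.svc.decision_function(X).reshape(-1, 1)
        self.platt_ = LogisticRegression(C=1e3).fit(margins, y)
        self.classes_ = self.platt_.classes_
        return self

    def predict_proba(self, X):
        margins = self.svc.decision_function(X).reshape(-1, 1)
        return self.platt_.predict_proba(margins)

from .labeling import LabeledSpectraSet
from .metrics import roc_auc

__all__ = [
    "ClassifierKind",
    "HyperparameterSet",
    "TrainedModel",
    "GAConfig",
    "train_classifier",
    "predict",
    "ga_optimize",
    "default_search_space",
]

POSITIVE_CLASS = "malignant"
NEGATIVE_CLASS = "benign"


class ClassifierKind(str, enum.Enum):
    SVM_LINEAR = "svm_linear"
    SVM_RBF = "svm_rbf"
    SVM_SIGMOID = "svm_sigmoid"
    RF = "rf"
    ANN = "ann"


@dataclass(frozen=True)
class HyperparameterSet:
    """Hyperparameters for one classifier; only the fields the chosen
    classifier reads are meaningful.

    ``gamma`` and ``slope`` default to 1/n_features, resolved at fit time
    (None here means "use that default").
    """

    classifier: ClassifierKind
    C: float = 1.0
    gamma: float | None = None
    slope: float | None = None
    intercept: float = 0.0
    n_trees: int = 500
    neurons: tuple[int, int, int, int] = (1, 1, 1, 1)

    def __post_init__(self) -> None:
        object.__setattr__(self, "classifier", ClassifierKind(self.classifier))
        if self.C <= 0:
            raise ValueError("C must be positive")
        if self.gamma is not None and self.gamma <= 0:
            raise ValueError("gamma must be positive")
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if len(self.neurons) != 4 or any(n < 1 for n in self.neurons):
            raise ValueError("neurons must be 4 positive integers")


@dataclass
class TrainedModel:
    kind: ClassifierKind
    hyperparameters: HyperparameterSet
    estimator: object
    n_features: int
    class_order: tuple[str, str]  # (negative, positive)
    seed: int


def _build_estimator(hp: HyperparameterSet, n_features: int, seed: int):
    gamma = hp.gamma if hp.gamma is not None else 1.0 / n_features
    slope = hp.slope if hp.slope is not None else 1.0 / n_features
    kind = hp.classifier
    if kind is ClassifierKind.SVM_LINEAR:
        return _PlattSVC(SVC(kernel="linear", C=hp.C, random_state=seed))
    if kind is ClassifierKind.SVM_RBF:
        return _PlattSVC(SVC(kernel="rbf", C=hp.C, gamma=gamma, random_state=seed))
    if kind is ClassifierKind.SVM_SIGMOID:
        # tanh(s <x,y> + cf); a callable kernel because the slope may be
        # negative, which sklearn's built-in sigmoid kernel rejects.
        def sigmoid_kernel(X, Y, s=slope, cf=hp.intercept):
            return np.tanh(s * (X @ Y.T) + cf)

        return _PlattSVC(SVC(kernel=sigmoid_kernel, C=hp.C, random_state=seed))
    if kind is ClassifierKind.RF:
        return RandomForestClassifier(n_estimators=hp.n_trees, random_state=seed)
    if kind is ClassifierKind.ANN:
        return MLPClassifier(
            hidden_layer_sizes=tuple(hp.neurons),
            activation="logistic",
            max_iter=200,
            random_state=seed,
        )
    raise ValueError(kind)


def train_classifier(
    train: LabeledSpectraSet, hp: HyperparameterSet, seed: int = 0
) -> TrainedModel:
    """Fit a benign-vs-malignant model on the lesion rows of ``train``.

    Skin rows, if present, are ignored; both lesion classes must be
    represented.  SVM scores come from Platt-style probability
    calibration, random forests from the tree-vote fraction, and the
    neural network from its output activation.
    """
    lesion = np.isin(train.classes, (NEGATIVE_CLASS, POSITIVE_CLASS))
    X = train.spectra[lesion]
    y = (train.classes[lesion] == POSITIVE_CLASS).astype(int)
    if len(np.unique(y)) < 2:
        raise ValueError("training set must contain both lesion classes")
    est = _build_estimator(hp, X.shape[1], seed)
    est.fit(X, y)
    return TrainedModel(
        kind=hp.classifier,
        hyperparameters=hp,
        estimator=est,
        n_features=X.shape[1],
        class_order=(NEGATIVE_CLASS, POSITIVE_CLASS),
        seed=seed,
    )


def predict(model: TrainedModel, spectra: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-sample (label, malignancy score in [0, 1])."""
    spectra = np.asarray(spectra, dtype=float)
    if spectra.ndim != 2:
        raise ValueError("spectra must be a 2-D matrix")
    if spectra.shape[0] == 0:
        return np.empty(0, dtype=object), np.empty(0)
    if spectra.shape[1] != model.n_features:
        raise ValueError(
            f"model expects {model.n_features} features, got {spectra.shape[1]}"
        )
    proba = model.estimator.predict_proba(spectra)
    pos_col = list(model.estimator.classes_).index(1)
    scores = proba[:, pos_col]
    labels = np.where(scores > 0.5, POSITIVE_CLASS, NEGATIVE_CLASS).astype(object)
    return labels, scores


# ---------------------------------------------------------------------------
# Genetic-algorithm hyperparameter search


@dataclass(frozen=True)
class ParamSpec:
    """One searched hyperparameter: bounds, optional log10 scaling for the
    genome representation, and integer rounding on decode."""

    name: str
    low: float
    high: float
    log: bool = False
    integer: bool = False

    def encode(self, value: float) -> float:
        return math.log10(value) if self.log else float(value)

    def decode(self, gene: float) -> float:
        value = 10.0**gene if self.log else gene
        value = min(max(value, self.low), self.high)
        return int(round(value)) if self.integer else value

    @property
    def gene_low(self) -> float:
        return math.log10(self.low) if self.log else self.low

    @property
    def gene_high(self) -> float:
        return math.log10(self.high) if self.log else self.high


def default_search_space(kind: ClassifierKind) -> list[ParamSpec]:
    """Search intervals wide enough to contain typical tuned optima:
    C in [2^-5, 2^7] and gamma in [2^-10, 2^4] on a log scale, sigmoid
    slope/intercept in [-15, 15], trees and neurons in [1, 500]."""
    kind = ClassifierKind(kind)
    if kind is ClassifierKind.SVM_LINEAR:
        return [ParamSpec("C", 2.0**-5, 2.0**7, log=True)]
    if kind is ClassifierKind.SVM_RBF:
        return [
            ParamSpec("C", 2.0**-5, 2.0**7, log=True),
            ParamSpec("gamma", 2.0**-10, 2.0**4, log=True),
        ]
    if kind is ClassifierKind.SVM_SIGMOID:
        return [
            ParamSpec("C", 2.0**-5, 2.0**7, log=True),
            ParamSpec("slope", -15.0, 15.0),
            ParamSpec("intercept", -15.0, 15.0),
        ]
    if kind is ClassifierKind.RF:
        return [ParamSpec("n_trees", 1, 500, integer=True)]
    if kind is ClassifierKind.ANN:
        return [ParamSpec(f"neurons_{i}", 1, 500, integer=True) for i in range(4)]
    raise ValueError(kind)


@dataclass(frozen=True)
class GAConfig:
    population: int = 50
    generations: int = 30
    crossover_rate: float = 0.9
    mutation_rate: float = 0.1
    elitism: int = 2
    seed: int = 0
    bounds: tuple[ParamSpec, ...] | None = None  # None -> default_search_space

    def __post_init__(self) -> None:
        if not (0 <= self.crossover_rate <= 1 and 0 <= self.mutation_rate <= 1):
            raise ValueError("rates must lie in [0, 1]")
        if self.bounds is not None and len(self.bounds) == 0:
            raise ValueError("bounds must be non-empty when given")


def _hp_from_values(kind: ClassifierKind, values: dict[str, float]) -> HyperparameterSet:
    hp = HyperparameterSet(classifier=kind)
    neurons = list(hp.neurons)
    fields_: dict = {}
    for name, value in values.items():
        if name.startswith("neurons_"):
            neurons[int(name.split("_")[1])] = int(value)
        elif name == "n_trees":
            fields_["n_trees"] = int(value)
        else:
            fields_[name] = float(value)
    return replace(hp, neurons=tuple(neurons), **fields_)


def ga_optimize(
    classifier: ClassifierKind,
    train: LabeledSpectraSet,
    val: LabeledSpectraSet,
    cfg: GAConfig = GAConfig(),
) -> tuple[HyperparameterSet, float]:
    """Real-coded GA maximizing validation AUC; returns the best
    hyperparameters ever evaluated and their AUC.

    Training and validation sets must be patient-disjoint, otherwise the
    validation AUC is optimistically biased.
    """
    classifier = ClassifierKind(classifier)
    shared = set(train.patient_id) & set(val.patient_id)
    if shared:
        raise ValueError(f"train and validation sets share patients: {sorted(map(str, shared))}")
    lesion_val = np.isin(val.classes, (NEGATIVE_CLASS, POSITIVE_CLASS))
    X_val = val.spectra[lesion_val]
    y_val = (val.classes[lesion_val] == POSITIVE_CLASS).astype(int)
    if len(np.unique(y_val)) < 2:
        raise ValueError("validation set must contain both lesion classes")

    space = list(cfg.bounds) if cfg.bounds is not None else default_search_space(classifier)
    rng = np.random.default_rng(cfg.seed)
    lows = np.array([p.gene_low for p in space])
    highs = np.array([p.gene_high for p in space])
    sigma = 0.1 * (highs - lows)

    cache: dict[tuple, float] = {}

    def fitness(genome: np.ndarray) -> float:
        values = {p.name: p.decode(g) for p, g in zip(space, genome)}
        key = tuple(sorted(values.items()))
        if key not in cache:
            hp = _hp_from_values(classifier, values)
            model = train_classifier(train, hp, seed=cfg.seed)
            _, scores = predict(model, X_val)
            cache[key] = roc_auc(scores, y_val)
        return cache[key]

    # initial population: uniform in gene space, default hp injected first
    pop = rng.uniform(lows, highs, size=(cfg.population, len(space)))
    default_hp = HyperparameterSet(classifier=classifier)
    default_genome = np.array(
        [p.encode(_default_value(p, default_hp, train.spectra.shape[1])) for p in space]
    )
    pop[0] = np.clip(default_genome, lows, highs)

    fits = np.array([fitness(g) for g in pop])
    best_idx = int(np.argmax(fits))
    best_genome, best_fit = pop[best_idx].copy(), float(fits[best_idx])

    for _ in range(cfg.generations):
        elite_order = np.argsort(fits)[::-1][: cfg.elitism]
        new_pop = [pop[i].copy() for i in elite_order]
        while len(new_pop) < cfg.population:
            p1 = _tournament(pop, fits, rng)
            p2 = _tournament(pop, fits, rng)
            if rng.random() < cfg.crossover_rate:
                c1, c2 = _blend(p1, p2, rng)
            else:
                c1, c2 = p1.copy(), p2.copy()
            for child in (c1, c2):
                mutate = rng.random(len(space)) < cfg.mutation_rate
                child[mutate] += rng.normal(0.0, sigma[mutate])
                new_pop.append(np.clip(child, lows, highs))
        pop = np.array(new_pop[: cfg.population])
        fits = np.array([fitness(g) for g in pop])
        gen_best = int(np.argmax(fits))
        if fits[gen_best] > best_fit:
            best_genome, best_fit = pop[gen_best].copy(), float(fits[gen_best])

    best_values = {p.name: p.decode(g) for p, g in zip(space, best_genome)}
    return _hp_from_values(classifier, best_values), best_fit


def _default_value(p: ParamSpec, hp: HyperparameterSet, n_features: int) -> float:
    if p.name == "C":
        return hp.C
    if p.name == "gamma":
        return 1.0 / n_features
    if p.name == "slope":
        return 1.0 / n_features
    if p.name == "intercept":
        return hp.intercept
    if p.name == "n_trees":
        return hp.n_trees
    if p.name.startswith("neurons_"):
        return hp.neurons[int(p.name.split("_")[1])]
    # custom bounds for a parameter without a package default: midpoint
    return 0.5 * (p.low + p.high)


def _tournament(pop: np.ndarray, fits: np.ndarray, rng, k: int = 3) -> np.ndarray:
    idx = rng.integers(0, len(pop), size=k)
    return pop[idx[np.argmax(fits[idx])]].copy()


def _blend(p1: np.ndarray, p2: np.ndarray, rng, alpha: float = 0.5):
    # BLX-alpha: children sampled in the parent interval extended by alpha
    lo = np.minimum(p1, p2)
    hi = np.maximum(p1, p2)
    span = hi - lo
    a = lo - alpha * span
    b = hi + alpha * span
    return rng.uniform(a, b), rng.uniform(a, b)
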