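"""Registry of 34 classifier specifications.

The study compared 34 off-the-shelf classifier implementations spread
over four languages (several families appear once per language, each
with its own tuning grid). The registry reproduces that design: one
spec per published row — same family, same hyperparameter grid — all
backed by scikit-learn estimators, which is the single-toolkit reading
of the same experiment. Two families without a scikit-learn counterpart
(extreme learning machine, kernel Fisher discriminant) are provided as
small estimators in this module.

Grids whose size depends on the training data (the perceptron
hidden-layer rule h1 = max(1, floor(N / (I + C))), the random-forest
max-features list, ...) are stored as callables of (n_samples,
n_features) and resolved at tuning time.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.discriminant_analysis import (
    LinearDiscriminantAnalysis,
    QuadraticDiscriminantAnalysis,
)
from sklearn.ensemble import (
    AdaBoostClassifier,
    BaggingClassifier,
    GradientBoostingClassifier,
    RandomForestClassifier,
)
from sklearn.linear_model import LogisticRegression, RidgeClassifier, SGDClassifier
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC, LinearSVC
from sklearn.tree import DecisionTreeClassifier
from sklearn.utils.validation import check_is_fitted, validate_data

GridValue = Sequence | Callable[[int, int], Sequence]


class ExtremeLearningMachine(ClassifierMixin, BaseEstimator):
    """Single-hidden-layer network with random tanh features and a
    least-squares readout — the classic extreme learning machine."""

    def __init__(self, n_hidden: int = 20, alpha: float = 1e-3, random_state=None):
        self.n_hidden = n_hidden
        self.alpha = alpha
        self.random_state = random_state

    def fit(self, X, y):
        X, y = validate_data(self, X, y)
        self.classes_, y_idx = np.unique(y, return_inverse=True)
        rng = np.random.default_rng(self.random_state)
        n_features = X.shape[1]
        self.weights_ = rng.normal(size=(n_features, self.n_hidden))
        self.biases_ = rng.normal(size=self.n_hidden)
        hidden = np.tanh(X @ self.weights_ + self.biases_)
        targets = np.where(y_idx == 1, 1.0, -1.0)
        gram = hidden.T @ hidden + self.alpha * np.eye(self.n_hidden)
        self.beta_ = np.linalg.solve(gram, hidden.T @ targets)
        return self

    def decision_function(self, X):
        check_is_fitted(self)
        X = validate_data(self, X, reset=False)
        return np.tanh(X @ self.weights_ + self.biases_) @ self.beta_

    def predict(self, X):
        return self.classes_[(self.decision_function(X) >= 0).astype(int)]


class KernelFisherDiscriminant(ClassifierMixin, BaseEstimator):
    """RBF-kernel Fisher discriminant via its kernel ridge-regression
    equivalence: regularized least squares on ±1 targets in the RBF
    feature space, thresholded at zero."""

    def __init__(self, gamma: float = 1.0, alpha: float = 1e-2):
        self.gamma = gamma
        self.alpha = alpha

    def _kernel(self, A, B):
        sq = (
            np.sum(A**2, axis=1)[:, None]
            + np.sum(B**2, axis=1)[None, :]
            - 2.0 * A @ B.T
        )
        return np.exp(-self.gamma * np.maximum(sq, 0.0) / A.shape[1])

    def fit(self, X, y):
        X, y = validate_data(self, X, y)
        self.classes_, y_idx = np.unique(y, return_inverse=True)
        self.X_train_ = X
        K = self._kernel(X, X)
        targets = np.where(y_idx == 1, 1.0, -1.0)
        self.dual_coef_ = np.linalg.solve(K + self.alpha * np.eye(X.shape[0]), targets)
        return self

    def decision_function(self, X):
        check_is_fitted(self)
        X = validate_data(self, X, reset=False)
        return self._kernel(X, self.X_train_) @ self.dual_coef_

    def predict(self, X):
        return self.classes_[(self.decision_function(X) >= 0).astype(int)]


@dataclass(frozen=True)
class ClassifierSpec:
    """A classifier family with its tuning grid.

    ``make(params, random_state)`` builds a fresh estimator;
    ``supports_proba`` marks families whose slice scores feed the
    patient-level ROC (mean slice probability).
    """

    family_id: str
    make: Callable[[Mapping, int | None], BaseEstimator]
    grid: Mapping[str, GridValue] = field(default_factory=dict)
    supports_proba: bool = True
    #: grid key naming a boosting-ensemble size whose whole value list can
    #: be scored from one fit via staged predictions (exact shortcut)
    staged_param: str | None = None


def _mlp_hidden_grid(n_samples: int, n_features: int, n_classes: int = 2) -> list[int]:
    """Published hidden-size rule: h = h0 : step : h1 with n_h = 10 steps,
    h1 = max(1, floor(N/(I+C))), h0 = max(1, floor(h1/n_h))."""
    h1 = max(1, n_samples // (n_features + n_classes))
    h0 = max(1, h1 // 10)
    step = max(1, round((h1 - h0) / 10))
    return list(range(h0, h1 + 1, step))


def _elm_hidden_grid(n_samples: int, n_features: int, n_classes: int = 2) -> list[int]:
    """20 hidden-layer sizes spread over 1..floor(N/(I+C))."""
    upper = max(1, n_samples // (n_features + n_classes))
    return sorted(set(np.linspace(1, upper, 20).round().astype(int).tolist()))


def _rf_max_features_grid(n_samples: int, n_features: int) -> list[int]:
    return [f for f in range(3, n_features + 1, 2)] or [n_features]


def _tree_max_features_grid(n_samples: int, n_features: int) -> list[int]:
    i = n_features
    cand = {3, 4, i, max(1, i // 4), max(1, i // 2), max(1, int(np.log2(i)))}
    return sorted(f for f in cand if 1 <= f <= i)


def _pow2(start: float, step: float, stop: float) -> list[float]:
    return [2.0**e for e in np.arange(start, stop + 1e-9, step)]


def _mlp(params, rs):
    return MLPClassifier(
        hidden_layer_sizes=(params["h"],), alpha=params.get("alpha", 1e-4),
        max_iter=500, random_state=rs,
    )


def _avnnet(params, rs):
    # committee of perceptrons: bagged MLPs with averaged votes
    return BaggingClassifier(
        estimator=MLPClassifier(hidden_layer_sizes=(params["h"],),
                                alpha=params.get("alpha", 0.0),
                                max_iter=300, random_state=0),
        n_estimators=5, random_state=rs,
    )


def build_registry() -> dict[str, ClassifierSpec]:
    """All 34 specs, keyed by family id (stable order)."""
    specs: list[ClassifierSpec] = []

    def add(family_id, make, grid=None, supports_proba=True, staged_param=None):
        specs.append(
            ClassifierSpec(family_id, make, grid or {}, supports_proba, staged_param)
        )

    # --- discriminant analysis (4 lda rows + dlda + qda + kfd)
    for lang in ("octave", "matlab", "python", "r"):
        add(f"lda_{lang}", lambda p, rs: LinearDiscriminantAnalysis())
    add("dlda", lambda p, rs: LinearDiscriminantAnalysis(solver="lsqr", shrinkage=1.0))
    add("qda", lambda p, rs: QuadraticDiscriminantAnalysis(reg_param=1e-3))
    add("kfd", lambda p, rs: KernelFisherDiscriminant(), supports_proba=False)

    # --- neural networks
    add("mlp_matlab", _mlp, {"h": _mlp_hidden_grid})
    add("mlp_python", _mlp, {"h": _mlp_hidden_grid})
    add("nnet", _mlp, {"h": _mlp_hidden_grid, "alpha": [0.0, 1e-4, 1e-3, 1e-2, 1e-1]})
    add("neuralnet", _mlp, {"h": _mlp_hidden_grid})
    add(
        "elm",
        lambda p, rs: ExtremeLearningMachine(n_hidden=p["h"], random_state=rs),
        {"h": _elm_hidden_grid},
        supports_proba=False,
    )

    # --- support vector machine (RBF), lambda = C, gamma grids in powers of 2
    svm_grid = {"C": _pow2(-5, 2, 10), "gamma": _pow2(-15, 2, 10)}
    for lang in ("octave", "python", "r"):
        add(
            f"svm_{lang}",
            lambda p, rs: SVC(kernel="rbf", C=p["C"], gamma=p["gamma"],
                              probability=False, random_state=rs),
            svm_grid,
            supports_proba=False,
        )

    # --- k-nearest neighbors, k = 1:2:15
    knn_grid = {"k": list(range(1, 16, 2))}
    for lang in ("matlab", "r"):
        add(f"knn_{lang}",
            lambda p, rs: KNeighborsClassifier(n_neighbors=p["k"]), knn_grid)

    # --- ensembles
    add(
        "adaboost_matlab",
        lambda p, rs: AdaBoostClassifier(n_estimators=p["T"], random_state=rs),
        {"T": list(range(10, 51, 10))},
        staged_param="T",
    )
    add(
        "adaboost_python",
        lambda p, rs: AdaBoostClassifier(n_estimators=p["T"],
                                         learning_rate=p["lr"], random_state=rs),
        {"T": list(range(10, 51, 10)),
         "lr": [round(0.1 * i, 1) for i in range(1, 10)]},
        staged_param="T",
    )
    add("bagging", lambda p, rs: BaggingClassifier(n_estimators=50, random_state=rs))
    add(
        "rf",
        lambda p, rs: RandomForestClassifier(n_estimators=p["T"],
                                             max_features=p["F"], random_state=rs),
        {"T": list(range(5, 32, 5)), "F": _rf_max_features_grid},
    )
    add(
        "gbm",
        lambda p, rs: GradientBoostingClassifier(n_estimators=p["T"],
                                                 max_depth=p["D"], random_state=rs),
        {"T": [50, 100, 150, 200], "D": [1, 3, 6, 9]},
        staged_param="T",
    )
    add("avnnet", _avnnet,
        {"h": list(range(1, 10)), "alpha": [0.0, 1e-4, 1e-3, 1e-2, 1e-1]})

    # --- regularized linear models, lambda = 2^(-3:0.2:3)
    lam = _pow2(-3, 0.2, 3)
    add(
        "lasso",
        lambda p, rs: LinearSVC(penalty="l1", dual=False, C=1.0 / p["lam"],
                                max_iter=5000),
        {"lam": lam},
        supports_proba=False,
    )
    add(
        "ridge",
        lambda p, rs: RidgeClassifier(alpha=p["lam"]),
        {"lam": lam},
        supports_proba=False,
    )
    add(
        "sgd",
        lambda p, rs: SGDClassifier(alpha=p["alpha"], max_iter=2000, random_state=rs),
        {"alpha": sorted({10.0**-i for i in range(1, 6)}
                         | {5 * 10.0**-i for i in range(1, 6)})},
        supports_proba=False,
    )

    # --- logistic regression
    for lang in ("matlab", "python"):
        add(f"logreg_{lang}", lambda p, rs: LogisticRegression(max_iter=2000))

    # --- decision trees
    add("ctree_matlab", lambda p, rs: DecisionTreeClassifier(random_state=rs))
    add(
        "ctree_python",
        lambda p, rs: DecisionTreeClassifier(
            criterion=p["criterion"], splitter=p["splitter"],
            max_features=p["F"], random_state=rs),
        {"criterion": ["gini", "entropy"], "splitter": ["best", "random"],
         "F": _tree_max_features_grid},
    )
    add(
        "ctree_r",
        lambda p, rs: DecisionTreeClassifier(max_depth=p["depth"], random_state=rs),
        {"depth": [1, 2, 3, 4, 5]},
    )
    # rpart defaults: minsplit = 20, minbucket = minsplit/3
    add("rpart", lambda p, rs: DecisionTreeClassifier(
        min_samples_split=20, min_samples_leaf=7, random_state=rs))

    # --- naive Bayes
    for lang in ("matlab", "r"):
        add(f"nb_{lang}", lambda p, rs: GaussianNB())

    registry = {s.family_id: s for s in specs}
    assert len(registry) == len(specs), "duplicate family ids"
    return registry


REGISTRY = build_registry()


def get_classifier_spec(family_id: str) -> ClassifierSpec:
    try:
        return REGISTRY[family_id]
    except KeyError:
        raise KeyError(
            f"unknown classifier family {family_id!r}; "
            f"known: {sorted(REGISTRY)}"
        ) from None
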