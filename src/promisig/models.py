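"""DT/ST classifiers: k-NN, random forest, and Tanimoto-kernel SVM.

All three algorithms operate on binary fingerprints with the global class
convention DT = +1 (positive, promiscuous) and ST = -1.  Hyperparameters are
selected by an inner stratified k-fold grid search on the training half
(nested cross-validation: the repeated outer train/test trials form the outer
loop), maximising the Matthews correlation coefficient by default, and the
winning setting is refit on the full training half.

The SVM uses the Tanimoto kernel from :mod:`promisig.features` via
scikit-learn's precomputed-kernel path, and the fitted object keeps its dual
representation (support vectors, y(i)*lambda(i) coefficients, bias) because
the attribution module decomposes the decision function from exactly those
quantities.  k-NN uses Tanimoto distance (1 - similarity); an even vote split
would fall to ST, the conservative non-promiscuous side (the default grid
only holds odd k, so this matters only for user-supplied grids).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import joblib
import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import balanced_accuracy_score, matthews_corrcoef, make_scorer
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC

from promisig.features import tanimoto_matrix

__all__ = [
    "ALGORITHMS",
    "DEFAULT_GRIDS",
    "CVConfig",
    "FittedClassifier",
    "TrainingError",
    "train",
    "predict",
]

ALGORITHMS = ("knn", "rf", "svm")

DEFAULT_GRIDS: dict[str, dict[str, list]] = {
    "svm": {"C": [0.1, 1.0, 10.0, 100.0]},
    # tree count is a compute budget, not a regularisation knob: accuracy is
    # monotone (plateauing) in it, so it is fixed rather than cross-validated
    "rf": {"n_estimators": [100], "max_depth": [None, 20]},
    "knn": {"n_neighbors": [1, 3, 5]},
}

_SCORERS = {
    "mcc": make_scorer(matthews_corrcoef),
    "ba": make_scorer(balanced_accuracy_score),
}


class TrainingError(ValueError):
    """Raised for untrainable input (single class, empty grid, ...)."""


@dataclass(frozen=True)
class CVConfig:
    """Inner cross-validation setup for hyperparameter selection."""

    inner_folds: int = 5
    grids: Mapping[str, Mapping[str, list]] | None = None
    selection_metric: str = "mcc"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.inner_folds < 2:
            raise ValueError("inner_folds must be >= 2")
        if self.selection_metric not in _SCORERS:
            raise ValueError(f"unknown selection metric {self.selection_metric!r}")

    def grid_for(self, algorithm: str) -> dict[str, list]:
        grids = self.grids if self.grids is not None else DEFAULT_GRIDS
        grid = dict(grids.get(algorithm, {}))
        if not grid or any(len(v) == 0 for v in grid.values()):
            raise TrainingError(f"empty hyperparameter grid for {algorithm!r}")
        return grid


@dataclass
class FittedClassifier:
    """A trained model bound to one target pair and trial.

    For the SVM, ``dual_coef[i]`` is y(i)*lambda(i) of support vector i and
    the decision function is ``f(x) = sum_i dual_coef[i] * K(sv_i, x) +
    intercept`` with K the Tanimoto kernel; ``predict`` labels positives
    (f > 0) as DT and ties (f = 0) as ST.
    """

    algorithm: str
    hyperparams: dict
    pair_id: str
    trial_index: int
    n_bits: int
    estimator: object
    train_X: np.ndarray | None = None
    support_vectors: np.ndarray | None = None
    dual_coef: np.ndarray | None = None
    intercept: float | None = None

    def _check(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X)
        if X.ndim != 2 or X.shape[1] != self.n_bits:
            raise ValueError(
                f"expected fingerprints with {self.n_bits} bits, got shape {X.shape}"
            )
        return X

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        """SVM decision values (positive = DT evidence)."""
        if self.algorithm != "svm":
            raise ValueError("decision_function is defined for SVM models only")
        X = self._check(X)
        if X.shape[0] == 0:
            return np.zeros(0)
        K = tanimoto_matrix(X, self.train_X)
        return self.estimator.decision_function(K)

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Predict labels in {+1 (DT), -1 (ST)}; empty input yields empty output."""
        X = self._check(X)
        if X.shape[0] == 0:
            return np.zeros(0, dtype=int)
        if self.algorithm == "svm":
            return np.where(self.decision_function(X) > 0, 1, -1)
        if self.algorithm == "knn":
            D = 1.0 - tanimoto_matrix(X, self.train_X)
            return self.estimator.predict(D).astype(int)
        return self.estimator.predict(X).astype(int)

    def save(self, path: str | Path) -> None:
        joblib.dump(self, path)

    @staticmethod
    def load(path: str | Path) -> "FittedClassifier":
        model = joblib.load(path)
        if not isinstance(model, FittedClassifier):
            raise TypeError(f"{path} does not hold a FittedClassifier")
        return model


def _inner_cv(cv: CVConfig) -> StratifiedKFold:
    return StratifiedKFold(
        n_splits=cv.inner_folds, shuffle=True, random_state=cv.seed % (2**31)
    )


def train(
    algorithm: str,
    X: np.ndarray,
    y: Sequence[int],
    cv: CVConfig = CVConfig(),
    pair_id: str = "",
    trial_index: int = 0,
) -> FittedClassifier:
    """Train one classifier with inner-CV hyperparameter selection.

    ``X`` holds binary fingerprints (one row per training compound), ``y``
    labels in {+1, -1}.  The grid point with the best mean inner-CV score is
    refit on the full training data; identical inputs and ``cv.seed``
    reproduce the same model.
    """
    if algorithm not in ALGORITHMS:
        raise TrainingError(f"unknown algorithm {algorithm!r}")
    X = np.asarray(X)
    y = np.asarray(y, dtype=int)
    if X.shape[0] != y.shape[0]:
        raise TrainingError("X and y disagree on sample count")
    if len(np.unique(y)) < 2:
        raise TrainingError("training data holds a single class")
    grid = cv.grid_for(algorithm)
    scorer = _SCORERS[cv.selection_metric]
    folds = _inner_cv(cv)

    if algorithm == "svm":
        K = tanimoto_matrix(X, X)
        search = GridSearchCV(
            SVC(kernel="precomputed"), grid, scoring=scorer, cv=folds, refit=True
        )
        search.fit(K, y)
        est = search.best_estimator_
        support = est.support_
        return FittedClassifier(
            algorithm="svm",
            hyperparams=dict(search.best_params_),
            pair_id=pair_id,
            trial_index=trial_index,
            n_bits=X.shape[1],
            estimator=est,
            train_X=X,
            support_vectors=X[support],
            dual_coef=est.dual_coef_[0].copy(),
            intercept=float(est.intercept_[0]),
        )

    if algorithm == "knn":
        D = 1.0 - tanimoto_matrix(X, X)
        search = GridSearchCV(
            KNeighborsClassifier(metric="precomputed"),
            grid,
            scoring=scorer,
            cv=folds,
            refit=True,
        )
        search.fit(D, y)
        return FittedClassifier(
            algorithm="knn",
            hyperparams=dict(search.best_params_),
            pair_id=pair_id,
            trial_index=trial_index,
            n_bits=X.shape[1],
            estimator=search.best_estimator_,
            train_X=X,
        )

    search = GridSearchCV(
        RandomForestClassifier(random_state=cv.seed % (2**31), n_jobs=1),
        grid,
        scoring=scorer,
        cv=folds,
        refit=True,
    )
    search.fit(X, y)
    return FittedClassifier(
        algorithm="rf",
        hyperparams=dict(search.best_params_),
        pair_id=pair_id,
        trial_index=trial_index,
        n_bits=X.shape[1],
        estimator=search.best_estimator_,
    )


def predict(model: FittedClassifier, X: np.ndarray) -> np.ndarray:
    """Functional alias for :meth:`FittedClassifier.predict`."""
    return model.predict(X)
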