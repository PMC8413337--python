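"""L2-regularized logistic regression over pair target profiles.

The learner minimizes

    (1/2) w'w + C * sum_i log(1 + exp(-y_i (w'x_i + b)))

with labels y in {-1, +1}, an (optional) unpenalized intercept b, and the
regularizer C conventionally tuned on the grid {2^i : -16 <= i <= 16}. A
trained model carries a fingerprint of the gene universe it was fitted on and
refuses to score feature vectors built on a different universe.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy import sparse
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .profiles import GeneUniverse

#: Regularizer grid: powers of two from 2^-16 to 2^16.
DEFAULT_C_GRID: tuple[float, ...] = tuple(2.0 ** i for i in range(-16, 17))


class UniverseMismatchError(ValueError):
    """Feature vectors were built on a different gene universe than the model."""


@dataclass
class TrainedModel:
    """Fitted weight vector (one per universe gene) plus metadata."""

    weights: np.ndarray
    intercept: float
    C: float
    universe_fingerprint: str | None = None

    @property
    def n_features(self) -> int:
        return int(self.weights.shape[0])


def _as_matrix(X) -> sparse.csr_matrix | np.ndarray:
    if sparse.issparse(X):
        return X.tocsr()
    return np.asarray(X, dtype=np.float64)


def _validate_labels(y: np.ndarray) -> None:
    classes = set(np.unique(y).tolist())
    if not classes <= {-1, 1}:
        raise ValueError(f"labels must be in {{-1, +1}}, got {sorted(classes)}")
    if len(classes) < 2:
        raise ValueError("training data contains a single class; need both "
                         "interacting (+1) and non-interacting (-1) pairs")


def objective(weights: np.ndarray, intercept: float, X, y: np.ndarray,
              C: float) -> float:
    """Primal objective value at (weights, intercept); intercept unpenalized."""
    X = _as_matrix(X)
    margins = np.asarray(y, dtype=np.float64) * (X @ weights + intercept)
    # log(1 + exp(-m)) computed stably for large |m|
    loss = np.logaddexp(0.0, -margins).sum()
    return 0.5 * float(weights @ weights) + C * float(loss)


def train(X, y, C: float = 1.0, *,
          universe: GeneUniverse | None = None,
          fit_intercept: bool = True,
          tol: float = 1e-8,
          max_iter: int = 5000,
          seed: int = 0) -> TrainedModel:
    """Fit the l2-regularized logistic regression on pair profiles.

    The solver (L-BFGS on the primal) is deterministic given the inputs; the
    seed parameter is accepted for interface uniformity.
    """
    if C <= 0:
        raise ValueError(f"regularizer C must be positive, got {C}")
    X = _as_matrix(X)
    y = np.asarray(y, dtype=np.int64)
    if X.shape[0] != y.shape[0]:
        raise ValueError("X and y have different numbers of rows")
    _validate_labels(y)
    data = X.data if sparse.issparse(X) else X
    if not np.all(np.isfinite(data)):
        raise ValueError("feature matrix contains non-finite entries")

    clf = LogisticRegression(
        C=C, solver="lbfgs", tol=tol, max_iter=max_iter,
        fit_intercept=fit_intercept, random_state=seed)
    clf.fit(X, y)
    # sklearn orders classes_ ascending: [-1, 1]; coef_ is for the +1 class.
    weights = clf.coef_.ravel().astype(np.float64)
    intercept = float(clf.intercept_[0]) if fit_intercept else 0.0
    return TrainedModel(
        weights=weights, intercept=intercept, C=C,
        universe_fingerprint=universe.fingerprint if universe is not None else None)


def _check_universe(model: TrainedModel, X,
                    universe: GeneUniverse | None) -> None:
    if universe is not None and model.universe_fingerprint is not None:
        if universe.fingerprint != model.universe_fingerprint:
            raise UniverseMismatchError(
                "feature vectors were built on a different gene universe than "
                "the model was trained on")
    if X.shape[1] != model.n_features:
        raise UniverseMismatchError(
            f"model expects {model.n_features} features, got {X.shape[1]}")


def decision_function(model: TrainedModel, X,
                      universe: GeneUniverse | None = None) -> np.ndarray:
    X = _as_matrix(X)
    _check_universe(model, X, universe)
    return np.asarray(X @ model.weights + model.intercept, dtype=np.float64)


def predict_proba(model: TrainedModel, X,
                  universe: GeneUniverse | None = None) -> np.ndarray:
    """P(interaction) = 1 / (1 + exp(-(w'x + b))) per row."""
    scores = decision_function(model, X, universe)
    return 1.0 / (1.0 + np.exp(-scores))


def classify(model: TrainedModel, X, threshold: float = 0.5,
             universe: GeneUniverse | None = None) -> np.ndarray:
    """Label +1 where P(interaction) >= threshold, else -1 (boundary inclusive)."""
    if not 0.0 < threshold < 1.0:
        raise ValueError(f"threshold must lie in (0, 1), got {threshold}")
    proba = predict_proba(model, X, universe)
    return np.where(proba >= threshold, 1, -1).astype(np.int64)


def tune_C(X, y, grid: Iterable[float] = DEFAULT_C_GRID, k: int = 5,
           seed: int = 0, **train_kwargs) -> tuple[float, dict[float, float]]:
    """Pick C maximizing mean k-fold ROC-AUC; ties go to the smaller C.

    Preferring the smaller C at equal validation performance keeps the more
    strongly regularized model.
    """
    grid = sorted(set(float(c) for c in grid))
    if not grid:
        raise ValueError("empty C grid")
    if k < 2:
        raise ValueError("k-fold tuning needs k >= 2")
    X = _as_matrix(X)
    y = np.asarray(y, dtype=np.int64)
    _validate_labels(y)

    splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    folds = list(splitter.split(np.zeros(len(y)), y))
    scores: dict[float, float] = {}
    for C in grid:
        aucs = []
        for train_idx, test_idx in folds:
            if len(np.unique(y[train_idx])) < 2 or len(np.unique(y[test_idx])) < 2:
                raise ValueError("degenerate single-class fold during C tuning")
            model = train(X[train_idx], y[train_idx], C=C, seed=seed,
                          **train_kwargs)
            s = decision_function(model, X[test_idx])
            aucs.append(roc_auc_score(y[test_idx], s))
        scores[C] = float(np.mean(aucs))
    best = grid[0]
    for C in grid[1:]:
        if scores[C] > scores[best]:
            best = C
    return best, scores


# ---------------------------------------------------------------------------
# Plain-text model persistence
# ---------------------------------------------------------------------------

def save_model(model: TrainedModel, universe: GeneUniverse,
               path: str | Path) -> None:
    """Write the model as a portable key-value text file."""
    if model.n_features != len(universe):
        raise ValueError("model and universe sizes disagree")
    if (model.universe_fingerprint is not None
            and model.universe_fingerprint != universe.fingerprint):
        raise UniverseMismatchError(
            "universe fingerprint does not match the model")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# universe_sha256={universe.fingerprint}\n")
        fh.write(f"# C={float(model.C)!r}\n")
        for gene, w in zip(universe.genes, model.weights):
            fh.write(f"{gene}\t{float(w)!r}\n")
        fh.write(f"__intercept__\t{float(model.intercept)!r}\n")


def load_model(path: str | Path) -> tuple[TrainedModel, GeneUniverse]:
    """Read a model file back into a (model, universe) pair."""
    fingerprint: str | None = None
    C: float | None = None
    genes: list[str] = []
    weights: list[float] = []
    intercept = 0.0
    with open(path, encoding="utf-8") as fh:
        for raw in fh:
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if body.startswith("universe_sha256="):
                    fingerprint = body.split("=", 1)[1]
                elif body.startswith("C="):
                    C = float(body.split("=", 1)[1])
                continue
            key, value = line.split("\t")
            if key == "__intercept__":
                intercept = float(value)
            else:
                genes.append(key)
                weights.append(float(value))
    if C is None or fingerprint is None:
        raise ValueError(f"model file {path} lacks C or universe fingerprint")
    universe = GeneUniverse(tuple(genes))
    if universe.fingerprint != fingerprint:
        raise UniverseMismatchError(
            f"model file {path}: stored gene list does not hash to the "
            "recorded universe fingerprint")
    model = TrainedModel(
        weights=np.asarray(weights, dtype=np.float64),
        intercept=intercept, C=C, universe_fingerprint=fingerprint)
    return model, universe
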