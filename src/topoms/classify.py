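"""Classification of persistence features with grouped cross-validation.

Two classifiers are fitted on persistence matrices: unpenalized logistic
regression with the logit link (class 1 iff the fitted probability exceeds
the threshold ``c``, default 0.5) and a random forest in its original
formulation — 1000 CART trees on bootstrap samples of size ``n``, Gini
splitting over ``floor(sqrt(q))`` candidate covariates per split, minimum
terminal-node size one, majority vote, fixed seed 1234.

Evaluation uses balanced accuracy — the mean of the per-class recalls,
insensitive to class imbalance in the test fold — under cross-validation
grouped at the tissue-microarray (TMA) level: either leave-one-group-out or
a two-way split of the groups, so that spectra from one TMA never appear in
both the training and the test side of a fold.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import expit
from sklearn.ensemble import RandomForestClassifier
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression

from .matrix import PersistenceMatrix

__all__ = [
    "LabeledDataset",
    "LogisticModel",
    "ForestConfig",
    "CVResult",
    "balanced_accuracy",
    "fit_logistic",
    "fit_forest",
    "run_group_cv",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class LabeledDataset:
    """Persistence matrix with binary labels and group (TMA) identifiers."""

    Z: PersistenceMatrix
    labels: np.ndarray
    groups: np.ndarray

    def __post_init__(self) -> None:
        y = np.asarray(self.labels)
        g = np.asarray(self.groups)
        n = self.Z.values.shape[0]
        if y.shape != (n,) or g.shape != (n,):
            raise ValueError("labels and groups must have one entry per spectrum")
        if not np.isin(y, [0, 1]).all():
            raise ValueError("labels must be binary (0/1)")
        if np.unique(y).size < 2:
            raise ValueError("both classes must be present")
        object.__setattr__(self, "labels", y.astype(int))
        object.__setattr__(self, "groups", g)


def balanced_accuracy(truth, predicted) -> float:
    """Mean of the per-class recalls, ``(recall_0 + recall_1) / 2``."""
    y = np.asarray(truth).astype(int)
    p = np.asarray(predicted).astype(int)
    if y.shape != p.shape:
        raise ValueError("truth and predicted must have equal length")
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("truth contains a single class; balanced accuracy undefined")
    recalls = [np.mean(p[y == c] == c) for c in classes]
    return float(np.mean(recalls))


@dataclass
class LogisticModel:
    """Fitted unpenalized logistic-regression model with decision threshold."""

    intercept: float
    coefficients: np.ndarray
    threshold: float = 0.5
    converged: bool = True

    def predict_proba(self, Z) -> np.ndarray:
        """Fitted probability of class 1 via the logistic response."""
        eta = self.intercept + np.asarray(Z, dtype=float) @ self.coefficients
        return expit(eta)

    def predict(self, Z) -> np.ndarray:
        """Class 1 iff the fitted probability strictly exceeds the threshold."""
        return (self.predict_proba(Z) > self.threshold).astype(int)

    def log_likelihood(self, Z, y) -> float:
        """Binomial log-likelihood of labels ``y`` under the fitted model."""
        eta = self.intercept + np.asarray(Z, dtype=float) @ self.coefficients
        y = np.asarray(y, dtype=float)
        return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


def fit_logistic(
    Z, y, threshold: float = 0.5, tol: float = 1e-8, max_iter: int = 1000
) -> LogisticModel:
    """Maximum-likelihood logistic regression without regularization.

    Sparse persistence features can be linearly separable, in which case the
    likelihood has no finite maximizer; the optimizer then stops at the
    iteration cap and a warning is logged, mirroring how unpenalized fits
    behave in practice.
    """
    Z = np.asarray(Z, dtype=float)
    y = np.asarray(y).astype(int)
    if not np.all(np.isfinite(Z)):
        raise ValueError("non-finite values in the design matrix")
    if np.unique(y).size < 2:
        raise ValueError("both classes must be present to fit")
    est = LogisticRegression(C=np.inf, tol=tol, max_iter=max_iter, solver="lbfgs")
    converged = True
    with warnings.catch_warnings():
        warnings.simplefilter("error", ConvergenceWarning)
        try:
            est.fit(Z, y)
        except ConvergenceWarning:
            converged = False
            logger.warning(
                "logistic regression hit the iteration cap (%d); "
                "training data may be separable",
                max_iter,
            )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", ConvergenceWarning)
                est = LogisticRegression(
                    C=np.inf, tol=tol, max_iter=max_iter, solver="lbfgs"
                ).fit(Z, y)
    return LogisticModel(
        intercept=float(est.intercept_[0]),
        coefficients=est.coef_[0].copy(),
        threshold=threshold,
        converged=converged,
    )


@dataclass(frozen=True)
class ForestConfig:
    """Random-forest settings: the original formulation with typical defaults."""

    n_trees: int = 1000
    min_leaf: int = 1
    seed: int = 1234

    def __post_init__(self) -> None:
        if self.n_trees < 1 or self.min_leaf < 1:
            raise ValueError("n_trees and min_leaf must be positive")


def fit_forest(Z, y, config: ForestConfig | None = None) -> RandomForestClassifier:
    """Fit a seeded random forest on persistence features.

    ``max_features="sqrt"`` truncates to ``floor(sqrt(q))`` candidate
    covariates per split; bootstrap samples have size ``n`` drawn with
    replacement.  The same seed and data give identical predictions.
    """
    Z = np.asarray(Z, dtype=float)
    y = np.asarray(y).astype(int)
    if Z.ndim != 2 or Z.shape[1] == 0:
        raise ValueError("design matrix must have at least one column")
    if np.unique(y).size < 2:
        raise ValueError("both classes must be present to fit")
    config = config or ForestConfig()
    est = RandomForestClassifier(
        n_estimators=config.n_trees,
        criterion="gini",
        max_features="sqrt",
        min_samples_leaf=config.min_leaf,
        bootstrap=True,
        random_state=config.seed,
        n_jobs=1,
    )
    est.fit(Z, y)
    return est


@dataclass(frozen=True)
class CVResult:
    """Per-fold balanced accuracies with summary statistics."""

    fold_ids: tuple
    per_fold: np.ndarray

    def summary(self) -> dict[str, float]:
        """mean / min / max / median / std (sample, n-1 denominator)."""
        s = np.asarray(self.per_fold, dtype=float)
        return {
            "mean": float(np.mean(s)),
            "min": float(np.min(s)),
            "max": float(np.max(s)),
            "median": float(np.median(s)),
            "std": float(np.std(s, ddof=1)) if s.size > 1 else 0.0,
        }


def _fit_predict(model_kind, Z_train, y_train, Z_test, forest_config, threshold):
    if model_kind == "lr":
        model = fit_logistic(Z_train, y_train, threshold=threshold)
        return model.predict(Z_test)
    if model_kind == "rf":
        est = fit_forest(Z_train, y_train, forest_config)
        return est.predict(Z_test)
    raise ValueError(f"unknown model kind {model_kind!r}; use 'lr' or 'rf'")


def run_group_cv(
    data: LabeledDataset,
    model_kind: str = "rf",
    scheme: str = "logo",
    split: tuple | None = None,
    forest_config: ForestConfig | None = None,
    threshold: float = 0.5,
) -> CVResult:
    """Group-level cross-validation with balanced-accuracy scoring.

    ``scheme="logo"`` holds out one group per fold (folds in ascending
    group-id order); ``scheme="two-split"`` takes a partition ``(A, B)`` of
    the group ids and evaluates train-A/test-B and train-B/test-A.  A test
    fold containing a single class raises an error naming the fold.
    """
    Z = data.Z.values
    y = data.labels
    g = data.groups
    unique_groups = np.unique(g)
    if unique_groups.size < 2:
        raise ValueError("grouped cross-validation needs at least two groups")

    if scheme == "logo":
        folds = [(gid, g != gid, g == gid) for gid in unique_groups]
    elif scheme == "two-split":
        if split is None:
            raise ValueError("two-split scheme requires a partition (A, B) of groups")
        A, B = (np.asarray(side) for side in split)
        covered = np.sort(np.concatenate([A, B]))
        if not np.array_equal(covered, unique_groups):
            raise ValueError("split (A, B) must partition the group ids")
        in_A = np.isin(g, A)
        folds = [("B", in_A, ~in_A), ("A", ~in_A, in_A)]
    else:
        raise ValueError(f"unknown scheme {scheme!r}; use 'logo' or 'two-split'")

    fold_ids, scores = [], []
    for fold_id, train_mask, test_mask in folds:
        if np.unique(y[test_mask]).size < 2:
            raise ValueError(f"test fold {fold_id!r} contains a single class")
        pred = _fit_predict(
            model_kind, Z[train_mask], y[train_mask], Z[test_mask],
            forest_config, threshold,
        )
        score = balanced_accuracy(y[test_mask], pred)
        logger.info("fold %s: balanced accuracy %.3f", fold_id, score)
        fold_ids.append(fold_id)
        scores.append(score)
    return CVResult(fold_ids=tuple(fold_ids), per_fold=np.asarray(scores))
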