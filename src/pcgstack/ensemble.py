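"""AUC-weighted heterogeneous stacking ensemble.

Four first-order base learners (one texture RFE-SVM, three PCA-RF models
on deep features) produce calibrated class posteriors P_mu in [0, 1].
Each learner's pooled out-of-fold AUC h_mu on the training set becomes its
weight

    w_mu = h_mu / sum_nu h_nu        (weights sum to 1),

and the meta-learner — an MLP with hidden layers (256, 128, 64) — is
trained on the weighted posteriors

    zeta[:, mu] = w_mu * P[:, mu].

Out-of-fold stacking: the training set is partitioned into K
subject-grouped, label-stratified folds; each base learner is fitted K
times on K-1 folds and predicts the held-out fold, so every training
sample gets exactly one posterior per learner from a model that never saw
any segment of its subject.  Final base learners are refitted on the full
training set; Platt calibration is fitted on the pooled out-of-fold
posteriors.

Two baselines share the same fitted base learners: soft voting (the
unweighted mean of calibrated posteriors) and plain stacking (the
meta-learner on unweighted posteriors, w = 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Callable

import numpy as np
from sklearn.model_selection import StratifiedGroupKFold
from sklearn.neural_network import MLPClassifier

from . import learners as L
from .errors import InvalidConfigError, InvalidInputError, NotFittedError
from .evaluation import roc_auc

__all__ = [
    "EnsembleWeights",
    "LearnerSpec",
    "StackedEnsemble",
    "auc_weights",
    "build_meta_input",
    "out_of_fold_stack",
    "train_meta_mlp",
    "predict_ensemble",
    "baseline_predict",
    "fit_stacked_ensemble",
    "texture_svm_spec",
    "deep_pca_rf_spec",
]


@dataclass(frozen=True)
class EnsembleWeights:
    """Normalized AUC-derived weights, ordered like the base learners."""

    omega: np.ndarray
    source_aucs: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.omega, dtype=float)
        object.__setattr__(self, "omega", w)
        object.__setattr__(self, "source_aucs",
                           np.asarray(self.source_aucs, dtype=float))
        if abs(w.sum() - 1.0) > 1e-9:
            raise InvalidInputError("weights must sum to 1")


def auc_weights(aucs: np.ndarray) -> EnsembleWeights:
    """w_i = h_i / sum(h); every h must lie in (0, 1]."""
    h = np.asarray(aucs, dtype=float)
    if h.ndim != 1 or len(h) == 0:
        raise InvalidInputError("aucs must be a non-empty 1-D vector")
    if np.any(h <= 0) or np.any(h > 1):
        raise InvalidInputError("validation AUCs must lie in (0, 1]")
    return EnsembleWeights(omega=h / h.sum(), source_aucs=h)


def build_meta_input(P: np.ndarray, w: EnsembleWeights) -> np.ndarray:
    """zeta[:, i] = w_i * P[:, i] (columnwise scaling of posteriors)."""
    P = np.asarray(P, dtype=float)
    if P.ndim != 2 or P.shape[1] != len(w.omega):
        raise InvalidInputError("posterior matrix width must equal the number "
                                "of weights")
    return P * w.omega[None, :]


@dataclass(frozen=True)
class LearnerSpec:
    """Recipe for one base learner.

    ``factory(seed)`` returns a fresh adapter with ``fit(X, y)`` and
    ``predict_posterior(X)``; ``feature_key`` names the feature set the
    learner consumes.
    """

    name: str
    feature_key: str
    factory: Callable[[int], Any]


class _SkAdapter:
    def __init__(self, train_fn: Callable[[np.ndarray, np.ndarray], L.BaseLearner]):
        self._train_fn = train_fn
        self.model: L.BaseLearner | None = None

    def fit(self, X: np.ndarray, y: np.ndarray) -> "_SkAdapter":
        self.model = self._train_fn(X, y)
        return self

    def predict_posterior(self, X: np.ndarray) -> np.ndarray:
        if self.model is None:
            raise NotFittedError("adapter not fitted")
        return L.predict_posterior(self.model, X)


def texture_svm_spec(name: str = "texture", feature_key: str = "texture",
                     n_select: int = 10, **kw) -> LearnerSpec:
    def factory(seed: int) -> _SkAdapter:
        return _SkAdapter(lambda X, y: L.train_texture_svm_rfe(
            X, y, n_select=n_select, seed=seed, **kw))
    return LearnerSpec(name=name, feature_key=feature_key, factory=factory)


def deep_pca_rf_spec(name: str, feature_key: str,
                     variance_fraction: float = 0.95, n_trees: int = 500) -> LearnerSpec:
    def factory(seed: int) -> _SkAdapter:
        return _SkAdapter(lambda X, y: L.train_deep_pca_rf(
            X, y, variance_fraction=variance_fraction, n_trees=n_trees,
            seed=seed))
    return LearnerSpec(name=name, feature_key=feature_key, factory=factory)


def out_of_fold_stack(feature_sets: dict[str, np.ndarray],
                      specs: list[LearnerSpec], y: np.ndarray,
                      groups: np.ndarray, k_folds: int = 5,
                      seed: int = 0) -> tuple[list[Any], np.ndarray, np.ndarray, dict]:
    """K-fold out-of-fold stacking on the training set.

    Returns (final fitted learners, OOF posterior matrix (n, mu), pooled
    OOF AUC per learner, fold log).  Folds are grouped by subject and
    stratified by label, so no learner predicts a segment of a subject it
    trained on.
    """
    y = np.asarray(y)
    groups = np.asarray(groups)
    n = len(y)
    if k_folds < 2:
        raise InvalidConfigError("k_folds must be >= 2")
    for cls in (-1, 1):
        if len(np.unique(groups[y == cls])) < k_folds:
            raise InvalidConfigError(
                f"fewer than {k_folds} subjects in class {cls}")
    for spec in specs:
        if spec.feature_key not in feature_sets:
            raise InvalidInputError(f"missing feature set '{spec.feature_key}'")
        if len(feature_sets[spec.feature_key]) != n:
            raise InvalidInputError("feature sets and labels disagree in length")

    skf = StratifiedGroupKFold(n_splits=k_folds, shuffle=True, random_state=seed)
    oof = np.full((n, len(specs)), np.nan)
    fold_log = {"seed": seed, "k_folds": k_folds, "assignments": np.empty(n, dtype=int)}
    for fold, (tr, te) in enumerate(skf.split(np.zeros(n), y, groups)):
        fold_log["assignments"][te] = fold
        for j, spec in enumerate(specs):
            X = feature_sets[spec.feature_key]
            learner = spec.factory(seed + 101 * fold + 7 * j)
            learner.fit(X[tr], y[tr])
            oof[te, j] = learner.predict_posterior(X[te])
    if np.isnan(oof).any():
        raise InvalidInputError("folds did not partition the training set")
    aucs = np.array([roc_auc(oof[:, j], y) for j in range(len(specs))])
    final = []
    for j, spec in enumerate(specs):
        learner = spec.factory(seed + 7 * j)
        learner.fit(feature_sets[spec.feature_key], y)
        final.append(learner)
    return final, oof, aucs, fold_log


def train_meta_mlp(Z: np.ndarray, y: np.ndarray, seed: int = 0,
                   hidden: tuple[int, ...] = (256, 128, 64)) -> MLPClassifier:
    """MLP meta-learner on the weighted posteriors; deterministic per seed."""
    y = np.asarray(y)
    if len(set(np.unique(y))) < 2:
        raise InvalidInputError("meta training needs both classes")
    mlp = MLPClassifier(hidden_layer_sizes=hidden, activation="relu",
                        solver="adam", max_iter=500, early_stopping=True,
                        validation_fraction=0.1, n_iter_no_change=25,
                        random_state=seed)
    mlp.fit(np.asarray(Z, dtype=float), y)
    return mlp


@dataclass
class StackedEnsemble:
    """Fitted ensemble: base learners + calibrators + weights + meta-MLP."""

    specs: list[LearnerSpec]
    base_learners: list[Any]
    calibrators: list[L.PlattCalibrator | None]
    weights: EnsembleWeights
    meta: MLPClassifier
    strategy: str = "weighted_stacking"
    oof_aucs: np.ndarray | None = None
    fold_log: dict | None = None

    def base_posteriors(self, feature_sets: dict[str, np.ndarray]) -> np.ndarray:
        cols = []
        for spec, learner, cal in zip(self.specs, self.base_learners,
                                      self.calibrators):
            p = learner.predict_posterior(feature_sets[spec.feature_key])
            if cal is not None:
                p = np.clip(cal(p), 0.0, 1.0)
            cols.append(p)
        return np.column_stack(cols)


def _meta_posterior(meta: MLPClassifier, Z: np.ndarray) -> np.ndarray:
    proba = meta.predict_proba(Z)
    pos = int(np.nonzero(meta.classes_ == 1)[0][0])
    return proba[:, pos]


def predict_ensemble(model: StackedEnsemble,
                     feature_sets: dict[str, np.ndarray]) -> np.ndarray:
    """Calibrated base posteriors -> AUC weighting -> meta posterior p(+1)."""
    first = model.specs[0].feature_key
    if len(feature_sets[first]) == 0:
        return np.zeros(0)
    P = model.base_posteriors(feature_sets)
    return baseline_predict(model.strategy, model, P)


def baseline_predict(strategy: str, model: StackedEnsemble,
                     P: np.ndarray) -> np.ndarray:
    """Fuse calibrated base posteriors P under one of the three strategies."""
    if strategy == "voting":
        return P.mean(axis=1)
    if strategy == "plain_stacking":
        return _meta_posterior(model.meta, P)
    if strategy == "weighted_stacking":
        return _meta_posterior(model.meta, build_meta_input(P, model.weights))
    raise InvalidConfigError(f"unknown strategy: {strategy}")


def fit_stacked_ensemble(feature_sets: dict[str, np.ndarray],
                         specs: list[LearnerSpec], y: np.ndarray,
                         groups: np.ndarray, k_folds: int = 5, seed: int = 0,
                         strategy: str = "weighted_stacking",
                         calibrate: bool = True) -> StackedEnsemble:
    """Full training-side procedure on the training set."""
    final, oof, aucs, fold_log = out_of_fold_stack(feature_sets, specs, y,
                                                   groups, k_folds, seed)
    fold_log["oof"] = oof
    calibrators: list[L.PlattCalibrator | None] = []
    P_oof = np.empty_like(oof)
    for j in range(len(specs)):
        if calibrate:
            lr_cal = _fit_platt(oof[:, j], y)
            calibrators.append(lr_cal)
            P_oof[:, j] = np.clip(lr_cal(oof[:, j]), 0.0, 1.0)
        else:
            calibrators.append(None)
            P_oof[:, j] = oof[:, j]
    w = auc_weights(np.clip(aucs, 1e-6, 1.0))
    if strategy == "plain_stacking":
        Z = P_oof
    else:
        Z = build_meta_input(P_oof, w)
    meta = train_meta_mlp(Z, y, seed=seed)
    return StackedEnsemble(specs=specs, base_learners=final,
                           calibrators=calibrators, weights=w, meta=meta,
                           strategy=strategy, oof_aucs=aucs, fold_log=fold_log)


def _fit_platt(p: np.ndarray, y: np.ndarray) -> L.PlattCalibrator:
    return L.fit_platt(p, y)
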