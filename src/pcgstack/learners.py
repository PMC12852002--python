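"""First-order base models with calibrated class-posterior outputs.

Two kinds:

* ``texture_svm_rfe`` — feature standardization, recursive feature
  elimination ranked by linear-SVM weight magnitudes (removing 10% of the
  remaining features per iteration by default), and a final RBF SVM with
  probability outputs on the selected features;
* ``deep_pca_rf`` — PCA dimensionality reduction (fitted on training
  features only) followed by a random forest.

Posteriors are two-class and complementary: p(-1) + p(+1) = 1 per sample.
An optional Platt (sigmoid) calibration map can be fitted on held-out
predictions; being monotone (for positively-associated scores), it leaves
the ranking — hence the AUC — unchanged while improving probability
calibration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Any

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.feature_selection import RFE
from sklearn.linear_model import LogisticRegression
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .deep_features import PCAModel, fit_pca, transform_pca
from .errors import InvalidInputError, NotFittedError

__all__ = [
    "BaseLearner",
    "PlattCalibrator",
    "train_texture_svm_rfe",
    "train_deep_pca_rf",
    "calibrate",
    "predict_posterior",
]


@dataclass(frozen=True)
class PlattCalibrator:
    """Sigmoid map p -> 1 / (1 + exp(-(a*p + b))) fitted by logistic
    regression of the held-out labels on the raw posterior."""

    a: float
    b: float

    def __call__(self, p: np.ndarray) -> np.ndarray:
        return 1.0 / (1.0 + np.exp(-(self.a * np.asarray(p) + self.b)))


@dataclass
class BaseLearner:
    """A fitted first-order model plus its preprocessing and calibration."""

    kind: str                      # "texture_svm_rfe" | "deep_pca_rf"
    scaler: StandardScaler | None = None
    rfe_support: np.ndarray | None = None
    pca: PCAModel | None = None
    clf: Any = None
    calibrator: PlattCalibrator | None = None
    validation_auc: float | None = None

    def _raw_posterior(self, X: np.ndarray) -> np.ndarray:
        if self.clf is None:
            raise NotFittedError("base learner is not fitted")
        X = np.asarray(X, dtype=float)
        if X.shape[0] == 0:
            return np.zeros(0)
        if self.scaler is not None:
            X = self.scaler.transform(X)
        if self.rfe_support is not None:
            X = X[:, self.rfe_support]
        if self.pca is not None:
            X = transform_pca(self.pca, X)
        proba = self.clf.predict_proba(X)
        pos_col = int(np.nonzero(self.clf.classes_ == 1)[0][0])
        return proba[:, pos_col]


def _check_two_classes(y: np.ndarray) -> np.ndarray:
    y = np.asarray(y)
    if set(np.unique(y)) != {-1, 1}:
        raise InvalidInputError("labels must contain both classes -1 and +1")
    return y


def train_texture_svm_rfe(X: np.ndarray, y: np.ndarray, n_select: int = 10,
                          rfe_step: float = 0.1, C: float = 1.0,
                          gamma: str | float = "scale",
                          seed: int = 0) -> BaseLearner:
    """RFE (linear-SVM weight ranking) down to ``n_select`` features, then
    an RBF SVM with probability outputs on the selected features."""
    X = np.asarray(X, dtype=float)
    y = _check_two_classes(y)
    if n_select > X.shape[1]:
        raise InvalidInputError("n_select exceeds the feature count")
    scaler = StandardScaler().fit(X)
    Xs = scaler.transform(X)
    rfe = RFE(SVC(kernel="linear", C=C), n_features_to_select=n_select,
              step=rfe_step)
    rfe.fit(Xs, y)
    support = rfe.support_
    clf = SVC(kernel="rbf", C=C, gamma=gamma, probability=True,
              random_state=seed)
    with warnings.catch_warnings():
        # sklearn 1.9 deprecation chatter for probability=True
        warnings.simplefilter("ignore", FutureWarning)
        clf.fit(Xs[:, support], y)
    return BaseLearner(kind="texture_svm_rfe", scaler=scaler,
                       rfe_support=support, clf=clf)


def train_deep_pca_rf(F: np.ndarray, y: np.ndarray,
                      variance_fraction: float = 0.95, n_trees: int = 500,
                      seed: int = 0) -> BaseLearner:
    """PCA (training features only) then a random forest."""
    F = np.asarray(F, dtype=float)
    y = _check_two_classes(y)
    pca = fit_pca(F, variance_fraction)
    Z = transform_pca(pca, F)
    clf = RandomForestClassifier(n_estimators=n_trees, random_state=seed,
                                 n_jobs=1)
    clf.fit(Z, y)
    return BaseLearner(kind="deep_pca_rf", pca=pca, clf=clf)


def fit_platt(p: np.ndarray, y: np.ndarray) -> PlattCalibrator:
    """Platt map from raw posteriors ``p`` and labels ``y``.

    The slope/intercept are rescaled so |a*p + b| <= 30 on [0, 1]: the
    sigmoid then stays strictly monotone in double precision (no saturated
    ties), which preserves the score ranking exactly.
    """
    y = _check_two_classes(y)
    p = np.asarray(p, dtype=float)
    lr = LogisticRegression(C=1e6, solver="lbfgs", max_iter=1000)
    lr.fit(p[:, None], y)
    a = float(lr.coef_[0, 0])
    b = float(lr.intercept_[0])
    peak = max(abs(b), abs(a + b))
    if peak > 30.0:
        a *= 30.0 / peak
        b *= 30.0 / peak
    return PlattCalibrator(a=a, b=b)


def calibrate(learner: BaseLearner, X_val: np.ndarray,
              y_val: np.ndarray) -> BaseLearner:
    """Fit a Platt sigmoid on held-out predictions; returns a new learner."""
    p = learner._raw_posterior(X_val)
    return replace(learner, calibrator=fit_platt(p, y_val))


def predict_posterior(learner: BaseLearner, X: np.ndarray) -> np.ndarray:
    """Calibrated p(+1) per sample (raw posterior if no calibrator)."""
    p = learner._raw_posterior(X)
    if learner.calibrator is not None:
        p = learner.calibrator(p)
    return np.clip(p, 0.0, 1.0)
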