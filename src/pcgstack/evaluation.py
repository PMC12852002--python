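"""Evaluation protocol: subject-grouped stratified splits, the metric
panel, DeLong variance/tests for correlated ROC AUCs, and repeated
evaluation.

AUC is computed as the Mann-Whitney U statistic divided by
n_pos * n_neg with ties counted 1/2.  The DeLong machinery uses placement
values (midranks), giving a distribution-free estimate of the variance of
one AUC and of the covariance between two correlated AUCs computed on the
same samples; the two-sided test statistic is
z = (AUC_A - AUC_B) / sqrt(var(AUC_A - AUC_B)).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.stats import rankdata

from .errors import InvalidInputError

__all__ = [
    "MetricsReport",
    "SplitPlan",
    "roc_auc",
    "binary_metrics",
    "delong_test",
    "auc_ci",
    "subject_stratified_split",
    "repeated_evaluation",
]


@dataclass(frozen=True)
class MetricsReport:
    auc: float
    auc_ci_low: float
    auc_ci_high: float
    accuracy: float
    sensitivity: float
    specificity: float
    precision: float
    f1: float
    threshold: float
    n_pos: int
    n_neg: int
    precision_defined: bool = True

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in (
            "auc", "auc_ci_low", "auc_ci_high", "accuracy", "sensitivity",
            "specificity", "precision", "f1", "threshold", "n_pos", "n_neg")}


@dataclass(frozen=True)
class SplitPlan:
    train_subjects: frozenset[str]
    test_subjects: frozenset[str]
    ratio: float
    seed: int
    repeat_index: int = 0


def _check_labels(labels: np.ndarray) -> np.ndarray:
    y = np.asarray(labels)
    pos = y == 1
    if pos.all() or (~pos).all():
        raise InvalidInputError("both classes must be present")
    return y


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Mann-Whitney AUC with ties counted 1/2."""
    y = _check_labels(labels)
    s = np.asarray(scores, dtype=float)
    pos = y == 1
    n_pos = int(pos.sum())
    n_neg = int((~pos).sum())
    ranks = rankdata(s)
    u = ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def binary_metrics(scores: np.ndarray, labels: np.ndarray,
                   threshold: float = 0.5, ci_level: float = 0.95) -> MetricsReport:
    """Confusion-matrix panel at ``threshold`` plus AUC with a DeLong CI."""
    y = _check_labels(labels)
    s = np.asarray(scores, dtype=float)
    pred = s >= threshold
    pos = y == 1
    tp = int(np.sum(pred & pos))
    fp = int(np.sum(pred & ~pos))
    fn = int(np.sum(~pred & pos))
    tn = int(np.sum(~pred & ~pos))
    sens = tp / (tp + fn) if tp + fn else 0.0
    spec = tn / (tn + fp) if tn + fp else 0.0
    prec_def = (tp + fp) > 0
    prec = tp / (tp + fp) if prec_def else 0.0
    acc = (tp + tn) / len(y)
    f1 = (2 * prec * sens / (prec + sens)) if prec + sens > 0 else 0.0
    auc = roc_auc(s, y)
    lo, hi = auc_ci(s, y, ci_level)
    return MetricsReport(auc=auc, auc_ci_low=lo, auc_ci_high=hi, accuracy=acc,
                         sensitivity=sens, specificity=spec, precision=prec,
                         f1=f1, threshold=threshold, n_pos=int(pos.sum()),
                         n_neg=int((~pos).sum()), precision_defined=prec_def)


def _placements(scores: np.ndarray, pos: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Placement values V10 (per positive) and V01 (per negative) for one
    score vector, plus the AUC."""
    s = np.asarray(scores, dtype=float)
    n_pos = int(pos.sum())
    n_neg = int((~pos).sum())
    all_ranks = rankdata(s)
    pos_ranks = rankdata(s[pos])
    neg_ranks = rankdata(s[~pos])
    v10 = (all_ranks[pos] - pos_ranks) / n_neg
    v01 = 1.0 - (all_ranks[~pos] - neg_ranks) / n_pos
    auc = float(v10.mean())
    return v10, v01, auc


def _delong_cov(score_list: list[np.ndarray], labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """AUCs and their DeLong covariance matrix for k correlated score sets."""
    y = _check_labels(labels)
    pos = y == 1
    n_pos = int(pos.sum())
    n_neg = int((~pos).sum())
    v10s, v01s, aucs = [], [], []
    for s in score_list:
        v10, v01, a = _placements(s, pos)
        v10s.append(v10)
        v01s.append(v01)
        aucs.append(a)
    V10 = np.vstack(v10s)
    V01 = np.vstack(v01s)

    def _cov(V: np.ndarray) -> np.ndarray:
        if V.shape[1] < 2:  # a single subject in the class: no spread info
            return np.zeros((V.shape[0], V.shape[0]))
        return np.atleast_2d(np.cov(V))

    cov = _cov(V10) / n_pos + _cov(V01) / n_neg
    return np.asarray(aucs), cov


def delong_test(scores_a: np.ndarray, scores_b: np.ndarray,
                labels: np.ndarray) -> tuple[float, float]:
    """Two-sided DeLong test for a difference between correlated AUCs.

    Returns (z, p).  Zero variance with zero AUC difference gives p = 1;
    zero variance with a nonzero difference is a degenerate case.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.shape != b.shape:
        raise InvalidInputError("score vectors must cover identical samples")
    aucs, cov = _delong_cov([a, b], labels)
    dauc = aucs[0] - aucs[1]
    var = cov[0, 0] + cov[1, 1] - 2 * cov[0, 1]
    if var <= 1e-15:
        if abs(dauc) < 1e-12:
            return 0.0, 1.0
        raise InvalidInputError("zero variance with nonzero AUC difference")
    z = float(dauc / np.sqrt(var))
    p = float(2.0 * stats.norm.sf(abs(z)))
    return z, p


def auc_ci(scores: np.ndarray, labels: np.ndarray,
           level: float = 0.95) -> tuple[float, float]:
    """DeLong-variance normal-approximation CI, clipped to [0, 1]."""
    aucs, cov = _delong_cov([np.asarray(scores, dtype=float)], labels)
    se = float(np.sqrt(max(cov[0, 0], 0.0)))
    zq = stats.norm.ppf(0.5 + level / 2.0)
    return (float(np.clip(aucs[0] - zq * se, 0.0, 1.0)),
            float(np.clip(aucs[0] + zq * se, 0.0, 1.0)))


def subject_stratified_split(subject_ids: np.ndarray, labels: np.ndarray,
                             ratio: float = 0.7, seed: int = 0,
                             repeat_index: int = 0) -> SplitPlan:
    """Split subjects (not segments) into train/test, stratified by class.

    Every segment of a subject lands on one side of the split.  Per-class
    train counts are round(ratio * n_class).
    """
    subject_ids = np.asarray(subject_ids)
    labels = np.asarray(labels)
    subj_label: dict[str, int] = {}
    for s, l in zip(subject_ids, labels):
        if s in subj_label and subj_label[s] != l:
            raise InvalidInputError(f"subject {s} appears with both labels")
        subj_label[s] = int(l)
    rng = np.random.default_rng(seed)
    train: list[str] = []
    test: list[str] = []
    for cls in (-1, 1):
        subs = sorted(s for s, l in subj_label.items() if l == cls)
        if len(subs) < 2:
            raise InvalidInputError("need at least 2 subjects per class")
        perm = rng.permutation(len(subs))
        n_train = int(round(ratio * len(subs)))
        n_train = min(max(n_train, 1), len(subs) - 1)
        train.extend(subs[i] for i in perm[:n_train])
        test.extend(subs[i] for i in perm[n_train:])
    return SplitPlan(train_subjects=frozenset(train),
                     test_subjects=frozenset(test), ratio=ratio, seed=seed,
                     repeat_index=repeat_index)


def repeated_evaluation(dataset, cfg=None, repeats: int = 10, k_folds: int = 5,
                        seeds: list[int] | None = None):
    """Repeat split -> out-of-fold stacking -> test metrics; average results.

    Thin forwarding wrapper; the implementation lives with the pipeline
    wiring (it needs the full stack).
    """
    from .pipeline import repeated_evaluation as _impl
    return _impl(dataset, cfg, repeats=repeats, k_folds=k_folds, seeds=seeds)
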