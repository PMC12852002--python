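"""AUC-weighted stacking: weights, meta inputs, out-of-fold protocol."""

import numpy as np
import pytest

from pcgstack import (auc_weights, baseline_predict, build_meta_input,
                      out_of_fold_stack, train_meta_mlp)
from pcgstack.ensemble import (LearnerSpec, StackedEnsemble,
                               fit_stacked_ensemble, predict_ensemble,
                               texture_svm_spec, deep_pca_rf_spec)
from pcgstack.errors import InvalidConfigError, InvalidInputError
from pcgstack.evaluation import roc_auc


class TestAucWeights:
    def test_equal_aucs_give_uniform_weights(self):
        w = auc_weights(np.array([0.8, 0.8, 0.8, 0.8]))
        assert np.allclose(w.omega, 0.25)

    def test_two_learner_arithmetic(self):
        w = auc_weights(np.array([0.9, 0.6]))
        assert np.allclose(w.omega, [0.6, 0.4])

    @pytest.mark.parametrize("h", [[0.5, 0.7], [0.91, 0.88, 0.93, 0.77],
                                   [1.0], [0.01, 0.99]])
    def test_weights_sum_to_one(self, h):
        assert abs(auc_weights(np.array(h)).omega.sum() - 1.0) < 1e-12

    def test_nonpositive_auc_rejected(self):
        with pytest.raises(InvalidInputError):
            auc_weights(np.array([0.8, 0.0]))


class TestMetaInput:
    def test_uniform_weights_quarter_scaling(self):
        w = auc_weights(np.array([0.8] * 4))
        P = np.random.default_rng(0).random((6, 4))
        assert np.allclose(build_meta_input(P, w), P / 4)

    def test_zero_column_stays_zero(self):
        w = auc_weights(np.array([0.9, 0.6]))
        P = np.zeros((3, 2))
        assert np.all(build_meta_input(P, w) == 0.0)

    def test_row_arithmetic(self):
        w = auc_weights(np.array([0.9, 0.6]))
        z = build_meta_input(np.array([[0.5, 0.5]]), w)
        assert np.allclose(z, [[0.30, 0.20]])

    def test_entries_bounded_by_weights(self):
        w = auc_weights(np.array([0.7, 0.9, 0.5, 0.8]))
        P = np.random.default_rng(1).random((10, 4))
        Z = build_meta_input(P, w)
        assert np.all(Z <= w.omega[None, :] + 1e-12)

    def test_shape_mismatch_rejected(self):
        w = auc_weights(np.array([0.9, 0.6]))
        with pytest.raises(InvalidInputError):
            build_meta_input(np.zeros((3, 4)), w)


def _grouped_data(seed=0, n_subjects=20, segs=3, n_feat=10, shift=2.0):
    rng = np.random.default_rng(seed)
    X, y, groups = [], [], []
    for s in range(n_subjects):
        label = -1 if s < n_subjects // 2 else 1
        mu = rng.normal(size=n_feat) * 0.3
        for g in range(segs):
            row = rng.normal(size=n_feat) + mu
            if label == 1:
                row[:3] += shift
            X.append(row)
            y.append(label)
            groups.append(f"subj{s}")
    return np.array(X), np.array(y), np.array(groups)


class _Memorizer:
    """Pathological learner: posterior 1 iff the exact sample was in its
    training data.  In-fold it is perfect; out-of-fold it knows nothing."""

    def __init__(self):
        self.seen = None

    def fit(self, X, y):
        self.seen = {tuple(np.round(r, 10)) for r in X}
        return self

    def predict_posterior(self, X):
        return np.array([1.0 if tuple(np.round(r, 10)) in self.seen else 0.0
                         for r in X])


class TestOutOfFoldStack:
    def test_memorizer_defeated_by_oof_protocol(self):
        X, y, groups = _grouped_data()
        spec = LearnerSpec(name="memo", feature_key="f",
                           factory=lambda seed: _Memorizer())
        _, oof, aucs, _ = out_of_fold_stack({"f": X}, [spec], y, groups,
                                            k_folds=5, seed=0)
        assert np.all(oof == 0.0)     # no OOF sample was memorized
        assert abs(aucs[0] - 0.5) < 1e-12  # all-tie scores -> AUC exactly 1/2

    def test_oof_shape_and_partition(self):
        X, y, groups = _grouped_data(1)
        specs = [deep_pca_rf_spec("rf1", "f", n_trees=30),
                 deep_pca_rf_spec("rf2", "f", n_trees=30)]
        _, oof, aucs, log = out_of_fold_stack({"f": X}, specs, y, groups,
                                              k_folds=4, seed=1)
        assert oof.shape == (len(y), 2)
        assert not np.isnan(oof).any()
        # fold assignments partition the samples and respect subjects
        assign = log["assignments"]
        assert set(assign) == set(range(4))
        for subj in np.unique(groups):
            assert len(np.unique(assign[groups == subj])) == 1

    def test_too_few_subjects_rejected(self):
        X, y, groups = _grouped_data(2, n_subjects=6)
        spec = deep_pca_rf_spec("rf", "f", n_trees=10)
        with pytest.raises(InvalidConfigError):
            out_of_fold_stack({"f": X}, [spec], y, groups, k_folds=5)


class TestMetaMLP:
    def test_separable_meta_input_learned(self):
        rng = np.random.default_rng(0)
        n = 200
        y = np.repeat([-1, 1], n // 2)
        Z = rng.random((n, 4)) * 0.2
        Z[y == 1] += 0.6
        mlp = train_meta_mlp(Z, y, seed=0)
        assert (mlp.predict(Z) == y).mean() >= 0.99

    def test_same_seed_identical_predictions(self):
        rng = np.random.default_rng(1)
        Z = rng.random((80, 4))
        y = np.where(Z.sum(1) > 2, 1, -1)
        p1 = train_meta_mlp(Z, y, seed=3).predict_proba(Z)
        p2 = train_meta_mlp(Z, y, seed=3).predict_proba(Z)
        assert np.array_equal(p1, p2)

    def test_posteriors_in_unit_interval(self):
        rng = np.random.default_rng(2)
        Z = rng.random((60, 4))
        y = np.where(Z[:, 0] > 0.5, 1, -1)
        p = train_meta_mlp(Z, y, seed=0).predict_proba(Z)
        assert np.all((p >= 0) & (p <= 1))

    def test_single_class_rejected(self):
        with pytest.raises(InvalidInputError):
            train_meta_mlp(np.zeros((5, 4)), np.ones(5, dtype=int))


@pytest.fixture(scope="module")
def fitted():
    X, y, groups = _grouped_data(3, n_subjects=24, shift=3.0)
    feats = {"texture": X, "deep": X + 0.01}
    specs = [texture_svm_spec(n_select=5),
             deep_pca_rf_spec("deep", "deep", n_trees=50)]
    model = fit_stacked_ensemble(feats, specs, y, groups, k_folds=4, seed=0)
    return model, feats, y


class TestEndToEndEnsemble:
    def test_weights_sum_to_one(self, fitted):
        model, _, _ = fitted
        assert abs(model.weights.omega.sum() - 1.0) < 1e-12

    def test_prediction_deterministic(self, fitted):
        model, feats, _ = fitted
        assert np.array_equal(predict_ensemble(model, feats),
                              predict_ensemble(model, feats))

    def test_separable_data_recovered(self, fitted):
        model, feats, y = fitted
        assert roc_auc(predict_ensemble(model, feats), y) >= 0.95

    def test_empty_batch_empty_output(self, fitted):
        model, feats, _ = fitted
        empty = {k: v[:0] for k, v in feats.items()}
        assert predict_ensemble(model, empty).size == 0

    def test_voting_is_posterior_mean(self, fitted):
        model, _, _ = fitted
        P = np.array([[0.2, 0.4], [0.8, 0.6]])
        assert np.allclose(baseline_predict("voting", model, P), [0.3, 0.7])

    def test_voting_of_equal_posteriors_is_identity(self, fitted):
        model, _, _ = fitted
        P = np.tile(np.array([[0.2], [0.9]]), (1, 2))
        assert np.allclose(baseline_predict("voting", model, P), [0.2, 0.9])


def test_equal_aucs_reduce_weighted_to_scaled_plain():
    """With equal validation AUCs the weighted meta input equals the plain
    stacking input scaled by 1/mu."""
    w = auc_weights(np.array([0.85] * 4))
    P = np.random.default_rng(5).random((12, 4))
    assert np.allclose(build_meta_input(P, w), P / 4.0)


def test_voting_mean_of_four():
    class Dummy:  # strategy dispatch needs no fitted model for voting
        pass

    P = np.array([[0.2, 0.4, 0.6, 0.8]])
    model = StackedEnsemble(specs=[], base_learners=[], calibrators=[],
                            weights=auc_weights(np.array([1.0])),
                            meta=None)
    assert np.allclose(baseline_predict("voting", model, P), [0.5])
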