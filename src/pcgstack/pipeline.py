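"""End-to-end wiring: recordings -> conditioned signals -> gammatonegram
images -> {texture, deep} feature sets -> base learners -> AUC-weighted
stacking -> test metrics.

The desk profile keeps every stage CPU-cheap: 64x64 spectrogram images,
the deterministic ``desk_default`` backbone standing in for the three
pretrained CNNs (three different seeds provide learner diversity), and
modest learner sizes.  Swapping in real pretrained backbones is a config
change (``PipelineConfig.backbones``), not a code change.

Feature extraction is unsupervised and per-recording, so features are
computed once for the whole dataset and cached keyed by a hash of the
upstream configuration; the train/test and fold splits operate on sample
indices afterwards.  All supervised fitting (RFE, PCA, scalers,
classifiers, calibration, meta-learner) happens strictly inside training
folds.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, replace

import numpy as np

from . import ensemble as E
from . import evaluation as ev
from .deep_features import BackboneSpec, extract_features
from .errors import StageError
from .gammatone import gammatonegram_image
from .preprocess import PreprocessConfig, preprocess_recording
from .simulate import PCGRecording, SimulationConfig, simulate_dataset
from .texture import FEATURE_NAMES, extract_texture_features, feature_vector

__all__ = [
    "PipelineConfig",
    "PipelineResult",
    "compute_features",
    "run_pipeline",
    "run_strategy_comparison",
    "repeated_evaluation",
]


@dataclass(frozen=True)
class GammatonegramConfig:
    n_channels: int = 64
    fmin_hz: float = 20.0
    fmax_hz: float = 1000.0
    frame_ms: float = 25.0
    hop_ms: float = 10.0
    dynamic_range_db: float = 60.0
    image_size: tuple[int, int] = (64, 64)


@dataclass(frozen=True)
class TextureConfig:
    n_gray_levels: int = 32
    gldm_delta: int = 0
    gldm_distance: int = 1


@dataclass(frozen=True)
class LearnerConfig:
    svm_n_select: int = 10
    svm_c: float = 1.0
    pca_variance_fraction: float = 0.95
    rf_n_trees: int = 300


@dataclass(frozen=True)
class PipelineConfig:
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    gammatonegram: GammatonegramConfig = field(default_factory=GammatonegramConfig)
    texture: TextureConfig = field(default_factory=TextureConfig)
    backbones: tuple[BackboneSpec, ...] = (
        BackboneSpec(name="desk_default", seed=11),
        BackboneSpec(name="desk_default", seed=22),
        BackboneSpec(name="desk_default", seed=33),
    )
    learner: LearnerConfig = field(default_factory=LearnerConfig)
    k_folds: int = 5
    split_ratio: float = 0.7
    threshold: float = 0.5
    calibrate: bool = True
    seed: int = 0

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        d["preprocess"] = PreprocessConfig(**d["preprocess"])
        g = dict(d["gammatonegram"])
        g["image_size"] = tuple(g["image_size"])
        d["gammatonegram"] = GammatonegramConfig(**g)
        d["texture"] = TextureConfig(**d["texture"])
        d["learner"] = LearnerConfig(**d["learner"])
        backbones = []
        for b in d["backbones"]:
            b = dict(b)
            ts = b.pop("train_settings", None)
            if ts is not None:
                from .deep_features import TrainSettings
                b["train_settings"] = TrainSettings(**ts)
            backbones.append(BackboneSpec(**b))
        d["backbones"] = tuple(backbones)
        return cls(**d)

    def upstream_hash(self) -> str:
        payload = json.dumps({k: self.to_dict()[k] for k in
                              ("preprocess", "gammatonegram", "texture",
                               "backbones")}, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class PipelineResult:
    model: E.StackedEnsemble
    metrics: ev.MetricsReport
    weights: np.ndarray
    oof_aucs: np.ndarray
    base_test_aucs: dict[str, float]
    test_scores: np.ndarray
    test_labels: np.ndarray
    split: ev.SplitPlan
    provenance: dict


_FEATURE_CACHE: dict[tuple, dict[str, np.ndarray]] = {}


def _dataset_hash(recordings: list[PCGRecording]) -> str:
    """Content hash of a dataset: ids, rates, and the raw sample bytes.

    Keying the cache on content (not just segment ids) means two datasets
    that happen to share naming can never alias each other's features.
    """
    h = hashlib.sha256()
    for r in recordings:
        h.update(r.segment_id.encode())
        h.update(str(r.fs).encode())
        h.update(np.ascontiguousarray(r.samples).tobytes())
    return h.hexdigest()


def compute_features(recordings: list[PCGRecording], cfg: PipelineConfig,
                     use_cache: bool = True) -> dict[str, np.ndarray]:
    """Per-recording image features for every learner pathway.

    Returns feature sets keyed 'texture', 'deep_0', 'deep_1', ... plus a
    cached entry keyed by (config hash, segment ids).
    """
    key = (cfg.upstream_hash(), _dataset_hash(recordings))
    if use_cache and key in _FEATURE_CACHE:
        return _FEATURE_CACHE[key]
    g = cfg.gammatonegram
    images = []
    tex_rows = []
    for rec in recordings:
        try:
            pp = preprocess_recording(rec, cfg.preprocess)
        except Exception as exc:
            raise StageError("preprocess", f"segment {rec.segment_id}: {exc}")
        try:
            img = gammatonegram_image(
                pp.samples, pp.fs, n_channels=g.n_channels, fmin=g.fmin_hz,
                fmax=g.fmax_hz, frame_ms=g.frame_ms, hop_ms=g.hop_ms,
                dynamic_range_db=g.dynamic_range_db, out_shape=g.image_size)
        except Exception as exc:
            raise StageError("gammatonegram", f"segment {rec.segment_id}: {exc}")
        images.append(img)
        try:
            feats = extract_texture_features(
                img, ng=cfg.texture.n_gray_levels, delta=cfg.texture.gldm_delta,
                distance=cfg.texture.gldm_distance)
        except Exception as exc:
            raise StageError("texture", f"segment {rec.segment_id}: {exc}")
        tex_rows.append(feature_vector(feats))
    stack = np.asarray(images)
    out: dict[str, np.ndarray] = {"texture": np.vstack(tex_rows)}
    for i, spec in enumerate(cfg.backbones):
        out[f"deep_{i}"] = extract_features(stack, spec)
    if use_cache:
        _FEATURE_CACHE[key] = out
    return out


def default_specs(cfg: PipelineConfig) -> list[E.LearnerSpec]:
    lc = cfg.learner
    specs = [E.texture_svm_spec(n_select=lc.svm_n_select, C=lc.svm_c)]
    for i in range(len(cfg.backbones)):
        specs.append(E.deep_pca_rf_spec(
            name=f"deep_{i}", feature_key=f"deep_{i}",
            variance_fraction=lc.pca_variance_fraction, n_trees=lc.rf_n_trees))
    return specs


def _split_dataset(recordings: list[PCGRecording], cfg: PipelineConfig,
                   seed: int, repeat_index: int = 0):
    subj = np.array([r.subject_id for r in recordings])
    y = np.array([r.label for r in recordings])
    plan = ev.subject_stratified_split(subj, y, ratio=cfg.split_ratio,
                                       seed=seed, repeat_index=repeat_index)
    tr = np.array([s in plan.train_subjects for s in subj])
    return plan, tr, ~tr, subj, y


def run_pipeline(recordings: list[PCGRecording],
                 cfg: PipelineConfig = PipelineConfig(),
                 strategy: str = "weighted_stacking",
                 features: dict[str, np.ndarray] | None = None,
                 split_seed: int | None = None) -> PipelineResult:
    """Train on a 7:3 subject-stratified split and evaluate on the test side."""
    seed = cfg.seed if split_seed is None else split_seed
    plan, tr, te, subj, y = _split_dataset(recordings, cfg, seed)
    if features is None:
        features = compute_features(recordings, cfg)
    feats_tr = {k: v[tr] for k, v in features.items()}
    feats_te = {k: v[te] for k, v in features.items()}
    model = E.fit_stacked_ensemble(feats_tr, default_specs(cfg), y[tr],
                                   subj[tr], k_folds=cfg.k_folds,
                                   seed=cfg.seed, strategy=strategy,
                                   calibrate=cfg.calibrate)
    scores = E.predict_ensemble(model, feats_te)
    metrics = ev.binary_metrics(scores, y[te], threshold=cfg.threshold)
    P_te = model.base_posteriors(feats_te)
    base_aucs = {spec.name: ev.roc_auc(P_te[:, j], y[te])
                 for j, spec in enumerate(model.specs)}
    provenance = {"config": cfg.to_dict(), "config_hash": cfg.upstream_hash(),
                  "split_seed": seed, "train_subjects": sorted(plan.train_subjects),
                  "fold_seed": model.fold_log["seed"] if model.fold_log else None}
    return PipelineResult(model=model, metrics=metrics,
                          weights=model.weights.omega, oof_aucs=model.oof_aucs,
                          base_test_aucs=base_aucs, test_scores=scores,
                          test_labels=y[te], split=plan, provenance=provenance)


def run_strategy_comparison(recordings: list[PCGRecording],
                            cfg: PipelineConfig = PipelineConfig(),
                            features: dict[str, np.ndarray] | None = None) -> dict:
    """Evaluate voting / plain stacking / weighted stacking on identical
    splits, folds, and fitted base learners; DeLong-compare their AUCs."""
    plan, tr, te, subj, y = _split_dataset(recordings, cfg, cfg.seed)
    if features is None:
        features = compute_features(recordings, cfg)
    feats_tr = {k: v[tr] for k, v in features.items()}
    feats_te = {k: v[te] for k, v in features.items()}
    base = E.fit_stacked_ensemble(feats_tr, default_specs(cfg), y[tr],
                                  subj[tr], k_folds=cfg.k_folds, seed=cfg.seed,
                                  strategy="weighted_stacking",
                                  calibrate=cfg.calibrate)
    # plain stacking needs its own meta (trained on unweighted posteriors)
    oof = _oof_matrix(base)
    P_oof = np.column_stack([
        np.clip(cal(oof[:, j]), 0, 1) if cal is not None else oof[:, j]
        for j, cal in enumerate(base.calibrators)])
    plain_meta = E.train_meta_mlp(P_oof, y[tr], seed=cfg.seed)
    P_te = base.base_posteriors(feats_te)
    scores = {
        "voting": E.baseline_predict("voting", base, P_te),
        "plain_stacking": E._meta_posterior(plain_meta, P_te),
        "weighted_stacking": E.baseline_predict("weighted_stacking", base, P_te),
    }
    report: dict = {"strategies": {}, "delong": {}}
    for name, sc in scores.items():
        report["strategies"][name] = ev.binary_metrics(
            sc, y[te], threshold=cfg.threshold).as_dict()
    for a, b in (("weighted_stacking", "voting"),
                 ("weighted_stacking", "plain_stacking"),
                 ("plain_stacking", "voting")):
        z, p = ev.delong_test(scores[a], scores[b], y[te])
        report["delong"][f"{a}_vs_{b}"] = {"z": z, "p": p}
    return report


def _oof_matrix(model: E.StackedEnsemble) -> np.ndarray:
    if model.fold_log is None or "oof" not in model.fold_log:
        raise StageError("ensemble", "fold log lacks OOF posteriors")
    return model.fold_log["oof"]


def repeated_evaluation(recordings: list[PCGRecording],
                        cfg: PipelineConfig | None = None, repeats: int = 10,
                        k_folds: int | None = None,
                        seeds: list[int] | None = None) -> dict:
    """Fresh split -> stacking -> test metrics per repeat; averaged panel."""
    cfg = cfg or PipelineConfig()
    if k_folds is not None:
        cfg = replace(cfg, k_folds=k_folds)
    if seeds is None:
        seeds = [cfg.seed + 1000 * r for r in range(repeats)]
    features = compute_features(recordings, cfg)
    per_repeat = []
    for r, s in enumerate(seeds[:repeats]):
        res = run_pipeline(recordings, cfg, features=features, split_seed=s)
        per_repeat.append(res.metrics.as_dict())
    mean = {k: float(np.mean([m[k] for m in per_repeat]))
            for k in per_repeat[0] if k not in ("threshold",)}
    mean["threshold"] = cfg.threshold
    return {"mean": mean, "per_repeat": per_repeat, "seeds": list(seeds[:repeats])}


def simulate_and_run(sim_cfg: SimulationConfig | None = None,
                     cfg: PipelineConfig | None = None) -> PipelineResult:
    """Convenience: simulate a dataset and run the full pipeline once."""
    sim_cfg = sim_cfg or SimulationConfig()
    cfg = cfg or PipelineConfig(seed=sim_cfg.seed)
    return run_pipeline(simulate_dataset(sim_cfg), cfg)
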