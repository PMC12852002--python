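"""Synthetic phonocardiogram (PCG) generator.

Produces seeded datasets with the statistical structure the detection
pipeline assumes: ~10-s single-channel recordings grouped by subject
(several segments per subject share one label), quasi-periodic S1/S2
heart-sound bursts, per-subject random effects, and a tunable
class-dependent spectral difference plus additive white noise.

The waveform model is deliberately simple — each cardiac cycle contains a
Gaussian-windowed S1 tone in the 30–60 Hz region and a shorter S2 tone in
the 50–90 Hz region at a spacing set by the heart rate.  The positive
("case") class adds a low-frequency third component after S2 and shifts the
S2 center frequency upward; both effects scale linearly with
``effect_size``, so ``effect_size = 0`` makes the two class-conditional
distributions identical.  The class difference manifests as a band-energy
(hence spectrogram-texture) difference, which is exactly the signal the
texture and deep-feature pathways are meant to detect.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.io import wavfile

from .errors import InvalidConfigError

__all__ = [
    "SimulationConfig",
    "PCGRecording",
    "SubjectEffects",
    "simulate_recording",
    "simulate_dataset",
    "write_wav_dataset",
    "load_wav_dataset",
]

# Base acoustic parameters (Hz / seconds); chosen to sit inside the
# physiological S1/S2 bands so the band-pass preprocessing keeps them.
_S1_FREQ = 45.0
_S1_WIDTH = 0.045
_S2_FREQ = 70.0
_S2_WIDTH = 0.030
_S2_AMP = 0.8
_SYSTOLE_FRACTION = 0.35  # S2 onset as a fraction of the cardiac cycle
_EXTRA_FREQ = 25.0        # class-dependent low-frequency component
_EXTRA_WIDTH = 0.060
_EXTRA_AMP = 0.35         # per unit effect_size
_S2_SHIFT_HZ = 12.0       # per unit effect_size


@dataclass(frozen=True)
class SimulationConfig:
    """World description for one synthetic dataset.

    Defaults mirror the scale of a small clinical auscultation study:
    tens of subjects per class, five ~10-s segments per subject, recorded
    at 4410 Hz so the downsample-to-2205-Hz preprocessing step is real.
    """

    n_subjects_per_class: int = 40
    segments_per_subject: int = 5
    duration_s: float = 10.0
    fs: int = 4410
    heart_rate_bpm: float = 70.0
    effect_size: float = 1.0
    noise_sd: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects_per_class < 1 or self.segments_per_subject < 1:
            raise InvalidConfigError("subject/segment counts must be positive")
        if self.duration_s <= 0 or self.fs <= 0:
            raise InvalidConfigError("duration_s and fs must be positive")
        n = self.duration_s * self.fs
        if abs(n - round(n)) > 1e-9 or round(n) < 1:
            raise InvalidConfigError("duration_s * fs must be a positive integer")
        if self.heart_rate_bpm <= 0:
            raise InvalidConfigError("heart_rate_bpm must be positive")
        if self.effect_size < 0 or self.noise_sd < 0:
            raise InvalidConfigError("effect_size and noise_sd must be non-negative")

    @property
    def n_samples(self) -> int:
        return int(round(self.duration_s * self.fs))


@dataclass(frozen=True)
class SubjectEffects:
    """Per-subject random effects: amplitude scale, timing jitter scale,
    and a small subject-specific frequency offset (class-independent)."""

    amplitude: float = 1.0
    timing_jitter_sd: float = 0.01
    freq_offset_hz: float = 0.0


@dataclass(frozen=True)
class PCGRecording:
    """A labeled, subject-tagged single-channel heart-sound signal."""

    samples: np.ndarray
    fs: int
    subject_id: str
    label: int  # -1 (non-case) or +1 (case)
    segment_id: str = ""

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        object.__setattr__(self, "samples", samples)
        if samples.size == 0:
            raise InvalidConfigError("recording must contain at least one sample")
        if self.label not in (-1, 1):
            raise InvalidConfigError("label must be -1 or +1")
        if self.fs <= 0:
            raise InvalidConfigError("fs must be positive")


def _gaussian_burst(t: np.ndarray, center: float, width: float, freq: float,
                    amp: float) -> np.ndarray:
    env = np.exp(-0.5 * ((t - center) / width) ** 2)
    return amp * env * np.cos(2.0 * np.pi * freq * (t - center))


def simulate_recording(cls: int, subject_effects: SubjectEffects,
                       cfg: SimulationConfig, seed: int) -> PCGRecording:
    """Synthesize one recording for class ``cls`` (+1 case / -1 control).

    Deterministic given ``(cls, subject_effects, cfg, seed)``.
    """
    if cls not in (-1, 1):
        raise InvalidConfigError("cls must be -1 or +1")
    rng = np.random.default_rng(seed)
    n = cfg.n_samples
    t = np.arange(n) / cfg.fs
    x = np.zeros(n)

    cycle = 60.0 / cfg.heart_rate_bpm
    n_cycles = int(np.ceil(cfg.duration_s / cycle)) + 1
    eff = cfg.effect_size if cls == 1 else 0.0
    f1 = _S1_FREQ + subject_effects.freq_offset_hz
    f2 = _S2_FREQ + subject_effects.freq_offset_hz + eff * _S2_SHIFT_HZ

    for k in range(n_cycles):
        jitter = rng.normal(0.0, subject_effects.timing_jitter_sd)
        t0 = k * cycle + jitter
        amp_jit = 1.0 + 0.05 * rng.normal()
        x += _gaussian_burst(t, t0, _S1_WIDTH, f1, amp_jit)
        x += _gaussian_burst(t, t0 + _SYSTOLE_FRACTION * cycle, _S2_WIDTH,
                             f2, _S2_AMP * amp_jit)
        if eff > 0:
            # low-frequency extra component after S2 (S3-gallop-like)
            x += _gaussian_burst(t, t0 + (_SYSTOLE_FRACTION + 0.12) * cycle,
                                 _EXTRA_WIDTH, _EXTRA_FREQ,
                                 eff * _EXTRA_AMP * amp_jit)

    x *= subject_effects.amplitude
    if cfg.noise_sd > 0:
        x = x + rng.normal(0.0, cfg.noise_sd, size=n)
    return PCGRecording(samples=x, fs=cfg.fs, subject_id="", label=cls)


def _draw_subject_effects(rng: np.random.Generator) -> SubjectEffects:
    return SubjectEffects(
        amplitude=float(np.exp(rng.normal(0.0, 0.15))),
        timing_jitter_sd=float(np.abs(rng.normal(0.01, 0.003))),
        freq_offset_hz=float(rng.normal(0.0, 2.0)),
    )


def simulate_dataset(cfg: SimulationConfig) -> list[PCGRecording]:
    """Generate the full grouped dataset described by ``cfg``.

    ``n_subjects_per_class * 2`` subjects, each contributing
    ``segments_per_subject`` recordings that share subject_id and label.
    All per-recording seeds derive deterministically from ``cfg.seed``.
    """
    ss = np.random.SeedSequence(cfg.seed)
    recordings: list[PCGRecording] = []
    n_subj = cfg.n_subjects_per_class
    subj_seeds = ss.spawn(2 * n_subj)
    for ci, cls in enumerate((-1, 1)):
        for s in range(n_subj):
            child = subj_seeds[ci * n_subj + s]
            rng = np.random.default_rng(child)
            effects = _draw_subject_effects(rng)
            tag = "neg" if cls == -1 else "pos"
            subject_id = f"{tag}_subj{s:03d}"
            seg_seeds = rng.integers(0, 2**31 - 1, size=cfg.segments_per_subject)
            for g in range(cfg.segments_per_subject):
                rec = simulate_recording(cls, effects, cfg, int(seg_seeds[g]))
                recordings.append(replace(
                    rec, subject_id=subject_id,
                    segment_id=f"{subject_id}_seg{g}"))
    return recordings


def write_wav_dataset(recordings: list[PCGRecording], out_dir: str) -> str:
    """Write 16-bit PCM WAVs plus a CSV manifest; returns the manifest path."""
    os.makedirs(out_dir, exist_ok=True)
    rows = []
    for rec in recordings:
        path = os.path.join(out_dir, f"{rec.segment_id}.wav")
        x = rec.samples
        peak = np.max(np.abs(x)) or 1.0
        pcm = np.clip(x / peak, -1.0, 1.0)
        wavfile.write(path, rec.fs, (pcm * 32767).astype(np.int16))
        rows.append({"segment_id": rec.segment_id, "subject_id": rec.subject_id,
                     "label": rec.label, "path": path})
    manifest = os.path.join(out_dir, "manifest.csv")
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def load_wav_dataset(manifest_path: str) -> list[PCGRecording]:
    """Load a manifest written by :func:`write_wav_dataset`."""
    df = pd.read_csv(manifest_path)
    recs = []
    for row in df.itertuples():
        if not os.path.exists(row.path):
            raise FileNotFoundError(
                f"audio file missing for segment_id={row.segment_id}: {row.path}")
        fs, pcm = wavfile.read(row.path)
        x = pcm.astype(float) / 32767.0
        recs.append(PCGRecording(samples=x, fs=int(fs),
                                 subject_id=str(row.subject_id),
                                 label=int(row.label),
                                 segment_id=str(row.segment_id)))
    return recs
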