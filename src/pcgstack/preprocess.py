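"""Signal conditioning for raw PCG audio.

The chain, in order: Butterworth band-pass (10–1000 Hz, zero-phase),
linear-phase FIR notch at the 50 Hz mains frequency, optional
SVD + wavelet denoising, resampling to 2205 Hz, and z-score
normalization.

The notch is a fixed linear-phase FIR band-stop applied zero-phase
(symmetric taps, centred convolution); an LMS-adaptive variant that tracks
the mains component with a sin/cos reference pair is available behind
``adaptive=True``.

The denoiser embeds the signal in a Hankel matrix (window = fs/10 by
default), keeps the leading singular components carrying 95% of the
singular-value energy, reconstructs by anti-diagonal averaging, then
applies a 5-level db4 wavelet shrinkage with a soft universal threshold
estimated from the finest-detail median absolute deviation.  A small
periodized discrete wavelet transform is implemented here because no DWT
library is available in the runtime.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from fractions import Fraction

import numpy as np
from scipy import signal

from .errors import DegenerateInputError, InvalidConfigError, InvalidInputError
from .simulate import PCGRecording

__all__ = [
    "PreprocessConfig",
    "bandpass_butterworth",
    "notch_filter",
    "denoise_svd_wavelet",
    "standardize",
    "preprocess_recording",
]


@dataclass(frozen=True)
class PreprocessConfig:
    band_low_hz: float = 10.0
    band_high_hz: float = 1000.0
    butter_order: int = 4
    notch_hz: float = 50.0
    notch_design_halfwidth_hz: float = 6.0
    notch_numtaps: int = 2401
    target_fs: int = 2205
    denoise_enabled: bool = False
    svd_energy: float = 0.95
    wavelet_levels: int = 5

    def __post_init__(self) -> None:
        if not (0 < self.band_low_hz < self.band_high_hz):
            raise InvalidConfigError("need 0 < band_low_hz < band_high_hz")
        if self.notch_hz <= 0 or self.target_fs <= 0:
            raise InvalidConfigError("notch_hz and target_fs must be positive")
        if self.notch_numtaps % 2 == 0:
            raise InvalidConfigError("notch_numtaps must be odd (linear phase, "
                                     "integer group delay)")


def bandpass_butterworth(x: np.ndarray, fs: float,
                         cfg: PreprocessConfig = PreprocessConfig()) -> np.ndarray:
    """Zero-phase Butterworth band-pass (applied forward-backward)."""
    x = np.asarray(x, dtype=float)
    if cfg.band_high_hz >= fs / 2:
        raise InvalidConfigError(
            f"band_high_hz={cfg.band_high_hz} must be below Nyquist {fs / 2}")
    sos = signal.butter(cfg.butter_order,
                        [cfg.band_low_hz, cfg.band_high_hz],
                        btype="bandpass", fs=fs, output="sos")
    return signal.sosfiltfilt(sos, x)


def _notch_taps(fs: float, cfg: PreprocessConfig) -> np.ndarray:
    low = cfg.notch_hz - cfg.notch_design_halfwidth_hz
    high = cfg.notch_hz + cfg.notch_design_halfwidth_hz
    if high >= fs / 2 or low <= 0:
        raise InvalidConfigError("notch band must lie inside (0, Nyquist)")
    return signal.firwin(cfg.notch_numtaps, [low, high], fs=fs, window="hamming")


def notch_filter(x: np.ndarray, fs: float,
                 cfg: PreprocessConfig = PreprocessConfig(),
                 adaptive: bool = False) -> np.ndarray:
    """Remove the mains (default 50 Hz) component.

    Fixed mode: symmetric FIR band-stop, centred ('same') convolution, so the
    net filter is zero-phase.  Adaptive mode: two-weight LMS canceller with
    quadrature sinusoidal references at ``notch_hz``.
    """
    x = np.asarray(x, dtype=float)
    if cfg.notch_hz >= fs / 2:
        raise InvalidConfigError("notch_hz must be below Nyquist")
    if adaptive:
        return _lms_notch(x, fs, cfg.notch_hz)
    taps = _notch_taps(fs, cfg)
    return signal.fftconvolve(x, taps, mode="same")


def _lms_notch(x: np.ndarray, fs: float, f0: float, mu: float = 0.01) -> np.ndarray:
    n = np.arange(len(x))
    ref_c = np.cos(2 * np.pi * f0 * n / fs)
    ref_s = np.sin(2 * np.pi * f0 * n / fs)
    w = np.zeros(2)
    out = np.empty_like(x)
    for i in range(len(x)):
        est = w[0] * ref_c[i] + w[1] * ref_s[i]
        e = x[i] - est
        out[i] = e
        w += 2 * mu * e * np.array([ref_c[i], ref_s[i]])
    return out


# ---------------------------------------------------------------------------
# SVD + wavelet denoising
# ---------------------------------------------------------------------------

# Daubechies-4 decomposition low-pass coefficients.
_DB4_LO = np.array([
    -0.010597401784997278, 0.032883011666982945, 0.030841381835986965,
    -0.18703481171888114, -0.02798376941698385, 0.6308807679295904,
    0.7148465705525415, 0.23037781330885523,
])
_DB4_HI = (_DB4_LO[::-1] * np.array([(-1) ** k for k in range(len(_DB4_LO))]))


def _dwt_periodic(a: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """One level of the periodized db4 DWT: approximation, detail."""
    n = len(a)
    if n % 2:  # pad by wrap to even length
        a = np.concatenate([a, a[:1]])
        n += 1
    idx = (np.arange(n)[None, :] + np.arange(len(_DB4_LO))[:, None]) % n
    win = a[idx]  # taps x n
    lo_full = _DB4_LO @ win
    hi_full = _DB4_HI @ win
    return lo_full[::2], hi_full[::2]


def _idwt_periodic(lo: np.ndarray, hi: np.ndarray, out_len: int) -> np.ndarray:
    n2 = 2 * len(lo)
    up_lo = np.zeros(n2)
    up_hi = np.zeros(n2)
    up_lo[::2] = lo
    up_hi[::2] = hi
    taps = len(_DB4_LO)
    rec = np.zeros(n2)
    # synthesis filters are time-reversed analysis filters (orthogonal bank)
    for k in range(taps):
        rec += np.roll(up_lo, k) * _DB4_LO[k] + np.roll(up_hi, k) * _DB4_HI[k]
    return rec[:out_len]


def _wavelet_shrink(x: np.ndarray, levels: int) -> np.ndarray:
    coeffs = []
    lens = []
    a = x
    for _ in range(levels):
        if len(a) < len(_DB4_LO):
            break
        lens.append(len(a))
        a, d = _dwt_periodic(a)
        coeffs.append(d)
    if not coeffs:
        return x.copy()
    sigma = np.median(np.abs(coeffs[0])) / 0.6745
    thr = sigma * np.sqrt(2.0 * np.log(max(len(x), 2)))
    shrunk = [np.sign(d) * np.maximum(np.abs(d) - thr, 0.0) for d in coeffs]
    for d, n in zip(reversed(shrunk), reversed(lens)):
        a = _idwt_periodic(a, d, n)
    return a


def _hankel_svd(x: np.ndarray, window: int, energy: float) -> np.ndarray:
    n = len(x)
    K = n - window + 1
    idx = np.arange(window)[:, None] + np.arange(K)[None, :]
    H = x[idx]
    U, s, Vt = np.linalg.svd(H, full_matrices=False)
    e = np.cumsum(s ** 2) / np.sum(s ** 2) if np.sum(s ** 2) > 0 else np.ones_like(s)
    m = int(np.searchsorted(e, energy - 1e-12) + 1)
    Hr = (U[:, :m] * s[:m]) @ Vt[:m]
    # anti-diagonal averaging back to a 1-D signal
    out = np.zeros(n)
    counts = np.zeros(n)
    np.add.at(out, idx.ravel(), Hr.ravel())
    np.add.at(counts, idx.ravel(), 1.0)
    return out / counts


def denoise_svd_wavelet(x: np.ndarray, window: int | None = None,
                        energy: float = 0.95, levels: int = 5) -> np.ndarray:
    """Hankel-SVD subspace projection followed by db4 soft-threshold shrinkage.

    ``window`` defaults to len(x)//10 (the fs/10 convention for ~1-s spans).
    """
    x = np.asarray(x, dtype=float)
    if window is None:
        window = max(8, len(x) // 10)
    if len(x) < 2 * window:
        raise InvalidInputError(
            f"signal of length {len(x)} too short for embedding window {window}")
    if not np.any(x):
        return np.zeros_like(x)
    y = _hankel_svd(x, window, energy)
    return _wavelet_shrink(y, levels)


def standardize(x: np.ndarray, fs: float,
                cfg: PreprocessConfig = PreprocessConfig()) -> tuple[np.ndarray, int]:
    """Resample to ``cfg.target_fs`` then z-score; returns (signal, fs)."""
    x = np.asarray(x, dtype=float)
    if cfg.target_fs > fs:
        raise InvalidConfigError("target_fs must not exceed the input rate")
    if cfg.target_fs != fs:
        frac = Fraction(int(cfg.target_fs), int(fs))
        # padtype="line" keeps constant/linear trends intact at the edges
        x = signal.resample_poly(x, frac.numerator, frac.denominator,
                                 padtype="line")
    sd = np.std(x)
    if sd <= 1e-12 * max(1.0, abs(float(np.mean(x)))):
        raise DegenerateInputError("constant signal cannot be z-scored")
    return (x - np.mean(x)) / sd, cfg.target_fs


def preprocess_recording(rec: PCGRecording,
                         cfg: PreprocessConfig = PreprocessConfig()) -> PCGRecording:
    """Full conditioning chain: band-pass, notch, optional denoise,
    resample + z-score.  Filtering precedes resampling."""
    x = bandpass_butterworth(rec.samples, rec.fs, cfg)
    x = notch_filter(x, rec.fs, cfg)
    if cfg.denoise_enabled:
        x = denoise_svd_wavelet(x, window=max(8, int(rec.fs) // 10),
                                energy=cfg.svd_energy, levels=cfg.wavelet_levels)
    x, fs = standardize(x, rec.fs, cfg)
    return replace(rec, samples=x, fs=fs)
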