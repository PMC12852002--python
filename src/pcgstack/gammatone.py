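"""Gammatone filterbank spectrograms ("gammatonegrams").

The gammatone impulse response is the product of a gamma-distribution
envelope and a sinusoidal carrier,

    g(t, fc) = a * t**(n-1) * exp(-2*pi*b*t) * cos(2*pi*fc*t + phi),  t >= 0,

with order ``n`` (default 4), per-channel bandwidth ``b`` tied to the
equivalent rectangular bandwidth (ERB) of the channel's center frequency
(Glasberg-Moore: b = 1.019 * ERB(fc)), so low-frequency channels are
narrow and high-frequency channels broad — the auditory-style frequency
resolution that motivates the representation for heart sounds, whose
diagnostic energy sits below a few hundred Hz.

Center frequencies are spaced uniformly on the ERB-rate scale.  Each
channel filters the signal causally (truncated FIR realization of the
analytic response); per-channel short-time RMS over overlapping frames is
stacked into a channels x frames matrix, which can be log-compressed and
resized into a gray image for the texture and deep-feature stages.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import fftconvolve
from skimage.transform import resize

from .errors import InvalidConfigError, InvalidInputError

__all__ = [
    "erb",
    "erb_rate",
    "erb_center_freqs",
    "GammatoneFilterbank",
    "Gammatonegram",
    "impulse_response",
    "compute_gammatonegram",
    "to_image",
    "gammatonegram_image",
]


def erb(f: np.ndarray | float) -> np.ndarray | float:
    """Equivalent rectangular bandwidth (Hz) at frequency ``f`` (Hz)."""
    return 24.7 * (4.37e-3 * np.asarray(f, dtype=float) + 1.0)


def erb_rate(f: np.ndarray | float) -> np.ndarray | float:
    """ERB-rate (number of ERBs below ``f``)."""
    return 21.4 * np.log10(4.37e-3 * np.asarray(f, dtype=float) + 1.0)


def _erb_rate_inv(r: np.ndarray) -> np.ndarray:
    return (10.0 ** (r / 21.4) - 1.0) / 4.37e-3


def erb_center_freqs(fmin: float, fmax: float, n_channels: int) -> np.ndarray:
    """``n_channels`` frequencies from fmin to fmax inclusive, equally
    spaced on the ERB-rate scale (hence denser at low frequency)."""
    if not (0 < fmin < fmax):
        raise InvalidConfigError("need 0 < fmin < fmax")
    if n_channels < 2:
        raise InvalidConfigError("n_channels must be >= 2")
    rates = np.linspace(erb_rate(fmin), erb_rate(fmax), n_channels)
    fc = _erb_rate_inv(rates)
    fc[0], fc[-1] = fmin, fmax  # pin endpoints against round-off
    return fc


@dataclass(frozen=True)
class GammatoneFilterbank:
    """Bank of gammatone channels sharing order/amplitude/phase."""

    center_freqs: np.ndarray
    fs: float
    order: int = 4
    bandwidths: np.ndarray | None = None  # default 1.019 * ERB(fc)
    amplitude: float = 1.0
    phase: float = 0.0

    def __post_init__(self) -> None:
        fc = np.asarray(self.center_freqs, dtype=float)
        object.__setattr__(self, "center_freqs", fc)
        if fc.ndim != 1 or len(fc) == 0:
            raise InvalidConfigError("center_freqs must be a non-empty 1-D array")
        if np.any(np.diff(fc) <= 0):
            raise InvalidConfigError("center_freqs must be strictly increasing")
        if np.any(fc >= self.fs / 2):
            raise InvalidConfigError("all center frequencies must be below Nyquist")
        b = self.bandwidths
        b = 1.019 * erb(fc) if b is None else np.asarray(b, dtype=float)
        if len(b) != len(fc) or np.any(b <= 0):
            raise InvalidConfigError("bandwidths must be positive, one per channel")
        object.__setattr__(self, "bandwidths", b)

    @classmethod
    def design(cls, fs: float, n_channels: int = 64, fmin: float = 20.0,
               fmax: float = 1000.0, order: int = 4) -> "GammatoneFilterbank":
        return cls(center_freqs=erb_center_freqs(fmin, fmax, n_channels),
                   fs=fs, order=order)

    def kernels(self, envelope_cutoff: float = 1e-5,
                max_dur_s: float = 1.0) -> list[np.ndarray]:
        """Truncated FIR realizations of each channel's impulse response.

        Truncation point: where the gamma envelope falls below
        ``envelope_cutoff`` times its peak.
        """
        out = []
        for fc, b in zip(self.center_freqs, self.bandwidths):
            t = np.arange(int(max_dur_s * self.fs)) / self.fs
            env = t ** (self.order - 1) * np.exp(-2.0 * np.pi * b * t)
            peak = env.max()
            keep = np.nonzero(env >= envelope_cutoff * peak)[0]
            n_keep = int(keep[-1]) + 1 if len(keep) else len(t)
            out.append(impulse_response(t[:n_keep], fc, b, self.order,
                                        self.amplitude, self.phase))
        return out


def impulse_response(t: np.ndarray | float, fc: float, b: float,
                     order: int = 4, amplitude: float = 1.0,
                     phase: float = 0.0) -> np.ndarray | float:
    """Causal gammatone impulse response; zero for t < 0."""
    t = np.asarray(t, dtype=float)
    tp = np.where(t >= 0, t, 0.0)
    g = (amplitude * tp ** (order - 1) * np.exp(-2.0 * np.pi * b * tp)
         * np.cos(2.0 * np.pi * fc * tp + phase))
    return np.where(t >= 0, g, 0.0)


@dataclass(frozen=True)
class Gammatonegram:
    """channels x frames matrix of non-negative short-time RMS values."""

    values: np.ndarray
    center_freqs: np.ndarray
    frame_times: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.ndim != 2:
            raise InvalidInputError("values must be 2-D (channels x frames)")
        if np.any(v < 0):
            raise InvalidInputError("gammatonegram entries must be non-negative")
        if v.shape[0] != len(self.center_freqs):
            raise InvalidInputError("row count must equal channel count")


def filter_channels(x: np.ndarray, bank: GammatoneFilterbank) -> np.ndarray:
    """Causal per-channel filtering: row k = channel k's output, same length
    as the input (output at time t depends only on x[<=t])."""
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise InvalidInputError("empty signal")
    rows = []
    for h in bank.kernels():
        rows.append(fftconvolve(x, h, mode="full")[: len(x)])
    return np.vstack(rows)


def compute_gammatonegram(x: np.ndarray, fs: float, bank: GammatoneFilterbank,
                          frame_len: int, hop: int) -> Gammatonegram:
    """Frame each channel's filtered signal into per-frame RMS energies.

    Frame count is floor((len - frame_len) / hop) + 1.
    """
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise InvalidInputError("empty signal")
    if frame_len > len(x):
        raise InvalidInputError("frame_len exceeds signal length")
    if hop < 1 or frame_len < 1:
        raise InvalidConfigError("frame_len and hop must be >= 1")
    if abs(bank.fs - fs) > 1e-9:
        raise InvalidConfigError("filterbank fs does not match the signal fs")
    y = filter_channels(x, bank)
    n_frames = (len(x) - frame_len) // hop + 1
    frames = np.lib.stride_tricks.sliding_window_view(y, frame_len, axis=1)[:, ::hop, :]
    frames = frames[:, :n_frames, :]
    values = np.sqrt(np.mean(frames ** 2, axis=2))
    frame_times = (np.arange(n_frames) * hop + frame_len / 2) / fs
    return Gammatonegram(values=values, center_freqs=bank.center_freqs,
                         frame_times=frame_times)


def to_image(G: Gammatonegram, dynamic_range_db: float = 60.0,
             out_shape: tuple[int, int] = (224, 224)) -> np.ndarray:
    """Log-compress (dB), clip to the top ``dynamic_range_db``, min-max scale
    to [0, 1], and bilinearly resize to ``out_shape``.

    Degenerate cases: an all-zero (or constant) matrix maps to an all-zero
    image, since min-max scaling has no spread to normalize.
    """
    v = G.values
    if v.size == 0:
        raise InvalidInputError("empty gammatonegram")
    vmax = v.max()
    if vmax <= 0:
        return np.zeros(out_shape)
    with np.errstate(divide="ignore"):
        db = 20.0 * np.log10(v / vmax)
    db = np.clip(db, -dynamic_range_db, 0.0)
    lo, hi = db.min(), db.max()
    img = np.zeros_like(db) if hi - lo < 1e-12 else (db - lo) / (hi - lo)
    if img.shape != tuple(out_shape):
        img = resize(img, out_shape, order=1, mode="edge",
                     anti_aliasing=False, preserve_range=True)
    return np.clip(img, 0.0, 1.0)


def gammatonegram_image(x: np.ndarray, fs: float,
                        n_channels: int = 64, fmin: float = 20.0,
                        fmax: float = 1000.0, frame_ms: float = 25.0,
                        hop_ms: float = 10.0, dynamic_range_db: float = 60.0,
                        out_shape: tuple[int, int] = (224, 224)) -> np.ndarray:
    """Convenience: signal -> gammatonegram -> gray image in [0, 1]."""
    bank = GammatoneFilterbank.design(fs, n_channels, fmin, min(fmax, fs / 2 * 0.99))
    frame_len = max(1, int(round(frame_ms * 1e-3 * fs)))
    hop = max(1, int(round(hop_ms * 1e-3 * fs)))
    G = compute_gammatonegram(x, fs, bank, frame_len, hop)
    return to_image(G, dynamic_range_db, out_shape)
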