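"""Independent brute-force oracles used by the tests.

Everything here is written directly from the defining statements of the
quantities (pair enumeration, flood fill, all-pairs AUC, direct linear
solves), deliberately sharing no code with the package implementation.
"""

import numpy as np


def glcm_brute(levels: np.ndarray, ng: int, offset: tuple[int, int],
               symmetric: bool = True) -> np.ndarray:
    """Count pixel pairs (I(x,y)=gi and I(x+dx, y+dy)=gj) one by one.

    (x, y) = (column, row), y downward; returns the normalized matrix.
    """
    dx, dy = offset
    h, w = levels.shape
    counts = np.zeros((ng, ng))
    for y in range(h):
        for x in range(w):
            x2, y2 = x + dx, y + dy
            if 0 <= x2 < w and 0 <= y2 < h:
                counts[levels[y, x] - 1, levels[y2, x2] - 1] += 1
    if symmetric:
        counts = counts + counts.T
    return counts / counts.sum()


def glrlm_brute(levels: np.ndarray, ng: int, step: tuple[int, int]) -> np.ndarray:
    """Enumerate maximal constant-level runs along ``step`` = (dx, dy)."""
    dx, dy = step
    h, w = levels.shape
    counts = np.zeros((ng, max(h, w)))
    seen = set()
    for y in range(h):
        for x in range(w):
            # only start from positions with no predecessor on the line
            px, py = x - dx, y - dy
            if 0 <= px < w and 0 <= py < h:
                continue
            cx, cy = x, y
            run_level, run_len = None, 0
            while 0 <= cx < w and 0 <= cy < h:
                lv = levels[cy, cx]
                if lv == run_level:
                    run_len += 1
                else:
                    if run_level is not None:
                        counts[run_level - 1, run_len - 1] += 1
                    run_level, run_len = lv, 1
                cx += dx
                cy += dy
            counts[run_level - 1, run_len - 1] += 1
    return counts


def glszm_brute(levels: np.ndarray, ng: int) -> np.ndarray:
    """Flood-fill 8-connected constant-level zones."""
    h, w = levels.shape
    visited = np.zeros((h, w), dtype=bool)
    counts = np.zeros((ng, h * w))
    for y in range(h):
        for x in range(w):
            if visited[y, x]:
                continue
            g = levels[y, x]
            stack = [(y, x)]
            visited[y, x] = True
            size = 0
            while stack:
                cy, cx = stack.pop()
                size += 1
                for ddy in (-1, 0, 1):
                    for ddx in (-1, 0, 1):
                        ny, nx = cy + ddy, cx + ddx
                        if (0 <= ny < h and 0 <= nx < w and not visited[ny, nx]
                                and levels[ny, nx] == g):
                            visited[ny, nx] = True
                            stack.append((ny, nx))
            counts[g - 1, size - 1] += 1
    smax = max(1, int(np.max(np.nonzero(counts.any(axis=0))[0])) + 1)
    return counts[:, :smax]


def gldm_brute(levels: np.ndarray, ng: int, delta: int,
               distance: int) -> np.ndarray:
    """Per-pixel neighbor enumeration within Chebyshev ``distance``."""
    h, w = levels.shape
    deps = np.zeros((h, w), dtype=int)
    for y in range(h):
        for x in range(w):
            d = 0
            for ddy in range(-distance, distance + 1):
                for ddx in range(-distance, distance + 1):
                    if ddy == 0 and ddx == 0:
                        continue
                    ny, nx = y + ddy, x + ddx
                    if 0 <= ny < h and 0 <= nx < w and \
                            abs(int(levels[y, x]) - int(levels[ny, nx])) <= delta:
                        d += 1
            deps[y, x] = d
    counts = np.zeros((ng, deps.max() + 1))
    for y in range(h):
        for x in range(w):
            counts[levels[y, x] - 1, deps[y, x]] += 1
    return counts


def auc_brute(scores: np.ndarray, labels: np.ndarray) -> float:
    """All-pairs comparison; ties count one half."""
    pos = np.asarray(scores)[np.asarray(labels) == 1]
    neg = np.asarray(scores)[np.asarray(labels) == -1]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


def auc_vectorized(scores: np.ndarray, labels: np.ndarray) -> float:
    """All-pairs AUC via broadcasting (for bootstrap loops)."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    pos = s[y == 1][:, None]
    neg = s[y == -1][None, :]
    return float(((pos > neg) + 0.5 * (pos == neg)).mean())


def gp_direct_solve(X: np.ndarray, y: np.ndarray, xstar: np.ndarray,
                    length_scale: float, jitter: float) -> tuple[float, float]:
    """Plain GP regression solve (standardized y, unit signal variance)."""
    y = np.asarray(y, dtype=float)
    mu, sd = y.mean(), (y.std() if y.std() > 1e-12 else 1.0)
    yn = (y - mu) / sd
    def k(a, b):
        return np.exp(-0.5 * np.sum((a - b) ** 2) / length_scale ** 2)
    n = len(X)
    K = np.array([[k(X[i], X[j]) for j in range(n)] for i in range(n)])
    K += jitter * np.eye(n)
    ks = np.array([k(xstar, X[i]) for i in range(n)])
    Kinv = np.linalg.inv(K)
    mean = ks @ Kinv @ yn
    var = 1.0 - ks @ Kinv @ ks
    return float(mean * sd + mu), float(max(var, 0.0) * sd ** 2)


def envelope_peak_count(x: np.ndarray, fs: float, min_sep_s: float = 0.4,
                        rel_height: float = 0.3) -> int:
    """Count S1-scale bursts from the smoothed amplitude envelope."""
    from scipy.signal import find_peaks

    env = np.abs(x)
    win = max(1, int(0.03 * fs))
    kernel = np.ones(win) / win
    smooth = np.convolve(env, kernel, mode="same")
    peaks, _ = find_peaks(smooth, height=rel_height * smooth.max(),
                          distance=int(min_sep_s * fs))
    return len(peaks)
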