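"""Gray-level texture matrices and the 70-feature panel.

Computes, from a quantized gray image, the four classical texture matrices

* GLCM  — gray-level co-occurrence: joint counts of level pairs separated
  by a fixed displacement (dx, dy), optionally symmetrized, normalized to
  a joint probability table;
* GLRLM — gray-level run length: counts of maximal constant-level runs of
  each length along a direction;
* GLSZM — gray-level size zone: counts of 8-connected constant-level zones
  of each size (direction-free);
* GLDM  — gray-level dependence: for each pixel, the number of neighbors
  within a Chebyshev distance whose level differs by at most ``delta``;
  counts of (level, dependence) pairs;

and the standard IBSI-style scalar features over them: 24 GLCM + 16 GLRLM
+ 16 GLSZM + 14 GLDM = 70 features.  GLCM and GLRLM features are averaged
over the four 2-D directions (0, 45, 90, 135 degrees).

Coordinate convention (used everywhere): images are row-major arrays
indexed ``[row, col]``; a displacement is given as (dx, dy) = (column
offset, row offset) with the origin at the top-left, y increasing
downward.

Degenerate inputs follow fixed conventions so every feature is finite:
correlation-type features are 0 when a marginal variance vanishes, and
the GLCM maximal correlation coefficient (MCC) is 0 when fewer than two
gray levels are occupied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import InvalidConfigError, InvalidInputError

__all__ = [
    "QuantizedImage",
    "TextureMatrices",
    "quantize",
    "glcm",
    "glrlm",
    "glszm",
    "gldm",
    "DIRECTIONS",
    "glcm_features",
    "glrlm_features",
    "glszm_features",
    "gldm_features",
    "texture_features",
    "extract_texture_features",
    "FEATURE_NAMES",
]

_EPS = np.finfo(float).tiny

# (dx, dy) unit steps for the four standard 2-D directions.
DIRECTIONS: dict[int, tuple[int, int]] = {
    0: (1, 0),     # horizontal
    45: (1, -1),   # up-right
    90: (0, -1),   # vertical
    135: (-1, -1), # up-left
}


@dataclass(frozen=True)
class QuantizedImage:
    """Integer image with levels in 1..ng."""

    levels: np.ndarray
    ng: int

    def __post_init__(self) -> None:
        lv = np.asarray(self.levels)
        if not np.issubdtype(lv.dtype, np.integer):
            lv = lv.astype(np.int64)
        object.__setattr__(self, "levels", lv)
        if lv.ndim != 2 or lv.size == 0:
            raise InvalidInputError("levels must be a non-empty 2-D array")
        if self.ng < 1:
            raise InvalidConfigError("ng must be >= 1")
        if lv.min() < 1 or lv.max() > self.ng:
            raise InvalidInputError("levels must lie in 1..ng")


@dataclass(frozen=True)
class TextureMatrices:
    """The four matrices computed from one QuantizedImage.

    ``glcm_by_dir``/``glrlm_by_dir`` are keyed by direction in degrees;
    GLCMs are normalized probability tables, the rest are raw counts.
    """

    glcm_by_dir: dict[int, np.ndarray]
    glrlm_by_dir: dict[int, np.ndarray]
    glszm: np.ndarray
    gldm: np.ndarray
    ng: int
    n_pixels: int


def quantize(image: np.ndarray, ng: int = 32) -> QuantizedImage:
    """Equal-width binning of [min, max] into ``ng`` levels 1..ng.

    The minimum maps to level 1 and the maximum to level ng; a constant
    image maps to all-1 (documented degenerate case, not an error).
    """
    if ng < 2:
        raise InvalidConfigError("ng must be >= 2")
    img = np.asarray(image, dtype=float)
    if img.ndim != 2 or img.size == 0:
        raise InvalidInputError("image must be a non-empty 2-D array")
    lo, hi = img.min(), img.max()
    if hi - lo < 1e-15:
        return QuantizedImage(np.ones(img.shape, dtype=np.int64), ng)
    lv = np.floor((img - lo) / (hi - lo) * ng).astype(np.int64) + 1
    return QuantizedImage(np.minimum(lv, ng), ng)


def glcm(q: QuantizedImage, offset: tuple[int, int] = (1, 0),
         symmetric: bool = True, normalize: bool = True) -> np.ndarray:
    """Co-occurrence matrix for displacement ``offset`` = (dx, dy)."""
    dx, dy = offset
    if dx == 0 and dy == 0:
        raise InvalidConfigError("offset must be nonzero")
    lv = q.levels
    h, w = lv.shape
    r0 = max(0, -dy)
    r1 = h - max(0, dy)
    c0 = max(0, -dx)
    c1 = w - max(0, dx)
    if r1 <= r0 or c1 <= c0:
        raise InvalidInputError("offset larger than the image: no pixel pairs")
    a = lv[r0:r1, c0:c1]
    b = lv[r0 + dy:r1 + dy, c0 + dx:c1 + dx]
    counts = np.zeros((q.ng, q.ng), dtype=float)
    np.add.at(counts, (a.ravel() - 1, b.ravel() - 1), 1.0)
    if symmetric:
        counts = counts + counts.T
    if normalize:
        counts = counts / counts.sum()
    return counts


def _direction_lines(shape: tuple[int, int], step: tuple[int, int]):
    """Yield index arrays (rows, cols) tracing each maximal line of the
    image grid along ``step`` = (dx, dy)."""
    h, w = shape
    dx, dy = step
    if dy == 0:          # horizontal
        for r in range(h):
            yield np.full(w, r), np.arange(w)
    elif dx == 0:        # vertical
        for c in range(w):
            yield np.arange(h), np.full(h, c)
    else:
        # diagonals: walk anti-diagonals (dx=1,dy=-1) or diagonals (dx=-1,dy=-1)
        sgn = 1 if dx * dy < 0 else -1
        # For step (1,-1): lines of constant r+c. For (-1,-1): constant c-r.
        rows, cols = np.indices(shape)
        key = rows + cols if sgn == 1 else cols - rows
        for k in np.unique(key):
            mask = key == k
            r = rows[mask]
            c = cols[mask]
            order = np.argsort(c if dx > 0 else -c)
            yield r[order], c[order]


def glrlm(q: QuantizedImage, direction: int = 0) -> np.ndarray:
    """Run-length count matrix (ng x max run length) along ``direction``
    (one of 0, 45, 90, 135 degrees)."""
    if direction not in DIRECTIONS:
        raise InvalidConfigError("direction must be one of 0, 45, 90, 135")
    lv = q.levels
    rmax = max(lv.shape)
    counts = np.zeros((q.ng, rmax), dtype=float)
    for rr, cc in _direction_lines(lv.shape, DIRECTIONS[direction]):
        line = lv[rr, cc]
        # run-length encode
        breaks = np.nonzero(np.diff(line))[0]
        starts = np.concatenate([[0], breaks + 1])
        ends = np.concatenate([breaks, [len(line) - 1]])
        lengths = ends - starts + 1
        np.add.at(counts, (line[starts] - 1, lengths - 1), 1.0)
    return counts


def glszm(q: QuantizedImage) -> np.ndarray:
    """Size-zone count matrix (ng x max zone size); zones are maximal
    8-connected constant-level components."""
    lv = q.levels
    n_pix = lv.size
    counts = np.zeros((q.ng, n_pix), dtype=float)
    structure = np.ones((3, 3), dtype=int)
    for g in np.unique(lv):
        labeled, n = ndimage.label(lv == g, structure=structure)
        if n == 0:
            continue
        sizes = np.bincount(labeled.ravel())[1:]
        np.add.at(counts, (np.full(n, g - 1), sizes - 1), 1.0)
    smax = int(np.max(np.nonzero(counts.any(axis=0))[0])) + 1
    return counts[:, :smax]


def gldm(q: QuantizedImage, delta: int = 0, distance: int = 1) -> np.ndarray:
    """Dependence count matrix (ng x (max dependence + 1)).

    A pixel's dependence d is the number of neighbors within Chebyshev
    ``distance`` whose level differs from it by at most ``delta``; column
    index j of the returned matrix corresponds to d = j (so d = 0 is the
    first column).  Neighbors outside the image do not count.
    """
    if delta < 0 or distance < 1:
        raise InvalidConfigError("need delta >= 0 and distance >= 1")
    lv = q.levels
    h, w = lv.shape
    dep = np.zeros((h, w), dtype=np.int64)
    for dy in range(-distance, distance + 1):
        for dx in range(-distance, distance + 1):
            if dx == 0 and dy == 0:
                continue
            r0, r1 = max(0, -dy), h - max(0, dy)
            c0, c1 = max(0, -dx), w - max(0, dx)
            if r1 <= r0 or c1 <= c0:
                continue
            a = lv[r0:r1, c0:c1]
            b = lv[r0 + dy:r1 + dy, c0 + dx:c1 + dx]
            dep[r0:r1, c0:c1] += np.abs(a - b) <= delta
    dmax = int(dep.max())
    counts = np.zeros((q.ng, dmax + 1), dtype=float)
    np.add.at(counts, (lv.ravel() - 1, dep.ravel()), 1.0)
    return counts


def compute_all_matrices(q: QuantizedImage, delta: int = 0,
                         distance: int = 1) -> TextureMatrices:
    return TextureMatrices(
        glcm_by_dir={d: glcm(q, DIRECTIONS[d], symmetric=True)
                     for d in DIRECTIONS},
        glrlm_by_dir={d: glrlm(q, d) for d in DIRECTIONS},
        glszm=glszm(q),
        gldm=gldm(q, delta=delta, distance=distance),
        ng=q.ng,
        n_pixels=q.levels.size,
    )


# ---------------------------------------------------------------------------
# Scalar features
# ---------------------------------------------------------------------------

def _xlog2(p: np.ndarray) -> np.ndarray:
    return p * np.log2(p + _EPS) * (p > 0)


def glcm_features(P: np.ndarray) -> dict[str, float]:
    """24 features from one normalized symmetric GLCM."""
    ng = P.shape[0]
    i = np.arange(1, ng + 1)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    px = P.sum(axis=1)
    py = P.sum(axis=0)
    mux = float(np.sum(i * px))
    muy = float(np.sum(i * py))
    sigx = float(np.sqrt(np.sum((i - mux) ** 2 * px)))
    sigy = float(np.sqrt(np.sum((i - muy) ** 2 * py)))

    # p_{x+y}(k), k = 2..2ng ; p_{x-y}(k), k = 0..ng-1
    pxy_sum = np.zeros(2 * ng - 1)
    np.add.at(pxy_sum, (ii + jj).ravel() - 2, P.ravel())
    k_sum = np.arange(2, 2 * ng + 1)
    pxy_diff = np.zeros(ng)
    np.add.at(pxy_diff, np.abs(ii - jj).ravel(), P.ravel())
    k_diff = np.arange(ng)

    hx = float(-np.sum(_xlog2(px)))
    hy = float(-np.sum(_xlog2(py)))
    hxy = float(-np.sum(_xlog2(P)))
    pxpy = np.outer(px, py)
    hxy1 = float(-np.sum(P * np.log2(pxpy + _EPS) * (pxpy > 0)))
    hxy2 = float(-np.sum(_xlog2(pxpy)))

    diff_avg = float(np.sum(k_diff * pxy_diff))

    f: dict[str, float] = {}
    f["glcm_autocorrelation"] = float(np.sum(ii * jj * P))
    f["glcm_joint_average"] = mux
    f["glcm_cluster_prominence"] = float(np.sum((ii + jj - mux - muy) ** 4 * P))
    f["glcm_cluster_shade"] = float(np.sum((ii + jj - mux - muy) ** 3 * P))
    f["glcm_cluster_tendency"] = float(np.sum((ii + jj - mux - muy) ** 2 * P))
    f["glcm_contrast"] = float(np.sum((ii - jj) ** 2 * P))
    f["glcm_correlation"] = (
        0.0 if sigx * sigy < 1e-15
        else float((np.sum(ii * jj * P) - mux * muy) / (sigx * sigy)))
    f["glcm_difference_average"] = diff_avg
    f["glcm_difference_entropy"] = float(-np.sum(_xlog2(pxy_diff)))
    f["glcm_difference_variance"] = float(
        np.sum((k_diff - diff_avg) ** 2 * pxy_diff))
    f["glcm_joint_energy"] = float(np.sum(P ** 2))
    f["glcm_joint_entropy"] = hxy
    den = max(hx, hy)
    f["glcm_imc1"] = 0.0 if den < 1e-15 else float((hxy - hxy1) / den)
    f["glcm_imc2"] = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - hxy)))))
    f["glcm_idm"] = float(np.sum(P / (1.0 + (ii - jj) ** 2)))
    f["glcm_idmn"] = float(np.sum(P / (1.0 + ((ii - jj) / ng) ** 2)))
    f["glcm_id"] = float(np.sum(P / (1.0 + np.abs(ii - jj))))
    f["glcm_idn"] = float(np.sum(P / (1.0 + np.abs(ii - jj) / ng)))
    off = ii != jj
    f["glcm_inverse_variance"] = float(
        np.sum(P[off] / (ii[off] - jj[off]) ** 2))
    f["glcm_maximum_probability"] = float(P.max())
    f["glcm_sum_average"] = float(np.sum(k_sum * pxy_sum))
    f["glcm_sum_entropy"] = float(-np.sum(_xlog2(pxy_sum)))
    f["glcm_sum_squares"] = float(np.sum((ii - mux) ** 2 * P))
    f["glcm_mcc"] = _glcm_mcc(P, px, py)
    return f


def _glcm_mcc(P: np.ndarray, px: np.ndarray, py: np.ndarray) -> float:
    """Maximal correlation coefficient: sqrt of the second-largest
    eigenvalue of Q(i,j) = sum_k P(i,k) P(j,k) / (px(i) py(k)).

    Defined as 0 when fewer than two gray levels are occupied.
    """
    occ = px > 0
    if occ.sum() < 2:
        return 0.0
    Ps = P[np.ix_(occ, occ)]
    pxs = px[occ]
    pys = py[occ]
    Q = (Ps / pxs[:, None]) @ (Ps / pys[:, None]).T
    ev = np.sort(np.abs(np.linalg.eigvals(Q)))
    return float(np.sqrt(max(0.0, ev[-2].real)))


def _run_zone_features(P: np.ndarray, n_pixels: int, prefix: str,
                       names: tuple[str, ...]) -> dict[str, float]:
    """Shared feature machinery for GLRLM / GLSZM / GLDM.

    ``P`` is a count matrix (levels x sizes); size index j corresponds to
    run length / zone size / dependence-count j+1.
    """
    nz = P.sum()
    if nz <= 0:
        return {f"{prefix}_{n}": 0.0 for n in names}
    g = np.arange(1, P.shape[0] + 1, dtype=float)
    r = np.arange(1, P.shape[1] + 1, dtype=float)
    gg, rr = np.meshgrid(g, r, indexing="ij")
    p = P / nz
    pg = p.sum(axis=1)
    pr = p.sum(axis=0)
    mug = float(np.sum(g * pg))
    mur = float(np.sum(r * pr))
    vals = {
        "short_emphasis": float(np.sum(p / rr ** 2)),
        "long_emphasis": float(np.sum(p * rr ** 2)),
        "gray_level_non_uniformity": float(np.sum(P.sum(axis=1) ** 2) / nz),
        "gray_level_non_uniformity_normalized": float(np.sum(pg ** 2)),
        "size_non_uniformity": float(np.sum(P.sum(axis=0) ** 2) / nz),
        "size_non_uniformity_normalized": float(np.sum(pr ** 2)),
        "percentage": float(nz / n_pixels),
        "gray_level_variance": float(np.sum((gg - mug) ** 2 * p)),
        "size_variance": float(np.sum((rr - mur) ** 2 * p)),
        "entropy": float(-np.sum(_xlog2(p))),
        "low_gray_level_emphasis": float(np.sum(p / gg ** 2)),
        "high_gray_level_emphasis": float(np.sum(p * gg ** 2)),
        "short_low_gray_level_emphasis": float(np.sum(p / (gg ** 2 * rr ** 2))),
        "short_high_gray_level_emphasis": float(np.sum(p * gg ** 2 / rr ** 2)),
        "long_low_gray_level_emphasis": float(np.sum(p * rr ** 2 / gg ** 2)),
        "long_high_gray_level_emphasis": float(np.sum(p * gg ** 2 * rr ** 2)),
    }
    return {f"{prefix}_{n}": vals[k] for n, k in zip(names, _RZ_KEYS[prefix])}


_GLRLM_NAMES = (
    "short_run_emphasis", "long_run_emphasis", "gray_level_non_uniformity",
    "gray_level_non_uniformity_normalized", "run_length_non_uniformity",
    "run_length_non_uniformity_normalized", "run_percentage",
    "gray_level_variance", "run_variance", "run_entropy",
    "low_gray_level_run_emphasis", "high_gray_level_run_emphasis",
    "short_run_low_gray_level_emphasis", "short_run_high_gray_level_emphasis",
    "long_run_low_gray_level_emphasis", "long_run_high_gray_level_emphasis",
)
_GLSZM_NAMES = (
    "small_area_emphasis", "large_area_emphasis", "gray_level_non_uniformity",
    "gray_level_non_uniformity_normalized", "size_zone_non_uniformity",
    "size_zone_non_uniformity_normalized", "zone_percentage",
    "gray_level_variance", "zone_variance", "zone_entropy",
    "low_gray_level_zone_emphasis", "high_gray_level_zone_emphasis",
    "small_area_low_gray_level_emphasis", "small_area_high_gray_level_emphasis",
    "large_area_low_gray_level_emphasis", "large_area_high_gray_level_emphasis",
)
# GLDM has 14 features: no normalized gray-level non-uniformity, no percentage.
_GLDM_NAMES = (
    "small_dependence_emphasis", "large_dependence_emphasis",
    "gray_level_non_uniformity", "dependence_non_uniformity",
    "dependence_non_uniformity_normalized", "gray_level_variance",
    "dependence_variance", "dependence_entropy",
    "low_gray_level_emphasis", "high_gray_level_emphasis",
    "small_dependence_low_gray_level_emphasis",
    "small_dependence_high_gray_level_emphasis",
    "large_dependence_low_gray_level_emphasis",
    "large_dependence_high_gray_level_emphasis",
)
_RZ_KEYS = {
    "glrlm": ("short_emphasis", "long_emphasis", "gray_level_non_uniformity",
              "gray_level_non_uniformity_normalized", "size_non_uniformity",
              "size_non_uniformity_normalized", "percentage",
              "gray_level_variance", "size_variance", "entropy",
              "low_gray_level_emphasis", "high_gray_level_emphasis",
              "short_low_gray_level_emphasis", "short_high_gray_level_emphasis",
              "long_low_gray_level_emphasis", "long_high_gray_level_emphasis"),
    "glszm": ("short_emphasis", "long_emphasis", "gray_level_non_uniformity",
              "gray_level_non_uniformity_normalized", "size_non_uniformity",
              "size_non_uniformity_normalized", "percentage",
              "gray_level_variance", "size_variance", "entropy",
              "low_gray_level_emphasis", "high_gray_level_emphasis",
              "short_low_gray_level_emphasis", "short_high_gray_level_emphasis",
              "long_low_gray_level_emphasis", "long_high_gray_level_emphasis"),
    "gldm": ("short_emphasis", "long_emphasis", "gray_level_non_uniformity",
             "size_non_uniformity", "size_non_uniformity_normalized",
             "gray_level_variance", "size_variance", "entropy",
             "low_gray_level_emphasis", "high_gray_level_emphasis",
             "short_low_gray_level_emphasis", "short_high_gray_level_emphasis",
             "long_low_gray_level_emphasis", "long_high_gray_level_emphasis"),
}


def glrlm_features(P: np.ndarray, n_pixels: int) -> dict[str, float]:
    return _run_zone_features(P, n_pixels, "glrlm", _GLRLM_NAMES)


def glszm_features(P: np.ndarray, n_pixels: int) -> dict[str, float]:
    return _run_zone_features(P, n_pixels, "glszm", _GLSZM_NAMES)


def gldm_features(P: np.ndarray, n_pixels: int) -> dict[str, float]:
    """GLDM features; the dependence size used in the formulas is d + 1
    (the pixel itself counts as part of its dependence group), which keeps
    small-dependence emphases finite at d = 0."""
    return _run_zone_features(P, n_pixels, "gldm", _GLDM_NAMES)


def _mean_dicts(dicts: list[dict[str, float]]) -> dict[str, float]:
    keys = dicts[0].keys()
    return {k: float(np.mean([d[k] for d in dicts])) for k in keys}


def texture_features(m: TextureMatrices) -> dict[str, float]:
    """All 70 features: GLCM and GLRLM averaged over the four directions,
    plus GLSZM and GLDM.  Returned in a stable documented order."""
    f: dict[str, float] = {}
    f.update(_mean_dicts([glcm_features(m.glcm_by_dir[d]) for d in sorted(m.glcm_by_dir)]))
    f.update(_mean_dicts([glrlm_features(m.glrlm_by_dir[d], m.n_pixels)
                          for d in sorted(m.glrlm_by_dir)]))
    f.update(glszm_features(m.glszm, m.n_pixels))
    f.update(gldm_features(m.gldm, m.n_pixels))
    assert len(f) == 70, f"expected 70 features, got {len(f)}"
    return f


def extract_texture_features(image: np.ndarray, ng: int = 32,
                             delta: int = 0, distance: int = 1) -> dict[str, float]:
    """Gray image in [0, 1] -> quantize -> matrices -> 70 named features."""
    q = quantize(image, ng)
    return texture_features(compute_all_matrices(q, delta=delta, distance=distance))


FEATURE_NAMES: list[str] = (
    [f"glcm_{n}" for n in (
        "autocorrelation", "joint_average", "cluster_prominence",
        "cluster_shade", "cluster_tendency", "contrast", "correlation",
        "difference_average", "difference_entropy", "difference_variance",
        "joint_energy", "joint_entropy", "imc1", "imc2", "idm", "idmn",
        "id", "idn", "inverse_variance", "maximum_probability",
        "sum_average", "sum_entropy", "sum_squares", "mcc")]
    + [f"glrlm_{n}" for n in _GLRLM_NAMES]
    + [f"glszm_{n}" for n in _GLSZM_NAMES]
    + [f"gldm_{n}" for n in _GLDM_NAMES]
)


def feature_vector(features: dict[str, float]) -> np.ndarray:
    """Stable 70-vector in FEATURE_NAMES order."""
    return np.array([features[name] for name in FEATURE_NAMES])
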