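"""Vocal coordination measures for a turn-pair.

Two measures are computed between the frame-level feature matrices of two
consecutive speaker turns:

* **DTWD** — the dynamic-time-warping distance: minimal cumulative frame-wise
  Euclidean cost over monotone warping paths.  Larger = less synchronous.
* **SCDC** — per-feature sample entropies of each turn form two complexity
  vectors; their squared cosine ``sigma`` is a similarity in [0, 1]
  (1 = parallel complexity profiles).  ``1 - sigma`` is exposed as the
  distance form so all measures share the "larger = less synchronous"
  orientation used downstream.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .transcript_io import FrameFeatureMatrix

try:  # JIT-compiled DP kernel; the pure-numpy path below is the fallback
    import numba

    @numba.njit
    def _dtw_accumulate(D: np.ndarray) -> np.ndarray:  # pragma: no cover
        tx, ty = D.shape
        acc = np.full((tx + 1, ty + 1), np.inf)
        acc[0, 0] = 0.0
        for i in range(1, tx + 1):
            for j in range(1, ty + 1):
                best = acc[i - 1, j - 1]
                if acc[i - 1, j] < best:
                    best = acc[i - 1, j]
                if acc[i, j - 1] < best:
                    best = acc[i, j - 1]
                acc[i, j] = D[i - 1, j - 1] + best
        return acc

except ImportError:  # pragma: no cover
    def _dtw_accumulate(D: np.ndarray) -> np.ndarray:
        tx, ty = D.shape
        acc = np.full((tx + 1, ty + 1), np.inf)
        acc[0, 0] = 0.0
        for i in range(1, tx + 1):
            row, prev, d = acc[i], acc[i - 1], D[i - 1]
            for j in range(1, ty + 1):
                row[j] = d[j - 1] + min(prev[j - 1], prev[j], row[j - 1])
        return acc

__all__ = [
    "DtwResult",
    "SampEnConfig",
    "ComplexityVector",
    "ScdcResult",
    "dtw_distance",
    "sample_entropy",
    "complexity_vector",
    "scdc",
    "znormalize",
]


@dataclass(frozen=True)
class DtwResult:
    distance: float
    path_len: int
    normalized: bool


@dataclass(frozen=True)
class SampEnConfig:
    """Sample-entropy parameters: template length m and tolerance factor.

    The tolerance is ``r = r_factor * std(series)``, recomputed from each
    individual series (population std).
    """

    m: int = 2
    r_factor: float = 0.25

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ValueError("m must be >= 1")
        if self.r_factor <= 0:
            raise ValueError("r_factor must be positive")


@dataclass(frozen=True)
class ComplexityVector:
    """Per-feature sample entropies with a validity mask.

    Entries where sample entropy is undefined (series too short, or no
    template matches at either length) are masked out rather than imputed.
    """

    values: np.ndarray
    valid_mask: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        m = np.asarray(self.valid_mask, dtype=bool)
        if v.shape != m.shape or v.ndim != 1:
            raise ValueError("values and valid_mask must be equal-length vectors")
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "valid_mask", m)


@dataclass(frozen=True)
class ScdcResult:
    sigma: float
    distance: float


def _as_matrix(x) -> np.ndarray:
    v = x.values if isinstance(x, FrameFeatureMatrix) else np.asarray(x, dtype=float)
    if v.ndim == 1:
        v = v[:, None]
    return v


def dtw_distance(X, Y, normalize: bool = True) -> DtwResult:
    """Classic DTW distance between two T x d feature matrices.

    Local cost is the Euclidean distance between frame vectors; the DP uses
    steps {(1,0), (0,1), (1,1)} with no band constraint or slope weights.
    With ``normalize`` the cumulative cost is divided by the optimal path
    length H (ties broken preferring the diagonal step), removing the
    dependence of the raw cost on turn length.
    """
    x, y = _as_matrix(X), _as_matrix(Y)
    if x.shape[0] < 1 or y.shape[0] < 1:
        raise ValueError("empty feature matrix")
    if x.shape[1] != y.shape[1]:
        raise ValueError(f"feature dimension mismatch: {x.shape[1]} vs {y.shape[1]}")
    tx, ty = x.shape[0], y.shape[0]
    # local cost matrix, (tx, ty)
    D = cdist(x, y, metric="euclidean")
    acc = _dtw_accumulate(D)
    dist = float(acc[tx, ty])

    # backtrack for path length; ties prefer the diagonal, then the i-step
    i, j, h = tx, ty, 1
    while i > 1 or j > 1:
        if i == 1:
            j -= 1
        elif j == 1:
            i -= 1
        else:
            diag, up, left = acc[i - 1, j - 1], acc[i - 1, j], acc[i, j - 1]
            if diag <= up and diag <= left:
                i, j = i - 1, j - 1
            elif up <= left:
                i -= 1
            else:
                j -= 1
        h += 1
    return DtwResult(dist / h if normalize else dist, h, normalize)


def sample_entropy(series, cfg: SampEnConfig | None = None) -> float:
    """Sample entropy of a 1-d series; NaN when undefined.

    ``S_e = -ln(E_{m+1}(r) / E_m(r))`` where ``E_m(r)`` counts ordered
    template pairs (i != j) whose Chebyshev distance is strictly below
    ``r = r_factor * std``.  Both counts run over the same template index
    range ``i < T - m`` so every m-template has an (m+1)-length extension.

    Conventions: a zero-variance series returns 0.0 (perfectly regular);
    a series shorter than m + 2, or one with a zero count at either
    template length, returns NaN (undefined, flagged not thrown).
    """
    cfg = cfg or SampEnConfig()
    x = np.asarray(series, dtype=float).ravel()
    n = len(x)
    m = cfg.m
    if n < m + 2:
        return math.nan
    sd = float(np.std(x))
    if sd == 0.0:
        return 0.0
    r = cfg.r_factor * sd
    n_templ = n - m  # templates of length m+1: x[i : i+m+1], i < n-m
    idx = np.arange(n_templ)[:, None] + np.arange(m + 1)[None, :]
    templ = x[idx]  # (n_templ, m+1)
    # Chebyshev distances between all template pairs, lengths m and m+1
    cheb_m = cdist(templ[:, :m], templ[:, :m], metric="chebyshev")
    cheb_m1 = cdist(templ, templ, metric="chebyshev")
    off = ~np.eye(n_templ, dtype=bool)
    e_m = int(np.count_nonzero((cheb_m < r) & off))
    e_m1 = int(np.count_nonzero((cheb_m1 < r) & off))
    if e_m == 0 or e_m1 == 0:
        return math.nan
    return -math.log(e_m1 / e_m)


def complexity_vector(X, cfg: SampEnConfig | None = None) -> ComplexityVector:
    """Column-wise sample entropies of a T x d feature matrix."""
    cfg = cfg or SampEnConfig()
    x = _as_matrix(X)
    vals = np.array([sample_entropy(x[:, j], cfg) for j in range(x.shape[1])])
    mask = np.isfinite(vals)
    if not mask.any():
        raise ValueError("no valid complexity features")
    return ComplexityVector(np.where(mask, vals, 0.0), mask)


def scdc(c1: ComplexityVector, c2: ComplexityVector) -> ScdcResult | None:
    """Squared-cosine similarity of two complexity vectors.

    ``sigma = ((c1 . c2) / (|c1| |c2|))^2`` over the jointly valid
    features; ``distance = 1 - sigma``.  Returns None (pair excluded) when
    no feature is jointly valid or a masked vector has zero norm.
    """
    joint = c1.valid_mask & c2.valid_mask
    if not joint.any():
        return None
    v1, v2 = c1.values[joint], c2.values[joint]
    n1, n2 = float(np.linalg.norm(v1)), float(np.linalg.norm(v2))
    if n1 == 0.0 or n2 == 0.0:
        return None
    cos = float(v1 @ v2) / (n1 * n2)
    sigma = min(cos * cos, 1.0)
    return ScdcResult(sigma=sigma, distance=1.0 - sigma)


def znormalize(values: np.ndarray, mean: np.ndarray, std: np.ndarray) -> np.ndarray:
    """Z-score columns against externally supplied statistics.

    Used to normalize each turn's features with its session-and-speaker
    level statistics before DTW, so no single high-variance feature (e.g.
    pitch in Hz) dominates the Euclidean local cost.  Zero-variance columns
    are centered only.
    """
    std = np.where(np.asarray(std) > 0, std, 1.0)
    return (np.asarray(values, dtype=float) - mean) / std
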