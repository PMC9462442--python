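"""Word mover's distance between the embedding matrices of two turns.

Each turn is a point cloud of word embeddings with uniform mass (1/m per
word; repeated tokens keep separate mass units, since contextual backends
give position-dependent vectors).  The WMD is the optimal value of the
transportation problem

    WMD(X1, X2) = min_{T >= 0} sum_ij T_ij ||b_i - b_j||_2
    s.t.  sum_j T_ij = 1/m,   sum_i T_ij = 1/n,

solved exactly as a linear program.  Lower WMD = greater lexical synchrony.

Embedding backends are pluggable through :class:`EmbeddingProvider`.  The
built-in :class:`FixtureEmbeddingProvider` maps each token to a seeded,
deterministic unit vector (keyed hash of the token string), which makes the
whole lexical pipeline runnable offline; a contextual-transformer backend
can be dropped in via the same interface.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from typing import Protocol, Sequence, runtime_checkable

import numpy as np
import scipy.optimize
import scipy.sparse
from scipy.spatial.distance import cdist

__all__ = [
    "EmbeddingMatrix",
    "TransportPlan",
    "WmdResult",
    "EmbeddingProvider",
    "FixtureEmbeddingProvider",
    "embed_turn",
    "word_distance",
    "wmd",
]


@dataclass(frozen=True)
class EmbeddingMatrix:
    """n x D embedding matrix with row-aligned tokens."""

    vectors: np.ndarray
    tokens: tuple[str, ...]

    def __post_init__(self) -> None:
        v = np.asarray(self.vectors, dtype=float)
        toks = tuple(self.tokens)
        if v.ndim != 2 or v.shape[0] < 1:
            raise ValueError("embedding matrix must be n x D with n >= 1")
        if len(toks) != v.shape[0]:
            raise ValueError(f"{len(toks)} tokens for {v.shape[0]} embedding rows")
        object.__setattr__(self, "vectors", v)
        object.__setattr__(self, "tokens", toks)


@dataclass(frozen=True)
class TransportPlan:
    """m x n non-negative transport matrix with uniform marginals."""

    matrix: np.ndarray

    def marginal_error(self) -> float:
        """Largest deviation of a row/column sum from its uniform target."""
        t = self.matrix
        m, n = t.shape
        return float(
            max(
                np.abs(t.sum(axis=1) - 1.0 / m).max(),
                np.abs(t.sum(axis=0) - 1.0 / n).max(),
            )
        )


@dataclass(frozen=True)
class WmdResult:
    distance: float
    plan: TransportPlan


@runtime_checkable
class EmbeddingProvider(Protocol):
    """Maps an ordered token list to an n x D embedding matrix."""

    dim: int

    def embed(self, tokens: Sequence[str]) -> np.ndarray: ...


class FixtureEmbeddingProvider:
    """Deterministic, seeded, non-contextual embeddings for offline use.

    Each token maps to a fixed unit vector obtained by seeding a PRNG with
    a keyed BLAKE2 hash of the token; the same (seed, token) always yields
    the same vector, different seeds yield unrelated vectors.  Dimension
    defaults to 768 to mirror transformer-base hidden size.
    """

    def __init__(self, dim: int = 768, seed: int = 0):
        if dim < 1:
            raise ValueError("dim must be >= 1")
        self.dim = int(dim)
        self.seed = int(seed)
        self._cache: dict[str, np.ndarray] = {}

    def _vector(self, token: str) -> np.ndarray:
        vec = self._cache.get(token)
        if vec is None:
            key = self.seed.to_bytes(8, "little", signed=False)
            digest = hashlib.blake2b(token.encode("utf-8"), key=key, digest_size=8).digest()
            rng = np.random.default_rng(int.from_bytes(digest, "little"))
            vec = rng.standard_normal(self.dim)
            vec /= np.linalg.norm(vec)
            self._cache[token] = vec
        return vec

    def embed(self, tokens: Sequence[str]) -> np.ndarray:
        if not tokens:
            raise ValueError("empty token list")
        return np.stack([self._vector(t) for t in tokens])


def embed_turn(tokens: Sequence[str], provider: EmbeddingProvider) -> EmbeddingMatrix:
    """Embed a turn's tokens, one row per token in order."""
    if not tokens:
        raise ValueError("empty token list")
    vectors = provider.embed(tokens)
    return EmbeddingMatrix(vectors=vectors, tokens=tuple(tokens))


def word_distance(b_i: np.ndarray, b_j: np.ndarray) -> float:
    """Euclidean distance between two word embeddings."""
    b_i = np.asarray(b_i, dtype=float).ravel()
    b_j = np.asarray(b_j, dtype=float).ravel()
    if b_i.shape != b_j.shape:
        raise ValueError(f"dimension mismatch: {b_i.shape} vs {b_j.shape}")
    return float(np.linalg.norm(b_i - b_j))


def wmd(X1: EmbeddingMatrix, X2: EmbeddingMatrix) -> WmdResult:
    """Word mover's distance and optimal plan between two turns.

    Solved as an exact LP (HiGHS); with m + n mass units the problem has
    m*n variables, trivially cheap at conversational turn lengths.  Raises
    RuntimeError with solver diagnostics if the solve fails (the uniform-
    marginal problem is always feasible, so failure indicates a numerical
    problem worth surfacing).
    """
    a, b = X1.vectors, X2.vectors
    if a.shape[1] != b.shape[1]:
        raise ValueError(f"embedding dimension mismatch: {a.shape[1]} vs {b.shape[1]}")
    m, n = a.shape[0], b.shape[0]
    cost = cdist(a, b, metric="euclidean")

    # equality constraints: m row-sum rows then n column-sum rows
    rows, cols = [], []
    for i in range(m):
        rows.extend([i] * n)
        cols.extend(range(i * n, (i + 1) * n))
    for j in range(n):
        rows.extend([m + j] * m)
        cols.extend(range(j, m * n, n))
    A_eq = scipy.sparse.csr_matrix(
        (np.ones(2 * m * n), (rows, cols)), shape=(m + n, m * n)
    )
    b_eq = np.concatenate([np.full(m, 1.0 / m), np.full(n, 1.0 / n)])
    res = scipy.optimize.linprog(
        cost.ravel(), A_eq=A_eq, b_eq=b_eq, bounds=(0, None), method="highs"
    )
    if not res.success:
        raise RuntimeError(f"WMD transport LP failed: {res.status}: {res.message}")
    plan = TransportPlan(np.clip(res.x.reshape(m, n), 0.0, None))
    return WmdResult(distance=float(res.fun), plan=plan)
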