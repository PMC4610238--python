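"""Congruence among distance matrices: Kendall's W and the Mantel test.

Two samples-by-samples distance matrices computed from different data layers
(drug responses, target addictions, expression, tissue labels, ...) agree
when they rank the sample pairs similarly.  Each matrix is unfolded to its
upper triangle — one entry per unordered pair — and the unfolded vectors are
compared:

* Kendall's coefficient of concordance W measures the agreement of m ranked
  vectors, from 0 (no agreement) to 1 (complete agreement), with average
  ranks and the classical tie correction (tissue-label distances are almost
  entirely ties);
* the Mantel statistic is the Pearson correlation of two unfolded vectors.

Significance comes from a permutation null that shuffles the object order
(rows and columns jointly) of every matrix but the first, preserving each
matrix's internal distance structure, with the add-one rule

    p = (1 + #{permuted statistic >= observed}) / (1 + n_perm).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.spatial.distance import squareform
from scipy.stats import rankdata

from .clustering import DistanceMatrix
from .errors import InvalidConfigError, UndefinedCorrelationError

__all__ = [
    "CongruenceResult",
    "MantelResult",
    "unfold",
    "refold",
    "kendall_w",
    "cadm_permutation_test",
    "mantel_test",
]


@dataclass(frozen=True)
class CongruenceResult:
    """Kendall-W concordance among m distance matrices with permutation p."""

    w: float
    n_pairs: int
    n_matrices: int
    tie_correction: float
    p_value: float | None = None
    n_perm: int | None = None
    seed: int | None = None
    spearman_rho: float | None = None  # auxiliary, m=2 only: W = (1 + rho)/2


@dataclass(frozen=True)
class MantelResult:
    """Mantel correlation between two distance matrices with permutation p."""

    r: float
    p_value: float
    n_perm: int
    seed: int


def _as_square(m: DistanceMatrix | np.ndarray) -> np.ndarray:
    if isinstance(m, DistanceMatrix):
        return m.values
    return np.asarray(m, dtype=float)


def _check_same_objects(matrices: Sequence[DistanceMatrix | np.ndarray]) -> int:
    n = _as_square(matrices[0]).shape[0]
    ids0 = matrices[0].ids if isinstance(matrices[0], DistanceMatrix) else None
    for m in matrices[1:]:
        sq = _as_square(m)
        if sq.shape[0] != n:
            raise InvalidConfigError("distance matrices differ in size")
        if ids0 is not None and isinstance(m, DistanceMatrix) and m.ids != ids0:
            raise InvalidConfigError("distance matrices are over different object sets")
    return n


def unfold(matrix: DistanceMatrix | np.ndarray) -> np.ndarray:
    """Upper-triangle vector in row-major pair order (1,2),(1,3),...,(n-1,n)."""
    return squareform(_as_square(matrix), checks=False)


def refold(vector: np.ndarray) -> np.ndarray:
    """Inverse of :func:`unfold`: square symmetric matrix with zero diagonal."""
    return squareform(np.asarray(vector, dtype=float), checks=False)


def _tie_term(ranks: np.ndarray) -> float:
    """Classical tie correction sum(t^3 - t) over tie groups of one ranking."""
    _, counts = np.unique(ranks, return_counts=True)
    return float(np.sum(counts.astype(float) ** 3 - counts))


def _kendall_w_from_vectors(vectors: np.ndarray) -> tuple[float, float]:
    """W and tie correction for an (m, N) array of unfolded distances."""
    m, n_pairs = vectors.shape
    ranks = rankdata(vectors, axis=1)
    tie = float(sum(_tie_term(ranks[i]) for i in range(m)))
    rank_sums = ranks.sum(axis=0)
    s = float(np.sum((rank_sums - rank_sums.mean()) ** 2))
    denom = m * m * (n_pairs**3 - n_pairs) - m * tie
    if denom <= 0:
        # all vectors fully tied: complete (degenerate) agreement
        return 1.0, tie
    return 12.0 * s / denom, tie


def kendall_w(matrices: Sequence[DistanceMatrix | np.ndarray]) -> CongruenceResult:
    """Kendall's coefficient of concordance among unfolded distance matrices.

    W = 12 * sum_j (R_j - mean R)^2 / (m^2 (N^3 - N) - m T), where R_j is the
    rank sum of pair j across the m matrices, N = n(n-1)/2 pairs, and T the
    tie correction.  For m = 2 without ties, W = (1 + rho_s) / 2 with rho_s
    the Spearman correlation of the two vectors.
    """
    if len(matrices) < 2:
        raise InvalidConfigError("need >=2 distance matrices")
    n = _check_same_objects(matrices)
    if n * (n - 1) // 2 < 2:
        raise InvalidConfigError("need >=2 object pairs (n >= 3)")
    vectors = np.vstack([unfold(m) for m in matrices])
    w, tie = _kendall_w_from_vectors(vectors)
    rho = 2.0 * w - 1.0 if len(matrices) == 2 else None
    return CongruenceResult(
        w=w,
        n_pairs=vectors.shape[1],
        n_matrices=len(matrices),
        tie_correction=tie,
        spearman_rho=rho,
    )


def _permuted_vectors(square: np.ndarray, perms: np.ndarray) -> np.ndarray:
    """Unfolded vectors of square[perm][:, perm] for each permutation row."""
    n = square.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    return square[perms[:, iu], perms[:, ju]]


def cadm_permutation_test(
    matrices: Sequence[DistanceMatrix | np.ndarray],
    n_perm: int = 10000,
    seed: int = 0,
) -> CongruenceResult:
    """Congruence-among-distance-matrices test: W with a permutation null.

    The null jointly permutes the object order (rows and columns) of every
    matrix but the first and recomputes W; the first matrix is held fixed,
    which is equivalent under the null and keeps the observed pair order as
    the reference frame.

    Permuting objects only reorders the unfolded entries of a matrix, so its
    within-matrix ranks permute along and its tie correction is invariant;
    the null distribution is therefore computed from pre-ranked matrices in
    one vectorised pass.
    """
    if n_perm < 1:
        raise InvalidConfigError("n_perm must be >= 1")
    observed = kendall_w(matrices)
    n = _as_square(matrices[0]).shape[0]
    rng = np.random.default_rng(seed)
    perms = np.vstack([rng.permutation(n) for _ in range(n_perm)])

    m = len(matrices)
    n_pairs = observed.n_pairs
    ranks_fixed = rankdata(unfold(matrices[0]))
    # rank matrices of the permuted ones: refold ranks, then permute objects
    rank_squares = [refold(rankdata(unfold(mm))) for mm in matrices[1:]]
    rank_sums = np.broadcast_to(ranks_fixed, (n_perm, n_pairs)).copy()
    for rs in rank_squares:
        rank_sums += _permuted_vectors(rs, perms)
    s_perm = np.sum((rank_sums - rank_sums.mean(axis=1, keepdims=True)) ** 2, axis=1)
    denom = m * m * (n_pairs**3 - n_pairs) - m * observed.tie_correction
    w_perm = np.ones(n_perm) if denom <= 0 else 12.0 * s_perm / denom
    count = int(np.sum(w_perm >= observed.w - 1e-12))
    p = (1.0 + count) / (1.0 + n_perm)
    return CongruenceResult(
        w=observed.w,
        n_pairs=n_pairs,
        n_matrices=m,
        tie_correction=observed.tie_correction,
        p_value=p,
        n_perm=n_perm,
        seed=seed,
        spearman_rho=observed.spearman_rho,
    )


def mantel_test(
    m1: DistanceMatrix | np.ndarray,
    m2: DistanceMatrix | np.ndarray,
    n_perm: int = 10000,
    seed: int = 0,
) -> MantelResult:
    """Mantel randomisation test between two distance matrices.

    r is the Pearson correlation of the unfolded vectors; the null permutes
    the object order of the second matrix.  One-sided (greater) p with the
    add-one rule.
    """
    if n_perm < 1:
        raise InvalidConfigError("n_perm must be >= 1")
    _check_same_objects([m1, m2])
    v1 = unfold(m1)
    sq2 = _as_square(m2)
    v2 = unfold(sq2)
    if np.ptp(v1) == 0 or np.ptp(v2) == 0:
        raise UndefinedCorrelationError("constant unfolded distance vector")

    def _pearson(a: np.ndarray, b: np.ndarray) -> np.ndarray:
        a = (a - a.mean()) / a.std()
        b = (b - b.mean(axis=-1, keepdims=True)) / b.std(axis=-1, keepdims=True)
        return (a * b).mean(axis=-1)

    r_obs = float(_pearson(v1, v2))
    n = sq2.shape[0]
    rng = np.random.default_rng(seed)
    perms = np.vstack([rng.permutation(n) for _ in range(n_perm)])
    perm_vecs = _permuted_vectors(sq2, perms)
    with np.errstate(invalid="ignore"):
        r_perm = _pearson(v1, perm_vecs)
    count = int(np.sum(r_perm >= r_obs - 1e-12))
    p = (1.0 + count) / (1.0 + n_perm)
    return MantelResult(r=r_obs, p_value=p, n_perm=n_perm, seed=seed)
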