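"""Concordance between genetic and climatic structure.

Tree-to-tree distances (Robinson-Foulds on bipartitions, least-squares and
Euclidean distances on patristic matrices) plus matrix-level permutation tests:
the Mantel test on distance-matrix correlation and PROTEST, the Procrustean
randomization test on PCoA ordinations.

All permutation p-values follow the add-one rule
``p = (1 + #{permuted >= observed}) / (1 + permutations)`` (one-sided, upper
tail), so a p-value of exactly zero is never reported. Passing
``all_permutations=True`` enumerates every taxon permutation instead and
returns the exact p-value ``#{stat_perm >= stat_obs} / n!`` (the identity
permutation is included, so p >= 1/n!).
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import rankdata
from skbio import DistanceMatrix, TreeNode

from .trees import tree_bipartitions, leaf_set

__all__ = [
    "TestResult", "patristic_matrix", "mean_patristic_matrix",
    "robinson_foulds", "least_squares_distance", "euclidean_tree_distance",
    "mantel_test", "pcoa", "procrustes_m2", "protest",
    "read_matrix_csv", "write_matrix_csv",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TestResult:
    """Outcome of a permutation test; ``degenerate`` marks an undefined
    statistic (e.g. a constant distance vector)."""

    statistic: float
    p_value: float
    permutations: int
    method: str
    seed: int | None
    degenerate: bool = False


# ---------------------------------------------------------------------------
# Patristic matrices and tree distances
# ---------------------------------------------------------------------------


def patristic_matrix(tree: TreeNode, missing_as_zero: bool = False) -> DistanceMatrix:
    """Path-length (patristic) distances between all leaf pairs, with ids in
    sorted label order."""
    work = tree
    missing = [n for n in tree.traverse(include_self=False) if n.length is None]
    if missing:
        if not missing_as_zero:
            raise ValueError(
                f"{len(missing)} edge(s) lack branch lengths; pass "
                "missing_as_zero=True to treat them as zero"
            )
        work = tree.copy()
        for n in work.traverse(include_self=False):
            if n.length is None:
                n.length = 0.0
    dm = work.tip_tip_distances()
    return dm.filter(sorted(dm.ids))


def mean_patristic_matrix(trees: list[TreeNode], missing_as_zero: bool = False) -> DistanceMatrix:
    """Mean of the patristic matrices of a set of trees on one leaf set.

    This is the genetic-side input to the Mantel test: averaging over bootstrap
    replicate trees integrates out replicate-to-replicate noise.
    """
    if not trees:
        raise ValueError("empty tree set")
    mats = [patristic_matrix(t, missing_as_zero) for t in trees]
    ids = mats[0].ids
    for m in mats[1:]:
        if m.ids != ids:
            raise ValueError("trees do not share a leaf set")
    return DistanceMatrix(np.mean([m.data for m in mats], axis=0), ids=ids)


def _check_leaves(t1: TreeNode, t2: TreeNode) -> None:
    l1, l2 = leaf_set(t1), leaf_set(t2)
    if l1 != l2:
        raise ValueError(
            f"leaf sets differ: only-in-first={sorted(l1 - l2)}, "
            f"only-in-second={sorted(l2 - l1)}"
        )


def robinson_foulds(t1: TreeNode, t2: TreeNode, normalized: bool = False) -> float:
    """Robinson-Foulds distance: size of the symmetric difference of the
    nontrivial bipartition sets. The normalized variant divides by
    ``|B1| + |B2|`` and is 0 when both trees are stars."""
    _check_leaves(t1, t2)
    b1, b2 = tree_bipartitions(t1), tree_bipartitions(t2)
    rf = len(b1 ^ b2)
    if not normalized:
        return float(rf)
    denom = len(b1) + len(b2)
    return rf / denom if denom else 0.0


def _paired_patristic(t1: TreeNode, t2: TreeNode) -> tuple[np.ndarray, np.ndarray]:
    _check_leaves(t1, t2)
    m1, m2 = patristic_matrix(t1), patristic_matrix(t2)
    return m1.condensed_form(), m2.condensed_form()


def least_squares_distance(t1: TreeNode, t2: TreeNode) -> float:
    """sqrt of the summed squared differences of patristic distances over
    unordered leaf pairs."""
    v1, v2 = _paired_patristic(t1, t2)
    return float(np.sqrt(np.sum((v1 - v2) ** 2)))


def euclidean_tree_distance(t1: TreeNode, t2: TreeNode, vectorization: str = "patristic") -> float:
    """Euclidean distance between vector representations of two trees.

    ``patristic`` (default) flattens the upper-triangle patristic matrices
    (pair order fixed by sorted labels) — numerically identical to
    :func:`least_squares_distance`. ``clades`` uses 0/1 bipartition indicator
    vectors, giving sqrt(RF)."""
    if vectorization == "patristic":
        return least_squares_distance(t1, t2)
    if vectorization == "clades":
        _check_leaves(t1, t2)
        b1, b2 = tree_bipartitions(t1), tree_bipartitions(t2)
        return float(math.sqrt(len(b1 ^ b2)))
    raise ValueError(f"unknown vectorization {vectorization!r}")


# ---------------------------------------------------------------------------
# Mantel test
# ---------------------------------------------------------------------------


def _aligned_pair(m1: DistanceMatrix, m2: DistanceMatrix) -> tuple[DistanceMatrix, DistanceMatrix]:
    if set(m1.ids) != set(m2.ids):
        raise ValueError("distance matrices are over different taxa")
    return m1, m2.filter(m1.ids)


def _corr(v1: np.ndarray, v2: np.ndarray, method: str) -> float:
    if method == "spearman":
        v1, v2 = rankdata(v1), rankdata(v2)  # average ranks for ties
    elif method != "pearson":
        raise ValueError(f"unknown correlation method {method!r}")
    v1 = v1 - v1.mean()
    v2 = v2 - v2.mean()
    denom = np.sqrt((v1 @ v1) * (v2 @ v2))
    return float(v1 @ v2 / denom)


def mantel_test(
    m1: DistanceMatrix,
    m2: DistanceMatrix,
    permutations: int = 999,
    method: str = "pearson",
    rng_seed: int | None = None,
    alternative: str = "greater",
    all_permutations: bool = False,
) -> TestResult:
    """Mantel test of matrix correlation under taxon-relabeling permutations.

    The statistic is the (Pearson or Spearman) correlation of the two condensed
    upper-triangle vectors; the null permutes the rows and columns of ``m2``
    simultaneously by a random taxon permutation. ``alternative`` is
    ``greater`` (default, concordance) or ``two-sided``.
    """
    m1, m2 = _aligned_pair(m1, m2)
    v1 = m1.condensed_form()
    M2 = m2.data
    n = m1.shape[0]
    v2 = m2.condensed_form()
    if np.ptp(v1) == 0 or np.ptp(v2) == 0:
        logger.warning("mantel: constant distance vector; statistic undefined")
        return TestResult(float("nan"), float("nan"), 0, f"mantel-{method}",
                          rng_seed, degenerate=True)
    def stat_for(perm) -> float:
        vp = squareform(M2[np.ix_(perm, perm)], checks=False)
        return _corr(v1, vp, method)

    # evaluate the observed statistic through the identical code path as the
    # permuted ones, so the identity permutation ties it exactly (bit-for-bit)
    obs = stat_for(np.arange(n))

    if all_permutations:
        stats = np.array([stat_for(list(p)) for p in itertools.permutations(range(n))])
        extreme = _count_extreme(stats, obs, alternative)
        return TestResult(obs, extreme / len(stats), len(stats),
                          f"mantel-{method}-exact", rng_seed)
    if permutations < 1:
        raise ValueError("permutations must be >= 1")
    rng = np.random.default_rng(rng_seed)
    stats = np.array([stat_for(rng.permutation(n)) for _ in range(permutations)])
    extreme = _count_extreme(stats, obs, alternative)
    return TestResult(obs, (1 + extreme) / (1 + permutations), permutations,
                      f"mantel-{method}", rng_seed)


def _count_extreme(stats: np.ndarray, obs: float, alternative: str) -> int:
    if alternative == "greater":
        return int(np.sum(stats >= obs))
    if alternative == "two-sided":
        return int(np.sum(np.abs(stats) >= abs(obs)))
    raise ValueError(f"unknown alternative {alternative!r}")


# ---------------------------------------------------------------------------
# PCoA, Procrustes, PROTEST
# ---------------------------------------------------------------------------


def pcoa(dm: DistanceMatrix, k: int) -> np.ndarray:
    """Classical scaling (principal coordinates) of a distance matrix.

    Double-centers -D²/2, eigendecomposes, and returns the axes of the top-k
    *positive* eigenvalues scaled by sqrt(eigenvalue) (rows follow ``dm.ids``).
    Negative eigenvalues (non-Euclidean input) are dropped with a warning; if
    fewer than k positive eigenvalues exist, fewer axes are returned.
    """
    n = dm.shape[0]
    if k > n - 1:
        raise ValueError(f"k={k} exceeds n-1={n - 1}")
    D2 = dm.data**2
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ D2 @ J
    evals, evecs = np.linalg.eigh(B)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    scale = max(float(np.abs(evals).max()), 1.0)
    if evals.min() < -1e-8 * scale:
        logger.warning("pcoa: negative eigenvalues dropped (non-Euclidean distances)")
    pos = evals > 1e-12 * scale
    if pos.sum() < k:
        logger.warning("pcoa: only %d positive axes available (k=%d requested)",
                       int(pos.sum()), k)
    keep = min(k, int(pos.sum()))
    if keep == 0:
        return np.zeros((n, 1))
    return evecs[:, :keep] * np.sqrt(evals[:keep])


def _normalized_config(X: np.ndarray) -> np.ndarray:
    X = X - X.mean(axis=0)
    ss = np.sqrt(np.sum(X**2))
    if ss == 0:
        raise ValueError("configuration has zero total variance")
    return X / ss


def procrustes_m2(X: np.ndarray, Y: np.ndarray, allow_reflection: bool = True) -> float:
    """Procrustes m² between two point configurations (same row count).

    Both configurations are centered and scaled to unit sum of squares; the
    optimal orthogonal rotation (optionally reflection-free) and scaling give
    ``m2 = 1 - (sum of singular values)²`` in [0, 1]. Invariant to translation,
    rotation and positive scaling of either input.
    """
    X, Y = np.asarray(X, float), np.asarray(Y, float)
    if X.shape[0] != Y.shape[0]:
        raise ValueError("configurations must have the same number of rows")
    width = max(X.shape[1], Y.shape[1])
    X = np.pad(X, ((0, 0), (0, width - X.shape[1])))
    Y = np.pad(Y, ((0, 0), (0, width - Y.shape[1])))
    X, Y = _normalized_config(X), _normalized_config(Y)
    U, s, Vt = np.linalg.svd(X.T @ Y)
    if not allow_reflection and np.linalg.det(U @ Vt) < 0:
        s = s.copy()
        s[-1] = -s[-1]
    return float(np.clip(1.0 - s.sum() ** 2, 0.0, 1.0))


def protest(
    m_genetic: DistanceMatrix,
    m_climatic: DistanceMatrix,
    k: int | None = None,
    permutations: int = 999,
    rng_seed: int | None = None,
    all_permutations: bool = False,
    allow_reflection: bool = True,
) -> TestResult:
    """PROTEST: Procrustean randomization test on PCoA ordinations.

    Both matrices are ordinated with :func:`pcoa` (k defaults to min(3, n-1));
    the statistic is the Procrustes correlation sqrt(1 - m²). The null permutes
    the rows of the second configuration; the p-value follows the add-one rule.
    """
    m1, m2 = _aligned_pair(m_genetic, m_climatic)
    n = m1.shape[0]
    k = min(3, n - 1) if k is None else k
    X = pcoa(m1, k)
    Y = pcoa(m2, k)

    def stat_for(perm) -> float:
        return math.sqrt(1.0 - procrustes_m2(X, Y[list(perm), :], allow_reflection))

    # same code path as the permutations: the identity ties obs bit-for-bit
    obs = stat_for(range(n))

    if all_permutations:
        stats = np.array([stat_for(p) for p in itertools.permutations(range(n))])
        extreme = _count_extreme(stats, obs, "greater")
        return TestResult(obs, extreme / len(stats), len(stats), "protest-exact", rng_seed)
    if permutations < 1:
        raise ValueError("permutations must be >= 1")
    rng = np.random.default_rng(rng_seed)
    stats = np.array([stat_for(rng.permutation(n)) for _ in range(permutations)])
    extreme = _count_extreme(stats, obs, "greater")
    return TestResult(obs, (1 + extreme) / (1 + permutations), permutations,
                      "protest", rng_seed)


# ---------------------------------------------------------------------------
# Square-matrix CSV I/O (pipeline bypass inputs/outputs)
# ---------------------------------------------------------------------------


def read_matrix_csv(path) -> DistanceMatrix:
    """Read a square labeled distance matrix from CSV (labels in header and
    first column)."""
    df = pd.read_csv(path, index_col=0)
    if list(df.index) != list(df.columns):
        raise ValueError(f"matrix in {path} is not square-labeled")
    return DistanceMatrix(df.values.astype(float), ids=[str(x) for x in df.index])


def write_matrix_csv(dm: DistanceMatrix, path) -> None:
    pd.DataFrame(dm.data, index=dm.ids, columns=dm.ids).to_csv(path)
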