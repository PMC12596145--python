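"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive — exhaustive recursion/enumeration kept
separate from the package's implementations so the two routes can disagree.
"""

from __future__ import annotations

import itertools
from functools import lru_cache

import numpy as np

NEG = float("-inf")


# --- alignment scores (linear gap penalty) ---------------------------------


def brute_global_score(a: str, b: str, match: float, mismatch: float, gap: float) -> float:
    """Optimal global alignment score by exhaustive recursion."""

    @lru_cache(maxsize=None)
    def go(i: int, j: int) -> float:
        if i == len(a) and j == len(b):
            return 0.0
        best = NEG
        if i < len(a) and j < len(b):
            s = match if a[i] == b[j] else mismatch
            best = max(best, s + go(i + 1, j + 1))
        if i < len(a):
            best = max(best, gap + go(i + 1, j))
        if j < len(b):
            best = max(best, gap + go(i, j + 1))
        return best

    return go(0, 0)


def brute_local_score(a: str, b: str, match: float, mismatch: float, gap: float) -> float:
    """Optimal local score: best global score over all substring pairs (>= 0)."""
    best = 0.0
    subs_a = {a[i:j] for i in range(len(a)) for j in range(i + 1, len(a) + 1)}
    subs_b = {b[i:j] for i in range(len(b)) for j in range(i + 1, len(b) + 1)}
    for sa in subs_a:
        for sb in subs_b:
            best = max(best, brute_global_score(sa, sb, match, mismatch, gap))
    return best


# --- string metrics --------------------------------------------------------


def brute_levenshtein(a: str, b: str) -> int:
    @lru_cache(maxsize=None)
    def go(i: int, j: int) -> int:
        if i == len(a):
            return len(b) - j
        if j == len(b):
            return len(a) - i
        best = go(i + 1, j + 1) + (a[i] != b[j])
        best = min(best, go(i + 1, j) + 1, go(i, j + 1) + 1)
        return best

    return go(0, 0)


def brute_osa(a: str, b: str) -> int:
    """Restricted Damerau-Levenshtein by exhaustive recursion (a transposed
    pair is consumed atomically, never edited again)."""

    @lru_cache(maxsize=None)
    def go(i: int, j: int) -> int:
        if i == len(a):
            return len(b) - j
        if j == len(b):
            return len(a) - i
        best = go(i + 1, j + 1) + (a[i] != b[j])
        best = min(best, go(i + 1, j) + 1, go(i, j + 1) + 1)
        if (i + 1 < len(a) and j + 1 < len(b)
                and a[i] == b[j + 1] and a[i + 1] == b[j]):
            best = min(best, go(i + 2, j + 2) + 1)
        return best

    return go(0, 0)


def brute_jaro(a: str, b: str) -> float:
    """Jaro similarity from its definition, written independently."""
    if a == b:
        return 1.0
    if not a or not b:
        return 0.0
    win = max(len(a), len(b)) // 2 - 1
    used = [False] * len(b)
    pairs = []
    for i, ca in enumerate(a):
        for j in range(max(0, i - win), min(len(b), i + win + 1)):
            if not used[j] and b[j] == ca:
                used[j] = True
                pairs.append((i, j))
                break
    m = len(pairs)
    if m == 0:
        return 0.0
    b_matched_order = [b[j] for j in sorted(j for _, j in pairs)]
    a_matched = [a[i] for i, _ in pairs]
    t = sum(x != y for x, y in zip(a_matched, b_matched_order)) / 2
    return (m / len(a) + m / len(b) + (m - t) / m) / 3.0


def brute_jaccard(a: str, b: str, k: int) -> float:
    ka = {a[i:i + k] for i in range(len(a) - k + 1)}
    kb = {b[i:i + k] for i in range(len(b) - k + 1)}
    return len(ka & kb) / len(ka | kb)


def brute_dice(a: str, b: str) -> float:
    from collections import Counter

    ca = Counter(a[i:i + 2] for i in range(len(a) - 1))
    cb = Counter(b[i:i + 2] for i in range(len(b) - 1))
    shared = sum(min(ca[g], cb[g]) for g in set(ca) | set(cb))
    return 2 * shared / (sum(ca.values()) + sum(cb.values()))


# --- permutation tests -----------------------------------------------------


def exhaustive_mantel_p(M1: np.ndarray, M2: np.ndarray) -> tuple[float, float]:
    """Exact Mantel p over all n! relabelings of M2 (Pearson, upper tail)."""
    from scipy.stats import pearsonr

    n = M1.shape[0]
    iu = np.triu_indices(n, k=1)
    v1 = M1[iu]
    stats = []
    for p in itertools.permutations(range(n)):
        Mp = M2[np.ix_(p, p)]
        stats.append(pearsonr(v1, Mp[iu]).statistic)
    stats = np.array(stats)
    obs = stats[0]  # identity permutation comes first
    return float(obs), float(np.sum(stats >= obs) / len(stats))


def classical_mds(D: np.ndarray, k: int) -> np.ndarray:
    """Torgerson scaling, written independently of the package's pcoa."""
    n = D.shape[0]
    H = np.eye(n) - 1.0 / n
    B = -0.5 * H @ (D**2) @ H
    w, V = np.linalg.eigh(B)
    idx = np.argsort(w)[::-1]
    w, V = w[idx], V[:, idx]
    keep = [i for i in range(len(w)) if w[i] > 1e-10 * max(1.0, abs(w).max())][:k]
    if not keep:
        return np.zeros((n, 1))
    return V[:, keep] * np.sqrt(w[keep])


def procrustes_corr(X: np.ndarray, Y: np.ndarray) -> float:
    """sqrt(1 - m2) via numpy SVD, independent formulation."""
    def norm(Z):
        Z = Z - Z.mean(0)
        return Z / np.linalg.norm(Z)

    w = max(X.shape[1], Y.shape[1])
    X = np.pad(np.asarray(X, float), ((0, 0), (0, w - X.shape[1])))
    Y = np.pad(np.asarray(Y, float), ((0, 0), (0, w - Y.shape[1])))
    s = np.linalg.svd(norm(X).T @ norm(Y), compute_uv=False)
    return float(np.sqrt(max(0.0, 1.0 - (1.0 - s.sum() ** 2))))


def exhaustive_protest_p(M1: np.ndarray, M2: np.ndarray, k: int) -> tuple[float, float]:
    """Exact PROTEST p over all row permutations of the second ordination."""
    X = classical_mds(M1, k)
    Y = classical_mds(M2, k)
    stats = [procrustes_corr(X, Y[list(p), :]) for p in itertools.permutations(range(len(Y)))]
    obs = stats[0]  # identity permutation comes first
    return float(obs), float(np.mean(np.array(stats) >= obs))
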