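"""String similarity and distance metrics for scoring window variability.

Eight metrics spanning strict character distances (Hamming, Levenshtein,
Damerau-Levenshtein), alignment scores (Smith-Waterman), set/multiset overlap
(Jaccard on k-mers, Sørensen-Dice on bigrams) and probabilistic matching (Jaro,
Jaro-Winkler). Gap characters inside a window are treated as ordinary
characters: the metrics rank windows by divergence, including indel divergence,
and are not used for phylogenetic inference itself.

Damerau-Levenshtein is the optimal-string-alignment (restricted) variant: a
substring is never edited twice, so e.g. d("CA","ABC") = 3, not 2.
"""

from __future__ import annotations

from collections import Counter

import numpy as np
from skbio import DistanceMatrix

from .seqio import Alignment, ScoringScheme, alignment_score

__all__ = [
    "hamming", "levenshtein", "damerau_levenshtein", "smith_waterman_similarity",
    "jaccard", "jaro", "jaro_winkler", "sorensen_dice",
    "METRICS", "pairwise_metric_matrix",
]


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError(f"hamming distance needs equal lengths ({len(a)} != {len(b)})")
    return sum(x != y for x, y in zip(a, b))


def levenshtein(a: str, b: str) -> int:
    """Minimum number of insertions, deletions and substitutions."""
    if len(a) < len(b):
        a, b = b, a
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, start=1):
        cur = [i]
        for j, cb in enumerate(b, start=1):
            cur.append(min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + (ca != cb)))
        prev = cur
    return prev[-1]


def damerau_levenshtein(a: str, b: str) -> int:
    """Optimal-string-alignment distance: Levenshtein plus adjacent transposition."""
    la, lb = len(a), len(b)
    d = [[0] * (lb + 1) for _ in range(la + 1)]
    for i in range(la + 1):
        d[i][0] = i
    for j in range(lb + 1):
        d[0][j] = j
    for i in range(1, la + 1):
        for j in range(1, lb + 1):
            cost = a[i - 1] != b[j - 1]
            d[i][j] = min(d[i - 1][j] + 1, d[i][j - 1] + 1, d[i - 1][j - 1] + cost)
            if i > 1 and j > 1 and a[i - 1] == b[j - 2] and a[i - 2] == b[j - 1]:
                d[i][j] = min(d[i][j], d[i - 2][j - 2] + 1)
    return d[la][lb]


def smith_waterman_similarity(a: str, b: str, scheme: ScoringScheme | None = None) -> float:
    """Optimal local alignment score (>= 0; 0 when nothing aligns)."""
    scheme = scheme or ScoringScheme()
    if scheme.mode != "local":
        scheme = ScoringScheme(scheme.match, scheme.mismatch, scheme.gap_open,
                               scheme.gap_extend, "local")
    if not a or not b:
        return 0.0
    return alignment_score(a, b, scheme)


def _kmers(s: str, k: int) -> set[str]:
    return {s[i : i + k] for i in range(len(s) - k + 1)}


def jaccard(a: str, b: str, k: int = 3) -> float:
    """Jaccard similarity of the two k-mer sets."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if len(a) < k or len(b) < k:
        raise ValueError(f"both strings must be at least k={k} long")
    ka, kb = _kmers(a, k), _kmers(b, k)
    return len(ka & kb) / len(ka | kb)


def jaro(a: str, b: str) -> float:
    """Jaro similarity: matches within a sliding window, transposition-corrected."""
    if a == b:
        return 1.0
    la, lb = len(a), len(b)
    if la == 0 or lb == 0:
        return 0.0
    window = max(max(la, lb) // 2 - 1, 0)
    match_a = [False] * la
    match_b = [False] * lb
    m = 0
    for i, ca in enumerate(a):
        lo, hi = max(0, i - window), min(lb, i + window + 1)
        for j in range(lo, hi):
            if not match_b[j] and b[j] == ca:
                match_a[i] = match_b[j] = True
                m += 1
                break
    if m == 0:
        return 0.0
    bs = [b[j] for j in range(lb) if match_b[j]]
    t = sum(ca != cb for ca, cb in zip((a[i] for i in range(la) if match_a[i]), bs)) / 2
    return (m / la + m / lb + (m - t) / m) / 3


def jaro_winkler(a: str, b: str, p: float = 0.1, max_prefix: int = 4) -> float:
    """Jaro similarity boosted by the length of the shared prefix."""
    if p * max_prefix > 1.0:
        raise ValueError("p * max_prefix must be <= 1 to keep the result <= 1")
    j = jaro(a, b)
    ell = 0
    for ca, cb in zip(a[:max_prefix], b[:max_prefix]):
        if ca != cb:
            break
        ell += 1
    return j + ell * p * (1.0 - j)


def _bigrams(s: str) -> Counter:
    return Counter(s[i : i + 2] for i in range(len(s) - 1))


def sorensen_dice(a: str, b: str) -> float:
    """Sørensen-Dice similarity on bigram multisets."""
    if len(a) < 2 or len(b) < 2:
        raise ValueError("both strings must have length >= 2")
    ba, bb = _bigrams(a), _bigrams(b)
    shared = sum((ba & bb).values())
    return 2.0 * shared / (sum(ba.values()) + sum(bb.values()))


#: metric name -> (callable, kind); the callable takes (a, b, **params)
METRICS: dict[str, tuple] = {
    "hamming": (hamming, "distance"),
    "levenshtein": (levenshtein, "distance"),
    "damerau_levenshtein": (damerau_levenshtein, "distance"),
    "smith_waterman": (smith_waterman_similarity, "similarity"),
    "jaccard": (jaccard, "similarity"),
    "jaro": (jaro, "similarity"),
    "jaro_winkler": (jaro_winkler, "similarity"),
    "sorensen_dice": (sorensen_dice, "similarity"),
}


def pairwise_metric_matrix(alignment: Alignment, metric_name: str, **params) -> DistanceMatrix:
    """Symmetric taxon-by-taxon dissimilarity matrix under one string metric.

    Similarities s in [0,1] are converted to 1 - s; the unbounded
    Smith-Waterman score is first normalized by match_score * min(|a|, |b|).
    """
    if metric_name not in METRICS:
        raise ValueError(f"unknown metric {metric_name!r}; choose from {sorted(METRICS)}")
    func, kind = METRICS[metric_name]
    seqs = [r.residues for r in alignment.records]
    labels = alignment.labels
    n = len(seqs)
    if n < 2:
        raise ValueError("need at least 2 taxa")
    scheme = params.pop("scheme", None) or ScoringScheme()
    if metric_name == "smith_waterman":
        params["scheme"] = scheme
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            v = func(seqs[i], seqs[j], **params)
            if metric_name == "smith_waterman":
                denom = scheme.match * min(len(seqs[i]), len(seqs[j]))
                v = 1.0 - v / denom if denom > 0 else 1.0
            elif kind == "similarity":
                v = 1.0 - v
            out[i, j] = out[j, i] = v
    return DistanceMatrix(out, ids=labels)
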