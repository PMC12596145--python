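"""Sliding windows over an alignment, plus column- and window-level filters.

Coordinates are 0-based, half-open ``[start, end)`` in the parent alignment's
column system throughout; gap-column removal never changes a window's reported
bounds, only its retained columns.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .seqio import Alignment

__all__ = ["WindowSpec", "AlignmentWindow", "slide_windows", "filter_gap_columns",
           "window_variability_filter"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class WindowSpec:
    size: int
    step: int

    def __post_init__(self) -> None:
        if self.size < 1 or self.step < 1:
            raise ValueError("window size and step must be >= 1")


@dataclass
class AlignmentWindow:
    """A contiguous column slice of a parent alignment.

    ``start``/``end`` always refer to parent coordinates; ``removed_columns``
    lists parent column indices dropped by the gap filter.
    """

    start: int
    end: int
    alignment: Alignment | None
    source_id: str = ""
    removed_columns: list[int] = field(default_factory=list)

    @property
    def is_empty(self) -> bool:
        return self.alignment is None

    @property
    def n_columns(self) -> int:
        return 0 if self.alignment is None else self.alignment.length

    @property
    def labels(self) -> list[str]:
        return [] if self.alignment is None else self.alignment.labels


def slide_windows(
    alignment: Alignment,
    spec: WindowSpec,
    keep_partial: bool = True,
    source_id: str = "",
) -> list[AlignmentWindow]:
    """Cut the alignment into windows at starts 0, step, 2*step, ...

    A trailing window shorter than ``spec.size`` is emitted only when
    ``keep_partial`` is true and it spans at least 2 columns. A window size
    exceeding the alignment length degrades to a single full-length window
    (with a warning).
    """
    L = alignment.length
    if spec.size > L:
        logger.warning(
            "window size %d exceeds alignment length %d; using a single window",
            spec.size, L,
        )
        return [AlignmentWindow(0, L, alignment.slice_columns(0, L), source_id)]
    windows: list[AlignmentWindow] = []
    start = 0
    while start < L:
        end = min(start + spec.size, L)
        if end - start < spec.size:  # trailing partial window
            if keep_partial and end - start >= 2:
                windows.append(
                    AlignmentWindow(start, end, alignment.slice_columns(start, end), source_id)
                )
            break
        windows.append(
            AlignmentWindow(start, end, alignment.slice_columns(start, end), source_id)
        )
        if end == L:
            break
        start += spec.step
    return windows


def filter_gap_columns(
    window: AlignmentWindow,
    max_gap_fraction: float,
    gap_chars: str = "-N",
) -> AlignmentWindow:
    """Drop columns whose gap fraction exceeds ``max_gap_fraction``.

    ``-`` and, by default, ``N`` count as gaps. Returns a new window with the
    same parent bounds and the removed parent-column indices recorded; a window
    losing every column is flagged empty (``alignment is None``) so the caller
    can exclude it. Idempotent.
    """
    if not 0.0 <= max_gap_fraction <= 1.0:
        raise ValueError("max_gap_fraction must lie in [0, 1]")
    if window.is_empty:
        return window
    aln = window.alignment
    n = len(aln)
    keep: list[int] = []
    removed: list[int] = list(window.removed_columns)
    for j in range(aln.length):
        gap_frac = sum(c in gap_chars for c in aln.column(j)) / n
        if gap_frac <= max_gap_fraction:
            keep.append(j)
        else:
            removed.append(_parent_column(window, j))
    removed.sort()
    if not keep:
        logger.warning(
            "window [%d, %d): all columns exceeded gap fraction %.3f; window excluded",
            window.start, window.end, max_gap_fraction,
        )
        return AlignmentWindow(window.start, window.end, None, window.source_id, removed)
    return AlignmentWindow(
        window.start, window.end, aln.take_columns(keep), window.source_id, removed
    )


def _parent_column(window: AlignmentWindow, local_j: int) -> int:
    """Map a local column index to the parent coordinate, accounting for
    columns already removed by a previous filter pass."""
    surviving = [
        c for c in range(window.start, window.end) if c not in set(window.removed_columns)
    ]
    return surviving[local_j]


def mean_pairwise_dissimilarity(window: AlignmentWindow, metric_name: str, **params) -> float:
    """Mean off-diagonal dissimilarity of the window under a string metric."""
    from .metrics import pairwise_metric_matrix  # local import: avoid cycle

    dm = pairwise_metric_matrix(window.alignment, metric_name, **params)
    n = dm.shape[0]
    return float(dm.condensed_form().mean()) if n > 1 else 0.0


def window_variability_filter(
    windows: list[AlignmentWindow],
    metric_name: str,
    threshold: float,
    **params,
) -> list[AlignmentWindow]:
    """Retain windows whose mean pairwise dissimilarity is >= ``threshold``.

    Low-variability windows carry little phylogenetic signal; this mirrors the
    use of string metrics to keep only the most variable alignment regions.
    Every keep/drop decision is logged with its score.
    """
    retained: list[AlignmentWindow] = []
    for w in windows:
        if w.is_empty:
            logger.info("window [%d, %d): empty, dropped", w.start, w.end)
            continue
        score = mean_pairwise_dissimilarity(w, metric_name, **params)
        if score >= threshold:
            logger.info("window [%d, %d): variability %.6g >= %.6g, retained",
                        w.start, w.end, score, threshold)
            retained.append(w)
        else:
            logger.info("window [%d, %d): variability %.6g < %.6g, dropped",
                        w.start, w.end, score, threshold)
    return retained
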