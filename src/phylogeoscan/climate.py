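"""Climatic table handling and per-variable climate trees.

Each retained environmental variable yields a neighbor-joining tree built from
the Euclidean distances between taxa in climate-variable space; these trees are
the reference the per-window genetic phylogenies are compared against. If
geographic coordinates are supplied as columns they are treated as ordinary
variables.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix, TreeNode

from .trees import neighbor_joining

__all__ = ["ClimaticTable", "read_climate_csv", "variance_filter",
           "climatic_dissimilarity", "build_climate_trees", "COMBINED_TREE_NAME"]

logger = logging.getLogger(__name__)

COMBINED_TREE_NAME = "all_variables"


@dataclass
class ClimaticTable:
    """Numeric environmental variables indexed by taxon label."""

    data: pd.DataFrame  # index = taxon labels, columns = variables

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            dupes = sorted(self.data.index[self.data.index.duplicated()].unique())
            raise ValueError(f"duplicate taxa in climatic table: {dupes}")
        if self.data.isna().any().any():
            raise ValueError("climatic table contains missing values")

    @property
    def taxa(self) -> list[str]:
        return list(self.data.index)

    @property
    def variables(self) -> list[str]:
        return list(self.data.columns)

    def subset_taxa(self, taxa: list[str]) -> "ClimaticTable":
        missing = [t for t in taxa if t not in self.data.index]
        if missing:
            raise KeyError(f"taxa absent from climatic table: {missing}")
        return ClimaticTable(self.data.loc[taxa].copy())


def read_climate_csv(path, id_column: str = "id") -> ClimaticTable:
    """Load a climatic CSV: one identifier column plus numeric variables.

    Any non-numeric or missing cell is an error naming the offending
    row (taxon) and column.
    """
    # keep_default_na=False so a literal "NA" cell is reported verbatim as
    # non-numeric rather than silently treated as missing
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    raw = raw.apply(lambda s: s.str.strip() if s.dtype == object else s)
    if id_column not in raw.columns:
        raise ValueError(f"id column {id_column!r} not found in {path} "
                         f"(columns: {list(raw.columns)})")
    raw = raw.set_index(id_column)
    numeric = raw.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna()
    if bad.any().any():
        r, c = np.argwhere(bad.values)[0]
        cell = raw.iloc[r, c]
        what = "missing value" if cell == "" else f"non-numeric value {cell!r}"
        raise ValueError(
            f"{what} at row {raw.index[r]!r}, column {bad.columns[c]!r} in {path}"
        )
    return ClimaticTable(numeric.astype(float))


def variance_filter(table: ClimaticTable, threshold: float = 0.0):
    """Drop variables whose sample variance (n-1 denominator) is not strictly
    above ``threshold``; returns (filtered table, dropped variable names)."""
    if threshold < 0:
        raise ValueError("variance threshold must be >= 0")
    variances = table.data.var(ddof=1)
    keep = [v for v in table.variables if variances[v] > threshold]
    dropped = [v for v in table.variables if v not in keep]
    if not keep:
        raise ValueError(
            f"variance filter at threshold {threshold} removed every variable "
            f"({dropped}); lower the threshold"
        )
    for v in dropped:
        logger.info("variable %r dropped (variance %.6g <= %.6g)", v, variances[v], threshold)
    return ClimaticTable(table.data[keep].copy()), dropped


def climatic_dissimilarity(
    table: ClimaticTable,
    variable_subset: list[str],
    standardize: bool = False,
) -> DistanceMatrix:
    """Euclidean distances between taxa in the space of the chosen variables.

    A single-variable subset reduces to absolute value differences. With
    ``standardize`` each variable is z-scored first, so mixed units cannot
    dominate the combined distance.
    """
    if not variable_subset:
        raise ValueError("variable subset must be nonempty")
    missing = [v for v in variable_subset if v not in table.variables]
    if missing:
        raise KeyError(f"unknown climatic variable(s): {missing}")
    X = table.data[variable_subset].values.astype(float)
    if standardize:
        X = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
    return DistanceMatrix(squareform(pdist(X, metric="euclidean"), checks=False),
                          ids=table.taxa)


def build_climate_trees(
    table: ClimaticTable,
    variance_threshold: float = 0.0,
    standardize: bool = False,
    build_combined_tree: bool = True,
) -> dict[str, TreeNode]:
    """Variance-filter the table, then build one NJ tree per retained variable
    (plus a combined tree over all retained variables, keyed
    ``all_variables``)."""
    if len(table.taxa) < 3:
        raise ValueError("need at least 3 taxa to build climate trees")
    filtered, _ = variance_filter(table, variance_threshold)
    out: dict[str, TreeNode] = {}
    for var in filtered.variables:
        out[var] = neighbor_joining(climatic_dissimilarity(filtered, [var]))
    if build_combined_tree and len(filtered.variables) > 1:
        dm = climatic_dissimilarity(filtered, filtered.variables, standardize=standardize)
        out[COMBINED_TREE_NAME] = neighbor_joining(dm)
    return out


def climatic_matrices(
    table: ClimaticTable,
    variance_threshold: float = 0.0,
    standardize: bool = False,
    build_combined: bool = True,
) -> dict[str, DistanceMatrix]:
    """Per-variable (and optional combined) Euclidean dissimilarity matrices,
    after variance filtering — the climatic side of the Mantel/PROTEST tests."""
    filtered, _ = variance_filter(table, variance_threshold)
    out = {v: climatic_dissimilarity(filtered, [v]) for v in filtered.variables}
    if build_combined and len(filtered.variables) > 1:
        out[COMBINED_TREE_NAME] = climatic_dissimilarity(
            filtered, filtered.variables, standardize=standardize
        )
    return out
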