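"""End-to-end orchestration: align -> window -> filter -> trees -> compare.

The run is fully deterministic: every window draws its random streams from a
seed derived by a stable hash of ``(rng_seed, window_start)``, so the worker
count, scheduling order and the presence of other windows can never change a
window's results. Identical (inputs, config, seed) produce a byte-identical
artifact directory.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
import math
from concurrent.futures import ProcessPoolExecutor
from dataclasses import dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .climate import (ClimaticTable, build_climate_trees, climatic_dissimilarity,
                      read_climate_csv, variance_filter, COMBINED_TREE_NAME)
from .compare import (euclidean_tree_distance, least_squares_distance,
                      mantel_test, mean_patristic_matrix, protest,
                      robinson_foulds)
from .seqio import Alignment, ScoringScheme, build_msa, read_fasta, write_fasta
from .trees import (bootstrap_trees, collapse_low_support, external_engine,
                    majority_rule_consensus, newick_write, node_support,
                    neighbor_joining)
from .windows import (AlignmentWindow, WindowSpec, filter_gap_columns,
                      mean_pairwise_dissimilarity, slide_windows)

__all__ = ["PipelineConfig", "PipelineStageError", "run_pipeline",
           "write_results", "parallel_map", "RESULT_COLUMNS", "derive_seed"]

logger = logging.getLogger(__name__)

RESULT_COLUMNS = [
    "window_start", "window_end", "climatic_variable",
    "rf", "rf_normalized", "lsd", "euclidean",
    "mantel_r", "mantel_p", "protest_stat", "protest_p",
    "n_taxa", "n_bootstrap", "mean_support",
]

_INT_COLUMNS = {"window_start", "window_end", "n_taxa", "n_bootstrap"}


class PipelineStageError(RuntimeError):
    def __init__(self, stage: str, cause: BaseException, window: tuple[int, int] | None = None):
        at = f" at window [{window[0]}, {window[1]})" if window else ""
        super().__init__(f"stage {stage!r}{at} failed: {cause}")
        self.stage = stage
        self.window = window
        self.__cause__ = cause


@dataclass
class PipelineConfig:
    """All pipeline parameters; unknown keys are rejected when loading."""

    # paths
    fasta_path: str = ""
    climate_path: str = ""
    output_dir: str = "results"
    id_column: str = "id"
    # alignment
    match: float = 1.0
    mismatch: float = -1.0
    gap_open: float = -2.0
    gap_extend: float = -0.5
    reference: str = "auto"
    align: str = "auto"  # auto | always | never
    # windows
    window_size: int = 100
    step_size: int = 100
    keep_partial: bool = True
    max_gap_fraction: float = 0.5
    n_as_gap: bool = True
    # variability filter
    variability_metric: str = "hamming"
    variability_threshold: float = 0.0
    jaccard_k: int = 3
    # genetic trees
    bootstrap_replicates: int = 100
    consensus_threshold: float = 0.5
    min_clade_support: float | None = None
    tree_engine: str = "nj"  # "nj" or "external:<executable> [args...]"
    # climate
    variance_threshold: float = 0.0
    standardize: bool = False
    build_combined_tree: bool = True
    # statistics
    permutations: int = 999
    mantel_method: str = "pearson"
    protest_axes: int = 3
    euclidean_vectorization: str = "patristic"
    # execution
    rng_seed: int = 42
    workers: int = 1
    drop_unmatched: bool = False

    def __post_init__(self) -> None:
        if self.align not in ("auto", "always", "never"):
            raise ValueError("align must be auto, always or never")
        if not 0.0 <= self.max_gap_fraction <= 1.0:
            raise ValueError("max_gap_fraction must lie in [0, 1]")
        if not 0.5 <= self.consensus_threshold < 1.0:
            raise ValueError("consensus_threshold must lie in [0.5, 1)")
        if self.variance_threshold < 0 or self.variability_threshold < 0:
            raise ValueError("thresholds must be >= 0")
        if self.bootstrap_replicates < 1 or self.permutations < 1:
            raise ValueError("bootstrap_replicates and permutations must be >= 1")
        if self.workers < 1:
            raise ValueError("workers must be >= 1")
        if self.mantel_method not in ("pearson", "spearman"):
            raise ValueError("mantel_method must be pearson or spearman")

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in fields(cls)}
        unknown = sorted(set(d) - known)
        if unknown:
            raise ValueError(f"unknown config key(s): {unknown}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValueError(f"config file {path} must hold a mapping")
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @property
    def scoring(self) -> ScoringScheme:
        return ScoringScheme(self.match, self.mismatch, self.gap_open, self.gap_extend)

    @property
    def gap_chars(self) -> str:
        return "-N" if self.n_as_gap else "-"


def derive_seed(*parts) -> int:
    """Stable sub-2^31 seed from arbitrary parts (reproducible across runs)."""
    digest = hashlib.sha256(":".join(str(p) for p in parts).encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def parallel_map(func, tasks: list, workers: int = 1) -> list:
    """Apply ``func`` over tasks, serially or across processes; results come
    back in task order either way, and any worker error propagates."""
    if workers <= 1 or len(tasks) <= 1:
        return [func(t) for t in tasks]
    with ProcessPoolExecutor(max_workers=workers) as pool:
        return list(pool.map(func, tasks))


# ---------------------------------------------------------------------------
# Per-window worker
# ---------------------------------------------------------------------------


def _resolve_engine(spec: str):
    if spec == "nj":
        return None
    if spec.startswith("external:"):
        exe, *args = spec[len("external:"):].split()
        return external_engine(exe, args)
    raise ValueError(f"unknown tree_engine {spec!r}")


def _variability_params(cfg: PipelineConfig) -> dict:
    if cfg.variability_metric == "jaccard":
        return {"k": cfg.jaccard_k}
    if cfg.variability_metric == "smith_waterman":
        return {"scheme": cfg.scoring}
    return {}


def _process_window(task) -> dict:
    """Everything downstream of windowing for one window; pure function of the
    task payload so process-pool scheduling cannot affect the result."""
    window, cfg, clim_trees, clim_dms = task
    seed = derive_seed(cfg.rng_seed, window.start)
    coords = (window.start, window.end)

    try:
        window = filter_gap_columns(window, cfg.max_gap_fraction, cfg.gap_chars)
    except Exception as exc:  # pragma: no cover - defensive
        raise PipelineStageError("gap_filter", exc, coords)
    if window.is_empty:
        return {"rows": [], "skip": "all columns removed by gap filter", "coords": coords}

    try:
        score = mean_pairwise_dissimilarity(window, cfg.variability_metric,
                                            **_variability_params(cfg))
    except Exception as exc:
        raise PipelineStageError("variability_filter", exc, coords)
    if score < cfg.variability_threshold:
        return {"rows": [], "skip": f"variability {score:.6g} below threshold",
                "coords": coords}

    try:
        boots = bootstrap_trees(window.alignment, cfg.bootstrap_replicates, seed,
                                engine=_resolve_engine(cfg.tree_engine))
        consensus = majority_rule_consensus(boots, cfg.consensus_threshold)
        if cfg.min_clade_support is not None:
            consensus = collapse_low_support(consensus, cfg.min_clade_support)
        mean_pat = mean_patristic_matrix(boots)
    except Exception as exc:
        raise PipelineStageError("tree_inference", exc, coords)

    supports = [s for s in (node_support(n) for n in consensus.non_tips()) if s is not None]
    mean_support = float(np.mean(supports)) if supports else float("nan")

    rows = []
    for var in sorted(clim_trees):
        try:
            ctree = clim_trees[var]
            cdm = clim_dms[var]
            mt = mantel_test(mean_pat, cdm, cfg.permutations, cfg.mantel_method,
                             rng_seed=derive_seed(seed, var, "mantel"))
            try:
                pt = protest(mean_pat, cdm, k=min(cfg.protest_axes, len(cdm.ids) - 1),
                             permutations=cfg.permutations,
                             rng_seed=derive_seed(seed, var, "protest"))
                p_stat, p_p = pt.statistic, pt.p_value
            except ValueError:
                p_stat = p_p = float("nan")
            rows.append({
                "window_start": window.start,
                "window_end": window.end,
                "climatic_variable": var,
                "rf": robinson_foulds(consensus, ctree),
                "rf_normalized": robinson_foulds(consensus, ctree, normalized=True),
                "lsd": least_squares_distance(consensus, ctree),
                "euclidean": euclidean_tree_distance(
                    consensus, ctree, cfg.euclidean_vectorization),
                "mantel_r": mt.statistic,
                "mantel_p": mt.p_value,
                "protest_stat": p_stat,
                "protest_p": p_p,
                "n_taxa": len(window.labels),
                "n_bootstrap": cfg.bootstrap_replicates,
                "mean_support": mean_support,
            })
        except PipelineStageError:
            raise
        except Exception as exc:
            raise PipelineStageError(f"comparison[{var}]", exc, coords)

    fasta_lines = []
    for rec in window.alignment.records:
        fasta_lines.append(f">{rec.label}")
        fasta_lines.extend(rec.residues[i:i + 60] for i in range(0, len(rec.residues), 60))
    return {
        "rows": rows,
        "coords": coords,
        "fasta": "\n".join(fasta_lines) + "\n",
        "newick": newick_write(consensus) + "\n",
    }


# ---------------------------------------------------------------------------
# Results table
# ---------------------------------------------------------------------------


def _fmt(col: str, value) -> str:
    if col in _INT_COLUMNS:
        return str(int(value))
    if col == "climatic_variable":
        return str(value)
    return f"{float(value):.6g}"


def write_results(rows: list[dict], path) -> pd.DataFrame:
    """Write the results CSV (fixed column order, rows sorted by window start
    then variable, floats at 6 significant digits); returns the table."""
    if not rows:
        logger.warning("no result rows; writing header-only results file")
    ordered = sorted(rows, key=lambda r: (r["window_start"], r["climatic_variable"]))
    with open(path, "w") as fh:
        fh.write(",".join(RESULT_COLUMNS) + "\n")
        for row in ordered:
            fh.write(",".join(_fmt(c, row[c]) for c in RESULT_COLUMNS) + "\n")
    return pd.DataFrame(ordered, columns=RESULT_COLUMNS)


# ---------------------------------------------------------------------------
# Pipeline driver
# ---------------------------------------------------------------------------


def _load_alignment(cfg: PipelineConfig) -> Alignment:
    records = read_fasta(cfg.fasta_path)
    lengths = {len(r) for r in records}
    if cfg.align == "always" or (cfg.align == "auto" and len(lengths) > 1):
        logger.info("aligning %d sequences (star alignment, reference=%s)",
                    len(records), cfg.reference)
        return build_msa(records, cfg.scoring, cfg.reference)
    if len(lengths) > 1:
        raise ValueError(
            "align=never but input sequences have unequal lengths; provide a "
            "pre-aligned FASTA or enable alignment"
        )
    return Alignment(records)


def _reconcile(alignment: Alignment, climate: ClimaticTable, cfg: PipelineConfig):
    seq_taxa = [lab.strip() for lab in alignment.labels]
    clim_taxa = {t.strip() for t in climate.taxa}
    missing_clim = [t for t in seq_taxa if t not in clim_taxa]
    missing_seq = sorted(clim_taxa - set(seq_taxa))
    if (missing_clim or missing_seq) and not cfg.drop_unmatched:
        raise ValueError(
            f"taxa mismatch between FASTA and climate table: "
            f"no-climate={missing_clim}, no-sequence={missing_seq} "
            f"(use drop_unmatched to intersect)"
        )
    if missing_clim or missing_seq:
        logger.warning("dropping unmatched taxa: %s", sorted(set(missing_clim) | set(missing_seq)))
    kept = [t for t in seq_taxa if t in clim_taxa]
    if len(kept) < 3:
        raise ValueError(f"only {len(kept)} taxa shared between inputs; need >= 3")
    aln = Alignment([r for r in alignment.records if r.label.strip() in clim_taxa])
    return aln, climate.subset_taxa(kept)


def run_pipeline(cfg: PipelineConfig) -> tuple[pd.DataFrame, Path]:
    """Run the full pipeline; returns (results table, artifact directory).

    The artifact directory holds ``results.csv``, per-window filtered
    alignments and consensus trees under ``windows/``, the climate trees under
    ``climate_trees/`` and the resolved configuration (``config.used.yaml``).
    """
    out = Path(cfg.output_dir)
    try:
        alignment = _load_alignment(cfg)
    except Exception as exc:
        raise PipelineStageError("alignment", exc)
    try:
        climate = read_climate_csv(cfg.climate_path, cfg.id_column)
        alignment, climate = _reconcile(alignment, climate, cfg)
    except PipelineStageError:
        raise
    except Exception as exc:
        raise PipelineStageError("climate_input", exc)

    try:
        clim_trees = build_climate_trees(
            climate, cfg.variance_threshold, cfg.standardize, cfg.build_combined_tree
        )
        filtered, _ = variance_filter(climate, cfg.variance_threshold)
        clim_dms = {v: climatic_dissimilarity(filtered, [v]) for v in filtered.variables}
        if COMBINED_TREE_NAME in clim_trees:
            clim_dms[COMBINED_TREE_NAME] = climatic_dissimilarity(
                filtered, filtered.variables, standardize=cfg.standardize
            )
    except Exception as exc:
        raise PipelineStageError("climate_trees", exc)

    windows = slide_windows(alignment, WindowSpec(cfg.window_size, cfg.step_size),
                            cfg.keep_partial)
    tasks = [(w, cfg, clim_trees, clim_dms) for w in windows]
    outputs = parallel_map(_process_window, tasks, cfg.workers)

    out.mkdir(parents=True, exist_ok=True)
    (out / "windows").mkdir(exist_ok=True)
    (out / "climate_trees").mkdir(exist_ok=True)
    rows: list[dict] = []
    for res in outputs:
        if res.get("skip"):
            logger.info("window [%d, %d) skipped: %s", *res["coords"], res["skip"])
            continue
        rows.extend(res["rows"])
        s, e = res["coords"]
        (out / "windows" / f"window_{s:06d}_{e:06d}.fasta").write_text(res["fasta"])
        (out / "windows" / f"window_{s:06d}_{e:06d}.nwk").write_text(res["newick"])
    for var, tree in sorted(clim_trees.items()):
        (out / "climate_trees" / f"{var}.nwk").write_text(newick_write(tree) + "\n")

    table = write_results(rows, out / "results.csv")
    resolved = {"phylogeoscan_version": __version__, **cfg.to_dict()}
    (out / "config.used.yaml").write_text(yaml.safe_dump(resolved, sort_keys=True))
    return table, out
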