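"""Synthetic sequence + climate fixtures with a planted genotype-environment
association.

The generator emulates the signal the pipeline exists to detect: a genomic
"hotspot" interval where taxa split into groups (group-specific substitutions
relative to a shared ancestral sequence) while one climate variable separates
the same groups. Everything outside the hotspot is i.i.d. background noise, and
the remaining climate variables are pure noise. Group structure is
star-phylogeny-per-group — deliberately simpler than coalescent simulation, but
it produces exactly the block-structured trees the comparison stage must
recognize, with a known truth record for assertions.

Defaults encode the planted-truth evaluation scenario: 12 taxa in 2 groups,
500 bp, hotspot [200, 300) (one default-sized window), 30% between-group
divergence inside the hotspot, 1% background noise, a 3-SD climate effect and
3 noise variables.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, field
from pathlib import Path

import numpy as np
import pandas as pd
from skbio import DistanceMatrix, TreeNode

from .climate import ClimaticTable
from .seqio import Alignment, SequenceRecord, write_fasta

__all__ = ["FixtureSpec", "Fixture", "generate_fixture", "make_additive_tree_matrix",
           "MATCHED_VARIABLE"]

BASES = np.array(list("ACGT"))
MATCHED_VARIABLE = "env_signal"


@dataclass(frozen=True)
class FixtureSpec:
    n_taxa: int = 12
    seq_length: int = 500
    n_groups: int = 2
    hotspot_interval: tuple[int, int] = (200, 300)
    hotspot_divergence: float = 0.3
    background_noise: float = 0.01
    climate_effect: float = 3.0
    n_noise_variables: int = 3
    rng_seed: int = 0

    def __post_init__(self) -> None:
        s, e = self.hotspot_interval
        if not (0 <= s < e <= self.seq_length):
            raise ValueError("hotspot must lie inside [0, seq_length)")
        for p in (self.hotspot_divergence, self.background_noise):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.n_groups < 2:
            raise ValueError("need at least 2 groups")
        if self.n_taxa < self.n_groups:
            raise ValueError("need at least one taxon per group")


@dataclass
class Fixture:
    alignment: Alignment
    climate: ClimaticTable
    truth: dict

    def write(self, out_dir) -> tuple[Path, Path, Path]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        fasta, csv, truth = out / "sequences.fasta", out / "climate.csv", out / "truth.json"
        write_fasta(self.alignment, fasta)
        self.climate.data.rename_axis("id").to_csv(csv)
        truth.write_text(json.dumps(self.truth, indent=2) + "\n")
        return fasta, csv, truth


def _mutate(rng: np.random.Generator, seq: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Substitute masked sites with a uniformly chosen *different* base."""
    out = seq.copy()
    idx = np.flatnonzero(mask)
    for i in idx:
        choices = BASES[BASES != out[i]]
        out[i] = rng.choice(choices)
    return out


def generate_fixture(spec: FixtureSpec = FixtureSpec()) -> Fixture:
    """Generate the planted-association fixture; deterministic per seed."""
    rng = np.random.default_rng(spec.rng_seed)
    L = spec.seq_length
    s, e = spec.hotspot_interval
    groups = [i % spec.n_groups for i in range(spec.n_taxa)]
    labels = [f"taxon{i:02d}" for i in range(spec.n_taxa)]

    ancestral = rng.choice(BASES, size=L)
    hotspot = np.zeros(L, dtype=bool)
    hotspot[s:e] = True

    # each group gets its own substitution pattern inside the hotspot
    group_seqs = []
    for _ in range(spec.n_groups):
        mask = hotspot & (rng.random(L) < spec.hotspot_divergence)
        group_seqs.append(_mutate(rng, ancestral, mask))

    records = []
    for label, g in zip(labels, groups):
        noise = (~hotspot) & (rng.random(L) < spec.background_noise)
        records.append(SequenceRecord(label, "".join(_mutate(rng, group_seqs[g], noise))))
    alignment = Alignment(records)

    data = {MATCHED_VARIABLE: [g * spec.climate_effect + rng.standard_normal()
                               for g in groups]}
    for v in range(spec.n_noise_variables):
        data[f"noise{v}"] = rng.standard_normal(spec.n_taxa)
    climate = ClimaticTable(pd.DataFrame(data, index=pd.Index(labels, name="id")))

    truth = {
        "groups": dict(zip(labels, groups)),
        "hotspot": [s, e],
        "matched_variable": MATCHED_VARIABLE,
        "spec": {**asdict(spec), "hotspot_interval": [s, e]},
    }
    return Fixture(alignment, climate, truth)


# ---------------------------------------------------------------------------
# Random additive trees (oracle inputs for neighbor-joining)
# ---------------------------------------------------------------------------


def _random_topology(labels: list[str], rng: np.random.Generator) -> TreeNode:
    if len(labels) == 1:
        return TreeNode(name=labels[0])
    k = int(rng.integers(1, len(labels)))
    return TreeNode(children=[_random_topology(labels[:k], rng),
                              _random_topology(labels[k:], rng)])


def make_additive_tree_matrix(
    n_leaves: int, rng_seed: int = 0, min_length: float = 0.05, max_length: float = 1.0
) -> tuple[TreeNode, DistanceMatrix]:
    """Random binary tree with positive branch lengths and its (additive by
    construction) patristic distance matrix."""
    if n_leaves < 4:
        raise ValueError("need at least 4 leaves")
    rng = np.random.default_rng(rng_seed)
    labels = [f"L{i:02d}" for i in range(n_leaves)]
    perm = [labels[i] for i in rng.permutation(n_leaves)]
    tree = _random_topology(perm, rng)
    for node in tree.traverse(include_self=False):
        node.length = float(rng.uniform(min_length, max_length))
    dm = tree.tip_tip_distances()
    return tree, dm.filter(sorted(dm.ids))
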