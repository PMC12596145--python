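"""Per-window phylogeny construction.

The internal inference engine is p-distance + neighbor-joining: fast, exact on
additive matrices and dependency-free, which keeps the whole pipeline
deterministic and testable. An adapter seam (`tree_engine` as a callable or an
external FASTA->Newick executable) lets users substitute any other engine.

Trees are ``skbio.TreeNode`` objects; bootstrap support values are carried as
internal node names (the common Newick dialect) and branch lengths are written
with 6 significant digits.

Neighbor-joining details that matter for reproducibility:

* the Q-matrix minimum is tie-broken toward the smallest ``(i, j)`` index pair;
* a negative branch length is clamped to zero and its deficit moved to the
  sister edge, preserving the pair's summed length (standard practice);
* joining order is a function of the input label order only, so permuting the
  input relabels but never re-shapes the result.
"""

from __future__ import annotations

import io
import logging
import shutil
import subprocess
import tempfile
from pathlib import Path

import numpy as np
from skbio import DistanceMatrix, TreeNode

from .seqio import Alignment, SequenceRecord, write_fasta

__all__ = [
    "NewickParseError",
    "newick_read", "newick_write",
    "p_distance_matrix", "neighbor_joining",
    "bootstrap_resample", "bootstrap_trees",
    "majority_rule_consensus", "collapse_low_support",
    "tree_bipartitions", "external_engine",
]

logger = logging.getLogger(__name__)

GAP_CHARS = "-N"  # characters excluded pairwise in p-distances


# ---------------------------------------------------------------------------
# Newick I/O
# ---------------------------------------------------------------------------


class NewickParseError(ValueError):
    def __init__(self, message: str, offset: int):
        super().__init__(f"{message} (offset {offset})")
        self.offset = offset


def _structural_offset(text: str) -> int:
    """Character offset of the first structural problem in a Newick string."""
    depth = 0
    for i, ch in enumerate(text):
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
            if depth < 0:
                return i
        elif ch == ";" and depth > 0:
            return i
    return len(text)


def newick_read(text: str) -> TreeNode:
    """Parse a Newick string (branch lengths and internal support labels)."""
    try:
        return TreeNode.read(io.StringIO(text), convert_underscores=False)
    except Exception as exc:
        raise NewickParseError(f"invalid Newick: {exc}", _structural_offset(text)) from None


def _fmt_len(x) -> str:
    return "" if x is None else f":{float(x):.6g}"


def _newick_node(node: TreeNode) -> str:
    if node.is_tip():
        return f"{node.name or ''}{_fmt_len(node.length)}"
    inner = ",".join(_newick_node(c) for c in node.children)
    label = "" if node.name is None else str(node.name)
    return f"({inner}){label}{_fmt_len(node.length)}"


def newick_write(tree: TreeNode) -> str:
    """Serialize with lengths at 6 significant digits, support as internal labels."""
    return _newick_node(tree) + ";"


def node_support(node: TreeNode) -> float | None:
    """Bootstrap support parsed from an internal node's label, if numeric."""
    if node.is_tip() or node.name is None:
        return None
    try:
        return float(node.name)
    except (TypeError, ValueError):
        return None


# ---------------------------------------------------------------------------
# Distances
# ---------------------------------------------------------------------------


def _encoded(alignment: Alignment) -> tuple[np.ndarray, np.ndarray]:
    arr = np.array([list(r.residues) for r in alignment.records])
    valid = ~np.isin(arr, list(GAP_CHARS))
    return arr, valid


def p_distance_matrix(alignment: Alignment, max_distance: float = 1.0) -> DistanceMatrix:
    """Uncorrected p-distances with pairwise deletion of gap/N sites.

    Entry (i, j) is mismatches / comparable columns, where a column is
    comparable when neither row holds a gap or ``N`` there. A pair with no
    comparable column gets ``max_distance`` (with a warning).
    """
    if len(alignment) < 3:
        raise ValueError("need at least 3 taxa for tree-building distances")
    arr, valid = _encoded(alignment)
    n = len(alignment)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            comparable = valid[i] & valid[j]
            m = int(comparable.sum())
            if m == 0:
                logger.warning(
                    "no comparable columns between %s and %s; distance set to %g",
                    alignment.labels[i], alignment.labels[j], max_distance,
                )
                d = max_distance
            else:
                d = float(((arr[i] != arr[j]) & comparable).sum()) / m
            out[i, j] = out[j, i] = d
    return DistanceMatrix(out, ids=alignment.labels)


# ---------------------------------------------------------------------------
# Neighbor-joining
# ---------------------------------------------------------------------------


def neighbor_joining(dm: DistanceMatrix) -> TreeNode:
    """Saitou-Nei neighbor-joining; exact on additive matrices.

    Returns an unrooted tree represented with a trifurcating root. Deterministic
    for a given input order (Q ties broken by the smallest index pair); negative
    branch lengths are clamped to zero with the deficit transferred to the
    sister edge.
    """
    if np.any(dm.data < 0):
        raise ValueError("distance matrix must be nonnegative")
    n = dm.shape[0]
    if n < 3:
        raise ValueError("neighbor-joining needs at least 3 taxa")
    D = dm.data.astype(float).copy()
    nodes: list[TreeNode] = [TreeNode(name=name) for name in dm.ids]

    while len(nodes) > 3:
        m = len(nodes)
        r = D.sum(axis=0)
        Q = (m - 2) * D - r[:, None] - r[None, :]
        iu = np.triu_indices(m, k=1)
        flat = Q[iu]
        best = int(np.argmin(flat))  # first minimum in row-major upper-triangle
        i, j = int(iu[0][best]), int(iu[1][best])

        li = 0.5 * D[i, j] + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = D[i, j] - li
        li, lj = _clamp_pair(li, lj)

        parent = TreeNode()
        ci, cj = nodes[i], nodes[j]
        ci.length, cj.length = li, lj
        parent.append(ci)
        parent.append(cj)

        du = 0.5 * (D[i, :] + D[j, :] - D[i, j])
        du = np.maximum(du, 0.0)
        keep = [k for k in range(m) if k not in (i, j)]
        newD = np.zeros((m - 1, m - 1))
        newD[:-1, :-1] = D[np.ix_(keep, keep)]
        newD[-1, :-1] = newD[:-1, -1] = du[keep]
        D = newD
        nodes = [nodes[k] for k in keep] + [parent]

    # closed-form three-point resolution
    a, b, c = nodes
    dab, dac, dbc = D[0, 1], D[0, 2], D[1, 2]
    la = max(0.0, 0.5 * (dab + dac - dbc))
    lb = max(0.0, 0.5 * (dab + dbc - dac))
    lc = max(0.0, 0.5 * (dac + dbc - dab))
    root = TreeNode()
    for node, ln in ((a, la), (b, lb), (c, lc)):
        node.length = ln
        root.append(node)
    return root


def _clamp_pair(li: float, lj: float) -> tuple[float, float]:
    if li < 0:
        lj += li
        li = 0.0
    if lj < 0:
        li = max(0.0, li + lj)
        lj = 0.0
    return li, lj


# ---------------------------------------------------------------------------
# Bootstrap
# ---------------------------------------------------------------------------


def bootstrap_resample(alignment: Alignment, rng_seed: int) -> Alignment:
    """Resample alignment columns i.i.d. with replacement (same column count)."""
    rng = np.random.default_rng(rng_seed)
    cols = rng.integers(0, alignment.length, size=alignment.length)
    arr = np.array([list(r.residues) for r in alignment.records])
    res = arr[:, cols]
    return Alignment(
        [SequenceRecord(lab, "".join(row)) for lab, row in zip(alignment.labels, res)]
    )


def _nj_engine(alignment: Alignment) -> TreeNode:
    return neighbor_joining(p_distance_matrix(alignment))


def external_engine(executable: str, args: list[str] | None = None):
    """Adapter seam: wrap any FASTA -> Newick program as a tree engine.

    Example: ``external_engine("fasttree", ["-nt", "-quiet"])``. Raises at
    construction time if the executable is not on PATH, naming it.
    """
    if shutil.which(executable) is None:
        raise FileNotFoundError(
            f"tree engine executable {executable!r} not found on PATH"
        )

    def engine(alignment: Alignment) -> TreeNode:
        with tempfile.TemporaryDirectory() as tmp:
            fasta = Path(tmp) / "window.fasta"
            write_fasta(alignment, fasta)
            with open(fasta) as fh:
                proc = subprocess.run(
                    [executable, *(args or [])], stdin=fh,
                    capture_output=True, text=True, check=True,
                )
        return newick_read(proc.stdout.strip())

    return engine


def bootstrap_trees(
    alignment: Alignment,
    n_replicates: int = 100,
    rng_seed: int = 0,
    engine=None,
) -> list[TreeNode]:
    """One tree per bootstrap replicate; replicate seeds derive from rng_seed."""
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    engine = engine or _nj_engine
    seeds = np.random.SeedSequence(rng_seed).generate_state(n_replicates) % (2**31)
    return [engine(bootstrap_resample(alignment, int(s))) for s in seeds]


# ---------------------------------------------------------------------------
# Bipartitions and majority-rule consensus
# ---------------------------------------------------------------------------


def leaf_set(tree: TreeNode) -> frozenset[str]:
    return frozenset(t.name for t in tree.tips())


def tree_bipartitions(tree: TreeNode) -> set[frozenset[str]]:
    """Nontrivial bipartitions, each canonicalized as the side *not* containing
    the lexicographically smallest leaf."""
    leaves = leaf_set(tree)
    ref = min(leaves)
    n = len(leaves)
    out: set[frozenset[str]] = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if ref in side:
            side = leaves - side
        if 2 <= len(side) <= n - 2:
            out.add(side)
    return out


def _clades_with_lengths(tree: TreeNode, leaves: frozenset[str], ref: str):
    """(canonical bipartition, edge length) per internal edge, plus pendant lengths."""
    n = len(leaves)
    clades: dict[frozenset[str], float | None] = {}
    pendant: dict[str, float | None] = {}
    for node in tree.postorder(include_self=False):
        if node.is_tip():
            pendant[node.name] = node.length
            continue
        side = frozenset(t.name for t in node.tips())
        if ref in side:
            side = leaves - side
        if 2 <= len(side) <= n - 2:
            # a degree-2 root shows the same bipartition from both children;
            # keep the first length encountered
            clades.setdefault(side, node.length)
    return clades, pendant


def majority_rule_consensus(trees: list[TreeNode], threshold: float = 0.5) -> TreeNode:
    """Majority-rule consensus retaining bipartitions with frequency strictly
    greater than ``threshold``.

    The strict inequality means a split present in exactly half of the
    replicates is *not* retained. Retained internal edges carry their
    replicate frequency as support (the node label) and the mean branch length
    over the replicates containing them; pendant edges carry the mean over all
    replicates. ``threshold >= 0.5`` guarantees the retained set is compatible.
    """
    if not trees:
        raise ValueError("empty tree set")
    if threshold < 0.5:
        raise ValueError("consensus threshold must be >= 0.5")
    leaves = leaf_set(trees[0])
    for t in trees[1:]:
        if leaf_set(t) != leaves:
            raise ValueError("all trees must share one leaf set")
    ref = min(leaves)

    counts: dict[frozenset[str], int] = {}
    length_sums: dict[frozenset[str], float] = {}
    pendant_sums: dict[str, float] = {name: 0.0 for name in leaves}
    have_lengths = True
    for t in trees:
        clades, pendant = _clades_with_lengths(t, leaves, ref)
        for side, ln in clades.items():
            counts[side] = counts.get(side, 0) + 1
            if ln is None:
                have_lengths = False
            else:
                length_sums[side] = length_sums.get(side, 0.0) + float(ln)
        for name, ln in pendant.items():
            if ln is None:
                have_lengths = False
            else:
                pendant_sums[name] += float(ln)

    n_trees = len(trees)
    retained = {side: c / n_trees for side, c in counts.items() if c / n_trees > threshold}

    # Build the rooted representation: clades nest because they are compatible
    # and none contains the reference leaf.
    order = sorted(retained, key=lambda s: (-len(s), sorted(s)))
    nodes: dict[frozenset[str], TreeNode] = {}
    parent_of: dict[frozenset[str], frozenset[str] | None] = {}
    for side in order:
        node = TreeNode(name=f"{retained[side]:.6g}")
        if have_lengths and counts[side]:
            node.length = length_sums.get(side, 0.0) / counts[side]
        nodes[side] = node
        parent = None
        for other in order:
            if other is side or len(other) <= len(side):
                continue
            if side <= other and (parent is None or len(other) < len(parent)):
                parent = other
        parent_of[side] = parent

    root = TreeNode()
    for side in order:
        (nodes[parent_of[side]] if parent_of[side] is not None else root).append(nodes[side])
    for name in sorted(leaves):
        tip = TreeNode(name=name)
        if have_lengths:
            tip.length = pendant_sums[name] / n_trees
        host = None
        for side in order:
            if name in side and (host is None or len(side) < len(host)):
                host = side
        (nodes[host] if host is not None else root).append(tip)
    return root


def collapse_low_support(tree: TreeNode, min_support: float) -> TreeNode:
    """Collapse internal edges whose support is below ``min_support`` into
    polytomies (child edges inherit the collapsed edge's length)."""
    tree = tree.copy()
    for node in list(tree.non_tips(include_self=False)):
        sup = node_support(node)
        if sup is not None and sup < min_support:
            parent = node.parent
            for child in list(node.children):
                node.remove(child)
                if node.length is not None and child.length is not None:
                    child.length += node.length
                parent.append(child)
            parent.remove(node)
    return tree
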