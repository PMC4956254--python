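"""Neighbour-joining trees with Felsenstein bootstrap support.

NJ is the classic agglomerative distance method: it minimises the
Q-criterion at each step and exactly recovers any additive (tree-like)
distance matrix. Bootstrap support for an internal edge is the fraction of
trees, rebuilt from alignments whose columns were resampled with
replacement, that contain the same bipartition of specimens.

Trees are :class:`skbio.TreeNode` objects; the root is a trifurcation
standing in for an unrooted topology. Internal nodes carry a ``support``
attribute in [0, 1] once bootstrap has run.
"""

from __future__ import annotations

import itertools
import logging
import math
import re
from pathlib import Path

import numpy as np
from skbio import TreeNode

from .distance import (
    DistanceMatrix,
    SaturatedPairError,
    count_differences,
    k2p_distance,
)
from .io import Dataset

logger = logging.getLogger(__name__)


def neighbor_joining(dm: DistanceMatrix) -> TreeNode:
    """Standard NJ agglomeration (Saitou-Nei with Studier-Keppler Q).

    Negative branch lengths are clamped to zero with the deficit moved to
    the sister edge so pairwise path lengths are preserved where possible.
    Ties in the Q-criterion break deterministically on the lowest index
    pair, so the result is a pure function of the matrix.
    """
    n = len(dm.ids)
    if n < 3:
        raise ValueError("neighbour joining needs at least 3 records")
    if dm.has_missing:
        raise ValueError(
            "distance matrix has undefined entries; remove or impute those "
            "records before tree building"
        )
    D = dm.values.astype(float).copy()
    nodes: list[TreeNode] = [TreeNode(name=i) for i in dm.ids]
    while len(nodes) > 3:
        m = len(nodes)
        r = D.sum(axis=1)
        Q = (m - 2) * D - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        i, j = np.unravel_index(np.argmin(Q), Q.shape)  # C-order => lowest pair
        i, j = (int(min(i, j)), int(max(i, j)))
        li = 0.5 * D[i, j] + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = D[i, j] - li
        li, lj = _clamp_pair(li, lj)
        parent = TreeNode(children=[nodes[i], nodes[j]])
        nodes[i].length = li
        nodes[j].length = lj
        d_new = 0.5 * (D[i, :] + D[j, :] - D[i, j])
        keep = [k for k in range(m) if k not in (i, j)]
        D_next = np.empty((m - 1, m - 1))
        D_next[: m - 2, : m - 2] = D[np.ix_(keep, keep)]
        D_next[: m - 2, m - 2] = D_next[m - 2, : m - 2] = d_new[keep]
        D_next[m - 2, m - 2] = 0.0
        D = D_next
        nodes = [nodes[k] for k in keep] + [parent]
    # resolve the final three nodes around an unrooted trifurcation
    (a, b, c) = nodes
    la = 0.5 * (D[0, 1] + D[0, 2] - D[1, 2])
    lb = 0.5 * (D[0, 1] + D[1, 2] - D[0, 2])
    lc = 0.5 * (D[0, 2] + D[1, 2] - D[0, 1])
    a.length, b.length, c.length = (max(0.0, x) for x in (la, lb, lc))
    return TreeNode(children=[a, b, c])


def _clamp_pair(li: float, lj: float) -> tuple[float, float]:
    if li < 0.0:
        lj += li
        li = 0.0
    if lj < 0.0:
        li += lj
        lj = 0.0
    return li, max(0.0, lj)


def path_length(tree: TreeNode, tip_a: str, tip_b: str) -> float:
    """Sum of branch lengths on the path between two tips."""
    return tree.find(tip_a).distance(tree.find(tip_b))


def bipartitions(tree: TreeNode) -> set[frozenset]:
    """Non-trivial splits of an unrooted tree, as canonical tip-name sets.

    Each internal edge splits the tips in two; the side not containing the
    lexicographically smallest tip is the canonical representative. Trivial
    splits (single tip on one side) are excluded.
    """
    tips = frozenset(t.name for t in tree.tips())
    ref = min(tips)
    splits: set[frozenset] = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if len(side) < 2 or len(tips - side) < 2:
            continue
        splits.add(side if ref not in side else tips - side)
    return splits


def _k2p_values(enc: np.ndarray) -> np.ndarray:
    """Pairwise K2P matrix (NaN where undefined) from an encoded alignment."""
    n = enc.shape[0]
    vals = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        comp = count_differences(enc[i], enc[j])
        try:
            d = k2p_distance(comp) if comp is not None else math.nan
        except SaturatedPairError:
            d = math.nan
        vals[i, j] = vals[j, i] = d
    return vals


def bootstrap_support(
    dataset: Dataset, replicates: int = 1000, seed: int = 0
) -> TreeNode:
    """NJ tree of the dataset with bootstrap supports on internal nodes.

    Alignment columns are resampled with replacement ``replicates`` times;
    each replicate's K2P + NJ tree votes for the bipartitions it contains.
    Replicates yielding undefined distances are skipped (and counted; a
    warning is logged when more than 1% are lost). Deterministic given
    ``seed``.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    enc = dataset.encoded()
    base_vals = _k2p_values(enc)
    if np.isnan(base_vals[~np.eye(len(dataset), dtype=bool)]).any():
        raise ValueError("distance matrix has undefined entries")
    base_dm = DistanceMatrix(ids=dataset.ids, values=base_vals)
    tree = neighbor_joining(base_dm)
    counts: dict[frozenset, int] = {s: 0 for s in bipartitions(tree)}
    rng = np.random.default_rng(seed)
    L = dataset.alignment_length
    used = 0
    skipped = 0
    for _ in range(replicates):
        cols = rng.integers(0, L, size=L)
        vals = _k2p_values(enc[:, cols])
        if np.isnan(vals[~np.eye(len(dataset), dtype=bool)]).any():
            skipped += 1
            continue
        used += 1
        rep_tree = neighbor_joining(DistanceMatrix(ids=dataset.ids, values=vals))
        for split in bipartitions(rep_tree):
            if split in counts:
                counts[split] += 1
    if skipped > 0.01 * replicates:
        logger.warning("%d of %d bootstrap replicates skipped", skipped, replicates)
    tips = frozenset(t.name for t in tree.tips())
    ref = min(tips)
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if len(side) < 2 or len(tips - side) < 2:
            continue
        key = side if ref not in side else tips - side
        node.support = counts[key] / used if used else math.nan
    tree.bootstrap_replicates_used = used
    tree.bootstrap_replicates_skipped = skipped
    return tree


_SAFE_LABEL = re.compile(r"^[A-Za-z0-9_.+|/-]+$")


def _format_label(label: str) -> str:
    if _SAFE_LABEL.match(label):
        return label
    return "'" + label.replace("'", "''") + "'"


def _newick_node(node: TreeNode) -> str:
    if node.is_tip():
        s = _format_label(str(node.name))
    else:
        inner = ",".join(_newick_node(c) for c in node.children)
        support = getattr(node, "support", None)
        label = f"{support:.4g}" if support is not None else ""
        s = f"({inner}){label}"
    if node.length is not None:
        s += f":{node.length:.10g}"
    return s


def write_newick(tree: TreeNode, path: str | Path) -> None:
    """Serialize a tree as single-line Newick with branch lengths.

    Bootstrap supports become internal-node labels; tip labels containing
    Newick metacharacters (spaces, parentheses, colons, ...) are quoted,
    never altered.
    """
    with open(path, "w") as fh:
        fh.write(_newick_node(tree) + ";\n")


def read_newick(path: str | Path) -> TreeNode:
    """Parse a Newick file; numeric internal labels become ``support``."""
    tree = TreeNode.read(str(path), convert_underscores=False)
    for node in tree.non_tips(include_self=False):
        if node.name is not None:
            try:
                node.support = float(node.name)
            except ValueError:
                pass
    return tree
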