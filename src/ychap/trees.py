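"""Neighbor-joining trees and bootstrap support.

The NJ implementation follows the Saitou-Nei/Studier-Keppler
agglomeration on a rate-corrected Q criterion.  Ties on Q are broken by
lexicographic pair label order (internal clusters carry the smallest
leaf label they contain), so the result is deterministic.  Negative
branch length estimates are clamped to zero with the deficit moved to
the sister branch.  Trees are skbio ``TreeNode`` objects, unrooted in
meaning and stored with a trifurcating root.
"""

from __future__ import annotations

import logging
from collections import Counter

import numpy as np
from skbio import DistanceMatrix, TreeNode

from .seqdist import (
    Alignment,
    SaturationError,
    SubstitutionModelParams,
    distance_matrix,
    strip_gap_columns,
)

__all__ = [
    "nj_tree",
    "bipartitions",
    "tree_distance_matrix",
    "bootstrap_support",
]

logger = logging.getLogger(__name__)


def _clamped(b_i: float, b_j: float) -> tuple[float, float]:
    """Clamp a negative branch length to 0, transferring the deficit to
    the sister branch (which is itself floored at 0)."""
    if b_i < 0:
        logger.debug("clamping negative NJ branch length %.4g", b_i)
        b_j = max(b_j + b_i, 0.0)
        b_i = 0.0
    return b_i, b_j


def nj_tree(dm: DistanceMatrix) -> TreeNode:
    """Neighbor-joining tree from a symmetric distance matrix.

    Requires >= 3 taxa.  On an additive (tree-like) matrix the result
    has exactly the generating topology and branch lengths.
    """
    ids = list(dm.ids)
    if len(ids) < 3:
        raise ValueError("neighbor joining requires at least 3 taxa")

    # label -> (sort key, subtree); sort key = smallest leaf label inside
    nodes: dict[str, TreeNode] = {i: TreeNode(name=i) for i in ids}
    d: dict[str, dict[str, float]] = {
        a: {b: float(dm[a, b]) for b in ids if b != a} for a in ids
    }

    while len(nodes) > 3:
        labels = sorted(nodes)
        r = len(labels)
        R = {a: sum(d[a].values()) for a in labels}
        best_pair, best_q = None, np.inf
        for i, a in enumerate(labels):
            for b in labels[i + 1 :]:
                q = (r - 2) * d[a][b] - R[a] - R[b]
                if q < best_q - 1e-12 or (abs(q - best_q) <= 1e-12 and (a, b) < best_pair):
                    best_q, best_pair = q, (a, b)
        a, b = best_pair
        dab = d[a][b]
        b_a = 0.5 * dab + (R[a] - R[b]) / (2 * (r - 2))
        b_b = dab - b_a
        b_a, b_b = _clamped(b_a, b_b)
        b_b, b_a = _clamped(b_b, b_a)

        child_a, child_b = nodes.pop(a), nodes.pop(b)
        child_a.length, child_b.length = b_a, b_b
        parent = TreeNode(children=[child_a, child_b])
        new_label = min(a, b)

        d_new: dict[str, float] = {}
        for c in nodes:
            dc = 0.5 * (d[a][c] + d[b][c] - dab)
            d_new[c] = dc
        for c in (a, b):
            d.pop(c)
        for c in list(d):
            d[c].pop(a, None)
            d[c].pop(b, None)
            d[c][new_label] = d_new[c]
        d[new_label] = d_new
        nodes[new_label] = parent

    (a, b, c) = sorted(nodes)
    b_a = 0.5 * (d[a][b] + d[a][c] - d[b][c])
    b_b = 0.5 * (d[a][b] + d[b][c] - d[a][c])
    b_c = 0.5 * (d[a][c] + d[b][c] - d[a][b])
    children = []
    for label, length in ((a, b_a), (b, b_b), (c, b_c)):
        node = nodes[label]
        node.length = max(length, 0.0)
        children.append(node)
    return TreeNode(children=children)


def bipartitions(tree: TreeNode) -> set[frozenset]:
    """Non-trivial splits of the (unrooted) tree.

    Each split is represented canonically by the tip-label set on the
    side *not* containing the lexicographically smallest tip.
    """
    all_tips = frozenset(t.name for t in tree.tips())
    ref = min(all_tips)
    splits: set[frozenset] = set()
    for node in tree.traverse(include_self=False):
        if node.is_tip():
            continue
        side = frozenset(t.name for t in node.tips())
        if len(side) < 2 or len(side) > len(all_tips) - 2:
            continue
        if ref in side:
            side = all_tips - side
        splits.add(side)
    return splits


def tree_distance_matrix(tree: TreeNode) -> DistanceMatrix:
    """Leaf-to-leaf path-length (patristic) distances."""
    return tree.tip_tip_distances()


def bootstrap_support(
    aln: Alignment,
    model: str = "jc",
    params: SubstitutionModelParams | None = None,
    n_reps: int = 100,
    seed: int = 0,
) -> tuple[TreeNode, dict[frozenset, float]]:
    """Site-resampling bootstrap support for the full-data NJ tree.

    Columns of the gap-stripped alignment are resampled with
    replacement ``n_reps`` times; each replicate's NJ tree contributes
    its bipartitions.  Supports (percent of replicates containing each
    split) are mapped onto the full-data tree as internal node names.
    Replicates whose distances saturate are redrawn (and logged).  The
    procedure is canonicalized on sorted taxon ids, so the result does
    not depend on input sequence order.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    aln = strip_gap_columns(aln).subset(sorted(aln.ids))
    full = nj_tree(distance_matrix(aln, model=model, params=params))
    rng = np.random.default_rng(seed)
    counts: Counter = Counter()
    done = retries = 0
    while done < n_reps:
        idx = rng.integers(0, aln.length, size=aln.length)
        rep = aln.select_columns(idx)
        try:
            tree = nj_tree(distance_matrix(rep, model=model, params=params))
        except SaturationError:
            retries += 1
            logger.warning("bootstrap replicate saturated; resampling (%d)", retries)
            if retries > 100 + 10 * n_reps:
                raise
            continue
        counts.update(bipartitions(tree))
        done += 1

    supports = {split: 100.0 * counts.get(split, 0) / n_reps for split in bipartitions(full)}
    all_tips = frozenset(aln.ids)
    ref = min(all_tips)
    for node in full.traverse(include_self=False):
        if node.is_tip():
            continue
        side = frozenset(t.name for t in node.tips())
        if ref in side:
            side = all_tips - side
        if side in supports:
            node.name = f"{supports[side]:.0f}"
    return full, supports
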