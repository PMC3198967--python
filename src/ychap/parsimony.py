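"""Maximum parsimony: Fitch small parsimony and exact branch-and-bound search.

``fitch_length`` scores a fixed binary (unrooted) topology by the Fitch
set method, summing the minimum number of substitutions per alignment
column.  ``mp_search`` enumerates unrooted binary topologies by
stepwise taxon addition, pruning partial trees whose Fitch length
already exceeds the best complete tree found (a max-mini
branch-and-bound), and returns *all* most-parsimonious topologies.
Both treat gaps and N as missing data (compatible with any base).
"""

from __future__ import annotations

from collections import Counter
from typing import Iterable, Sequence

from skbio import TreeNode

from .seqdist import Alignment

__all__ = ["fitch_length", "mp_search"]

_BITS = {"A": 1, "C": 2, "G": 4, "T": 8}
_MISSING = 15


def _encode_patterns(aln: Alignment, order: Sequence[str]) -> list[tuple[tuple[int, ...], int]]:
    """Column patterns as bitmask tuples in taxon order, with multiplicities."""
    rows = [aln.sequence(sid) for sid in order]
    patterns = Counter(
        tuple(_BITS.get(row[c], _MISSING) for row in rows) for c in range(aln.length)
    )
    return list(patterns.items())


def _fitch_adj(adj: dict, root: int, pattern: Sequence[int]) -> int:
    """Fitch changes for one column on an adjacency map rooted at a leaf.

    Leaves are indices < len(pattern); internal nodes fold their
    children pairwise (exact for binary topologies).
    """
    changes = 0
    # iterative post-order
    stack = [(root, -1, False)]
    state: dict[int, int] = {}
    while stack:
        node, parent, expanded = stack.pop()
        if not expanded:
            stack.append((node, parent, True))
            for nb in adj[node]:
                if nb != parent:
                    stack.append((nb, node, False))
        else:
            if node < len(pattern):
                state[node] = pattern[node]
                continue
            s = 0
            for nb in adj[node]:
                if nb == parent:
                    continue
                cs = state[nb]
                if s == 0:
                    s = cs
                elif s & cs:
                    s &= cs
                else:
                    s |= cs
                    changes += 1
            state[node] = s
    # fold the root leaf itself
    root_child = next(nb for nb in adj[root])
    if not (pattern[root] & state[root_child]):
        changes += 1
    return changes


def _tree_length(edges: Iterable[tuple[int, int]], patterns) -> int:
    adj: dict[int, list[int]] = {}
    for u, v in edges:
        adj.setdefault(u, []).append(v)
        adj.setdefault(v, []).append(u)
    total = 0
    for pattern, weight in patterns:
        total += weight * _fitch_adj(adj, 0, pattern)
    return total


def fitch_length(tree: TreeNode, aln: Alignment) -> int:
    """Fitch parsimony length of an alignment on a fixed topology.

    The tree's tip names must match the alignment ids exactly.  The
    score is invariant under rerooting of a binary topology.
    """
    tips = [t.name for t in tree.tips()]
    if set(tips) != set(aln.ids) or len(tips) != len(aln.ids):
        raise ValueError("tree tips do not match alignment ids")
    order = tips
    index = {name: i for i, name in enumerate(order)}
    # build adjacency over int ids: tips 0..n-1, internals from n
    adj_edges: list[tuple[int, int]] = []
    next_internal = [len(order)]
    node_id: dict[int, int] = {}

    def visit(node) -> int:
        if node.is_tip():
            return index[node.name]
        my_id = next_internal[0]
        next_internal[0] += 1
        for child in node.children:
            adj_edges.append((my_id, visit(child)))
        return my_id

    visit(tree)
    patterns = _encode_patterns(aln, order)
    return _tree_length(adj_edges, patterns)


def _edges_to_treenode(edges: list[tuple[int, int]], names: Sequence[str]) -> TreeNode:
    adj: dict[int, list[int]] = {}
    for u, v in edges:
        adj.setdefault(u, []).append(v)
        adj.setdefault(v, []).append(u)
    n = len(names)
    root_internal = adj[0][0]  # internal neighbor of taxon 0

    def build(node: int, parent: int) -> TreeNode:
        if node < n:
            return TreeNode(name=names[node])
        return TreeNode(children=[build(nb, node) for nb in adj[node] if nb != parent])

    children = [TreeNode(name=names[0])] + [
        build(nb, root_internal) for nb in adj[root_internal] if nb != 0
    ]
    return TreeNode(children=children)


def mp_search(aln: Alignment, max_taxa: int = 12) -> tuple[list[TreeNode], int]:
    """All most-parsimonious unrooted topologies by branch and bound.

    Taxa are added in alignment order; a partial tree is abandoned as
    soon as its Fitch length exceeds the current best complete length
    (adding taxa can never decrease parsimony length).  Exact, but
    exponential: refuse above ``max_taxa`` taxa.
    """
    n = len(aln)
    if n > max_taxa:
        raise ValueError(f"{n} taxa exceeds max_taxa={max_taxa}")
    if n < 3:
        raise ValueError("parsimony search requires >= 3 taxa")
    patterns = _encode_patterns(aln, aln.ids)

    first_internal = n
    start_edges = [(first_internal, 0), (first_internal, 1), (first_internal, 2)]
    best = [float("inf")]
    found: list[list[tuple[int, int]]] = []

    def recurse(edges: list[tuple[int, int]], next_taxon: int, next_internal: int) -> None:
        length = _tree_length(edges, patterns)
        if length > best[0]:
            return
        if next_taxon == n:
            if length < best[0]:
                best[0] = length
                found.clear()
            found.append(list(edges))
            return
        for i in range(len(edges)):
            u, v = edges[i]
            w = next_internal
            new_edges = edges[:i] + edges[i + 1 :] + [(u, w), (w, v), (w, next_taxon)]
            recurse(new_edges, next_taxon + 1, next_internal + 1)

    recurse(start_edges, 3, first_internal + 1)
    trees = [_edges_to_treenode(e, aln.ids) for e in found]
    return trees, int(best[0])
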