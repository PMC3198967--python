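"""Independent brute-force reference implementations used only by tests.

These deliberately avoid the package's own algorithms: topologies are
enumerated explicitly, parsimony is scored by exhaustive ancestral-state
assignment, and least-squares branch lengths come from nonnegative least
squares on the path-incidence system.
"""

import itertools

import numpy as np
from scipy.optimize import nnls


def enumerate_topologies(n):
    """All unrooted binary topologies on leaves 0..n-1 as edge lists.

    Leaves are 0..n-1, internal nodes n, n+1, ...  (1, 3, 15, 105, 945,
    10395 trees for n = 3..8.)
    """
    trees = [[(n, 0), (n, 1), (n, 2)]]
    next_internal = n + 1
    for leaf in range(3, n):
        new_trees = []
        for edges in trees:
            for i in range(len(edges)):
                u, v = edges[i]
                w = next_internal
                new_trees.append(edges[:i] + edges[i + 1 :] + [(u, w), (w, v), (w, leaf)])
        trees = new_trees
        next_internal += 1
    return trees


def edge_bipartitions(edges, n):
    """Set of non-trivial splits; each split is the frozenset of leaves
    on the side not containing leaf 0."""
    adj = {}
    for u, v in edges:
        adj.setdefault(u, []).append(v)
        adj.setdefault(v, []).append(u)
    splits = set()
    for u, v in edges:
        # leaves on v's side when edge (u, v) removed
        stack, seen = [v], {u, v}
        side = set()
        while stack:
            node = stack.pop()
            if node < n:
                side.add(node)
            for nb in adj[node]:
                if nb not in seen:
                    seen.add(nb)
                    stack.append(nb)
        if 2 <= len(side) <= n - 2:
            if 0 in side:
                side = set(range(n)) - side
            splits.add(frozenset(side))
    return splits


def bruteforce_parsimony(edges, n, columns):
    """Minimum substitutions by exhaustive assignment of internal states.

    columns: list of tuples of state sets (frozensets over 'ACGT') per
    leaf; missing data is the full set.
    """
    internals = sorted({u for e in edges for u in e if u >= n})
    total = 0
    for col in columns:
        best = None
        for assignment in itertools.product("ACGT", repeat=len(internals)):
            state = dict(zip(internals, assignment))
            cost = 0
            for u, v in edges:
                su = {state[u]} if u >= n else col[u]
                sv = {state[v]} if v >= n else col[v]
                if not (set(su) & set(sv)):
                    cost += 1
            if best is None or cost < best:
                best = cost
        total += best
    return total


def least_squares_fit(edges, n, dm):
    """Nonnegative least-squares branch lengths for a topology against a
    distance matrix (numpy array over leaves 0..n-1); returns SSE."""
    adj = {}
    for idx, (u, v) in enumerate(edges):
        adj.setdefault(u, []).append((v, idx))
        adj.setdefault(v, []).append((u, idx))
    pairs = list(itertools.combinations(range(n), 2))
    A = np.zeros((len(pairs), len(edges)))
    for row, (a, b) in enumerate(pairs):
        # path from a to b by DFS
        stack = [(a, -1, [])]
        while stack:
            node, parent, path = stack.pop()
            if node == b:
                for e in path:
                    A[row, e] = 1.0
                break
            for nb, eidx in adj[node]:
                if nb != parent:
                    stack.append((nb, node, path + [eidx]))
    y = np.array([dm[a, b] for a, b in pairs])
    lengths, _ = nnls(A, y)
    resid = A @ lengths - y
    return float(resid @ resid)
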