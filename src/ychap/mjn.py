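"""Weighted median-joining networks for mixed SNP + microsatellite haplotypes.

A median-joining network (MJN) generalizes the minimum-spanning network
by inserting inferred intermediate node vectors ("median vectors",
unsampled haplotypes) where they shorten the network.  Characters are
weighted by mutability: under the default scheme a mononucleotide
repeat step costs 1, a trinucleotide step 2, a pentanucleotide step 3
and a SNP change 4, so distances are integral and the algorithm's
cost-reduction loop terminates.

Construction follows the classic recipe:

1. the epsilon-relaxed minimum-spanning network: a link (u, v) is
   feasible when d(u, v) <= m(u, v) + epsilon, where m is the minimax
   path distance (the largest link on the minimum-spanning-tree path);
   epsilon = 0 yields the union of all minimum spanning trees;
2. for every pair of links sharing a node, the median of the triple is
   computed (majority state for binary characters, integer median for
   ordered repeat counts); medians whose connection cost is within
   epsilon of the round's minimum are admitted, and each is kept only
   if it strictly lowers the minimum-spanning-tree cost of the node
   set; the loop repeats until no median helps;
3. unsampled nodes of degree < 3 are peeled off and the network is
   rebuilt.

Sampled haplotypes may sit at internal positions of the network, which
is the property that distinguishes this family of methods from trees.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Sequence

import networkx as nx

from .haplotypes import CharacterScheme, CompositeHaplotype, HaplotypeTable

__all__ = [
    "MJConfig",
    "HaploNetwork",
    "weighted_distance",
    "build_mjn",
    "haplogroups",
    "network_metrics",
    "snp_separation",
    "write_edgelist",
]

_EPS = 1e-9


@dataclass(frozen=True)
class MJConfig:
    """Median-joining run parameters; the defaults (epsilon = 0, full
    SNP+STR scheme, no extra parsimony cleanup) give the sparse network."""

    epsilon: float = 0.0
    scheme: CharacterScheme = field(default_factory=CharacterScheme.default)
    mp_cleanup: bool = False

    def __post_init__(self) -> None:
        if self.epsilon < 0:
            raise ValueError("epsilon must be nonnegative")


def _state_distance(a: tuple, b: tuple, scheme: CharacterScheme) -> float:
    total = 0.0
    for ch, sa, sb in zip(scheme.characters, a, b):
        if ch.kind == "binary":
            total += ch.weight * (sa != sb)
        else:
            total += ch.weight * abs(sa - sb)
    return total


def weighted_distance(
    a: CompositeHaplotype, b: CompositeHaplotype, scheme: CharacterScheme | None = None
) -> float:
    """Mutability-weighted distance between two composite haplotypes:
    sum over characters of w_c (state mismatch for SNPs, |repeat
    difference| for microsatellite motifs)."""
    scheme = scheme or CharacterScheme.default()
    return _state_distance(scheme.states(a), scheme.states(b), scheme)


class HaploNetwork:
    """Sampled + inferred median nodes with change-labelled edges."""

    def __init__(self, graph: nx.Graph, scheme: CharacterScheme):
        self.graph = graph
        self.scheme = scheme

    @property
    def sampled(self) -> list[str]:
        return sorted(n for n, d in self.graph.nodes(data=True) if d["sampled"])

    @property
    def medians(self) -> list[str]:
        return sorted(n for n, d in self.graph.nodes(data=True) if not d["sampled"])

    def states(self, node: str) -> tuple:
        return self.graph.nodes[node]["states"]

    def edge_length(self, u: str, v: str) -> float:
        return self.graph.edges[u, v]["length"]

    def total_cost(self) -> float:
        return sum(d["length"] for _, _, d in self.graph.edges(data=True))


def _edge_changes(a: tuple, b: tuple, scheme: CharacterScheme) -> list[tuple]:
    """Per-character changes along an edge: (name, state_a, state_b) for
    SNPs, (name, delta_repeats) for motifs."""
    changes = []
    for ch, sa, sb in zip(scheme.characters, a, b):
        if sa == sb:
            continue
        if ch.kind == "binary":
            changes.append((ch.name, sa, sb))
        else:
            changes.append((ch.name, int(sb - sa)))
    return changes


def _mst_cost(states: Sequence[tuple], scheme: CharacterScheme) -> float:
    g = nx.Graph()
    g.add_nodes_from(range(len(states)))
    for i, j in itertools.combinations(range(len(states)), 2):
        g.add_edge(i, j, weight=_state_distance(states[i], states[j], scheme))
    return sum(d["weight"] for _, _, d in nx.minimum_spanning_edges(g, data=True))


def _msn_edges(
    states: Sequence[tuple], scheme: CharacterScheme, epsilon: float
) -> list[tuple[int, int, float]]:
    """Feasible links of the epsilon-relaxed minimum-spanning network."""
    n = len(states)
    d = [[_state_distance(states[i], states[j], scheme) for j in range(n)] for i in range(n)]
    g = nx.Graph()
    g.add_nodes_from(range(n))
    for i, j in itertools.combinations(range(n), 2):
        g.add_edge(i, j, weight=d[i][j])
    mst = nx.minimum_spanning_tree(g)
    # minimax path distance via the MST: largest link on the unique path
    minimax = [[0.0] * n for _ in range(n)]
    for src in range(n):
        # DFS carrying the running max edge weight
        stack = [(src, -1, 0.0)]
        while stack:
            node, parent, running = stack.pop()
            minimax[src][node] = running
            for nb in mst.neighbors(node):
                if nb != parent:
                    stack.append((nb, node, max(running, mst.edges[node, nb]["weight"])))
    return [
        (i, j, d[i][j])
        for i, j in itertools.combinations(range(n), 2)
        if d[i][j] <= minimax[i][j] + epsilon + _EPS
    ]


def _median_vector(triple: Sequence[tuple], scheme: CharacterScheme) -> tuple:
    out = []
    for idx, ch in enumerate(scheme.characters):
        vals = [t[idx] for t in triple]
        if ch.kind == "binary":
            # majority state of the three
            out.append(max(set(vals), key=vals.count))
        else:
            out.append(sorted(vals)[1])
    return tuple(out)


def build_mjn(table: HaplotypeTable, config: MJConfig | None = None) -> HaploNetwork:
    """Median-joining network of the table's haplotypes.

    Haplotypes identical under the scheme are merged into one node.
    Median (unsampled) nodes are labelled ``mv1``, ``mv2``, ... in
    insertion order; ties everywhere are broken lexicographically, so
    the construction is deterministic.
    """
    config = config or MJConfig()
    scheme = config.scheme
    if len(table.haplotypes) < 2:
        raise ValueError("network requires at least 2 haplotypes")

    # collapse haplotypes identical under the scheme
    by_state: dict[tuple, list[str]] = {}
    for h in table.haplotypes:
        by_state.setdefault(scheme.states(h), []).append(h.id)
    states = sorted(by_state)
    labels = {s: "+".join(sorted(by_state[s])) for s in states}
    freqs = {s: int(table.group_counts("all")[by_state[s]].sum()) for s in states}

    # --- median insertion loop ---------------------------------------
    while True:
        edges = _msn_edges(states, scheme, config.epsilon)
        adj: dict[int, set[int]] = {i: set() for i in range(len(states))}
        for i, j, _ in edges:
            adj[i].add(j)
            adj[j].add(i)
        known = set(states)
        candidates: dict[tuple, float] = {}
        for u in range(len(states)):
            for v, w in itertools.combinations(sorted(adj[u]), 2):
                triple = (states[u], states[v], states[w])
                m = _median_vector(triple, scheme)
                if m in known:
                    continue
                cost = sum(_state_distance(m, t, scheme) for t in triple)
                if m not in candidates or cost < candidates[m]:
                    candidates[m] = cost
        if not candidates:
            break
        lam = min(candidates.values())
        admitted = sorted(
            (m for m, c in candidates.items() if c <= lam + config.epsilon + _EPS),
            key=lambda m: (candidates[m], m),
        )
        base_cost = _mst_cost(states, scheme)
        added = False
        for m in admitted:
            if _mst_cost(states + [m], scheme) < base_cost - _EPS:
                states = sorted(states + [m])
                added = True
                break  # re-enter the loop with the enlarged node set
        if not added:
            break

    # --- cleanup: peel unsampled nodes of degree < 3 ------------------
    while True:
        edges = _msn_edges(states, scheme, config.epsilon)
        degree = {i: 0 for i in range(len(states))}
        for i, j, _ in edges:
            degree[i] += 1
            degree[j] += 1
        drop = {
            i
            for i in range(len(states))
            if states[i] not in by_state and degree[i] < 3
        }
        if config.mp_cleanup:
            # also drop medians whose removal does not raise the MST cost
            for i in range(len(states)):
                if states[i] in by_state or i in drop:
                    continue
                rest = [s for k, s in enumerate(states) if k != i]
                if _mst_cost(rest, scheme) <= _mst_cost(states, scheme) + _EPS:
                    drop.add(i)
        if not drop:
            break
        states = [s for i, s in enumerate(states) if i not in drop]

    # --- assemble the labelled graph ----------------------------------
    graph = nx.Graph()
    median_counter = itertools.count(1)
    node_names: dict[tuple, str] = {}
    for s in states:
        if s in by_state:
            name = labels[s]
            graph.add_node(name, states=s, sampled=True, frequency=freqs[s])
        else:
            name = f"mv{next(median_counter)}"
            graph.add_node(name, states=s, sampled=False, frequency=0)
        node_names[s] = name
    for i, j, dist in _msn_edges(states, scheme, config.epsilon):
        a, b = states[i], states[j]
        graph.add_edge(
            node_names[a],
            node_names[b],
            length=dist,
            changes=_edge_changes(a, b, scheme),
        )
    if not nx.is_connected(graph):
        raise AssertionError("median-joining network must be connected")
    return HaploNetwork(graph, scheme)


def haplogroups(
    source: HaploNetwork | HaplotypeTable, by: str = "sry_snp"
) -> dict[str, list[str]]:
    """Partition of sampled haplotypes by their state at one character."""
    if isinstance(source, HaploNetwork):
        scheme = source.scheme
        if by not in scheme.names:
            raise KeyError(f"character {by!r} not in scheme")
        idx = scheme.names.index(by)
        groups: dict[str, list[str]] = {}
        for node in source.sampled:
            state = source.states(node)[idx]
            groups.setdefault(str(state), []).append(node)
    else:
        from .haplotypes import _CHAR_ATTR

        if by not in _CHAR_ATTR:
            raise KeyError(f"unknown character {by!r}")
        groups = {}
        for h in source.haplotypes:
            groups.setdefault(str(getattr(h, _CHAR_ATTR[by])), []).append(h.id)
    return {k: sorted(v) for k, v in sorted(groups.items())}


def snp_separation(net: HaploNetwork, by: str = "sry_snp") -> int:
    """Minimum number of SNP (binary-character) changes on any network
    path connecting the two haplogroups defined by ``by``."""
    groups = haplogroups(net, by=by)
    if len(groups) != 2:
        raise ValueError(f"character {by!r} does not split the sample in two")
    for u, v, data in net.graph.edges(data=True):
        data["snp_changes"] = sum(
            1
            for ch in data["changes"]
            if net.scheme.characters[net.scheme.names.index(ch[0])].kind == "binary"
        )
    (ga, gb) = groups.values()
    best = None
    for a in ga:
        lengths = nx.single_source_dijkstra_path_length(net.graph, a, weight="snp_changes")
        for b in gb:
            if best is None or lengths[b] < best:
                best = lengths[b]
    return int(best)


def network_metrics(net: HaploNetwork) -> dict:
    """Deterministic summary: node/edge/median counts, total weighted
    cost, and the total number of mutational steps per character."""
    per_char = {name: 0 for name in net.scheme.names}
    for _, _, data in net.graph.edges(data=True):
        for ch in data["changes"]:
            if len(ch) == 3:
                per_char[ch[0]] += 1
            else:
                per_char[ch[0]] += abs(ch[1])
    return {
        "n_nodes": net.graph.number_of_nodes(),
        "n_sampled": len(net.sampled),
        "n_medians": len(net.medians),
        "n_edges": net.graph.number_of_edges(),
        "total_cost": net.total_cost(),
        "steps_per_character": per_char,
        "connected": nx.is_connected(net.graph),
    }


def write_edgelist(net: HaploNetwork, path) -> None:
    """Edge-list TSV: from, to, weighted length, per-character changes."""
    with open(path, "w") as fh:
        fh.write("# from\tto\tlength\tchanges\n")
        for u, v, data in sorted(net.graph.edges(data=True)):
            changes = ";".join(
                f"{c[0]}:{c[1]}>{c[2]}" if len(c) == 3 else f"{c[0]}:{c[1]:+d}"
                for c in data["changes"]
            )
            fh.write(f"{u}\t{v}\t{data['length']:g}\t{changes}\n")
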