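"""Median-joining haplotype networks with inverse-origin site weighting.

The construction follows the Bandelt median-joining scheme: build the
epsilon-relaxed minimum spanning network (MSN) under weighted Hamming
distance, generate quasi-median (Steiner) candidate sequences from node
triplets, add candidates that reduce the total network cost (minimum
spanning tree weight over the augmented node set), and prune median
vectors that no longer help. Sites are then weighted inversely to the
number of distinct edges on which they mutate: a site mutating once keeps
the base weight (90), a site mutating on r edges gets 90/r, and the
network is rebuilt under the new weights.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Optional, Sequence

import networkx as nx
import numpy as np

from .seqio import HaplotypeTable

_TOL = 1e-9


@dataclass
class SiteWeights:
    """Per-site weights; sites absent from ``weights`` take ``base_weight``."""

    base_weight: float = 90.0
    weights: dict = field(default_factory=dict)

    def get(self, site: int) -> float:
        return self.weights.get(site, self.base_weight)

    def __post_init__(self):
        if self.base_weight <= 0 or any(w <= 0 for w in self.weights.values()):
            raise ValueError("weights must be positive")


@dataclass
class HaplotypeNetwork:
    graph: nx.Graph  # node attrs: sequence, is_median, count, counts_by_locality
    epsilon: float
    weights: SiteWeights

    @property
    def observed_nodes(self) -> list[str]:
        return [n for n, d in self.graph.nodes(data=True) if not d["is_median"]]

    @property
    def median_nodes(self) -> list[str]:
        return [n for n, d in self.graph.nodes(data=True) if d["is_median"]]

    def cost(self) -> float:
        """Total weight of a minimum spanning tree over the node set."""
        return _mst_cost(
            [self.graph.nodes[n]["sequence"] for n in self.graph.nodes], self.weights
        )

    def edge_list(self) -> list[tuple[str, str, int, tuple[int, ...]]]:
        out = []
        for u, v, d in self.graph.edges(data=True):
            out.append((u, v, len(d["sites"]), tuple(d["sites"])))
        return out

    def node_table(self, haplogroup_labels: Optional[dict] = None):
        """Per-node attribute table (id, sequence, is_median, count, one
        column per locality, optional haplogroup label) for figure overlays."""
        import pandas as pd

        locs: list[str] = []
        for _, d in self.graph.nodes(data=True):
            for loc in d["counts_by_locality"]:
                if loc not in locs:
                    locs.append(loc)
        rows = []
        for n, d in self.graph.nodes(data=True):
            row = {
                "node": n,
                "sequence": d["sequence"],
                "is_median": d["is_median"],
                "count": d["count"],
            }
            if haplogroup_labels is not None:
                row["haplogroup"] = haplogroup_labels.get(n, "")
            for loc in locs:
                row[loc] = d["counts_by_locality"].get(loc, 0)
            rows.append(row)
        return pd.DataFrame(rows)

    def to_graphml(self, path) -> None:
        g = nx.Graph()
        for n, d in self.graph.nodes(data=True):
            g.add_node(
                n,
                sequence=d["sequence"],
                is_median=bool(d["is_median"]),
                count=int(d["count"]),
            )
        for u, v, d in self.graph.edges(data=True):
            g.add_edge(
                u,
                v,
                n_mutations=len(d["sites"]),
                sites=",".join(map(str, d["sites"])),
                weight=float(d["weight"]),
            )
        nx.write_graphml(g, path)


def _diff_sites(x: str, y: str) -> list[int]:
    return [j for j, (a, b) in enumerate(zip(x, y)) if a != b]


def _wdist(x: str, y: str, w: SiteWeights) -> float:
    return sum(w.get(j) for j in _diff_sites(x, y))


def _dist_matrix(seqs: Sequence[str], w: SiteWeights) -> np.ndarray:
    k = len(seqs)
    m = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            m[i, j] = m[j, i] = _wdist(seqs[i], seqs[j], w)
    return m


def _mst_cost(seqs: Sequence[str], w: SiteWeights) -> float:
    if len(seqs) < 2:
        return 0.0
    m = _dist_matrix(seqs, w)
    g = nx.Graph()
    k = len(seqs)
    g.add_weighted_edges_from(
        (i, j, m[i, j]) for i in range(k) for j in range(i + 1, k)
    )
    return float(
        sum(d["weight"] for _, _, d in nx.minimum_spanning_edges(g, data=True))
    )


def _msn_edges(seqs: Sequence[str], w: SiteWeights, epsilon: float) -> list[tuple[int, int]]:
    """Epsilon-relaxed minimum spanning network.

    Pair (i, j) is linked iff d(i, j) <= delta(i, j) + epsilon, where delta
    is the minimax path value (the distance level at which i and j first
    join during Kruskal growth) — the classic MSN for epsilon = 0.
    """
    k = len(seqs)
    m = _dist_matrix(seqs, w)
    g = nx.Graph()
    g.add_weighted_edges_from(
        (i, j, m[i, j]) for i in range(k) for j in range(i + 1, k)
    )
    mst = nx.minimum_spanning_tree(g)
    edges = []
    for i in range(k):
        lengths = _minimax_from(mst, i, k)
        for j in range(i + 1, k):
            if m[i, j] <= lengths[j] + epsilon + _TOL:
                edges.append((i, j))
    return edges


def _minimax_from(mst: nx.Graph, src: int, k: int) -> np.ndarray:
    """Max edge weight on the unique MST path from src to every node."""
    out = np.zeros(k)
    stack = [(src, -1, 0.0)]
    while stack:
        node, parent, mx = stack.pop()
        out[node] = mx
        for nb in mst.neighbors(node):
            if nb != parent:
                stack.append((nb, node, max(mx, mst[node][nb]["weight"])))
    return out


def _quasi_medians(u: str, v: str, w: str, cap: int = 729) -> list[str]:
    """Sitewise majority consensus; sites where all three differ branch."""
    fixed: list[Sequence[str]] = []
    n_branch = 1
    for a, b, c in zip(u, v, w):
        if a == b or a == c:
            fixed.append(a)
        elif b == c:
            fixed.append(b)
        else:
            fixed.append((a, b, c))
            n_branch *= 3
            if n_branch > cap:
                return []
    combos = itertools.product(
        *[(s,) if isinstance(s, str) else s for s in fixed]
    )
    return ["".join(c) for c in combos]


def median_joining_network(
    ht: HaplotypeTable,
    weights: Optional[SiteWeights] = None,
    epsilon: float = 0.0,
) -> HaplotypeNetwork:
    """Build the median-joining network for a haplotype table.

    Iteratively adds the quasi-median candidate that most reduces the
    network cost (deterministic tie-break: lexicographically smallest
    sequence), prunes median vectors of degree <= 2, and returns the final
    epsilon-relaxed MSN with edges annotated by mutated sites.
    """
    if ht.n_haplotypes < 2:
        raise ValueError("need >= 2 haplotypes")
    seqs = list(ht.sequences)
    if len(set(seqs)) != len(seqs):
        raise ValueError("duplicate sequences; collapse haplotypes first")
    w = weights or SiteWeights()
    nodes = list(seqs)
    observed = set(seqs)

    cost = _mst_cost(nodes, w)
    while True:
        links = _msn_edges(nodes, w, epsilon)
        adj: dict[int, set[int]] = {i: set() for i in range(len(nodes))}
        for i, j in links:
            adj[i].add(j)
            adj[j].add(i)
        if len(nodes) <= 12:
            triples = itertools.combinations(range(len(nodes)), 3)
        else:
            triples = _linked_triples(adj)
        candidates: set[str] = set()
        node_set = set(nodes)
        for a, b, c in triples:
            for m in _quasi_medians(nodes[a], nodes[b], nodes[c]):
                if m not in node_set:
                    candidates.add(m)
        # lexicographic iteration + strict improvement = deterministic ties
        best_seq, best_cost = None, cost
        for m in sorted(candidates):
            c_new = _mst_cost(nodes + [m], w)
            if c_new < best_cost - _TOL:
                best_seq, best_cost = m, c_new
        if best_seq is None:
            break
        nodes.append(best_seq)
        cost = best_cost

    # prune: median vectors of degree <= 2 never reduce MST cost
    while True:
        links = _msn_edges(nodes, w, epsilon)
        deg = {i: 0 for i in range(len(nodes))}
        for i, j in links:
            deg[i] += 1
            deg[j] += 1
        drop = [
            i
            for i in range(len(nodes))
            if nodes[i] not in observed and deg[i] <= 2
        ]
        if not drop:
            break
        nodes = [s for k, s in enumerate(nodes) if k not in set(drop)]

    return _assemble(nodes, ht, w, epsilon)


def _linked_triples(adj: dict[int, set[int]]):
    seen = set()
    for u, nbrs in adj.items():
        for v, x in itertools.combinations(sorted(nbrs), 2):
            key = tuple(sorted((u, v, x)))
            if key not in seen:
                seen.add(key)
                yield key


def _assemble(
    nodes: list[str], ht: HaplotypeTable, w: SiteWeights, epsilon: float
) -> HaplotypeNetwork:
    by_seq = {h["sequence"]: h for h in ht.haplotypes}
    g = nx.Graph()
    ids = []
    mv = 0
    for s in nodes:
        if s in by_seq:
            h = by_seq[s]
            g.add_node(
                h["haplotype_id"],
                sequence=s,
                is_median=False,
                count=h["total_count"],
                counts_by_locality=dict(h["counts_by_locality"]),
            )
            ids.append(h["haplotype_id"])
        else:
            mv += 1
            g.add_node(
                f"mv{mv}",
                sequence=s,
                is_median=True,
                count=0,
                counts_by_locality={},
            )
            ids.append(f"mv{mv}")
    for i, j in _msn_edges(nodes, w, epsilon):
        sites = _diff_sites(nodes[i], nodes[j])
        g.add_edge(
            ids[i],
            ids[j],
            sites=tuple(sites),
            weight=sum(w.get(s) for s in sites),
        )
    return HaplotypeNetwork(g, epsilon, w)


def reweight_sites(
    net: HaplotypeNetwork, base_weight: float = 90.0
) -> SiteWeights:
    """Inverse-origin weights: base for single-origin sites, base/r for
    sites mutating on r >= 2 distinct network edges."""
    origins: dict[int, int] = {}
    for _, _, d in net.graph.edges(data=True):
        for s in d["sites"]:
            origins[s] = origins.get(s, 0) + 1
    weights = {
        s: (base_weight if r <= 1 else base_weight / r) for s, r in origins.items()
    }
    return SiteWeights(base_weight=base_weight, weights=weights)


def build_network_with_reweighting(
    ht: HaplotypeTable,
    epsilon: float = 0.0,
    base_weight: float = 90.0,
    passes: int = 2,
) -> tuple[HaplotypeNetwork, HaplotypeNetwork, SiteWeights]:
    """Two-pass construction: uniform weights, count mutation origins on the
    resulting network, rebuild under the inverse-origin weights.

    Returns (final network, first-pass network, final site weights).
    """
    if passes < 1:
        raise ValueError("passes must be >= 1")
    w = SiteWeights(base_weight=base_weight)
    net = median_joining_network(ht, w, epsilon)
    first = net
    for _ in range(passes - 1):
        w = reweight_sites(net, base_weight)
        net = median_joining_network(ht, w, epsilon)
    return net, first, w
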