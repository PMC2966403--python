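"""Median-joining haplotype networks.

Builds the classic haplotype graph combining a minimum-spanning network
(every edge that participates in some minimum spanning tree under Hamming
distance, relaxed by an integer tolerance ε) with inferred intermediate
"median" haplotypes: for triples of mutually close sequences the per-site
majority consensus (quasi-median) is added when novel, and the network is
rebuilt until no new medians arise. Median vectors that end up with degree
<= 2 are pruned (they no longer shorten any connection) and the network is
recomputed, so surviving medians are genuine branch points.

All tie-breaking is by node index (observed haplotypes in input order,
medians in creation order), making the output deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations, product

import networkx as nx
import numpy as np

from .seqio import AlignmentError, HaplotypeTable


def hamming(a: str, b: str) -> int:
    return sum(c1 != c2 for c1, c2 in zip(a, b))


def _distance_matrix(seqs: list[str]) -> np.ndarray:
    arr = np.array([list(s) for s in seqs], dtype="U1")
    n = len(seqs)
    d = np.zeros((n, n), dtype=int)
    for i in range(n):
        d[i, i + 1 :] = (arr[i] != arr[i + 1 :]).sum(axis=1)
        d[i + 1 :, i] = d[i, i + 1 :]
    return d


def minimum_spanning_network(seqs: list[str], epsilon: int = 0) -> nx.Graph:
    """ε-relaxed minimum-spanning network over sequences.

    Processing distinct Hamming weights in ascending order, an edge of
    weight w joins nodes u, v iff u and v are not already connected using
    edges of weight < w - ε (so ε=0 gives the union of all MSTs, and
    larger ε admits slightly longer alternative links).
    """
    n = len(seqs)
    g = nx.Graph()
    g.add_nodes_from(range(n))
    if n == 1:
        return g
    d = _distance_matrix(seqs)
    weights = sorted(set(d[np.triu_indices(n, 1)].tolist()))
    for w in weights:
        if w == 0:
            continue
        # connectivity from strictly lighter admitted edges only
        lighter = nx.Graph()
        lighter.add_nodes_from(range(n))
        lighter.add_edges_from(
            (u, v) for u, v, data in g.edges(data=True) if data["weight"] < w - epsilon
        )
        comp = {node: i for i, c in enumerate(nx.connected_components(lighter)) for node in c}
        for i, j in combinations(range(n), 2):
            if d[i, j] == w and comp[i] != comp[j]:
                g.add_edge(i, j, weight=int(w))
    return g


def _quasi_medians(u: str, v: str, w: str, max_ambiguous: int = 2) -> list[str]:
    """Per-site majority consensus of a triple; sites where all three
    states differ branch into one sequence per state (capped at
    ``max_ambiguous`` such sites to bound the combinatorics)."""
    fixed: list[str] = []
    options: list[tuple[str, ...]] = []
    n_amb = 0
    for a, b, c in zip(u, v, w):
        if a == b or a == c:
            options.append((a,))
        elif b == c:
            options.append((b,))
        else:
            n_amb += 1
            if n_amb > max_ambiguous:
                return []
            options.append(tuple(sorted({a, b, c})))
    return ["".join(choice) for choice in product(*options)]


@dataclass(frozen=True)
class HaploNetwork:
    """Observed haplotypes plus inferred medians with mutation-count edges."""

    graph: nx.Graph  # nodes carry: sequence, count, is_median, members

    @property
    def observed_nodes(self) -> list:
        return [n for n, d in self.graph.nodes(data=True) if not d["is_median"]]

    @property
    def median_nodes(self) -> list:
        return [n for n, d in self.graph.nodes(data=True) if d["is_median"]]

    def total_edge_weight(self) -> int:
        return sum(d["weight"] for _, _, d in self.graph.edges(data=True))


def median_joining(haps: HaplotypeTable, epsilon: int = 0, max_rounds: int = 20) -> HaploNetwork:
    """Median-joining network of a haplotype table.

    Raises :class:`AlignmentError` on unequal haplotype lengths. A single
    haplotype yields a single node and no edges.
    """
    seqs = list(haps.haplotypes)
    if len({len(s) for s in seqs}) > 1:
        raise AlignmentError("haplotypes must share one length")
    n_obs = len(seqs)

    # -- iterate: MSN -> add novel quasi-medians -> repeat ---------------
    for _ in range(max_rounds):
        msn = minimum_spanning_network(seqs, epsilon)
        known = set(seqs)
        new: list[str] = []
        for u in sorted(msn.nodes):
            nbrs = sorted(msn.neighbors(u))
            for v, w in combinations(nbrs, 2):
                for med in _quasi_medians(seqs[u], seqs[v], seqs[w]):
                    if med not in known:
                        known.add(med)
                        new.append(med)
        if not new:
            break
        seqs.extend(new)

    # -- prune obsolete medians (degree <= 2), recompute, repeat ---------
    while True:
        msn = minimum_spanning_network(seqs, epsilon)
        doomed = [
            i for i in range(n_obs, len(seqs)) if msn.degree(i) <= 2
        ]
        if not doomed:
            break
        keep = [i for i in range(len(seqs)) if i not in set(doomed)]
        seqs = [seqs[i] for i in keep]
        # observed haplotypes always precede medians, so n_obs is stable

    msn = minimum_spanning_network(seqs, epsilon)
    g = nx.Graph()
    for i, seq in enumerate(seqs):
        if i < n_obs:
            g.add_node(
                i,
                sequence=seq,
                count=haps.counts[i],
                members=list(haps.members[i]),
                is_median=False,
            )
        else:
            g.add_node(i, sequence=seq, count=0, members=[], is_median=True)
    for u, v, d in msn.edges(data=True):
        g.add_edge(u, v, weight=int(d["weight"]))
    return HaploNetwork(graph=g)


# ---------------------------------------------------------------------------
# Export


def to_graphml(net: HaploNetwork, path, assignment: dict[str, str] | None = None) -> None:
    """Write GraphML with count / population-composition / is_median node
    attributes and the mutation count on edges."""
    g = nx.Graph()
    for node, d in net.graph.nodes(data=True):
        comp = ""
        if assignment and d["members"]:
            from collections import Counter

            comp = ";".join(
                f"{p}:{c}"
                for p, c in sorted(Counter(assignment[m] for m in d["members"]).items())
            )
        g.add_node(
            node,
            sequence=d["sequence"],
            count=int(d["count"]),
            is_median=bool(d["is_median"]),
            populations=comp,
        )
    for u, v, d in net.graph.edges(data=True):
        g.add_edge(u, v, mutations=int(d["weight"]))
    nx.write_graphml(g, path)


def to_dot(net: HaploNetwork, path) -> None:
    """Minimal DOT export for quick rendering."""
    lines = ["graph haplonet {"]
    for node, d in net.graph.nodes(data=True):
        if d["is_median"]:
            lines.append(f'  {node} [label="mv", shape=point];')
        else:
            lines.append(f'  {node} [label="H{node + 1} (n={d["count"]})"];')
    for u, v, d in net.graph.edges(data=True):
        lines.append(f'  {u} -- {v} [label="{d["weight"]}"];')
    lines.append("}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
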