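"""Overlapping community detection by k-clique percolation (CPM).

A k-clique community is a connected component of the clique graph in which
two k-cliques are adjacent iff they share exactly k−1 nodes; the community
node set is the union of its cliques, so nodes may belong to several
communities and nodes in no k-clique stay unassigned. This is the
unweighted CPM of CFinder; k = 3 is the pipeline default, meaning every
community member has at least two intra-community connections.

Communities are named with the "clades-nodes-connections" convention: the
sorted distinct group labels of the member genes, the node count and the
induced edge count, hyphen-joined (e.g. a pure group-VI community of 16
genes with 45 connections is "VI-16-45").
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx
import pandas as pd


@dataclass(frozen=True)
class CliqueCommunity:
    community_id: int
    nodes: frozenset
    k: int
    cliques: tuple[tuple, ...] = ()
    name: str = ""

    def __len__(self) -> int:
        return len(self.nodes)


def enumerate_k_cliques(graph: nx.Graph, k: int) -> list[tuple]:
    """All complete subgraphs of exactly ``k`` nodes, as sorted tuples.

    Exact enumeration (every k-subset inducing a complete subgraph is
    reported once), not a maximal-clique heuristic.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    out: list[tuple] = []
    for clique in nx.enumerate_all_cliques(graph):
        if len(clique) > k:
            break
        if len(clique) == k:
            out.append(tuple(sorted(clique)))
    return sorted(out)


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, x: int) -> int:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[max(ra, rb)] = min(ra, rb)


def clique_percolation(graph: nx.Graph, k: int = 3) -> list[CliqueCommunity]:
    """Unweighted k-clique percolation communities.

    Two k-cliques are adjacent iff they share k−1 nodes; since two distinct
    k-cliques sharing a (k−1)-subset share exactly k−1 nodes, adjacency is
    found by hashing every (k−1)-subset of every clique and joining cliques
    that collide (union–find). Community ids are assigned by descending
    node count, then by smallest member id, so numbering is deterministic.
    """
    if k < 3:
        raise ValueError("k must be >= 3")
    cliques = enumerate_k_cliques(graph, k)
    if not cliques:
        return []
    uf = _UnionFind(len(cliques))
    subset_owner: dict[tuple, int] = {}
    for i, clique in enumerate(cliques):
        for sub in itertools.combinations(clique, k - 1):
            j = subset_owner.setdefault(sub, i)
            if j != i:
                uf.union(i, j)
    comps: dict[int, list[int]] = {}
    for i in range(len(cliques)):
        comps.setdefault(uf.find(i), []).append(i)
    raw = []
    for idxs in comps.values():
        nodes = frozenset(n for i in idxs for n in cliques[i])
        raw.append((nodes, tuple(cliques[i] for i in sorted(idxs))))
    raw.sort(key=lambda t: (-len(t[0]), sorted(t[0])[0]))
    return [CliqueCommunity(community_id=i, nodes=nodes, k=k, cliques=cls)
            for i, (nodes, cls) in enumerate(raw)]


def name_community(community: CliqueCommunity, network: nx.Graph,
                   groups=None) -> str:
    """Name per the clades-nodes-connections convention.

    Sorted distinct group labels of the member genes, then the node count,
    then the induced edge count, hyphen-joined.
    """
    get = (groups or {}).get if groups is not None else \
        (lambda n, d=None: network.nodes[n].get("group", d))
    labels = sorted({get(n, "unclassified") or "unclassified"
                     for n in community.nodes})
    sub = network.subgraph(community.nodes)
    parts = labels + [str(len(community.nodes)), str(sub.number_of_edges())]
    return "-".join(parts)


def composition_matrix(communities: Sequence[CliqueCommunity],
                       network: nx.Graph) -> pd.DataFrame:
    """Species × community counts of community members.

    Cell (s, c) is the number of genes of species s in community c, so each
    column sums to the community size; binary presence (the usual heatmap)
    is just ``matrix > 0``.
    """
    species = sorted({network.nodes[n].get("species", "") for n in network})
    cols = [c.community_id for c in communities]
    mat = pd.DataFrame(0, index=species, columns=cols, dtype=int)
    for c in communities:
        for n in c.nodes:
            mat.loc[network.nodes[n].get("species", ""), c.community_id] += 1
    return mat


def community_coverage(communities: Sequence[CliqueCommunity],
                       network: nx.Graph) -> float:
    """Fraction of network nodes belonging to at least one community."""
    if network.number_of_nodes() == 0:
        raise ValueError("empty network")
    covered: set = set()
    for c in communities:
        covered |= c.nodes
    return len(covered & set(network.nodes)) / network.number_of_nodes()


def community_summary(communities: Sequence[CliqueCommunity],
                      network: nx.Graph) -> pd.DataFrame:
    """Per-community table: name, sizes, species count and group set."""
    rows = []
    for c in communities:
        sub = network.subgraph(c.nodes)
        species = {network.nodes[n].get("species", "") for n in c.nodes}
        groups = sorted({network.nodes[n].get("group", "unclassified")
                         for n in c.nodes})
        rows.append({
            "community_id": c.community_id,
            "name": name_community(c, network),
            "n_nodes": len(c.nodes),
            "n_edges": sub.number_of_edges(),
            "n_species": len(species),
            "groups": ",".join(groups),
        })
    return pd.DataFrame(rows, columns=["community_id", "name", "n_nodes",
                                       "n_edges", "n_species", "groups"])


def membership_table(communities: Sequence[CliqueCommunity],
                     network: nx.Graph) -> pd.DataFrame:
    """Long-format gene → community membership (overlap preserved)."""
    rows = [{"gene_id": n, "community_id": c.community_id,
             "name": name_community(c, network)}
            for c in communities for n in sorted(c.nodes)]
    return pd.DataFrame(rows, columns=["gene_id", "community_id", "name"])
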