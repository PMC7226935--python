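"""Family-anchored synteny network extraction and summaries.

Nodes are family genes (plus truncated syntelogs); an undirected edge joins
two genes that appear together as an anchor pair in at least one collinear
block. Parallel anchors between the same gene pair collapse to a single
edge that carries the list of supporting block ids; the raw anchor-pair
count is kept as a graph attribute so both tallies can be reported.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd

from .collinearity import CollinearBlock


@dataclass(frozen=True)
class SyntelogRecord:
    """A truncated gene recovered through synteny with a full member."""

    gene_id: str
    status: str  # "member" | "truncated"
    group: str
    partner_count: int


def pct(numerator: int, denominator: int) -> float:
    """Percentage rounded to one decimal, as printed in reports."""
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    return round(100.0 * numerator / denominator, 1)


def build_family_synteny_network(blocks: Sequence[CollinearBlock],
                                 members: set[str],
                                 species: Mapping[str, str] | None = None,
                                 groups: Mapping[str, str] | None = None,
                                 statuses: Mapping[str, str] | None = None,
                                 ) -> nx.Graph:
    """Synteny network over ``members`` from block anchor pairs.

    An edge is created for every anchor pair with both genes in ``members``;
    nodes are exactly the genes incident to at least one such edge (family
    genes with no syntenic partner stay out and can be recovered as
    ``members - set(G.nodes)``). Node attributes ``species``, ``group`` and
    ``status`` are filled from the optional mappings.
    """
    G = nx.Graph(raw_anchor_pairs=0)
    for b in blocks:
        for qa, sa in b.anchors:
            u, v = qa.gene_id, sa.gene_id
            if u == v or u not in members or v not in members:
                continue
            G.graph["raw_anchor_pairs"] += 1
            if G.has_edge(u, v):
                if b.block_id not in G.edges[u, v]["blocks"]:
                    G.edges[u, v]["blocks"].append(b.block_id)
            else:
                G.add_edge(u, v, blocks=[b.block_id])
    for n in G.nodes:
        G.nodes[n]["species"] = (species or {}).get(n, "")
        G.nodes[n]["group"] = (groups or {}).get(n, "unclassified")
        G.nodes[n]["status"] = (statuses or {}).get(n, "member")
    return G


def detect_truncated_syntelogs(blocks: Sequence[CollinearBlock],
                               members: set[str], partial: set[str],
                               groups: Mapping[str, str] | None = None,
                               ) -> list[SyntelogRecord]:
    """Partial-domain genes anchored to a full member in any block.

    These are the truncated syntelogs: homologous and syntenic to annotated
    family members, but failing the two-domain identification rule. Partner
    count is the number of distinct member genes they pair with.
    """
    partners: dict[str, set[str]] = {}
    for b in blocks:
        for qa, sa in b.anchors:
            u, v = qa.gene_id, sa.gene_id
            if u in partial and v in members:
                partners.setdefault(u, set()).add(v)
            if v in partial and u in members:
                partners.setdefault(v, set()).add(u)
    return [SyntelogRecord(g, "truncated", (groups or {}).get(g, "unclassified"),
                           len(ps))
            for g, ps in sorted(partners.items())]


def syntenic_fraction(members: set[str], network: nx.Graph) -> float:
    """Fraction of family members with at least one syntenic partner."""
    if not members:
        raise ValueError("members must be nonempty")
    syntenic = sum(1 for m in members if network.has_node(m))
    return syntenic / len(members)


def intergroup_edge_summary(network: nx.Graph,
                            groups: Iterable[str] | None = None,
                            ) -> tuple[pd.DataFrame, int]:
    """Symmetric per-group-pair edge counts and the inter-group total.

    The total counts edges whose endpoints carry two different group labels,
    excluding any endpoint labelled "unclassified".
    """
    labels = sorted(set(groups) if groups is not None else
                    {network.nodes[n].get("group", "unclassified")
                     for n in network.nodes})
    if "unclassified" not in labels:
        labels.append("unclassified")
    mat = pd.DataFrame(0, index=labels, columns=labels, dtype=int)
    inter = 0
    for u, v in network.edges:
        gu = network.nodes[u].get("group", "unclassified")
        gv = network.nodes[v].get("group", "unclassified")
        a, b = sorted((gu, gv))
        mat.loc[a, b] += 1
        if a != b:
            mat.loc[b, a] += 1
            if "unclassified" not in (a, b):
                inter += 1
    return mat, inter


def export_network(network: nx.Graph, path, fmt: str = "edgelist") -> None:
    """Write the network as an edge-list TSV or GraphML.

    The edge list carries species and group of both endpoints plus the
    supporting block ids; GraphML preserves all node/edge attributes
    (block lists serialised as comma-joined strings) for viewers such as
    Gephi or Cytoscape.
    """
    if fmt == "edgelist":
        rows = []
        for u, v, data in network.edges(data=True):
            rows.append({
                "gene_a": u, "gene_b": v,
                "species_a": network.nodes[u].get("species", ""),
                "species_b": network.nodes[v].get("species", ""),
                "group_a": network.nodes[u].get("group", ""),
                "group_b": network.nodes[v].get("group", ""),
                "block_ids": ",".join(str(b) for b in data.get("blocks", [])),
            })
        cols = ["gene_a", "gene_b", "species_a", "species_b",
                "group_a", "group_b", "block_ids"]
        pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)
    elif fmt == "graphml":
        H = network.copy()
        for u, v in H.edges:
            H.edges[u, v]["blocks"] = ",".join(
                str(b) for b in H.edges[u, v].get("blocks", []))
        nx.write_graphml(H, path)
    else:
        raise ValueError(f"unknown export format {fmt!r}")


def import_network(path, fmt: str = "edgelist") -> nx.Graph:
    """Read a network written by :func:`export_network`."""
    if fmt == "edgelist":
        df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
        G = nx.Graph()
        for row in df.itertuples(index=False):
            blocks = [int(b) for b in row.block_ids.split(",") if b != ""]
            G.add_edge(row.gene_a, row.gene_b, blocks=blocks)
            G.nodes[row.gene_a]["species"] = row.species_a
            G.nodes[row.gene_a]["group"] = row.group_a
            G.nodes[row.gene_b]["species"] = row.species_b
            G.nodes[row.gene_b]["group"] = row.group_b
        return G
    if fmt == "graphml":
        G = nx.read_graphml(path)
        H = nx.Graph()
        for u, v, data in G.edges(data=True):
            blocks = [int(b) for b in str(data.get("blocks", "")).split(",")
                      if b != ""]
            H.add_edge(u, v, blocks=blocks)
        for n in G.nodes:
            H.add_node(n, **G.nodes[n])
        return H
    raise ValueError(f"unknown export format {fmt!r}")


def syntelog_report(network: nx.Graph) -> pd.DataFrame:
    """Per-node table: status, group, species and partner (degree) count."""
    rows = [{
        "gene_id": n,
        "species": network.nodes[n].get("species", ""),
        "group": network.nodes[n].get("group", ""),
        "status": network.nodes[n].get("status", ""),
        "partner_count": network.degree[n],
    } for n in sorted(network.nodes)]
    return pd.DataFrame(rows, columns=["gene_id", "species", "group",
                                       "status", "partner_count"])
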