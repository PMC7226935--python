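"""Reconciling synteny communities with gene trees to call events.

The expert by-eye reading of community composition and tree topology
is codified as three explicit rules:

* **Duplication** (species-overlap rule): an internal node of a rooted gene
  tree is a duplication iff its two child clades share at least one
  species. Calls whose node or child support falls below ``min_support``
  are flagged low-confidence but kept.
* **Transposition**: a community of at least ``min_community_size`` genes
  from >= 2 species, all of one lineage, whose genes are monophyletic in
  the gene tree, while a sibling community of the same group reaches
  outside that lineage — evidence that the lineage's genes moved into a
  new genomic context on the lineage stem.
* **Ancient tandem duplication**: a community mixing two or more group
  labels (the reciprocal-loss signature: tandem paralogues of different
  groups survive in complementary lineages, so their neighbourhoods stay
  syntenic across groups).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import dendropy
import networkx as nx
import pandas as pd

from .communities import CliqueCommunity
from .phylo import GeneTree, is_monophyletic, node_support

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class EventCall:
    """One inferred evolutionary event with its supporting evidence."""

    kind: str  # "duplication" | "transposition" | "ancient_tandem"
    scope: str  # lineage label, or clade descriptor for duplications
    communities: tuple[int, ...] = ()
    stats: dict = field(default_factory=dict)


@dataclass
class LineageMap:
    """Species → lineage labels, with an optional shallow parent hierarchy."""

    species_to_lineage: dict[str, str]
    parent: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for lin in self.parent:
            seen = set()
            cur: str | None = lin
            while cur is not None:
                if cur in seen:
                    raise ValueError(f"lineage hierarchy cycle at {cur!r}")
                seen.add(cur)
                cur = self.parent.get(cur)

    def lineage(self, species: str) -> str:
        try:
            return self.species_to_lineage[species]
        except KeyError:
            raise KeyError(f"species {species!r} has no lineage") from None

    def to_frame(self) -> pd.DataFrame:
        rows = [{"species": sp, "lineage": lin,
                 "parent": self.parent.get(lin, "")}
                for sp, lin in sorted(self.species_to_lineage.items())]
        return pd.DataFrame(rows, columns=["species", "lineage", "parent"])


def lineages_from_tree(tree: dendropy.Tree, max_clade_size: int = 3
                       ) -> LineageMap:
    """Cut a species tree into lineages of <= ``max_clade_size`` species.

    Recursing from the root, every clade at or below the size threshold
    becomes one lineage, named after its alphabetically first species.
    Larger enclosing clades become parent lineages in the hierarchy.
    """
    species_to_lineage: dict[str, str] = {}
    parent: dict[str, str] = {}

    def name_of(node: dendropy.Node) -> str:
        # size prefix keeps nested clades sharing a first species distinct
        leaves = sorted(lf.taxon.label for lf in node.leaf_iter())
        return f"lin{len(leaves)}_{leaves[0]}"

    def rec(node: dendropy.Node, parent_lin: str | None) -> None:
        leaves = sorted(lf.taxon.label for lf in node.leaf_iter())
        if len(leaves) <= max_clade_size:
            lin = name_of(node)
            for sp in leaves:
                species_to_lineage[sp] = lin
            if parent_lin is not None:
                parent[lin] = parent_lin
            return
        lin = name_of(node)
        if parent_lin is not None:
            parent[lin] = parent_lin
        for child in node.child_nodes():
            rec(child, lin)

    rec(tree.seed_node, None)
    return LineageMap(species_to_lineage, parent)


# ---------------------------------------------------------------------------
# duplications


def infer_duplications(gt: GeneTree, min_support: float = 80.0
                       ) -> list[EventCall]:
    """Species-overlap duplication calls on a rooted gene tree.

    Every internal node whose child clades share >= 1 species is a
    duplication. Each call records the shared species, the support values
    of the node and both children (``None`` where absent, e.g. NJ trees),
    and a low-confidence flag when any present value is below
    ``min_support``. Calls are never dropped for low support.
    """
    if not gt.rooted:
        raise ValueError("duplication inference requires a rooted tree "
                         "(apply root_with_outgroup or root_at_midpoint)")
    calls: list[EventCall] = []
    species_sets: dict[int, frozenset] = {}
    for node in gt.tree.postorder_node_iter():
        if node.is_leaf():
            lab = node.taxon.label
            species_sets[id(node)] = frozenset(
                (gt.species_map.get(lab, lab),))
            continue
        kids = node.child_nodes()
        species_sets[id(node)] = frozenset().union(
            *(species_sets[id(c)] for c in kids))
        overlap: set[str] = set()
        for i in range(len(kids)):
            for j in range(i + 1, len(kids)):
                overlap |= species_sets[id(kids[i])] & species_sets[id(kids[j])]
        if not overlap:
            continue
        supports = [node_support(node)] + [
            node_support(c) for c in kids if not c.is_leaf()]
        present = [s for s in supports if s is not None]
        low = any(s < min_support for s in present)
        clade = sorted(lf.taxon.label for lf in node.leaf_iter())
        calls.append(EventCall(
            kind="duplication",
            scope="+".join(sorted(species_sets[id(node)])),
            stats={
                "shared_species": tuple(sorted(overlap)),
                "n_shared_species": len(overlap),
                "supports": tuple(supports),
                "low_confidence": low,
                "clade_leaves": tuple(clade),
            }))
    return calls


# ---------------------------------------------------------------------------
# transpositions


def _community_groups(comm: CliqueCommunity, network: nx.Graph) -> set[str]:
    return {network.nodes[n].get("group", "unclassified")
            for n in comm.nodes} - {"unclassified", "", None}


def call_transpositions(communities: Sequence[CliqueCommunity],
                        network: nx.Graph, gt: GeneTree,
                        lineages: LineageMap,
                        min_community_size: int = 4) -> list[EventCall]:
    """Lineage-specific transposition calls from community composition.

    A transposition is called on the stem of lineage L when some community
    (i) has >= ``min_community_size`` genes from >= 2 species that all map
    to L, (ii) is monophyletic in the gene tree, and (iii) at least one
    other community sharing a group label contains genes from outside L —
    so the restriction to L reflects a relocation, not a family-wide
    pattern. Communities containing genes missing from the tree are
    skipped with a logged warning.
    """
    calls: list[EventCall] = []
    tree_leaves = set(gt.leaf_labels())
    for comm in communities:
        genes = sorted(comm.nodes)
        missing = [g for g in genes if g not in tree_leaves]
        if missing:
            logger.warning(
                "community %d skipped: %d gene(s) absent from the gene tree "
                "(e.g. %s)", comm.community_id, len(missing), missing[0])
            continue
        if len(genes) < min_community_size:
            continue
        species = {network.nodes[g].get("species", "") for g in genes}
        if len(species) < 2:
            continue
        lins = {lineages.lineage(sp) for sp in species}
        if len(lins) != 1:
            continue
        (lin,) = lins
        own_groups = _community_groups(comm, network)
        wider = False
        for other in communities:
            if other.community_id == comm.community_id:
                continue
            if own_groups and not (own_groups & _community_groups(other,
                                                                  network)):
                continue
            other_species = {network.nodes[g].get("species", "")
                             for g in other.nodes if g in network}
            if any(lineages.species_to_lineage.get(sp) != lin
                   for sp in other_species):
                wider = True
                break
        if not wider:
            continue
        if not is_monophyletic(gt, genes):
            continue
        calls.append(EventCall(
            kind="transposition", scope=lin,
            communities=(comm.community_id,),
            stats={
                "n_genes": len(genes),
                "n_species": len(species),
                "species": tuple(sorted(species)),
                "groups": tuple(sorted(own_groups)),
                "monophyletic": True,
            }))
    return calls


# ---------------------------------------------------------------------------
# ancient tandem duplications


def flag_ancient_tandem(communities: Sequence[CliqueCommunity],
                        network: nx.Graph,
                        groups: Mapping[str, str] | None = None
                        ) -> list[EventCall]:
    """Flag communities mixing >= 2 group labels as ancient tandems.

    Records the per-group member counts and the induced cross-group edges
    (pairs of syntenic genes from different groups — the reciprocal-loss
    signature, where an ancient tandem pair survives as one group's copy in
    some lineages and the other group's copy elsewhere).
    """
    get = (groups or {}).get if groups is not None else \
        (lambda n, d=None: network.nodes[n].get("group", d))
    calls: list[EventCall] = []
    for comm in communities:
        label_of = {n: (get(n, "unclassified") or "unclassified")
                    for n in comm.nodes}
        real = sorted({g for g in label_of.values() if g != "unclassified"})
        if len(real) < 2:
            continue
        counts: dict[str, int] = {}
        for g in label_of.values():
            counts[g] = counts.get(g, 0) + 1
        sub = network.subgraph(comm.nodes)
        cross = sorted(
            tuple(sorted((u, v)))
            for u, v in sub.edges
            if label_of[u] != label_of[v]
            and "unclassified" not in (label_of[u], label_of[v]))
        calls.append(EventCall(
            kind="ancient_tandem", scope="-".join(real),
            communities=(comm.community_id,),
            stats={"group_counts": dict(sorted(counts.items())),
                   "cross_group_edges": tuple(cross)}))
    return calls


def events_to_frame(calls: Sequence[EventCall]) -> pd.DataFrame:
    rows = [{
        "kind": c.kind, "scope": c.scope,
        "communities": ",".join(str(i) for i in c.communities),
        "stats": repr(dict(sorted(c.stats.items()))),
    } for c in calls]
    return pd.DataFrame(rows, columns=["kind", "scope", "communities",
                                       "stats"])


def write_itol_connections(network: nx.Graph,
                           communities: Sequence[CliqueCommunity],
                           path) -> None:
    """iTOL connection-dataset dialect mapping syntenic edges to leaf pairs.

    One data line per intra-community edge, coloured per community id, for
    drawing syntenic connections inside a circular gene tree.
    """
    palette = ["#1b9e77", "#d95f02", "#7570b3", "#e7298a", "#66a61e",
               "#e6ab02", "#a6761d", "#666666"]
    with open(path, "w") as fh:
        fh.write("DATASET_CONNECTION\nSEPARATOR COMMA\n"
                 "DATASET_LABEL,synteny\nCOLOR,#ff0ff0\n"
                 "DRAW_ARROWS,0\nARROW_SIZE,0\nCURVE_ANGLE,0\nDATA\n")
        for comm in communities:
            color = palette[comm.community_id % len(palette)]
            sub = network.subgraph(comm.nodes)
            for u, v in sorted(map(lambda e: tuple(sorted(e)), sub.edges)):
                fh.write(f"{u},{v},1,{color},normal,"
                         f"community_{comm.community_id}\n")
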