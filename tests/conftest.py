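"""Shared fixtures and independent oracles used across the suite."""

import itertools

import dendropy
import networkx as nx
import pytest

import synnet as sn
from synnet.collinearity import GeneLocus


@pytest.fixture
def quiet_params():
    """No events, no noise, no truncation: the identity regime."""
    return sn.SimParams(rate_wgd=0, rate_tandem=0, rate_transposition=0,
                        rate_loss=0, truncated_fraction=0, hit_score_noise=0,
                        spurious_hit_rate=0, seed=7)


def make_loci(spec):
    """Loci from {species: {chrom: [gene ids in rank order]}}."""
    loci = {}
    for sp, chroms in spec.items():
        for chrom, genes in chroms.items():
            for rank, g in enumerate(genes):
                loci[g] = GeneLocus(g, sp, chrom, rank)
    return loci


# ---------------------------------------------------------------------------
# brute-force oracles (kept independent of the implementations they check)


def brute_best_chain(anchors, min_anchors, max_gap, match_score=50.0,
                     gap_penalty=-1.0):
    """Exhaustive search over orientation-consistent monotone anchor
    subsets; returns the best chain score with >= min_anchors anchors, or
    None. Anchors are (qrank, srank) pairs."""
    anchors = sorted(anchors)
    n = len(anchors)
    best = None
    for r in range(min_anchors, n + 1):
        for sub in itertools.combinations(range(n), r):
            qs = [anchors[i][0] for i in sub]
            ss = [anchors[i][1] for i in sub]
            for sign in (1, -1):
                score = match_score
                ok = True
                for k in range(1, r):
                    dq = qs[k] - qs[k - 1]
                    ds = (ss[k] - ss[k - 1]) * sign
                    if dq <= 0 or ds <= 0 or dq > max_gap or ds > max_gap:
                        ok = False
                        break
                    score += match_score + gap_penalty * ((dq - 1) + (ds - 1))
                if ok and (best is None or score > best):
                    best = score
    return best


def brute_cpm(graph, k):
    """Clique percolation by full k-subset enumeration + component search."""
    cliques = [c for c in itertools.combinations(sorted(graph.nodes), k)
               if all(graph.has_edge(u, v)
                      for u, v in itertools.combinations(c, 2))]
    H = nx.Graph()
    H.add_nodes_from(range(len(cliques)))
    for i, j in itertools.combinations(range(len(cliques)), 2):
        if len(set(cliques[i]) & set(cliques[j])) == k - 1:
            H.add_edge(i, j)
    return {frozenset(n for i in comp for n in cliques[i])
            for comp in nx.connected_components(H)}


def mrca_monophyly_oracle(newick, leaves):
    """Monophyly via dendropy MRCA on the clade and on its complement."""
    tree = dendropy.Tree.get(data=newick, schema="newick",
                             suppress_internal_node_taxa=True,
                             preserve_underscores=True)
    tree.is_rooted = True
    all_leaves = {lf.taxon.label for lf in tree.leaf_node_iter()}
    target = set(leaves)
    if len(target) == 1 or target == all_leaves:
        return True

    def clade_equals(subset):
        taxa = [tree.taxon_namespace.get_taxon(x) for x in subset]
        mrca = tree.mrca(taxa=taxa)
        return {lf.taxon.label for lf in mrca.leaf_iter()} == subset

    return clade_equals(target) or clade_equals(all_leaves - target)
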