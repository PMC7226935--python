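"""Gene-tree I/O, p-distances, neighbor joining and monophyly tests.

Trees are carried as dendropy trees wrapped with leaf→species and
leaf→group maps. Maximum-likelihood inference is out of scope: externally
built trees are read from newick (support values as internal-node labels),
and a neighbor-joining construction from p-distances serves as the built-in
fallback. NJ uses the standard Q-criterion agglomeration with a
deterministic tie-break on taxon labels, so repeated runs agree exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd


class NewickParseError(ValueError):
    """Malformed newick input."""


@dataclass
class GeneTree:
    """A gene tree plus the leaf metadata the event rules need.

    ``rooted`` records whether a rooting directive (outgroup or midpoint)
    has been applied; duplication inference requires it.
    """

    tree: dendropy.Tree
    species_map: dict[str, str] = field(default_factory=dict)
    group_map: dict[str, str] = field(default_factory=dict)
    rooted: bool = False

    def leaf_labels(self) -> list[str]:
        return [lf.taxon.label for lf in self.tree.leaf_node_iter()]

    def n_leaves(self) -> int:
        return sum(1 for _ in self.tree.leaf_node_iter())

    def n_internal(self) -> int:
        return sum(1 for n in self.tree.preorder_node_iter()
                   if not n.is_leaf())


def node_support(node: dendropy.Node) -> float | None:
    """Support value of an internal node (its newick label), if numeric."""
    if node.label is None:
        return None
    try:
        return float(node.label)
    except ValueError:
        return None


def read_newick(text: str, species_map: Mapping[str, str] | None = None,
                group_map: Mapping[str, str] | None = None) -> GeneTree:
    """Parse a newick string; internal labels are kept as support values."""
    try:
        tree = dendropy.Tree.get(
            data=text, schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several parse error types
        raise NewickParseError(f"malformed newick: {exc}") from exc
    if not any(True for _ in tree.leaf_node_iter()):
        raise NewickParseError("malformed newick: no leaves parsed")
    sm = dict(species_map or {})
    if not sm:
        # default: leaf labels of the form "<species>_<gene>"
        for lf in tree.leaf_node_iter():
            lab = lf.taxon.label
            sm[lab] = lab.split("_")[0] if "_" in lab else lab
    return GeneTree(tree=tree, species_map=sm, group_map=dict(group_map or {}))


def _canonicalize(tree: dendropy.Tree) -> None:
    """Order children by smallest descendant leaf label (stable output)."""
    order: dict[int, str] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            order[id(node)] = node.taxon.label
        else:
            kids = sorted(node.child_nodes(), key=lambda c: order[id(c)])
            node.set_child_nodes(kids)
            order[id(node)] = order[id(kids[0])]


def write_newick(gt: GeneTree) -> str:
    """Canonical newick text (children sorted; supports as labels)."""
    _canonicalize(gt.tree)
    return gt.tree.as_string(
        schema="newick", suppress_rooting=True,
        unquoted_underscores=True).strip() + "\n"


# ---------------------------------------------------------------------------
# distances and neighbor joining


def p_distance_matrix(aln: Mapping[str, str], gap_char: str = "-"
                      ) -> pd.DataFrame:
    """Pairwise p-distances (fraction of differing comparable sites).

    Sites where either sequence has a gap are excluded from the pair's
    comparison; a pair with no comparable site is an error (naming the
    pair), since its distance is undefined.
    """
    labels = list(aln)
    if len(labels) < 2:
        raise ValueError("need at least two sequences")
    lengths = {len(s) for s in aln.values()}
    if len(lengths) != 1:
        raise ValueError(f"unequal sequence lengths: {sorted(lengths)}")
    arr = np.frombuffer("".join(aln.values()).encode("ascii"),
                        dtype=np.uint8).reshape(len(labels), -1)
    gap = ord(gap_char)
    n = len(labels)
    D = np.zeros((n, n))
    for i in range(n):
        a = arr[i]
        ok_a = a != gap
        for j in range(i + 1, n):
            b = arr[j]
            comparable = ok_a & (b != gap)
            m = int(comparable.sum())
            if m == 0:
                raise ValueError("no comparable sites between "
                                 f"{labels[i]!r} and {labels[j]!r}")
            d = int((a[comparable] != b[comparable]).sum()) / m
            D[i, j] = D[j, i] = d
    return pd.DataFrame(D, index=labels, columns=labels)


def nj_tree(dist: pd.DataFrame | np.ndarray,
            labels: Sequence[str] | None = None) -> GeneTree:
    """Neighbor-joining tree from a symmetric distance matrix.

    Standard Saitou–Nei agglomeration on the Q-criterion; among tied
    minimal pairs the one with the lexicographically smallest (label,
    label) is joined, where an internal node inherits the smallest leaf
    label below it. Negative branch-length estimates are clamped to 0.
    Returns an unrooted tree (trifurcating seed node).
    """
    if isinstance(dist, pd.DataFrame):
        labels = list(dist.index)
        D = dist.to_numpy(dtype=float)
    else:
        D = np.asarray(dist, dtype=float)
        if labels is None:
            labels = [f"t{i}" for i in range(len(D))]
    n = len(D)
    if D.shape != (n, n):
        raise ValueError("distance matrix must be square")
    if not np.allclose(D, D.T, atol=1e-9):
        raise ValueError("distance matrix must be symmetric")
    if (D < -1e-12).any():
        raise ValueError("distance matrix must be nonnegative")
    if n < 3:
        raise ValueError("need at least three taxa")

    tns = dendropy.TaxonNamespace()
    nodes = [dendropy.Node(taxon=tns.new_taxon(lab)) for lab in labels]
    names = list(labels)
    M = D.copy()

    while len(nodes) > 3:
        m = len(nodes)
        r = M.sum(axis=1)
        Q = (m - 2) * M - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        qmin = Q.min()
        ties = np.argwhere(Q <= qmin + 1e-12)
        cand = []
        for i, j in ties:
            if i < j:
                a, b = sorted((names[i], names[j]))
                cand.append((a, b, int(i), int(j)))
        _, _, i, j = min(cand)
        li = 0.5 * M[i, j] + (r[i] - r[j]) / (2 * (m - 2))
        lj = M[i, j] - li
        li, lj = max(li, 0.0), max(lj, 0.0)
        parent = dendropy.Node()
        pairs = [(nodes[i], li, names[i]), (nodes[j], lj, names[j])]
        for child, ln, _ in sorted(pairs, key=lambda t: t[2]):
            parent.add_child(child)
            child.edge.length = round(float(ln), 9)
        new_name = min(names[i], names[j])
        dnew = 0.5 * (M[i, :] + M[j, :] - M[i, j])
        dnew = np.maximum(np.delete(dnew, [i, j]), 0.0)
        M = np.delete(np.delete(M, [i, j], axis=0), [i, j], axis=1)
        M = np.pad(M, ((0, 1), (0, 1)))
        M[-1, :-1] = dnew
        M[:-1, -1] = dnew
        for idx in sorted((i, j), reverse=True):
            nodes.pop(idx)
            names.pop(idx)
        nodes.append(parent)
        names.append(new_name)

    # final three taxa: trifurcating root with closed-form branch lengths
    d01, d02, d12 = M[0, 1], M[0, 2], M[1, 2]
    lens = [0.5 * (d01 + d02 - d12), 0.5 * (d01 + d12 - d02),
            0.5 * (d02 + d12 - d01)]
    root = dendropy.Node()
    triple = sorted(zip(nodes, lens, names), key=lambda t: t[2])
    for child, ln, _ in triple:
        root.add_child(child)
        child.edge.length = round(float(max(ln, 0.0)), 9)
    tree = dendropy.Tree(taxon_namespace=tns, seed_node=root)
    tree.is_rooted = False
    return GeneTree(tree=tree, rooted=False)


# ---------------------------------------------------------------------------
# monophyly and rooting


def _leaf_sets(tree: dendropy.Tree) -> list[frozenset]:
    sets: list[frozenset] = []
    memo: dict[int, frozenset] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            memo[id(node)] = frozenset((node.taxon.label,))
        else:
            memo[id(node)] = frozenset().union(
                *(memo[id(c)] for c in node.child_nodes()))
        sets.append(memo[id(node)])
    return sets


def is_monophyletic(gt: GeneTree, leaves: Iterable[str]) -> bool:
    """Is ``leaves`` one side of some bipartition of the (unrooted) tree?

    On a rooted tree this is the usual clade test, made insensitive to root
    placement by also accepting the complement side. Singletons and the
    full leaf set are trivially monophyletic.
    """
    target = frozenset(leaves)
    all_leaves = frozenset(gt.leaf_labels())
    unknown = target - all_leaves
    if unknown:
        raise KeyError(f"unknown leaf: {sorted(unknown)[0]}")
    if not target:
        raise ValueError("empty leaf set")
    if len(target) == 1 or target == all_leaves:
        return True
    complement = all_leaves - target
    for s in _leaf_sets(gt.tree):
        if s == target or s == complement:
            return True
    return False


def root_with_outgroup(gt: GeneTree, outgroup_species: str) -> GeneTree:
    """Root on the edge above the MRCA of the outgroup species' genes."""
    og_labels = [lab for lab in gt.leaf_labels()
                 if gt.species_map.get(lab) == outgroup_species]
    if not og_labels:
        raise ValueError(f"no leaves of outgroup species {outgroup_species!r}")
    tree = gt.tree.clone(depth=1)
    tree.is_rooted = True
    taxa = [tree.taxon_namespace.get_taxon(lab) for lab in og_labels]
    mrca = tree.mrca(taxa=taxa)
    if mrca is tree.seed_node:
        # outgroup spans the current root: root between it and the rest
        others = [lab for lab in gt.leaf_labels() if lab not in set(og_labels)]
        taxa = [tree.taxon_namespace.get_taxon(lab) for lab in others]
        mrca = tree.mrca(taxa=taxa)
    if mrca is not tree.seed_node:
        L = mrca.edge.length or 0.0
        tree.reroot_at_edge(mrca.edge, length1=L / 2, length2=L / 2)
    tree.is_rooted = True
    return GeneTree(tree=tree, species_map=dict(gt.species_map),
                    group_map=dict(gt.group_map), rooted=True)


def root_at_midpoint(gt: GeneTree) -> GeneTree:
    """Root at the midpoint of the longest leaf-to-leaf path."""
    tree = gt.tree.clone(depth=1)
    tree.reroot_at_midpoint(update_bipartitions=False)
    tree.is_rooted = True
    return GeneTree(tree=tree, species_map=dict(gt.species_map),
                    group_map=dict(gt.group_map), rooted=True)
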