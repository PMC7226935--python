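"""Synthetic genome-evolution simulator.

Evolves multi-genome gene orders down a known species tree under four event
kinds — whole-genome duplication (WGD), tandem duplication, single-gene
transposition and gene loss — and emits the tables the downstream synteny
pipeline consumes: per-genome gene orders, blast-style homology hits, a
two-signature-domain annotation table and toy nucleotide sequences for the
focal gene family. Every event is recorded in a ground-truth event log so
that inference stages can be scored against what actually happened.

Events are sampled per branch as Poisson(rate × branch length) and applied
in a uniformly shuffled order; forced events can be planted on a named clade
stem for parameter-recovery experiments. All randomness flows from
``SimParams.seed`` via independent numpy substreams, so identical
(params, seed) give byte-identical outputs.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd

#: Group labels of the focal transcription-factor family (six angiosperm
#: clades, named as in the ARF literature).
GROUP_LABELS: tuple[str, ...] = ("I", "II", "III", "IV", "V", "VI")

#: The two signature Pfam domains whose co-occurrence defines family
#: membership (B3 DNA-binding and Auxin-response domains).
SIGNATURE_DOMAINS: tuple[str, str] = ("PF02362", "PF06507")

EVENT_KINDS = ("wgd", "tandem", "transposition", "loss")

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


class SimulationError(ValueError):
    """Invalid simulator arguments or parameters."""


@dataclass(frozen=True)
class SimParams:
    """Parameters of one simulated genome-evolution study.

    Rates are per unit branch length; with the default branch lengths
    (uniform on [0.2, 1.0]) the default rates give a handful of events per
    branch at most, which is the regime the collinearity signal survives.

    ``truncated_fraction`` is the probability that an extant family member is
    emitted with a "truncated" flag (its domain-table row then carries only
    one of the two signature domains); the default 0.08 matches the observed
    ratio of truncated to total syntelogs in large plant-family surveys.
    """

    n_ancestral_genes: int = 200
    n_chromosomes: int = 4
    family_fraction: float = 0.10
    rate_wgd: float = 0.05
    rate_tandem: float = 0.4
    rate_transposition: float = 0.3
    rate_loss: float = 0.4
    truncated_fraction: float = 0.08
    hit_score_noise: float = 5.0
    spurious_hit_rate: float = 0.01
    hit_base_score: float = 500.0
    hit_divergence_scale: float = 20.0
    seq_length: int = 300
    subst_rate: float = 0.05
    #: private stem branch (time units) separating each ancestral family
    #: gene from the family root sequence: subfamilies are anciently
    #: diverged, so cross-orthogroup distances exceed ortholog distances
    orthogroup_stem: float = 2.0
    group_labels: tuple[str, ...] = GROUP_LABELS
    seed: int = 0

    def validate(self) -> None:
        if self.n_ancestral_genes < 1:
            raise SimulationError("n_ancestral_genes must be positive")
        if self.n_chromosomes < 1:
            raise SimulationError("n_chromosomes must be positive")
        for name in ("family_fraction", "truncated_fraction", "spurious_hit_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise SimulationError(f"{name} must be in [0, 1], got {v}")
        for name in ("rate_wgd", "rate_tandem", "rate_transposition", "rate_loss",
                     "hit_score_noise"):
            if getattr(self, name) < 0:
                raise SimulationError(f"{name} must be >= 0")
        if self.seq_length < 1:
            raise SimulationError("seq_length must be >= 1")
        if not 0.0 <= self.subst_rate < 0.75:
            raise SimulationError("subst_rate must be in [0, 0.75)")


@dataclass(frozen=True)
class GeneCopy:
    """One gene copy in an (ancestral or extant) genome."""

    gid: str
    orthogroup: str
    family: bool
    group: str | None


@dataclass(frozen=True)
class SimEvent:
    """A single recorded evolutionary event on a species-tree branch.

    ``clade`` identifies the branch by the sorted leaf labels of its child
    node; ``genes`` are the internal gene ids directly affected (the moved,
    lost, or duplicated-template genes).
    """

    clade: tuple[str, ...]
    kind: str
    genes: tuple[str, ...]
    details: dict = field(default_factory=dict)


@dataclass
class EventLog:
    """Ordered ground-truth record of all simulated events."""

    events: list[SimEvent] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.events)

    def __iter__(self):
        return iter(self.events)

    def of_kind(self, kind: str) -> list[SimEvent]:
        return [e for e in self.events if e.kind == kind]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "clade": ";".join(e.clade),
                "kind": e.kind,
                "genes": ";".join(e.genes),
                "details": repr(e.details),
            }
            for e in self.events
        ]
        return pd.DataFrame(rows, columns=["clade", "kind", "genes", "details"])


@dataclass(frozen=True)
class ForcedEvent:
    """An event planted deterministically on the stem branch of ``clade``.

    For transpositions ``family_target=True`` restricts the moved gene to
    family members, so the planted signal is visible to the family-level
    pipeline.
    """

    clade: tuple[str, ...]
    kind: str
    family_target: bool = True


@dataclass
class SyntheticGenomeSet:
    """Extant genomes plus the ground truth needed to score inference.

    ``genomes`` maps species → chromosome → ordered extant gene ids; ranks
    along a chromosome are implicitly the list indices (consecutive from 0).
    Internal bookkeeping (per-node ancestral genomes, duplicate origins,
    species patristic distances) is retained so sequence emission and hit
    scoring can run without re-walking the tree.
    """

    genomes: dict[str, dict[str, list[str]]]
    family_flags: dict[str, str]
    true_orthogroups: dict[str, str]
    true_group: dict[str, str]
    species_of: dict[str, str]
    gid_of: dict[str, str]
    node_genomes: dict[frozenset, dict[str, list[GeneCopy]]]
    gene_origin: dict[str, tuple[str | None, frozenset]]
    species_distance: dict[tuple[str, str], float]

    def species(self) -> list[str]:
        return sorted(self.genomes)

    def all_gene_ids(self) -> list[str]:
        out: list[str] = []
        for sp in self.species():
            for chrom in self.genomes[sp]:
                out.extend(self.genomes[sp][chrom])
        return out

    def genes_of_species(self, sp: str) -> list[str]:
        out: list[str] = []
        for chrom in self.genomes[sp]:
            out.extend(self.genomes[sp][chrom])
        return out

    def family_gene_ids(self) -> list[str]:
        return [g for g in self.all_gene_ids()
                if self.family_flags[g] in ("member", "truncated")]

    def flanking_genes(self, gene: str) -> tuple[str | None, str | None]:
        """Extant neighbours of ``gene`` on its chromosome (None at ends)."""
        sp = self.species_of[gene]
        for chrom, genes in self.genomes[sp].items():
            if gene in genes:
                i = genes.index(gene)
                prev = genes[i - 1] if i > 0 else None
                nxt = genes[i + 1] if i + 1 < len(genes) else None
                return prev, nxt
        raise KeyError(gene)


# ---------------------------------------------------------------------------
# species tree


def clade_key(node: dendropy.Node) -> frozenset:
    """Identify a tree node by the set of leaf labels below it."""
    return frozenset(lf.taxon.label for lf in node.leaf_iter())


def simulate_species_tree(n_species: int, seed: int) -> dendropy.Tree:
    """Random rooted binary species tree with ``n_species`` labelled leaves.

    Topology is built by uniformly joining random pairs of subtrees; branch
    lengths are uniform on [0.2, 1.0] (arbitrary time units). Children are
    ordered by their smallest descendant label, so the newick string is a
    deterministic function of the seed.
    """
    if n_species < 2:
        raise SimulationError("n_species must be >= 2")
    rng = np.random.default_rng(seed)
    taxa = dendropy.TaxonNamespace()
    nodes: list[dendropy.Node] = []
    for i in range(n_species):
        label = f"sp{i + 1}"
        node = dendropy.Node(taxon=taxa.new_taxon(label))
        node.min_leaf = label  # type: ignore[attr-defined]
        nodes.append(node)
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False).tolist())
        b = nodes.pop(j)
        a = nodes.pop(i)
        parent = dendropy.Node()
        for child in sorted((a, b), key=lambda n: n.min_leaf):
            parent.add_child(child)
            child.edge.length = round(float(rng.uniform(0.2, 1.0)), 6)
        parent.min_leaf = min(a.min_leaf, b.min_leaf)  # type: ignore[attr-defined]
        nodes.append(parent)
    tree = dendropy.Tree(taxon_namespace=taxa, seed_node=nodes[0])
    tree.is_rooted = True
    return tree


def tree_to_newick(tree: dendropy.Tree) -> str:
    return tree.as_string(schema="newick", suppress_rooting=True).strip() + "\n"


# ---------------------------------------------------------------------------
# genome evolution

Genome = dict[str, list[GeneCopy]]


class _Evolver:
    def __init__(self, params: SimParams, rng: np.random.Generator):
        self.params = params
        self.rng = rng
        self._counter = itertools.count()
        self.origin: dict[str, tuple[str | None, frozenset]] = {}
        self.events: list[SimEvent] = []

    def new_gid(self) -> str:
        return f"G{next(self._counter):06d}"

    def ancestral_genome(self) -> Genome:
        p = self.params
        n = p.n_ancestral_genes
        fam_n = int(round(n * p.family_fraction))
        fam_idx = set(self.rng.choice(n, size=fam_n, replace=False).tolist()) \
            if fam_n else set()
        genes: list[GeneCopy] = []
        for i in range(n):
            fam = i in fam_idx
            group = None
            if fam:
                group = p.group_labels[int(self.rng.integers(len(p.group_labels)))]
            genes.append(GeneCopy(self.new_gid(), f"OG{i:05d}", fam, group))
        genome: Genome = {}
        bounds = np.linspace(0, n, p.n_chromosomes + 1).astype(int)
        for c in range(p.n_chromosomes):
            genome[f"chr{c + 1}"] = genes[bounds[c]:bounds[c + 1]]
        return genome

    # -- event application ---------------------------------------------------

    @staticmethod
    def _flat(genome: Genome) -> list[tuple[str, int]]:
        return [(chrom, i) for chrom in genome for i in range(len(genome[chrom]))]

    def _pick_gene(self, genome: Genome, family_only: bool = False
                   ) -> tuple[str, int] | None:
        positions = self._flat(genome)
        if family_only:
            positions = [(c, i) for c, i in positions if genome[c][i].family]
        if not positions:
            return None
        return positions[int(self.rng.integers(len(positions)))]

    def apply_wgd(self, genome: Genome, ck: frozenset) -> None:
        originals = [g.gid for chrom in genome for g in genome[chrom]]
        new_chroms: Genome = {}
        for chrom in list(genome):
            name = f"{chrom}x"
            while name in genome or name in new_chroms:
                name += "x"
            copies = []
            for g in genome[chrom]:
                copy = GeneCopy(self.new_gid(), g.orthogroup, g.family, g.group)
                self.origin[copy.gid] = (g.gid, ck)
                copies.append(copy)
            new_chroms[name] = copies
        genome.update(new_chroms)
        self.events.append(SimEvent(
            tuple(sorted(ck)), "wgd", tuple(originals),
            {"n_duplicated": len(originals)}))

    def apply_tandem(self, genome: Genome, ck: frozenset) -> None:
        pos = self._pick_gene(genome)
        if pos is None:
            return
        chrom, i = pos
        parent = genome[chrom][i]
        copy = GeneCopy(self.new_gid(), parent.orthogroup, parent.family,
                        parent.group)
        self.origin[copy.gid] = (parent.gid, ck)
        genome[chrom].insert(i + 1, copy)
        self.events.append(SimEvent(
            tuple(sorted(ck)), "tandem", (parent.gid,),
            {"copy": copy.gid, "chrom": chrom, "n_duplicated": 1}))

    def apply_transposition(self, genome: Genome, ck: frozenset,
                            family_only: bool = False) -> None:
        pos = self._pick_gene(genome, family_only=family_only)
        if pos is None:
            return
        chrom, i = pos
        gene = genome[chrom][i]
        src = genome[chrom]
        source_flanks = (src[i - 1].gid if i > 0 else None,
                         src[i + 1].gid if i + 1 < len(src) else None)
        del src[i]
        others = [c for c in genome if c != chrom and genome[c]]
        dest_chrom = (others[int(self.rng.integers(len(others)))]
                      if others else chrom)
        dest = genome[dest_chrom]
        j = int(self.rng.integers(len(dest) + 1))
        dest.insert(j, gene)
        dest_flanks = (dest[j - 1].gid if j > 0 else None,
                       dest[j + 1].gid if j + 1 < len(dest) else None)
        self.events.append(SimEvent(
            tuple(sorted(ck)), "transposition", (gene.gid,),
            {"source_chrom": chrom, "source_flanks": source_flanks,
             "dest_chrom": dest_chrom, "dest_flanks": dest_flanks}))

    def apply_loss(self, genome: Genome, ck: frozenset) -> None:
        if sum(len(v) for v in genome.values()) <= 1:
            return
        pos = self._pick_gene(genome)
        if pos is None:
            return
        chrom, i = pos
        gene = genome[chrom][i]
        del genome[chrom][i]
        self.events.append(SimEvent(
            tuple(sorted(ck)), "loss", (gene.gid,), {"chrom": chrom}))

    def evolve_branch(self, genome: Genome, blen: float, ck: frozenset,
                      forced: Sequence[ForcedEvent]) -> None:
        p = self.params
        kinds: list[tuple[str, bool]] = []
        for kind, rate in (("wgd", p.rate_wgd), ("tandem", p.rate_tandem),
                           ("transposition", p.rate_transposition),
                           ("loss", p.rate_loss)):
            kinds.extend([(kind, False)] * int(self.rng.poisson(rate * blen)))
        if kinds:
            order = self.rng.permutation(len(kinds))
            kinds = [kinds[k] for k in order]
        kinds.extend((fe.kind, fe.family_target) for fe in forced)
        for kind, family_only in kinds:
            if kind == "wgd":
                self.apply_wgd(genome, ck)
            elif kind == "tandem":
                self.apply_tandem(genome, ck)
            elif kind == "transposition":
                self.apply_transposition(genome, ck, family_only=family_only)
            elif kind == "loss":
                self.apply_loss(genome, ck)
            else:  # pragma: no cover - guarded by ForcedEvent construction
                raise SimulationError(f"unknown event kind {kind!r}")


def evolve_genomes(tree: dendropy.Tree, params: SimParams,
                   forced_events: Sequence[ForcedEvent] = (),
                   ) -> tuple[SyntheticGenomeSet, EventLog]:
    """Evolve an ancestral genome down ``tree`` and collect extant genomes.

    Returns the extant genome set (with ground-truth orthogroups, family
    flags and group labels) and the event log. Events are applied on each
    branch in a random order; ``forced_events`` are applied after the sampled
    ones on their named branch, which keeps planted signals intact.
    """
    params.validate()
    for fe in forced_events:
        if fe.kind not in EVENT_KINDS:
            raise SimulationError(f"unknown event kind {fe.kind!r}")
    rng = np.random.default_rng([params.seed, 0])
    ev = _Evolver(params, rng)

    root = tree.seed_node
    keys = {node: clade_key(node) for node in tree.preorder_node_iter()}
    known_clades = set(keys.values())
    for fe in forced_events:
        if frozenset(fe.clade) not in known_clades:
            raise SimulationError(f"forced event clade {fe.clade} is not a "
                                  "clade of the species tree")

    node_genomes: dict[frozenset, Genome] = {keys[root]: ev.ancestral_genome()}
    for node in tree.preorder_node_iter():
        if node is root:
            continue
        parent_genome = node_genomes[keys[node.parent_node]]
        genome: Genome = {c: list(gs) for c, gs in parent_genome.items()}
        ck = keys[node]
        forced_here = [fe for fe in forced_events if frozenset(fe.clade) == ck]
        ev.evolve_branch(genome, node.edge.length or 0.0, ck, forced_here)
        node_genomes[ck] = genome

    pdm = tree.phylogenetic_distance_matrix()
    leaves = [lf.taxon for lf in tree.leaf_node_iter()]
    species_distance = {
        (a.label, b.label): float(pdm.patristic_distance(a, b))
        for a in leaves for b in leaves
    }

    genomes: dict[str, dict[str, list[str]]] = {}
    family_flags: dict[str, str] = {}
    true_orthogroups: dict[str, str] = {}
    true_group: dict[str, str] = {}
    species_of: dict[str, str] = {}
    gid_of: dict[str, str] = {}
    for node in tree.leaf_node_iter():
        sp = node.taxon.label
        genome = node_genomes[keys[node]]
        genomes[sp] = {}
        for chrom, genes in genome.items():
            ids = []
            for g in genes:
                eid = f"{sp}_{g.gid}"
                ids.append(eid)
                species_of[eid] = sp
                gid_of[eid] = g.gid
                true_orthogroups[eid] = g.orthogroup
                if g.family:
                    truncated = (params.truncated_fraction > 0 and
                                 rng.random() < params.truncated_fraction)
                    family_flags[eid] = "truncated" if truncated else "member"
                    true_group[eid] = g.group or ""
                else:
                    family_flags[eid] = "non-family"
            genomes[sp][chrom] = ids

    genome_set = SyntheticGenomeSet(
        genomes=genomes, family_flags=family_flags,
        true_orthogroups=true_orthogroups, true_group=true_group,
        species_of=species_of, gid_of=gid_of,
        node_genomes=node_genomes, gene_origin=ev.origin,
        species_distance=species_distance,
    )
    return genome_set, EventLog(ev.events)


# ---------------------------------------------------------------------------
# emitted tables


def emit_homology_hits(genomes: SyntheticGenomeSet, params: SimParams,
                       include_true_hits: bool = True) -> pd.DataFrame:
    """Blast-style directed hit table over all genome pairs, self included.

    True hits connect every gene pair sharing an orthogroup; the score is a
    bitscore-like base minus a penalty proportional to the species patristic
    distance, plus Gaussian noise of sd ``hit_score_noise``. Self-gene hits
    (query == subject) are emitted at the base score — the downstream top-k
    filter removes them, as it would for real self-comparisons. Spurious
    cross-orthogroup hits are added at ``spurious_hit_rate`` (relative to the
    number of true hits in each comparison). E-values are a monotone
    transform of the score, for format completeness only.
    """
    rng = np.random.default_rng([params.seed, 17])
    species = genomes.species()
    by_og: dict[str, dict[str, list[str]]] = {sp: {} for sp in species}
    for sp in species:
        for g in genomes.genes_of_species(sp):
            by_og[sp].setdefault(genomes.true_orthogroups[g], []).append(g)

    rows_q: list[str] = []
    rows_s: list[str] = []
    rows_score: list[float] = []

    def add(q: str, s: str, score: float) -> None:
        rows_q.append(q)
        rows_s.append(s)
        rows_score.append(max(30.0, score))

    base = params.hit_base_score
    scale = params.hit_divergence_scale
    for qsp in species:
        for ssp in species:
            dist = genomes.species_distance[(qsp, ssp)]
            n_true = 0
            if include_true_hits:
                for og, qgenes in by_og[qsp].items():
                    sgenes = by_og[ssp].get(og)
                    if not sgenes:
                        continue
                    for q in qgenes:
                        for s in sgenes:
                            noise = (rng.normal(0.0, params.hit_score_noise)
                                     if params.hit_score_noise > 0 else 0.0)
                            add(q, s, base - scale * dist + float(noise))
                            n_true += 1
            if params.spurious_hit_rate > 0:
                qall = genomes.genes_of_species(qsp)
                sall = genomes.genes_of_species(ssp)
                n_spur = int(round(params.spurious_hit_rate *
                                   (n_true if n_true else len(qall) + len(sall))))
                for _ in range(n_spur):
                    q = qall[int(rng.integers(len(qall)))]
                    s = sall[int(rng.integers(len(sall)))]
                    if (genomes.true_orthogroups[q]
                            == genomes.true_orthogroups[s]):
                        continue
                    noise = (rng.normal(0.0, params.hit_score_noise)
                             if params.hit_score_noise > 0 else 0.0)
                    add(q, s, 0.4 * base + float(noise))

    hits = pd.DataFrame({"query": rows_q, "subject": rows_s,
                         "score": rows_score})
    hits["evalue"] = 10.0 ** (-hits["score"] / 10.0)
    return hits


def hits_by_comparison(hits: pd.DataFrame, species_of: Mapping[str, str]
                       ) -> dict[tuple[str, str], pd.DataFrame]:
    """Partition a hit table into per-proteome-comparison tables.

    Keys are directed (query genome, subject genome) pairs; with n genomes
    there are n(n−1) + n = n² of them (self-comparisons included), the
    bookkeeping of an all-vs-all run where every proteome queries every
    proteome.
    """
    qs = hits["query"].map(species_of)
    ss = hits["subject"].map(species_of)
    out: dict[tuple[str, str], pd.DataFrame] = {}
    for k, sub in hits.groupby(
            np.array([f"{a}|{b}" for a, b in zip(qs, ss)])):
        a, b = k.split("|")
        out[(a, b)] = sub.reset_index(drop=True)
    return out


def emit_domain_table(genomes: SyntheticGenomeSet,
                      required_domains: tuple[str, str] = SIGNATURE_DOMAINS,
                      seed: int = 0) -> pd.DataFrame:
    """Per-gene domain annotation table (gene id → domain accessions).

    Family members carry both signature domains; truncated members carry
    exactly one, chosen at random (seeded); non-family genes get an empty
    domain list.
    """
    rng = np.random.default_rng([seed, 29])
    rows = []
    for gene in genomes.all_gene_ids():
        flag = genomes.family_flags[gene]
        if flag == "member":
            doms: tuple[str, ...] = tuple(required_domains)
        elif flag == "truncated":
            doms = (required_domains[int(rng.integers(2))],)
        else:
            doms = ()
        rows.append({"gene_id": gene, "domains": doms})
    return pd.DataFrame(rows, columns=["gene_id", "domains"])


# ---------------------------------------------------------------------------
# sequences


def _mutate(seq: np.ndarray, p: float, rng: np.random.Generator) -> np.ndarray:
    if p <= 0:
        return seq.copy()
    out = seq.copy()
    mask = rng.random(out.size) < p
    n = int(mask.sum())
    if n:
        # substitute with one of the three other bases, uniformly
        out[mask] = (out[mask] + rng.integers(1, 4, size=n)) % 4
    return out


def emit_sequences(genomes: SyntheticGenomeSet, tree: dendropy.Tree,
                   params: SimParams) -> dict[str, str]:
    """Toy nucleotide sequences for every extant family gene.

    A single ancestral family sequence is drawn uniformly; each ancestral
    family gene diverges from it over a private stem branch of
    ``orthogroup_stem`` time units (ancient subfamily divergence) and is
    then evolved down the species tree by per-site substitution with
    probability min(subst_rate × branch length, 0.74). Orthogroups thus
    resolve as clades radiating from the family root, with cross-orthogroup
    distances exceeding ortholog distances; at subst_rate = 0 every family
    sequence is identical. A copy created by a duplication
    is seeded from its template's sequence at the end of the branch and
    mutated over half the branch (a mid-branch duplication approximation),
    so paralogues diverge from their duplication event onward and recent
    duplicates are each other's closest relatives. Substitution-only (no
    indels): all sequences stay aligned at ``seq_length`` columns.
    """
    params.validate()
    rng = np.random.default_rng([params.seed, 41])
    L = params.seq_length
    keys = {node: clade_key(node) for node in tree.preorder_node_iter()}
    root = tree.seed_node

    seqs: dict[frozenset, dict[str, np.ndarray]] = {}
    root_key = keys[root]
    ancestral = rng.integers(0, 4, size=L, dtype=np.uint8)
    p_stem = min(params.subst_rate * params.orthogroup_stem, 0.74)
    root_seqs: dict[str, np.ndarray] = {}
    for chrom in genomes.node_genomes[root_key]:
        for g in genomes.node_genomes[root_key][chrom]:
            if g.family:
                root_seqs[g.gid] = _mutate(ancestral, p_stem, rng)
    seqs[root_key] = root_seqs

    for node in tree.preorder_node_iter():
        if node is root:
            continue
        ck = keys[node]
        parent_seqs = seqs[keys[node.parent_node]]
        blen = node.edge.length or 0.0
        p = min(params.subst_rate * blen, 0.74)
        p_half = min(0.5 * params.subst_rate * blen, 0.74)
        here: dict[str, np.ndarray] = {}

        genome = genomes.node_genomes[ck]
        created: list[str] = []
        for chrom in genome:
            for g in genome[chrom]:
                if not g.family:
                    continue
                if g.gid in parent_seqs:
                    here[g.gid] = _mutate(parent_seqs[g.gid], p, rng)
                else:
                    created.append(g.gid)
        # duplicates evolve from their template's end-of-branch sequence
        # over half a branch; gid order guarantees templates come first.
        # A template lost later on the same branch is materialised lazily.
        ghost: dict[str, np.ndarray] = {}

        def end_seq(gid: str) -> np.ndarray:
            if gid in here:
                return here[gid]
            if gid not in ghost:
                if gid in parent_seqs:
                    ghost[gid] = _mutate(parent_seqs[gid], p, rng)
                else:
                    template, where = genomes.gene_origin[gid]
                    if template is None or where != ck:  # pragma: no cover
                        raise SimulationError(f"no sequence lineage for {gid}")
                    ghost[gid] = _mutate(end_seq(template), p_half, rng)
            return ghost[gid]

        for gid in sorted(created):
            template, where = genomes.gene_origin[gid]
            if template is None or where != ck:  # pragma: no cover
                raise SimulationError(f"no sequence lineage for {gid}")
            here[gid] = _mutate(end_seq(template), p_half, rng)
        seqs[ck] = here

    out: dict[str, str] = {}
    for node in tree.leaf_node_iter():
        sp = node.taxon.label
        leaf_seqs = seqs[keys[node]]
        for gene in genomes.genes_of_species(sp):
            if genomes.family_flags[gene] in ("member", "truncated"):
                arr = leaf_seqs[genomes.gid_of[gene]]
                out[gene] = _BASES[arr].tobytes().decode("ascii")
    return out
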