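# Methods

This note documents the models and procedures implemented in `synnet`,
the parameters that matter, and the choices made where the design was
genuinely open.

## The analysis model

The object of study is a gene family spread over many related genomes. Two
family genes are *syntelogs* when they occupy corresponding positions in a
collinear block — a run of ≥ `min_anchors` homologous gene pairs (anchors)
whose order is conserved, ascending or descending, between two chromosomal
regions (possibly of the same genome: intra-genome blocks are the
signature of polyploidy and are treated symmetrically). The family-anchored
synteny network has family genes as nodes and syntelog relations as edges;
its k-clique-percolation communities group genes sharing one ancestral
genomic context. Community composition, confronted with a gene tree,
supports three event calls:

* **Duplication** (species-overlap rule): an internal node of a rooted
  gene tree whose two child clades share ≥ 1 species. Support values of
  the node and its children, when present, are compared against
  `min_support` (default 80); failing calls are flagged low-confidence,
  never dropped.
* **Lineage-specific transposition**: a community of
  ≥ `min_community_size` genes from ≥ 2 species that all belong to one
  lineage, monophyletic in the gene tree, while another community of the
  same family group extends outside that lineage. The event is placed on
  the lineage stem. The third condition separates a relocation from a
  family-wide restriction; the monophyly condition separates one ancestral
  move from recurrent independent ones.
* **Ancient tandem duplication**: a community whose members carry ≥ 2
  distinct group labels. Under reciprocal loss of ancient tandem
  paralogues, one group's copy survives in some lineages and the other
  group's copy elsewhere, so their (shared) neighbourhood keeps them in
  one community; the cross-group edges are reported as the signature.

Known limitation: the transposition rule cannot orient a move when the
complement of the moved clade is itself a single lineage (two lineages,
two contexts, no outgroup context to vote); with ≥ 2 outgroup lineages the
ancestral context is identified implicitly and only the moved clade is
called.

## Collinearity chaining

Hits are first reduced to the top `k_hits` = 5 non-self hits per (query,
target genome) — the per-target-genome reading of the "top five" rule,
recorded in config so the alternative global reading is reproducible.
Optionally, tandem arrays (mutually hitting genes within
`max_tandem_gap` = 1 ranks on one chromosome, closed transitively) are
collapsed onto their best-self-scoring member, as MCScanX does.

Anchors of a chromosome pair are chained by a DP: anchor *j* extends *i*
when 0 < Δq ≤ `max_gap` and 0 < |Δs| ≤ `max_gap` with a consistent
subject-rank sign; the chain score is Σ `match_score` + `gap_penalty` ×
Σ((Δq−1) + (|Δs|−1)). Defaults (5, 25, 50, −1) mirror MCScanX, which
reports no overrides in this kind of analysis. Blocks are extracted
greedily by descending score with used anchors removed; the DP carries a
length-capped second dimension (best score per chain length up to
`min_anchors`), because with these scores a 2-anchor perfect diagonal can
outscore a legitimate 5-anchor chain, and a plain best-chain DP would then
stop extracting too early. For ≤ 12 anchors the DP is verified against
exhaustive search over all orientation-consistent monotone subsets.

## Clique percolation

Communities at clique size k are connected components of the clique graph
in which two k-cliques are adjacent iff they share exactly k−1 nodes
(CFinder's unweighted CPM). k-cliques are enumerated exactly; adjacency is
found by hashing every (k−1)-subset and union-finding collisions — two
distinct k-cliques sharing such a subset share exactly k−1 nodes, so this
realises the definition without pairwise comparisons. Community ids are
assigned by descending size, then smallest member id, making the numbering
deterministic. Nodes in no k-clique (singletons, nodes with one
connection) are unassigned by construction; no extra filter is applied.
k = 3 is the pipeline default; raising k can only shrink the covered node
set.

## Trees

Newick I/O, rooting and the tree container use dendropy; support values
ride as internal-node labels. The built-in fallback tree is neighbor
joining on p-distances (fraction of differing non-gap comparable sites):
the standard Q-criterion agglomeration, with ties broken by the
lexicographically smallest (label, label) pair — an internal node inherits
the smallest leaf label below it — and negative branch-length estimates
clamped to zero. On additive matrices NJ recovers the generating topology
(verified against dendropy's implementation); it stands in for external
maximum-likelihood trees, which the pipeline accepts as newick. Monophyly
is tested unrooted: a leaf set is monophyletic iff it or its complement is
the descendant set of some node. Duplication inference requires rooting:
an outgroup species when configured, midpoint otherwise.

## The simulator

The generator emulates the statistical structure the analysis assumes,
not molecular realism. An ancestral genome of `n_ancestral_genes` = 200
genes on `n_chromosomes` = 4 chromosomes (a `family_fraction` = 0.10 of
them family members with group labels I–VI) evolves down a random rooted
species tree (uniform pair joins; branch lengths uniform on [0.2, 1.0]).
Per branch, each event kind occurs Poisson(rate × branch length) times,
applied in uniformly shuffled order:

* **WGD** duplicates every chromosome wholesale under new chromosome ids,
  preserving order — as real WGDs preserve collinearity. Default
  `rate_wgd` = 0.05 (rare).
* **Tandem** inserts a copy adjacent to a uniformly chosen gene
  (`rate_tandem` = 0.4).
* **Transposition** moves one uniformly chosen gene to a uniform position
  on another chromosome, recording source and destination flanks
  (`rate_transposition` = 0.3).
* **Loss** deletes a uniformly chosen gene (`rate_loss` = 0.4).

These default densities give a handful of single-gene events per lineage
and occasional WGDs — enough turnover to exercise every code path while
leaving the collinearity signal intact. Forced events can be planted on a
named clade stem (for transpositions, restricted to family genes so the
family-level pipeline can see them). A ledger invariant holds exactly:
extant gene count = ancestral count + duplications − losses along the
root-to-leaf path.

Homology hits connect all gene pairs sharing an ancestral lineage
(orthogroup), scored as a bitscore-like base (500) minus a penalty
proportional to the species patristic distance (scale 20) plus Gaussian
noise (`hit_score_noise` = 5); spurious cross-orthogroup hits are added at
`spurious_hit_rate` = 0.01 of the true-hit count; e-values are a monotone
transform of the score, present only for format completeness (downstream
logic uses ranks). Self-gene hits are emitted and removed by the top-k
filter, as in real all-vs-all runs.

A fraction `truncated_fraction` = 0.08 of extant family members is
flagged truncated — the flag, not a literal sequence truncation, since the
pipeline only consumes domain presence. The value matches the observed
share of truncated syntelogs in large plant-family surveys (96 of 1192,
8.1%). Truncated genes receive exactly one of the two signature domains,
chosen at random (seeded).

Sequences are toy nucleotides, substitution-only (no indels, so they stay
aligned): one ancestral family sequence, a private stem branch of
`orthogroup_stem` = 2.0 time units per ancestral gene (subfamilies are
anciently diverged, which keeps every gene's nearest sequence neighbour
inside its own orthogroup), then per-site substitution with probability
min(`subst_rate` × branch length, 0.74). A duplicate is seeded from its
template's end-of-branch sequence and mutated over half a branch — a
mid-branch duplication approximation that makes recent duplicates each
other's closest relatives, as a mid-branch event implies. At
`subst_rate` = 0 all family sequences are identical.

What the simulator does *not* model — codon structure, rate heterogeneity,
indels, segmental (sub-genome) duplications, fractionation bias, assembly
fragmentation — bounds what passing tests show: they demonstrate the
pipeline's rules recover planted events from clean, fully observed gene
orders, not robustness to annotation noise or fragmented assemblies.

## Pipeline conventions and numerics

* All randomness flows from one seed; numpy substreams are derived per
  emitter, so outputs are byte-identical for identical (params, seed) and
  the run manifest is a pure function of (inputs, config, seed). Timings
  go to the log, never the manifest.
* Reported percentages (syntenic fraction, community coverage) are
  rounded to one decimal.
* Parallel anchors between the same two genes collapse to one network
  edge carrying the supporting block list; both the collapsed edge count
  and the raw anchor-pair count are reported, since "syntenic connections"
  can reasonably mean either.
* Truncated syntelogs enter the network (status `truncated`) and are
  classified by best global alignment to member sequences
  (match +1/mismatch −1, gap open −2/extend −0.5, `min_identity` = 0.3
  guard), but are excluded from the gene tree used for event calls; a
  community containing them is skipped by the transposition rule with a
  logged warning.
* `--resume` returns an existing manifest when its parameter echo matches
  the current config; any mismatch triggers a full rerun.
* Problem sizes in tests and the acceptance script (8 genomes × 200
  ancestral genes, 10 WGD replicates, 3 planted-transposition replicates)
  are desk-scale stand-ins chosen so the whole analysis reruns in seconds
  while still containing every structure the rules need; the published
  counts that depend on 52 external genomes are exercised as printed
  arithmetic, not re-derived.
* Planted-transposition recovery runs use `min_community_size` = 3: a
  stem transposition into a 3-species clade yields exactly one gene per
  species, hence a 3-node community, in a noise-free run. The config
  default stays 4, which in noisy data trades recall for precision.
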