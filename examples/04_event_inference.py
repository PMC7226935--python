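"""Infer a planted transposition and a planted WGD from scratch.

A transposition is planted on the stem of a 3-species clade and a WGD on
one terminal branch; the pipeline must rediscover both from the synteny
communities and the gene tree alone.
"""

import dendropy

import synnet as sn

nwk = ("(((s1:0.4,s2:0.4):0.3,s3:0.7):0.5,"
       "((s4:0.5,s5:0.5):0.4,(s6:0.6,(s7:0.3,s8:0.3):0.3):0.3):0.4);")
tree = dendropy.Tree.get(data=nwk, schema="newick")
tree.is_rooted = True

params = sn.SimParams(rate_wgd=0, rate_tandem=0, rate_transposition=0,
                      rate_loss=0, truncated_fraction=0, hit_score_noise=0,
                      spurious_hit_rate=0, subst_rate=0.08, seed=23)
genomes, log = sn.evolve_genomes(tree, params, [
    sn.ForcedEvent(("s1", "s2", "s3"), "transposition"),
    sn.ForcedEvent(("s5",), "wgd"),
])
print("planted:", [(e.kind, e.clade) for e in log])

loci = sn.loci_from_genomes(genomes)
hits = sn.filter_top_hits(sn.emit_homology_hits(genomes, params), loci)
blocks = sn.chain_collinear_blocks(hits, loci)
members = {g for g, f in genomes.family_flags.items() if f == "member"}
G = sn.build_family_synteny_network(
    blocks, members,
    species={g: l.species for g, l in loci.items()},
    groups=genomes.true_group)
comms = sn.clique_percolation(G, 3)

seqs = sn.emit_sequences(genomes, tree, params)
gt = sn.nj_tree(sn.p_distance_matrix({m: seqs[m] for m in sorted(members)}))
gt.species_map = {m: genomes.species_of[m] for m in members}

lineages = sn.lineages_from_tree(tree, max_clade_size=3)
transpositions = sn.call_transpositions(comms, G, gt, lineages,
                                        min_community_size=3)
duplications = sn.infer_duplications(sn.root_with_outgroup(gt, "s4"))
s5_dups = [c for c in duplications if c.stats["shared_species"] == ("s5",)]

print(f"transposition calls: "
      f"{[(c.scope, c.stats['species']) for c in transpositions]}")
print(f"{len(s5_dups)} duplication nodes specific to s5 "
      f"(one per retained WGD pair)")
# The transposition call names the lineage whose genes moved into a new
# genomic context; s5-specific duplication nodes are the WGD signature.
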