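"""Build the family synteny network and its k-clique communities.

Family members connected by block anchors form an undirected network;
k = 3 clique percolation splits it into overlapping communities named by
the clades-nodes-connections convention (e.g. "VI-16-45").
"""

import synnet as sn

params = sn.SimParams(seed=4)
tree = sn.simulate_species_tree(6, seed=4)
genomes, _ = sn.evolve_genomes(tree, params)
loci = sn.loci_from_genomes(genomes)

hits = sn.filter_top_hits(sn.emit_homology_hits(genomes, params), loci)
blocks = sn.chain_collinear_blocks(hits, loci)
members = {g for g, f in genomes.family_flags.items() if f == "member"}
G = sn.build_family_synteny_network(
    blocks, members,
    species={g: l.species for g, l in loci.items()},
    groups=genomes.true_group)

frac = sn.pct(sum(G.has_node(m) for m in members), len(members))
print(f"{len(members)} members, {G.number_of_nodes()} syntenic "
      f"({frac}%), {G.number_of_edges()} syntenic connections")

comms = sn.clique_percolation(G, k=3)
covered = set().union(*(c.nodes for c in comms)) if comms else set()
print(f"{len(comms)} communities cover "
      f"{sn.pct(len(covered), G.number_of_nodes())}% of syntelogs")
for c in comms[:5]:
    print(f"  community {c.community_id}: {sn.name_community(c, G)}")
# A community groups genes that share a conserved genomic context; its name
# lists the family groups present, the node count and the edge count.
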