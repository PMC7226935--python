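"""Simulate a small set of genomes evolving along a species tree.

Eight genomes descend from a 200-gene ancestor under whole-genome
duplication, tandem duplication, single-gene transposition and loss; the
event log records the ground truth that later stages are scored against.
"""

import synnet as sn
from synnet import simulate as sim

params = sn.SimParams(seed=4)
tree = sn.simulate_species_tree(8, seed=4)
genomes, log = sn.evolve_genomes(tree, params)

print("species tree:", sim.tree_to_newick(tree).strip())
for kind in sim.EVENT_KINDS:
    print(f"simulated {kind:14s}: {len(log.of_kind(kind))} events")
flags = list(genomes.family_flags.values())
print(f"{len(genomes.all_gene_ids())} extant genes; "
      f"{flags.count('member')} family members, "
      f"{flags.count('truncated')} truncated")
# Each genome's gene count equals the ancestor's plus duplications minus
# losses on its root-to-leaf path; family members are the genes the
# downstream synteny network is built from.
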