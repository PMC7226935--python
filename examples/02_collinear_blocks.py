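"""Detect collinear blocks between simulated genomes.

All-vs-all homology hits are reduced to the top five non-self hits per
query and target genome, tandem arrays are collapsed, and anchors are
chained into blocks by the collinearity dynamic program.
"""

import synnet as sn
from synnet import collinearity as C

params = sn.SimParams(seed=4)
tree = sn.simulate_species_tree(6, seed=4)
genomes, _ = sn.evolve_genomes(tree, params)
loci = sn.loci_from_genomes(genomes)

hits = sn.emit_homology_hits(genomes, params)
filtered = sn.filter_top_hits(hits, loci, k=5)
filtered, arrays = sn.collapse_tandem_arrays(filtered, loci)
blocks = sn.chain_collinear_blocks(filtered, loci)

print(f"{len(hits)} raw hits -> {len(filtered)} after top-5 filter "
      f"({len(arrays)} tandem arrays collapsed)")
print(f"{len(blocks)} collinear blocks; an all-vs-all run of "
      f"{len(genomes.species())} genomes means "
      f"{sn.count_proteome_comparisons(len(genomes.species()))} "
      "proteome comparisons")
best = max(blocks, key=lambda b: len(b.anchors))
print(f"largest block: {len(best.anchors)} anchors, "
      f"{best.species_pair[0]} {best.chrom_pair[0]} vs "
      f"{best.species_pair[1]} {best.chrom_pair[1]}, "
      f"{best.orientation}, score {best.score:.0f}")
# Each anchor is a homologous gene pair in conserved order; blocks of >= 5
# anchors are the syntenic evidence connecting family genes.
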