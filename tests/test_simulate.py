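"""Simulator: tree generation, event mechanics, emitted tables."""

import numpy as np
import pytest

import synnet as sn
from synnet import simulate as sim


def leaf_and_internal_counts(tree):
    leaves = sum(1 for _ in tree.leaf_node_iter())
    internal = sum(1 for n in tree.preorder_node_iter() if not n.is_leaf())
    return leaves, internal


class TestSpeciesTree:
    def test_two_species_is_a_cherry(self):
        tree = sn.simulate_species_tree(2, seed=1)
        assert leaf_and_internal_counts(tree) == (2, 1)

    def test_seed_determinism(self):
        a = sim.tree_to_newick(sn.simulate_species_tree(8, seed=7))
        b = sim.tree_to_newick(sn.simulate_species_tree(8, seed=7))
        assert a == b

    @pytest.mark.parametrize("seed", [7, 8])
    def test_node_counts_by_traversal(self, seed):
        tree = sn.simulate_species_tree(8, seed=seed)
        assert leaf_and_internal_counts(tree) == (8, 7)

    def test_too_few_species_rejected(self):
        with pytest.raises(ValueError):
            sn.simulate_species_tree(1, seed=0)


class TestEvolveGenomes:
    def test_no_event_identity(self, quiet_params):
        tree = sn.simulate_species_tree(5, seed=2)
        genomes, log = sn.evolve_genomes(tree, quiet_params)
        assert len(log) == 0
        ancestral = [
            [g.gid for g in genes]
            for genes in genomes.node_genomes[
                sim.clade_key(tree.seed_node)].values()]
        for sp in genomes.species():
            extant = [[genomes.gid_of[g] for g in genes]
                      for genes in genomes.genomes[sp].values()]
            assert extant == ancestral

    def test_forced_wgd_doubles_gene_count(self, quiet_params):
        tree = sn.simulate_species_tree(4, seed=3)
        genomes, log = sn.evolve_genomes(
            tree, quiet_params, [sn.ForcedEvent(("sp2",), "wgd")])
        assert len(log.of_kind("wgd")) == 1
        n0 = quiet_params.n_ancestral_genes
        assert len(genomes.genes_of_species("sp2")) == 2 * n0
        for sp in ("sp1", "sp3", "sp4"):
            assert len(genomes.genes_of_species(sp)) == n0

    def test_planted_transposition_changes_flanks(self, quiet_params):
        # fixed topology with a known 3-species clade
        import dendropy
        nwk = ("(((s1:0.4,s2:0.4):0.3,s3:0.7):0.5,"
               "((s4:0.5,s5:0.5):0.4,(s6:0.6,(s7:0.3,s8:0.3):0.3):0.3):0.4);")
        tree = dendropy.Tree.get(data=nwk, schema="newick")
        tree.is_rooted = True
        clade = ("s1", "s2", "s3")
        genomes, log = sn.evolve_genomes(
            tree, quiet_params, [sn.ForcedEvent(clade, "transposition")])
        assert [e.kind for e in log] == ["transposition"]
        moved_gid = log.events[0].genes[0]
        flanks = {}
        for sp in genomes.species():
            gene = f"{sp}_{moved_gid}"
            prev, nxt = genomes.flanking_genes(gene)
            flanks[sp] = (prev and genomes.gid_of[prev],
                          nxt and genomes.gid_of[nxt])
        for inside in clade:
            for outside in ("s4", "s5", "s6", "s7", "s8"):
                assert flanks[inside] != flanks[outside]

    def test_event_ledger_balances(self):
        params = sn.SimParams(rate_wgd=0.02, rate_tandem=0.2,
                              rate_transposition=0.1, rate_loss=0.2,
                              n_ancestral_genes=60, seed=5)
        tree = sn.simulate_species_tree(6, seed=5)
        genomes, log = sn.evolve_genomes(tree, params)
        for node in tree.leaf_node_iter():
            sp = node.taxon.label
            path_clades = set()
            cur = node
            while cur.parent_node is not None:
                path_clades.add(tuple(sorted(sim.clade_key(cur))))
                cur = cur.parent_node
            gained = sum(e.details.get("n_duplicated", 0) for e in log
                         if e.clade in path_clades
                         and e.kind in ("wgd", "tandem"))
            lost = sum(1 for e in log
                       if e.clade in path_clades and e.kind == "loss")
            assert (len(genomes.genes_of_species(sp))
                    == params.n_ancestral_genes + gained - lost)

    def test_unknown_forced_clade_rejected(self, quiet_params):
        tree = sn.simulate_species_tree(4, seed=1)
        with pytest.raises(ValueError):
            sn.evolve_genomes(tree, quiet_params,
                              [sn.ForcedEvent(("spX",), "wgd")])

    def test_byte_determinism(self):
        params = sn.SimParams(n_ancestral_genes=50, seed=9)
        tree = sn.simulate_species_tree(5, seed=9)
        a, loga = sn.evolve_genomes(tree, params)
        b, logb = sn.evolve_genomes(tree, params)
        assert a.genomes == b.genomes
        assert a.family_flags == b.family_flags
        assert loga.to_frame().equals(logb.to_frame())
        ha = sn.emit_homology_hits(a, params)
        hb = sn.emit_homology_hits(b, params)
        assert ha.equals(hb)
        assert sn.emit_sequences(a, tree, params) == \
            sn.emit_sequences(b, tree, params)


class TestHomologyHits:
    def test_noise_free_hits_equal_orthogroup_pairs(self, quiet_params):
        tree = sn.simulate_species_tree(3, seed=4)
        params = sn.SimParams(**{**quiet_params.__dict__,
                                 "n_ancestral_genes": 30})
        genomes, _ = sn.evolve_genomes(tree, params)
        hits = sn.emit_homology_hits(genomes, params)
        got = set(zip(hits["query"], hits["subject"]))
        genes = genomes.all_gene_ids()
        expected = {(q, s) for q in genes for s in genes
                    if genomes.true_orthogroups[q]
                    == genomes.true_orthogroups[s]}
        assert got == expected

    def test_comparison_table_partition(self, quiet_params):
        tree = sn.simulate_species_tree(3, seed=4)
        params = sn.SimParams(**{**quiet_params.__dict__,
                                 "n_ancestral_genes": 30})
        genomes, _ = sn.evolve_genomes(tree, params)
        hits = sn.emit_homology_hits(genomes, params)
        tables = sn.hits_by_comparison(hits, genomes.species_of)
        # n(n-1) + n = 9 directed comparisons for n = 3
        assert len(tables) == 9
        assert sum(len(t) for t in tables.values()) == len(hits)

    def test_spurious_only_hits_are_cross_orthogroup(self, quiet_params):
        tree = sn.simulate_species_tree(3, seed=4)
        params = sn.SimParams(**{**quiet_params.__dict__,
                                 "n_ancestral_genes": 30,
                                 "spurious_hit_rate": 1.0})
        genomes, _ = sn.evolve_genomes(tree, params)
        hits = sn.emit_homology_hits(genomes, params,
                                     include_true_hits=False)
        assert len(hits) > 0
        for q, s in zip(hits["query"], hits["subject"]):
            assert (genomes.true_orthogroups[q]
                    != genomes.true_orthogroups[s])


class TestDomainTable:
    def test_domain_rules(self):
        params = sn.SimParams(n_ancestral_genes=80, truncated_fraction=0.5,
                              rate_wgd=0, rate_tandem=0,
                              rate_transposition=0, rate_loss=0, seed=6)
        tree = sn.simulate_species_tree(3, seed=6)
        genomes, _ = sn.evolve_genomes(tree, params)
        table = sn.emit_domain_table(genomes)
        both = set(sim.SIGNATURE_DOMAINS)
        n_trunc = 0
        for gene, doms in zip(table["gene_id"], table["domains"]):
            flag = genomes.family_flags[gene]
            if flag == "member":
                assert set(doms) == both
            elif flag == "truncated":
                assert len(doms) == 1 and set(doms) < both
                n_trunc += 1
            else:
                assert doms == ()
        assert n_trunc > 0


class TestSequences:
    def test_zero_substitution_rate_gives_identical_sequences(
            self, quiet_params):
        tree = sn.simulate_species_tree(4, seed=8)
        params = sn.SimParams(**{**quiet_params.__dict__, "subst_rate": 0.0})
        genomes, _ = sn.evolve_genomes(tree, params)
        seqs = sn.emit_sequences(genomes, tree, params)
        assert len(set(seqs.values())) == 1

    def test_fixed_seed_fasta_byte_identical(self, quiet_params, tmp_path):
        from synnet import io as sio
        tree = sn.simulate_species_tree(4, seed=8)
        genomes, _ = sn.evolve_genomes(tree, quiet_params)
        for name in ("a.fasta", "b.fasta"):
            sio.write_fasta(
                sn.emit_sequences(genomes, tree, quiet_params),
                tmp_path / name)
        assert (tmp_path / "a.fasta").read_bytes() == \
            (tmp_path / "b.fasta").read_bytes()

    def test_p_distance_tracks_path_length(self):
        # Monte-Carlo: mean ortholog p-distance should rank with the
        # species-pair patristic distance
        from scipy.stats import spearmanr
        pooled_d, pooled_t = [], []
        for seed in range(20):
            params = sn.SimParams(n_ancestral_genes=20, family_fraction=0.5,
                                  rate_wgd=0, rate_tandem=0,
                                  rate_transposition=0, rate_loss=0,
                                  truncated_fraction=0, subst_rate=0.05,
                                  seed=seed)
            tree = sn.simulate_species_tree(6, seed=seed)
            genomes, _ = sn.evolve_genomes(tree, params)
            seqs = sn.emit_sequences(genomes, tree, params)
            fam_genes = genomes.family_gene_ids()
            by_og = {}
            for g in fam_genes:
                by_og.setdefault(genomes.true_orthogroups[g], []).append(g)
            for og_genes in by_og.values():
                for i, a in enumerate(og_genes):
                    for b in og_genes[i + 1:]:
                        sa, sb = genomes.species_of[a], genomes.species_of[b]
                        if sa == sb:
                            continue
                        diff = sum(x != y for x, y in
                                   zip(seqs[a], seqs[b])) / len(seqs[a])
                        pooled_d.append(diff)
                        pooled_t.append(genomes.species_distance[(sa, sb)])
        rho = spearmanr(pooled_t, pooled_d).statistic
        assert rho > 0


class TestParamValidation:
    @pytest.mark.parametrize("bad", [
        {"n_ancestral_genes": 0},
        {"family_fraction": 1.5},
        {"rate_loss": -0.1},
        {"subst_rate": 0.8},
        {"seq_length": 0},
    ])
    def test_invalid_params_rejected(self, bad):
        with pytest.raises(ValueError):
            sn.SimParams(**bad).validate()
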