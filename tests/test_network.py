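"""Synteny-network extraction, truncated syntelogs and summaries."""

import networkx as nx
import numpy as np
import pytest

import synnet as sn
from synnet import collinearity as C
from synnet import network as N
from conftest import make_loci


def block_from_pairs(pairs, loci, block_id=0):
    anchors = tuple((loci[a], loci[b]) for a, b in pairs)
    qa = anchors[0][0]
    sa = anchors[0][1]
    return C.CollinearBlock(block_id=block_id,
                            species_pair=(qa.species, sa.species),
                            chrom_pair=(qa.chromosome, sa.chromosome),
                            orientation="ascending", anchors=anchors,
                            score=100.0)


LOCI = make_loci({"A": {"c1": [f"A{i}" for i in range(6)]},
                  "B": {"c1": [f"B{i}" for i in range(6)]}})


class TestBuildNetwork:
    def test_single_member_pair_gives_one_edge(self):
        pairs = [(f"A{i}", f"B{i}") for i in range(5)]
        block = block_from_pairs(pairs, LOCI)
        G = sn.build_family_synteny_network([block], {"A2", "B2"})
        assert set(G.nodes) == {"A2", "B2"}
        assert G.number_of_edges() == 1
        assert G.edges["A2", "B2"]["blocks"] == [0]

    def test_no_member_anchors_empty_network(self):
        block = block_from_pairs([("A0", "B0")], LOCI)
        G = sn.build_family_synteny_network([block], {"A5", "B5"})
        assert G.number_of_nodes() == 0

    def test_parallel_anchors_collapse_to_one_edge(self):
        b0 = block_from_pairs([("A1", "B1")], LOCI, 0)
        b1 = block_from_pairs([("A1", "B1")], LOCI, 1)
        G = sn.build_family_synteny_network([b0, b1], {"A1", "B1"})
        assert G.number_of_edges() == 1
        assert G.edges["A1", "B1"]["blocks"] == [0, 1]
        assert G.graph["raw_anchor_pairs"] == 2

    def test_wgd_duplicate_pairs_all_connected(self, quiet_params):
        # ground-truth recall: every family WGD pair in a block is an edge
        tree = sn.simulate_species_tree(5, seed=13)
        genomes, log = sn.evolve_genomes(
            tree, quiet_params, [sn.ForcedEvent(("sp3",), "wgd")])
        loci = sn.loci_from_genomes(genomes)
        hits = sn.emit_homology_hits(genomes, quiet_params)
        filtered = C.filter_top_hits(hits, loci)
        blocks = C.chain_collinear_blocks(filtered, loci)
        members = {g for g, f in genomes.family_flags.items()
                   if f == "member"}
        G = sn.build_family_synteny_network(blocks, members)
        dup_pairs = []
        originals = set(log.of_kind("wgd")[0].genes)
        for eid, gid in genomes.gid_of.items():
            origin = genomes.gene_origin.get(gid)
            if origin and origin[0] in originals and eid in members:
                partner = f"sp3_{origin[0]}"
                if partner in members:
                    dup_pairs.append((eid, partner))
        assert dup_pairs
        for a, b in dup_pairs:
            assert G.has_edge(a, b), (a, b)


class TestTruncatedSyntelogs:
    def test_partial_anchored_to_member_is_truncated(self):
        block = block_from_pairs([("A1", "B1"), ("A2", "B2")], LOCI)
        recs = sn.detect_truncated_syntelogs([block], {"B1"}, {"A1", "A3"})
        assert [r.gene_id for r in recs] == ["A1"]
        assert recs[0].status == "truncated"
        assert recs[0].partner_count == 1

    def test_partial_without_member_anchor_not_added(self):
        block = block_from_pairs([("A1", "B1")], LOCI)
        assert sn.detect_truncated_syntelogs([block], set(), {"A1"}) == []

    def test_simulator_truncated_recovered_noise_free(self):
        params = sn.SimParams(rate_wgd=0, rate_tandem=0,
                              rate_transposition=0, rate_loss=0,
                              truncated_fraction=0.3, hit_score_noise=0,
                              spurious_hit_rate=0, seed=21)
        tree = sn.simulate_species_tree(4, seed=21)
        genomes, _ = sn.evolve_genomes(tree, params)
        loci = sn.loci_from_genomes(genomes)
        table = sn.emit_domain_table(genomes)
        members, partial = sn.identify_family_members(
            table, sn.simulate.SIGNATURE_DOMAINS
            if hasattr(sn, "simulate") else ("PF02362", "PF06507"))
        hits = C.filter_top_hits(sn.emit_homology_hits(genomes, params),
                                 loci)
        blocks = C.chain_collinear_blocks(hits, loci)
        recs = sn.detect_truncated_syntelogs(blocks, members, partial)
        member_ogs = {genomes.true_orthogroups[m] for m in members}
        # recoverable = truncated genes whose orthogroup retains at least
        # one intact member somewhere (otherwise no member anchor exists)
        truncated_truth = {
            g for g, f in genomes.family_flags.items()
            if f == "truncated"
            and genomes.true_orthogroups[g] in member_ogs}
        assert {r.gene_id for r in recs} == truncated_truth


class TestFractions:
    def test_published_worked_ratio(self):
        assert sn.pct(1096, 1227) == 89.3

    def test_syntenic_fraction_bounds(self):
        G = nx.Graph([("a", "b")])
        assert sn.syntenic_fraction({"a", "b"}, G) == 1.0
        assert sn.syntenic_fraction({"c"}, G) == 0.0
        with pytest.raises(ValueError):
            sn.syntenic_fraction(set(), G)

    def test_conservation_partition(self):
        G = nx.Graph([("a", "b")])
        members = {"a", "b", "c", "d"}
        syntenic = {m for m in members if G.has_node(m)}
        assert syntenic | (members - syntenic) == members


class TestIntergroup:
    @staticmethod
    def graph_with_groups(edges, groups):
        G = nx.Graph(edges)
        for n in G.nodes:
            G.nodes[n]["group"] = groups.get(n, "unclassified")
        return G

    def test_within_group_only_zero_intergroup(self):
        G = self.graph_with_groups([("a", "b"), ("b", "c")],
                                   {"a": "I", "b": "I", "c": "I"})
        _, inter = sn.intergroup_edge_summary(G)
        assert inter == 0

    def test_single_cross_group_edge_counted_once(self):
        # the basal-angiosperm IV–VI reciprocal-loss scenario
        G = self.graph_with_groups([("amb", "osa")],
                                   {"amb": "IV", "osa": "VI"})
        mat, inter = sn.intergroup_edge_summary(G)
        assert mat.loc["IV", "VI"] == 1 and mat.loc["VI", "IV"] == 1
        assert inter == 1

    def test_unclassified_endpoint_excluded_from_total(self):
        G = self.graph_with_groups([("a", "b")], {"a": "I"})
        _, inter = sn.intergroup_edge_summary(G)
        assert inter == 0

    def test_shuffled_groups_match_brute_recount(self):
        rng = np.random.default_rng(5)
        base = nx.gnp_random_graph(20, 0.3, seed=2)
        labels = ["I", "II", "III", "IV", "V", "VI", "unclassified"]
        for _ in range(5):
            groups = {n: labels[int(rng.integers(len(labels)))]
                      for n in base.nodes}
            G = self.graph_with_groups(list(base.edges), groups)
            _, inter = sn.intergroup_edge_summary(G)
            brute = sum(
                1 for u, v in G.edges
                if groups[u] != groups[v]
                and "unclassified" not in (groups[u], groups[v]))
            assert inter == brute


class TestExport:
    @staticmethod
    def example_network():
        G = nx.Graph()
        G.add_edge("A1", "B1", blocks=[0, 2])
        G.add_edge("B1", "B2", blocks=[1])
        for n, sp, gr in (("A1", "A", "I"), ("B1", "B", "I"),
                          ("B2", "B", "VI")):
            G.nodes[n].update(species=sp, group=gr, status="member")
        return G

    @pytest.mark.parametrize("fmt,fname", [("edgelist", "net.tsv"),
                                           ("graphml", "net.graphml")])
    def test_round_trip(self, tmp_path, fmt, fname):
        G = self.example_network()
        path = tmp_path / fname
        sn.export_network(G, path, fmt)
        H = sn.import_network(path, fmt)
        assert set(H.nodes) == set(G.nodes)
        assert {frozenset(e) for e in H.edges} == \
            {frozenset(e) for e in G.edges}
        for u, v in G.edges:
            assert H.edges[u, v]["blocks"] == G.edges[u, v]["blocks"]
        for n in G.nodes:
            assert H.nodes[n]["species"] == G.nodes[n]["species"]
            assert H.nodes[n]["group"] == G.nodes[n]["group"]

    def test_edge_list_line_count(self, tmp_path):
        G = nx.Graph([("a", "b")])
        path = tmp_path / "one.tsv"
        sn.export_network(G, path, "edgelist")
        lines = path.read_text().strip().split("\n")
        assert len(lines) == 2  # header + one edge

    def test_unknown_format_rejected(self, tmp_path):
        with pytest.raises(ValueError):
            sn.export_network(self.example_network(),
                              tmp_path / "x", "dot")
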