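"""Hit filtering, comparison bookkeeping and collinear-block chaining."""

import itertools

import numpy as np
import pandas as pd
import pytest

import synnet as sn
from synnet import collinearity as C
from conftest import brute_best_chain, make_loci


def hits_frame(rows):
    """Rows of (query, subject, score[, evalue])."""
    recs = []
    for r in rows:
        q, s, sc = r[:3]
        ev = r[3] if len(r) > 3 else 10.0 ** (-sc / 10)
        recs.append({"query": q, "subject": s, "score": float(sc),
                     "evalue": ev})
    return pd.DataFrame(recs, columns=["query", "subject", "score",
                                       "evalue"])


class TestProteomeComparisons:
    def test_published_52_genome_count(self):
        assert sn.count_proteome_comparisons(52) == 2704

    @pytest.mark.parametrize("n,expected", [(1, 1), (2, 4), (10, 100)])
    def test_small_cases(self, n, expected):
        assert sn.count_proteome_comparisons(n) == expected

    def test_formula_matches_enumeration(self):
        # directed non-self comparisons plus self-comparisons
        for n in range(1, 61):
            pairs = len(list(itertools.permutations(range(n), 2))) + n
            assert sn.count_proteome_comparisons(n) == pairs

    def test_invalid_argument(self):
        with pytest.raises(ValueError):
            sn.count_proteome_comparisons(0)


class TestFilterTopHits:
    LOCI = make_loci({"A": {"c1": [f"A{i}" for i in range(10)]},
                      "B": {"c1": [f"B{i}" for i in range(10)]}})

    def test_seven_hits_keep_five(self):
        hits = hits_frame([("A0", f"B{i}", 100 - i) for i in range(7)])
        out = C.filter_top_hits(hits, self.LOCI, 5)
        assert len(out) == 5
        assert set(out["subject"]) == {f"B{i}" for i in range(5)}

    def test_self_hit_only_gives_empty(self):
        hits = hits_frame([("A0", "A0", 500)])
        assert len(C.filter_top_hits(hits, self.LOCI, 5)) == 0

    def test_fewer_than_k_all_kept_in_score_order(self):
        hits = hits_frame([("A0", "B2", 50), ("A0", "B1", 90),
                           ("A0", "B0", 70)])
        out = C.filter_top_hits(hits, self.LOCI, 5)
        assert list(out["subject"]) == ["B1", "B0", "B2"]

    def test_per_target_genome_budget(self):
        # 6 hits to genome A and 6 to genome B: five survive in each
        hits = hits_frame([("A0", f"A{i}", 80 - i) for i in range(1, 7)]
                          + [("A0", f"B{i}", 80 - i) for i in range(6)])
        out = C.filter_top_hits(hits, self.LOCI, 5)
        assert len(out) == 10

    def test_tie_breaks_deterministic(self):
        hits = hits_frame([("A0", "B3", 50, 1e-9), ("A0", "B1", 50, 1e-9),
                           ("A0", "B2", 50, 1e-12)])
        out = C.filter_top_hits(hits, self.LOCI, 2)
        assert list(out["subject"]) == ["B2", "B1"]

    def test_unknown_gene_raises_with_name(self):
        hits = hits_frame([("A0", "Zmystery", 50)])
        with pytest.raises(KeyError, match="Zmystery"):
            C.filter_top_hits(hits, self.LOCI, 5)


class TestChaining:
    @staticmethod
    def two_genome_loci(n=8):
        return make_loci({"A": {"c1": [f"A{i}" for i in range(n)]},
                          "B": {"c1": [f"B{i}" for i in range(n)]}})

    def test_diagonal_gives_one_ascending_block(self):
        loci = self.two_genome_loci()
        hits = hits_frame([(f"A{i}", f"B{i}", 100) for i in range(1, 6)])
        blocks = C.chain_collinear_blocks(hits, loci, min_anchors=5)
        assert len(blocks) == 1
        assert blocks[0].orientation == "ascending"
        assert len(blocks[0].anchors) == 5

    def test_antidiagonal_gives_one_descending_block(self):
        loci = self.two_genome_loci()
        hits = hits_frame([(f"A{i}", f"B{6 - i}", 100)
                           for i in range(1, 6)])
        blocks = C.chain_collinear_blocks(hits, loci, min_anchors=5)
        assert len(blocks) == 1
        assert blocks[0].orientation == "descending"
        assert len(blocks[0].anchors) == 5

    def test_no_hits_no_blocks(self):
        assert C.chain_collinear_blocks(hits_frame([]),
                                        self.two_genome_loci()) == []

    def test_unknown_locus_raises_with_gene_name(self):
        loci = self.two_genome_loci()
        hits = hits_frame([("A0", "Bmissing", 100)])
        with pytest.raises(KeyError, match="Bmissing"):
            C.chain_collinear_blocks(hits, loci)

    def test_dp_matches_exhaustive_search(self):
        # oracle equivalence on random anchor sets of <= 12 anchors
        rng = np.random.default_rng(42)
        loci = make_loci(
            {"A": {"c1": [f"A{i}" for i in range(12)]},
             "B": {"c1": [f"B{i}" for i in range(12)]}})
        for _ in range(30):
            k = int(rng.integers(3, 13))
            qs = rng.choice(12, size=k, replace=False)
            ss = rng.integers(0, 12, size=k)
            anchors = sorted({(int(q), int(s)) for q, s in zip(qs, ss)})
            hits = hits_frame([(f"A{q}", f"B{s}", 100) for q, s in anchors])
            blocks = C.chain_collinear_blocks(hits, loci, min_anchors=3,
                                              max_gap=5)
            expected = brute_best_chain(anchors, min_anchors=3, max_gap=5)
            if expected is None:
                assert blocks == []
            else:
                assert blocks, f"missed chain for {anchors}"
                assert blocks[0].score == pytest.approx(expected)

    def test_blocks_satisfy_invariants(self):
        # monotone ranks, gap bounds, anchor disjointness per genome pair
        rng = np.random.default_rng(3)
        loci = make_loci(
            {"A": {"c1": [f"A{i}" for i in range(30)]},
             "B": {"c1": [f"B{i}" for i in range(30)]}})
        anchors = sorted({(int(q), int(s))
                          for q, s in zip(rng.integers(0, 30, 60),
                                          rng.integers(0, 30, 60))})
        hits = hits_frame([(f"A{q}", f"B{s}", 100) for q, s in anchors])
        blocks = C.chain_collinear_blocks(hits, loci, min_anchors=3,
                                          max_gap=10)
        seen = set()
        for b in blocks:
            qranks = [a.rank for a, _ in b.anchors]
            sranks = [s.rank for _, s in b.anchors]
            assert qranks == sorted(qranks)
            assert all(x < y for x, y in zip(qranks, qranks[1:]))
            diffs = np.diff(sranks)
            if b.orientation == "ascending":
                assert (diffs > 0).all()
            else:
                assert (diffs < 0).all()
            assert (np.diff(qranks) <= 10).all()
            assert (abs(diffs) <= 10).all()
            for pair in b.gene_pairs():
                assert pair not in seen
                seen.add(pair)

    def test_deterministic_block_ids(self):
        rng = np.random.default_rng(11)
        loci = make_loci(
            {"A": {"c1": [f"A{i}" for i in range(20)]},
             "B": {"c1": [f"B{i}" for i in range(20)]}})
        anchors = sorted({(int(q), int(s))
                          for q, s in zip(rng.integers(0, 20, 40),
                                          rng.integers(0, 20, 40))})
        hits = hits_frame([(f"A{q}", f"B{s}", 100) for q, s in anchors])
        b1 = C.chain_collinear_blocks(hits, loci, min_anchors=3)
        b2 = C.chain_collinear_blocks(hits, loci, min_anchors=3)
        assert b1 == b2


class TestTandemArrays:
    LOCI = make_loci({"A": {"c1": ["a0", "a1", "a2", "a3", "a4"]}})

    def test_adjacent_mutual_pair_collapses(self):
        hits = hits_frame([("a0", "a0", 500), ("a1", "a1", 490),
                           ("a0", "a1", 400), ("a1", "a0", 400)])
        out, arrays = C.collapse_tandem_arrays(hits, self.LOCI)
        assert arrays == [("a0", ["a0", "a1"])]
        assert set(zip(out["query"], out["subject"])) == {("a0", "a0")}

    def test_three_consecutive_genes_one_array(self):
        pairs = [("a0", "a1"), ("a1", "a0"), ("a1", "a2"), ("a2", "a1")]
        hits = hits_frame([(q, s, 400) for q, s in pairs])
        _, arrays = C.collapse_tandem_arrays(hits, self.LOCI)
        assert len(arrays) == 1
        assert arrays[0][1] == ["a0", "a1", "a2"]

    def test_no_mutual_adjacent_hits_identity(self):
        hits = hits_frame([("a0", "a2", 400), ("a2", "a0", 400),
                           ("a0", "a1", 300)])  # a0-a1 not mutual
        out, arrays = C.collapse_tandem_arrays(hits, self.LOCI)
        assert arrays == []
        assert out.equals(hits)

    def test_representative_by_self_score_then_lexicographic(self):
        hits = hits_frame([("a0", "a0", 450), ("a1", "a1", 480),
                           ("a0", "a1", 400), ("a1", "a0", 400)])
        _, arrays = C.collapse_tandem_arrays(hits, self.LOCI)
        assert arrays[0][0] == "a1"  # higher self score wins
        hits_tie = hits_frame([("a0", "a0", 450), ("a1", "a1", 450),
                               ("a0", "a1", 400), ("a1", "a0", 400)])
        _, arrays = C.collapse_tandem_arrays(hits_tie, self.LOCI)
        assert arrays[0][0] == "a0"  # tie: lexicographically smallest
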