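"""Homology-hit filtering and collinear-block chaining.

Mirrors the MCScanX-style workflow: keep the top five non-self hits per
query and target genome, optionally collapse tandem arrays to a single
representative, then chain anchors (homologous gene pairs) into collinear
blocks with a dynamic program over gene order ranks. Default chaining
parameters (min_anchors=5, max_gap=25, match_score=50, gap_penalty=-1)
follow MCScanX.

Within a genome pair the anchor set is processed per chromosome pair and
per orientation (subject ranks ascending or descending with query rank);
blocks are extracted greedily by descending chain score with used anchors
removed, so no anchor appears in two blocks of the same genome pair.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, NamedTuple, Sequence

import pandas as pd


class GeneLocus(NamedTuple):
    """A gene's position: genome, chromosome and 0-based order rank."""

    gene_id: str
    species: str
    chromosome: str
    rank: int


@dataclass(frozen=True)
class CollinearBlock:
    """One collinear block: an orientation-consistent chain of anchors."""

    block_id: int
    species_pair: tuple[str, str]
    chrom_pair: tuple[str, str]
    orientation: str  # "ascending" | "descending"
    anchors: tuple[tuple[GeneLocus, GeneLocus], ...]
    score: float

    def gene_pairs(self) -> list[tuple[str, str]]:
        return [(a.gene_id, b.gene_id) for a, b in self.anchors]


def count_proteome_comparisons(n_genomes: int) -> int:
    """Number of whole-proteome comparisons for an all-vs-all run.

    Each proteome is used as a query against every proteome, itself
    included, so the directed comparisons number n(n-1) + n = n²
    (for 52 genomes: 52 × 51 + 52 = 2704 blastp tables).
    """
    if n_genomes < 1:
        raise ValueError("n_genomes must be >= 1")
    return n_genomes * (n_genomes - 1) + n_genomes


def loci_from_genomes(genomes) -> dict[str, GeneLocus]:
    """Locus table from a :class:`~synnet.simulate.SyntheticGenomeSet`."""
    loci: dict[str, GeneLocus] = {}
    for sp in genomes.species():
        for chrom, genes in genomes.genomes[sp].items():
            for rank, gene in enumerate(genes):
                loci[gene] = GeneLocus(gene, sp, chrom, rank)
    return loci


def filter_top_hits(hits: pd.DataFrame, loci: Mapping[str, GeneLocus],
                    k: int = 5) -> pd.DataFrame:
    """Keep the top-``k`` non-self hits per (query, target genome).

    Self-hits (query == subject) are dropped first. Ties are broken by
    score descending, then e-value ascending, then subject id, so the
    result is a deterministic function of the input.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if hits.empty:
        return hits.iloc[0:0].copy()
    out = hits.loc[hits["query"] != hits["subject"]].copy()
    if out.empty:
        return out
    missing = set(out["query"]).union(out["subject"]) - set(loci)
    if missing:
        raise KeyError(f"hit references unknown gene id: {sorted(missing)[0]}")
    out["_tsp"] = out["subject"].map(lambda g: loci[g].species)
    out = out.sort_values(["query", "_tsp", "score", "evalue", "subject"],
                          ascending=[True, True, False, True, True],
                          kind="mergesort")
    out = out.groupby(["query", "_tsp"], sort=False).head(k)
    return out.drop(columns="_tsp").reset_index(drop=True)


# ---------------------------------------------------------------------------
# tandem arrays


def collapse_tandem_arrays(hits: pd.DataFrame, loci: Mapping[str, GeneLocus],
                           max_tandem_gap: int = 1
                           ) -> tuple[pd.DataFrame, list[tuple[str, list[str]]]]:
    """Collapse tandem arrays onto a single representative gene.

    Genes on the same chromosome within ``max_tandem_gap`` ranks of each
    other that hit each other in both directions are grouped transitively
    into an array. The member with the highest self-proteome hit score
    (ties: lexicographically smallest id) represents the array; all hits of
    array members are remapped onto the representative, self-hits created by
    the remap are dropped and duplicates keep the best score.

    Returns the remapped hit table and the array table as
    (representative, sorted members) pairs for arrays of size >= 2.
    """
    if hits.empty:
        return hits.copy(), []
    pair_set = set(zip(hits["query"], hits["subject"]))
    self_score: dict[str, float] = {}
    sel = hits["query"] == hits["subject"]
    for q, s in zip(hits.loc[sel, "query"], hits.loc[sel, "score"]):
        self_score[q] = max(self_score.get(q, float("-inf")), float(s))

    parent: dict[str, str] = {}

    def find(x: str) -> str:
        while parent.get(x, x) != x:
            parent[x] = parent.get(parent[x], parent[x])
            x = parent[x]
        return x

    def union(a: str, b: str) -> None:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[max(ra, rb)] = min(ra, rb)

    by_chrom: dict[tuple[str, str], list[GeneLocus]] = {}
    for loc in loci.values():
        by_chrom.setdefault((loc.species, loc.chromosome), []).append(loc)
    for locs in by_chrom.values():
        locs.sort(key=lambda l: l.rank)
        for i, a in enumerate(locs):
            for b in locs[i + 1:]:
                if b.rank - a.rank > max_tandem_gap:
                    break
                if ((a.gene_id, b.gene_id) in pair_set
                        and (b.gene_id, a.gene_id) in pair_set):
                    union(a.gene_id, b.gene_id)

    groups: dict[str, list[str]] = {}
    for g in parent:
        groups.setdefault(find(g), []).append(g)
    arrays: list[tuple[str, list[str]]] = []
    remap: dict[str, str] = {}
    for root, members in sorted(groups.items()):
        members = sorted(set(members) | {root})
        if len(members) < 2:
            continue
        rep = max(members,
                  key=lambda g: (self_score.get(g, float("-inf")),
                                 [-ord(c) for c in g]))
        arrays.append((rep, members))
        for m in members:
            remap[m] = rep

    if not remap:
        return hits.copy(), []
    out = hits.copy()
    out["query"] = out["query"].map(lambda g: remap.get(g, g))
    out["subject"] = out["subject"].map(lambda g: remap.get(g, g))
    # drop self-hits created by the remap; keep genuine self-hits
    was_self = (hits["query"] == hits["subject"]).to_numpy()
    keep = ~(~was_self & (out["query"] == out["subject"]).to_numpy())
    out = out.loc[keep]
    out = (out.sort_values("score", ascending=False, kind="mergesort")
              .drop_duplicates(["query", "subject"], keep="first")
              .sort_index().reset_index(drop=True))
    return out, arrays


# ---------------------------------------------------------------------------
# chaining DP


def _anchor_sets(hits: pd.DataFrame, loci: Mapping[str, GeneLocus]
                 ) -> dict[tuple, list[tuple[int, int, str, str]]]:
    """Deduplicated anchors keyed by (species pair, chrom pair).

    Anchors are oriented so the query side belongs to the lexicographically
    smaller species; intra-genome anchors are canonicalised to (lower locus,
    higher locus) and self-pairs dropped, so each unordered gene pair yields
    one anchor.
    """
    missing = set(hits["query"]).union(hits["subject"]) - set(loci)
    if missing:
        raise KeyError(f"hit references unknown gene id: {sorted(missing)[0]}")
    anchors: dict[tuple, set[tuple[int, int, str, str]]] = {}
    for q, s in zip(hits["query"], hits["subject"]):
        if q == s:
            continue
        a, b = loci[q], loci[s]
        if (a.species, a.chromosome, a.rank) > (b.species, b.chromosome, b.rank):
            a, b = b, a
        key = ((a.species, b.species), (a.chromosome, b.chromosome))
        anchors.setdefault(key, set()).add((a.rank, b.rank, a.gene_id, b.gene_id))
    return {k: sorted(v) for k, v in anchors.items()}


def _chain_dp(anchors: list[tuple[int, int]], sign: int, min_anchors: int,
              max_gap: int, match_score: float, gap_penalty: float
              ) -> tuple[float, list[int]] | None:
    """Best chain with >= min_anchors anchors for one orientation.

    ``anchors`` are (qrank, srank) sorted ascending; ``sign`` +1 chains
    subject ranks ascending, -1 descending. The DP carries a length-capped
    second dimension so a long valid chain is found even when a shorter
    chain scores higher. Returns (score, anchor indices) or None.
    """
    n = len(anchors)
    m = min_anchors
    NEG = float("-inf")
    # dp[i][l]: best score of a chain ending at i whose length, capped at m,
    # is l+1; back[i][l] = (j, lj) predecessor.
    dp = [[NEG] * m for _ in range(n)]
    back: list[list[tuple[int, int] | None]] = [[None] * m for _ in range(n)]
    for i in range(n):
        qi, si = anchors[i]
        dp[i][0] = match_score
        for j in range(i - 1, -1, -1):
            qj, sj = anchors[j]
            dq = qi - qj
            if dq > max_gap:
                break
            ds = (si - sj) * sign
            if dq <= 0 or ds <= 0 or ds > max_gap:
                continue
            step = match_score + gap_penalty * ((dq - 1) + (ds - 1))
            for l in range(m):
                if dp[j][l] == NEG:
                    continue
                nl = min(l + 1, m - 1)
                cand = dp[j][l] + step
                if cand > dp[i][nl]:
                    dp[i][nl] = cand
                    back[i][nl] = (j, l)
    best: tuple[float, int] | None = None
    for i in range(n):
        if dp[i][m - 1] != NEG:
            if best is None or dp[i][m - 1] > best[0]:
                best = (dp[i][m - 1], i)
    if best is None:
        return None
    score, i = best
    chain: list[int] = []
    l = m - 1
    while True:
        chain.append(i)
        prev = back[i][l]
        if prev is None:
            break
        i, l = prev
    chain.reverse()
    return score, chain


def chain_collinear_blocks(hits: pd.DataFrame, loci: Mapping[str, GeneLocus],
                           min_anchors: int = 5, max_gap: int = 25,
                           match_score: float = 50.0,
                           gap_penalty: float = -1.0) -> list[CollinearBlock]:
    """Chain filtered homology hits into collinear blocks.

    Per genome pair and chromosome pair, anchors sorted by query rank are
    chained by a DP in both orientations; extending from anchor i to j
    requires 0 < Δquery_rank <= max_gap and 0 < |Δsubject_rank| <= max_gap
    with a consistent subject-rank sign. Chain score is
    Σ match_score + gap_penalty × Σ((Δq−1) + (|Δs|−1)). Chains with
    >= min_anchors anchors are reported greedily by descending score, used
    anchors removed, until none remains. Deterministic: block ids follow the
    sorted (species pair, chromosome pair) iteration order.
    """
    blocks: list[CollinearBlock] = []
    if hits.empty:
        return blocks
    anchor_sets = _anchor_sets(hits, loci)
    block_id = 0
    for key in sorted(anchor_sets):
        (sp_pair, chrom_pair) = key
        remaining = list(anchor_sets[key])
        if sp_pair[0] == sp_pair[1] and chrom_pair[0] == chrom_pair[1]:
            # self chromosome comparison: the canonicalised (low, high)
            # anchors already exclude the trivial self-diagonal
            pass
        while len(remaining) >= min_anchors:
            cands = []
            coords = [(a[0], a[1]) for a in remaining]
            for sign, orient in ((1, "ascending"), (-1, "descending")):
                res = _chain_dp(coords, sign, min_anchors, max_gap,
                                match_score, gap_penalty)
                if res is not None:
                    cands.append((res[0], orient, res[1]))
            if not cands:
                break
            cands.sort(key=lambda c: (-c[0], c[1]))
            score, orient, idx = cands[0]
            chosen = [remaining[i] for i in idx]
            anchors = tuple(
                (loci[qg], loci[sg]) for (_, _, qg, sg) in chosen)
            blocks.append(CollinearBlock(
                block_id=block_id, species_pair=sp_pair,
                chrom_pair=chrom_pair, orientation=orient,
                anchors=anchors, score=score))
            block_id += 1
            used = set(idx)
            remaining = [a for i, a in enumerate(remaining) if i not in used]
    return blocks


def blocks_to_frame(blocks: Sequence[CollinearBlock]) -> pd.DataFrame:
    """Long-format anchor table (one row per anchor pair)."""
    rows = []
    for b in blocks:
        for qa, sa in b.anchors:
            rows.append({
                "block_id": b.block_id, "orientation": b.orientation,
                "score": b.score,
                "species_a": qa.species, "chrom_a": qa.chromosome,
                "rank_a": qa.rank, "gene_a": qa.gene_id,
                "species_b": sa.species, "chrom_b": sa.chromosome,
                "rank_b": sa.rank, "gene_b": sa.gene_id,
            })
    cols = ["block_id", "orientation", "score", "species_a", "chrom_a",
            "rank_a", "gene_a", "species_b", "chrom_b", "rank_b", "gene_b"]
    return pd.DataFrame(rows, columns=cols)


def write_collinearity(blocks: Sequence[CollinearBlock], path) -> None:
    """MCScanX-style collinearity text file."""
    with open(path, "w") as fh:
        fh.write("############### collinear blocks ###############\n")
        for b in blocks:
            sp = f"{b.species_pair[0]}&{b.species_pair[1]}"
            orient = "plus" if b.orientation == "ascending" else "minus"
            fh.write(f"## Alignment {b.block_id}: score={b.score:.1f} "
                     f"e_value=0 N={len(b.anchors)} {sp} "
                     f"{b.chrom_pair[0]}&{b.chrom_pair[1]} {orient}\n")
            for i, (qa, sa) in enumerate(b.anchors):
                fh.write(f"{b.block_id}-{i}:\t{qa.gene_id}\t{sa.gene_id}\t0\n")
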