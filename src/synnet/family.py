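"""Gene-family membership, alignment trimming and group classification.

Family membership follows the two-signature-domain rule: a gene is a member
iff its domain annotation contains every required domain (for the auxin
response factors: the B3 DNA-binding domain PF02362 and the Auxin-response
domain PF06507). Genes carrying some but not all required domains are
"partial" — candidates for truncated-syntelog labelling downstream.

Alignment columns are trimmed by the >20%-gap rule; unlabelled or truncated
genes are assigned a group by their best-scoring global pairwise alignment
to classified reference genes.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import pandas as pd
from Bio import Align

Alignment = dict[str, str]

UNCLASSIFIED = "unclassified"


def _domains_of(value) -> frozenset:
    if isinstance(value, str):
        parts = [p for p in value.replace(";", ",").split(",") if p.strip()]
        return frozenset(p.strip() for p in parts)
    return frozenset(value)


def identify_family_members(domain_table: pd.DataFrame,
                            required_domains: Iterable[str],
                            ) -> tuple[set[str], set[str]]:
    """Split genes into full members and partial (truncated) candidates.

    ``members`` hold every required domain; ``partial`` hold at least one
    but not all; genes with none of the required domains appear in neither.
    The two sets are disjoint by construction.
    """
    required = frozenset(required_domains)
    if not required:
        raise ValueError("required_domains must be nonempty")
    members: set[str] = set()
    partial: set[str] = set()
    if len(domain_table) == 0:
        return members, partial
    for gene, doms in zip(domain_table["gene_id"], domain_table["domains"]):
        have = _domains_of(doms) & required
        if have == required:
            members.add(gene)
        elif have:
            partial.add(gene)
    return members, partial


def trim_alignment_columns(aln: Alignment, max_gap_fraction: float = 0.20,
                           gap_char: str = "-") -> Alignment:
    """Drop alignment columns whose gap fraction exceeds the threshold.

    A column is kept iff gaps/rows <= max_gap_fraction, i.e. a column with
    strictly more than 20% gaps (at the default) is removed and one with
    exactly 20% is retained. Row order is preserved; the gap denominator is
    the full row count, fully-gapped rows included.
    """
    if not aln:
        raise ValueError("empty alignment")
    lengths = {len(s) for s in aln.values()}
    if len(lengths) != 1:
        raise ValueError(f"unequal row lengths: {sorted(lengths)}")
    (ncol,) = lengths
    nrow = len(aln)
    rows = list(aln.values())
    keep = [c for c in range(ncol)
            if sum(r[c] == gap_char for r in rows) / nrow <= max_gap_fraction]
    return {name: "".join(seq[c] for c in keep) for name, seq in aln.items()}


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = -1.0
    aligner.open_gap_score = -2.0
    aligner.extend_gap_score = -0.5
    return aligner


def _identity(alignment) -> float:
    a, b = alignment[0], alignment[1]
    n = len(a)
    if n == 0:
        return 0.0
    same = sum(1 for x, y in zip(a, b) if x == y and x != "-")
    return same / n


def classify_by_reference(queries: Mapping[str, str],
                          references: Mapping[str, tuple[str, str]],
                          min_identity: float = 0.3) -> dict[str, str]:
    """Label each query with the group of its best-aligning reference.

    ``references`` maps reference id → (sequence, group label). Scoring is
    a global pairwise alignment (match +1 / mismatch −1, gap open −2,
    extend −0.5); the winner is chosen by (score descending, reference id
    ascending) so ties resolve deterministically. Queries whose best
    alignment falls below ``min_identity`` fraction of identical aligned
    positions are labelled ``"unclassified"``.
    """
    if not references:
        raise ValueError("references must be nonempty")
    aligner = _make_aligner()
    out: dict[str, str] = {}
    ref_items = sorted(references.items())
    for qid, qseq in queries.items():
        best: tuple[float, str, str, float] | None = None
        for rid, (rseq, group) in ref_items:
            alns = aligner.align(qseq, rseq)
            score = alns.score
            if best is None or score > best[0]:
                best = (score, rid, group, _identity(alns[0]))
        assert best is not None
        out[qid] = best[2] if best[3] >= min_identity else UNCLASSIFIED
    return out
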