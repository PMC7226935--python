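"""Readers and writers for the pipeline's standard file formats.

Gene orders travel as BED (one file per genome; rank encoded as
start = rank × 1000), homology hits as 12-column blast outfmt-6 tables,
domain annotations as a 2-column TSV, sequences as FASTA (via biopython),
species/gene trees as newick (via dendropy) and the event log, lineage map
and classification tables as plain TSV.
"""

from __future__ import annotations

import os
from pathlib import Path
from typing import Iterable, Mapping

import dendropy
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .collinearity import GeneLocus

RANK_SPACING = 1000


# ---------------------------------------------------------------------------
# BED gene orders


def write_bed(genomes, out_dir) -> dict[str, Path]:
    """One BED file per genome: chrom, start, end, gene id (rank order)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for sp in genomes.species():
        path = out_dir / f"{sp}.bed"
        with open(path, "w") as fh:
            for chrom, genes in genomes.genomes[sp].items():
                for rank, gene in enumerate(genes):
                    start = rank * RANK_SPACING
                    fh.write(f"{chrom}\t{start}\t{start + RANK_SPACING - 1}"
                             f"\t{gene}\n")
        paths[sp] = path
    return paths


def read_bed(paths: Mapping[str, os.PathLike | str]) -> dict[str, GeneLocus]:
    """Locus table from per-species BED files (ranks from sorted starts)."""
    loci: dict[str, GeneLocus] = {}
    for sp, path in sorted(paths.items()):
        rows: list[tuple[str, int, str]] = []
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                parts = line.split("\t")
                if len(parts) < 4:
                    raise ValueError(f"{path}:{lineno}: BED needs >=4 columns")
                try:
                    start = int(parts[1])
                except ValueError:
                    raise ValueError(
                        f"{path}:{lineno}: non-integer start {parts[1]!r}")
                rows.append((parts[0], start, parts[3]))
        rows.sort(key=lambda r: (r[0], r[1]))
        rank = 0
        prev_chrom = None
        for chrom, _, gene in rows:
            if chrom != prev_chrom:
                rank = 0
                prev_chrom = chrom
            loci[gene] = GeneLocus(gene, sp, chrom, rank)
            rank += 1
    return loci


def read_bed_dir(directory) -> dict[str, GeneLocus]:
    """All ``<species>.bed`` files in a directory."""
    directory = Path(directory)
    paths = {p.stem: p for p in sorted(directory.glob("*.bed"))}
    if not paths:
        raise ValueError(f"no .bed files in {directory}")
    return read_bed(paths)


def read_gff3(paths: Mapping[str, os.PathLike | str]) -> dict[str, GeneLocus]:
    """Locus table from per-species GFF3 (type ``gene``, ID attribute)."""
    loci: dict[str, GeneLocus] = {}
    for sp, path in sorted(paths.items()):
        rows: list[tuple[str, int, str]] = []
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) != 9:
                    raise ValueError(f"{path}:{lineno}: GFF3 needs 9 columns")
                if parts[2] != "gene":
                    continue
                attrs = dict(kv.split("=", 1) for kv in parts[8].split(";")
                             if "=" in kv)
                if "ID" not in attrs:
                    raise ValueError(f"{path}:{lineno}: gene without ID")
                rows.append((parts[0], int(parts[3]), attrs["ID"]))
        rows.sort(key=lambda r: (r[0], r[1]))
        rank = 0
        prev = None
        for chrom, _, gene in rows:
            if chrom != prev:
                rank, prev = 0, chrom
            loci[gene] = GeneLocus(gene, sp, chrom, rank)
            rank += 1
    return loci


# ---------------------------------------------------------------------------
# blast outfmt-6 hit tables

OUTFMT6_COLUMNS = ["qseqid", "sseqid", "pident", "length", "mismatch",
                   "gapopen", "qstart", "qend", "sstart", "send",
                   "evalue", "bitscore"]


def write_hits(hits: pd.DataFrame, path, aln_length: int = 100) -> None:
    """Write hits as a 12-column blast outfmt-6 table.

    Positional columns are synthetic placeholders; downstream consumers use
    only query, subject, e-value and bitscore.
    """
    df = pd.DataFrame({
        "qseqid": hits["query"], "sseqid": hits["subject"],
        "pident": (hits["score"] / hits["score"].max() * 100).round(2),
        "length": aln_length, "mismatch": 0, "gapopen": 0,
        "qstart": 1, "qend": aln_length, "sstart": 1, "send": aln_length,
        "evalue": hits["evalue"].map(lambda e: f"{e:.3g}"),
        "bitscore": hits["score"].round(1),
    })
    df.to_csv(path, sep="\t", header=False, index=False)


def read_hits(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, names=OUTFMT6_COLUMNS,
                     dtype={"qseqid": str, "sseqid": str})
    if df.shape[1] != 12:
        raise ValueError(f"{path}: expected 12 columns, got {df.shape[1]}")
    return pd.DataFrame({"query": df["qseqid"], "subject": df["sseqid"],
                         "score": df["bitscore"].astype(float),
                         "evalue": df["evalue"].astype(float)})


# ---------------------------------------------------------------------------
# domain tables


def write_domain_table(table: pd.DataFrame, path) -> None:
    """2-column TSV: gene id, comma-joined domain accessions."""
    with open(path, "w") as fh:
        for gene, doms in zip(table["gene_id"], table["domains"]):
            joined = ",".join(doms) if not isinstance(doms, str) else doms
            fh.write(f"{gene}\t{joined}\n")


def read_domain_table(path) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) == 1:
                parts.append("")
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected 2 columns")
            doms = tuple(d for d in parts[1].split(",") if d)
            rows.append({"gene_id": parts[0], "domains": doms})
    return pd.DataFrame(rows, columns=["gene_id", "domains"])


# ---------------------------------------------------------------------------
# FASTA


def write_fasta(seqs: Mapping[str, str], path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="")
               for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


# ---------------------------------------------------------------------------
# trees and tables


def write_tree(tree: dendropy.Tree, path) -> None:
    with open(path, "w") as fh:
        fh.write(tree.as_string(schema="newick",
                                suppress_rooting=True).strip() + "\n")


def read_tree(path) -> dendropy.Tree:
    tree = dendropy.Tree.get(path=str(path), schema="newick",
                             suppress_internal_node_taxa=True,
                             preserve_underscores=True)
    tree.is_rooted = True
    return tree


def write_event_log(log, path) -> None:
    log.to_frame().to_csv(path, sep="\t", index=False)


def write_lineage_map(lineages, path) -> None:
    lineages.to_frame().to_csv(path, sep="\t", index=False)


def read_lineage_map(path):
    from .events import LineageMap
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    parent = {r.lineage: r.parent for r in df.itertuples(index=False)
              if r.parent}
    return LineageMap({r.species: r.lineage
                       for r in df.itertuples(index=False)}, parent)


def write_members_table(members: set, partial: set, groups: Mapping[str, str],
                        path) -> None:
    rows = ([{"gene_id": g, "status": "member",
              "group": groups.get(g, "unclassified")} for g in sorted(members)]
            + [{"gene_id": g, "status": "partial",
                "group": groups.get(g, "unclassified")}
               for g in sorted(partial)])
    pd.DataFrame(rows, columns=["gene_id", "status", "group"]).to_csv(
        path, sep="\t", index=False)


def read_members_table(path) -> tuple[set, set, dict[str, str]]:
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    members = set(df.loc[df["status"] == "member", "gene_id"])
    partial = set(df.loc[df["status"] == "partial", "gene_id"])
    groups = {r.gene_id: r.group for r in df.itertuples(index=False)
              if r.group and r.group != "unclassified"}
    return members, partial, groups
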