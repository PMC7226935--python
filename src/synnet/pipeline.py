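"""End-to-end pipeline: simulate → annotate → synteny → network →
communities → events, as one configured, logged, seeded run.

Every stage writes its intermediate artifacts into the output directory and
contributes counts to a run manifest. The manifest is a pure function of
(inputs, config, seed): timings go to the log, never into the manifest, so
identical runs produce byte-identical ``manifest.json`` files.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import pandas as pd
import yaml

from . import collinearity as coll
from . import communities as comm
from . import events as ev
from . import family as fam
from . import io as sio
from . import network as net
from . import phylo
from . import simulate as sim

logger = logging.getLogger(__name__)

_DEFAULT_DOMAINS = sim.SIGNATURE_DOMAINS


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    """All stage parameters of one run, validated before any stage starts.

    With ``inputs`` unset the run starts from the simulator; otherwise
    ``inputs`` maps input kinds to paths (``bed_dir``, ``hits``,
    ``domains``; optional ``fasta``, ``tree``, ``lineages``, ``groups``).
    """

    # simulator
    n_species: int = 8
    sim: sim.SimParams = field(default_factory=sim.SimParams)
    forced_events: list = field(default_factory=list)
    # external inputs (disable the simulator when set)
    inputs: dict | None = None
    # stage parameters
    k_hits: int = 5
    min_anchors: int = 5
    max_gap: int = 25
    match_score: float = 50.0
    gap_penalty: float = -1.0
    collapse_tandems: bool = True
    max_tandem_gap: int = 1
    cpm_k: int = 3
    max_gap_fraction: float = 0.20
    min_identity: float = 0.3
    min_support: float = 80.0
    min_community_size: int = 4
    max_lineage_clade: int = 3
    outgroup: str | None = None
    required_domains: tuple = _DEFAULT_DOMAINS
    seed: int = 0
    out_dir: str = "synnet_out"
    log_level: str = "INFO"

    def validate(self) -> None:
        if self.inputs is None and self.n_species < 2:
            raise ValueError("n_species must be >= 2")
        if self.k_hits < 1:
            raise ValueError("k_hits must be >= 1")
        if self.min_anchors < 1:
            raise ValueError("min_anchors must be >= 1")
        if self.max_gap < 1:
            raise ValueError("max_gap must be >= 1")
        if self.cpm_k < 3:
            raise ValueError("cpm_k must be >= 3")
        if not 0 <= self.max_gap_fraction <= 1:
            raise ValueError("max_gap_fraction must be in [0, 1]")
        if self.min_community_size < 2:
            raise ValueError("min_community_size must be >= 2")
        self.sim.validate()

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["sim"] = dataclasses.asdict(self.sim)
        d["required_domains"] = list(self.required_domains)
        d["forced_events"] = [dataclasses.asdict(fe) if not isinstance(fe, dict)
                              else fe for fe in self.forced_events]
        return d

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "PipelineConfig":
        d = dict(d)
        simd = d.pop("sim", {})
        if isinstance(simd, sim.SimParams):
            params = simd
        else:
            simd = dict(simd)
            if "group_labels" in simd:
                simd["group_labels"] = tuple(simd["group_labels"])
            params = sim.SimParams(**simd)
        fes = []
        for fe in d.pop("forced_events", []):
            if isinstance(fe, sim.ForcedEvent):
                fes.append(fe)
            else:
                fe = dict(fe)
                fe["clade"] = tuple(fe["clade"])
                fes.append(sim.ForcedEvent(**fe))
        if "required_domains" in d:
            d["required_domains"] = tuple(d["required_domains"])
        cfg = cls(sim=params, forced_events=fes, **d)
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            t0 = time.perf_counter()
            logger.info("stage %s: start", name)
            try:
                out = fn(*args, **kwargs)
            except Exception as exc:
                raise StageError(f"stage {name!r} failed: {exc}") from exc
            logger.info("stage %s: done in %.2fs", name,
                        time.perf_counter() - t0)
            return out
        return wrapped
    return deco


def run_pipeline(config: PipelineConfig, resume: bool = False) -> dict:
    """Execute all stages and return (and write) the run manifest.

    With ``resume=True`` an existing manifest whose parameter echo matches
    the current config is returned as-is, skipping recomputation.
    """
    config.validate()
    logging.basicConfig(level=getattr(logging, config.log_level.upper(),
                                      logging.INFO))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest_path = out / "manifest.json"
    config_echo = config.to_dict()
    if resume and manifest_path.exists():
        with open(manifest_path) as fh:
            prior = json.load(fh)
        if prior.get("config") == json.loads(json.dumps(config_echo)):
            logger.info("resume: manifest matches config, skipping run")
            return prior

    files: list[str] = []

    def record(path: Path) -> Path:
        files.append(str(path.relative_to(out)))
        return path

    # ----- stage: inputs (simulate or load) --------------------------------
    @_stage("simulate")
    def stage_inputs():
        if config.inputs is not None:
            loci = sio.read_bed_dir(config.inputs["bed_dir"])
            hits = sio.read_hits(config.inputs["hits"])
            domains = sio.read_domain_table(config.inputs["domains"])
            seqs = (sio.read_fasta(config.inputs["fasta"])
                    if config.inputs.get("fasta") else {})
            species_tree = (sio.read_tree(config.inputs["tree"])
                            if config.inputs.get("tree") else None)
            lineages = (sio.read_lineage_map(config.inputs["lineages"])
                        if config.inputs.get("lineages") else None)
            groups: dict[str, str] = {}
            if config.inputs.get("groups"):
                df = pd.read_csv(config.inputs["groups"], sep="\t", dtype=str)
                groups = dict(zip(df.iloc[:, 0], df.iloc[:, 1]))
            return (loci, hits, domains, seqs, species_tree, lineages,
                    groups, None, None)
        params = dataclasses.replace(config.sim, seed=config.seed)
        species_tree = sim.simulate_species_tree(config.n_species,
                                                 config.seed)
        genomes, event_log = sim.evolve_genomes(species_tree, params,
                                                config.forced_events)
        hits = sim.emit_homology_hits(genomes, params)
        domains = sim.emit_domain_table(genomes, config.required_domains,
                                        seed=params.seed)
        seqs = sim.emit_sequences(genomes, species_tree, params)
        loci = coll.loci_from_genomes(genomes)
        lineages = ev.lineages_from_tree(species_tree,
                                         config.max_lineage_clade)
        groups = {g: genomes.true_group[g]
                  for g in genomes.true_group if genomes.true_group[g]}
        # write the simulated inputs in their standard formats
        sio.write_bed(genomes, out / "genomes")
        for sp in genomes.species():
            record(out / "genomes" / f"{sp}.bed")
        sio.write_hits(hits, record(out / "hits.tsv"))
        sio.write_domain_table(domains, record(out / "domains.tsv"))
        if seqs:
            sio.write_fasta(seqs, record(out / "family.fasta"))
        sio.write_tree(species_tree, record(out / "species_tree.nwk"))
        sio.write_event_log(event_log, record(out / "event_log.tsv"))
        sio.write_lineage_map(lineages, record(out / "lineages.tsv"))
        return (loci, hits, domains, seqs, species_tree, lineages, groups,
                genomes, event_log)

    (loci, hits, domains, seqs, species_tree, lineages, groups, genomes,
     event_log) = stage_inputs()

    # ----- stage: annotate -------------------------------------------------
    @_stage("annotate")
    def stage_annotate():
        members, partial = fam.identify_family_members(
            domains, config.required_domains)
        sio.write_members_table(members, partial, groups,
                                record(out / "family_members.tsv"))
        return members, partial

    members, partial = stage_annotate()

    # ----- stage: synteny --------------------------------------------------
    @_stage("synteny")
    def stage_synteny():
        filtered = coll.filter_top_hits(hits, loci, config.k_hits)
        arrays: list = []
        if config.collapse_tandems:
            filtered, arrays = coll.collapse_tandem_arrays(
                filtered, loci, config.max_tandem_gap)
        blocks = coll.chain_collinear_blocks(
            filtered, loci, config.min_anchors, config.max_gap,
            config.match_score, config.gap_penalty)
        coll.write_collinearity(blocks, record(out / "collinearity.txt"))
        coll.blocks_to_frame(blocks).to_csv(
            record(out / "anchors.tsv"), sep="\t", index=False)
        pd.DataFrame(
            [{"representative": rep, "members": ",".join(ms)}
             for rep, ms in arrays],
            columns=["representative", "members"]).to_csv(
            record(out / "tandem_arrays.tsv"), sep="\t", index=False)
        return filtered, arrays, blocks

    filtered, arrays, blocks = stage_synteny()

    # ----- stage: network --------------------------------------------------
    @_stage("network")
    def stage_network():
        truncated = net.detect_truncated_syntelogs(blocks, members, partial)
        truncated_ids = {r.gene_id for r in truncated}
        # classify truncated syntelogs against member sequences
        all_groups = dict(groups)
        if seqs and truncated_ids:
            refs = {g: (seqs[g], all_groups[g]) for g in sorted(members)
                    if g in seqs and g in all_groups}
            queries = {g: seqs[g] for g in sorted(truncated_ids)
                       if g in seqs}
            if refs and queries:
                all_groups.update(fam.classify_by_reference(
                    queries, refs, config.min_identity))
        species_of = {g: l.species for g, l in loci.items()}
        statuses = {g: "member" for g in members}
        statuses.update({g: "truncated" for g in truncated_ids})
        G = net.build_family_synteny_network(
            blocks, members | truncated_ids, species=species_of,
            groups=all_groups, statuses=statuses)
        frac = net.syntenic_fraction(members, G) if members else 0.0
        matrix, inter = net.intergroup_edge_summary(G)
        net.export_network(G, record(out / "network_edges.tsv"), "edgelist")
        net.export_network(G, record(out / "network.graphml"), "graphml")
        net.syntelog_report(G).to_csv(
            record(out / "syntelog_report.tsv"), sep="\t", index=False)
        matrix.to_csv(record(out / "intergroup_matrix.tsv"), sep="\t")
        return G, truncated, frac, inter, all_groups

    G, truncated, frac, inter, all_groups = stage_network()

    # ----- stage: communities ----------------------------------------------
    @_stage("communities")
    def stage_communities():
        comms = comm.clique_percolation(G, config.cpm_k)
        coverage = (comm.community_coverage(comms, G)
                    if G.number_of_nodes() else 0.0)
        comm.membership_table(comms, G).to_csv(
            record(out / "communities.tsv"), sep="\t", index=False)
        comm.composition_matrix(comms, G).to_csv(
            record(out / "composition_matrix.tsv"), sep="\t")
        comm.community_summary(comms, G).to_csv(
            record(out / "community_summary.tsv"), sep="\t", index=False)
        return comms, coverage

    comms, coverage = stage_communities()

    # ----- stage: events ---------------------------------------------------
    @_stage("events")
    def stage_events():
        calls: list[ev.EventCall] = []
        gene_tree = None
        member_seqs = {g: seqs[g] for g in sorted(members) if g in seqs}
        if len(member_seqs) >= 3:
            D = phylo.p_distance_matrix(member_seqs)
            gene_tree = phylo.nj_tree(D)
            gene_tree.species_map = {
                g: loci[g].species for g in member_seqs if g in loci}
            gene_tree.group_map = {g: all_groups.get(g, "unclassified")
                                   for g in member_seqs}
            with open(record(out / "gene_tree.nwk"), "w") as fh:
                fh.write(phylo.write_newick(gene_tree))
            rooted = (phylo.root_with_outgroup(gene_tree, config.outgroup)
                      if config.outgroup else phylo.root_at_midpoint(gene_tree))
            calls.extend(ev.infer_duplications(rooted, config.min_support))
            if lineages is not None:
                calls.extend(ev.call_transpositions(
                    comms, G, gene_tree, lineages,
                    config.min_community_size))
        calls.extend(ev.flag_ancient_tandem(comms, G))
        ev.events_to_frame(calls).to_csv(
            record(out / "event_calls.tsv"), sep="\t", index=False)
        if gene_tree is not None:
            ev.write_itol_connections(G, comms,
                                      record(out / "itol_connections.txt"))
        return calls

    calls = stage_events()

    n_dup = sum(1 for c in calls if c.kind == "duplication")
    n_tra = [c for c in calls if c.kind == "transposition"]
    n_tan = sum(1 for c in calls if c.kind == "ancient_tandem")
    manifest = {
        "config": json.loads(json.dumps(config_echo)),
        "files": sorted(files),
        "counts": {
            "genes_total": len(loci),
            "members": len(members),
            "partial": len(partial),
            "truncated_syntelogs": len(truncated),
            "tandem_arrays": len(arrays),
            "blocks": len(blocks),
            "network_nodes": G.number_of_nodes(),
            "network_edges": G.number_of_edges(),
            "raw_anchor_pairs": G.graph.get("raw_anchor_pairs", 0),
            "syntenic_fraction_pct": net.pct(
                sum(1 for m in members if G.has_node(m)), len(members))
            if members else 0.0,
            "intergroup_edges": inter,
            "communities": len(comms),
            "community_coverage_pct": net.pct(
                len(set().union(*(c.nodes for c in comms)) & set(G.nodes)),
                G.number_of_nodes()) if comms and G.number_of_nodes() else 0.0,
            "duplication_calls": n_dup,
            "transposition_calls": len(n_tra),
            "transposition_lineages": sorted(c.scope for c in n_tra),
            "ancient_tandem_flags": n_tan,
        },
        "seed": config.seed,
    }
    if event_log is not None:
        manifest["counts"]["simulated_events"] = {
            kind: len(event_log.of_kind(kind)) for kind in sim.EVENT_KINDS}
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest


# ---------------------------------------------------------------------------
# input validation


def validate_inputs(paths: Mapping[str, Any]) -> pd.DataFrame:
    """Check input files for parseability; never raises, reports per file.

    ``paths`` maps kind → path (or list of paths) with kinds ``bed``,
    ``hits``, ``domains``, ``tree``, ``fasta``. Each report row carries the
    file, kind, pass/fail and, on failure, a message with a line number
    where available.
    """
    rows = []

    def check(kind: str, path) -> tuple[bool, str]:
        try:
            if kind == "bed":
                with open(path) as fh:
                    for lineno, line in enumerate(fh, 1):
                        line = line.rstrip("\n")
                        if not line or line.startswith(("#", "track")):
                            continue
                        parts = line.split("\t")
                        if len(parts) < 4:
                            return False, f"line {lineno}: <4 columns"
                        try:
                            int(parts[1]), int(parts[2])
                        except ValueError:
                            return (False,
                                    f"line {lineno}: non-integer coordinate")
            elif kind == "hits":
                with open(path) as fh:
                    for lineno, line in enumerate(fh, 1):
                        if not line.strip():
                            continue
                        n = len(line.rstrip("\n").split("\t"))
                        if n != 12:
                            return False, f"line {lineno}: {n} columns, " \
                                          "expected 12"
            elif kind == "domains":
                sio.read_domain_table(path)
            elif kind == "tree":
                sio.read_tree(path)
            elif kind == "fasta":
                if not sio.read_fasta(path):
                    return False, "no FASTA records"
            else:
                return False, f"unknown input kind {kind!r}"
            return True, ""
        except Exception as exc:
            return False, str(exc)

    for kind, value in sorted(paths.items()):
        for path in (value if isinstance(value, (list, tuple)) else [value]):
            ok, msg = check(kind, path)
            rows.append({"file": str(path), "kind": kind,
                         "ok": ok, "message": msg})
    return pd.DataFrame(rows, columns=["file", "kind", "ok", "message"])
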