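"""End-to-end orchestration: clean -> assemble -> scan -> exclude ->
fold/validate -> targets -> network, with a JSON manifest of artifacts."""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import precursor as precursor_mod
from .io import (RunConfig, SeqRecord, read_fasta, read_table, to_dna, to_rna,
                 write_fasta, write_table)
from .network import annotate_nodes, build_network, neighborhood_report
from .precursor import PrecursorCandidate, excise_and_fold, fold
from .preprocess import assemble, clean_ests, unigene_stats
from .scan import exclusion_filter, scan_unigene
from .targets import predict_targets

logger = logging.getLogger(__name__)

__all__ = ["PipelineInputs", "RunManifest", "run_all"]

HIT_SCHEMA = ["unigene_id", "mirna_ref_id", "strand", "start", "stop",
              "predicted_mature", "n_mismatch", "n_bulges", "max_bulge_size"]
# column names mirror the per-candidate feature table of the method:
# coordinates, MFEs, MFEI, arm, duplex statistics and verdict
CANDIDATE_SCHEMA = ["unigene_id", "mirna_ref_id", "strand", "precursor_start",
                    "precursor_stop", "precursor_len", "pri_mfe", "pre_mfe",
                    "amfe", "mfei", "gc_frac", "mature_arm", "duplex_mismatch",
                    "duplex_bulges", "max_bulge", "duplex_interruptions",
                    "n_flanked_bases_unpaired_duplex_ends", "star_start",
                    "star_stop", "n_homolog_mismatch", "verdict", "reasons"]
TARGET_SCHEMA = ["mirna_id", "transcript_id", "description", "start", "stop",
                 "site_seq", "total_mismatch", "max_consecutive",
                 "mismatch_positions", "inhibition"]


@dataclass
class PipelineInputs:
    ests: str | Path
    mirna_refs: str | Path
    contaminants: str | Path | None = None
    exclusion_refs: str | Path | None = None
    transcripts: str | Path | None = None
    expression: str | Path | None = None
    annotation: str | Path | None = None


@dataclass
class RunManifest:
    config: dict
    fold_engine: str = precursor_mod.FOLD_ENGINE
    stages: dict = field(default_factory=dict)
    artifacts: dict = field(default_factory=dict)
    completed: bool = False
    failed_stage: str | None = None

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=1))


def _candidate_row(c: PrecursorCandidate) -> dict:
    return {
        "unigene_id": c.hit.unigene_id,
        "mirna_ref_id": c.hit.mirna_ref_id,
        "strand": c.hit.strand,
        "precursor_start": c.start,
        "precursor_stop": c.stop,
        "precursor_len": c.stop - c.start + 1,
        "pri_mfe": c.pri_mfe,
        "pre_mfe": c.pre_mfe,
        "amfe": c.amfe,
        "mfei": c.mfei,
        "gc_frac": c.gc_frac,
        "mature_arm": c.mature_arm,
        "duplex_mismatch": c.duplex_mismatch,
        "duplex_bulges": c.duplex_bulges,
        "max_bulge": c.max_bulge,
        "duplex_interruptions": c.duplex_interruptions,
        "n_flanked_bases_unpaired_duplex_ends": c.n_flanked_bases,
        "star_start": c.star_start,
        "star_stop": c.star_stop,
        "n_homolog_mismatch": c.hit.n_mismatch,
        "verdict": "pass" if c.verdict else "fail",
        "reasons": ";".join(c.reasons),
    }


def run_all(cfg: RunConfig, inputs: PipelineInputs, outdir: str | Path) -> RunManifest:
    """Run every stage for which inputs are present; write artifacts and a
    manifest.  A stage failure is recorded in the manifest and re-raised."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=dataclasses.asdict(cfg))
    stage = "clean"
    try:
        ests = read_fasta(inputs.ests)
        refs = read_fasta(inputs.mirna_refs)
        contaminants = read_fasta(inputs.contaminants) if inputs.contaminants else []

        cleaned, report = clean_ests(ests, contaminants, cfg)
        write_fasta(cleaned, outdir / "cleaned.fasta")
        write_table([dataclasses.asdict(report)], outdir / "clean_report.tsv",
                    ["n_input", "n_discarded_short", "n_discarded_ambig",
                     "n_masked", "n_passed"])
        manifest.stages["clean"] = {"n_in": report.n_input, "n_out": report.n_passed}
        manifest.artifacts["cleaned"] = str(outdir / "cleaned.fasta")

        stage = "assemble"
        unigenes = assemble(cleaned, cfg)
        write_fasta([SeqRecord(id=u.id, seq=u.seq, description=u.kind)
                     for u in unigenes], outdir / "unigenes.fasta")
        membership = [{"unigene_id": u.id, "kind": u.kind, "est_id": m}
                      for u in unigenes for m in u.members]
        write_table(membership, outdir / "membership.tsv",
                    ["unigene_id", "kind", "est_id"])
        stats = unigene_stats(unigenes)
        write_table([stats], outdir / "unigene_stats.tsv", list(stats.keys()))
        manifest.stages["assemble"] = {"n_in": report.n_passed, "n_out": len(unigenes)}
        manifest.artifacts["unigenes"] = str(outdir / "unigenes.fasta")

        stage = "scan"
        hits = []
        for u in unigenes:
            hits.extend(scan_unigene(u, refs, cfg))
        logger.info("scan: %d unigenes x %d refs -> %d hits (<=%d mismatches)",
                    len(unigenes), len(refs), len(hits), cfg.max_mismatch_scan)
        manifest.stages["scan"] = {"n_in": len(unigenes), "n_out": len(hits)}

        stage = "exclude"
        exclusion = read_fasta(inputs.exclusion_refs) if inputs.exclusion_refs else []
        hits = exclusion_filter(hits, unigenes, exclusion,
                                cfg.exclusion_min_identity, cfg.exclusion_min_cov)
        write_table(hits, outdir / "hits.tsv", HIT_SCHEMA)
        manifest.stages["exclude"] = {"n_out": len(hits)}
        manifest.artifacts["hits"] = str(outdir / "hits.tsv")

        stage = "validate"
        by_id = {u.id: u for u in unigenes}
        candidates = []
        pri_cache: dict[str, float] = {}
        for hit in hits:
            uni = by_id[hit.unigene_id]
            if hit.unigene_id not in pri_cache:
                pri_cache[hit.unigene_id] = fold(
                    to_rna(uni.seq), cfg.fold_temperature, cfg.max_loop_size)[1]
            candidates.append(excise_and_fold(uni, hit, cfg,
                                              pri_mfe=pri_cache[hit.unigene_id]))
        write_table([_candidate_row(c) for c in candidates],
                    outdir / "candidates.tsv", CANDIDATE_SCHEMA)
        passing = [c for c in candidates if c.verdict]
        write_fasta(
            [SeqRecord(id=f"{c.hit.unigene_id}|{c.hit.mirna_ref_id}|{c.start}-{c.stop}",
                       seq=c.seq, description="validated precursor")
             for c in passing],
            outdir / "precursors.fasta")
        with (outdir / "structures.txt").open("w") as fh:
            for c in passing:
                fh.write(f">{c.hit.unigene_id}|{c.hit.mirna_ref_id}|{c.start}-{c.stop}\n"
                         f"{c.seq}\n{c.structure}\n")
        manifest.stages["validate"] = {"n_in": len(hits), "n_out": len(passing)}
        manifest.artifacts["candidates"] = str(outdir / "candidates.tsv")
        manifest.artifacts["precursors"] = str(outdir / "precursors.fasta")

        stage = "targets"
        target_rows: list[dict] = []
        if inputs.transcripts:
            transcripts = read_fasta(inputs.transcripts)
            mature_records = [
                SeqRecord(id=f"{c.hit.unigene_id}|{c.hit.mirna_ref_id}",
                          seq=to_dna(c.hit.predicted_mature))
                for c in passing
            ] or []
            sites = predict_targets(mature_records, transcripts, cfg)
            desc = {t.id: t.description for t in transcripts}
            rows = [{
                "mirna_id": s.mirna_id, "transcript_id": s.transcript_id,
                "description": desc.get(s.transcript_id, ""),
                "start": s.start, "stop": s.stop, "site_seq": s.site_seq,
                "total_mismatch": s.total_mismatch,
                "max_consecutive": s.max_consecutive,
                "mismatch_positions": ",".join(map(str, s.mismatch_positions)),
                "inhibition": s.inhibition,
            } for s in sites]
            target_rows = rows
            write_table(rows, outdir / "targets.tsv", TARGET_SCHEMA)
            manifest.stages["targets"] = {"n_mirnas": len(mature_records),
                                          "n_out": len(sites)}
            manifest.artifacts["targets"] = str(outdir / "targets.tsv")
        else:
            manifest.stages["targets"] = {"skipped": "no transcripts supplied"}

        stage = "network"
        if inputs.expression:
            expr = pd.read_csv(inputs.expression, sep="\t", index_col=0)
            seeds = {r["transcript_id"] for r in target_rows} & set(expr.index)
            graph = build_network(expr, seeds, cfg.corr_threshold, cfg.corr_mode)
            if inputs.annotation:
                graph = annotate_nodes(graph, read_table(inputs.annotation))
            edges = [{"gene_a": u, "gene_b": v, "r": d["weight"]}
                     for u, v, d in graph.edges(data=True)]
            write_table(edges, outdir / "network_edges.tsv",
                        ["gene_a", "gene_b", "r"])
            neighborhood_report(graph, seeds).to_csv(
                outdir / "network_nodes.tsv", sep="\t", index=False)
            manifest.stages["network"] = {"n_nodes": graph.number_of_nodes(),
                                          "n_edges": graph.number_of_edges()}
            manifest.artifacts["network_edges"] = str(outdir / "network_edges.tsv")
        else:
            manifest.stages["network"] = {"skipped": "no expression matrix supplied"}

        manifest.completed = True
    except Exception:
        manifest.failed_stage = stage
        manifest.to_json(outdir / "manifest.json")
        raise
    manifest.to_json(outdir / "manifest.json")
    return manifest
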