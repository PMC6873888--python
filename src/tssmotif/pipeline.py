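"""End-to-end pipeline: simulate -> call -> classify -> discover -> scan ->
re-annotate, with per-stage seeding and a JSON-serialisable report.

Every stage writes its output to disk, so any downstream stage can be
re-entered from the files alone. The global seed is fanned out per stage
through a stable hash of the stage name, making stages independently
reproducible.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
import time
import zlib
from dataclasses import dataclass, field

from . import io_formats, motif_discovery, motif_scanning, reannotation
from .io_formats import TAP_MINUS, TAP_PLUS
from .motif_discovery import DiscoveryParams
from .synthetic_data import SimulationParams, generate_genome, simulate_libraries, write_simulation
from .tss_annotation import annotate_tss, base_preference, per_gene_tss_histogram, utr_records, utr_summary
from .tss_calling import TSSCallParams, call_tss

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    outdir: str = "tssmotif_run"
    seed: int = 0
    # either simulate, or point at existing inputs
    simulate: SimulationParams | None = None
    fasta: str | None = None
    gff: str | None = None
    tap_plus_fwd: str | None = None
    tap_plus_rev: str | None = None
    tap_minus_fwd: str | None = None
    tap_minus_rev: str | None = None
    # stage parameters (defaults follow the standard analysis settings)
    call: TSSCallParams = field(default_factory=TSSCallParams)
    classify_window: int = 250
    discovery: DiscoveryParams = field(default_factory=lambda: DiscoveryParams(n_motifs=5))
    discovery_window: int = 50
    sd_window: int = 30
    sd_range: tuple[int, int] = (9, 14)
    scan_window: int = 300
    scan_p_threshold: float = 1e-4
    log_level: str = "INFO"


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2^31."""
    return (int(global_seed) * 1000003 + zlib.crc32(stage.encode())) % (2**31 - 1)


def _summary_to_json(obj):
    if dataclasses.is_dataclass(obj):
        return {k: _summary_to_json(v) for k, v in dataclasses.asdict(obj).items()}
    if hasattr(obj, "tolist"):
        return obj.tolist()
    if isinstance(obj, dict):
        return {str(k): _summary_to_json(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_summary_to_json(v) for v in obj]
    return obj


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all stages; returns the report dict (also written as JSON)."""
    logging.basicConfig(level=config.log_level)
    os.makedirs(config.outdir, exist_ok=True)
    manifest: dict = {"seed": config.seed, "stages": []}
    report: dict = {}

    def record(stage: str, t0: float, **counts):
        manifest["stages"].append(
            {"stage": stage, "wall_s": round(time.time() - t0, 3), **counts}
        )

    # --- inputs -----------------------------------------------------------
    t0 = time.time()
    if config.simulate is not None:
        sim = dataclasses.replace(config.simulate, seed=stage_seed(config.seed, "simulate"))
        genome, genes, truth = generate_genome(sim)
        tap_plus, tap_minus = simulate_libraries(
            truth, genome, sim, seed=stage_seed(config.seed, "libraries")
        )
        paths = write_simulation(config.outdir, genome, genes, truth, tap_plus, tap_minus)
        record("simulate", t0, genes=len(genes), planted_tss=len(truth.tss_list))
    else:
        genome = io_formats.read_fasta(config.fasta)
        genes = io_formats.read_gff(config.gff)
        tap_plus = io_formats.read_bedgraph_pair(
            config.tap_plus_fwd, config.tap_plus_rev, genome, TAP_PLUS
        )
        tap_minus = io_formats.read_bedgraph_pair(
            config.tap_minus_fwd, config.tap_minus_rev, genome, TAP_MINUS
        )
        record("load", t0, genes=len(genes))

    # --- TSS calling ------------------------------------------------------
    t0 = time.time()
    tss = call_tss(tap_plus, tap_minus, config.call)
    io_formats.write_tss_table(tss, os.path.join(config.outdir, "tss.tsv"))
    record("call_tss", t0, tss=len(tss))

    # --- classification and summaries -------------------------------------
    t0 = time.time()
    annotate_tss(tss, genes, window=config.classify_window)
    io_formats.write_tss_table(tss, os.path.join(config.outdir, "tss_annotated.tsv"))
    class_counts: dict[str, int] = {}
    for t in tss:
        for c in t.classes:
            class_counts[c] = class_counts.get(c, 0) + 1
    utrs = utr_records(tss)
    report["n_tss"] = len(tss)
    report["class_counts"] = class_counts
    report["per_gene_tss_histogram"] = per_gene_tss_histogram(tss)
    report["utr_summary"] = _summary_to_json(utr_summary(utrs))
    profile = base_preference(tss, genome)
    report["base_preference"] = {
        "positions": profile.positions,
        "fractions": profile.fractions.tolist(),
        "n_tss": profile.n_tss,
    }
    record("classify", t0, primary=class_counts.get("primary", 0))

    # --- promoter motif discovery ------------------------------------------
    t0 = time.time()
    primary = [t for t in tss if "primary" in t.classes]
    upstream = motif_discovery.extract_upstream(primary, genome, config.discovery_window)
    motifs = motif_discovery.zoops_em(
        upstream, config.discovery, seed=stage_seed(config.seed, "discover")
    )
    if motifs:
        motif_discovery.write_meme(motifs, os.path.join(config.outdir, "motifs.meme"))
    report["motifs"] = [
        {
            "name": m.name,
            "width": m.width,
            "consensus": m.consensus,
            "e_value": m.e_value,
            "n_assigned": m.n_assigned,
        }
        for m in motifs
    ]
    record("discover", t0, motifs=len(motifs))

    # --- Shine-Dalgarno ----------------------------------------------------
    t0 = time.time()
    sd_params = dataclasses.replace(config.discovery, n_motifs=10, max_width=30)
    sd_motif, sd_spacings = motif_discovery.find_shine_dalgarno(
        genes, genome, window=config.sd_window, params=sd_params,
        seed=stage_seed(config.seed, "shine_dalgarno"),
    )
    report["shine_dalgarno"] = (
        {
            "consensus": sd_motif.consensus,
            "e_value": sd_motif.e_value,
            "n_genes_with_site": len(sd_spacings),
            "spacing_histogram": {
                str(d): sum(1 for v in sd_spacings.values() if v == d)
                for d in sorted(set(sd_spacings.values()))
            },
        }
        if sd_motif
        else None
    )
    record("shine_dalgarno", t0, genes_with_site=len(sd_spacings))

    # --- cross-genome style occurrence scan (this genome) ------------------
    t0 = time.time()
    if motifs:
        hits, occ = motif_scanning.scan_upstream_regions(
            motifs[0], genome, genes, window=config.scan_window,
            p_threshold=config.scan_p_threshold, species="this_genome",
        )
        report["occurrence"] = {
            "motif": motifs[0].name,
            "genes_with_hit": occ.hits,
            "n_genes": occ.n_genes,
            "rate": occ.rate,
        }
        record("scan", t0, hits=len(hits))

    # --- start-codon re-annotation -----------------------------------------
    t0 = time.time()
    if sd_motif is not None:
        proposals = reannotation.reannotate_genes(
            tss, genes, genome, sd_motif, sd_range=config.sd_range
        )
        status_counts: dict[str, int] = {}
        for p in proposals:
            status_counts[p.status] = status_counts.get(p.status, 0) + 1
        report["reannotation"] = status_counts
        with open(os.path.join(config.outdir, "reannotation.tsv"), "w") as fh:
            fh.write("gene_id\tstatus\told_start\tproposed_start\tstart_codon\tsd_offset\n")
            for p in proposals:
                fh.write(
                    f"{p.gene_id}\t{p.status}\t{p.old_start + 1}\t"
                    f"{'' if p.proposed_start is None else p.proposed_start + 1}\t"
                    f"{p.start_codon or ''}\t{'' if p.sd_offset is None else p.sd_offset}\n"
                )
        record("reannotate", t0, proposals=len(proposals))

    report["manifest"] = manifest
    with open(os.path.join(config.outdir, "run_manifest.json"), "w") as fh:
        json.dump(_summary_to_json(manifest), fh, indent=1)
    with open(os.path.join(config.outdir, "report.json"), "w") as fh:
        json.dump(_summary_to_json(report), fh, indent=1, sort_keys=True)
    return report
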