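"""Synthetic genomes with planted transcriptional architecture.

The generator emulates the data a differential RNA-seq (dRNA-seq) TSS
analysis consumes: a bacterial genome with non-overlapping protein-coding
genes on both strands, each with

* a start codon from {ATG, GTG, TTG, CTG} and a proper stop codon, with no
  in-frame internal stops;
* a Shine-Dalgarno ribosome binding site (consensus AGGAGG) ending 9-14 nt
  upstream of the start codon;
* a transcription start site (TSS) at a drawn 5'UTR length upstream of the
  start codon (log-normal, median 63 nt by default; a small configurable
  fraction of genes is leaderless with a <10 nt 5'UTR);
* a promoter motif instance from a catalog placed at a fixed offset
  upstream of the TSS.

5'-end read-start counts for the TAP+ (primary-transcript enriched) and
TAP- (processed) libraries are independent Poisson draws: at a planted
primary TSS the TAP+ mean is the site strength and the TAP- mean is
strength x leakage; at processed sites both libraries share one mean; all
other positions carry background noise. Everything is deterministic under
the configured seed, and the full ground truth is returned for recovery
testing.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field

import numpy as np

from ._seq import BASES, decode, encode, revcomp
from .io_formats import (
    TAP_MINUS,
    TAP_PLUS,
    EndCoverage,
    GeneAnnotation,
    GenomeRecord,
    write_bedgraph,
    write_fasta,
    write_gff,
)

START_CODONS = ("ATG", "GTG", "TTG", "CTG")
START_WEIGHTS = (0.78, 0.14, 0.06, 0.02)
STOP_CODONS = ("TAA", "TAG", "TGA")
STOP_WEIGHTS = (0.6, 0.2, 0.2)

# Canonical 38-nt core of the interspaced (A/T)G promoter class, used as the
# default consensus for that class.
PCAUTO_CORE = "CTGGAGCAGGTTTTGTAGTTGCAGTAACTGGTTCAATA"


@dataclass(frozen=True)
class MotifSpec:
    """A promoter motif class to plant upstream of TSSs.

    ``consensus`` may contain N (uninformative position, random base);
    ``identity`` is the per-position probability of planting the consensus
    base; ``offset`` is the gap in nt between the motif's 3' end and the
    TSS on the transcribed strand.
    """

    name: str
    consensus: str
    identity: float = 0.85
    offset: int = 5

    @property
    def width(self) -> int:
        return len(self.consensus)


def default_motif_catalog() -> list[MotifSpec]:
    """The three default promoter classes: extended -10, -35/-10, and the
    interspaced (A/T)G class."""
    return [
        MotifSpec("extended_minus10", "TATGNTATAAT", identity=0.85, offset=5),
        MotifSpec(
            "minus35_minus10", "TTGACA" + "N" * 17 + "TATAAT", identity=0.85, offset=5
        ),
        MotifSpec("p_cauto", PCAUTO_CORE, identity=0.85, offset=6),
    ]


@dataclass
class SimulationParams:
    n_genes: int = 200
    contig_id: str = "synchr1"
    gc_content: float = 0.31
    # gene body length: log-normal number of codons
    codon_log_mean: float = 5.7  # median ~300 codons
    codon_log_sigma: float = 0.3
    codon_min: int = 60
    codon_max: int = 1000
    # intergenic slack beyond the reserved regulatory space
    intergenic_scale: float = 100.0
    intergenic_min: int = 20
    # 5'UTR lengths: discretised log-normal, resampled into [utr_min, utr_max]
    utr_median: float = 63.0
    utr_sigma: float = 0.4
    utr_min: int = 10
    utr_max: int = 250
    leaderless_fraction: float = 0.02  # exact count of genes, UTR ~ U{1..9}
    # Shine-Dalgarno
    sd_consensus: str = "AGGAGG"
    sd_identity: float = 1.0
    sd_spacing: tuple[int, int] = (9, 14)
    # promoters
    motif_catalog: list[MotifSpec] = field(default_factory=default_motif_catalog)
    promoter_fraction: float = 1.0
    # base preference at the TSS (+1) position: P(A or G), split evenly
    plus_one_ag_bias: float = 0.9
    # extra TSS classes per gene (expected counts)
    internal_tss_rate: float = 0.05
    antisense_tss_rate: float = 0.05
    # count model
    depth: float = 1.0
    tss_strength: float = 100.0
    enrichment_ratio: float = 10.0
    leakage: float | None = None  # defaults to 1/enrichment_ratio
    processed_site_rate: float = 0.3  # expected processed sites per gene
    processed_strength: float = 50.0
    # genome sizing
    genome_length: int | None = None  # minimum length; required if n_genes == 0
    margin: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("gc_content", "leaderless_fraction", "promoter_fraction",
                     "plus_one_ag_bias"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.depth <= 0:
            raise ValueError("depth must be > 0")
        if self.enrichment_ratio <= 1:
            raise ValueError("enrichment_ratio must be > 1")
        if self.leakage is not None and not 0.0 <= self.leakage <= 1.0:
            raise ValueError("leakage must be in [0, 1]")
        if self.n_genes == 0 and self.genome_length is None:
            raise ValueError("genome_length is required when n_genes == 0")

    @property
    def effective_leakage(self) -> float:
        return self.leakage if self.leakage is not None else 1.0 / self.enrichment_ratio


@dataclass(frozen=True)
class PlantedTSS:
    contig_id: str
    position: int
    strand: str
    tss_class: str  # primary | internal | antisense
    strength: float
    gene_id: str | None = None


@dataclass(frozen=True)
class PlantedMotif:
    motif_name: str
    contig_id: str
    start: int  # genome coordinate of the instance, 0-based
    strand: str
    sequence: str  # instance on the transcribed strand


@dataclass
class SyntheticTruth:
    tss_list: list[PlantedTSS]
    motif_instances: list[PlantedMotif]
    sd_offsets: dict[str, int]
    utr_lengths: dict[str, int]
    processed_sites: list[tuple[str, int, str, float]]
    params: SimulationParams

    def primary_tss(self) -> list[PlantedTSS]:
        return [t for t in self.tss_list if t.tss_class == "primary"]


class _GenomeBuffer:
    """Mutable encoded genome with a strand-aware write helper."""

    def __init__(self, length: int, gc: float, rng: np.random.Generator):
        p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
        self.arr = rng.choice(4, size=length, p=p).astype(np.int8)

    def write(self, start: int, seq: str, strand: str) -> None:
        """Write ``seq`` so that reading the transcribed strand 5'->3' over
        [start, start+len) yields ``seq`` (i.e. reverse complement on -)."""
        enc = encode(seq if strand == "+" else revcomp(seq))
        self.arr[start : start + len(enc)] = enc

    def __getitem__(self, sl):
        return self.arr[sl]


def _draw_seq(rng: np.random.Generator, consensus: str, identity: float, gc: float) -> str:
    """Instance of a consensus: per-position consensus base w.p. identity,
    otherwise one of the three other bases; N positions are random."""
    out = []
    p_bg = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    for c in consensus:
        if c == "N":
            out.append(BASES[rng.choice(4, p=p_bg)])
        elif rng.random() < identity:
            out.append(c)
        else:
            others = [b for b in BASES if b != c]
            out.append(others[rng.integers(3)])
    return "".join(out)


def _gene_body(rng: np.random.Generator, n_codons: int, gc: float) -> str:
    """Start codon + n_codons sense codons + stop codon, no in-frame stops."""
    start = START_CODONS[rng.choice(4, p=START_WEIGHTS)]
    stop = STOP_CODONS[rng.choice(3, p=STOP_WEIGHTS)]
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    body = rng.choice(4, size=3 * n_codons, p=p).astype(np.int8)
    codons = body.reshape(-1, 3)
    # T?A / T?G patterns that form stops: TAA, TAG, TGA -> fix the middle base
    is_stop = (codons[:, 0] == 3) & (
        ((codons[:, 1] == 0) & ((codons[:, 2] == 0) | (codons[:, 2] == 2)))
        | ((codons[:, 1] == 2) & (codons[:, 2] == 0))
    )
    codons[is_stop, 1] = 1  # -> TC?, always sense
    return start + decode(codons.reshape(-1)) + stop


def generate_genome(
    params: SimulationParams,
) -> tuple[list[GenomeRecord], list[GeneAnnotation], SyntheticTruth]:
    """Generate a genome, its annotation and the planted ground truth."""
    rng = np.random.default_rng(params.seed)
    n = params.n_genes
    catalog = params.motif_catalog
    sd_lo, sd_hi = params.sd_spacing

    # per-gene draws
    strands = np.where(rng.random(n) < 0.5, "+", "-")
    n_leaderless = int(round(params.leaderless_fraction * n))
    leaderless_idx = set(rng.choice(n, size=n_leaderless, replace=False)) if n else set()
    utrs = np.empty(n, dtype=int)
    for i in range(n):
        if i in leaderless_idx:
            utrs[i] = rng.integers(1, 10)
        else:
            u = 0
            while not (params.utr_min <= u <= params.utr_max):
                u = int(round(np.exp(np.log(params.utr_median)
                                     + params.utr_sigma * rng.standard_normal())))
            utrs[i] = u
    motif_idx = [
        int(rng.integers(len(catalog)))
        if catalog and rng.random() < params.promoter_fraction
        else None
        for _ in range(n)
    ]
    n_codons = np.clip(
        np.round(np.exp(params.codon_log_mean
                        + params.codon_log_sigma * rng.standard_normal(n))),
        params.codon_min,
        params.codon_max,
    ).astype(int)

    # layout: left-to-right cursor; each gene reserves its regulatory space
    # (UTR + promoter footprint + pad) on its own upstream side
    pad = 10
    starts = np.empty(n, dtype=int)
    ends = np.empty(n, dtype=int)
    cursor = params.margin
    for i in range(n):
        spec = catalog[motif_idx[i]] if motif_idx[i] is not None else None
        upspace = int(utrs[i]) + (spec.offset + spec.width if spec else 0) + pad
        slack = int(rng.exponential(params.intergenic_scale)) + params.intergenic_min
        length = 3 * int(n_codons[i]) + 6
        if strands[i] == "+":
            starts[i] = cursor + slack + upspace
            ends[i] = starts[i] + length
            cursor = ends[i]
        else:
            starts[i] = cursor + slack
            ends[i] = starts[i] + length
            cursor = ends[i] + upspace
    total = cursor + params.margin
    if params.genome_length is not None:
        total = max(total, params.genome_length)

    buf = _GenomeBuffer(total, params.gc_content, rng)
    genes: list[GeneAnnotation] = []
    tss_list: list[PlantedTSS] = []
    motif_instances: list[PlantedMotif] = []
    sd_offsets: dict[str, int] = {}
    utr_lengths: dict[str, int] = {}
    contig = params.contig_id

    def t2g(tss_pos: int, strand: str, x: int) -> int:
        """Transcribed coordinate (0 at the TSS base) -> genome coordinate."""
        return tss_pos + x if strand == "+" else tss_pos - x

    for i in range(n):
        gid = f"sg{i + 1:05d}"
        strand = str(strands[i])
        gs, ge = int(starts[i]), int(ends[i])
        utr = int(utrs[i])
        genes.append(GeneAnnotation(gid, contig, gs, ge, strand))
        utr_lengths[gid] = utr
        buf.write(gs, _gene_body(rng, int(n_codons[i]), params.gc_content), strand)

        tss = gs - utr if strand == "+" else (ge - 1) + utr
        tss_list.append(PlantedTSS(contig, tss, strand, "primary",
                                   params.tss_strength, gid))

        # Shine-Dalgarno inside the UTR: spacing d between SD end and start
        # codon, constrained so the SD is transcribed (utr >= d + width)
        sdw = len(params.sd_consensus)
        if utr >= sd_lo + sdw:
            d = int(rng.integers(sd_lo, min(sd_hi, utr - sdw) + 1))
            sd_seq = _draw_seq(rng, params.sd_consensus, params.sd_identity,
                               params.gc_content)
            a = utr - d - sdw  # transcribed coord of SD start
            g0 = t2g(tss, strand, a)
            gstart = g0 if strand == "+" else g0 - sdw + 1
            buf.write(gstart, sd_seq, strand)
            sd_offsets[gid] = d

        # promoter instance upstream of the TSS
        if motif_idx[i] is not None:
            spec = catalog[motif_idx[i]]
            inst = _draw_seq(rng, spec.consensus, spec.identity, params.gc_content)
            a = -(spec.offset + spec.width)  # transcribed coord of motif start
            g0 = t2g(tss, strand, a)
            gstart = g0 if strand == "+" else g0 - spec.width + 1
            buf.write(gstart, inst, strand)
            motif_instances.append(PlantedMotif(spec.name, contig, gstart, strand, inst))

        # +1 base preference (A/G-rich on the transcribed strand)
        b = params.plus_one_ag_bias
        plus_one = BASES[rng.choice(4, p=[b / 2, (1 - b) / 2, b / 2, (1 - b) / 2])]
        buf.write(tss if strand == "+" else tss, plus_one, strand)

        # optional extra TSS classes inside the gene body
        for _ in range(rng.poisson(params.internal_tss_rate)):
            pos = int(rng.integers(gs, ge))
            tss_list.append(PlantedTSS(contig, pos, strand, "internal",
                                       params.tss_strength, gid))
        for _ in range(rng.poisson(params.antisense_tss_rate)):
            pos = int(rng.integers(gs, ge))
            anti = "-" if strand == "+" else "+"
            tss_list.append(PlantedTSS(contig, pos, anti, "antisense",
                                       params.tss_strength, gid))

    # processed 5'-ends, equally represented in both libraries
    processed: list[tuple[str, int, str, float]] = []
    n_proc = rng.poisson(params.processed_site_rate * n) if n else 0
    occupied = {(t.position, t.strand) for t in tss_list}
    for _ in range(n_proc):
        pos = int(rng.integers(params.margin, total - params.margin))
        strand = "+" if rng.random() < 0.5 else "-"
        if (pos, strand) in occupied:
            continue
        occupied.add((pos, strand))
        processed.append((contig, pos, strand, params.processed_strength))

    genome = [GenomeRecord(contig, decode(buf.arr))]
    truth = SyntheticTruth(tss_list, motif_instances, sd_offsets, utr_lengths,
                           processed, params)
    return genome, genes, truth


def simulate_libraries(
    truth: SyntheticTruth,
    genome: list[GenomeRecord],
    params: SimulationParams | None = None,
    seed: int | None = None,
) -> tuple[EndCoverage, EndCoverage]:
    """Draw TAP+ and TAP- 5'-end counts for a generated genome.

    Counts are independent Poisson draws per position: background mean
    ``depth`` everywhere, replaced at planted TSSs by (strength,
    strength x leakage) and at processed sites by one shared mean.
    """
    params = params or truth.params
    rng = np.random.default_rng(params.seed + 7919 if seed is None else seed)
    leak = params.effective_leakage
    tap_plus = EndCoverage(library_label=TAP_PLUS)
    tap_minus = EndCoverage(library_label=TAP_MINUS)
    lengths = {g.contig_id: len(g) for g in genome}
    for contig_id, L in lengths.items():
        for strand in "+-":
            tap_plus.counts[(contig_id, strand)] = rng.poisson(params.depth, L)
            tap_minus.counts[(contig_id, strand)] = rng.poisson(params.depth, L)
    for t in truth.tss_list:
        key = (t.contig_id, t.strand)
        tap_plus.counts[key][t.position] = rng.poisson(t.strength)
        tap_minus.counts[key][t.position] = rng.poisson(t.strength * leak)
    for contig_id, pos, strand, strength in truth.processed_sites:
        key = (contig_id, strand)
        tap_plus.counts[key][pos] = rng.poisson(strength)
        tap_minus.counts[key][pos] = rng.poisson(strength)
    return tap_plus, tap_minus


# ---------------------------------------------------------------------------
# fixture output


def _truth_to_json(truth: SyntheticTruth) -> dict:
    d = {
        "tss_list": [dataclasses.asdict(t) for t in truth.tss_list],
        "motif_instances": [dataclasses.asdict(m) for m in truth.motif_instances],
        "sd_offsets": truth.sd_offsets,
        "utr_lengths": truth.utr_lengths,
        "processed_sites": [list(p) for p in truth.processed_sites],
        "params": dataclasses.asdict(truth.params),
    }
    d["params"]["motif_catalog"] = [dataclasses.asdict(m) for m in truth.params.motif_catalog]
    return d


def write_simulation(outdir, genome, genes, truth, tap_plus, tap_minus) -> dict:
    """Write a complete fixture (FASTA, GFF3, 4 bedGraphs, truth JSON)."""
    os.makedirs(outdir, exist_ok=True)
    paths = {
        "fasta": os.path.join(outdir, "genome.fa"),
        "gff": os.path.join(outdir, "genes.gff3"),
        "tap_plus_fwd": os.path.join(outdir, "tap_plus.fwd.bedgraph"),
        "tap_plus_rev": os.path.join(outdir, "tap_plus.rev.bedgraph"),
        "tap_minus_fwd": os.path.join(outdir, "tap_minus.fwd.bedgraph"),
        "tap_minus_rev": os.path.join(outdir, "tap_minus.rev.bedgraph"),
        "truth": os.path.join(outdir, "truth.json"),
    }
    write_fasta(genome, paths["fasta"])
    write_gff(genes, paths["gff"])
    write_bedgraph(tap_plus, paths["tap_plus_fwd"], paths["tap_plus_rev"])
    write_bedgraph(tap_minus, paths["tap_minus_fwd"], paths["tap_minus_rev"])
    with open(paths["truth"], "w") as fh:
        json.dump(_truth_to_json(truth), fh, indent=1)
    return paths
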