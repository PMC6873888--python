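"""TSS classification against gene annotations and downstream statistics.

Classes follow the standard dRNA-seq scheme:

* primary   - at most 250 nt (inclusive) strictly upstream of a same-strand
              gene's first base;
* internal  - inside a same-strand gene;
* antisense - inside an opposite-strand gene;
* orphan    - none of the above.

A TSS may carry several labels with respect to different genes, and may be
primary for more than one gene inside the window. 5'UTR length is the
distance from the TSS to the start codon's first base; transcripts with a
<10 nt 5'UTR are counted as leaderless.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from ._seq import BASE_INDEX, BASES, revcomp
from .io_formats import GeneAnnotation, GenomeRecord
from .tss_calling import TSSRecord

logger = logging.getLogger(__name__)

LEADERLESS_MAX_UTR = 10  # strict upper bound: leaderless iff utr < 10


@dataclass(frozen=True)
class UTRRecord:
    gene_id: str
    tss_position: int
    utr_length: int
    leaderless: bool

    def __post_init__(self) -> None:
        if self.utr_length < 0:
            raise ValueError("negative 5'UTR length")
        if self.leaderless != (self.utr_length < LEADERLESS_MAX_UTR):
            raise ValueError("leaderless flag inconsistent with UTR length")


@dataclass
class BasePreferenceProfile:
    """Base fractions at positions -flank..-1, +1..+flank around the TSS
    (+1 is the TSS base itself; there is no position 0)."""

    positions: list[int]
    fractions: np.ndarray  # shape (4, n_positions), rows in A,C,G,T order
    n_tss: int

    def fraction(self, base: str, position: int) -> float:
        return float(self.fractions[BASE_INDEX[base], self.positions.index(position)])


def make_utr_record(gene_id: str, tss_position: int, utr_length: int) -> UTRRecord:
    return UTRRecord(gene_id, tss_position, utr_length,
                     leaderless=utr_length < LEADERLESS_MAX_UTR)


def classify_tss(
    tss: TSSRecord, genes: list[GeneAnnotation], window: int = 250
) -> TSSRecord:
    """Attach class labels and gene assignments to a TSS (in place).

    Upstream distance d to a same-strand gene's first base must satisfy
    1 <= d <= window for a primary call; a TSS exactly on the start codon's
    first base falls inside the gene interval and is internal.
    """
    tss.classes = set()
    tss.assigned_genes = []
    pos = tss.position
    for g in genes:
        if g.contig_id != tss.contig_id:
            continue
        inside = g.start <= pos < g.end
        if g.strand == tss.strand:
            if inside:
                tss.classes.add("internal")
                tss.assigned_genes.append((g.gene_id, "internal", None))
            else:
                d = g.start - pos if g.strand == "+" else pos - (g.end - 1)
                if 1 <= d <= window:
                    tss.classes.add("primary")
                    tss.assigned_genes.append((g.gene_id, "primary", d))
        elif inside:
            tss.classes.add("antisense")
            tss.assigned_genes.append((g.gene_id, "antisense", None))
    if not tss.classes:
        tss.classes.add("orphan")
    return tss


def annotate_tss(
    tss_list: list[TSSRecord], genes: list[GeneAnnotation], window: int = 250
) -> list[TSSRecord]:
    """Classify every TSS; genes are bucketed per contig for speed."""
    by_contig: dict[str, list[GeneAnnotation]] = {}
    for g in genes:
        by_contig.setdefault(g.contig_id, []).append(g)
    for t in tss_list:
        classify_tss(t, by_contig.get(t.contig_id, []), window)
    return tss_list


def compute_utr(tss: TSSRecord, gene: GeneAnnotation) -> UTRRecord:
    """5'UTR record for a TSS that is primary for ``gene``."""
    if gene.strand == "+":
        utr = gene.start - tss.position
    else:
        utr = tss.position - (gene.end - 1)
    if utr < 0:
        raise ValueError(
            f"TSS {tss.position} is downstream of gene {gene.gene_id} start"
        )
    return make_utr_record(gene.gene_id, tss.position, utr)


def utr_records(tss_list: list[TSSRecord]) -> list[UTRRecord]:
    """One UTR record per (TSS, gene) primary assignment."""
    out = []
    for t in tss_list:
        for gid, cls, utr in t.assigned_genes:
            if cls == "primary":
                out.append(make_utr_record(gid, t.position, utr))
    return out


@dataclass
class UTRSummary:
    n: int
    median: float | None
    fraction_below_100: float | None
    leaderless_count: int
    leaderless_fraction: float | None
    histogram: dict[int, int]  # 10-nt bin start -> count


def utr_summary(records: list[UTRRecord], bin_width: int = 10) -> UTRSummary:
    """Median (lower median for even n), <100 nt fraction, leaderless stats."""
    if not records:
        return UTRSummary(0, None, None, 0, None, {})
    lengths = sorted(r.utr_length for r in records)
    n = len(lengths)
    median = float(lengths[(n - 1) // 2])  # lower median
    frac100 = sum(1 for x in lengths if x < 100) / n
    n_leaderless = sum(1 for r in records if r.leaderless)
    hist: dict[int, int] = {}
    for x in lengths:
        b = (x // bin_width) * bin_width
        hist[b] = hist.get(b, 0) + 1
    return UTRSummary(n, median, frac100, n_leaderless, n_leaderless / n, hist)


def per_gene_tss_histogram(tss_list: list[TSSRecord]) -> dict[int, int]:
    """Map: number of primary TSSs per gene -> number of such genes."""
    per_gene: dict[str, int] = {}
    for t in tss_list:
        for gid, cls, _ in t.assigned_genes:
            if cls == "primary":
                per_gene[gid] = per_gene.get(gid, 0) + 1
    hist: dict[int, int] = {}
    for count in per_gene.values():
        hist[count] = hist.get(count, 0) + 1
    return hist


def base_preference(
    tss_list: list[TSSRecord], genome: list[GenomeRecord], flank: int = 5
) -> BasePreferenceProfile:
    """Base fractions around TSSs, read on the transcribed strand.

    Positions are labelled -flank..-1, +1..+flank with +1 the TSS base.
    TSSs closer than ``flank`` to a contig edge are skipped with a log note.
    """
    seqs = {g.contig_id: g.sequence for g in genome}
    width = 2 * flank  # flank upstream + TSS base + (flank - 1) downstream
    counts = np.zeros((4, width), dtype=float)
    used = 0
    for t in tss_list:
        seq = seqs[t.contig_id]
        if t.strand == "+":
            lo, hi = t.position - flank, t.position + flank
            if lo < 0 or hi > len(seq):
                logger.info("TSS %s:%d too close to contig edge; skipped",
                            t.contig_id, t.position)
                continue
            window = seq[lo:hi]
        else:
            lo, hi = t.position - flank + 1, t.position + flank + 1
            if lo < 0 or hi > len(seq):
                logger.info("TSS %s:%d too close to contig edge; skipped",
                            t.contig_id, t.position)
                continue
            window = revcomp(seq[lo:hi])
        for j, c in enumerate(window):
            counts[BASE_INDEX[c], j] += 1
        used += 1
    positions = list(range(-flank, 0)) + list(range(1, flank + 1))
    if used:
        fractions = counts / used
    else:
        fractions = np.zeros_like(counts)
    return BasePreferenceProfile(positions, fractions, used)
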