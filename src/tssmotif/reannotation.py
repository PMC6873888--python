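"""Start-codon re-annotation from TSS evidence and Shine-Dalgarno placement.

For a gene with a primary TSS, the transcribed strand is scanned from the
TSS to the annotated stop codon for ribosome-binding-site (SD) matches
followed, at a spacing of 9-14 nt, by a start codon from {ATG, CTG, GTG,
TTG} that is in frame with the annotated stop and leaves an open reading
frame of at least 30 codons with no internal stop. Candidates are ranked by
SD match score, then spacing closest to 11 nt (the centre of the conserved
band), then ORF length; the best candidate is compared with the annotated
start.
"""

from __future__ import annotations

from dataclasses import dataclass

from ._seq import revcomp
from .io_formats import GeneAnnotation, GenomeRecord
from .motif_discovery import PWMMotif
from .motif_scanning import pwm_score
from .tss_calling import TSSRecord

START_CODONS = ("ATG", "CTG", "GTG", "TTG")
STOP_CODONS = ("TAA", "TAG", "TGA")


class AnnotationError(ValueError):
    """Gene annotation inconsistent with the genome sequence."""


@dataclass
class ReannotationRecord:
    gene_id: str
    old_start: int  # genome coordinate of the annotated start codon's first base
    proposed_start: int | None
    start_codon: str | None
    sd_offset: int | None  # nt between SD match end and the proposed start
    sd_score: float | None
    evidence_tss: int
    status: str  # proposed | unchanged | conflict


def _transcribed(gene: GeneAnnotation, tss: TSSRecord, seq: str) -> tuple[str, int, int]:
    """mRNA-strand sequence from the TSS to the annotated gene 3' end.

    Returns (sequence, start_codon_index, stop_codon_index) where indices
    are 0-based positions of the annotated start/stop first base within the
    returned sequence.
    """
    if gene.strand == "+":
        sub = seq[tss.position : gene.end]
        start_idx = gene.start - tss.position
    else:
        sub = revcomp(seq[gene.start : tss.position + 1])
        start_idx = tss.position - (gene.end - 1)
    stop_idx = len(sub) - 3
    return sub, start_idx, stop_idx


def _to_genome(gene: GeneAnnotation, tss: TSSRecord, idx: int) -> int:
    return tss.position + idx if gene.strand == "+" else tss.position - idx


def propose_start_codon(
    gene: GeneAnnotation,
    tss: TSSRecord,
    genome: list[GenomeRecord],
    sd_pwm: PWMMotif,
    sd_range: tuple[int, int] = (9, 14),
    sd_p_threshold: float = 1e-3,
    min_orf_codons: int = 30,
) -> ReannotationRecord:
    """Propose a start codon for ``gene`` given a primary TSS.

    Status is ``unchanged`` when the best SD-consistent candidate is the
    annotated start, ``proposed`` when it differs, and ``conflict`` when no
    candidate exists.
    """
    seqs = {g.contig_id: g.sequence for g in genome}
    seq = seqs[gene.contig_id]
    sub, start_idx, stop_idx = _transcribed(gene, tss, seq)
    if sub[stop_idx : stop_idx + 3] not in STOP_CODONS:
        raise AnnotationError(
            f"gene {gene.gene_id}: annotated span does not end in a stop codon"
        )
    if start_idx < 0:
        raise AnnotationError(
            f"gene {gene.gene_id}: TSS lies downstream of the annotated start"
        )
    # SD matches on the mRNA strand only
    _, sd_hits = pwm_score(sd_pwm, sub, revcomp_scan=False,
                           p_threshold=sd_p_threshold, target_id=gene.gene_id)
    candidates = []  # (-score, |d-11|, -orf_len, cand_idx, ...)
    lo, hi = sd_range
    for hit in sd_hits:
        sd_end = hit.offset + sd_pwm.width
        for d in range(lo, hi + 1):
            cand = sd_end + d
            codon = sub[cand : cand + 3]
            if codon not in START_CODONS:
                continue
            if (stop_idx - cand) % 3 != 0:
                continue  # out of frame with the annotated stop
            orf_codons = (stop_idx - cand) // 3
            if orf_codons < min_orf_codons:
                continue
            if any(sub[j : j + 3] in STOP_CODONS for j in range(cand, stop_idx, 3)):
                continue  # internal stop
            candidates.append((-hit.score, abs(d - 11), -orf_codons, cand, codon, d,
                               hit.score))
    if not candidates:
        return ReannotationRecord(
            gene_id=gene.gene_id,
            old_start=gene.five_prime,
            proposed_start=None,
            start_codon=None,
            sd_offset=None,
            sd_score=None,
            evidence_tss=tss.position,
            status="conflict",
        )
    candidates.sort()
    _, _, _, cand, codon, d, score = candidates[0]
    proposed = _to_genome(gene, tss, cand)
    status = "unchanged" if cand == start_idx else "proposed"
    return ReannotationRecord(
        gene_id=gene.gene_id,
        old_start=gene.five_prime,
        proposed_start=proposed,
        start_codon=codon,
        sd_offset=d,
        sd_score=score,
        evidence_tss=tss.position,
        status=status,
    )


def reannotate_genes(
    tss_list: list[TSSRecord],
    genes: list[GeneAnnotation],
    genome: list[GenomeRecord],
    sd_pwm: PWMMotif,
    **kwargs,
) -> list[ReannotationRecord]:
    """Run :func:`propose_start_codon` for every gene with a primary TSS.

    When a gene has several primary TSSs the one closest to the gene
    (shortest 5'UTR) is used as evidence.
    """
    by_gene: dict[str, tuple[int, TSSRecord]] = {}
    gene_map = {g.gene_id: g for g in genes}
    for t in tss_list:
        for gid, cls, utr in t.assigned_genes:
            if cls != "primary":
                continue
            if gid not in by_gene or utr < by_gene[gid][0]:
                by_gene[gid] = (utr, t)
    out = []
    for gid, (_, t) in sorted(by_gene.items()):
        out.append(propose_start_codon(gene_map[gid], t, genome, sd_pwm, **kwargs))
    return out
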