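"""FIMO-style PWM scanning with exact p-values.

Log-odds scores are computed in bits against a 0-order background on a
lattice of LOG_ODDS_EPS-bit steps; the null score distribution of a random
background sequence of motif width is then exact by dynamic programming
over the integer lattice, giving p-values identical to exhaustive
enumeration of all 4^w sequences scored with the same (quantised) matrix.

Upstream-window scanning mirrors the cross-genome occurrence analysis: up
to 300 nt upstream of each annotated gene is scanned on both strands, a
gene "has the motif" when at least one hit reaches the p-value threshold
(default 1e-4, FIMO's default output threshold), and per-species occurrence
rates are normalised by the number of annotated genes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._seq import encode, revcomp
from .io_formats import GeneAnnotation, GenomeRecord
from .motif_discovery import LOG_ODDS_EPS, PWMMotif


@dataclass(frozen=True)
class MotifHit:
    target_id: str
    contig_id: str
    offset: int  # 0-based start of the match within the scanned sequence
    strand: str
    score: float  # log-odds, bits
    p_value: float


@dataclass
class SpeciesOccurrence:
    species: str
    hits: int  # genes with >= 1 hit
    n_genes: int

    @property
    def rate(self) -> float:
        return self.hits / self.n_genes if self.n_genes else 0.0


@dataclass
class OccurrenceReport:
    reference: str
    rows: dict[str, SpeciesOccurrence]
    relative: dict[str, float | None]  # None when the reference rate is zero


def build_pwm(
    instances: list[str],
    pseudocount: float = 1.0,
    background: np.ndarray | None = None,
    name: str = "pwm",
) -> PWMMotif:
    """PWM from equal-length aligned instances.

    Probability matrix is (counts + pseudocount*background) / (n +
    pseudocount); log-odds are in bits against the background (uniform by
    default).
    """
    if not instances:
        raise ValueError("at least one instance required")
    w = len(instances[0])
    if any(len(s) != w for s in instances):
        raise ValueError("instances must have equal lengths")
    bg = np.full(4, 0.25) if background is None else np.asarray(background, float)
    counts = np.zeros((4, w))
    for s in instances:
        e = encode(s)
        counts[e, np.arange(w)] += 1
    return PWMMotif(count_matrix=counts, background=bg, pseudocount=pseudocount,
                    n_sites=float(len(instances)), name=name)


# ---------------------------------------------------------------------------
# exact p-values


def _int_matrix(pwm: PWMMotif) -> np.ndarray:
    return np.round(pwm.log_odds / LOG_ODDS_EPS).astype(np.int64)


def _score_sf(pwm: PWMMotif) -> tuple[int, np.ndarray]:
    """Exact null survival function on the integer score lattice.

    Returns (base, sf) where sf[i] = P(score >= (base + i) * eps) for a
    width-length i.i.d. background sequence. Cached on the motif object.
    """
    cached = getattr(pwm, "_sf_cache", None)
    if cached is not None:
        return cached
    K = _int_matrix(pwm)
    bg = pwm.background
    mins = K.min(axis=0)
    maxs = K.max(axis=0)
    dist = np.zeros(1)
    dist[0] = 1.0
    for t in range(pwm.width):
        span = maxs[t] - mins[t]
        new = np.zeros(len(dist) + span)
        for b in range(4):
            off = K[b, t] - mins[t]
            new[off : off + len(dist)] += bg[b] * dist
        dist = new
    sf = np.cumsum(dist[::-1])[::-1]
    base = int(mins.sum())
    pwm._sf_cache = (base, sf)
    return base, sf


def pwm_pvalue(pwm: PWMMotif, score: float) -> float:
    """P(random background sequence of motif width scores >= ``score``).

    Exact on the quantised log-odds lattice; monotone non-increasing in the
    score and always in (0, 1].
    """
    base, sf = _score_sf(pwm)
    k = int(round(score / LOG_ODDS_EPS)) - base
    if k <= 0:
        return 1.0
    if k >= len(sf):
        k = len(sf) - 1  # scores above the attainable maximum
    return float(min(max(sf[k], sf[-1]), 1.0))


# ---------------------------------------------------------------------------
# scanning


def _window_scores(K: np.ndarray, enc: np.ndarray) -> np.ndarray:
    w = K.shape[1]
    m = len(enc) - w + 1
    if m <= 0:
        return np.empty(0, dtype=np.int64)
    win = np.lib.stride_tricks.sliding_window_view(enc, w)
    out = np.zeros(m, dtype=np.int64)
    for t in range(w):
        out += K[win[:, t], t]
    return out


def pwm_score(
    pwm: PWMMotif,
    sequence: str,
    revcomp_scan: bool = True,
    p_threshold: float | None = 1e-4,
    target_id: str = "",
    contig_id: str = "",
) -> tuple[MotifHit | None, list[MotifHit]]:
    """Scan one sequence; return the best hit and all hits at p <= threshold.

    The reverse strand is scanned via the reverse-complement matrix, so a
    '-' hit at offset j covers sequence[j:j+w] read on the other strand.
    """
    enc = encode(sequence)
    K = _int_matrix(pwm)
    strands = [("+", K)]
    if revcomp_scan:
        strands.append(("-", K[::-1, ::-1]))
    best: MotifHit | None = None
    hits: list[MotifHit] = []
    for strand, mat in strands:
        ints = _window_scores(mat, enc)
        for j, si in enumerate(ints):
            score = float(si) * LOG_ODDS_EPS
            p = pwm_pvalue(pwm, score)
            hit = MotifHit(target_id, contig_id, j, strand, score, p)
            if best is None or score > best.score:
                best = hit
            if p_threshold is not None and p <= p_threshold:
                hits.append(hit)
    return best, hits


def _upstream_window(
    gene: GeneAnnotation,
    seq: str,
    window: int,
    neighbor_bound: tuple[int, int] | None,
) -> str:
    if gene.strand == "+":
        lo = max(0, gene.start - window)
        if neighbor_bound is not None:
            lo = max(lo, neighbor_bound[0])
        return seq[lo : gene.start]
    hi = min(len(seq), gene.end + window)
    if neighbor_bound is not None:
        hi = min(hi, neighbor_bound[1])
    return seq[gene.end : hi]


def scan_upstream_regions(
    pwm: PWMMotif,
    genome: list[GenomeRecord],
    genes: list[GeneAnnotation],
    window: int = 300,
    p_threshold: float = 1e-4,
    truncate_at_neighbor: bool = False,
    species: str = "genome",
) -> tuple[list[MotifHit], SpeciesOccurrence]:
    """Scan up to ``window`` nt upstream of every gene on both strands.

    A gene has the motif iff at least one hit reaches ``p_threshold``.
    Windows truncate at contig edges; with ``truncate_at_neighbor`` they
    additionally stop at the nearest flanking gene boundary.
    """
    seqs = {g.contig_id: g.sequence for g in genome}
    bounds: dict[str, tuple[int, int]] = {}
    if truncate_at_neighbor:
        by_contig: dict[str, list[GeneAnnotation]] = {}
        for g in genes:
            by_contig.setdefault(g.contig_id, []).append(g)
        for g in genes:
            others = [o for o in by_contig[g.contig_id] if o.gene_id != g.gene_id]
            lo = max((o.end for o in others if o.end <= g.start), default=0)
            hi = min((o.start for o in others if o.start >= g.end),
                     default=len(seqs[g.contig_id]))
            bounds[g.gene_id] = (lo, hi)
    all_hits: list[MotifHit] = []
    hit_genes = 0
    for g in genes:
        sub = _upstream_window(g, seqs[g.contig_id], window,
                               bounds.get(g.gene_id) if truncate_at_neighbor else None)
        if len(sub) < pwm.width:
            continue
        _, hits = pwm_score(pwm, sub, revcomp_scan=True, p_threshold=p_threshold,
                            target_id=g.gene_id, contig_id=g.contig_id)
        if hits:
            hit_genes += 1
            all_hits.extend(hits)
    return all_hits, SpeciesOccurrence(species, hit_genes, len(genes))


def relative_occurrence(
    rows: list[SpeciesOccurrence], reference: str
) -> OccurrenceReport:
    """Per-species occurrence rate divided by the reference species' rate."""
    by_name = {r.species: r for r in rows}
    if reference not in by_name:
        raise ValueError(f"reference species {reference!r} missing")
    ref_rate = by_name[reference].rate
    relative: dict[str, float | None] = {}
    for name, r in by_name.items():
        relative[name] = (r.rate / ref_rate) if ref_rate > 0 else None
    return OccurrenceReport(reference, by_name, relative)
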