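"""Differential TSS calling from paired TAP+/TAP- 5'-end coverage.

A position is a transcription start site candidate when its TAP+ (primary
transcript enriched) 5'-end count significantly exceeds the TAP- (processed)
count under a Skellam test: the difference of two independent Poisson
variables with locally estimated rates. Candidates passing a raw-count noise
threshold and the p-value cutoff are merged within a small range, keeping
the strongest position of each cluster.

Default thresholds: p-value 1e-3, noise threshold 10 (minimum raw TAP+
count), merge range 5 nt.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .io_formats import EndCoverage

logger = logging.getLogger(__name__)


@dataclass
class TSSCallParams:
    pvalue_threshold: float = 1e-3
    noise_threshold: int = 10
    merge_range: int = 5
    background_window: int = 1000
    trim_fraction: float = 0.1  # trimmed-mean tail fraction for background
    lambda_floor: float = 1e-3

    def __post_init__(self) -> None:
        if self.pvalue_threshold <= 0 or self.noise_threshold <= 0:
            raise ValueError("thresholds must be positive")
        if self.merge_range < 0:
            raise ValueError("merge_range must be >= 0")
        if self.background_window < 10:
            raise ValueError("background_window must be >= 10")


@dataclass(frozen=True)
class SkellamParams:
    """Null Poisson rates for the two libraries, both on the TAP+ scale."""

    lambda_plus: float
    lambda_minus: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.lambda_plus) and np.isfinite(self.lambda_minus)):
            raise ValueError("non-finite lambda")
        if self.lambda_plus < 0 or self.lambda_minus < 0:
            raise ValueError("lambda must be >= 0")


@dataclass
class TSSRecord:
    contig_id: str
    position: int  # 0-based
    strand: str
    tap_plus_count: int
    tap_minus_count: int
    p_value: float
    classes: set = field(default_factory=set)
    assigned_genes: list = field(default_factory=list)  # (gene_id, class, utr|None)


def skellam_sf(k: int, lam: SkellamParams) -> float:
    """P(X - Y >= k) for X ~ Poisson(lambda_plus), Y ~ Poisson(lambda_minus).

    Degenerate rates (either lambda equal to zero) reduce to a single
    Poisson tail and are handled analytically; the general case uses the
    Skellam distribution.
    """
    lp, lm = lam.lambda_plus, lam.lambda_minus
    if lp == 0.0 and lm == 0.0:
        return 1.0 if k <= 0 else 0.0
    if lm == 0.0:  # difference is X itself
        return float(stats.poisson.sf(k - 1, lp))
    if lp == 0.0:  # difference is -Y
        return 0.0 if k > 0 else float(stats.poisson.cdf(-k, lm))
    return float(np.clip(stats.skellam.sf(k - 1, lp, lm), 0.0, 1.0))


def _trimmed_mean_excluding(arr: np.ndarray, pos: int, half: int, trim: float) -> float:
    lo = max(0, pos - half)
    hi = min(len(arr), pos + half + 1)
    window = np.concatenate((arr[lo:pos], arr[pos + 1 : hi]))
    if window.size == 0:
        return 0.0
    return float(stats.trim_mean(window, trim))


def estimate_background(
    tap_plus: EndCoverage,
    tap_minus: EndCoverage,
    contig_id: str,
    strand: str,
    pos: int,
    params: TSSCallParams,
    size_ratio: float | None = None,
) -> SkellamParams:
    """Local null rates at ``pos``, both scaled to the TAP+ library.

    Each rate is the trimmed mean of its library's counts in a window of
    ``background_window`` nt centred on ``pos`` (the position itself is
    excluded, windows truncate at contig ends). The TAP- rate is multiplied
    by the TAP+/TAP- library-size ratio. Rates are floored at a small
    positive constant so the test never degenerates.
    """
    if size_ratio is None:
        nm = tap_minus.library_size
        size_ratio = tap_plus.library_size / nm if nm > 0 else 1.0
    half = params.background_window // 2
    lp = _trimmed_mean_excluding(
        tap_plus.array(contig_id, strand), pos, half, params.trim_fraction
    )
    lm = _trimmed_mean_excluding(
        tap_minus.array(contig_id, strand), pos, half, params.trim_fraction
    )
    return SkellamParams(
        lambda_plus=max(lp, params.lambda_floor),
        lambda_minus=max(lm * size_ratio, params.lambda_floor),
    )


def merge_tss(candidates: list[TSSRecord], merge_range: int) -> list[TSSRecord]:
    """Collapse candidate clusters, keeping the strongest position.

    Candidates on the same contig/strand whose positions chain together
    with gaps <= ``merge_range`` (transitive closure) form one cluster; the
    representative is the member with maximal TAP+ count, ties broken by
    the most upstream position in transcription direction (smallest
    coordinate on +, largest on -). Counts are not summed.
    """
    out: list[TSSRecord] = []
    by_key: dict[tuple[str, str], list[TSSRecord]] = {}
    for c in candidates:
        by_key.setdefault((c.contig_id, c.strand), []).append(c)
    for (contig, strand), group in sorted(by_key.items()):
        group.sort(key=lambda r: r.position)
        cluster: list[TSSRecord] = []
        prev = None
        for rec in group + [None]:
            if rec is not None and (prev is None or rec.position - prev <= merge_range):
                cluster.append(rec)
            else:
                if strand == "+":
                    best = max(cluster, key=lambda r: (r.tap_plus_count, -r.position))
                else:
                    best = max(cluster, key=lambda r: (r.tap_plus_count, r.position))
                out.append(best)
                if rec is not None:
                    cluster = [rec]
            if rec is not None:
                prev = rec.position
    out.sort(key=lambda r: (r.contig_id, r.strand, r.position))
    return out


def call_tss(
    tap_plus: EndCoverage,
    tap_minus: EndCoverage,
    params: TSSCallParams | None = None,
) -> list[TSSRecord]:
    """Call TSSs from a TAP+/TAP- coverage pair.

    A position is emitted iff its raw TAP+ count >= ``noise_threshold`` and
    the one-sided Skellam p-value of the observed library-scaled count
    difference is <= ``pvalue_threshold``; nearby candidates are then merged
    (:func:`merge_tss`). Output is sorted by contig, strand, position.
    """
    params = params or TSSCallParams()
    if set(tap_plus.keys()) != set(tap_minus.keys()):
        raise ValueError("TAP+ and TAP- coverages have mismatched contigs/strands")
    n_minus = tap_minus.library_size
    size_ratio = tap_plus.library_size / n_minus if n_minus > 0 else 1.0
    candidates: list[TSSRecord] = []
    for contig_id, strand in sorted(tap_plus.keys()):
        n_before = len(candidates)
        plus = tap_plus.array(contig_id, strand)
        minus = tap_minus.array(contig_id, strand)
        for pos in np.flatnonzero(plus >= params.noise_threshold):
            pos = int(pos)
            lam = estimate_background(
                tap_plus, tap_minus, contig_id, strand, pos, params, size_ratio
            )
            k = int(plus[pos]) - int(round(minus[pos] * size_ratio))
            p = skellam_sf(k, lam)
            if p <= params.pvalue_threshold:
                candidates.append(
                    TSSRecord(
                        contig_id=contig_id,
                        position=pos,
                        strand=strand,
                        tap_plus_count=int(plus[pos]),
                        tap_minus_count=int(minus[pos]),
                        p_value=p,
                    )
                )
        logger.info("%s(%s): %d candidate positions", contig_id, strand,
                    len(candidates) - n_before)
    merged = merge_tss(candidates, params.merge_range)
    logger.info("%d candidates merged to %d TSSs", len(candidates), len(merged))
    return merged
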