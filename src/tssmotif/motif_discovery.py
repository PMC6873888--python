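"""De novo motif discovery by ZOOPS expectation-maximisation.

The model: each input sequence contains zero or one motif occurrence
(ZOOPS). A sequence is emitted by a 0-order background except, with prior
probability gamma, one window of width w drawn uniformly over offsets (and
strands, when reverse-complement scanning is on) which is emitted by the
motif's position probability matrix. EM alternates a posterior over
{no site, site at each offset/strand} per sequence with PWM and
occurrence-prior updates; the penalised observed-data log likelihood is
non-decreasing across iterations.

Multiple motifs are found sequentially: after each motif, its sites are
probabilistically erased (positions down-weighted by the site posterior)
and the search repeats. Widths are scanned over a geometric ladder and the
winning width per round is chosen by a permutation z-score.

Significance is assessed by a permutation scheme: the motif's
log-likelihood-ratio statistic, recomputed by an iteration-capped fit, is
compared with the same statistic on letter-shuffled sequences; a Gaussian
tail fitted to the null sample gives the p-value, multiplied by the number
of candidate widths tested to give the E-value.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as _stats

from ._seq import BASES, base_composition, decode, encode, revcomp
from .io_formats import GeneAnnotation, GenomeRecord
from .tss_calling import TSSRecord

logger = logging.getLogger(__name__)

DEFAULT_WIDTH_LADDER = (4, 5, 6, 8, 10, 12, 15, 19, 24, 30, 38, 48)
LOG_ODDS_EPS = 1e-3  # quantisation step of the log-odds matrix, in bits


@dataclass
class DiscoveryParams:
    window: int = 50  # upstream window length (for extraction callers)
    min_width: int = 4
    max_width: int = 50
    n_motifs: int = 50
    revcomp: bool = True
    evalue_cutoff: float = 0.05
    min_tss: int = 13  # minimum number of sequences assigned a site
    width_ladder: tuple[int, ...] = DEFAULT_WIDTH_LADDER
    gamma_init: float = 0.8
    pseudocount: float = 1.0  # total Dirichlet mass per column, spread as bg
    max_iter: int = 200
    tol: float = 1e-6
    n_seeds: int = 30
    seed_eval_iters: int = 2
    # permutation machinery: the significance statistic is computed by a
    # standardized fit (fixed seed count, capped iterations, no phase
    # refinement) applied identically to observed and shuffled sequences
    stat_seeds: int = 15
    stat_iters: int = 30
    n_sel_shuffles: int = 10
    n_eval_shuffles: int = 200
    max_failed_rounds: int = 3
    # width optimisation: trim the fitted PWM to the contiguous column block
    # maximising total information content minus this per-column charge, then
    # refit at the trimmed width (guards against one wide motif straddling
    # two distinct signals)
    trim_penalty_bits: float = 0.2

    def ladder(self) -> list[int]:
        return [w for w in self.width_ladder if self.min_width <= w <= self.max_width]


@dataclass(frozen=True)
class SiteAssignment:
    seq_index: int
    offset: int  # 0-based start of the occupied slice in the input sequence
    strand: str  # '+' motif read forward, '-' motif on the reverse complement
    posterior: float


@dataclass
class PWMMotif:
    """A position weight matrix with background and discovery statistics."""

    count_matrix: np.ndarray  # (4, w) expected base counts from sites
    background: np.ndarray  # (4,) base frequencies
    pseudocount: float = 1.0
    n_sites: float = 0.0  # expected number of sequences with a site
    e_value: float | None = None
    name: str = "motif"
    n_assigned: int = 0  # sequences with site posterior >= 0.5
    sites: list[SiteAssignment] = field(default_factory=list)
    objective_trace: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.count_matrix = np.asarray(self.count_matrix, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.count_matrix.shape[0] != 4:
            raise ValueError("count matrix must be 4 x width")
        if (self.count_matrix < 0).any():
            raise ValueError("negative counts")
        if abs(self.background.sum() - 1.0) > 1e-9:
            raise ValueError("background must sum to 1")

    @property
    def width(self) -> int:
        return self.count_matrix.shape[1]

    @property
    def prob_matrix(self) -> np.ndarray:
        """(counts + pseudocount*bg) / (column total + pseudocount)."""
        num = self.count_matrix + self.pseudocount * self.background[:, None]
        return num / num.sum(axis=0, keepdims=True)

    @property
    def log_odds(self) -> np.ndarray:
        """Log2(prob/background), floored at -30 bits (zero-probability
        cells) and quantised to LOG_ODDS_EPS bits."""
        prob = np.maximum(self.prob_matrix, self.background[:, None] * 2.0**-30)
        lo = np.log2(prob / self.background[:, None])
        return np.round(lo / LOG_ODDS_EPS) * LOG_ODDS_EPS

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in np.argmax(self.prob_matrix, axis=0))

    def max_score(self) -> float:
        return float(self.log_odds.max(axis=0).sum())

    def min_score(self) -> float:
        return float(self.log_odds.min(axis=0).sum())

    def reverse_complement(self) -> "PWMMotif":
        return PWMMotif(
            count_matrix=self.count_matrix[::-1, ::-1].copy(),
            background=self.background.copy(),
            pseudocount=self.pseudocount,
            n_sites=self.n_sites,
            e_value=self.e_value,
            name=self.name,
            n_assigned=self.n_assigned,
            sites=list(self.sites),
            objective_trace=list(self.objective_trace),
        )


# ---------------------------------------------------------------------------
# window bookkeeping


class _WindowSet:
    """All candidate motif windows of one width over a sequence set."""

    def __init__(self, enc_seqs, width, revcomp_mode, keep=None):
        self.width = width
        self.revcomp_mode = revcomp_mode
        xs, seq_id, offs, strands = [], [], [], []
        self.eligible = [i for i, s in enumerate(enc_seqs) if len(s) >= width]
        for i in self.eligible:
            s = enc_seqs[i]
            m = len(s) - width + 1
            win = np.lib.stride_tricks.sliding_window_view(s, width)
            xs.append(win)
            seq_id.append(np.full(m, i))
            offs.append(np.arange(m))
            strands.append(np.zeros(m, dtype=np.int8))
            if revcomp_mode:
                xs.append((3 - win)[:, ::-1])
                seq_id.append(np.full(m, i))
                offs.append(np.arange(m))
                strands.append(np.ones(m, dtype=np.int8))
        if not xs:
            raise ValueError("no sequence is long enough for this width")
        self.X = np.ascontiguousarray(np.concatenate(xs)).astype(np.int8)
        self.seq_id = np.concatenate(seq_id)
        self.offset = np.concatenate(offs)
        self.strand = np.concatenate(strands)
        # windows of one sequence are contiguous; segment starts for reduceat
        self.starts = np.flatnonzero(np.diff(self.seq_id, prepend=-1))
        self.n_seq_eligible = len(self.eligible)
        # per-window and per-sequence background log likelihood
        self._set_keep(enc_seqs, keep)
        # low-complexity mask: a window dominated by one homopolymer run
        # cannot be a motif site (otherwise the EM drifts into degenerate
        # poly-A/T optima on AT-rich genomes)
        run = _run_threshold(width)
        eq = self.X[:, 1:] == self.X[:, :-1]
        if eq.shape[1] >= run:
            lowc = (
                np.lib.stride_tricks.sliding_window_view(eq, run, axis=1)
                .all(axis=2)
                .any(axis=1)
            )
            self.log_u = np.where(lowc, -np.inf, self.log_u)

    def set_background(self, log_bg: np.ndarray) -> None:
        # bg loglik of the *forward* slice under the 0-order background
        fwd = np.where(self.strand[:, None] == 0, self.X, 3 - self.X[:, ::-1])
        self.lb_win = log_bg[fwd].sum(axis=1)

    def _set_keep(self, enc_seqs, keep) -> None:
        """Erasure weight per window: product of position keep-probabilities."""
        if keep is None:
            self.log_u = np.zeros(len(self.seq_id))
            return
        vals = np.empty(len(self.seq_id))
        w = self.width
        pos = 0
        for i in self.eligible:
            k = np.log(np.clip(keep[i], 1e-10, 1.0))
            pref = np.concatenate(([0.0], np.cumsum(k)))
            m = len(enc_seqs[i]) - w + 1
            span = pref[w:] - pref[:-w]
            vals[pos : pos + m] = span
            pos += m
            if self.revcomp_mode:
                # reverse-strand windows cover the same genomic slice
                vals[pos : pos + m] = span
                pos += m
        self.log_u = vals


def _motif_loglik(X: np.ndarray, log_theta: np.ndarray) -> np.ndarray:
    out = np.zeros(X.shape[0])
    for t in range(X.shape[1]):
        out += log_theta[X[:, t], t]
    return out


def _segment_lse(a: np.ndarray, starts: np.ndarray) -> np.ndarray:
    mx = np.maximum.reduceat(a, starts)
    safe_mx = np.where(np.isfinite(mx), mx, 0.0)
    shifted = a - np.repeat(safe_mx, np.diff(np.append(starts, len(a))))
    s = np.add.reduceat(np.exp(shifted), starts)
    out = safe_mx + np.log(s)
    return np.where(np.isfinite(mx), out, -np.inf)


@dataclass
class _FitResult:
    log_theta: np.ndarray
    gamma: float
    objective: float
    trace: list[float]
    Z: np.ndarray  # posterior per window
    p_site: np.ndarray  # per eligible sequence
    windows: "_WindowSet"


def _fit_em(
    ws: _WindowSet,
    log_bg: np.ndarray,
    theta0: np.ndarray,
    gamma0: float,
    pseudo: np.ndarray,
    lb_total: float,
    max_iter: int,
    tol: float,
) -> _FitResult:
    """Run ZOOPS EM to convergence from one starting PWM."""
    log_theta = np.log(theta0)
    gamma = gamma0
    counts_m = np.diff(np.append(ws.starts, len(ws.seq_id)))
    log_m = np.log(np.repeat(counts_m, counts_m))
    trace: list[float] = []
    prev = -np.inf
    Z = np.zeros(len(ws.seq_id))
    p_site = np.zeros(ws.n_seq_eligible)
    for _ in range(max_iter):
        # E-step
        lm = _motif_loglik(ws.X, log_theta)
        a = np.log(gamma) + ws.log_u - log_m + (lm - ws.lb_win)
        seg = _segment_lse(a, ws.starts)
        total = np.logaddexp(np.log1p(-gamma), seg)
        Z = np.exp(a - np.repeat(total, counts_m))
        p_site = np.exp(seg - total)
        obj = lb_total + float(total.sum()) + float((pseudo * log_theta).sum())
        trace.append(obj)
        if prev > -np.inf and abs(obj - prev) <= tol * abs(prev):
            break
        prev = obj
        # M-step
        C = pseudo.copy()
        for t in range(ws.width):
            np.add.at(C[:, t], ws.X[:, t], Z)
        log_theta = np.log(C / C.sum(axis=0, keepdims=True))
        gamma = float(np.clip(p_site.mean(), 1e-4, 1 - 1e-4))
    return _FitResult(log_theta, gamma, trace[-1], trace, Z, p_site, ws)


def _zoops_gain(ws: _WindowSet, log_theta: np.ndarray, gamma: float) -> float:
    """Observed-data log-likelihood gain over background for a fixed PWM."""
    counts_m = np.diff(np.append(ws.starts, len(ws.seq_id)))
    log_m = np.log(np.repeat(counts_m, counts_m))
    lm = _motif_loglik(ws.X, log_theta)
    a = np.log(gamma) + ws.log_u - log_m + (lm - ws.lb_win)
    seg = _segment_lse(a, ws.starts)
    total = np.logaddexp(np.log1p(-gamma), seg)
    return float(total.sum())


def _run_threshold(width: int) -> int:
    """A run of more than max(3, width//2) identical bases marks a window
    as low-complexity (the mask tests for `threshold` consecutive equal
    neighbour pairs, i.e. a run of threshold+1 bases)."""
    return max(3, width // 2)


def _max_run(digits: np.ndarray) -> int:
    best = run = 1
    for i in range(1, len(digits)):
        run = run + 1 if digits[i] == digits[i - 1] else 1
        best = max(best, run)
    return best


def _seed_thetas(
    ws: _WindowSet, rng: np.random.Generator, n_seeds: int, bg: np.ndarray
) -> list[np.ndarray]:
    """Starting PWMs from candidate windows.

    Candidates are ranked by the *excess* of their anchored k-mer's
    erasure-weighted count (exact plus discounted one-mismatch neighbours)
    over its 0-order background expectation. Background-typical words —
    the AT-rich k-mers that dominate raw counts in a low-GC genome — score
    near zero by construction, while a planted motif's instances are pure
    excess. Low-complexity k-mers (a single-base run over half the k-mer)
    are excluded, and the list is topped up with random windows under the
    same filter.
    """
    fwd = np.flatnonzero(ws.strand == 0)
    w = ws.width
    k = min(w, 8)
    u = np.exp(ws.log_u[fwd])
    total_u = u.sum()
    anchors = sorted({0, (w - k) // 2, w - k})
    powers = 4 ** np.arange(k)
    picks: list[int] = []
    n_top = max(2, n_seeds // 2)
    per_anchor = max(1, n_top // len(anchors) + 1)
    for a in anchors:
        block = ws.X[fwd][:, a : a + k]
        keys = block.astype(np.int64) @ powers
        uniq, first, inv = np.unique(keys, return_index=True, return_inverse=True)
        n0 = np.bincount(inv, weights=u)
        # one-mismatch neighbour mass via per-position wildcard grouping
        n1 = np.zeros(len(uniq))
        for p in range(k):
            rkey = keys - block[:, p].astype(np.int64) * powers[p]
            _, rinv = np.unique(rkey, return_inverse=True)
            wsum = np.bincount(rinv, weights=u)
            n1 += wsum[rinv[first]]
        n1 -= k * n0
        digits = block[first]
        e0 = total_u * np.prod(bg[digits], axis=1)
        e1 = e0 * ((1.0 - bg[digits]) / bg[digits]).sum(axis=1)
        score = (n0 - e0) + 0.3 * (n1 - e1)
        order = np.argsort(score)[::-1]
        taken = 0
        for idx in order:
            if taken >= per_anchor:
                break
            if _max_run(digits[idx]) > _run_threshold(k):
                continue
            cands = np.flatnonzero(inv == idx)
            take = cands[np.argsort(-u[cands])[:2]]
            picks.extend(int(fwd[c]) for c in take)
            taken += 1
    picks = list(dict.fromkeys(picks))[:n_top]
    chosen = set(picks)
    remaining = [int(i) for i in fwd
                 if int(i) not in chosen and _max_run(ws.X[i]) <= _run_threshold(w)]
    if remaining and len(picks) < n_seeds:
        extra = rng.choice(remaining, size=min(n_seeds - len(picks), len(remaining)),
                           replace=False)
        picks.extend(int(e) for e in extra)
    thetas = []
    for p in picks:
        th = np.full((4, w), 0.1)
        th[ws.X[p], np.arange(w)] = 0.7
        thetas.append(th)
    return thetas


def _fit_width(
    enc_seqs,
    width: int,
    params: DiscoveryParams,
    bg: np.ndarray,
    rng: np.random.Generator,
    keep=None,
    max_iter: int | None = None,
    n_seeds: int | None = None,
    refine: bool = True,
) -> _FitResult | None:
    eligible = [s for s in enc_seqs if len(s) >= width]
    if len(eligible) < 2:
        return None
    ws = _WindowSet(enc_seqs, width, params.revcomp, keep)
    log_bg = np.log(bg)
    ws.set_background(log_bg)
    lb_total = float(sum(log_bg[s].sum() for s in enc_seqs))
    pseudo = params.pseudocount * bg[:, None] * np.ones((4, width))
    n_eff = n_seeds or params.n_seeds
    thetas = _seed_thetas(ws, rng, 3 * n_eff, bg)
    # screen candidates by composition-discounted evidence: the ZOOPS gain
    # on the data minus the gain on one letter-shuffled copy; a candidate
    # that merely reflects base composition scores near zero
    ws_null = _WindowSet(_shuffled(enc_seqs, rng), width, params.revcomp, keep)
    ws_null.set_background(log_bg)
    gains = np.array([
        _zoops_gain(ws, np.log(th), params.gamma_init)
        - _zoops_gain(ws_null, np.log(th), params.gamma_init)
        for th in thetas
    ])
    best = None
    for idx in np.argsort(gains)[::-1][: max(4, n_eff // 3)]:
        r = _fit_em(ws, log_bg, thetas[idx], params.gamma_init, pseudo, lb_total,
                    max_iter=params.seed_eval_iters, tol=0.0)
        if best is None or r.objective > best[0].objective:
            best = (r, thetas[idx])
    r = _fit_em(ws, log_bg, best[1], params.gamma_init, pseudo, lb_total,
                max_iter=max_iter or params.max_iter, tol=params.tol)
    # phase-shift refinement: EM can converge in a register shifted by a few
    # columns; try shifted starts and keep the best converged objective
    improved = refine
    guard = 0
    while improved and guard < 4:
        improved = False
        guard += 1
        for shift in (-2, -1, 1, 2):
            th = np.tile(bg[:, None], (1, width))
            src = np.exp(r.log_theta)
            if shift > 0:
                th[:, shift:] = src[:, : width - shift]
            else:
                th[:, :shift] = src[:, -shift:]
            r2 = _fit_em(ws, log_bg, th, r.gamma, pseudo, lb_total,
                         max_iter=max_iter or params.max_iter, tol=params.tol)
            if r2.objective > r.objective * (1 - 1e-9) and r2.objective > r.objective:
                r = r2
                improved = True
    return r


def _fit_statistic(enc_seqs, width, params, bg, rng, keep=None) -> float:
    """Standardized fit statistic used for significance; the identical
    procedure is applied to observed and shuffled data."""
    r = _fit_width(enc_seqs, width, params, bg, rng, keep,
                   max_iter=params.stat_iters, n_seeds=params.stat_seeds,
                   refine=False)
    if r is None:
        return 0.0
    return r.objective


def _best_block(theta: np.ndarray, bg: np.ndarray, penalty: float):
    """Maximum-subarray block of per-column information content minus a
    per-column charge; returns (start, end, score)."""
    w = theta.shape[1]
    ic = (theta * np.log2(theta / bg[:, None])).sum(axis=0) - penalty
    best_sum, best = -np.inf, (0, w)
    cur, start = 0.0, 0
    for t in range(w):
        if cur <= 0:
            cur, start = ic[t], t
        else:
            cur += ic[t]
        if cur > best_sum:
            best_sum, best = cur, (start, t + 1)
    return best[0], best[1], best_sum


def _refit(enc_seqs, params, bg, keep, theta0, gamma, max_iter=None) -> _FitResult:
    width = theta0.shape[1]
    ws = _WindowSet(enc_seqs, width, params.revcomp, keep)
    log_bg = np.log(bg)
    ws.set_background(log_bg)
    lb_total = float(sum(log_bg[s].sum() for s in enc_seqs))
    pseudo = params.pseudocount * bg[:, None] * np.ones((4, width))
    return _fit_em(ws, log_bg, theta0, gamma, pseudo, lb_total,
                   max_iter=max_iter or params.max_iter, tol=params.tol)


def _trim_width(
    r: _FitResult,
    enc_seqs,
    params: DiscoveryParams,
    bg: np.ndarray,
    keep,
) -> _FitResult:
    """Trim the converged PWM to its best contiguous column block.

    If the block is a proper sub-block of at least min_width columns, the
    motif is refit at the trimmed width from the trimmed probabilities.
    """
    theta = np.exp(r.log_theta)
    w = theta.shape[1]
    a, b, _ = _best_block(theta, bg, params.trim_penalty_bits)
    if b - a < params.min_width or (a, b) == (0, w):
        return r
    return _refit(enc_seqs, params, bg, keep, theta[:, a:b], r.gamma)


def _optimize_width(
    r: _FitResult,
    enc_seqs,
    params: DiscoveryParams,
    bg: np.ndarray,
    keep,
) -> _FitResult:
    """Width optimisation: widen the fitted motif by background-padded
    flanks, refit, and keep whichever of (original, widened) has the
    stronger maximum-information column block, trimmed to that block.

    Widening rescues motifs whose selected ladder width clipped real
    flanking signal (which would otherwise resurface later as fragment
    motifs); trimming guards against one wide motif straddling two
    distinct signals.
    """
    w = r.windows.width
    pad = 5
    longest = max(len(s) for s in enc_seqs)
    w2 = min(w + 2 * pad, longest)
    cand = _trim_width(r, enc_seqs, params, bg, keep)
    _, _, s1 = _best_block(np.exp(r.log_theta), bg, params.trim_penalty_bits)
    if w2 > w and sum(len(s) >= w2 for s in enc_seqs) >= 2:
        theta = np.exp(r.log_theta)
        left = (w2 - w) // 2
        th2 = np.tile(bg[:, None], (1, w2))
        th2[:, left : left + w] = theta
        r2 = _refit(enc_seqs, params, bg, keep, th2, r.gamma)
        _, _, s2 = _best_block(np.exp(r2.log_theta), bg, params.trim_penalty_bits)
        if s2 > s1:
            return _trim_width(r2, enc_seqs, params, bg, keep)
    return cand


def _shuffled(enc_seqs, rng) -> list[np.ndarray]:
    return [rng.permutation(s) for s in enc_seqs]


def _null_stats(enc_seqs, width, params, bg, rng, n, keep=None) -> np.ndarray:
    out = np.empty(n)
    for i in range(n):
        out[i] = _fit_statistic(_shuffled(enc_seqs, rng), width, params, bg, rng, keep)
    return out


def _evalue_from_null(obs: float, null: np.ndarray, n_widths: int) -> float:
    """Gaussian tail fitted to the permutation null, scaled by the number of
    candidate widths (multiple testing over the width ladder)."""
    mu, sd = float(null.mean()), float(null.std(ddof=1))
    if sd <= 0:
        p = 1.0 if obs <= mu else 0.0
    else:
        p = float(_stats.norm.sf((obs - mu) / sd))
    return min(p * n_widths, float(n_widths))


def motif_evalue(
    motif: PWMMotif,
    sequences: list[str],
    params: DiscoveryParams | None = None,
    n_shuffles: int | None = None,
    seed: int = 0,
    n_widths: int = 1,
) -> float:
    """Permutation E-value of a fitted motif on its training sequences."""
    params = params or DiscoveryParams()
    rng = np.random.default_rng(seed)
    enc = [encode(s) for s in sequences if s]
    bg = base_composition(enc)
    n = n_shuffles or params.n_eval_shuffles
    obs = _fit_statistic(enc, motif.width, params, bg, rng)
    null = _null_stats(enc, motif.width, params, bg, rng, n)
    return _evalue_from_null(obs, null, n_widths)


def _result_to_motif(
    r: _FitResult, bg: np.ndarray, params: DiscoveryParams, name: str
) -> PWMMotif:
    ws = r.windows
    counts = np.zeros((4, ws.width))
    for t in range(ws.width):
        np.add.at(counts[:, t], ws.X[:, t], r.Z)
    sites: list[SiteAssignment] = []
    starts = np.append(ws.starts, len(ws.seq_id))
    for si in range(len(ws.starts)):
        sl = slice(starts[si], starts[si + 1])
        j = int(np.argmax(r.Z[sl])) + starts[si]
        p = float(r.p_site[si])
        if p >= 0.5:
            sites.append(
                SiteAssignment(
                    seq_index=int(ws.eligible[si]),
                    offset=int(ws.offset[j]),
                    strand="+" if ws.strand[j] == 0 else "-",
                    posterior=p,
                )
            )
    motif = PWMMotif(
        count_matrix=counts,
        background=bg.copy(),
        pseudocount=params.pseudocount,
        n_sites=float(r.p_site.sum()),
        name=name,
        n_assigned=len(sites),
        sites=sites,
        objective_trace=list(r.trace),
    )
    # canonical orientation: majority of sites on the forward strand
    if sites and sum(1 for s in sites if s.strand == "-") * 2 > len(sites):
        flipped = motif.reverse_complement()
        flipped.sites = [
            SiteAssignment(s.seq_index, s.offset,
                           "+" if s.strand == "-" else "-", s.posterior)
            for s in sites
        ]
        motif = flipped
    return motif


def zoops_em(
    sequences: list[str],
    params: DiscoveryParams | None = None,
    seed: int = 0,
) -> list[PWMMotif]:
    """Sequentially discover up to ``n_motifs`` motifs in ``sequences``.

    Returns motifs passing the E-value cutoff and the minimum assigned
    sequence count, ranked by discovery order (each round reports the most
    significant remaining motif). Deterministic under ``seed``.
    """
    params = params or DiscoveryParams()
    rng = np.random.default_rng(seed)
    enc = []
    for s in sequences:
        if len(s) >= params.min_width:
            enc.append(encode(s))
        else:
            logger.info("dropping sequence of length %d < min_width", len(s))
    if len(enc) < 2:
        logger.warning("fewer than 2 usable sequences; no motifs searched")
        return []
    bg = base_composition(enc)
    widths = [w for w in params.ladder() if sum(len(s) >= w for s in enc) >= 2]
    if not widths:
        logger.warning("no width in the ladder fits the sequences")
        return []
    keep = [np.ones(len(s)) for s in enc]
    motifs: list[PWMMotif] = []
    failed_rounds = 0
    for round_no in range(params.n_motifs):
        fits: dict[int, _FitResult] = {}
        obs_stats: dict[int, float] = {}
        zscores: dict[int, float] = {}
        sel_nulls: dict[int, np.ndarray] = {}
        for w in widths:
            # independent child streams per (round, width): one width's rng
            # consumption never perturbs another's result
            rng_fit = np.random.default_rng([seed, round_no, w, 0])
            rng_stat = np.random.default_rng([seed, round_no, w, 1])
            r = _fit_width(enc, w, params, bg, rng_fit, keep)
            if r is None:
                continue
            obs = _fit_statistic(enc, w, params, bg, rng_stat, keep)
            null = _null_stats(enc, w, params, bg, rng_stat,
                               params.n_sel_shuffles, keep)
            sd = null.std(ddof=1)
            zscores[w] = (obs - null.mean()) / sd if sd > 0 else 0.0
            fits[w] = r
            obs_stats[w] = obs
            sel_nulls[w] = null
        if not fits:
            break
        w_best = max(zscores, key=lambda w: zscores[w])
        r = _optimize_width(fits[w_best], enc, params, bg, keep)
        rng_eval = np.random.default_rng([seed, round_no, w_best, 2])
        extra = _null_stats(enc, w_best, params, bg, rng_eval,
                            params.n_eval_shuffles - params.n_sel_shuffles, keep)
        null = np.concatenate([sel_nulls[w_best], extra])
        e_value = _evalue_from_null(obs_stats[w_best], null, n_widths=len(widths))
        motif = _result_to_motif(r, bg, params, name=f"motif_{round_no + 1}")
        motif.e_value = e_value
        passed = e_value <= params.evalue_cutoff and motif.n_assigned >= params.min_tss
        logger.info(
            "round %d: width %d, E=%.3g, %d sequences assigned, %s",
            round_no + 1, w_best, e_value, motif.n_assigned,
            "kept" if passed else "rejected",
        )
        if passed:
            motifs.append(motif)
            failed_rounds = 0
            # probabilistic erasing of the kept motif's windows; rejected
            # rounds erase nothing so a misjudged motif can be retried
            ws = r.windows
            for si, off, z in zip(ws.seq_id, ws.offset, r.Z):
                if z > 1e-6:
                    keep[si][off : off + ws.width] *= 1.0 - z
        else:
            failed_rounds += 1
            if failed_rounds >= params.max_failed_rounds:
                break
    return motifs


# ---------------------------------------------------------------------------
# sequence extraction and Shine-Dalgarno search


def extract_upstream(
    tss_list: list[TSSRecord], genome: list[GenomeRecord], length: int
) -> list[str]:
    """Upstream sequences read 5'->3' on the transcribed strand, ending at
    the base immediately before each TSS; truncated at contig edges.

    The returned list is parallel to ``tss_list`` (possibly with entries
    shorter than requested, down to the empty string at a contig edge).
    """
    if length not in (50, 100, 150):
        logger.warning("non-standard upstream window length %d", length)
    seqs = {g.contig_id: g.sequence for g in genome}
    out = []
    for t in tss_list:
        s = seqs[t.contig_id]
        if t.strand == "+":
            out.append(s[max(0, t.position - length) : t.position])
        else:
            out.append(revcomp(s[t.position + 1 : t.position + 1 + length]))
    return out


def extract_gene_upstream(
    genes: list[GeneAnnotation], genome: list[GenomeRecord], length: int
) -> list[str]:
    """Windows ending at the base immediately before each gene's start codon."""
    seqs = {g.contig_id: g.sequence for g in genome}
    out = []
    for g in genes:
        s = seqs[g.contig_id]
        if g.strand == "+":
            out.append(s[max(0, g.start - length) : g.start])
        else:
            out.append(revcomp(s[g.end : g.end + length]))
    return out


def find_shine_dalgarno(
    genes: list[GeneAnnotation],
    genome: list[GenomeRecord],
    window: int = 30,
    params: DiscoveryParams | None = None,
    seed: int = 0,
) -> tuple[PWMMotif | None, dict[str, int]]:
    """Search the ribosome-binding-site motif upstream of start codons.

    Runs the ZOOPS search on the ``window`` nt ending at each annotated
    start codon (default parameters mirror the promoter search but with
    n_motifs=10 and max_width=30). Returns the top motif and, for each gene
    with a forward-strand site, the spacing in nt between the motif match
    end and the start codon's first base.
    """
    params = params or DiscoveryParams(n_motifs=10, max_width=30, window=window)
    seqs = extract_gene_upstream(genes, genome, window)
    motifs = zoops_em(seqs, params, seed=seed)
    if not motifs:
        return None, {}
    top = motifs[0]
    spacings: dict[str, int] = {}
    for site in top.sites:
        if site.strand != "+":
            continue  # the SD must lie on the mRNA strand
        gene = genes[site.seq_index]
        wlen = len(seqs[site.seq_index])
        spacings[gene.gene_id] = wlen - (site.offset + top.width)
    return top, spacings


# ---------------------------------------------------------------------------
# MEME minimal motif format


def write_meme(motifs: list[PWMMotif], path) -> None:
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n")
        bg = motifs[0].background if motifs else np.full(4, 0.25)
        fh.write("Background letter frequencies\n")
        fh.write(" ".join(f"{b} {f:.5f}" for b, f in zip(BASES, bg)) + "\n\n")
        for m in motifs:
            fh.write(f"MOTIF {m.name}\n")
            ev = m.e_value if m.e_value is not None else 0.0
            fh.write(
                f"letter-probability matrix: alength= 4 w= {m.width} "
                f"nsites= {m.n_sites:.1f} E= {ev:.3g}\n"
            )
            for col in m.prob_matrix.T:
                fh.write(" ".join(f"{x:.6f}" for x in col) + "\n")
            fh.write("\n")


def read_meme(path) -> list[PWMMotif]:
    motifs: list[PWMMotif] = []
    bg = np.full(4, 0.25)
    with open(path) as fh:
        lines = fh.readlines()
    i = 0
    while i < len(lines):
        line = lines[i].strip()
        if line.startswith("Background letter frequencies"):
            parts = lines[i + 1].split()
            bg = np.array([float(parts[j]) for j in (1, 3, 5, 7)])
            bg = bg / bg.sum()  # file rounding
            i += 2
            continue
        if line.startswith("MOTIF"):
            name = line.split()[1]
            i += 1
            header = lines[i].strip()
            fields = dict(
                zip(header.split()[2::2], header.split()[3::2])
            )  # alength= / w= / nsites= / E=
            w = int(fields["w="])
            nsites = float(fields.get("nsites=", 0.0))
            ev = float(fields.get("E=", 0.0))
            rows = []
            for j in range(w):
                i += 1
                rows.append([float(x) for x in lines[i].split()])
            probs = np.array(rows).T
            counts = probs * max(nsites, 1.0)
            m = PWMMotif(count_matrix=counts, background=bg, pseudocount=0.0,
                         n_sites=nsites, e_value=ev, name=name)
            motifs.append(m)
        i += 1
    return motifs
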