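import numpy as np
import pytest
from scipy.stats import poisson

from tssmotif.io_formats import TAP_MINUS, TAP_PLUS, EndCoverage
from tssmotif.synthetic_data import SimulationParams, generate_genome, simulate_libraries
from tssmotif.tss_calling import (
    SkellamParams,
    TSSCallParams,
    TSSRecord,
    call_tss,
    estimate_background,
    merge_tss,
    skellam_sf,
)


def convolution_sf(k, lam_plus, lam_minus):
    """Independent oracle: truncated double-Poisson convolution of
    P(X - Y >= k), terms to below 1e-15."""
    n = int(max(lam_plus, lam_minus) * 20 + 400)
    px = poisson.pmf(np.arange(n), lam_plus) if lam_plus > 0 else np.eye(1, n)[0]
    cy = (
        np.cumsum(poisson.pmf(np.arange(n), lam_minus))
        if lam_minus > 0
        else np.ones(n)
    )
    total = 0.0
    for x in range(n):
        ymax = x - k
        if ymax >= 0:
            total += px[x] * cy[min(ymax, n - 1)]
    return total


class TestSkellamSf:
    def test_degenerate_zero_rates(self):
        assert skellam_sf(1, SkellamParams(0.0, 0.0)) == 0.0
        assert skellam_sf(0, SkellamParams(0.0, 0.0)) == 1.0

    def test_whole_support(self):
        assert skellam_sf(-(10**6), SkellamParams(1.0, 1.0)) == pytest.approx(1.0, abs=1e-12)

    def test_frozen_convolution_values(self):
        # regression constants computed with convolution_sf before the build
        assert skellam_sf(5, SkellamParams(1.0, 1.0)) == pytest.approx(
            0.0015809281437018576, abs=1e-12
        )
        assert skellam_sf(3, SkellamParams(0.5, 2.0)) == pytest.approx(
            0.0024705085232580313, abs=1e-12
        )

    @pytest.mark.parametrize("lam", [0.1, 1.0, 5.0, 20.0])
    def test_agrees_with_convolution_oracle(self, lam):
        ks = list(range(-50, 51, 7)) + [-1, 0, 1, 2]
        for k in ks:
            assert skellam_sf(k, SkellamParams(lam, lam)) == pytest.approx(
                convolution_sf(k, lam, lam), abs=1e-10
            )

    def test_one_sided_zero_lambda_minus(self):
        # difference reduces to X alone
        assert skellam_sf(3, SkellamParams(2.0, 0.0)) == pytest.approx(
            poisson.sf(2, 2.0), abs=1e-12
        )

    def test_monotone_in_k(self):
        lam = SkellamParams(2.0, 1.0)
        vals = [skellam_sf(k, lam) for k in range(-20, 21)]
        assert all(a >= b - 1e-15 for a, b in zip(vals, vals[1:]))

    def test_non_finite_lambda_rejected(self):
        with pytest.raises(ValueError):
            SkellamParams(np.inf, 1.0)


def _coverage(plus_arr, minus_arr):
    tp = EndCoverage(TAP_PLUS)
    tm = EndCoverage(TAP_MINUS)
    tp.counts[("c1", "+")] = np.asarray(plus_arr, dtype=np.int64)
    tp.counts[("c1", "-")] = np.zeros_like(tp.counts[("c1", "+")])
    tm.counts[("c1", "+")] = np.asarray(minus_arr, dtype=np.int64)
    tm.counts[("c1", "-")] = np.zeros_like(tm.counts[("c1", "+")])
    return tp, tm


class TestEstimateBackground:
    def test_all_zero_window_floors(self):
        tp, tm = _coverage(np.zeros(2000), np.zeros(2000))
        lam = estimate_background(tp, tm, "c1", "+", 1000, TSSCallParams())
        assert lam.lambda_plus == 1e-3 and lam.lambda_minus == 1e-3

    def test_constant_coverage_mean(self):
        tp, tm = _coverage(np.full(2000, 4), np.full(2000, 4))
        lam = estimate_background(tp, tm, "c1", "+", 1000, TSSCallParams(),
                                  size_ratio=1.0)
        assert lam.lambda_plus == pytest.approx(4.0)

    def test_library_size_scaling(self):
        # equal raw window means, TAP+ library twice as deep: lambda_minus doubles
        tp, tm = _coverage(np.full(2000, 4), np.full(2000, 4))
        lam = estimate_background(tp, tm, "c1", "+", 1000, TSSCallParams(),
                                  size_ratio=2.0)
        assert lam.lambda_minus == pytest.approx(2 * lam.lambda_plus)

    def test_window_truncated_at_edge(self):
        tp, tm = _coverage(np.full(100, 3), np.full(100, 3))
        lam = estimate_background(tp, tm, "c1", "+", 0, TSSCallParams(), size_ratio=1.0)
        assert lam.lambda_plus == pytest.approx(3.0)


def _rec(pos, count, strand="+"):
    return TSSRecord("c1", pos, strand, count, 0, 1e-9)


def merge_oracle(positions_counts, merge_range, strand="+"):
    """Brute-force transitive clustering oracle."""
    recs = sorted(positions_counts)
    clusters = []
    for pos, cnt in recs:
        if clusters and pos - clusters[-1][-1][0] <= merge_range:
            clusters[-1].append((pos, cnt))
        else:
            clusters.append([(pos, cnt)])
    out = []
    for cl in clusters:
        best_cnt = max(c for _, c in cl)
        tied = [p for p, c in cl if c == best_cnt]
        out.append(min(tied) if strand == "+" else max(tied))
    return out


class TestMergeTss:
    def test_max_count_wins(self):
        merged = merge_tss([_rec(100, 50), _rec(103, 80)], 5)
        assert [(r.position, r.tap_plus_count) for r in merged] == [(103, 80)]

    def test_gap_above_range_kept_separate(self):
        merged = merge_tss([_rec(100, 50), _rec(106, 80)], 5)
        assert [r.position for r in merged] == [100, 106]

    def test_transitive_chain_collapses(self):
        merged = merge_tss([_rec(100, 10), _rec(104, 30), _rec(108, 20)], 5)
        assert [r.position for r in merged] == [104]

    def test_upstream_tie_break_respects_strand(self):
        plus = merge_tss([_rec(100, 10), _rec(104, 10)], 5)
        minus = merge_tss([_rec(100, 10, "-"), _rec(104, 10, "-")], 5)
        assert plus[0].position == 100 and minus[0].position == 104

    def test_agrees_with_bruteforce_oracle(self, rng):
        for _ in range(300):
            n = int(rng.integers(1, 15))
            positions = sorted(rng.choice(200, size=n, replace=False))
            counts = rng.integers(10, 100, size=n)
            pc = list(zip([int(p) for p in positions], [int(c) for c in counts]))
            merged = merge_tss([_rec(p, c) for p, c in pc], 5)
            assert [r.position for r in merged] == merge_oracle(pc, 5)


class TestCallTss:
    def test_all_zero_coverage_empty(self):
        tp, tm = _coverage(np.zeros(5000), np.zeros(5000))
        assert call_tss(tp, tm) == []

    def test_single_strong_site_called_exactly_once(self, rng):
        plus = rng.poisson(1.0, 5000)
        minus = rng.poisson(1.0, 5000)
        plus[2500] = 100
        minus[2500] = 0
        tp, tm = _coverage(plus, minus)
        tss = call_tss(tp, tm)
        strong = [t for t in tss if t.position == 2500]
        assert len(strong) == 1 and strong[0].p_value < 1e-10

    def test_noise_threshold_excludes_low_counts(self):
        plus = np.zeros(5000, dtype=int)
        minus = np.zeros(5000, dtype=int)
        plus[2500] = 9  # arbitrarily significant against a zero background
        tp, tm = _coverage(plus, minus)
        assert call_tss(tp, tm) == []
        plus[2500] = 10
        tp, tm = _coverage(plus, minus)
        assert [t.position for t in call_tss(tp, tm)] == [2500]

    def test_mismatched_contigs_rejected(self):
        tp, tm = _coverage(np.zeros(100), np.zeros(100))
        del tm.counts[("c1", "-")]
        with pytest.raises(ValueError):
            call_tss(tp, tm)

    def test_output_invariant_to_contig_insertion_order(self, rng):
        plus1 = rng.poisson(1.0, 3000); plus1[100] = 80
        plus2 = rng.poisson(1.0, 3000); plus2[200] = 90
        tp = EndCoverage(TAP_PLUS); tm = EndCoverage(TAP_MINUS)
        for name, arr in (("b", plus2), ("a", plus1)):
            tp.counts[(name, "+")] = arr.copy()
            tp.counts[(name, "-")] = np.zeros(3000, dtype=int)
            tm.counts[(name, "+")] = np.zeros(3000, dtype=int)
            tm.counts[(name, "-")] = np.zeros(3000, dtype=int)
        order1 = [(t.contig_id, t.position) for t in call_tss(tp, tm)]
        tp2 = EndCoverage(TAP_PLUS, dict(sorted(tp.counts.items())))
        tm2 = EndCoverage(TAP_MINUS, dict(sorted(tm.counts.items())))
        order2 = [(t.contig_id, t.position) for t in call_tss(tp2, tm2)]
        assert order1 == order2 == sorted(order1)

    def test_recovery_on_simulated_data(self, small_simulation):
        _, _, _, truth, tap_plus, tap_minus = small_simulation
        called = {(t.position, t.strand) for t in call_tss(tap_plus, tap_minus)}
        planted = {(t.position, t.strand) for t in truth.primary_tss()}
        exact = len(planted & called) / len(planted)
        assert exact >= 0.9
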