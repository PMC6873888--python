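import numpy as np
import pytest

from tssmotif._seq import revcomp
from tssmotif.io_formats import GeneAnnotation, GenomeRecord
from tssmotif.motif_discovery import (
    DiscoveryParams,
    PWMMotif,
    extract_upstream,
    find_shine_dalgarno,
    motif_evalue,
    read_meme,
    write_meme,
    zoops_em,
)
from tssmotif.synthetic_data import SimulationParams, generate_genome
from tssmotif.tss_calling import TSSRecord


def plant(rng, n, length, consensus, fraction=1.0, identity=1.0):
    seqs = []
    n_with = int(round(fraction * n))
    for i in range(n):
        s = list("".join("ACGT"[j] for j in rng.integers(0, 4, length)))
        if i < n_with:
            pos = int(rng.integers(0, length - len(consensus) + 1))
            for t, c in enumerate(consensus):
                if rng.random() < identity:
                    s[pos + t] = c
                else:
                    s[pos + t] = [b for b in "ACGT" if b != c][rng.integers(3)]
        seqs.append("".join(s))
    return seqs


class TestExtractUpstream:
    def test_plus_strand_slice(self):
        genome = [GenomeRecord("c1", "A" * 200)]
        t = TSSRecord("c1", 100, "+", 1, 0, 0.0)
        (seq,) = extract_upstream([t], genome, 50)
        assert seq == genome[0].sequence[50:100]

    def test_minus_strand_revcomp(self):
        raw = "".join("ACGT"[i % 4] for i in range(200))
        genome = [GenomeRecord("c1", raw)]
        t = TSSRecord("c1", 100, "-", 1, 0, 0.0)
        (seq,) = extract_upstream([t], genome, 50)
        assert seq == revcomp(raw[101:151])

    def test_truncated_at_edge(self):
        genome = [GenomeRecord("c1", "ACGT" * 50)]
        t = TSSRecord("c1", 20, "+", 1, 0, 0.0)
        (seq,) = extract_upstream([t], genome, 50)
        assert seq == genome[0].sequence[0:20]


class TestZoopsEm:
    def test_perfect_planted_signal(self, rng):
        seqs = plant(rng, 20, 30, "GATTACA")
        p = DiscoveryParams(min_width=7, max_width=7, width_ladder=(7,),
                            n_motifs=1, min_tss=5)
        (m,) = zoops_em(seqs, p, seed=2)
        assert m.consensus == "GATTACA"
        assert m.prob_matrix.max(axis=0).min() >= 0.95
        assert m.n_assigned == 20
        assert m.e_value <= 1e-6

    def test_noisy_planted_recovery(self, rng):
        cons = "TGCATACGGTAC"
        seqs = plant(rng, 100, 50, cons, fraction=0.8, identity=0.85)
        p = DiscoveryParams(min_width=12, max_width=12, width_ladder=(12,), n_motifs=1)
        (m,) = zoops_em(seqs, p, seed=3)
        ham = min(
            sum(a != b for a, b in zip(c, cons))
            for c in (m.consensus, revcomp(m.consensus))
        )
        assert ham <= 1
        assert 70 <= m.n_sites <= 90

    def test_em_objective_monotone(self, rng):
        seqs = plant(rng, 30, 40, "CCGGTTAA", identity=0.9)
        p = DiscoveryParams(min_width=8, max_width=8, width_ladder=(8,),
                            n_motifs=1, min_tss=5)
        (m,) = zoops_em(seqs, p, seed=1)
        tr = m.objective_trace
        assert len(tr) >= 2
        assert all(b >= a - 1e-8 * abs(a) for a, b in zip(tr, tr[1:]))

    def test_deterministic_under_seed(self, rng):
        seqs = plant(rng, 25, 40, "GGATCCA", identity=0.9)
        p = DiscoveryParams(min_width=7, max_width=7, width_ladder=(7,),
                            n_motifs=1, min_tss=5, n_eval_shuffles=40)
        m1 = zoops_em(seqs, p, seed=9)
        m2 = zoops_em(seqs, p, seed=9)
        assert [m.consensus for m in m1] == [m.consensus for m in m2]
        assert [m.e_value for m in m1] == [m.e_value for m in m2]

    def test_revcomp_symmetry(self, rng):
        seqs = plant(rng, 30, 40, "GGATCCATT", identity=0.95)
        p = DiscoveryParams(min_width=9, max_width=9, width_ladder=(9,),
                            n_motifs=1, min_tss=5, n_eval_shuffles=40)
        (m_fwd,) = zoops_em(seqs, p, seed=5)
        (m_rc,) = zoops_em([revcomp(s) for s in seqs], p, seed=5)
        assert m_rc.consensus in (m_fwd.consensus, revcomp(m_fwd.consensus))

    def test_too_short_sequences_yield_empty(self):
        p = DiscoveryParams(min_width=8, max_width=8, width_ladder=(8,))
        assert zoops_em(["ACG", "TGA", "CCC"], p, seed=0) == []

    def test_min_tss_filter(self, rng):
        # strong motif in only 8 sequences: rejected at min_tss=13
        seqs = plant(rng, 40, 40, "TTGACATGC", fraction=0.2, identity=1.0)
        p = DiscoveryParams(min_width=9, max_width=9, width_ladder=(9,),
                            n_motifs=1, min_tss=13, n_eval_shuffles=40)
        motifs = zoops_em(seqs, p, seed=0)
        assert all(m.n_assigned >= 13 for m in motifs)


class TestEvalue:
    def test_null_calibration(self, rng):
        """Random sequences without a planted motif: the median E-value over
        seeded runs stays above the significance cutoff."""
        evs = []
        for seed in range(20):
            r = np.random.default_rng(1000 + seed)
            seqs = ["".join("ACGT"[j] for j in r.integers(0, 4, 40)) for _ in range(40)]
            m = PWMMotif(np.ones((4, 8)), np.full(4, 0.25))
            evs.append(motif_evalue(m, seqs, n_shuffles=60, seed=seed))
        assert np.median(evs) >= 0.05

    def test_width_factor_monotone(self, rng):
        seqs = plant(rng, 20, 30, "GATTACA")
        m = PWMMotif(np.ones((4, 7)), np.full(4, 0.25))
        e1 = motif_evalue(m, seqs, n_shuffles=40, seed=3, n_widths=1)
        e2 = motif_evalue(m, seqs, n_shuffles=40, seed=3, n_widths=2)
        assert e2 == pytest.approx(2 * e1)


class TestShineDalgarno:
    def test_planted_sd_recovered_with_spacings(self):
        params = SimulationParams(n_genes=150, seed=31)
        genome, genes, truth = generate_genome(params)
        p = DiscoveryParams(n_motifs=2, max_width=12,
                            width_ladder=(4, 5, 6, 8, 10, 12),
                            min_tss=13, n_eval_shuffles=60)
        motif, spacings = find_shine_dalgarno(genes, genome, params=p, seed=7)
        assert motif is not None
        assert "AGGAGG" in motif.consensus or motif.consensus in "AGGAGG"
        in_band = [
            1 for gid, d in spacings.items()
            if gid in truth.sd_offsets and 9 <= d <= 14
        ]
        assert len(spacings) >= 0.8 * len(truth.sd_offsets)
        assert sum(in_band) >= 0.9 * len(spacings)

    def test_spacings_match_planted_offsets(self):
        params = SimulationParams(n_genes=120, seed=32)
        genome, genes, truth = generate_genome(params)
        p = DiscoveryParams(n_motifs=1, min_width=6, max_width=6,
                            width_ladder=(6,), min_tss=13, n_eval_shuffles=60)
        motif, spacings = find_shine_dalgarno(genes, genome, params=p, seed=3)
        assert motif is not None and motif.consensus == "AGGAGG"
        hits = [gid for gid in spacings if gid in truth.sd_offsets]
        agree = sum(1 for gid in hits if spacings[gid] == truth.sd_offsets[gid])
        assert agree >= 0.9 * len(hits)


class TestMemeFormat:
    def test_round_trip(self, tmp_path, rng):
        seqs = plant(rng, 20, 30, "GATTACA")
        p = DiscoveryParams(min_width=7, max_width=7, width_ladder=(7,),
                            n_motifs=1, min_tss=5, n_eval_shuffles=40)
        motifs = zoops_em(seqs, p, seed=2)
        path = tmp_path / "m.meme"
        write_meme(motifs, path)
        back = read_meme(path)
        assert len(back) == 1
        assert back[0].consensus == motifs[0].consensus
        np.testing.assert_allclose(back[0].prob_matrix, motifs[0].prob_matrix, atol=5e-3)
        np.testing.assert_allclose(back[0].background, motifs[0].background, atol=1e-4)
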