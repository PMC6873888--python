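import numpy as np
import pytest

from tssmotif._seq import revcomp
from tssmotif.io_formats import GeneAnnotation, GenomeRecord
from tssmotif.tss_annotation import (
    BasePreferenceProfile,
    annotate_tss,
    base_preference,
    classify_tss,
    compute_utr,
    make_utr_record,
    per_gene_tss_histogram,
    utr_records,
    utr_summary,
)
from tssmotif.tss_calling import TSSRecord


def _tss(pos, strand="+"):
    return TSSRecord("c1", pos, strand, 50, 0, 1e-9)


GENE = GeneAnnotation("g1", "c1", 1000, 2000, "+")


class TestClassify:
    def test_primary_within_window(self):
        t = classify_tss(_tss(800), [GENE])
        assert t.classes == {"primary"}
        assert t.assigned_genes == [("g1", "primary", 200)]

    def test_internal_and_antisense(self):
        assert classify_tss(_tss(1500), [GENE]).classes == {"internal"}
        assert classify_tss(_tss(1500, "-"), [GENE]).classes == {"antisense"}

    def test_window_boundary_inclusive_at_250(self):
        assert classify_tss(_tss(750), [GENE]).classes == {"primary"}
        assert classify_tss(_tss(749), [GENE]).classes == {"orphan"}

    def test_tss_on_start_codon_is_internal(self):
        assert classify_tss(_tss(1000), [GENE]).classes == {"internal"}

    def test_multi_label_and_multi_gene_primary(self):
        g2 = GeneAnnotation("g2", "c1", 900, 950, "-")
        g3 = GeneAnnotation("g3", "c1", 810, 1000, "+")
        t = classify_tss(_tss(800), [GENE, g2, g3])
        # primary for g3 (d=10); g1 is shadowed by distance > 250? d=200 -> also primary
        labels = {(gid, cls) for gid, cls, _ in t.assigned_genes}
        assert ("g1", "primary") in labels and ("g3", "primary") in labels
        assert "orphan" not in t.classes

    def test_orphan_exclusive(self):
        t = classify_tss(_tss(100), [GENE])
        assert t.classes == {"orphan"} and t.assigned_genes == []


def classify_oracle(tss, genes, window=250):
    """All-pairs rule applied literally, independent of the implementation."""
    labels = set()
    for g in genes:
        if g.contig_id != tss.contig_id:
            continue
        same = g.strand == tss.strand
        inside = g.start <= tss.position < g.end
        if same and inside:
            labels.add("internal")
        if (not same) and inside:
            labels.add("antisense")
        if same and not inside:
            if g.strand == "+":
                d = g.start - tss.position
            else:
                d = tss.position - (g.end - 1)
            if 1 <= d <= window:
                labels.add("primary")
    return labels or {"orphan"}


def _random_config(rng):
    genes = []
    pos = 0
    for i in range(int(rng.integers(1, 8))):
        start = pos + int(rng.integers(0, 300))
        end = start + int(rng.integers(30, 900))
        genes.append(GeneAnnotation(f"g{i}", "c1", start, end,
                                    "+-"[int(rng.integers(2))]))
        pos = end + int(rng.integers(0, 100))
    length = pos + 400
    tss = _tss(int(rng.integers(0, length)), "+-"[int(rng.integers(2))])
    return tss, genes, length


def _mirror(tss, genes, length):
    mt = TSSRecord("c1", length - 1 - tss.position,
                   "-" if tss.strand == "+" else "+",
                   tss.tap_plus_count, tss.tap_minus_count, tss.p_value)
    mg = [
        GeneAnnotation(g.gene_id, "c1", length - g.end, length - g.start,
                       "-" if g.strand == "+" else "+")
        for g in genes
    ]
    return mt, mg


class TestClassificationProperties:
    def test_agrees_with_bruteforce_oracle(self, rng):
        for _ in range(1000):
            tss, genes, _ = _random_config(rng)
            assert classify_tss(tss, genes).classes == classify_oracle(tss, genes)

    def test_strand_mirror_invariance(self, rng):
        for _ in range(500):
            tss, genes, length = _random_config(rng)
            direct = classify_tss(tss, genes)
            mt, mg = _mirror(tss, genes, length)
            mirrored = classify_tss(mt, mg)
            assert direct.classes == mirrored.classes
            assert sorted(direct.assigned_genes) == sorted(mirrored.assigned_genes)


class TestUtr:
    def test_arithmetic(self):
        r = compute_utr(_tss(937), GENE)
        assert (r.utr_length, r.leaderless) == (63, False)

    def test_tss_at_start_is_utr_zero(self):
        assert compute_utr(_tss(1000), GENE).utr_length == 0

    def test_leaderless_strict_threshold(self):
        assert make_utr_record("g", 0, 9).leaderless is True
        assert make_utr_record("g", 0, 10).leaderless is False

    def test_negative_distance_rejected(self):
        with pytest.raises(ValueError):
            compute_utr(_tss(1500), GENE)

    def test_minus_strand_mirror(self):
        gm = GeneAnnotation("gm", "c1", 1000, 2000, "-")
        assert compute_utr(_tss(2062, "-"), gm).utr_length == 63

    def test_summary_basics(self):
        recs = [make_utr_record("a", 0, 0), make_utr_record("b", 0, 63),
                make_utr_record("c", 0, 200)]
        s = utr_summary(recs)
        assert s.median == 63 and s.fraction_below_100 == pytest.approx(2 / 3)
        assert s.leaderless_count == 1

    def test_summary_lower_median_and_constant(self):
        recs = [make_utr_record(str(i), 0, 50) for i in range(4)]
        s = utr_summary(recs)
        assert s.median == 50 and s.fraction_below_100 == 1.0
        # lower median for even n
        recs = [make_utr_record(str(i), 0, v) for i, v in enumerate([10, 20, 30, 40])]
        assert utr_summary(recs).median == 20

    def test_empty_summary_sentinel(self):
        s = utr_summary([])
        assert s.n == 0 and s.median is None and s.leaderless_fraction is None


class TestHistogram:
    def test_counts(self):
        tss = [
            TSSRecord("c1", 1, "+", 1, 0, 0.0, assigned_genes=[("a", "primary", 5)]),
            TSSRecord("c1", 2, "+", 1, 0, 0.0, assigned_genes=[("b", "primary", 5)]),
            TSSRecord("c1", 3, "+", 1, 0, 0.0, assigned_genes=[("c", "primary", 5)]),
            TSSRecord("c1", 4, "+", 1, 0, 0.0, assigned_genes=[("c", "primary", 9)]),
            TSSRecord("c1", 5, "+", 1, 0, 0.0, assigned_genes=[("c", "primary", 12)]),
        ]
        assert per_gene_tss_histogram(tss) == {1: 2, 3: 1}

    def test_empty(self):
        assert per_gene_tss_histogram([]) == {}

    def test_total_conservation(self, small_simulation):
        _, _, genes, truth, _, _ = small_simulation
        tss = [TSSRecord(t.contig_id, t.position, t.strand, 50, 0, 0.0)
               for t in truth.tss_list]
        annotate_tss(tss, genes)
        hist = per_gene_tss_histogram(tss)
        genes_with_primary = {
            gid for t in tss for gid, cls, _ in t.assigned_genes if cls == "primary"
        }
        assert sum(hist.values()) == len(genes_with_primary)


class TestBasePreference:
    def test_single_tss_one_hot(self):
        genome = [GenomeRecord("c1", "ACGTAGTACGT")]
        prof = base_preference([_tss(5)], genome)
        assert prof.fraction("G", 1) == 1.0  # +1 column is the TSS base G
        assert prof.fraction("A", -1) == 1.0

    def test_columns_sum_to_one(self, small_simulation):
        _, genome, _, truth, _, _ = small_simulation
        tss = [TSSRecord(t.contig_id, t.position, t.strand, 50, 0, 0.0)
               for t in truth.primary_tss()]
        prof = base_preference(tss, genome)
        np.testing.assert_allclose(prof.fractions.sum(axis=0), 1.0, atol=1e-12)

    def test_minus_strand_reads_transcribed_base(self):
        genome = [GenomeRecord("c1", "ACGTACGTACG")]
        # TSS at 5 on '-': transcribed +1 base is complement of genome[5]='C' -> G
        prof = base_preference([_tss(5, "-")], genome)
        assert prof.fraction("G", 1) == 1.0

    def test_edge_tss_skipped(self):
        genome = [GenomeRecord("c1", "ACGTACGTACG")]
        prof = base_preference([_tss(1)], genome)
        assert prof.n_tss == 0

    def test_strand_mirror_invariance(self, small_simulation):
        _, genome, _, truth, _, _ = small_simulation
        tss = [TSSRecord(t.contig_id, t.position, t.strand, 50, 0, 0.0)
               for t in truth.primary_tss()]
        prof = base_preference(tss, genome)
        L = len(genome[0])
        mirror_genome = [GenomeRecord("c1", revcomp(genome[0].sequence))]
        mtss = [TSSRecord("c1", L - 1 - t.position,
                          "-" if t.strand == "+" else "+", 50, 0, 0.0) for t in tss]
        mprof = base_preference(mtss, mirror_genome)
        np.testing.assert_allclose(prof.fractions, mprof.fractions, atol=1e-12)

    def test_planted_ag_bias_recovered(self):
        from tssmotif.synthetic_data import SimulationParams, generate_genome

        p = SimulationParams(n_genes=500, seed=21, processed_site_rate=0.0)
        genome, _, truth = generate_genome(p)
        tss = [TSSRecord(t.contig_id, t.position, t.strand, 50, 0, 0.0)
               for t in truth.primary_tss()]
        prof = base_preference(tss, genome)
        ag = prof.fraction("A", 1) + prof.fraction("G", 1)
        assert ag == pytest.approx(0.90, abs=0.05)
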