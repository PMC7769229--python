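import numpy as np
import pytest

from flatpeach.haplotype_model import build_inverted_haplotype, reverse_complement
from flatpeach.synthetic_data import (
    classify_fruit_shape,
    generate_reference,
    make_accession,
    plant_inversion_site,
    simulate_cross,
    simulate_expression_counts,
    simulate_long_reads,
    simulate_short_reads,
    simulate_snp_panel,
)
from flatpeach.association_stats import segregation_chisq


class TestGenerateReference:
    def test_seeded_determinism(self):
        a = generate_reference(10_000, gc=0.5, seed=7)
        b = generate_reference(10_000, gc=0.5, seed=7)
        assert a.seq == b.seq

    def test_gc_fraction_close_to_target(self):
        seq = generate_reference(10_000, gc=0.5, seed=7).seq
        gc = (seq.count("G") + seq.count("C")) / len(seq)
        assert abs(gc - 0.5) <= 0.03  # 99.9% binomial bound at n=10000

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            generate_reference(50, gc=0.5, seed=1)


class TestPlantInversionSite:
    def test_overwrites_deletion_motif(self):
        seg = generate_reference(100, seed=1)
        seg = type(seg)(id="t", seq="TTTTGGGATGCCGGGG" + seg.seq[16:])
        planted, spec = plant_inversion_site(seg, 7, 12)
        assert planted.seq[:16] == "TTTTACAATGCCGGGG"
        assert (spec.pb, spec.db) == (7, 12)

    def test_planted_segment_builds_without_error(self):
        seg = generate_reference(5000, seed=2)
        planted, spec = plant_inversion_site(seg, 1000, 4000)
        pair = build_inverted_haplotype(planted, spec)
        assert len(pair.h2.seq) == len(planted.seq) - 1

    def test_planted_breakpoints_are_unambiguous(self):
        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
        for seed in range(5):
            seg = generate_reference(2000, seed=seed)
            planted, spec = plant_inversion_site(seg, 500, 1500)
            p = spec.pb - len(spec.del_motif)
            assert planted.seq[p - 1] != comp[planted.seq[spec.db]]
            assert planted.seq[p] != comp[planted.seq[spec.db - 1]]

    def test_breakpoint_too_close_to_origin_rejected(self):
        seg = generate_reference(200, seed=1)
        with pytest.raises(ValueError):
            plant_inversion_site(seg, 2, 100)


class TestSimulateCross:
    def test_backcross_segregates_one_to_one(self):
        offspring = simulate_cross("H1H1", "H1H2", 10_000, seed=1)
        genotypes = {g for _, g, _ in offspring}
        assert genotypes == {"H1H1", "H1H2"}
        counts = [sum(1 for _, g, _ in offspring if g == x) for x in ("H1H1", "H1H2")]
        assert segregation_chisq(counts, (1, 1)).p > 0.001

    def test_intercross_segregates_one_two_one(self):
        offspring = simulate_cross("H1H2", "H1H2", 10_000, seed=2)
        counts = [sum(1 for _, g, _ in offspring if g == x)
                  for x in ("H1H1", "H1H2", "H2H2")]
        assert segregation_chisq(counts, (1, 2, 1)).p > 0.001
        assert all(ph == "aborted" for _, g, ph in offspring if g == "H2H2")
        assert all(ph == "flat" for _, g, ph in offspring if g == "H1H2")

    def test_monomorphic_cross(self):
        offspring = simulate_cross("H1H1", "H1H1", 5, seed=3)
        assert [(g, ph) for _, g, ph in offspring] == [("H1H1", "round")] * 5

    def test_accessions_carry_matching_haplotypes(self, toy_pair):
        acc = make_accession("a1", "H1H2", toy_pair)
        assert acc.hapA.seq == toy_pair.h1.seq
        assert acc.hapB.seq == toy_pair.h2.seq
        assert acc.phenotype == "flat"


class TestSimulateShortReads:
    def test_pair_count_formula(self):
        ref = generate_reference(20_000, seed=4)
        planted, spec = plant_inversion_site(ref, 5000, 15_000)
        pair = build_inverted_haplotype(planted, spec)
        acc = make_accession("a", "H1H2", pair)  # 20 kb + (20 kb - 1)
        pairs = simulate_short_reads(acc, coverage=30, read_len=150,
                                     insert_mean=400, err_rate=0.0, seed=1)
        assert len(pairs) == round(30 * 39_999 / 600) == 2000

    def test_error_free_reads_match_truth_locus(self, small_locus):
        pair, _ = small_locus
        acc = make_accession("a", "H1H2", pair)
        pairs = simulate_short_reads(acc, coverage=2, err_rate=0.0, seed=5)
        for r1, r2 in pairs:
            hap = acc.hapA.seq if r1.truth_hap == "A" else acc.hapB.seq
            assert r1.seq == hap[r1.truth_pos : r1.truth_pos + len(r1.seq)]
            assert r2.seq == reverse_complement(
                hap[r2.truth_pos : r2.truth_pos + len(r2.seq)])

    def test_observed_error_rate_is_binomial(self, small_locus):
        pair, _ = small_locus
        acc = make_accession("a", "H1H1", pair)
        err = 0.01
        pairs = simulate_short_reads(acc, coverage=5, err_rate=err, seed=6)
        mism = total = 0
        for r1, r2 in pairs:
            hap = acc.hapA.seq if r1.truth_hap == "A" else acc.hapB.seq
            truth1 = hap[r1.truth_pos : r1.truth_pos + len(r1.seq)]
            truth2 = reverse_complement(hap[r2.truth_pos : r2.truth_pos + len(r2.seq)])
            mism += sum(a != b for a, b in zip(r1.seq, truth1))
            mism += sum(a != b for a, b in zip(r2.seq, truth2))
            total += len(r1.seq) + len(r2.seq)
        sd = np.sqrt(err * (1 - err) / total)
        assert abs(mism / total - err) <= 3 * sd

    def test_insert_longer_than_haplotype_rejected(self, toy_pair):
        acc = make_accession("a", "H1H1", toy_pair)
        with pytest.raises(ValueError):
            simulate_short_reads(acc, coverage=1, read_len=30, insert_mean=60, seed=1)


class TestSimulateLongReads:
    def test_zero_coverage_gives_no_reads(self, small_locus):
        pair, _ = small_locus
        acc = make_accession("a", "H2H2", pair)
        assert simulate_long_reads(acc, coverage=0, seed=1) == []

    def test_error_free_reads_match_truth(self, small_locus):
        pair, _ = small_locus
        acc = make_accession("a", "H2H2", pair)
        reads = simulate_long_reads(acc, coverage=2, len_mean=2000, len_sd=500,
                                    err_rate=0.0, seed=7)
        assert reads
        for r in reads:
            hap = acc.hapA.seq if r.truth_hap == "A" else acc.hapB.seq
            truth = hap[r.truth_pos : r.truth_pos + len(r.seq)]
            assert r.seq == (truth if r.truth_strand == "+" else reverse_complement(truth))

    def test_junctions_are_covered_at_moderate_coverage(self, small_locus):
        pair, _ = small_locus
        acc = make_accession("a", "H2H2", pair)
        reads = simulate_long_reads(acc, coverage=10, len_mean=2000, len_sd=300,
                                    err_rate=0.0, seed=8)
        for junction in (pair.pb2, pair.db2):
            assert any(r.truth_pos < junction < r.truth_pos + len(r.seq) for r in reads)


class TestSimulateSnpPanel:
    def test_degenerate_frequencies(self):
        panel = simulate_snp_panel(4, 3, [0.0, 1.0], [0.0, 0.0], seed=1)
        flat = panel.genotypes[:4]
        rnd = panel.genotypes[4:]
        assert (flat[:, 0] == 0).all() and (rnd[:, 0] == 0).all()
        assert (flat[:, 1] == 2).all() and (rnd[:, 1] == 0).all()

    def test_mean_dosage_tracks_frequency(self):
        panel = simulate_snp_panel(200, 200, [0.5], [0.5], seed=2)
        mean = panel.genotypes.mean()
        sd = np.sqrt(2 * 0.5 * 0.5 / 400)
        assert abs(mean - 1.0) <= 3 * sd

    def test_frequency_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            simulate_snp_panel(2, 2, [0.5, 0.5], [0.5], seed=1)


class TestSimulateExpressionCounts:
    def test_planted_fold_change_recovered(self):
        """Observed log2 FP/RP ratio of the planted gene ~ planted value (20 reps)."""
        lfcs = []
        for seed in range(20):
            sim = simulate_expression_counts(["FP"] * 3 + ["RP"] * 3, 300,
                                             planted_log2fc=5.0, seed=seed)
            i = sim.gene_ids.index(sim.planted_gene)
            fp = sim.counts[i, :3].mean()
            rp = sim.counts[i, 3:].mean()
            lfcs.append(np.log2((fp + 0.5) / (rp + 0.5)))
        assert abs(np.mean(lfcs) - 5.0) <= 0.5

    def test_null_planted_gene_is_unremarkable(self):
        sim = simulate_expression_counts(["FP"] * 3 + ["RP"] * 3, 300,
                                         planted_log2fc=0.0, seed=3)
        i = sim.gene_ids.index(sim.planted_gene)
        fp, rp = sim.counts[i, :3].mean(), sim.counts[i, 3:].mean()
        assert 0.5 <= (fp + 1) / (rp + 1) <= 2.0

    def test_library_size_scales_expected_counts(self):
        a = simulate_expression_counts(["FP"] * 3 + ["RP"] * 3, 400, 0.0,
                                       lib_size=500_000, seed=4)
        b = simulate_expression_counts(["FP"] * 3 + ["RP"] * 3, 400, 0.0,
                                       lib_size=1_000_000, seed=4)
        ratio = b.counts.sum() / a.counts.sum()
        assert 1.9 <= ratio <= 2.1

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            simulate_expression_counts(["FP"] * 4, 100, 1.0, seed=1)


@pytest.mark.parametrize("cheek,vertical,expected", [
    (64, 40, "flat"),        # ratio 1.6 > 1.5
    (55, 50, "round"),       # ratio 1.1 < 1.2
    (13, 10, "unclassified"),  # ratio 1.3, between thresholds
])
def test_classify_fruit_shape(cheek, vertical, expected):
    assert classify_fruit_shape(cheek, vertical) == expected


def test_classify_fruit_shape_rejects_nonpositive():
    with pytest.raises(ValueError):
        classify_fruit_shape(0, 10)


def test_simulators_are_bit_reproducible(small_locus):
    pair, _ = small_locus
    acc = make_accession("a", "H1H2", pair)
    a = simulate_short_reads(acc, coverage=1, seed=9)
    b = simulate_short_reads(acc, coverage=1, seed=9)
    assert a == b
    la = simulate_long_reads(acc, coverage=1, seed=9)
    lb = simulate_long_reads(acc, coverage=1, seed=9)
    assert la == lb
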