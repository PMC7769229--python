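import numpy as np
import pytest

from flatpeach.haplotype_model import reverse_complement
from flatpeach.inversion_genotyping import (
    JunctionSupport,
    PcrPattern,
    PrimerPair,
    call_genotype,
    design_assay,
    genotype_by_pcr,
    genotype_from_reads,
    insilico_pcr,
    pcr_genotype,
    refine_breakpoints,
)
from flatpeach.synthetic_data import make_accession, simulate_long_reads, simulate_short_reads


class TestCallGenotype:
    @pytest.mark.parametrize("support,expected", [
        ((10, 9, 0, 0), "H1H1"),
        ((6, 5, 4, 7), "H1H2"),
        ((0, 0, 8, 11), "H2H2"),
        ((1, 1, 1, 1), "no_call"),
        ((10, 2, 0, 0), "no_call"),  # one wild junction below threshold
    ])
    def test_decision_rule(self, support, expected):
        call = call_genotype(JunctionSupport(*support), min_reads=3)
        assert call.genotype == expected
        if expected == "no_call":
            assert call.reason == "insufficient junction support"

    def test_min_reads_must_be_positive(self):
        with pytest.raises(ValueError):
            call_genotype(JunctionSupport(), min_reads=0)


class TestInsilicoPcr:
    def test_wild_template_amplifies(self, toy_pair):
        pp = PrimerPair("P1", fwd="TACA", rev="GGCA", max_amplicon=50, min_len=4)
        present, size = insilico_pcr(pp, toy_pair.h1)
        assert present and size == 9  # product TACAATGCC

    def test_inverted_template_loses_the_site(self, toy_pair):
        pp = PrimerPair("P1", fwd="TACA", rev="GGCA", max_amplicon=50, min_len=4)
        present, size = insilico_pcr(pp, toy_pair.h2)
        assert not present and size is None

    def test_same_direction_primers_give_no_product(self, toy_pair):
        # rev written as a forward-strand sequence: both primers prime rightward
        pp = PrimerPair("X", fwd="TACA", rev="TGCC", max_amplicon=50, min_len=4)
        assert insilico_pcr(pp, toy_pair.h1) == (False, None)

    def test_amplicon_cap_suppresses_product(self, toy_pair):
        pp = PrimerPair("P1", fwd="TACA", rev="GGCA", max_amplicon=8, min_len=4)
        assert insilico_pcr(pp, toy_pair.h1) == (False, None)


class TestPcrGenotype:
    @pytest.mark.parametrize("pattern,expected", [
        ((True, False, False), "H1H1"),
        ((True, True, True), "H1H2"),
        ((False, True, True), "H2H2"),
        ((True, True, False), "no_call"),  # P2 and P3 both assay H2, must co-occur
        ((False, False, False), "no_call"),
    ])
    def test_band_patterns(self, pattern, expected):
        call = pcr_genotype(PcrPattern(*pattern))
        assert call.genotype == expected
        if expected == "no_call":
            assert call.reason == "inconsistent band pattern"

    def test_designed_assay_recovers_all_genotypes(self, small_locus):
        pair, _ = small_locus
        assay = design_assay(pair)
        for genotype, bands in (
            ("H1H1", (True, False, False)),
            ("H1H2", (True, True, True)),
            ("H2H2", (False, True, True)),
        ):
            acc = make_accession("a", genotype, pair)
            call, pattern = genotype_by_pcr(acc, assay)
            assert (pattern.p1, pattern.p2, pattern.p3) == bands
            assert call.genotype == genotype


class TestRefineBreakpoints:
    def test_toy_split_read(self, toy_pair):
        read = toy_pair.h2.seq[0:9]  # TTTTGGCAT crosses the proximal junction
        res = refine_breakpoints([read], toy_pair.h1, ((2, 10), (9, 16)),
                                 k=4, min_part=2)
        assert [(e.u, e.v) for e in res.per_read] == [(4, 12)]  # (pb-3, db)
        assert (res.consensus_u, res.consensus_v) == (4, 12)

    def test_mirrored_orientation_gives_same_estimate(self, toy_pair):
        read = reverse_complement(toy_pair.h2.seq[0:9])
        res = refine_breakpoints([read], toy_pair.h1, ((2, 10), (9, 16)),
                                 k=4, min_part=2)
        assert [(e.u, e.v) for e in res.per_read] == [(4, 12)]

    def test_read_inside_inverted_segment_gives_no_estimate(self, toy_pair):
        read = reverse_complement(toy_pair.h1.seq[8:12])
        res = refine_breakpoints([read], toy_pair.h1, ((2, 10), (9, 16)),
                                 k=4, min_part=2)
        assert res.per_read == [] and res.no_estimate == ["read_0"]

    def test_matches_brute_force_on_short_reads(self, small_locus):
        """Seeded search equals exhaustive search over all (split, offsets)."""
        pair, _ = small_locus
        spec = pair.spec
        h1 = pair.h1.seq
        win = ((spec.pb - 20, spec.pb + 20), (spec.db - 20, spec.db + 20))
        rng = np.random.default_rng(29)
        h2 = pair.h2.seq
        reads = []
        for _ in range(5):
            n = int(rng.integers(150, 300))
            start = pair.pb2 - int(rng.integers(40, n - 40))
            reads.append(h2[start : start + n])
        res = refine_breakpoints(reads, pair.h1, win, k=13, min_part=20)
        assert len(res.per_read) == len(reads)
        for read, est in zip(reads, res.per_read):
            assert (est.u, est.v, est.score) == _brute_force_split(read, h1, win)

    def test_simulated_long_reads_recover_planted_breakpoints(self, small_locus):
        pair, _ = small_locus
        spec = pair.spec
        acc = make_accession("a", "H2H2", pair)
        reads = simulate_long_reads(acc, coverage=8, len_mean=2500, len_sd=500,
                                    err_rate=0.0, seed=31)
        res = refine_breakpoints(
            reads, pair.h1,
            ((spec.pb - 500, spec.pb + 500), (spec.db - 500, spec.db + 500)))
        assert (res.consensus_u, res.consensus_v) == (spec.pb - 3, spec.db)
        assert len(res.per_read) >= 3


def _brute_force_split(read, h1, win, min_part=20, min_id=0.8):
    """Exhaustive (orientation, split, both offsets) search with the same
    scoring and tie rules as refine_breakpoints.

    Every offset that can place a junction-side coordinate inside a search
    window is enumerated; for a fixed split the prefix and suffix optima are
    independent, so the search is exact yet tractable.
    """
    windows = list(win)
    n_ref = len(h1)
    rc = reverse_complement(h1)
    best = None

    def part_tables(oriented, ref, offsets):
        """cumulative matches along each diagonal: rows offsets, cols split s."""
        L = len(oriented)
        read_a = np.frombuffer(oriented.encode(), dtype=np.uint8)
        ref_a = np.frombuffer(ref.encode(), dtype=np.uint8)
        table = np.zeros((len(offsets), L + 1), dtype=int)
        for row, d in enumerate(offsets):
            ind = np.zeros(L, dtype=bool)
            j0, j1 = max(0, -d), min(L, n_ref - d)
            if j1 > j0:
                ind[j0:j1] = read_a[j0:j1] == ref_a[j0 + d : j1 + d]
            table[row, 1:] = np.cumsum(ind)
        return table

    for oriented in (read, reverse_complement(read)):
        L = len(oriented)
        f_offs = sorted({d for lo, hi in windows for d in range(lo - L, hi)})
        r_offs = sorted({d for lo, hi in windows
                         for d in range(n_ref - hi - L + 1, n_ref - lo + 1)})
        pre = part_tables(oriented, h1, f_offs)
        rcum = part_tables(oriented, rc, r_offs)
        suf = rcum[:, -1:] - rcum
        f_offs = np.array(f_offs)
        r_offs = np.array(r_offs)
        for s in range(L + 1):
            u_f = f_offs + s
            v_r = n_ref - r_offs - s
            p = pre[:, s]
            q = suf[:, s]
            ok_p = (p >= min_part) & ((s == 0) | (p >= min_id * s))
            ok_q = (q >= min_part) & ((s == L) | (q >= min_id * (L - s)))
            for (w1_lo, w1_hi), (w2_lo, w2_hi), swap in (
                (windows[0], windows[1], False),  # forward part at proximal side
                (windows[1], windows[0], True),   # mirrored orientation
            ):
                sel_f = ok_p & (u_f >= w1_lo) & (u_f < w1_hi)
                sel_r = ok_q & (v_r >= w2_lo) & (v_r < w2_hi)
                if not sel_f.any() or not sel_r.any():
                    continue
                bp = p[sel_f].max()
                bq = q[sel_r].max()
                cand_u = u_f[sel_f & (p == bp)]
                cand_v = v_r[sel_r & (q == bq)]
                uu, vv = (int(cand_v.min()), int(cand_u.min())) if swap else \
                    (int(cand_u.min()), int(cand_v.min()))
                key = (-(int(bp) + int(bq)), uu, vv)
                if best is None or key < best:
                    best = key
    return (best[1], best[2], -best[0])


class TestEndToEnd:
    def test_low_coverage_yields_more_no_calls(self, small_locus):
        pair, js = small_locus
        acc = make_accession("a", "H1H2", pair)
        lo = sum(
            genotype_from_reads(
                [r for pr in simulate_short_reads(acc, coverage=1, seed=s) for r in pr],
                js).genotype == "no_call"
            for s in range(10)
        )
        hi = sum(
            genotype_from_reads(
                [r for pr in simulate_short_reads(acc, coverage=30, seed=s) for r in pr],
                js).genotype == "no_call"
            for s in range(3)
        )
        assert lo > hi == 0
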