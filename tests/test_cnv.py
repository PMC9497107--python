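"""Purity-aware copy-number arithmetic and SV integration."""

import numpy as np
import pytest

from svlandscape.cnv import (
    PuritySample,
    breakpoint_concordance,
    classify_segments,
    enrichment_factor,
    expected_copy_ratio,
    genome_fraction_by_state,
    overlap_percent,
    separability,
    snr,
)
from svlandscape.formats import Breakend, CnvSegment, ProbeRatio, SvCall
from svlandscape.simulate import DerivativeGenome, TruthSet, emit_cnv_profile


class TestExpectedRatio:
    def test_neutral_is_one_for_every_purity(self):
        for p in (0.0, 0.24, 0.45, 0.58, 1.0):
            assert expected_copy_ratio(2, p) == 1.0

    def test_pure_tumor_hom_del_is_zero(self):
        assert expected_copy_ratio(0, 1.0) == 0.0

    def test_mixture_value_at_p58(self):
        assert expected_copy_ratio(0, 0.58) == pytest.approx(0.42)
        assert expected_copy_ratio(1, 0.58) == pytest.approx(0.71)

    def test_affine_in_q_and_p(self):
        # r is affine in q at fixed p and affine in p at fixed q
        for p in (0.2, 0.6):
            diffs = [expected_copy_ratio(q + 1, p) - expected_copy_ratio(q, p)
                     for q in range(5)]
            assert all(abs(d - diffs[0]) < 1e-12 for d in diffs)
        for q in (0, 3):
            d1 = expected_copy_ratio(q, 0.4) - expected_copy_ratio(q, 0.2)
            d2 = expected_copy_ratio(q, 0.8) - expected_copy_ratio(q, 0.6)
            assert abs(d1 - d2) < 1e-12

    def test_negative_q_rejected(self):
        with pytest.raises(ValueError):
            expected_copy_ratio(-1, 0.5)


class TestClassify:
    def test_nearest_ratio_assignment(self):
        segs = [CnvSegment("c", 0, 1_000, 1.0), CnvSegment("c", 1_000, 2_000, 0.42),
                CnvSegment("c", 2_000, 3_000, 0.71)]
        out = classify_segments(segs, 0.58)
        assert [(s.q, s.zygosity) for s in out] == \
               [(2, "neutral"), (0, "hom-del"), (1, "het-del")]

    def test_refuses_p_zero(self):
        with pytest.raises(ValueError, match="no tumor signal"):
            classify_segments([CnvSegment("c", 0, 10, 1.0)], 0.0)

    def test_noiseless_profile_perfect_recovery(self, small_ref):
        """classify_segments on a noiseless emitted profile recovers every
        implanted q exactly (sigma = 0), and nearly always at sigma = 0.05."""
        dg = DerivativeGenome(small_ref)
        dg.add_deletion("tumor-1", "chr1", 20_000, 60_000)
        dg.add_deletion("tumor-1", "chr2", 30_000, 70_000)
        dg.add_deletion("tumor-2", "chr2", 30_000, 70_000)
        dg.add_duplication("tumor-1", "chr1", 100_000, 140_000)
        truth = TruthSet(dg, 0.58, 0)
        for sd, min_acc in ((0.0, 1.0), (0.05, 1.0), (0.1, 0.75)):
            probes, segs = emit_cnv_profile(truth, 1_000, sd, seed=4)
            seg_means = []
            for s in segs:
                inside = [p.r for p in probes
                          if p.contig == s.contig and s.start <= p.start < s.end]
                seg_means.append(CnvSegment(s.contig, s.start, s.end,
                                            float(np.mean(inside)) if inside else s.r))
            out = classify_segments(seg_means, 0.58)
            acc = np.mean([o.q == s.q for o, s in zip(out, segs)])
            assert acc >= min_acc, sd


class TestSnr:
    def _neutral_probes(self, x):
        # probe ratios alternating 1 +- x: median 1, MAD exactly x
        return [ProbeRatio("c", i * 100, i * 100 + 50, 1.0 + (x if i % 2 else -x))
                for i in range(40)]

    def test_closed_form(self):
        """p = 0.58 and sigma = 0.10 give snr_del = snr_amp = 2.9."""
        x = 0.10 / 1.4826
        probes = self._neutral_probes(x)
        segs = [CnvSegment("c", 0, 4_000, 1.0, q=2, n_probes=40)]
        sd, sa, sm = snr(probes, segs, 0.58)
        assert sd == pytest.approx(2.9, abs=1e-9)
        assert sa == pytest.approx(2.9, abs=1e-9)
        assert sm == pytest.approx(2.9, abs=1e-9)

    def test_zero_purity_zero_snr(self):
        probes = self._neutral_probes(0.05)
        segs = [CnvSegment("c", 0, 4_000, 1.0, q=2)]
        assert snr(probes, segs, 0.0) == (0.0, 0.0, 0.0)

    def test_doubling_noise_halves_snr(self):
        segs = [CnvSegment("c", 0, 4_000, 1.0, q=2)]
        s1 = snr(self._neutral_probes(0.05), segs, 0.58)
        s2 = snr(self._neutral_probes(0.10), segs, 0.58)
        assert s2[0] == pytest.approx(s1[0] / 2)

    def test_no_neutral_segment_rejected(self):
        with pytest.raises(ValueError):
            snr([ProbeRatio("c", 0, 50, 0.4)], [CnvSegment("c", 0, 100, 0.4, q=1)], 0.58)


class TestWorkedArithmetic:
    def test_enrichment_factors(self):
        assert enrichment_factor(0.58, 0.24) == 2.42
        assert enrichment_factor(0.45, 0.24) == 1.88
        assert enrichment_factor(0.3, 0.3) == 1.00

    def test_enrichment_zero_denominator(self):
        with pytest.raises(ValueError):
            enrichment_factor(0.5, 0.0)

    def test_overlap_percent(self):
        assert overlap_percent(716, 737) == 97.2
        assert overlap_percent(737, 737) == 100.0
        assert overlap_percent(368, 737) == 49.9

    def test_overlap_bounds(self):
        with pytest.raises(ValueError):
            overlap_percent(10, 5)

    def test_separability_gap_ratio(self):
        """gap(p=0.58)/gap(p=0.24) = 2.4167: the arithmetic behind hom/het
        deletions separating only in the enriched sample."""
        ratio = separability(0.58) / separability(0.24)
        assert abs(ratio - 29 / 12) < 1e-9

    def test_purity_sample_validation(self):
        with pytest.raises(ValueError):
            PuritySample("CD3+", 1.2)


class TestGenomeFractions:
    def test_single_het_del_fraction(self):
        segs = [CnvSegment("c", 0, 71_600_000, 0.88, q=1)]
        frac = genome_fraction_by_state(segs, 1_000_000_000)
        assert frac["het-del"] == pytest.approx(7.16)

    def test_no_segments_all_neutral(self):
        frac = genome_fraction_by_state([], 1_000_000)
        assert frac["hom-del"] == frac["het-del"] == frac["amplified"] == 0.0
        assert frac["neutral"] == 100.0

    def test_random_profile_matches_truth_fractions(self, small_ref):
        dg = DerivativeGenome(small_ref)
        dg.add_deletion("tumor-1", "chr1", 0, 50_000)
        dg.add_deletion("tumor-2", "chr1", 10_000, 30_000)
        _, segs = emit_cnv_profile(TruthSet(dg, 0.58, 0), 1_000, 0.0, seed=1)
        out = classify_segments(segs, 0.58)
        frac = genome_fraction_by_state(out, 400_000)
        assert frac["hom-del"] == pytest.approx(100 * 20_000 / 400_000)
        assert frac["het-del"] == pytest.approx(100 * 30_000 / 400_000)


class TestConcordance:
    def test_breakend_exactly_at_boundary(self):
        segs = [CnvSegment("c", 0, 50_000, 1.0, q=2),
                CnvSegment("c", 50_000, 80_000, 0.71, q=1)]
        call = SvCall("x", "DEL", Breakend("c", 50_000, "L"), Breakend("c", 80_000, "R"),
                      30_000)
        rows, frac = breakpoint_concordance([call], segs)
        assert rows[0][2] == 0.0 and frac == 1.0

    def test_no_breakends_infinite_distance(self):
        segs = [CnvSegment("c", 0, 50_000, 1.0, q=2),
                CnvSegment("c", 50_000, 80_000, 0.71, q=1)]
        rows, frac = breakpoint_concordance([], segs)
        assert rows[0][2] == float("inf") and frac == 0.0

    def test_matched_construction_all_within_tolerance(self, small_ref):
        """CNVs implanted with matching SVs put every copy-number boundary
        within 10 kb of a called breakend."""
        dg = DerivativeGenome(small_ref)
        dg.add_deletion("tumor-1", "chr1", 40_000, 90_000)
        dg.add_deletion("tumor-1", "chr2", 60_000, 120_000)
        truth = TruthSet(dg, 0.58, 0)
        _, segs = emit_cnv_profile(truth, 1_000, 0.0, seed=2)
        calls = [SvCall(sv.id, "DEL",
                        Breakend(sv.junctions[0][0].contig, sv.junctions[0][0].pos + 800, "L"),
                        Breakend(sv.junctions[0][1].contig, sv.junctions[0][1].pos - 800, "R"),
                        sv.length) for sv in truth.svs]
        _, frac = breakpoint_concordance(calls, classify_segments(segs, 0.58), tol=10_000)
        assert frac == 1.0
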