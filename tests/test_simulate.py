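"""Synthetic-genome generator: implantation fidelity, reads, projection."""

import numpy as np
import pytest

from svlandscape.formats import revcomp
from svlandscape.simulate import (
    ConflictError,
    DerivativeGenome,
    TruthSet,
    emit_callset,
    emit_cnv_profile,
    expected_copy_ratio,
    make_reference,
    make_sparse_reference,
    project_alignments,
    simulate_reads,
    simulate_spanning_reads,
)


class TestReference:
    def test_forced_length_and_names(self):
        ref = make_reference(1, [10_000], seed=7)
        assert ref.lengths == {"chr1": 10_000}
        assert set(ref.contigs["chr1"]) <= set("ACGT")

    def test_seeded_determinism(self):
        assert make_reference(2, [5_000, 3_000], 9).contigs == \
               make_reference(2, [5_000, 3_000], 9).contigs

    def test_gc_fraction_near_half(self):
        """Binomial bound: at n >= 5e5 uniform bases, GC in [0.49, 0.51]."""
        ref = make_reference(2, [1_000_000, 500_000], seed=1)
        for seq in ref.contigs.values():
            gc = (seq.count("G") + seq.count("C")) / len(seq)
            assert 0.49 < gc < 0.51

    def test_invalid_length_rejected(self):
        with pytest.raises(ValueError):
            make_reference(1, [500], seed=1)

    def test_sparse_reference_random_only_in_windows(self):
        ref = make_sparse_reference({"c": (100_000, [(40_000, 42_000)])}, seed=3)
        seq = ref.contigs["c"]
        assert seq[:1000] == ("AACCT" * 200)
        window = seq[40_000:42_000]
        assert len(set(window[i:i + 5] for i in range(0, 1995))) > 100


class TestImplant:
    def test_deletion_shortens_haplotype_exactly(self, small_ref):
        dg = DerivativeGenome(small_ref)
        dg.add_deletion("tumor-1", "chr1", 50_000, 101_200)
        assert dg.haplotype_length("tumor-1") == \
               sum(small_ref.lengths.values()) - 51_200
        assert dg.haplotype_length("tumor-2") == sum(small_ref.lengths.values())

    def test_empty_spec_identity(self, small_ref):
        dg = DerivativeGenome(small_ref)
        assert dg.sequence("tumor-1", 0) == small_ref.contigs["chr1"]
        assert dg.junctions_of("tumor-1") == []

    def test_ti_bridge_junction_kmers_novel(self, small_ref):
        """Each new junction's 40-mer occurs in the derivative but nowhere
        in the unedited reference (chance collision < 4^-20)."""
        dg = DerivativeGenome(small_ref)
        dg.add_ti_bridge("tumor-1", "chr1", 60_000, 90_000,
                         ("chr2", 10_000, 12_800, "-"))
        juncs = dg.junctions_of("tumor-1")
        assert len(juncs) == 2
        deriv = dg.sequence("tumor-1", 0)
        for j in juncs:
            kmer = dg.junction_kmer(j, 40)
            assert kmer in deriv
            assert all(kmer not in seq and kmer not in revcomp(seq)
                       for seq in small_ref.contigs.values())

    def test_length_conservation_across_sv_classes(self, small_ref):
        dg = DerivativeGenome(small_ref)
        base = sum(small_ref.lengths.values())
        dg.add_deletion("tumor-1", "chr1", 10_000, 22_000)          # -12000
        dg.add_duplication("tumor-1", "chr1", 40_000, 45_000)       # +5000
        dg.add_inversion("tumor-1", "chr1", 60_000, 70_000)         # 0
        dg.add_ti_bridge("tumor-1", "chr2", 30_000, 50_000,
                         ("chr1", 150_000, 151_000, "+"))           # -20000 +1000
        assert dg.haplotype_length("tumor-1") == base - 12_000 + 5_000 - 20_000 + 1_000

    def test_unbalanced_inversion_pair_walk_and_loss(self, small_ref):
        dg = DerivativeGenome(small_ref)
        a, b, c, d = 20_000, 80_000, 150_000, 160_000
        sv1, sv2 = dg.add_unbalanced_inversion_pair("tumor-1", "chr1", a, b, c, d)
        # only one side of each break is rescued: [a,b) and [c,d) are lost
        assert dg.haplotype_length("tumor-1") == \
               sum(small_ref.lengths.values()) - (b - a) - (d - c)
        assert sv1.expected_calls[0].svlen == c - a
        assert sv2.expected_calls[0].svlen == d - b
        seq = dg.sequence("tumor-1", 0)
        ref1 = small_ref.contigs["chr1"]
        assert seq.startswith(ref1[:a] + revcomp(ref1[b:c])[:500])

    def test_overlapping_edits_conflict_names_both_svs(self, small_ref):
        dg = DerivativeGenome(small_ref)
        dg.add_deletion("tumor-1", "chr1", 10_000, 30_000, sv_id="svA")
        with pytest.raises(ConflictError, match="svA.*svB"):
            dg.add_deletion("tumor-1", "chr1", 25_000, 40_000, sv_id="svB")
        # same interval on the other haplotype is fine
        dg.add_deletion("tumor-2", "chr1", 25_000, 40_000, sv_id="svB")


class TestReads:
    def test_zero_purity_yields_no_tumor_reads(self, plain_genome):
        reads = simulate_reads(plain_genome, 0.0, 2.0, seed=5)
        assert reads and not any(r.is_tumor for r in reads)

    def test_tumor_fraction_matches_purity(self, plain_genome):
        """Tumor-origin fraction within 3 binomial SD of p = 0.58."""
        reads = simulate_reads(plain_genome, 0.58, 60.0, seed=6)
        n = len(reads)
        assert n >= 10_000
        frac = sum(r.is_tumor for r in reads) / n
        assert abs(frac - 0.58) < 3 * np.sqrt(0.58 * 0.42 / n)

    def test_mean_length_within_5_percent(self, plain_genome):
        reads = simulate_reads(plain_genome, 0.5, 60.0, mean_len=2100, seed=8)
        assert len(reads) >= 10_000
        mean = np.mean([len(r.sequence) for r in reads])
        assert abs(mean - 2100) / 2100 < 0.05

    def test_invalid_purity_rejected(self, plain_genome):
        with pytest.raises(ValueError):
            simulate_reads(plain_genome, 1.2, 5.0)

    def test_error_free_reads_match_reference(self, plain_genome):
        reads = simulate_reads(plain_genome, 0.5, 1.0, error_rates=(0, 0, 0), seed=9)
        r = reads[0]
        seq = plain_genome.sequence(r.haplotype, r.walk_index)
        assert r.sequence == seq[r.true_start:r.true_end]

    def test_seeded_determinism(self, plain_genome):
        a = simulate_reads(plain_genome, 0.5, 2.0, seed=11)
        b = simulate_reads(plain_genome, 0.5, 2.0, seed=11)
        assert [(r.id, r.sequence, r.haplotype) for r in a] == \
               [(r.id, r.sequence, r.haplotype) for r in b]


class TestProjection:
    def test_read_in_unedited_region_single_segment(self, small_ref):
        dg = DerivativeGenome(small_ref)
        reads = simulate_spanning_reads(dg, "normal-1", 0, 100_000, 1,
                                        error_rates=(0, 0, 0), seed=1)
        segs = project_alignments(reads, dg)
        assert len(segs) == 1
        assert segs[0].contig == "chr1" and segs[0].strand == "+"

    def test_deletion_spanning_read_two_flanking_segments(self, small_ref):
        dg = DerivativeGenome(small_ref)
        dg.add_deletion("tumor-1", "chr1", 50_000, 120_000)
        reads = simulate_spanning_reads(dg, "tumor-1", 0, 50_000, 1,
                                        error_rates=(0, 0, 0), seed=2)
        segs = project_alignments(reads, dg)
        assert len(segs) == 2
        assert segs[0].ref_end == 50_000 and segs[1].ref_start == 120_000

    def test_ti_bridge_read_three_segments_middle_at_donor(self, small_ref):
        """A read over a templated-insertion bridge splits into three
        segments, the middle one at the donor locus."""
        dg = DerivativeGenome(small_ref)
        donor = ("chr2", 10_000, 11_000, "+")
        dg.add_ti_bridge("tumor-1", "chr1", 60_000, 90_000, donor)
        reads = simulate_spanning_reads(dg, "tumor-1", 0, 60_500, 1, mean_len=4000,
                                        error_rates=(0, 0, 0), seed=3, min_flank=700)
        segs = project_alignments(reads, dg)
        assert len(segs) == 3
        assert segs[1].contig == "chr2"
        assert (segs[1].ref_start, segs[1].ref_end) == (10_000, 11_000)


class TestCallsetEmission:
    def _truth(self, small_ref):
        dg = DerivativeGenome(small_ref)
        dg.add_deletion("tumor-1", "chr1", 30_000, 50_000)
        dg.add_inversion("tumor-1", "chr2", 60_000, 80_000)
        return TruthSet(dg, 0.58, 0)

    def test_noiseless_calls_match_truth_positions(self, small_ref):
        truth = self._truth(small_ref)
        calls = emit_callset(truth, (0, 0.0, 0), seed=1)
        positions = {(c.svtype, c.bp1.pos, c.bp2.pos) for c in calls}
        assert ("DEL", 30_000, 50_000) in positions
        assert ("INV", 60_000, 80_000) in positions

    def test_fp_count_forced(self, small_ref):
        calls = emit_callset(self._truth(small_ref), (40, 0.0, 0), seed=2)
        assert sum(1 for c in calls if c.provenance == "fp") == 40

    def test_jitter_bounded(self, small_ref):
        truth = self._truth(small_ref)
        calls = emit_callset(truth, (0, 0.0, 50), seed=3)
        truth_pos = {(ec.contig1, ec.pos1) for sv in truth.svs for ec in sv.expected_calls} | \
                    {(ec.contig2, ec.pos2) for sv in truth.svs for ec in sv.expected_calls}
        for c in calls:
            for bp in (c.bp1, c.bp2):
                assert any(ctg == bp.contig and abs(bp.pos - p) <= 50
                           for ctg, p in truth_pos)


class TestCnvProfile:
    def test_neutral_genome_all_probes_at_one(self, small_ref):
        truth = TruthSet(DerivativeGenome(small_ref), 0.58, 0)
        probes, segs = emit_cnv_profile(truth, 1_000, 0.0, seed=1)
        assert all(p.r == 1.0 for p in probes)
        assert all(s.q == 2 for s in segs)

    def test_hom_del_ratio_follows_mixture(self, small_ref):
        """q=0 at p=0.58 gives ratio 0.42 = (0*0.58 + 2*0.42)/2."""
        dg = DerivativeGenome(small_ref)
        dg.add_deletion("tumor-1", "chr1", 40_000, 60_000)
        dg.add_deletion("tumor-2", "chr1", 40_000, 60_000)
        probes, segs = emit_cnv_profile(TruthSet(dg, 0.58, 0), 1_000, 0.0, seed=1)
        inside = [p for p in probes if p.contig == "chr1" and 40_000 <= p.start < 60_000]
        assert inside and all(abs(p.r - 0.42) < 1e-12 for p in inside)
        pure = emit_cnv_profile(TruthSet(dg, 1.0, 0), 1_000, 0.0, seed=1)[0]
        inside_pure = [p for p in pure if p.contig == "chr1" and 40_000 <= p.start < 60_000]
        assert all(p.r == 0.0 for p in inside_pure)

    def test_segment_boundaries_match_truth(self, small_ref):
        dg = DerivativeGenome(small_ref)
        dg.add_deletion("tumor-1", "chr1", 40_000, 60_000)
        _, segs = emit_cnv_profile(TruthSet(dg, 0.58, 0), 1_000, 0.0, seed=1)
        chr1 = [(s.start, s.end, s.q) for s in segs if s.contig == "chr1"]
        assert chr1 == [(0, 40_000, 2), (40_000, 60_000, 1), (60_000, 200_000, 2)]


def test_expected_copy_ratio_matches_cell_mixture_simulation(rng):
    """Monte-Carlo oracle: 10^6 cells, 58% carrying q=0, mean coverage
    ratio agrees with the closed form."""
    n = 1_000_000
    n_tumor = rng.binomial(n, 0.58)
    sim = (0 * n_tumor + 2 * (n - n_tumor)) / (2 * n)
    assert abs(expected_copy_ratio(0, 0.58) - sim) < 3 * np.sqrt(0.58 * 0.42 / n)
    assert expected_copy_ratio(2, 0.13) == 1.0
    assert expected_copy_ratio(0, 1.0) == 0.0
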