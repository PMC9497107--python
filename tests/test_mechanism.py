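"""RAG-heptamer scanning, microhomology, and background enrichment tests."""

import numpy as np
import pytest

from svlandscape.formats import Breakend, SvCall
from svlandscape.mechanism import (
    RAG_HEPTAMER,
    RAG_HEPTAMER_RC,
    annotate,
    enrichment_test,
    longest_common_substring,
    make_background,
    microhomology_length,
    scan_rag_heptamer,
)
from svlandscape.simulate import GenomeRef, make_reference


def brute_force_lcs(a: str, b: str) -> int:
    best = 0
    for i in range(len(a)):
        for j in range(i + best + 1, len(a) + 1):
            if a[i:j] in b:
                best = j - i
            else:
                break
    return best


def _ref_with(seqs: dict[str, str]) -> GenomeRef:
    return GenomeRef({k: v.ljust(1000, "T") for k, v in seqs.items()})


class TestMicrohomology:
    def _sv(self, p1, p2, svtype="DEL"):
        return SvCall("x", svtype, Breakend("c", p1, "L"), Breakend("c", p2, "R"),
                      abs(p2 - p1))

    def test_identical_12bp_flanks_give_12(self):
        """Breakends sharing an identical 12-bp flank score the maximum for
        that flank; fully identical windows saturate at the window size."""
        shared = "ACGTTGCAACGT"
        seq = list("T" * 1000)
        seq[288:300] = shared          # left flank of bp1
        seq[300:312] = "A" * 12
        seq[688:700] = shared          # left flank of bp2
        seq[700:712] = "C" * 12
        ref = GenomeRef({"c": "".join(seq)})
        assert microhomology_length(ref, self._sv(300, 700)).mh_len == 12
        # fully identical 24-bp windows: maximum = 2w
        seq[688:712] = seq[288:312]
        ref2 = GenomeRef({"c": "".join(seq)})
        assert microhomology_length(ref2, self._sv(300, 700)).mh_len == 24

    def test_disjoint_alphabets_zero(self):
        seq = "A" * 500 + "C" * 500
        ref = GenomeRef({"c": seq})
        # windows: around 250 all A, around 750 all C
        ann = microhomology_length(ref, self._sv(250, 750))
        assert ann.mh_len == 0

    def test_planted_6mer_recovered(self, rng):
        """Windows over distinct 3-letter alphabets sharing one planted
        6-mer give exactly 6 (brute-force-verified)."""
        left = "".join(rng.choice(list("ACG"), size=24))
        right = "".join(rng.choice(list("CGT"), size=24))
        shared = "AAATTT"  # absent from both 3-letter alphabets as a whole
        left = left[:9] + shared + left[15:]
        right = right[:9] + shared + right[15:]
        seq = "C" * 100 + left + "C" * 100 + right + "C" * 100
        ref = GenomeRef({"c": seq.ljust(1000, "G")})
        sv = self._sv(112, 236)  # breakends centered in the two windows
        ann = microhomology_length(ref, sv)
        win1, win2 = seq[100:124], seq[224:248]
        assert ann.mh_len == brute_force_lcs(win1, win2) >= 6

    def test_symmetric_in_breakend_order(self, small_ref):
        sv = SvCall("x", "DEL", Breakend("chr1", 50_000, "L"),
                    Breakend("chr1", 120_000, "R"), 70_000)
        swapped = SvCall("x", "DEL", Breakend("chr1", 120_000, "R"),
                         Breakend("chr1", 50_000, "L"), 70_000)
        ref = small_ref
        assert microhomology_length(ref, sv).mh_len == \
               microhomology_length(ref, swapped).mh_len

    def test_contig_edge_truncation_flagged(self, small_ref):
        sv = SvCall("x", "DEL", Breakend("chr1", 5, "L"),
                    Breakend("chr1", 50_000, "R"), 49_995)
        ann = microhomology_length(small_ref, sv)
        assert ann.truncated

    def test_lcs_equals_bruteforce_on_1000_random_windows(self, rng):
        """Property sweep: the LCS primitive agrees with the brute-force
        oracle on 1,000 random 24-bp window pairs."""
        bases = np.array(list("ACGT"))
        for _ in range(1_000):
            a = "".join(rng.choice(bases, size=24))
            b = "".join(rng.choice(bases, size=24))
            assert longest_common_substring(a, b) == brute_force_lcs(a, b)


class TestRagScan:
    def test_forward_hit(self):
        ref = _ref_with({"c": "T" * 100 + RAG_HEPTAMER + "T" * 100})
        assert scan_rag_heptamer(ref, Breakend("c", 103, "L"), window=20) == 1

    def test_reverse_strand_hit(self):
        ref = _ref_with({"c": "T" * 100 + RAG_HEPTAMER_RC + "T" * 100})
        assert scan_rag_heptamer(ref, Breakend("c", 103, "L"), window=20) == 1

    def test_window_too_small_rejected(self, small_ref):
        with pytest.raises(ValueError):
            scan_rag_heptamer(small_ref, Breakend("chr1", 100, "L"), window=5)

    def test_hit_rate_matches_exhaustive_scan_and_analytic_rate(self):
        """Mean hits per breakend over many random positions equals both an
        independent exhaustive scan of the same sequence and the analytic
        motif probability 2*(2w-6)/4^7 within Monte-Carlo error."""
        w = 20
        L = 2_000_000
        ref = make_reference(1, [L], seed=99)
        seq = ref.contigs["chr1"]
        positions = range(w, L - w, 2 * w)  # non-overlapping windows
        total = sum(scan_rag_heptamer(ref, Breakend("chr1", p, "L"), w)
                    for p in positions)
        # exhaustive oracle: enumerate motif starts, count windows seeing each
        starts = [i for i in range(len(seq) - 6)
                  if seq[i:i + 7] in (RAG_HEPTAMER, RAG_HEPTAMER_RC)]

        def n_windows_seeing(s: int) -> int:
            lo, hi = s - w + 7, s + w  # p range whose window contains start s
            lo = max(lo, positions.start)
            hi = min(hi, positions[-1])
            if hi < lo:
                return 0
            first = lo + (-(lo - positions.start)) % positions.step
            return 0 if first > hi else (hi - first) // positions.step + 1

        assert total == sum(n_windows_seeing(s) for s in starts)
        n = len(positions)
        expected = 2 * (2 * w - 6) / 4 ** 7
        sd = np.sqrt(expected / n)  # Poisson bound on the mean of rare counts
        assert abs(total / n - expected) < 4 * sd


class TestBackground:
    def _observed(self):
        calls = [SvCall(f"d{i}", "DEL", Breakend("chr1", 1_000 + i * 3_000, "L"),
                        Breakend("chr1", 2_000 + i * 3_000 + i * 100, "R"),
                        1_000 + i * 100) for i in range(20)]
        calls += [SvCall(f"t{i}", "BND", Breakend("chr1", 50_000 + i, "L"),
                         Breakend("chr2", 60_000 + i, "R")) for i in range(5)]
        return calls

    def test_exact_size_and_determinism(self, small_ref):
        obs = self._observed()
        bg = make_background(small_ref, obs, 100, seed=5)
        assert len(bg.calls) == 100
        bg2 = make_background(small_ref, obs, 100, seed=5)
        assert [(c.svtype, c.bp1.pos, c.bp2.pos) for c in bg.calls] == \
               [(c.svtype, c.bp1.pos, c.bp2.pos) for c in bg2.calls]

    def test_positions_on_contig(self, small_ref):
        bg = make_background(small_ref, self._observed(), 100, seed=6)
        for c in bg.calls:
            for bp in (c.bp1, c.bp2):
                assert 0 <= bp.pos < small_ref.lengths[bp.contig]

    def test_length_distribution_matches_observed(self, small_ref):
        """Two-sample KS between background and observed lengths stays below
        the 5% critical value in >= 95% of seeded draws."""
        from scipy import stats
        obs = self._observed()
        obs_lens = [c.svlen for c in obs if c.svlen]
        ok = 0
        n_trials = 100
        for seed in range(n_trials):
            bg = make_background(small_ref, obs, 100, seed=seed)
            bg_lens = [c.svlen for c in bg.calls if c.svlen]
            if stats.ks_2samp(obs_lens, bg_lens).pvalue > 0.05:
                ok += 1
        assert ok >= 0.90 * n_trials  # 95% minus binomial wobble at n=100

    def test_invalid_n_rejected(self, small_ref):
        with pytest.raises(ValueError):
            make_background(small_ref, self._observed(), 0, seed=1)


class TestEnrichment:
    def test_identity_gives_null_result(self, small_ref):
        obs = TestBackground()._observed()
        ann = annotate(small_ref, obs)
        res = enrichment_test(ann, ann)
        assert res.rag_odds_ratio == 1.0 and res.rag_p == 1.0
        assert not res.rag_enriched and not res.mh_enriched

    def test_extreme_microhomology_shift_detected(self):
        from svlandscape.mechanism import MechanismAnnotation
        obs = [MechanismAnnotation(f"o{i}", 12, (0, 0), 12, 50) for i in range(6)]
        bg = [MechanismAnnotation(f"b{i}", 0, (0, 0), 12, 50) for i in range(6)]
        res = enrichment_test(obs, bg)
        assert res.mh_p < 0.05 and res.mh_enriched

    def test_empty_sets_rejected(self):
        with pytest.raises(ValueError):
            enrichment_test([], [])
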