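"""SV clustering, cis/trans verdicts, and derivative-walk reconstruction."""

import pytest

from svlandscape.fixtures import cdkn2a_region, chromoplexy
from svlandscape.formats import Breakend, CnvSegment, SvCall
from svlandscape.phasing import (
    SvCluster,
    assign_haplotypes,
    classify_clusters,
    cluster_by_readnames,
    reconstruct_complex,
)


def _call(cid, pos=1_000, svtype="DEL", reads=(), contig="c1", pos2=None):
    pos2 = pos2 if pos2 is not None else pos + 10_000
    return SvCall(cid, svtype, Breakend(contig, pos, "L"),
                  Breakend(contig, pos2, "R"), pos2 - pos, len(reads) or 5,
                  0.4, tuple(reads))


class TestClustering:
    def test_shared_read_links_two_svs(self):
        a = _call("a", 1_000, reads=("r1", "r2"))
        b = _call("b", 50_000, reads=("r2", "r3"))
        clusters = cluster_by_readnames([a, b])
        assert len(clusters) == 1 and clusters[0].sv_ids == ["a", "b"]
        assert clusters[0].edges[0][2] == 1

    def test_disjoint_reads_are_singletons(self):
        a = _call("a", 1_000, reads=("r1",))
        b = _call("b", 50_000, reads=("r2",))
        clusters = cluster_by_readnames([a, b])
        assert [c.sv_ids for c in clusters] == [["a"], ["b"]]

    def test_transitive_chain_single_cluster(self):
        """a-b and b-c shared reads with no a-c share still produce one
        cluster {a, b, c} (transitive closure)."""
        a = _call("a", 1_000, reads=("r1",))
        b = _call("b", 50_000, reads=("r1", "r2"))
        c = _call("c", 90_000, reads=("r2",))
        clusters = cluster_by_readnames([a, b, c])
        assert len(clusters) == 1 and clusters[0].sv_ids == ["a", "b", "c"]
        assert clusters[0].classification == "complex"

    def test_input_order_invariance(self):
        calls = [_call("a", 1_000, reads=("r1",)), _call("b", 50_000, reads=("r1",)),
                 _call("c", 120_000, reads=("r9",))]
        forward = cluster_by_readnames(calls)
        backward = cluster_by_readnames(list(reversed(calls)))
        assert [c.sv_ids for c in forward] == [c.sv_ids for c in backward]

    def test_phase_set_link_without_shared_reads(self):
        """Two SVs phased in the same phase set cluster even with disjoint
        read sets (the long-range linkage channel)."""
        a = _call("a", 1_000, reads=("r1", "r2", "r3"))
        b = _call("b", 300_000, reads=("r7", "r8", "r9"))
        tags = {"r1": "1", "r2": "1", "r3": "1", "r7": "1", "r8": "1", "r9": "1"}
        clusters = cluster_by_readnames([a, b], tags=tags)
        assert len(clusters) == 1
        assert clusters[0].edges[0][3] == "1|1"
        # without tags they stay apart
        assert len(cluster_by_readnames([a, b])) == 2


class TestHaplotypeCalls:
    def test_same_haplotype_cis(self):
        a = _call("a", reads=("r1", "r2", "r3"))
        b = _call("b", 40_000, reads=("r4", "r5", "r6"))
        tags = {r: "1" for r in ("r1", "r2", "r3", "r4", "r5", "r6")}
        verdicts = assign_haplotypes([a, b], tags,
                                     [SvCluster(["a", "b"], [])])
        assert verdicts[0].verdict == "cis"

    def test_different_haplotypes_trans(self):
        a = _call("a", reads=("r1", "r2", "r3"))
        b = _call("b", 40_000, reads=("r4", "r5", "r6"))
        tags = {"r1": "1", "r2": "1", "r3": "1", "r4": "2", "r5": "2", "r6": "2"}
        verdicts = assign_haplotypes([a, b], tags, [SvCluster(["a", "b"], [])])
        assert verdicts[0].verdict == "trans"

    def test_split_tags_unresolved_at_majority(self):
        a = _call("a", reads=("r1", "r2", "r3", "r4"))
        b = _call("b", 40_000, reads=("r5", "r6"))
        tags = {"r1": "1", "r2": "1", "r3": "2", "r4": "2", "r5": "1", "r6": "1"}
        verdicts = assign_haplotypes([a, b], tags, [SvCluster(["a", "b"], [])],
                                     majority=0.8)
        assert verdicts[0].verdict == "unresolved"

    def test_no_tags_all_unresolved(self):
        a = _call("a", reads=("r1",))
        b = _call("b", 40_000, reads=("r2",))
        verdicts = assign_haplotypes([a, b], {}, [SvCluster(["a", "b"], [])])
        assert all(v.verdict == "unresolved" for v in verdicts)

    def test_perfect_accuracy_with_three_tagged_reads(self):
        """With >= 3 truth-tagged reads per SV every pair verdict matches
        the construction (cis for same haplotype, trans otherwise)."""
        import itertools
        svs, truth_hap, tags = [], {}, {}
        rid = 0
        for i in range(8):
            hap = "1" if i % 2 == 0 else "2"
            reads = tuple(f"r{rid + k}" for k in range(3))
            rid += 3
            for r in reads:
                tags[r] = hap
            sv = _call(f"s{i}", 1_000 + i * 30_000, reads=reads)
            svs.append(sv)
            truth_hap[sv.id] = hap
        verdicts = assign_haplotypes(svs, tags, [SvCluster([s.id for s in svs], [])])
        assert verdicts
        for v in verdicts:
            want = "cis" if truth_hap[v.sv_a] == truth_hap[v.sv_b] else "trans"
            assert v.verdict == want

    def test_cis_pair_promotion(self):
        a = _call("a", reads=("r1", "r2", "r3"))
        b = _call("b", 40_000, reads=("r1", "r4", "r5"))
        tags = {r: "1" for r in ("r1", "r2", "r3", "r4", "r5")}
        clusters = cluster_by_readnames([a, b], tags=tags)
        verdicts = assign_haplotypes([a, b], tags, clusters)
        classify_clusters(clusters, verdicts)
        assert clusters[0].classification == "cis-pair"


class TestReconstruction:
    def test_isolated_deletion_walk_of_two_flanks(self):
        call = _call("d", 50_000, pos2=120_000)
        cluster = SvCluster(["d"], [])
        rep = reconstruct_complex(cluster, [call], {"c1": 200_000})
        assert rep.attempted
        assert rep.walks == [[("c1", 0, 50_000, "+"), ("c1", 120_000, 200_000, "+")]]
        assert ("c1", 50_000, 120_000) in rep.orphans

    def test_fig4a_analogue_walk_matches_derivative(self):
        """The reconstructed walk reproduces the derivative segment order of
        the unbalanced-inversion pair: flank A, inverted donor, flank B,
        with the deleted intervals absent."""
        scen = cdkn2a_region(seed=5)
        dg = scen.truth.genome
        calls = []
        for sv in dg.svs:
            for k, ec in enumerate(sv.expected_calls):
                side1 = side2 = None
                (b1, b2, _ins) = sv.junctions[k if k < len(sv.junctions) else 0]
                calls.append(SvCall(sv.id, ec.svtype, Breakend(ec.contig1, ec.pos1, b1.side),
                                    Breakend(ec.contig2, ec.pos2, b2.side), ec.svlen))
        cluster = SvCluster([c.id for c in calls], [])
        rep = reconstruct_complex(cluster, calls, dg.ref.lengths)
        assert rep.attempted
        assert scen.expected["walk_tumor1"] in [
            [tuple(seg) for seg in walk] for walk in rep.walks]
        truth_walk = [(p.contig, p.start, p.end, p.strand)
                      for p in dg.walks["tumor-1"][0]]
        assert truth_walk in [[tuple(s) for s in w] for w in rep.walks]

    def test_chromoplexy_cluster_degrades_to_adjacency(self):
        """A 26-junction cluster is not reconstructed; the adjacency list is
        reported instead."""
        scen = chromoplexy(seed=2)
        dg = scen.truth.genome
        calls = []
        for i, (b1, b2, _ins) in enumerate(dg.svs[0].junctions):
            from svlandscape.simulate import expected_call_from_junction
            ec = expected_call_from_junction(b1, b2)
            calls.append(SvCall(f"j{i}", ec.svtype, Breakend(ec.contig1, ec.pos1, b1.side),
                                Breakend(ec.contig2, ec.pos2, b2.side), ec.svlen))
        cluster = SvCluster([c.id for c in calls], [])
        rep = reconstruct_complex(cluster, calls, dg.ref.lengths)
        assert not rep.attempted
        assert len(rep.adjacency) == scen.expected["n_junctions"] == 26
        assert "not attempted" in rep.note

    def test_copy_number_inconsistent_junction_flagged(self):
        call = _call("d", 50_000, pos2=120_000)
        segs = [CnvSegment("c1", 40_000, 60_000, 0.0, q=0)]
        rep = reconstruct_complex(SvCluster(["d"], []), [call], {"c1": 200_000}, segs)
        assert rep.cn_inconsistent == ["d"]
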