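"""Read-backed phasing of SVs and complex-rearrangement reconstruction.

SVs are linked into clusters through two channels: shared supporting reads
(direct physical linkage within a read length) and haplotype tags carried by
the supporting reads (phased SNP linkage over arbitrary distance, consumed
from an external phaser).  Cis/trans verdicts for SV pairs use tags only —
read sharing proves co-location but not phase beyond one read.  Clusters of
modest size are reconstructed into an ordered derivative walk when the
junction set admits exactly one; larger or ambiguous clusters degrade to an
adjacency report.
"""

from __future__ import annotations

import itertools
from collections import Counter
from dataclasses import dataclass, field

import networkx as nx

from svlandscape.formats import CnvSegment, SvCall


@dataclass
class SvCluster:
    """A connected component of the SV evidence graph."""

    sv_ids: list[str]
    edges: list[tuple[str, str, int, str | None]]  # (a, b, shared reads, shared tag)
    classification: str = "isolated"  # isolated | cis-pair | complex
    contigs: tuple[str, ...] = ()


@dataclass
class HaplotypeCall:
    """Cis/trans verdict for one SV pair."""

    sv_a: str
    sv_b: str
    verdict: str  # cis | trans | unresolved
    fractions: dict[str, dict[str, float]] = field(default_factory=dict)


def assign_sv_haplotype(call: SvCall, tags: dict[str, str],
                        majority: float = 0.8) -> tuple[str | None, dict[str, float]]:
    """Majority haplotype among a call's tagged supporting reads.

    Returns (haplotype or None, per-haplotype fractions).  A haplotype is
    assigned only when it carries at least ``majority`` of the tagged reads.
    """
    tagged = [tags[r] for r in call.read_names if r in tags and tags[r] is not None]
    if not tagged:
        return None, {}
    counts = Counter(tagged)
    total = sum(counts.values())
    fracs = {h: c / total for h, c in counts.items()}
    top, cnt = counts.most_common(1)[0]
    if cnt / total >= majority:
        return top, fracs
    return None, fracs


def cluster_by_readnames(calls: list[SvCall], min_shared: int = 1,
                         tags: dict[str, str] | None = None,
                         phase_sets: dict[str, str] | None = None,
                         majority: float = 0.8) -> list[SvCluster]:
    """Connected components of the SV evidence graph.

    Edges join SVs sharing at least ``min_shared`` supporting reads, or —
    when haplotype ``tags`` are supplied — SVs whose supporting reads are
    phased within the same phase set (both resolvable to a haplotype), which
    makes them comparable for a cis/trans verdict.  Ordering is
    deterministic by leftmost breakend.
    """
    calls = sorted(calls, key=lambda c: (c.bp1.contig, c.bp1.pos, c.id))
    g = nx.Graph()
    for c in calls:
        g.add_node(c.id)
    edges: dict[tuple[str, str], tuple[int, str | None]] = {}
    for a, b in itertools.combinations(calls, 2):
        shared = len(set(a.read_names) & set(b.read_names))
        tag_link: str | None = None
        if tags is not None:
            ha, _ = assign_sv_haplotype(a, tags, majority)
            hb, _ = assign_sv_haplotype(b, tags, majority)
            if ha is not None and hb is not None:
                ps_a = phase_sets.get(a.id) if phase_sets else "ps0"
                ps_b = phase_sets.get(b.id) if phase_sets else "ps0"
                if ps_a == ps_b:
                    tag_link = f"{ha}|{hb}"
        if shared >= min_shared or tag_link is not None:
            g.add_edge(a.id, b.id)
            edges[(a.id, b.id)] = (shared, tag_link)
    by_id = {c.id: c for c in calls}
    clusters = []
    for comp in nx.connected_components(g):
        ids = sorted(comp, key=lambda i: (by_id[i].bp1.contig, by_id[i].bp1.pos, i))
        comp_edges = [(a, b, s, t) for (a, b), (s, t) in edges.items()
                      if a in comp and b in comp]
        contigs = tuple(sorted({ctg for i in ids
                                for ctg in (by_id[i].bp1.contig, by_id[i].bp2.contig)}))
        n_junctions = len(ids)
        if len(ids) >= 3 or (len(contigs) >= 2 and n_junctions >= 3):
            cls = "complex"
        else:
            cls = "isolated"  # may be promoted to cis-pair once verdicts exist
        clusters.append(SvCluster(ids, comp_edges, cls, contigs))
    clusters.sort(key=lambda cl: (by_id[cl.sv_ids[0]].bp1.contig, by_id[cl.sv_ids[0]].bp1.pos))
    return clusters


def assign_haplotypes(calls: list[SvCall], tags: dict[str, str],
                      clusters: list[SvCluster] | None = None,
                      majority: float = 0.8) -> list[HaplotypeCall]:
    """Cis/trans verdict for every SV pair within a cluster.

    Each SV is assigned the haplotype carried by at least ``majority`` of
    its tagged supporting reads, else the pair is unresolved.  With no tags
    at all every pair is unresolved (as happens over runs of homozygosity
    where SNP phasing fails).
    """
    clusters = clusters or [SvCluster([c.id for c in calls], [])]
    by_id = {c.id: c for c in calls}
    out: list[HaplotypeCall] = []
    for cl in clusters:
        assigned = {}
        fracs = {}
        for sv_id in cl.sv_ids:
            if sv_id in by_id:
                assigned[sv_id], fracs[sv_id] = assign_sv_haplotype(by_id[sv_id], tags, majority)
        for a, b in itertools.combinations(cl.sv_ids, 2):
            ha, hb = assigned.get(a), assigned.get(b)
            if ha is None or hb is None:
                verdict = "unresolved"
            elif ha == hb:
                verdict = "cis"
            else:
                verdict = "trans"
            out.append(HaplotypeCall(a, b, verdict, {a: fracs.get(a, {}), b: fracs.get(b, {})}))
    return out


def classify_clusters(clusters: list[SvCluster],
                      verdicts: list[HaplotypeCall]) -> None:
    """Promote two-SV clusters with a cis verdict to ``cis-pair`` in place."""
    vmap = {(v.sv_a, v.sv_b): v.verdict for v in verdicts}
    vmap.update({(v.sv_b, v.sv_a): v.verdict for v in verdicts})
    for cl in clusters:
        if len(cl.sv_ids) == 2 and vmap.get((cl.sv_ids[0], cl.sv_ids[1])) == "cis":
            cl.classification = "cis-pair"


# ---------------------------------------------------------------------------
# Derivative-structure reconstruction
# ---------------------------------------------------------------------------

@dataclass
class ReconstructionReport:
    cluster_svs: list[str]
    attempted: bool
    walks: list[list[tuple[str, int, int, str]]] = field(default_factory=list)
    orphans: list[tuple[str, int, int]] = field(default_factory=list)  # lost segments
    adjacency: list[tuple[tuple[str, int, str], tuple[str, int, str]]] = field(default_factory=list)
    cn_inconsistent: list[str] = field(default_factory=list)
    note: str = ""


def _call_junctions(call: SvCall) -> list[tuple[tuple[str, int, str], tuple[str, int, str]]]:
    """Breakend adjacencies implied by one call (DUP flips the sides)."""
    b1 = (call.bp1.contig, call.bp1.pos, call.bp1.side)
    b2 = (call.bp2.contig, call.bp2.pos, call.bp2.side)
    if call.svtype == "DUP":
        # tandem duplication joins the end of the interval back to its start
        b1 = (call.bp2.contig, call.bp2.pos, "L")
        b2 = (call.bp1.contig, call.bp1.pos, "R")
    return [(b1, b2)]


def reconstruct_complex(cluster: SvCluster, calls: list[SvCall],
                        contig_lengths: dict[str, int],
                        cnv_segments: list[CnvSegment] | None = None,
                        max_junctions: int = 8) -> ReconstructionReport:
    """Emit an ordered derivative walk consistent with a cluster's junctions.

    The involved contigs are cut at every breakend; junction edges replace
    the reference adjacencies they break.  When the resulting graph is a set
    of unambiguous simple paths, walks are emitted (with deleted reference
    intervals reported as orphans); otherwise — or for clusters with more
    than ``max_junctions`` junctions — the junction adjacency list is
    reported with reconstruction not attempted.  Junctions whose breakends
    fall inside a fully deleted (q = 0) copy-number segment are flagged as
    copy-number inconsistent.
    """
    by_id = {c.id: c for c in calls}
    cluster_calls = [by_id[i] for i in cluster.sv_ids if i in by_id]
    junctions = []
    for c in cluster_calls:
        junctions.extend((c.id, j) for j in _call_junctions(c))

    cn_bad = []
    if cnv_segments:
        zero = [(s.contig, s.start, s.end) for s in cnv_segments if s.q == 0]
        for sv_id, (b1, b2) in junctions:
            for (ctg, pos, _side) in (b1, b2):
                if any(ctg == zc and zs < pos < ze for zc, zs, ze in zero):
                    cn_bad.append(sv_id)
                    break

    adjacency = [j for _sv, j in junctions]
    if len(junctions) > max_junctions:
        return ReconstructionReport(cluster.sv_ids, False, adjacency=adjacency,
                                    cn_inconsistent=sorted(set(cn_bad)),
                                    note="cluster too large; reconstruction not attempted")
    if any(c.svtype == "DUP" for c in cluster_calls):
        # copy gains need a multigraph walk; degrade to adjacency output
        return ReconstructionReport(cluster.sv_ids, False, adjacency=adjacency,
                                    cn_inconsistent=sorted(set(cn_bad)),
                                    note="copy-gain junction present; reconstruction not attempted")

    # cut contigs at breakends
    cuts: dict[str, set[int]] = {}
    for _sv, (b1, b2) in junctions:
        for (ctg, pos, _side) in (b1, b2):
            cuts.setdefault(ctg, set()).add(pos)
    pieces: list[tuple[str, int, int]] = []
    for ctg, ps in cuts.items():
        bounds = [0] + sorted(p for p in ps if 0 < p < contig_lengths[ctg]) + [contig_lengths[ctg]]
        for s, e in itertools.pairwise(bounds):
            pieces.append((ctg, s, e))

    # node = (contig, pos, side): the flank a junction or adjacency attaches to
    junction_nodes: Counter = Counter()
    for _sv, (b1, b2) in junctions:
        junction_nodes[b1] += 1
        junction_nodes[b2] += 1
    if any(v > 1 for v in junction_nodes.values()):
        return ReconstructionReport(cluster.sv_ids, False, adjacency=adjacency,
                                    cn_inconsistent=sorted(set(cn_bad)),
                                    note="breakend reused by several junctions; ambiguous")

    external: dict[tuple[str, int, str], tuple[str, int, str]] = {}
    for _sv, (b1, b2) in junctions:
        external[b1] = b2
        external[b2] = b1
    for ctg, ps in cuts.items():
        for p in sorted(ps):
            left, right = (ctg, p, "L"), (ctg, p, "R")
            if left not in external and right not in external:
                external[left] = right
                external[right] = left

    piece_of_node: dict[tuple[str, int, str], tuple[str, int, int]] = {}
    for ctg, s, e in pieces:
        piece_of_node[(ctg, e, "L")] = (ctg, s, e)  # right extremity
        piece_of_node[(ctg, s, "R")] = (ctg, s, e)  # left extremity

    def other_end(piece: tuple[str, int, int], node: tuple[str, int, str]):
        ctg, s, e = piece
        return (ctg, s, "R") if node == (ctg, e, "L") else (ctg, e, "L")

    visited: set[tuple[str, int, int]] = set()
    walks: list[list[tuple[str, int, int, str]]] = []
    # start at piece extremities with no external connection (telomeric ends)
    starts = [n for n in piece_of_node if n not in external]
    for start in sorted(starts):
        piece = piece_of_node[start]
        if piece in visited:
            continue
        walk: list[tuple[str, int, int, str]] = []
        node = start
        while True:
            piece = piece_of_node[node]
            if piece in visited:
                return ReconstructionReport(cluster.sv_ids, False, adjacency=adjacency,
                                            cn_inconsistent=sorted(set(cn_bad)),
                                            note="piece revisited; structure ambiguous")
            visited.add(piece)
            ctg, s, e = piece
            strand = "+" if node == (ctg, s, "R") else "-"
            walk.append((ctg, s, e, strand))
            exit_node = other_end(piece, node)
            nxt = external.get(exit_node)
            if nxt is None:
                break
            node = nxt
        if len(walk) == 1:
            continue  # a lone piece with no junction attached: a lost fragment
        walks.append(walk)
    orphans = [(c, s, e) for (c, s, e) in pieces
               if not any((c, s, e) == (wc, ws, we)
                          for w in walks for (wc, ws, we, _st) in w)]
    return ReconstructionReport(cluster.sv_ids, True, walks=walks, orphans=orphans,
                                adjacency=adjacency, cn_inconsistent=sorted(set(cn_bad)))
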