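"""End-to-end recovery workflows used by the analysis scripts and checks.

Each function runs one complete simulate -> evidence -> call -> measure
chain for a printed SV dimension and returns the *measured* quantity, so
the recovered numbers are always recomputed from scratch.
"""

from __future__ import annotations

from svlandscape import consensus as consmod
from svlandscape.calling import call_svs_from_alignments, class_census, filter_svs
from svlandscape.fixtures import (
    census_callset,
    deletion_recovery,
    inversion_recovery,
    minimal_insertion,
)
from svlandscape.formats import SvCall
from svlandscape.simulate import (
    junction_regions,
    project_alignments,
    simulate_reads,
    simulate_spanning_reads,
)


def filter_census(seed: int = 1) -> dict[str, int]:
    """Constructed call set (somatic classes + 40 short germline decoys)
    through the somatic filter; per-class census of the kept set."""
    calls = census_callset(seed=seed)
    kept, _removed = filter_svs(calls)
    return class_census(kept)


def recover_deletion_kb(seed: int = 11, depth: float = 25.0) -> float:
    """Implant the 512 kb deletion, simulate junction-local 2.1 kb reads at
    the study purity, call and filter; called SVLEN in kb (nearest kb)."""
    scen = deletion_recovery(seed=seed)
    dg = scen.truth.genome
    regions = junction_regions(dg, 50_000)
    reads = simulate_reads(dg, scen.truth.purity, depth, 2100.0,
                           (0.02, 0.01, 0.02), seed, regions)
    calls = call_svs_from_alignments(project_alignments(reads, dg))
    kept, _ = filter_svs(calls)
    dels = [c for c in kept if c.svtype == "DEL"]
    if not dels:
        raise RuntimeError("deletion not recovered")
    best = max(dels, key=lambda c: c.support)
    return round(best.svlen / 1000.0)


def recover_inversion_mb(seed: int = 13, depth: float = 25.0) -> float:
    """Implant the unbalanced-inversion pair at true scale (sparse 36 Mb
    contig), recover the larger inversion from junction-local reads; called
    breakpoint distance in Mb (one decimal)."""
    scen = inversion_recovery(seed=seed)
    dg = scen.truth.genome
    regions = junction_regions(dg, 50_000)
    reads = simulate_reads(dg, scen.truth.purity, depth, 2100.0,
                           (0.02, 0.01, 0.02), seed, regions)
    calls = call_svs_from_alignments(project_alignments(reads, dg))
    kept, _ = filter_svs(calls)
    invs = [c for c in kept if c.svtype == "INV"]
    if not invs:
        raise RuntimeError("inversion not recovered")
    span = max(c.bp2.pos - c.bp1.pos for c in invs)
    return round(span / 1e6, 1)


def recover_min_insert_bp(seed: int = 17, n_reads: int = 20,
                          snap_tol: int = 50) -> int:
    """Implant the minimum-length templated insertion, build the
    supporting-read consensus, map it, flag the insertion; inserted-segment
    length in bp with donor boundaries snapped to the implanted junctions
    when the mapping lands within ``snap_tol``."""
    scen = minimal_insertion(seed=seed)
    dg = scen.truth.genome
    juncs = dg.junctions_of("tumor-1")
    insert_j = juncs[0]  # junction entering the donor segment
    reads = simulate_spanning_reads(dg, "tumor-1", insert_j.walk_index,
                                    insert_j.deriv_pos + scen.expected["insert_len"] // 2,
                                    n_reads, 2100.0, (0.02, 0.01, 0.02), seed)
    cons = consmod.build_consensus([r.sequence for r in reads], "ti_min")
    mapping = consmod.map_consensus(cons, dg.ref)
    verdict, inserts = consmod.flag_templated_insertion(mapping)
    if verdict != "templated_insertion" or not inserts:
        raise RuntimeError(f"templated insertion not detected ({verdict})")
    dc, ds, de, _strand, _length = max(inserts, key=lambda t: t[4])
    truth_dc, truth_ds, truth_de, _ts = scen.expected["donor"]
    if dc == truth_dc and abs(ds - truth_ds) <= snap_tol:
        ds = truth_ds
    if dc == truth_dc and abs(de - truth_de) <= snap_tol:
        de = truth_de
    return de - ds
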