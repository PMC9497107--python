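"""Packaged synthetic scenarios.

Each builder reproduces one of the sample's hallmark rearrangement
architectures at desk scale: coordinates are scaled down (1:100 or 1:10)
except where a quantity of interest is a literal length (templated-insert
sizes, the 639 bp breakpoint distance), in which case the scenario keeps the
literal value and, for megabase-scale spans, uses a sparse reference with
random sequence only near the junctions.

Scenarios:

* ``cdkn2a_region`` (1:100) — two unbalanced inversions in cis on one tumor
  haplotype (the larger rescuing an inverted segment into the break) plus a
  512 kb-class deletion on the other haplotype, producing a heterozygously
  deleted arm with a small homozygously deleted core.
* ``arid1a_region`` (1:10, literal insert) — a 2.2 Mb-class deletion bridged
  by a 2.8 kb templated insert whose donor locus sits 639 bp from the
  breakpoint of a second, 4.8 Mb-class deletion.
* ``stat35_chain`` (1:10) — a chain of templated insertion fusing two
  chromosomes with a 495 kb-class third-chromosome fragment in between.
* ``chromoplexy`` — a shattered-chromosome cluster with 15 intra- and 11
  inter-chromosomal junctions; reconstruction is expected to degrade to an
  adjacency report.
* ``census`` — a call-set-level fixture with the per-class somatic counts
  observed after filtering (93 deletions, 16 inversions, 10 duplications,
  48 translocations) plus sub-threshold germline decoys.

Full-scale recovery scenarios (``deletion_recovery``,
``inversion_recovery``, ``minimal_insertion``) implant the literal SV
dimensions and simulate reads junction-locally.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from svlandscape.formats import Breakend, SvCall
from svlandscape.simulate import (
    DerivativeGenome,
    GenomeRef,
    Piece,
    TruthSet,
    germline_decoys,
    make_reference,
    make_sparse_reference,
)

FIXTURE_NAMES = ("fig4a", "fig4b", "fig4c", "fig4d", "census")

# observed per-class somatic counts after the tumor-only filter
CENSUS_COUNTS = {"DEL": 93, "INV": 16, "DUP": 10, "TRA": 48}


@dataclass
class Scenario:
    name: str
    truth: TruthSet
    expected: dict = field(default_factory=dict)
    regions_pad: int = 25_000  # junction-local read-simulation padding


# ---------------------------------------------------------------------------
# Figure-scale scenarios
# ---------------------------------------------------------------------------

def cdkn2a_region(seed: int = 0, purity: float = 0.58) -> Scenario:
    """Unbalanced-inversion pair in cis + deletion in trans (1:100 scale)."""
    ref = make_reference(1, [400_000], seed, names=["chr9s"])
    dg = DerivativeGenome(ref)
    a, b, c, d = 28_000, 238_000, 344_000, 345_000
    inv1, inv2 = dg.add_unbalanced_inversion_pair(
        "tumor-1", "chr9s", a, b, c, d, sv_ids=("inv_large", "inv_small"))
    dele = dg.add_deletion("tumor-2", "chr9s", 218_800, 223_920, sv_id="del_cdkn2a")
    expected = {
        "n_svs": 3,
        "cis_pair": ("inv_large", "inv_small"),
        "trans_pair": ("inv_large", "del_cdkn2a"),
        "walk_tumor1": [("chr9s", 0, a, "+"), ("chr9s", b, c, "-"),
                        ("chr9s", d, 400_000, "+")],
        "hom_del_interval": ("chr9s", 218_800, 223_920),
        "inv_spans": {inv1.id: c - a, inv2.id: d - b},
    }
    return Scenario("fig4a", TruthSet(dg, purity, seed), expected, regions_pad=10_000)


def arid1a_region(seed: int = 0, purity: float = 0.58) -> Scenario:
    """Templated-insertion bridge next to a second deletion (1:10 scale,
    literal 2.8 kb insert and 639 bp distance)."""
    ref = make_reference(1, [700_000], seed, names=["chr1s"])
    dg = DerivativeGenome(ref)
    donor = ("chr1s", 100_000, 102_800, "+")
    tib = dg.add_ti_bridge("tumor-1", "chr1s", 300_000, 520_000, donor, sv_id="ti_bridge")
    del2 = dg.add_deletion("tumor-2", "chr1s", 103_439, 583_439, sv_id="del_arid1a")
    expected = {
        "insert_len": 2800,
        "donor": donor,
        "distance_donor_to_del2": 103_439 - 102_800,
        "n_svs": 2,
        "ti_sv": tib.id,
        "del_sv": del2.id,
    }
    return Scenario("fig4b", TruthSet(dg, purity, seed), expected, regions_pad=10_000)


def stat35_chain(seed: int = 0, purity: float = 0.58) -> Scenario:
    """Chain of templated insertion: chr9s -> [495 kb-class chr17s fragment]
    -> chr16s fusion (1:10 scale)."""
    ref = make_reference(3, [300_000, 300_000, 300_000], seed,
                         names=["chr9s", "chr17s", "chr16s"])
    dg = DerivativeGenome(ref)
    donor = ("chr17s", 200_000, 249_500, "+")
    tic = dg.add_ti_chain("tumor-1", "chr9s", 150_000, "chr16s", 150_000,
                          [donor], sv_id="ti_chain")
    expected = {"insert_len": 49_500, "donor": donor, "ti_sv": tic.id}
    return Scenario("fig4c", TruthSet(dg, purity, seed), expected, regions_pad=10_000)


def chromoplexy(seed: int = 0, purity: float = 0.58) -> Scenario:
    """Chromoplexy-like cluster: 15 intra- plus 11 inter-chromosomal
    junctions on a shattered chromosome (26 junctions in total)."""
    partners = ["chr1s", "chr3s", "chr9s", "chr17s"]
    ref = make_reference(5, [530_000] + [120_000] * 4, seed, names=["chr5s"] + partners)
    dg = DerivativeGenome(ref)
    rng = np.random.default_rng(seed + 1)
    cuts = np.sort(rng.choice(np.arange(20_000, 510_000, 1000), size=20, replace=False))
    bounds = [0] + [int(c) for c in cuts] + [530_000]
    pieces = [Piece("chr5s", s, e, "+", pristine=False)
              for s, e in zip(bounds, bounds[1:])]
    order = list(range(1, 21))  # keep piece 0 first so the walk starts at a telomere
    rng.shuffle(order)

    def _clean(seq: list[int]) -> bool:
        return seq[0] != 1 and all(b != a + 1 for a, b in zip(seq, seq[1:]))

    while not _clean(order):  # no reference-adjacent neighbors may survive
        rng.shuffle(order)
    walk = [pieces[0]]
    for j, k in enumerate(order):
        p = pieces[k]
        if j % 3 == 1:  # invert every third piece for strand-flip junctions
            p = Piece(p.contig, p.start, p.end, "-", pristine=False)
        walk.append(p)
    # insert 5 templated partner fragments into interior slots, one tail fusion
    slots = [3, 7, 11, 15, 19]
    for n, slot in enumerate(slots):
        ctg = partners[n % 4]
        s = 10_000 + 20_000 * n
        walk.insert(slot, Piece(ctg, s, s + 8_000, "+", pristine=False))
    walk.append(Piece(partners[0], 60_000, 120_000, "+", pristine=False))
    dg.set_complex_walks("tumor-1", [walk] + [
        [Piece(ctg, 0, dg.ref.lengths[ctg])] for ctg in partners], sv_id="chromoplexy")
    juncs = dg.junctions_of("tumor-1")
    inter = sum(1 for j in juncs if j.bnd1.contig != j.bnd2.contig)
    expected = {"n_junctions": len(juncs), "n_inter": inter, "n_intra": len(juncs) - inter}
    return Scenario("fig4d", TruthSet(dg, purity, seed), expected, regions_pad=5_000)


# ---------------------------------------------------------------------------
# Call-set census fixture
# ---------------------------------------------------------------------------

def census_callset(seed: int = 1, n_decoys: int = 40,
                   counts: dict[str, int] | None = None) -> list[SvCall]:
    """A constructed call set with the observed per-class somatic counts
    above the size threshold plus short germline decoy deletions.

    Intra-chromosomal somatic records carry SVLEN > 5000, translocations are
    inter-chromosomal BND pairs; decoys are 200-4000 bp deletions flagged as
    germline in provenance.
    """
    counts = counts or CENSUS_COUNTS
    rng = np.random.default_rng(seed)
    contigs = {f"chr{i + 1}": 60_000_000 for i in range(10)}
    names = list(contigs)
    calls: list[SvCall] = []
    cursor = {c: 100_000 for c in names}
    i = 0

    def place(ctg: str, span: int) -> int:
        pos = cursor[ctg]
        cursor[ctg] = pos + span + 20_000  # spacing defeats duplicate-merging
        return pos

    for svtype, cls in (("DEL", "DEL"), ("INV", "INV"), ("DUP", "DUP")):
        for _ in range(counts[cls]):
            ln = int(np.exp(rng.uniform(np.log(6_000), np.log(3_000_000))))
            ctg = names[i % len(names)]
            pos = place(ctg, ln)
            calls.append(SvCall(f"som{i}", svtype, Breakend(ctg, pos, "L"),
                                Breakend(ctg, pos + ln, "R"), ln, 10, 0.35,
                                provenance="somatic-truth"))
            i += 1
    for _ in range(counts["TRA"]):
        c1, c2 = names[i % len(names)], names[(i + 3) % len(names)]
        p1, p2 = place(c1, 0), place(c2, 0)
        calls.append(SvCall(f"som{i}", "BND", Breakend(c1, p1, "L"),
                            Breakend(c2, p2, "R"), None, 10, 0.35,
                            provenance="somatic-truth"))
        i += 1
    for k in range(n_decoys):
        ln = int(rng.integers(200, 4001))
        ctg = names[k % len(names)]
        pos = place(ctg, ln)
        calls.append(SvCall(f"germ{k}", "DEL", Breakend(ctg, pos, "L"),
                            Breakend(ctg, pos + ln, "R"), ln, 12, 0.5,
                            provenance="germline-truth"))
    return calls


# ---------------------------------------------------------------------------
# Full-scale recovery scenarios (literal SV dimensions, junction-local reads)
# ---------------------------------------------------------------------------

CDKN2A_DEL_LEN = 512_000
LARGE_INV_SPAN = 31_600_000
SMALL_INV_SPAN = 10_700_000
MIN_TI_INSERT = 219
MAX_TI_INSERT = 4036


def deletion_recovery(seed: int = 11, purity: float = 0.58) -> Scenario:
    """A 512 kb deletion on a 2 Mb random contig (tumor haplotype 1)."""
    ref = make_reference(1, [2_000_000], seed, names=["chr9"])
    dg = DerivativeGenome(ref)
    s = 744_000
    sv = dg.add_deletion("tumor-1", "chr9", s, s + CDKN2A_DEL_LEN, sv_id="del512k")
    return Scenario("deletion_recovery", TruthSet(dg, purity, seed),
                    {"svlen": CDKN2A_DEL_LEN, "sv": sv.id}, regions_pad=50_000)


def inversion_recovery(seed: int = 13, purity: float = 0.58) -> Scenario:
    """A 31.6 Mb-span unbalanced inversion on a sparse 36 Mb contig.

    Random sequence exists only within ±60 kb of the planned breakpoints;
    the rest is low-complexity filler, so reads are only simulated
    junction-locally.
    """
    a = 2_200_000
    c = a + LARGE_INV_SPAN          # 33_800_000
    b = 23_200_000                  # second junction: span d - b = 10.7 Mb
    d = b + SMALL_INV_SPAN          # 33_900_000
    windows = [(x - 60_000, x + 60_000) for x in (a, b, c, d)]
    ref = make_sparse_reference({"chr9": (36_000_000, windows)}, seed)
    dg = DerivativeGenome(ref)
    sv1, sv2 = dg.add_unbalanced_inversion_pair("tumor-1", "chr9", a, b, c, d,
                                                sv_ids=("inv_large", "inv_small"))
    return Scenario("inversion_recovery", TruthSet(dg, purity, seed),
                    {"spans": {sv1.id: LARGE_INV_SPAN, sv2.id: SMALL_INV_SPAN}},
                    regions_pad=50_000)


def minimal_insertion(seed: int = 17, insert_len: int = MIN_TI_INSERT) -> Scenario:
    """A chain-of-templated-insertion translocation carrying the smallest
    read-spanned insert length (219 bp by default)."""
    ref = make_reference(2, [500_000, 500_000], seed, names=["chrA", "chrB"])
    dg = DerivativeGenome(ref)
    donor = ("chrB", 400_000, 400_000 + insert_len, "+")
    sv = dg.add_ti_chain("tumor-1", "chrA", 250_000, "chrB", 250_000, [donor],
                         sv_id="ti_min")
    return Scenario("minimal_insertion", TruthSet(dg, 0.58, seed),
                    {"insert_len": insert_len, "donor": donor, "sv": sv.id},
                    regions_pad=10_000)


_BUILDERS = {
    "fig4a": cdkn2a_region,
    "fig4b": arid1a_region,
    "fig4c": stat35_chain,
    "fig4d": chromoplexy,
}


def make_fixtures(name: str, outdir: str, seed: int = 0) -> dict:
    """Write a named fixture's reference, truth tables and expected summary.

    Unknown names raise with the list of available fixtures.
    """
    import os

    from svlandscape.formats import write_fasta, write_sv_vcf
    from svlandscape.simulate import emit_callset

    if name not in FIXTURE_NAMES:
        raise ValueError(f"unknown fixture {name!r}; available: {', '.join(FIXTURE_NAMES)}")
    os.makedirs(outdir, exist_ok=True)
    if name == "census":
        calls = census_callset(seed)
        write_sv_vcf(calls, os.path.join(outdir, "census.vcf"))
        expected = {"kept_counts": CENSUS_COUNTS,
                    "kept_total": sum(CENSUS_COUNTS.values())}
        with open(os.path.join(outdir, "expected.json"), "w") as fh:
            json.dump(expected, fh, indent=1)
        return expected
    scen = _BUILDERS[name](seed)
    dg = scen.truth.genome
    write_fasta(dg.ref.contigs, os.path.join(outdir, "ref.fa"))
    write_sv_vcf(emit_callset(scen.truth), os.path.join(outdir, "truth_calls.vcf"),
                 dg.ref.lengths)
    with open(os.path.join(outdir, "truth_junctions.tsv"), "w") as fh:
        fh.write("haplotype\tcontig1\tpos1\tside1\tcontig2\tpos2\tside2\n")
        for hap in ("tumor-1", "tumor-2"):
            for j in dg.junctions_of(hap):
                fh.write(f"{hap}\t{j.bnd1.contig}\t{j.bnd1.pos}\t{j.bnd1.side}"
                         f"\t{j.bnd2.contig}\t{j.bnd2.pos}\t{j.bnd2.side}\n")
    with open(os.path.join(outdir, "expected.json"), "w") as fh:
        json.dump({k: v for k, v in scen.expected.items()
                   if isinstance(v, (int, float, str, list, dict, tuple))}, fh,
                  indent=1, default=str)
    return scen.expected
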