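"""Split-read SV calling on alignment segments and tumor-only somatic filtering.

The caller turns adjacent split-alignment segments of single reads into
candidate junctions, clusters compatible junctions, and emits calls with
median breakpoints and read-level support.  The somatic filter then applies
the tumor-only criteria: keep an SV only if it is an inter-chromosomal
translocation or longer than a size threshold (default 5 kb — a rule that
removes roughly three quarters of germline SVs), with additional support,
allele-frequency and blacklist gates.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from statistics import median_low

from svlandscape.formats import AlignmentSegment, Breakend, SvCall


@dataclass
class FilterConfig:
    """Tumor-only somatic filter parameters.

    ``min_len`` is a strict threshold: an SV is kept by the size rule only
    if its length exceeds it.  Translocations are exempt from the size rule
    when ``keep_bnd_any_length`` is set.
    """

    min_len: int = 5000
    keep_bnd_any_length: bool = True
    min_support: int = 3
    min_af: float = 0.05
    blacklist: list[tuple[str, int, int]] = field(default_factory=list)
    dedupe_window: int = 500

    def __post_init__(self) -> None:
        if self.min_len < 0:
            raise ValueError("min_len must be >= 0")
        if not 0.0 <= self.min_af <= 1.0:
            raise ValueError("min_af must lie in [0, 1]")


@dataclass
class _Junction:
    svclass: str
    contig1: str
    pos1: int
    side1: str
    contig2: str
    pos2: int
    side2: str
    read_id: str


def _read_junctions(segs: list[AlignmentSegment], min_gap: int,
                    min_seg: int) -> list[_Junction]:
    """Candidate junctions from the ordered split segments of one read."""
    segs = sorted(segs, key=lambda s: s.read_start)
    out: list[_Junction] = []
    for s1, s2 in zip(segs, segs[1:]):
        if s1.length < min_seg or s2.length < min_seg:
            continue
        rid = s1.read_id
        if s1.contig != s2.contig:
            b1 = (s1.contig, s1.ref_end, "L") if s1.strand == "+" else (s1.contig, s1.ref_start, "R")
            b2 = (s2.contig, s2.ref_start, "R") if s2.strand == "+" else (s2.contig, s2.ref_end, "L")
            # canonical order so reciprocal observations cluster together
            if (b1[0], b1[1]) > (b2[0], b2[1]):
                b1, b2 = b2, b1
            out.append(_Junction("BND", b1[0], b1[1], b1[2], b2[0], b2[1], b2[2], rid))
        elif s1.strand == s2.strand == "+":
            gap = s2.ref_start - s1.ref_end
            if gap >= min_gap:
                out.append(_Junction("DEL", s1.contig, s1.ref_end, "L",
                                     s2.contig, s2.ref_start, "R", rid))
            elif gap <= -min_gap:
                out.append(_Junction("DUP", s1.contig, s2.ref_start, "R",
                                     s2.contig, s1.ref_end, "L", rid))
        elif s1.strand == s2.strand == "-":
            gap = s1.ref_start - s2.ref_end
            if gap >= min_gap:
                out.append(_Junction("DEL", s1.contig, s2.ref_end, "L",
                                     s2.contig, s1.ref_start, "R", rid))
            elif gap <= -min_gap:
                out.append(_Junction("DUP", s1.contig, s1.ref_start, "R",
                                     s2.contig, s2.ref_end, "L", rid))
        else:  # strand flip: inversion-type junction
            if s1.strand == "+":
                pa, pb, side = s1.ref_end, s2.ref_end, "L"
            else:
                pa, pb, side = s1.ref_start, s2.ref_start, "R"
            lo, hi = min(pa, pb), max(pa, pb)
            if hi - lo >= min_gap:
                out.append(_Junction("INV", s1.contig, lo, side, s2.contig, hi, side, rid))
    return out


def _coverage_at(segments: list[AlignmentSegment], contig: str, pos: int) -> int:
    reads = {s.read_id for s in segments
             if s.contig == contig and s.ref_start <= pos < s.ref_end}
    return len(reads)


def call_svs_from_alignments(segments: list[AlignmentSegment],
                             cluster_window: int = 100,
                             min_support: int = 3,
                             min_gap: int = 50,
                             min_seg: int = 100) -> list[SvCall]:
    """Cluster per-read junctions into SV calls.

    Junctions of the same class within ``cluster_window`` bp at both ends
    (matching orientation) merge; clusters with at least ``min_support``
    distinct reads become calls with median breakpoint positions, RNAMES set
    to the contributing reads, and AF estimated against local coverage.
    """
    by_read: dict[str, list[AlignmentSegment]] = defaultdict(list)
    for seg in segments:
        by_read[seg.read_id].append(seg)
    junctions: list[_Junction] = []
    for segs in by_read.values():
        junctions.extend(_read_junctions(segs, min_gap, min_seg))

    grouped: dict[tuple, list[_Junction]] = defaultdict(list)
    for j in junctions:
        grouped[(j.svclass, j.contig1, j.contig2, j.side1, j.side2)].append(j)

    calls: list[SvCall] = []
    idx = 0
    for key in sorted(grouped):
        js = sorted(grouped[key], key=lambda j: (j.pos1, j.pos2))
        cluster: list[_Junction] = []

        def flush(cluster: list[_Junction]) -> None:
            nonlocal idx
            reads = sorted({j.read_id for j in cluster})
            if len(reads) < min_support:
                return
            p1 = median_low([j.pos1 for j in cluster])
            p2 = median_low([j.pos2 for j in cluster])
            j0 = cluster[0]
            svlen = abs(p2 - p1) if j0.svclass != "BND" else None
            cov = _coverage_at(segments, j0.contig1, max(0, p1 - 1))
            af = len(reads) / cov if cov else 0.0
            calls.append(SvCall(f"sv{idx}", j0.svclass,
                                Breakend(j0.contig1, p1, j0.side1),
                                Breakend(j0.contig2, p2, j0.side2),
                                svlen, len(reads), af, tuple(reads)))
            idx += 1

        for j in js:
            if cluster and (abs(j.pos1 - cluster[0].pos1) > cluster_window
                            or abs(j.pos2 - cluster[0].pos2) > cluster_window):
                flush(cluster)
                cluster = []
            cluster.append(j)
        if cluster:
            flush(cluster)
    calls.sort(key=lambda c: (c.bp1.contig, c.bp1.pos, c.bp2.contig, c.bp2.pos))
    for i, c in enumerate(calls):
        c.id = f"sv{i}"
    return calls


def dedupe_calls(calls: list[SvCall], window: int = 500) -> tuple[list[SvCall], list[SvCall]]:
    """Merge same-class calls with both breakends within ``window`` bp,
    keeping the higher-support record.  Returns (kept, merged_away)."""
    kept: list[SvCall] = []
    removed: list[SvCall] = []
    for call in calls:
        dup = None
        for other in kept:
            if (other.svtype == call.svtype
                    and other.bp1.contig == call.bp1.contig
                    and other.bp2.contig == call.bp2.contig
                    and abs(other.bp1.pos - call.bp1.pos) <= window
                    and abs(other.bp2.pos - call.bp2.pos) <= window):
                dup = other
                break
        if dup is None:
            kept.append(call)
        elif call.support > dup.support:
            kept[kept.index(dup)] = call
            removed.append(dup)
        else:
            removed.append(call)
    return kept, removed


def _in_blacklist(call: SvCall, blacklist: list[tuple[str, int, int]]) -> bool:
    for bp in (call.bp1, call.bp2):
        for ctg, s, e in blacklist:
            if bp.contig == ctg and s <= bp.pos < e:
                return True
    return False


def filter_svs(calls: list[SvCall], cfg: FilterConfig | None = None
               ) -> tuple[list[SvCall], list[tuple[SvCall, str]]]:
    """Apply the tumor-only somatic filter.

    Kept iff (inter-chromosomal translocation) or (svlen strictly greater
    than ``min_len``), AND support and AF gates pass AND neither breakend
    falls in the blacklist.  Every removal carries a machine-readable
    reason; input order is preserved and kept/removed partition the input.
    """
    cfg = cfg or FilterConfig()
    deduped, merged_away = dedupe_calls(calls, cfg.dedupe_window)
    kept: list[SvCall] = []
    removed: list[tuple[SvCall, str]] = [(c, "duplicate") for c in merged_away]
    for call in deduped:
        size_ok = (call.svtype == "BND" and cfg.keep_bnd_any_length) or \
                  (call.svlen is not None and call.svlen > cfg.min_len)
        if not size_ok:
            removed.append((call, "min_len"))
        elif call.support < cfg.min_support:
            removed.append((call, "min_support"))
        elif call.af < cfg.min_af:
            removed.append((call, "min_af"))
        elif cfg.blacklist and _in_blacklist(call, cfg.blacklist):
            removed.append((call, "blacklist"))
        else:
            kept.append(call)
    return kept, removed


_CENSUS_CLASS = {"DEL": "DEL", "INV": "INV", "DUP": "DUP", "BND": "TRA", "INS": "INS"}


def class_census(kept: list[SvCall]) -> dict[str, int]:
    """Per-class SV counts plus ``total``; reciprocal BND pairs count once
    (they are already materialized as single logical calls)."""
    census = {"DEL": 0, "INV": 0, "DUP": 0, "TRA": 0, "INS": 0}
    for call in kept:
        census[_CENSUS_CLASS.get(call.svtype, call.svtype)] += 1
    census["total"] = sum(census.values())
    return census
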