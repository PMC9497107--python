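"""Supporting-read consensus and templated-insertion detection.

For each SV the supporting reads are collapsed into a consensus (star
alignment against the longest read, per-column majority vote), the consensus
is mapped back to the reference with an exact-seed / diagonal-chaining
mapper, and SVs whose consensus maps to more than two reference regions are
flagged as templated insertions; the non-terminal regions are the inserted
donor segments.
"""

from __future__ import annotations

import logging
import re
from collections import Counter, defaultdict
from dataclasses import dataclass, field

import edlib

from svlandscape.formats import AlignmentSegment, revcomp
from svlandscape.simulate import GenomeRef

log = logging.getLogger(__name__)

_CIGAR_RE = re.compile(r"(\d+)([=XIDM])")


@dataclass
class Consensus:
    """Majority-vote consensus over one SV's supporting reads."""

    sv_id: str
    sequence: str
    n_reads: int
    agreement: float  # mean winning-vote share over consensus columns

    def __post_init__(self) -> None:
        if self.n_reads < 1:
            raise ValueError("consensus requires >= 1 read")
        if not 0.0 <= self.agreement <= 1.0:
            raise ValueError("agreement must lie in [0, 1]")


@dataclass
class ConsensusMapping:
    """Reference mapping of a consensus, merged into distinct regions."""

    sv_id: str
    segments: list[AlignmentSegment] = field(default_factory=list)  # ordered by consensus coord
    region_count: int = 0
    inserted: list[tuple[str, int, int, str, int]] = field(default_factory=list)
    # inserted: (donor contig, donor start, donor end, strand, length bp)


def _vote_chunk(chunk: str, backbone: str, votes: list[Counter],
                insertions: list[Counter], max_dist_frac: float = 0.30) -> None:
    """Align one read chunk inside the backbone and add its column votes.

    Chunks that do not really lie inside the backbone (overhangs past the
    backbone ends, or off-target placements) show an edit distance far above
    the error budget and are discarded — an infix aligner would otherwise
    force them somewhere and corrupt the vote."""
    aln = edlib.align(chunk, backbone, task="path", mode="HW")
    if aln["editDistance"] > max_dist_frac * len(chunk):
        return
    t = aln["locations"][0][0]
    q = 0
    pending_ins = ""
    for m in _CIGAR_RE.finditer(aln["cigar"]):
        ln, op = int(m.group(1)), m.group(2)
        if op in ("=", "X", "M"):
            if pending_ins:
                insertions[t][pending_ins] += 1
                pending_ins = ""
            for _ in range(ln):
                votes[t][chunk[q]] += 1
                t += 1
                q += 1
        elif op == "D":  # gap in chunk: vote for deletion of backbone base
            if pending_ins:
                insertions[t][pending_ins] += 1
                pending_ins = ""
            for _ in range(ln):
                votes[t]["-"] += 1
                t += 1
        elif op == "I":  # extra chunk bases between backbone columns
            pending_ins += chunk[q:q + ln]
            q += ln
    if pending_ins:
        insertions[t][pending_ins] += 1


def build_consensus(reads: list[str], sv_id: str = "sv",
                    chunk: int = 600) -> Consensus:
    """Star alignment of reads against the longest read, majority vote.

    Each read is aligned to the backbone (the longest read) in ``chunk``-bp
    pieces; per backbone column the plurality base (or gap) wins, and
    insertions relative to the backbone are emitted where at least half of
    the reads carry one.  Deterministic for a fixed input order.
    """
    if not reads:
        raise ValueError("cannot build a consensus from an empty read set")
    if len(reads) == 1:
        return Consensus(sv_id, reads[0], 1, 1.0)
    backbone = max(reads, key=len)
    n = len(backbone)
    votes: list[Counter] = [Counter() for _ in range(n)]
    insertions: list[Counter] = [Counter() for _ in range(n + 1)]
    seen_backbone = False
    for read in reads:
        if read == backbone and not seen_backbone:
            seen_backbone = True
            for i, b in enumerate(read):
                votes[i][b] += 1
            continue
        for s in range(0, len(read), chunk):
            piece = read[s:s + chunk]
            if len(piece) >= 50:
                _vote_chunk(piece, backbone, votes, insertions)
    half = len(reads) / 2.0
    out: list[str] = []
    shares: list[float] = []
    for i in range(n + 1):
        ins = insertions[i]
        if ins and sum(ins.values()) >= half:
            out.append(ins.most_common(1)[0][0])
        if i == n:
            break
        col = votes[i]
        if not col:
            out.append(backbone[i])
            continue
        base, cnt = col.most_common(1)[0]
        shares.append(cnt / sum(col.values()))
        if base != "-":
            out.append(base)
    agreement = float(sum(shares) / len(shares)) if shares else 1.0
    return Consensus(sv_id, "".join(out), len(reads), agreement)


# ---------------------------------------------------------------------------
# Exact-seed reference mapper
# ---------------------------------------------------------------------------

class KmerIndex:
    """Exact k-mer index over a reference (both strands queried at look-up)."""

    def __init__(self, ref: GenomeRef, k: int = 21):
        if k < 11:
            raise ValueError("seed length k must be >= 11")
        self.k = k
        self.index: dict[str, list[tuple[str, int]]] = defaultdict(list)
        for name, seq in ref.contigs.items():
            for i in range(len(seq) - k + 1):
                self.index[seq[i:i + k]].append((name, i))

    def lookup(self, kmer: str) -> list[tuple[str, int]]:
        return self.index.get(kmer, [])


def map_consensus(cons: Consensus, ref: GenomeRef, k: int = 21,
                  min_segment: int = 150, merge_dist: int = 1000,
                  index: KmerIndex | None = None,
                  max_hits: int = 50) -> ConsensusMapping:
    """Map a consensus to the reference by exact k-mer seeding.

    Seeds are chained by diagonal consistency per (contig, strand), chains
    shorter than ``min_segment`` are dropped, and chains that are adjacent
    both on the consensus and on the reference (within ``merge_dist``) merge
    into one region.  Inserted segments are the non-terminal regions.
    """
    idx = index if index is not None and index.k == k else KmerIndex(ref, k)
    seq = cons.sequence
    # hits: (cons_pos, contig, strand, diagonal, ref_pos)
    hits: list[tuple[int, str, str, int, int]] = []
    for i in range(0, len(seq) - k + 1):
        kmer = seq[i:i + k]
        fwd = idx.lookup(kmer)
        if len(fwd) <= max_hits:
            for ctg, pos in fwd:
                hits.append((i, ctg, "+", pos - i, pos))
        rev = idx.lookup(revcomp(kmer))
        if len(rev) <= max_hits:
            for ctg, pos in rev:
                hits.append((i, ctg, "-", pos + i, pos))
    if not hits:
        log.warning("consensus %s is unmappable (no exact %d-mer seeds)", cons.sv_id, k)
        return ConsensusMapping(cons.sv_id, [], 0, [])

    band = 30  # diagonal wobble tolerated within one chain (indel budget)
    chains: dict[tuple[str, str, int], list[tuple[int, int]]] = defaultdict(list)
    for i, ctg, strand, diag, pos in sorted(hits):
        key = None
        for (c, s, d) in list(chains):
            if c == ctg and s == strand and abs(d - diag) <= band:
                key = (c, s, d)
                break
        if key is None:
            key = (ctg, strand, diag)
        chains[key].append((i, pos))

    segments: list[AlignmentSegment] = []
    for (ctg, strand, _diag), pairs in chains.items():
        pairs.sort()
        # split a chain where consecutive seeds are far apart on the consensus
        runs: list[list[tuple[int, int]]] = [[pairs[0]]]
        for prev, cur in zip(pairs, pairs[1:]):
            if cur[0] - prev[0] > merge_dist:
                runs.append([])
            runs[-1].append(cur)
        for run in runs:
            c0, c1 = run[0][0], run[-1][0] + k
            if c1 - c0 < min_segment:
                continue
            if strand == "+":
                r0, r1 = run[0][1], run[-1][1] + k
            else:
                r0, r1 = run[-1][1], run[0][1] + k
            segments.append(AlignmentSegment(cons.sv_id, ctg, r0, r1, c0, c1, strand))

    segments.sort(key=lambda s: (s.read_start, -(s.read_end - s.read_start)))
    # drop segments fully shadowed by a longer one on the consensus axis
    pruned: list[AlignmentSegment] = []
    for seg in segments:
        if any(o.read_start <= seg.read_start and seg.read_end <= o.read_end
               and o is not seg for o in pruned):
            continue
        pruned.append(seg)

    merged: list[AlignmentSegment] = []
    for seg in pruned:
        if merged:
            last = merged[-1]
            ref_adjacent = (
                last.contig == seg.contig and last.strand == seg.strand
                and ((seg.strand == "+" and abs(seg.ref_start - last.ref_end) <= merge_dist)
                     or (seg.strand == "-" and abs(last.ref_start - seg.ref_end) <= merge_dist)))
            cons_adjacent = seg.read_start - last.read_end <= merge_dist
            if ref_adjacent and cons_adjacent:
                merged[-1] = AlignmentSegment(
                    last.read_id, last.contig,
                    min(last.ref_start, seg.ref_start), max(last.ref_end, seg.ref_end),
                    last.read_start, seg.read_end, last.strand)
                continue
        merged.append(seg)

    inserted = [(s.contig, s.ref_start, s.ref_end, s.strand, s.ref_end - s.ref_start)
                for s in merged[1:-1]]
    return ConsensusMapping(cons.sv_id, merged, len(merged), inserted)


def flag_templated_insertion(mapping: ConsensusMapping) -> tuple[str, list[tuple[str, int, int, str, int]]]:
    """Classify a consensus mapping.

    Returns ``("templated_insertion", insertions)`` when the consensus maps
    to more than two reference regions (the non-terminal regions are the
    inserted donor segments), ``("simple", [])`` for one or two regions, and
    ``("unclassifiable", [])`` when the consensus could not be mapped.
    """
    if mapping.region_count == 0:
        return "unclassifiable", []
    if mapping.region_count > 2:
        return "templated_insertion", list(mapping.inserted)
    return "simple", []
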