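"""Shared genomic primitives and I/O for the external file formats.

Internally every coordinate is 0-based, half-open.  Conversions happen only
at the I/O boundary: VCF positions are 1-based, BED and the SEG-like tables
are 0-based half-open.

The VCF dialect is the Sniffles2-style one: symbolic ALTs for
intra-chromosomal SVs with ``SVTYPE``/``SVLEN``/``END`` INFO keys, paired
``BND`` records with bracket ALTs and ``MATEID``/``CHR2`` for
translocations, ``SUPPORT``/``RNAMES``/``AF`` for read-level evidence.
Unknown INFO keys are carried through verbatim.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from cyvcf2 import VCF

log = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string."""
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Breakend:
    """One side of an SV junction.

    ``side`` records which flank of ``pos`` is retained into the junction:
    ``"L"`` means the sequence left of ``pos`` continues into the junction,
    ``"R"`` means the sequence starting at ``pos`` does.
    """

    contig: str
    pos: int  # 0-based
    side: str = "L"  # "L" | "R"

    def __post_init__(self) -> None:
        if self.side not in ("L", "R"):
            raise ValueError(f"breakend side must be L or R, got {self.side!r}")
        if self.pos < 0:
            raise ValueError(f"negative breakend position {self.pos}")


@dataclass
class SvCall:
    """One structural-variant call (two breakends plus evidence).

    ``svlen`` is stored as a magnitude; the conventional sign (negative for
    deletions) is applied only when writing VCF.  Inter-chromosomal calls are
    a single logical record materialized from a reciprocal BND pair.
    """

    id: str
    svtype: str  # DEL | INS | DUP | INV | BND
    bp1: Breakend
    bp2: Breakend
    svlen: int | None = None
    support: int = 0
    af: float = 0.0
    read_names: tuple[str, ...] = ()
    precise: bool = True
    provenance: str = "unknown"  # somatic-truth | germline-truth | fp | unknown
    info: dict = field(default_factory=dict)  # unknown INFO keys, verbatim

    def __post_init__(self) -> None:
        if self.svtype in ("DEL", "DUP", "INV"):
            if self.bp1.contig != self.bp2.contig:
                raise ValueError(f"{self.id}: {self.svtype} breakends on different contigs")
            if self.bp1.pos > self.bp2.pos:
                self.bp1, self.bp2 = self.bp2, self.bp1
        if self.read_names:
            self.read_names = tuple(sorted(set(self.read_names)))
            if not self.support:
                self.support = len(self.read_names)

    @property
    def is_translocation(self) -> bool:
        return self.svtype == "BND" and self.bp1.contig != self.bp2.contig


@dataclass
class AlignmentSegment:
    """One aligned block of a read (or consensus) on the reference."""

    read_id: str
    contig: str
    ref_start: int
    ref_end: int
    read_start: int
    read_end: int
    strand: str = "+"
    haplotype_tag: str | None = None

    def __post_init__(self) -> None:
        if self.ref_start >= self.ref_end:
            raise ValueError(f"{self.read_id}: empty reference span")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be + or -, got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.ref_end - self.ref_start


@dataclass
class CnvSegment:
    """A segmented copy-number interval with linear copy ratio ``r``."""

    contig: str
    start: int
    end: int
    r: float
    q: int | None = None
    n_probes: int = 0
    zygosity: str | None = None

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError("segment start must be < end")
        if self.r < 0:
            raise ValueError("copy ratio must be >= 0")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class ProbeRatio:
    """One per-probe linear copy-ratio observation."""

    contig: str
    start: int
    end: int
    r: float


# ---------------------------------------------------------------------------
# VCF (Sniffles2 dialect)
# ---------------------------------------------------------------------------

_KNOWN_INFO = (
    "SVTYPE", "SVLEN", "END", "CHR2", "SUPPORT", "RNAMES", "AF",
    "PRECISE", "IMPRECISE", "MATEID", "PROVENANCE",
)

_VCF_HEADER_LINES = [
    '##INFO=<ID=SVTYPE,Number=1,Type=String,Description="Type of structural variant">',
    '##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="Length of structural variant">',
    '##INFO=<ID=END,Number=1,Type=Integer,Description="End position of structural variant">',
    '##INFO=<ID=CHR2,Number=1,Type=String,Description="Mate contig of a BND">',
    '##INFO=<ID=SUPPORT,Number=1,Type=Integer,Description="Number of supporting reads">',
    '##INFO=<ID=RNAMES,Number=.,Type=String,Description="Names of supporting reads">',
    '##INFO=<ID=AF,Number=A,Type=Float,Description="Allele frequency">',
    '##INFO=<ID=PRECISE,Number=0,Type=Flag,Description="Precise breakpoints">',
    '##INFO=<ID=IMPRECISE,Number=0,Type=Flag,Description="Imprecise breakpoints">',
    '##INFO=<ID=MATEID,Number=1,Type=String,Description="ID of mate breakend">',
    '##INFO=<ID=PROVENANCE,Number=1,Type=String,Description="Synthetic-truth provenance tag">',
    '##ALT=<ID=DEL,Description="Deletion">',
    '##ALT=<ID=DUP,Description="Duplication">',
    '##ALT=<ID=INV,Description="Inversion">',
    '##ALT=<ID=INS,Description="Insertion">',
]


def _fmt_float(x: float) -> str:
    return f"{x:.6g}"


def _bnd_alt(mate: Breakend) -> str:
    """Bracketed mate descriptor for the ALT column of a BND record."""
    p = mate.pos + 1
    if mate.side == "R":
        return f"[{mate.contig}:{p}["
    return f"]{mate.contig}:{p}]"


def _info_str(call: SvCall, bnd_leg: int | None = None, mate_id: str | None = None) -> str:
    parts = ["PRECISE" if call.precise else "IMPRECISE"]
    parts.append(f"SVTYPE={call.svtype}")
    if call.svtype != "BND":
        svlen = call.svlen if call.svlen is not None else 0
        if call.svtype == "DEL":
            svlen = -abs(svlen)
        parts.append(f"SVLEN={svlen}")
        parts.append(f"END={call.bp2.pos}")
    else:
        other = call.bp2 if bnd_leg == 1 else call.bp1
        parts.append(f"CHR2={other.contig}")
        if mate_id:
            parts.append(f"MATEID={mate_id}")
    parts.append(f"SUPPORT={call.support}")
    parts.append(f"AF={_fmt_float(call.af)}")
    if call.read_names:
        parts.append("RNAMES=" + ",".join(call.read_names))
    if call.provenance != "unknown":
        parts.append(f"PROVENANCE={call.provenance}")
    for k, v in call.info.items():
        parts.append(k if v is True else f"{k}={v}")
    return ";".join(parts)


def write_sv_vcf(calls: list[SvCall], path: str, contig_lengths: dict[str, int] | None = None) -> None:
    """Write calls as a Sniffles2-dialect VCF 4.2 text file.

    The writer is canonical and deterministic: reading a file written here
    and writing it again reproduces the bytes exactly.
    """
    extra_keys: list[str] = []
    for c in calls:
        for k in c.info:
            if k not in extra_keys:
                extra_keys.append(k)
    contigs: list[str] = []
    if contig_lengths:
        contigs = list(contig_lengths)
    else:
        for c in calls:
            for ctg in (c.bp1.contig, c.bp2.contig):
                if ctg not in contigs:
                    contigs.append(ctg)
        contigs.sort()
    lines = ["##fileformat=VCFv4.2", "##source=svlandscape"]
    lines += _VCF_HEADER_LINES
    for k in extra_keys:
        lines.append(f'##INFO=<ID={k},Number=.,Type=String,Description="Carried through">')
    for ctg in contigs:
        if contig_lengths:
            lines.append(f"##contig=<ID={ctg},length={contig_lengths[ctg]}>")
        else:
            lines.append(f"##contig=<ID={ctg}>")
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO")
    for call in calls:
        if call.svtype == "BND":
            a1 = _bnd_alt(call.bp2) if call.bp1.side == "R" else _bnd_alt(call.bp2)
            alt1 = ("N" + a1) if call.bp1.side == "L" else (a1 + "N")
            a2 = _bnd_alt(call.bp1)
            alt2 = ("N" + a2) if call.bp2.side == "L" else (a2 + "N")
            id1, id2 = f"{call.id}_1", f"{call.id}_2"
            lines.append("\t".join([
                call.bp1.contig, str(call.bp1.pos + 1), id1, "N", alt1, ".", "PASS",
                _info_str(call, bnd_leg=1, mate_id=id2)]))
            lines.append("\t".join([
                call.bp2.contig, str(call.bp2.pos + 1), id2, "N", alt2, ".", "PASS",
                _info_str(call, bnd_leg=2, mate_id=id1)]))
        else:
            lines.append("\t".join([
                call.bp1.contig, str(call.bp1.pos + 1), call.id, "N",
                f"<{call.svtype}>", ".", "PASS", _info_str(call)]))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def _parse_bnd_alt(alt: str) -> tuple[str, str, int, str]:
    """Return (this_side, mate_contig, mate_pos0, mate_side) from a bracket ALT."""
    this_side = "L" if (alt[0] not in "[]") else "R"
    br = "[" if "[" in alt else "]"
    inner = alt.split(br)[1]
    contig, pos = inner.rsplit(":", 1)
    mate_side = "R" if br == "[" else "L"
    return this_side, contig, int(pos) - 1, mate_side


def read_sv_vcf(path: str) -> list[SvCall]:
    """Read a Sniffles2-dialect SV VCF into logical :class:`SvCall` records.

    Reciprocal BND pairs (linked by ``MATEID``) are materialized as one
    logical call.  Records missing ``SVTYPE`` raise with their position;
    malformed ``RNAMES`` produce a warning and an empty read set.
    """
    calls: list[SvCall] = []
    expected_mates: set[str] = set()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        vcf = VCF(path)
        for i, v in enumerate(vcf):
            info = dict(v.INFO)
            svtype = info.pop("SVTYPE", None)
            if svtype is None:
                raise ValueError(f"{path}: record {i + 1} ({v.CHROM}:{v.POS}) lacks SVTYPE")
            precise = bool(info.pop("PRECISE", False)) or not info.pop("IMPRECISE", False)
            support = int(info.pop("SUPPORT", 0) or 0)
            af = float(info.pop("AF", 0.0) or 0.0)
            rnames_raw = info.pop("RNAMES", None)
            read_names: tuple[str, ...] = ()
            if rnames_raw is not None:
                try:
                    if isinstance(rnames_raw, (tuple, list)):
                        rnames_raw = ",".join(rnames_raw)
                    read_names = tuple(sorted(set(str(rnames_raw).split(","))))
                except Exception:  # malformed: keep going with empty set
                    log.warning("%s: record %s has malformed RNAMES; dropped", path, v.ID)
                    read_names = ()
            provenance = str(info.pop("PROVENANCE", "unknown"))
            if svtype == "BND":
                mate_id = info.pop("MATEID", None)
                info.pop("CHR2", None)
                rec_id = str(v.ID) if v.ID else f"bnd{i}"
                if rec_id in expected_mates:
                    continue  # second leg of an already-materialized pair
                this_side, m_ctg, m_pos, m_side = _parse_bnd_alt(v.ALT[0])
                bp1 = Breakend(v.CHROM, v.POS - 1, this_side)
                bp2 = Breakend(m_ctg, m_pos, m_side)
                base = rec_id[:-2] if rec_id.endswith(("_1", "_2")) else rec_id
                calls.append(SvCall(base, "BND", bp1, bp2, None, support, af,
                                    read_names, precise, provenance, dict(info)))
                if mate_id is not None:
                    expected_mates.add(str(mate_id))
            else:
                end = int(info.pop("END", v.POS))
                svlen = info.pop("SVLEN", None)
                svlen = abs(int(svlen)) if svlen is not None else None
                bp1 = Breakend(v.CHROM, v.POS - 1, "L")
                bp2 = Breakend(v.CHROM, end, "R")
                calls.append(SvCall(str(v.ID) if v.ID else f"sv{i}", svtype, bp1, bp2,
                                    svlen, support, af, read_names, precise,
                                    provenance, dict(info)))
    return calls


# ---------------------------------------------------------------------------
# BED / intervals
# ---------------------------------------------------------------------------

def merge_intervals(intervals: list[tuple[str, int, int]]) -> list[tuple[str, int, int]]:
    """Sort and union possibly-overlapping half-open intervals."""
    out: list[tuple[str, int, int]] = []
    for ctg, s, e in sorted(intervals):
        if out and out[-1][0] == ctg and s <= out[-1][2]:
            out[-1] = (ctg, out[-1][1], max(out[-1][2], e))
        else:
            out.append((ctg, s, e))
    return out


def make_target_bed(calls: list[SvCall], padding: int,
                    extra_regions: list[tuple[str, int, int]] | None = None,
                    contig_lengths: dict[str, int] | None = None) -> list[tuple[str, int, int]]:
    """Target intervals for adaptive-sampling style re-sequencing.

    One interval of ``2 * padding`` per breakend, clipped to contig bounds,
    unioned with ``extra_regions``, merged and sorted.
    """
    if padding < 0:
        raise ValueError("padding must be >= 0")
    raw: list[tuple[str, int, int]] = list(extra_regions or [])
    for call in calls:
        for bp in (call.bp1, call.bp2):
            s = max(0, bp.pos - padding)
            e = bp.pos + padding
            if contig_lengths and bp.contig in contig_lengths:
                e = min(e, contig_lengths[bp.contig])
            if e > s:
                raw.append((bp.contig, s, e))
    return merge_intervals(raw)


def write_bed(intervals: list[tuple[str, int, int]], path: str) -> None:
    with open(path, "w") as fh:
        for ctg, s, e in intervals:
            fh.write(f"{ctg}\t{s}\t{e}\n")


def read_bed(path: str) -> list[tuple[str, int, int]]:
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            f = line.split("\t")
            out.append((f[0], int(f[1]), int(f[2])))
    return out


# ---------------------------------------------------------------------------
# Coverage binning
# ---------------------------------------------------------------------------

def coverage_bins(segments: list[AlignmentSegment], bin_size: int,
                  contig_lengths: dict[str, int] | None = None) -> dict[str, np.ndarray]:
    """Aligned-base counts in fixed genomic bins (base-conserving).

    A segment straddling a bin boundary contributes its bases to each bin
    exactly; the grand total equals the total aligned bases.
    """
    if bin_size <= 0:
        raise ValueError("bin size must be > 0")
    maxima: dict[str, int] = dict(contig_lengths or {})
    for seg in segments:
        maxima[seg.contig] = max(maxima.get(seg.contig, 0), seg.ref_end)
    bins = {ctg: np.zeros(int(np.ceil(end / bin_size)) or 1, dtype=np.int64)
            for ctg, end in maxima.items()}
    for seg in segments:
        arr = bins[seg.contig]
        b0 = seg.ref_start // bin_size
        b1 = (seg.ref_end - 1) // bin_size
        for b in range(b0, b1 + 1):
            lo = max(seg.ref_start, b * bin_size)
            hi = min(seg.ref_end, (b + 1) * bin_size)
            arr[b] += hi - lo
    return bins


# ---------------------------------------------------------------------------
# SEG-like copy-number tables and probe ratios
# ---------------------------------------------------------------------------

_SEG_COLS = ["sample", "contig", "start", "end", "n_probes", "ratio"]


def write_seg(segments: list[CnvSegment], path: str, sample: str = "sample") -> None:
    rows = [(sample, s.contig, s.start, s.end, s.n_probes, s.r) for s in segments]
    pd.DataFrame(rows, columns=_SEG_COLS).to_csv(path, sep="\t", index=False)


def read_seg(path: str, log2: bool = False) -> list[CnvSegment]:
    """Read a SEG-like TSV; ``log2=True`` converts log2 ratios to linear."""
    df = pd.read_csv(path, sep="\t")
    df.columns = [c.lower() for c in df.columns]
    out = []
    for row in df.itertuples(index=False):
        r = float(row.ratio)
        if log2:
            r = 2.0 ** r
        out.append(CnvSegment(str(row.contig), int(row.start), int(row.end), r,
                              n_probes=int(getattr(row, "n_probes", 0) or 0)))
    return out


def write_probes(probes: list[ProbeRatio], path: str) -> None:
    pd.DataFrame([(p.contig, p.start, p.end, p.r) for p in probes],
                 columns=["contig", "start", "end", "ratio"]).to_csv(path, sep="\t", index=False)


def read_probes(path: str) -> list[ProbeRatio]:
    df = pd.read_csv(path, sep="\t")
    return [ProbeRatio(str(r.contig), int(r.start), int(r.end), float(r.ratio))
            for r in df.itertuples(index=False)]


# ---------------------------------------------------------------------------
# FASTA / FASTQ / split-alignment TSV
# ---------------------------------------------------------------------------

def write_fasta(seqs: dict[str, str], path: str, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def read_fasta(path: str) -> dict[str, str]:
    from Bio import SeqIO
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(path, "fasta")}


def write_fastq(reads, path: str) -> None:
    """Write objects with ``.id`` and ``.sequence`` as FASTQ (flat quality)."""
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.id}\n{r.sequence}\n+\n{'I' * len(r.sequence)}\n")


def read_fastq(path: str) -> dict[str, str]:
    from Bio import SeqIO
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(path, "fastq")}


_ALN_COLS = ["read_id", "contig", "ref_start", "ref_end",
             "read_start", "read_end", "strand", "haplotype_tag"]


def write_alignments(segments: list[AlignmentSegment], path: str) -> None:
    rows = [(s.read_id, s.contig, s.ref_start, s.ref_end, s.read_start,
             s.read_end, s.strand, s.haplotype_tag or ".") for s in segments]
    pd.DataFrame(rows, columns=_ALN_COLS).to_csv(path, sep="\t", index=False)


def read_alignments(path: str) -> list[AlignmentSegment]:
    df = pd.read_csv(path, sep="\t", dtype={"haplotype_tag": str})
    out = []
    for r in df.itertuples(index=False):
        tag = None if r.haplotype_tag in (".", None) or pd.isna(r.haplotype_tag) else str(r.haplotype_tag)
        out.append(AlignmentSegment(str(r.read_id), str(r.contig), int(r.ref_start),
                                    int(r.ref_end), int(r.read_start), int(r.read_end),
                                    str(r.strand), tag))
    return out


# ---------------------------------------------------------------------------
# Plot-ready exports (Circos-style arcs / rings as plain TSV)
# ---------------------------------------------------------------------------

def export_junction_table(calls: list[SvCall], path: str | None = None) -> pd.DataFrame:
    """Per-junction arc table (contig1, pos1, contig2, pos2, class)."""
    cls = {"BND": "TRA"}
    df = pd.DataFrame(
        [(c.bp1.contig, c.bp1.pos, c.bp2.contig, c.bp2.pos, cls.get(c.svtype, c.svtype))
         for c in calls],
        columns=["contig1", "pos1", "contig2", "pos2", "class"])
    if path:
        df.to_csv(path, sep="\t", index=False)
    return df


def export_cnv_ring(segments: list[CnvSegment], path: str | None = None) -> pd.DataFrame:
    df = pd.DataFrame([(s.contig, s.start, s.end, s.r, s.q if s.q is not None else "")
                       for s in segments],
                      columns=["contig", "start", "end", "ratio", "q"])
    if path:
        df.to_csv(path, sep="\t", index=False)
    return df
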