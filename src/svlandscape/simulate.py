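"""Synthetic genomes, implanted SVs, long reads, and truth-projected evidence.

The generator emulates the study conditions of a low-purity lymphoma sample
sequenced with short-ish long reads: a diploid reference, somatic SVs of the
observed archetypes implanted on tumor haplotypes, germline decoys, reads of
mean length ~2.1 kb with indel/substitution errors, tumor-purity mixing, and
noisy per-probe copy ratios.

A derivative haplotype is represented as a *walk*: an ordered list of
oriented reference pieces.  Junctions, derivative sequences, coordinate
projection and copy-number truth are all derived from walks, so every
downstream stage can be verified against construction.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from svlandscape.formats import (
    AlignmentSegment,
    Breakend,
    CnvSegment,
    ProbeRatio,
    SvCall,
    revcomp,
)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

TUMOR_HAPS = ("tumor-1", "tumor-2")
NORMAL_HAPS = ("normal-1", "normal-2")
ALL_HAPS = TUMOR_HAPS + NORMAL_HAPS


# ---------------------------------------------------------------------------
# Reference
# ---------------------------------------------------------------------------

class GenomeRef:
    """An ordered set of named contigs over the ACGT alphabet."""

    def __init__(self, contigs: dict[str, str]):
        if len(set(contigs)) != len(contigs):
            raise ValueError("contig names must be unique")
        for name, seq in contigs.items():
            if len(seq) < 1000:
                raise ValueError(f"contig {name} shorter than 1 kb")
        self.contigs = dict(contigs)

    @property
    def lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.contigs.items()}

    def seq(self, contig: str, start: int = 0, end: int | None = None) -> str:
        return self.contigs[contig][start:end]

    def __contains__(self, name: str) -> bool:
        return name in self.contigs


def _random_seq(n: int, rng: np.random.Generator) -> str:
    return rng.choice(_BASES, size=n).tobytes().decode()


def make_reference(n_contigs: int, lengths: list[int], seed: int,
                   names: list[str] | None = None) -> GenomeRef:
    """I.i.d. uniform-ACGT reference; byte-identical for identical seed."""
    if n_contigs != len(lengths):
        raise ValueError("n_contigs must match the number of lengths")
    if any(l < 1000 for l in lengths):
        raise ValueError("contig lengths must be >= 1000 bp")
    rng = np.random.default_rng(seed)
    names = names or [f"chr{i + 1}" for i in range(n_contigs)]
    return GenomeRef({name: _random_seq(int(l), rng) for name, l in zip(names, lengths)})


def make_sparse_reference(contig_specs: dict[str, tuple[int, list[tuple[int, int]]]],
                          seed: int, filler_unit: str = "AACCT") -> GenomeRef:
    """Reference with random sequence only inside chosen windows.

    Everything outside the windows is a low-complexity tile — enough to give
    Mb-scale coordinates without the cost (or mappability) of Mb-scale random
    sequence.  Used when an SV target cites megabase spans but reads are only
    simulated near the junctions.
    """
    rng = np.random.default_rng(seed)
    contigs = {}
    for name, (length, windows) in contig_specs.items():
        tile = (filler_unit * (length // len(filler_unit) + 1))[:length]
        arr = np.frombuffer(tile.encode(), dtype=np.uint8).copy()
        for s, e in windows:
            s, e = max(0, s), min(length, e)
            arr[s:e] = rng.choice(_BASES, size=e - s)
        contigs[name] = arr.tobytes().decode()
    return GenomeRef(contigs)


# ---------------------------------------------------------------------------
# Derivative walks
# ---------------------------------------------------------------------------

@dataclass
class Piece:
    """An oriented reference interval inside a derivative walk."""

    contig: str
    start: int
    end: int
    strand: str = "+"
    pristine: bool = True  # still an unedited copy of its reference interval

    @property
    def length(self) -> int:
        return self.end - self.start


Walk = list  # list[Piece]


@dataclass
class Junction:
    """A non-reference adjacency between two breakends in a walk."""

    bnd1: Breakend
    bnd2: Breakend
    deriv_pos: int  # position of the join in derivative coordinates
    haplotype: str = ""
    walk_index: int = 0


@dataclass
class ExpectedCall:
    """The SV call a perfect caller would emit for one implanted SV."""

    svtype: str
    contig1: str
    pos1: int
    contig2: str
    pos2: int
    svlen: int | None


@dataclass
class TruthSv:
    """One implanted SV with its junction set and expected calls."""

    id: str
    svclass: str  # DEL | DUP | INV | INV_UNBALANCED | TRA | TI_BRIDGE | TI_CHAIN | COMPLEX
    haplotypes: tuple[str, ...]
    junctions: list[tuple[Breakend, Breakend, tuple | None]]
    zygosity: str = "somatic"  # somatic | germline-het | germline-hom
    length: int = 0
    expected_calls: list[ExpectedCall] = field(default_factory=list)
    inserts: list[tuple[str, int, int, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.svclass in ("TI_BRIDGE", "TI_CHAIN") and not self.inserts:
            raise ValueError(f"{self.id}: templated-insertion SV without inserted segment")
        if self.svclass == "COMPLEX" and len(self.junctions) < 3:
            raise ValueError(f"{self.id}: COMPLEX SV needs >= 3 junctions")


class ConflictError(ValueError):
    """Two edits overlap on the same haplotype."""


class DerivativeGenome:
    """Reference plus per-haplotype derivative walks and the implanted truth.

    Haplotypes are ``tumor-1``/``tumor-2`` (editable) and
    ``normal-1``/``normal-2`` (always identical to the reference).  The
    parental phase of ``X-1`` haplotypes is "1", of ``X-2`` is "2"; somatic
    SVs on ``tumor-1`` therefore sit on parental haplotype 1.
    """

    def __init__(self, ref: GenomeRef):
        self.ref = ref
        self.walks: dict[str, list[Walk]] = {
            hap: [[Piece(name, 0, length)] for name, length in ref.lengths.items()]
            for hap in ALL_HAPS
        }
        self.svs: list[TruthSv] = []
        self._edited: dict[str, list[tuple[str, int, int, str]]] = {h: [] for h in ALL_HAPS}
        self._seq_cache: dict[tuple[str, int], str] = {}

    # -- bookkeeping -------------------------------------------------------

    def _check_conflict(self, hap: str, contig: str, s: int, e: int, sv_id: str) -> None:
        for (ctg, es, ee, other) in self._edited[hap]:
            if ctg == contig and s < ee and es < e:
                raise ConflictError(
                    f"SVs {other} and {sv_id} overlap on {hap} {contig}:{max(s, es)}-{min(e, ee)}")
        self._edited[hap].append((contig, s, e, sv_id))

    def _locate(self, hap: str, contig: str, pos: int) -> tuple[int, int]:
        for wi, walk in enumerate(self.walks[hap]):
            for pi, piece in enumerate(walk):
                if (piece.pristine and piece.strand == "+" and piece.contig == contig
                        and piece.start <= pos < piece.end):
                    return wi, pi
        raise ConflictError(f"position {contig}:{pos} not available on a pristine piece of {hap}")

    def _split(self, hap: str, contig: str, pos: int) -> tuple[int, int]:
        """Split the pristine piece containing pos; return (walk, index of right part)."""
        wi, pi = self._locate(hap, contig, pos)
        walk = self.walks[hap][wi]
        piece = walk[pi]
        if pos == piece.start:
            return wi, pi
        left = Piece(piece.contig, piece.start, pos, "+", piece.pristine)
        right = Piece(piece.contig, pos, piece.end, "+", piece.pristine)
        walk[pi:pi + 1] = [left, right]
        self._seq_cache.clear()
        return wi, pi + 1

    def _register(self, sv: TruthSv) -> None:
        self.svs.append(sv)
        self._seq_cache.clear()

    # -- edits -------------------------------------------------------------

    def add_deletion(self, hap: str, contig: str, s: int, e: int,
                     sv_id: str | None = None, zygosity: str = "somatic") -> TruthSv:
        sv_id = sv_id or f"del{len(self.svs)}"
        self._check_conflict(hap, contig, s, e, sv_id)
        wi, i0 = self._split(hap, contig, s)
        _, i1 = self._split(hap, contig, e)
        walk = self.walks[hap][wi]
        del walk[i0:i1]
        sv = TruthSv(sv_id, "DEL", (hap,),
                     [(Breakend(contig, s, "L"), Breakend(contig, e, "R"), None)],
                     zygosity, e - s,
                     [ExpectedCall("DEL", contig, s, contig, e, e - s)])
        self._register(sv)
        return sv

    def add_duplication(self, hap: str, contig: str, s: int, e: int,
                        sv_id: str | None = None, zygosity: str = "somatic") -> TruthSv:
        """Tandem duplication of [s, e)."""
        sv_id = sv_id or f"dup{len(self.svs)}"
        self._check_conflict(hap, contig, s, e, sv_id)
        wi, i0 = self._split(hap, contig, s)
        _, i1 = self._split(hap, contig, e)
        walk = self.walks[hap][wi]
        copy = [Piece(p.contig, p.start, p.end, p.strand, pristine=False) for p in walk[i0:i1]]
        walk[i1:i1] = copy
        sv = TruthSv(sv_id, "DUP", (hap,),
                     [(Breakend(contig, e, "L"), Breakend(contig, s, "R"), None)],
                     zygosity, e - s,
                     [ExpectedCall("DUP", contig, s, contig, e, e - s)])
        self._register(sv)
        return sv

    def add_inversion(self, hap: str, contig: str, s: int, e: int,
                      sv_id: str | None = None, zygosity: str = "somatic") -> TruthSv:
        """Balanced inversion of [s, e) (both reciprocal junctions retained)."""
        sv_id = sv_id or f"inv{len(self.svs)}"
        self._check_conflict(hap, contig, s, e, sv_id)
        wi, i0 = self._split(hap, contig, s)
        _, i1 = self._split(hap, contig, e)
        walk = self.walks[hap][wi]
        seg = walk[i0:i1]
        inv = [Piece(p.contig, p.start, p.end, "-", pristine=False) for p in reversed(seg)]
        walk[i0:i1] = inv
        sv = TruthSv(sv_id, "INV", (hap,),
                     [(Breakend(contig, s, "L"), Breakend(contig, e, "L"), None),
                      (Breakend(contig, s, "R"), Breakend(contig, e, "R"), None)],
                     zygosity, e - s,
                     [ExpectedCall("INV", contig, s, contig, e, e - s)])
        self._register(sv)
        return sv

    def add_unbalanced_inversion_pair(self, hap: str, contig: str,
                                      a: int, b: int, c: int, d: int,
                                      sv_ids: tuple[str, str] | None = None) -> tuple[TruthSv, TruthSv]:
        """Two unbalanced inversions in cis: walk becomes [0,a) + rev([b,c)) + [d, L).

        Each inversion keeps only one junction of a reciprocal pair: the
        first joins ``a`` to the inverted segment end ``c`` (span ``c - a``),
        the second joins the inverted segment start ``b`` to ``d`` (span
        ``d - b``).  Intervals [a,b) and [c,d) are lost — only one side of
        each original break is rescued.
        """
        if not a < b < c < d:
            raise ValueError("breakpoints must satisfy a < b < c < d")
        ids = sv_ids or (f"uinv{len(self.svs)}", f"uinv{len(self.svs) + 1}")
        self._check_conflict(hap, contig, a, d, ids[0])
        wi, i0 = self._split(hap, contig, a)
        _, ib = self._split(hap, contig, b)
        _, ic = self._split(hap, contig, c)
        _, i1 = self._split(hap, contig, d)
        walk = self.walks[hap][wi]
        seg = walk[ib:ic]
        inv = [Piece(p.contig, p.start, p.end, "-", pristine=False) for p in reversed(seg)]
        walk[i0:i1] = inv
        sv1 = TruthSv(ids[0], "INV_UNBALANCED", (hap,),
                      [(Breakend(contig, a, "L"), Breakend(contig, c, "L"), None)],
                      "somatic", c - a,
                      [ExpectedCall("INV", contig, a, contig, c, c - a)])
        sv2 = TruthSv(ids[1], "INV_UNBALANCED", (hap,),
                      [(Breakend(contig, b, "R"), Breakend(contig, d, "R"), None)],
                      "somatic", d - b,
                      [ExpectedCall("INV", contig, b, contig, d, d - b)])
        self._register(sv1)
        self._register(sv2)
        return sv1, sv2

    def add_translocation(self, hap: str, contig1: str, p1: int, contig2: str, p2: int,
                          sv_id: str | None = None, reciprocal: bool = True,
                          zygosity: str = "somatic") -> TruthSv:
        """Join contig1[0,p1) to contig2[p2,end); optionally keep the reciprocal."""
        sv_id = sv_id or f"tra{len(self.svs)}"
        if contig1 == contig2:
            raise ValueError("translocation requires two contigs")
        self._check_conflict(hap, contig1, p1, p1 + 1, sv_id)
        self._check_conflict(hap, contig2, p2, p2 + 1, sv_id)
        w1, i1 = self._split(hap, contig1, p1)
        w2, i2 = self._split(hap, contig2, p2)
        haps_walks = self.walks[hap]
        walk1, walk2 = haps_walks[w1], haps_walks[w2]
        left1, right1 = walk1[:i1], walk1[i1:]
        left2, right2 = walk2[:i2], walk2[i2:]
        new1 = left1 + right2
        new2 = (left2 + right1) if reciprocal else left2
        haps_walks[w1] = new1
        haps_walks[w2] = new2
        sv = TruthSv(sv_id, "TRA", (hap,),
                     [(Breakend(contig1, p1, "L"), Breakend(contig2, p2, "R"), None)],
                     zygosity, 0,
                     [ExpectedCall("BND", contig1, p1, contig2, p2, None)])
        self._register(sv)
        return sv

    def add_ti_bridge(self, hap: str, contig: str, s: int, e: int,
                      donor: tuple[str, int, int, str],
                      sv_id: str | None = None) -> TruthSv:
        """Deletion of [s, e) bridged by a copied donor segment.

        The donor (contig, start, end, strand) is copied — its source locus
        is untouched — producing two novel junctions and a net gain of the
        donor segment inside a net loss of [s, e).
        """
        sv_id = sv_id or f"tib{len(self.svs)}"
        dc, ds, de, dstrand = donor
        self._check_conflict(hap, contig, s, e, sv_id)
        wi, i0 = self._split(hap, contig, s)
        _, i1 = self._split(hap, contig, e)
        walk = self.walks[hap][wi]
        walk[i0:i1] = [Piece(dc, ds, de, dstrand, pristine=False)]
        d_enter = Breakend(dc, de, "L") if dstrand == "-" else Breakend(dc, ds, "R")
        d_exit = Breakend(dc, ds, "R") if dstrand == "-" else Breakend(dc, de, "L")
        # breakend side naming: enter/exit as seen from the receiving contig
        sv = TruthSv(sv_id, "TI_BRIDGE", (hap,),
                     [(Breakend(contig, s, "L"), d_enter, donor),
                      (d_exit, Breakend(contig, e, "R"), None)],
                     "somatic", e - s,
                     [ExpectedCall("BND" if dc != contig else "DEL", contig, s, dc,
                                   de if dstrand == "-" else ds, None),
                      ExpectedCall("BND" if dc != contig else "DEL", dc,
                                   ds if dstrand == "-" else de, contig, e, None)],
                     inserts=[donor])
        self._register(sv)
        return sv

    def add_ti_chain(self, hap: str, contig1: str, p1: int, contig2: str, p2: int,
                     donors: list[tuple[str, int, int, str]],
                     sv_id: str | None = None) -> TruthSv:
        """Translocation with one or more copied donor segments at the junction."""
        sv_id = sv_id or f"tic{len(self.svs)}"
        if not donors:
            raise ValueError("TI chain needs >= 1 donor segment")
        self._check_conflict(hap, contig1, p1, p1 + 1, sv_id)
        self._check_conflict(hap, contig2, p2, p2 + 1, sv_id)
        w1, i1 = self._split(hap, contig1, p1)
        w2, i2 = self._split(hap, contig2, p2)
        haps_walks = self.walks[hap]
        walk1, walk2 = haps_walks[w1], haps_walks[w2]
        inserted = [Piece(dc, ds, de, dstrand, pristine=False) for dc, ds, de, dstrand in donors]
        new1 = walk1[:i1] + inserted + walk2[i2:]
        new2 = walk2[:i2] + walk1[i1:]
        haps_walks[w1] = new1
        haps_walks[w2] = new2
        sv = TruthSv(sv_id, "TI_CHAIN", (hap,),
                     [(Breakend(contig1, p1, "L"), Breakend(contig2, p2, "R"), tuple(donors))],
                     "somatic", 0, [], inserts=list(donors))
        self._register(sv)
        return sv

    def set_complex_walks(self, hap: str, new_walks: list[Walk],
                          sv_id: str | None = None) -> TruthSv:
        """Replace a haplotype's walks wholesale (chromoplexy-style clusters).

        The junction list of the recorded COMPLEX SV is derived from the new
        walks' non-reference adjacencies.
        """
        sv_id = sv_id or f"cpx{len(self.svs)}"
        self.walks[hap] = [list(w) for w in new_walks]
        self._seq_cache.clear()
        juncs = [(j.bnd1, j.bnd2, None) for j in self.junctions_of(hap)]
        sv = TruthSv(sv_id, "COMPLEX", (hap,), juncs, "somatic", 0)
        self._register(sv)
        return sv

    # -- derived views -----------------------------------------------------

    @staticmethod
    def _piece_junction(p: Piece, q: Piece) -> tuple[Breakend, Breakend] | None:
        """The junction between adjacent pieces, or None if reference-adjacent."""
        if (p.strand == q.strand == "+" and p.contig == q.contig and p.end == q.start):
            return None
        if (p.strand == q.strand == "-" and p.contig == q.contig and q.end == p.start):
            return None
        b1 = Breakend(p.contig, p.end, "L") if p.strand == "+" else Breakend(p.contig, p.start, "R")
        b2 = Breakend(q.contig, q.start, "R") if q.strand == "+" else Breakend(q.contig, q.end, "L")
        return b1, b2

    def junctions_of(self, hap: str) -> list[Junction]:
        out = []
        for wi, walk in enumerate(self.walks[hap]):
            off = 0
            for p, q in itertools.pairwise(walk):
                off += p.length
                j = self._piece_junction(p, q)
                if j is not None:
                    out.append(Junction(j[0], j[1], off, hap, wi))
        return out

    def haplotype_length(self, hap: str) -> int:
        return sum(p.length for w in self.walks[hap] for p in w)

    def sequence(self, hap: str, walk_index: int = 0) -> str:
        key = (hap, walk_index)
        if key not in self._seq_cache:
            parts = []
            for p in self.walks[hap][walk_index]:
                s = self.ref.seq(p.contig, p.start, p.end)
                parts.append(s if p.strand == "+" else revcomp(s))
            self._seq_cache[key] = "".join(parts)
        return self._seq_cache[key]

    def junction_kmer(self, j: Junction, k: int = 40) -> str:
        """The k-mer centered on a junction in the derivative sequence."""
        seq = self.sequence(j.haplotype, j.walk_index)
        s = max(0, j.deriv_pos - k // 2)
        return seq[s:s + k]

    def tumor_copy_number(self, contig: str) -> list[tuple[int, int, int]]:
        """Integer copy number q over the two tumor haplotypes, as (start, end, q)."""
        length = self.ref.lengths[contig]
        events: dict[int, int] = {0: 0, length: 0}
        for hap in TUMOR_HAPS:
            for walk in self.walks[hap]:
                for p in walk:
                    if p.contig == contig:
                        events[p.start] = events.get(p.start, 0) + 1
                        events[p.end] = events.get(p.end, 0) - 1
        out = []
        depth = 0
        positions = sorted(events)
        for s, e in itertools.pairwise(positions):
            depth += events[s]
            if e > s:
                if out and out[-1][2] == depth and out[-1][1] == s:
                    out[-1] = (out[-1][0], e, depth)
                else:
                    out.append((s, e, depth))
        return out

    def somatic_svs(self) -> list[TruthSv]:
        return [sv for sv in self.svs if sv.zygosity == "somatic"]


@dataclass
class TruthSet:
    """Ground truth for one synthetic run: genome, purity, seed."""

    genome: DerivativeGenome
    purity: float
    seed: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.purity <= 1.0:
            raise ValueError(f"purity must lie in [0, 1], got {self.purity}")

    @property
    def svs(self) -> list[TruthSv]:
        return self.genome.svs


# ---------------------------------------------------------------------------
# Read simulation
# ---------------------------------------------------------------------------

@dataclass
class SimRead:
    """One simulated long read with its truth provenance."""

    id: str
    sequence: str
    haplotype: str  # tumor-1 | tumor-2 | normal-1 | normal-2
    walk_index: int
    true_start: int  # derivative coordinates, pre-error
    true_end: int

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"read {self.id} has empty sequence")

    @property
    def haplotype_tag(self) -> str:
        return self.haplotype.rsplit("-", 1)[1]

    @property
    def is_tumor(self) -> bool:
        return self.haplotype.startswith("tumor")


def apply_errors(seq: str, rates: tuple[float, float, float],
                 rng: np.random.Generator) -> str:
    """Independent per-base substitution / insertion / deletion errors."""
    sub, ins, dele = rates
    if sub == ins == dele == 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    n = arr.size
    u = rng.random(n)
    out = []
    subs_idx = u < sub
    if subs_idx.any():
        arr = arr.copy()
        # substitute with a uniformly chosen *different* base
        repl = rng.choice(_BASES, size=int(subs_idx.sum()))
        same = repl == arr[subs_idx]
        while same.any():
            repl[same] = rng.choice(_BASES, size=int(same.sum()))
            same = repl == arr[subs_idx]
        arr[subs_idx] = repl
    del_mask = rng.random(n) < dele
    ins_mask = rng.random(n) < ins
    ins_bases = rng.choice(_BASES, size=int(ins_mask.sum()))
    ins_iter = iter(ins_bases)
    for i in range(n):
        if ins_mask[i]:
            out.append(next(ins_iter))
        if not del_mask[i]:
            out.append(arr[i])
    return bytes(out).decode() if out else seq[:1]


def _draw_length(rng: np.random.Generator, mean_len: float, min_len: int = 100) -> int:
    # gamma with shape 2: right-skewed, like PCR-based nanopore libraries
    return max(min_len, int(rng.gamma(2.0, mean_len / 2.0)))


def simulate_reads(dg: DerivativeGenome, purity: float, depth: float,
                   mean_len: float = 2100.0,
                   error_rates: tuple[float, float, float] = (0.02, 0.01, 0.02),
                   seed: int = 0,
                   regions: dict[str, list[tuple[int, int, int]]] | None = None,
                   read_prefix: str = "read") -> list[SimRead]:
    """Draw reads from tumor haplotypes with probability ``purity``.

    ``regions`` optionally restricts read start positions per haplotype to
    ``(walk_index, start, end)`` windows in that haplotype's derivative
    coordinates; by default reads are drawn genome-wide.  ``depth`` is the
    fold coverage over the sampled space.
    """
    if not 0.0 <= purity <= 1.0:
        raise ValueError(f"purity must lie in [0, 1], got {purity}")
    if depth <= 0:
        raise ValueError("depth must be > 0")
    rng = np.random.default_rng(seed)
    hap_space: dict[str, list[tuple[int, int, int]]] = {}
    for hap in ALL_HAPS:
        if regions and hap in regions:
            hap_space[hap] = list(regions[hap])
        elif regions:
            continue
        else:
            hap_space[hap] = [(wi, 0, sum(p.length for p in w))
                              for wi, w in enumerate(dg.walks[hap]) if w]
    weights = {}
    for hap, windows in hap_space.items():
        share = purity / 2.0 if hap.startswith("tumor") else (1.0 - purity) / 2.0
        weights[hap] = share * sum(e - s for _, s, e in windows)
    total_w = sum(weights.values())
    if total_w == 0:
        return []
    total_space = sum(sum(e - s for _, s, e in v) for v in hap_space.values()) / len(hap_space)
    n_reads = max(1, int(round(depth * total_space / mean_len)))
    haps = list(weights)
    probs = np.array([weights[h] for h in haps]) / total_w
    reads: list[SimRead] = []
    choices = rng.choice(len(haps), size=n_reads, p=probs)
    for i in range(n_reads):
        hap = haps[choices[i]]
        windows = hap_space[hap]
        spans = np.array([e - s for _, s, e in windows], dtype=float)
        wi_idx = rng.choice(len(windows), p=spans / spans.sum()) if len(windows) > 1 else 0
        walk_index, ws, we = windows[wi_idx]
        seq = dg.sequence(hap, walk_index)
        length = _draw_length(rng, mean_len)
        start = int(rng.integers(ws, we))
        end = min(start + length, len(seq))
        if end - start < 100:
            start = max(0, end - 100)
        raw = seq[start:end]
        reads.append(SimRead(f"{read_prefix}{i}", apply_errors(raw, error_rates, rng),
                             hap, walk_index, start, end))
    return reads


def simulate_spanning_reads(dg: DerivativeGenome, hap: str, walk_index: int,
                            deriv_pos: int, n: int, mean_len: float = 2100.0,
                            error_rates: tuple[float, float, float] = (0.02, 0.01, 0.02),
                            seed: int = 0, min_flank: int = 300,
                            read_prefix: str = "span") -> list[SimRead]:
    """Reads guaranteed to span one derivative position with both flanks."""
    rng = np.random.default_rng(seed)
    seq = dg.sequence(hap, walk_index)
    reads = []
    for i in range(n):
        length = max(_draw_length(rng, mean_len), 2 * min_flank + 100)
        lo = max(0, deriv_pos + min_flank - length)
        hi = max(lo + 1, deriv_pos - min_flank)
        start = int(rng.integers(lo, hi))
        end = min(start + length, len(seq))
        raw = seq[start:end]
        reads.append(SimRead(f"{read_prefix}{i}", apply_errors(raw, error_rates, rng),
                             hap, walk_index, start, end))
    return reads


def junction_regions(dg: DerivativeGenome, pad: int) -> dict[str, list[tuple[int, int, int]]]:
    """Derivative windows of ±pad around every junction, plus the matching
    reference-coordinate windows on the unedited haplotypes (so normal reads
    cover the same loci)."""
    regions: dict[str, list[tuple[int, int, int]]] = {h: [] for h in ALL_HAPS}
    ref_windows: list[tuple[str, int, int]] = []
    for hap in TUMOR_HAPS:
        for j in dg.junctions_of(hap):
            total = sum(p.length for p in dg.walks[hap][j.walk_index])
            s, e = max(0, j.deriv_pos - pad), min(total, j.deriv_pos + pad)
            regions[hap].append((j.walk_index, s, e))
            for bnd in (j.bnd1, j.bnd2):
                ref_windows.append((bnd.contig, max(0, bnd.pos - pad),
                                    min(dg.ref.lengths[bnd.contig], bnd.pos + pad)))
    contig_order = list(dg.ref.lengths)
    for hap in ALL_HAPS:
        if hap in TUMOR_HAPS and regions[hap]:
            continue
        for ctg, s, e in ref_windows:
            regions[hap].append((contig_order.index(ctg), s, e))
    return {h: v for h, v in regions.items() if v}


# ---------------------------------------------------------------------------
# Truth projection (ideal-aligner stand-in)
# ---------------------------------------------------------------------------

def project_alignments(reads: list[SimRead], dg: DerivativeGenome,
                       min_seg: int = 50) -> list[AlignmentSegment]:
    """Map reads back to reference coordinates through the truth edit map.

    A read crossing k junctions yields k+1 segments with correct strands.
    Read coordinates refer to the pre-error read layout (an idealization of
    an external aligner's output on the same reads).
    """
    segments: list[AlignmentSegment] = []
    for read in reads:
        walk = dg.walks[read.haplotype][read.walk_index]
        off = 0
        rs, re = read.true_start, read.true_end
        if re <= rs:
            raise ValueError(f"read {read.id} lacks truth provenance coordinates")
        for piece in walk:
            p_lo, p_hi = off, off + piece.length
            off = p_hi
            a, b = max(rs, p_lo), min(re, p_hi)
            if b - a < min_seg:
                continue
            if piece.strand == "+":
                ref_s = piece.start + (a - p_lo)
                ref_e = piece.start + (b - p_lo)
            else:
                ref_s = piece.end - (b - p_lo)
                ref_e = piece.end - (a - p_lo)
            segments.append(AlignmentSegment(read.id, piece.contig, ref_s, ref_e,
                                             a - rs, b - rs, piece.strand,
                                             read.haplotype_tag))
    return segments


# ---------------------------------------------------------------------------
# Direct call-set emission (bypasses the read level)
# ---------------------------------------------------------------------------

def expected_call_from_junction(bnd1: Breakend, bnd2: Breakend) -> ExpectedCall:
    """Classify a single junction by breakend geometry."""
    if bnd1.contig != bnd2.contig:
        return ExpectedCall("BND", bnd1.contig, bnd1.pos, bnd2.contig, bnd2.pos, None)
    lo, hi = sorted((bnd1, bnd2), key=lambda b: b.pos)
    if bnd1.side == bnd2.side:
        return ExpectedCall("INV", bnd1.contig, lo.pos, bnd2.contig, hi.pos, hi.pos - lo.pos)
    if (lo.side, hi.side) == ("L", "R"):
        return ExpectedCall("DEL", bnd1.contig, lo.pos, bnd2.contig, hi.pos, hi.pos - lo.pos)
    return ExpectedCall("DUP", bnd1.contig, lo.pos, bnd2.contig, hi.pos, hi.pos - lo.pos)

def emit_callset(truth: TruthSet, noise: tuple[int, float, int] = (0, 0.0, 0),
                 seed: int = 0, support: int = 10, af: float = 0.35) -> list[SvCall]:
    """One SvCall per truth junction-level expected call, with optional noise.

    ``noise`` is (n_fp, germline_fraction, breakpoint_jitter_bp): n_fp random
    false calls, a germline-decoy count equal to round(fraction × number of
    somatic calls), and uniform breakpoint jitter within ±jitter.
    """
    n_fp, germ_frac, jitter = noise
    if jitter < 0:
        raise ValueError("jitter must be >= 0")
    if n_fp < 0 or germ_frac < 0:
        raise ValueError("noise counts must be >= 0")
    rng = np.random.default_rng(seed)
    lengths = truth.genome.ref.lengths
    contigs = list(lengths)
    calls: list[SvCall] = []
    i = 0

    def jit(pos: int, contig: str) -> int:
        if jitter == 0:
            return pos
        return int(np.clip(pos + rng.integers(-jitter, jitter + 1), 0, lengths[contig]))

    for sv in truth.svs:
        prov = "somatic-truth" if sv.zygosity == "somatic" else "germline-truth"
        expected = sv.expected_calls or [expected_call_from_junction(b1, b2)
                                         for b1, b2, _ins in sv.junctions]
        for ec in expected:
            p1, p2 = jit(ec.pos1, ec.contig1), jit(ec.pos2, ec.contig2)
            svlen = abs(p2 - p1) if ec.svlen is not None else None
            calls.append(SvCall(f"call{i}", ec.svtype,
                                Breakend(ec.contig1, p1, "L"),
                                Breakend(ec.contig2, p2, "R"),
                                svlen, support, af, (), True, prov))
            i += 1
    n_somatic = sum(len(sv.expected_calls) or len(sv.junctions)
                    for sv in truth.svs if sv.zygosity == "somatic")
    n_germ = int(round(germ_frac * n_somatic))
    calls += germline_decoys(lengths, n_germ, rng, start_index=i)
    i += n_germ
    for _ in range(n_fp):
        ctg = contigs[rng.integers(len(contigs))]
        pos = int(rng.integers(0, max(1, lengths[ctg] - 2000)))
        ln = int(rng.integers(50, 2000))
        calls.append(SvCall(f"call{i}", "DEL", Breakend(ctg, pos, "L"),
                            Breakend(ctg, pos + ln, "R"), ln, 2, 0.02, (), False, "fp"))
        i += 1
    return calls


def germline_decoys(lengths: dict[str, int], n: int, rng: np.random.Generator,
                    start_index: int = 0) -> list[SvCall]:
    """Germline SV decoys: 75% shorter than 5 kb (so a >5 kb size rule
    removes about three quarters of them), the rest 5–50 kb."""
    contigs = list(lengths)
    out = []
    for k in range(n):
        if rng.random() < 0.75:
            ln = int(np.exp(rng.uniform(np.log(300), np.log(4999))))
        else:
            ln = int(np.exp(rng.uniform(np.log(5001), np.log(50000))))
        ctg = contigs[rng.integers(len(contigs))]
        pos = int(rng.integers(0, max(1, lengths[ctg] - ln - 1)))
        svtype = "DEL" if rng.random() < 0.7 else ("DUP" if rng.random() < 0.5 else "INV")
        out.append(SvCall(f"call{start_index + k}", svtype,
                          Breakend(ctg, pos, "L"), Breakend(ctg, pos + ln, "R"),
                          ln, 12, 0.5, (), True, "germline-truth"))
    return out


# ---------------------------------------------------------------------------
# Copy-ratio profile emission
# ---------------------------------------------------------------------------

def expected_copy_ratio(q: int, p: float) -> float:
    """Two-population mixture: r = (p*q + 2*(1-p)) / 2; r(2, p) == 1."""
    if q < 0:
        raise ValueError("copy number q must be >= 0")
    if not 0.0 <= p <= 1.0:
        raise ValueError("purity must lie in [0, 1]")
    return (p * q + 2.0 * (1.0 - p)) / 2.0


def emit_cnv_profile(truth: TruthSet, probe_spacing: int = 1000,
                     noise_sd: float = 0.0, seed: int = 0,
                     probe_width: int = 100) -> tuple[list[ProbeRatio], list[CnvSegment]]:
    """Noisy per-probe linear copy ratios plus the true segment table."""
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    p = truth.purity
    probes: list[ProbeRatio] = []
    segments: list[CnvSegment] = []
    for contig in truth.genome.ref.lengths:
        cn = truth.genome.tumor_copy_number(contig)
        for (s, e, q) in cn:
            r_exp = expected_copy_ratio(q, p)
            n_pr = 0
            pos = s + probe_spacing // 2
            while pos + probe_width <= e:
                r = r_exp + (rng.normal(0.0, noise_sd) if noise_sd else 0.0)
                probes.append(ProbeRatio(contig, pos, pos + probe_width, max(0.0, r)))
                n_pr += 1
                pos += probe_spacing
            segments.append(CnvSegment(contig, s, e, r_exp, q=q, n_probes=n_pr))
    return probes, segments
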