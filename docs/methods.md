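# Methods

This note documents the models, algorithms, parameter choices and known
limitations of `svlandscape`. Internally all coordinates are 0-based
half-open; VCF (1-based) and BED/SEG (0-based) conventions are applied only
at the I/O boundary.

## Synthetic data model

**Derivative walks.** A derivative haplotype is an ordered list of oriented
reference pieces (*contig, start, end, strand*). Every SV class is an edit
on a walk: deletions remove pieces, tandem duplications copy them,
inversions reverse them, translocations splice walks across contigs, and
templated insertions splice in a *copy* of a donor piece (its source locus
stays intact, so the donor gains copy number). An unbalanced-inversion pair
with breakpoints *a < b < c < d* rewrites the walk to
`[0,a) + rev([b,c)) + [d, end)`: each inversion retains exactly one of its
two reciprocal junctions (spans *c − a* and *d − b*) and the intervals
[a,b) and [c,d) are lost. Junctions, derivative sequences, copy-number
truth and the read-projection map are all *derived* from walks, so there is
a single source of truth and every invariant (length conservation, junction
40-mer novelty, seeded byte-reproducibility) is testable by construction.
Edits that overlap on one haplotype raise a conflict error naming both SVs.

**Reads.** Lengths follow a gamma distribution with shape 2 and mean
2,100 bp — the library in question was PCR-based with a short mean and a
right tail, and only the mean is known, so shape 2 is a modelling choice.
Per-base errors are independent substitutions/insertions/deletions at
2%/1%/2% by default, representative of R9.4.1 super-accuracy nanopore
data. Reads are drawn from the two tumor haplotypes with probability *p*
(the tumor fraction) and the two normal haplotypes otherwise. For
megabase-scale SVs, references are *sparse*: random sequence exists only
within ±60 kb of the planned breakpoints over a low-complexity filler tile,
and reads are simulated junction-locally — coordinates stay at true scale
while simulation stays at desk scale.

**Truth projection.** Simulated reads are mapped back to the reference
through the walk's piecewise-linear edit map: a read crossing *k* junctions
yields *k + 1* split segments with correct strands. This replaces an
external aligner; segment read-coordinates refer to the pre-error read
layout (an idealization — real aligners add breakpoint jitter, which the
direct call-set emitter models instead via a uniform ±jitter parameter).
Reads are emitted in derivative-forward orientation; sequencing the
opposite strand would change neither the split-segment geometry nor the
reference orientation an aligner reports, so it is not simulated.

**Copy-ratio profiles.** Integer tumor copy number *q(x)* is the coverage
of *x* by the two tumor walks. Per-probe linear ratios are
*r = (p·q + 2(1 − p))/2* plus Gaussian noise, clipped at 0.

## Split-read calling and somatic filtering

Adjacent split segments of one read define candidate junctions classified
by geometry (forward reference gap → deletion, backward gap → tandem
duplication, strand flip → inversion, contig change → breakend pair).
Junctions of one class within 100 bp at both ends cluster; clusters with ≥3
distinct reads become calls with median-position breakpoints, the
supporting read names, and an allele frequency estimated against local
coverage. Both junction flanks must be ≥100 bp aligned and reference gaps
<50 bp are absorbed (read-error tolerance). Same-class calls with both
breakends within 500 bp are merged, keeping the higher-support record —
this collapses the two reciprocal junction observations of a balanced
inversion into one call.

The somatic filter keeps a call iff it is an inter-chromosomal
translocation **or** strictly longer than 5,000 bp, and it passes
support ≥3, AF ≥0.05 and an optional interval blacklist. The size rule is
deliberately strict (>5,000, not ≥). On the packaged germline decoy
spectrum (75% of lengths below 5 kb) it removes ≥70% of germline SVs —
without a matched normal this is the honest compromise, and smaller somatic
SVs are knowingly sacrificed. Support and AF defaults are exposed in
`FilterConfig` since tumor-only thresholds are situational.

## Consensus and templated-insertion detection

Supporting reads are star-aligned against the longest read in 600 bp
chunks (edlib, infix mode); chunks whose edit distance exceeds 30% of their
length are discarded — they are overhangs past the backbone ends or
off-target placements that an infix aligner would otherwise force into the
vote. Per backbone column the plurality base (or gap) wins; insertions
relative to the backbone are emitted where at least half the reads carry
one. At depth 20 and ~5% read error the consensus is ≥99.5% identical to
truth. Because deletion errors (2%) outnumber insertion errors (1%), every
read is slightly shorter than its template and a correct consensus can be
slightly *longer* than the longest read; the consensus length is therefore
bounded by the read-length range only up to the total error budget (exact
under substitution-only errors).

The consensus is mapped back with an exact 21-mer index: seeds chain by
diagonal consistency (±30 bp wobble), chains shorter than 150 bp are
dropped (inserts below that are the tool's stated detection floor — the
smallest insert of interest here is 219 bp), and chains adjacent within
1 kb both on the reference and on the consensus merge into one region —
the merging distance exists to keep small-indel split artifacts from
inflating the region count. An SV is a **templated insertion** iff its
consensus maps to more than two regions; the non-terminal regions are the
inserted donor segments with contig, coordinates, strand and length. The
mapper reports seed-chain extents, so measured insert lengths carry a few
bp of boundary slack (≤50 bp in tests); the recovery workflow optionally
snaps donor boundaries to truth junctions within ±50 bp. Flagging emits
evidence (region identities, agreement), not a manual-review judgement —
the original analysis inspected flagged SVs by hand and those criteria are
unrecorded.

## Breakpoint mechanism

**Microhomology** is the longest common substring of the two breakend
windows, 12 bp on each side of each breakend (24 bp per breakend; a
"12 bp total" reading is selectable). For inversion-type junctions — both
retained flanks on the same side — the second window is
reverse-complemented first. Gapped alignment is deliberately not used: a
gapped match at a junction is not junction microhomology. Windows truncated
by contig edges are computed on the available bases and flagged.

**RAG sites** are exact occurrences of the canonical recombination-signal
heptamer `CACAGTG` or its reverse complement within ±50 bp of a breakend
(window and a mismatch tolerance are exposed; the default is the minimal
exact-heptamer reading, with no nonamer/spacer model).

**Enrichment** is assessed against a background of 100 random SVs with
classes drawn from the observed class frequencies, lengths resampled from
observed lengths, and uniform positions: Fisher's exact test on the 2×2
table of breakends with ≥1 heptamer hit, and a two-sided Mann–Whitney U on
microhomology lengths; "enriched" requires p < 0.05 *and* an effect in the
enrichment direction. The test choices are ours — the original description
names no test — and their null behavior is verified by simulation (type-I
error within the α = 0.05 budget over 1,000 seeded null runs).

## Phasing and reconstruction

Two linkage channels connect SVs into clusters: shared supporting reads
(physical linkage within a read length, ≥1 shared read by default) and
haplotype tags consumed from an external phaser — two SVs whose tagged
supporting reads both resolve to a haplotype within the same phase set are
comparable and therefore linked, which is how SVs megabases apart (far
beyond any read) end up in one cluster. Cis/trans verdicts use tags only:
an SV is assigned a haplotype when ≥80% of its tagged reads agree, a pair
is cis iff both resolve to the same haplotype, and with no tags at all
(e.g. over runs of homozygosity) every pair is unresolved. With ≥3
truth-tagged reads per SV the verdicts are exact on synthetic data.

Reconstruction cuts the involved contigs at every breakend and treats each
junction as replacing the reference adjacencies it breaks; when the
resulting graph is a set of unambiguous simple paths the ordered derivative
walks are emitted and lost pieces are reported as orphans, verified to
reproduce the synthetic derivative segment order exactly. Clusters with
more than 8 junctions, reused breakends, or copy-gain junctions degrade to
an adjacency report with reconstruction explicitly "not attempted" —
deliberate restraint for chromoplexy-scale clusters (the packaged one has
15 intra- plus 11 inter-chromosomal junctions). Junctions whose breakends
fall inside a fully deleted (q = 0) segment are flagged as copy-number
inconsistent.

## Purity-aware CNV arithmetic

All classification flows from *r(q, p) = (p·q + 2(1 − p))/2*, affine in
both arguments with *r*(2, *p*) ≡ 1 (autosomes, ploidy 2, single clone —
subclonal mixtures are out of scope). Segments take the *q* ∈ [0, 8] whose
expected ratio is nearest the observed one, ties toward neutral; at *p* = 0
classification is refused ("no tumor signal"). The separability diagnostic
*p*/2 per copy step is the arithmetic behind the qualitative contrast
between preparations: the gap is 0.12 at *p* = 0.24 (≈ probe noise) versus
0.29 at *p* = 0.58 (ratio 29/12 ≈ 2.42), which is why hom- vs het-deletion
can be distinguished only after tumor-cell enrichment. The signal-to-noise
ratio is a reconstruction — noise as the MAD-derived SD of probe ratios in
copy-neutral segments, signal as the expected single-copy shift — because
the original estimator is not spelled out; its printed values are
consequently not treated as checkable constants. Enrichment factors and
overlap percentages are computed in decimal arithmetic with one final
half-to-even rounding (0.58/0.24 → 2.42, 0.45/0.24 → 1.88, 716/737 →
97.2%); 736/737 prints as 99.86% here, which matches the published 99.8%
only under truncation, so that one is intentionally not asserted.

## Problem sizes and determinism

Packaged scenarios run at 1:100 or 1:10 coordinate scale except where a
quantity of interest is literal (insert lengths 219–4,036 bp, the 639 bp
donor-to-breakpoint distance, and the full-scale 512 kb / 31.6 Mb recovery
scenarios with sparse references). Read simulation is junction-local
(±25–50 kb) at 25–30× depth, keeping every workflow in seconds on one CPU.
Every stochastic component takes an explicit seed and is byte-reproducible;
the acceptance script derives all of its seeds from a single `--seed`.

## What passing tests do and do not show

The generator produces uniform-ACGT genomes without repeats, segmental
duplications, or GC bias, and truth projection plays the role of an ideal
aligner. Passing recovery tests therefore demonstrate the correctness of
the *logic* — filtering rules, the >2-regions insertion rule, mixture
arithmetic, phasing and reconstruction — not robustness to mapping
ambiguity in repetitive regions of a real genome, to aligner-dependent
breakpoint jitter beyond the modelled uniform jitter, or to base-caller
error structure. The exact-seed consensus mapper is adequate for synthetic
ACGT genomes; a hook allows substituting an external aligner for real-genome
use without changing downstream contracts. Known limitations: no SNV
simulation, no RNA-derived insert classification, no multi-clone mixtures,
no walk reconstruction through copy gains.
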