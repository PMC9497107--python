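# svlandscape

Tumor-only structural-variant (SV) landscape analysis for low-purity
lymphoma samples sequenced with long reads — with a synthetic-data
generator so every stage runs, and is tested, without patient data.

## The problem

Early-stage mycosis fungoides (the most common cutaneous T-cell lymphoma)
biopsies contain a minority of malignant T cells. At tumor fraction
*p* ≈ 0.2–0.3, copy-number variants (CNVs) — the dominant mutation class in
this disease — are close to invisible in bulk sequencing, and without a
matched normal, somatic SV calling from long reads must rely on heuristic
filters. This package implements the downstream analysis chain for exactly
that setting:

1. **Somatic filtering** of a tumor-only long-read SV call set
   (Sniffles2-style VCF): keep an SV only if it is an inter-chromosomal
   translocation or longer than 5 kb — a rule that removes roughly three
   quarters of germline SVs — plus support/allele-frequency/blacklist gates.
2. **Templated-insertion detection**: each SV's supporting reads are
   collapsed into a consensus, mapped back to the reference, and flagged
   when the consensus maps to **more than two** reference regions; the
   non-terminal regions are the inserted donor segments (bridge and chain
   architectures, inserts from a few hundred bp to several kb).
3. **Breakpoint mechanism**: cryptic RAG recognition sites (exact
   heptamer `CACAGTG` on either strand near breakends) and junction
   microhomology (longest common substring of the 12 bp flanks), compared
   against a random background of 100 SVs matched in class and length
   (Fisher's exact test and Mann–Whitney U).
4. **Phasing & reconstruction**: SVs are clustered through shared
   supporting reads and haplotype tags, SV pairs get cis/trans verdicts,
   and small clusters are reconstructed into an ordered derivative walk;
   chromoplexy-scale clusters degrade honestly to an adjacency report.
5. **Purity-aware CNV integration**: the two-population mixture
   *r(q, p) = (p·q + 2(1 − p)) / 2* (linear copy ratio *r*, integer tumor
   copy number *q*, tumor fraction *p*; *r*(2, *p*) ≡ 1) drives integer-CN
   classification (homozygous vs heterozygous deletion vs gain),
   signal-to-noise diagnostics, genome-fraction statistics, and
   SV-breakpoint/segment-boundary concordance.

The synthetic generator (`svlandscape.simulate`) builds diploid references,
implants deletions, (unbalanced) inversions, duplications, translocations,
templated-insertion bridges/chains and chromoplexy-like clusters as
explicit derivative walks, simulates ~2.1 kb mean gamma-length reads with
indel/substitution errors at any purity, projects them back through the
truth edit map, and emits noisy per-probe copy ratios — so recovery can
always be checked against construction.

## Worked example

The numbered drivers under `analysis/` run the study's analyses at desk
scale and write tables to `results/`. For instance:

```bash
$ python analysis/02_cdkn2a_complex.py
recovered deletion: 512 kb (true 512 kb)
recovered inversion span: 31.6 Mb (true 31.6 Mb)
scaled pipeline: 3 SVs in 1 cluster; cis pair(s): ['sv0|sv2']; homozygous deletion visible: True
```

The first two lines are full-scale recoveries: a 512 kb deletion and a
31.6 Mb-span unbalanced inversion are implanted on synthetic contigs,
junction-local reads are simulated at purity 0.58, and the split-read
caller plus filter report the dimensions back. The third line runs the
complete pipeline on a 1:100-scale model of the same architecture — two
unbalanced inversions in cis on one haplotype, a deletion in trans on the
other — and finds one 3-SV cluster, the cis verdict for the inversion
pair, and the homozygously deleted core in the copy-ratio profile.

```bash
$ python analysis/06_cnv_purity.py
enrichment factors: CD3+ 2.42, CD4+ 1.88
clonal SNV overlap, unprocessed vs CD3+: 97.2%
unprocessed (p=0.24): SNR del/amp = 1.15/1.15, hom-het gap 0.12, q accuracy 1.00
       CD4+ (p=0.45): SNR del/amp = 2.16/2.16, hom-het gap 0.22, q accuracy 1.00
       CD3+ (p=0.58): SNR del/amp = 2.78/2.78, hom-het gap 0.29, q accuracy 1.00
```

Here the enrichment factors come straight from the measured tumor
fractions (0.58/0.24 and 0.45/0.24), and the per-purity rows show why
single-copy events are near the noise floor without enrichment: at
*p* = 0.24 the expected ratio gap between adjacent copy states (*p*/2 =
0.12) is comparable to per-probe noise, while at *p* = 0.58 it is ~3×
larger.

A CLI exposes the same stages on files
(`svlandscape filter|ti|mechanism|phase|cnv|run-all|fixtures`), e.g.

```bash
svlandscape filter --vcf calls.vcf --min-len 5000 --out kept.vcf --removed removed.tsv
```

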