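"""End-to-end pipeline: simulate -> call -> filter -> TI -> mechanism -> phase -> CNV.

``run_all`` executes the stages in order on a packaged scenario (or a
caller-supplied truth set), writes every stage's output into a run
directory, and aggregates a machine-readable ``summary.json``.  A run is a
pure function of (RunConfig, inputs): rerunning with the same seed
reproduces the outputs byte for byte.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
from dataclasses import dataclass, field

from svlandscape import cnv as cnvmod
from svlandscape import consensus as consmod
from svlandscape import mechanism as mechmod
from svlandscape import phasing as phasemod
from svlandscape.calling import FilterConfig, call_svs_from_alignments, class_census, filter_svs
from svlandscape.fixtures import (
    Scenario,
    arid1a_region,
    cdkn2a_region,
    census_callset,
    chromoplexy,
    stat35_chain,
)
from svlandscape.formats import (
    export_cnv_ring,
    export_junction_table,
    write_alignments,
    write_fasta,
    write_fastq,
    write_seg,
    write_sv_vcf,
)
from svlandscape.simulate import (
    TruthSet,
    emit_cnv_profile,
    junction_regions,
    project_alignments,
    simulate_reads,
)

log = logging.getLogger(__name__)

_SCENARIOS = {
    "fig4a": cdkn2a_region,
    "fig4b": arid1a_region,
    "fig4c": stat35_chain,
    "fig4d": chromoplexy,
}


@dataclass
class RunConfig:
    """All parameters of one pipeline run (serialized next to its outputs)."""

    seed: int = 0
    scenario: str = "fig4a"
    outdir: str = "run"
    purity: float = 0.58
    depth: float = 30.0
    mean_read_len: float = 2100.0
    error_rates: tuple[float, float, float] = (0.02, 0.01, 0.02)
    filter: FilterConfig = field(default_factory=FilterConfig)
    cluster_window: int = 100
    consensus_k: int = 21
    min_segment: int = 150
    merge_dist: int = 1000
    mh_window: int = 12
    rag_window: int = 50
    n_background: int = 100
    probe_spacing: int = 2000
    probe_noise_sd: float = 0.05
    haplotype_majority: float = 0.8
    write_reads: bool = False


def _json_ready(x):
    if isinstance(x, dict):
        return {str(k): _json_ready(v) for k, v in x.items()}
    if isinstance(x, (list, tuple)):
        return [_json_ready(v) for v in x]
    if isinstance(x, (int, float, str, bool)) or x is None:
        return x
    return str(x)


def run_all(config: RunConfig) -> dict:
    """Run every stage on the configured scenario; return the summary."""
    os.makedirs(config.outdir, exist_ok=True)
    with open(os.path.join(config.outdir, "run_config.json"), "w") as fh:
        json.dump(_json_ready(dataclasses.asdict(config)), fh, indent=1)

    stage = "simulate"
    try:
        if config.scenario not in _SCENARIOS:
            raise ValueError(f"unknown scenario {config.scenario!r}; "
                             f"available: {', '.join(_SCENARIOS)}")
        scen: Scenario = _SCENARIOS[config.scenario](config.seed, config.purity)
        truth: TruthSet = scen.truth
        dg = truth.genome
        write_fasta(dg.ref.contigs, os.path.join(config.outdir, "ref.fa"))
        regions = junction_regions(dg, scen.regions_pad)
        reads = simulate_reads(dg, truth.purity, config.depth, config.mean_read_len,
                               config.error_rates, config.seed, regions)
        if config.write_reads:
            write_fastq(reads, os.path.join(config.outdir, "reads.fq"))

        stage = "call"
        segments = project_alignments(reads, dg)
        write_alignments(segments, os.path.join(config.outdir, "alignments.tsv"))
        calls = call_svs_from_alignments(segments, config.cluster_window,
                                         config.filter.min_support)
        write_sv_vcf(calls, os.path.join(config.outdir, "calls_raw.vcf"), dg.ref.lengths)

        stage = "filter"
        kept, removed = filter_svs(calls, config.filter)
        census = class_census(kept)
        write_sv_vcf(kept, os.path.join(config.outdir, "calls_kept.vcf"), dg.ref.lengths)
        with open(os.path.join(config.outdir, "calls_removed.tsv"), "w") as fh:
            fh.write("id\tsvtype\treason\n")
            for call, reason in removed:
                fh.write(f"{call.id}\t{call.svtype}\t{reason}\n")

        stage = "ti"
        read_seq = {r.id: r.sequence for r in reads}
        kindex = consmod.KmerIndex(dg.ref, config.consensus_k)
        ti_rows = []
        n_ti = 0
        for call in kept:
            support_seqs = [read_seq[r] for r in call.read_names if r in read_seq]
            if not support_seqs:
                continue
            cons = consmod.build_consensus(support_seqs, call.id)
            mapping = consmod.map_consensus(cons, dg.ref, config.consensus_k,
                                            config.min_segment, config.merge_dist,
                                            index=kindex)
            verdict, inserts = consmod.flag_templated_insertion(mapping)
            if verdict == "templated_insertion":
                n_ti += 1
            ti_rows.append((call.id, verdict, len(inserts),
                            ";".join(f"{c}:{s}-{e}({st})" for c, s, e, st, _l in inserts),
                            ";".join(str(l) for *_x, l in inserts)))
        with open(os.path.join(config.outdir, "templated_insertions.tsv"), "w") as fh:
            fh.write("sv_id\tclassification\tn_insertions\tdonors\tinsert_lengths\n")
            for row in ti_rows:
                fh.write("\t".join(str(x) for x in row) + "\n")

        stage = "mechanism"
        mech_summary = {}
        if kept:
            obs_ann = mechmod.annotate(dg.ref, kept, config.mh_window, config.rag_window)
            bg = mechmod.make_background(dg.ref, kept, config.n_background, config.seed)
            bg_ann = mechmod.annotate(dg.ref, bg.calls, config.mh_window, config.rag_window)
            enr = mechmod.enrichment_test(obs_ann, bg_ann)
            mech_summary = {
                "rag_odds_ratio": enr.rag_odds_ratio, "rag_p": enr.rag_p,
                "rag_enriched": enr.rag_enriched, "mh_shift": enr.mh_shift,
                "mh_p": enr.mh_p, "mh_enriched": enr.mh_enriched,
            }

        stage = "phase"
        tags = {r.id: r.haplotype_tag for r in reads}
        clusters = phasemod.cluster_by_readnames(kept, tags=tags,
                                                 majority=config.haplotype_majority)
        verdicts = phasemod.assign_haplotypes(kept, tags, clusters,
                                              config.haplotype_majority)
        phasemod.classify_clusters(clusters, verdicts)
        stage = "cnv"
        probes, segments_cnv = emit_cnv_profile(truth, config.probe_spacing,
                                                config.probe_noise_sd, config.seed)
        classified = cnvmod.classify_segments(segments_cnv, truth.purity)
        fractions = cnvmod.genome_fraction_by_state(
            classified, sum(dg.ref.lengths.values()))
        _, concord = cnvmod.breakpoint_concordance(kept, classified)
        write_seg(classified, os.path.join(config.outdir, "cnv_segments.seg"))
        export_junction_table(kept, os.path.join(config.outdir, "plot_arcs.tsv"))
        export_cnv_ring(classified, os.path.join(config.outdir, "plot_cnv_ring.tsv"))

        recon = []
        for cl in clusters:
            rep = phasemod.reconstruct_complex(cl, kept, dg.ref.lengths, classified)
            recon.append({"svs": rep.cluster_svs, "attempted": rep.attempted,
                          "walks": rep.walks, "orphans": rep.orphans,
                          "note": rep.note})
        summary = {
            "scenario": config.scenario,
            "seed": config.seed,
            "purity": truth.purity,
            "n_reads": len(reads),
            "census": census,
            "n_templated_insertions": n_ti,
            "mechanism": mech_summary,
            "n_clusters": len(clusters),
            "cluster_sizes": sorted((len(c.sv_ids) for c in clusters), reverse=True),
            "verdicts": {f"{v.sv_a}|{v.sv_b}": v.verdict for v in verdicts},
            "cnv_fractions": fractions,
            "hom_del_present": any(s.q == 0 for s in classified),
            "breakpoint_concordance": concord,
            "reconstructions": recon,
        }
    except Exception as err:
        raise RuntimeError(
            f"pipeline stage {stage!r} failed (reproduce with: svlandscape run-all "
            f"--scenario {config.scenario} --seed {config.seed}): {err}") from err

    with open(os.path.join(config.outdir, "summary.json"), "w") as fh:
        json.dump(_json_ready(summary), fh, indent=1, sort_keys=True)
    return summary
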