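"""End-to-end pipeline driver.

Stage order follows the experimental workflow: simulate (or ingest) ->
align -> call -> filter -> profile -> differential (cytosines, islands,
tissue-specific) -> integrate with expression.  Every stage reads its inputs
from the run directory and writes its outputs there, so stages can be re-run
individually; a JSON manifest records parameters and content hashes.  All
outputs are deterministic for a fixed seed (no timestamps anywhere).
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import bsalign, diffmeth, filtering, integrate, io, profiles, simdata
from .config import PipelineConfig, save_config

log = logging.getLogger("rrbskit.pipeline")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


class PipelineRun:
    """Stage book-keeping over one output directory."""

    def __init__(self, config: PipelineConfig):
        self.config = config
        self.outdir = Path(config.outdir)
        self.outdir.mkdir(parents=True, exist_ok=True)
        self.manifest = {"tool": io.TOOL_TAG, "seed": config.seed, "stages": {}}
        self._dirty = False  # set once any stage recomputes

    def path(self, name: str) -> Path:
        return self.outdir / name

    def stage(self, name, outputs, func, params=None):
        paths = [self.path(p) for p in outputs]
        if not self._dirty and all(p.exists() for p in paths):
            log.info("stage %s: outputs present, skipped", name)
        else:
            log.info("stage %s: running", name)
            func()
            self._dirty = True
            missing = [p for p in paths if not p.exists()]
            if missing:
                self._write_manifest(failed=name)
                raise RuntimeError(f"stage {name} did not produce {missing}")
        self.manifest["stages"][name] = {
            "params": params or {},
            "outputs": {p.name: _sha256(p) for p in paths},
        }

    def _write_manifest(self, failed=None):
        m = dict(self.manifest)
        if failed:
            m["failed_stage"] = failed
        # stage insertion order is meaningful; don't sort
        self.path("manifest.json").write_text(json.dumps(m, indent=1) + "\n")


def run_pipeline(config: PipelineConfig) -> Path:
    """Run (or resume) the full pipeline; returns the output directory."""
    cfg = config
    cfg.simulation.seed = cfg.seed
    run = PipelineRun(cfg)
    samples = list(cfg.simulation.samples)
    # resolved config is recorded path-independently (outdir is environmental)
    import dataclasses as _dc

    save_config(_dc.replace(cfg, outdir="."), run.path("config_resolved.yaml"))

    # -- simulate -----------------------------------------------------------
    def do_simulate():
        genome = simdata.generate_genome(cfg.simulation)
        io.write_annotation(run.outdir, genome)
        landscape = simdata.sample_landscape(genome, cfg.simulation)
        truth = landscape.sites.copy()
        truth["true_prob"] = landscape.base_prob
        io.write_tsv(run.path("landscape_truth.tsv"), truth)
        shift_rows = []
        for s, (idx, vals) in sorted(landscape.sample_shifts.items()):
            for i, v in zip(idx, vals):
                shift_rows.append({
                    "sample": s, "chrom": truth["chrom"].iat[i],
                    "pos": int(truth["pos"].iat[i]), "strand": truth["strand"].iat[i],
                    "true_prob": v,
                })
        io.write_tsv(run.path("landscape_shifts.tsv"),
                     pd.DataFrame(shift_rows, columns=["sample", "chrom", "pos",
                                                       "strand", "true_prob"]))
        fragments = simdata.mspi_digest(genome, cfg.simulation.size_range)
        log.info("%d fragments retained by size selection", len(fragments))
        for s in samples:
            reads, sidecar = simdata.simulate_reads(
                fragments, landscape, cfg.simulation, s, genome)
            io.write_fastq(run.path(f"reads_{s}.fastq.gz"), reads)
            io.write_tsv(run.path(f"sidecar_{s}.tsv.gz"), sidecar)
        expr, meta = simdata.simulate_expression(genome, landscape, cfg.simulation)
        io.write_expression(run.path("expression.tsv"), expr.reset_index())
        io.write_tsv(run.path("expression_meta.tsv"), meta.reset_index())

    sim_outputs = (["genome.fa", "genes.bed", "cg_islands.bed", "repeats.bed",
                    "genome_meta.json", "landscape_truth.tsv", "landscape_shifts.tsv",
                    "expression.tsv", "expression_meta.tsv"]
                   + [f"reads_{s}.fastq.gz" for s in samples]
                   + [f"sidecar_{s}.tsv.gz" for s in samples])
    run.stage("simulate", sim_outputs, do_simulate,
              {"seed": cfg.seed, "n_samples": len(samples)})

    # -- align + call -------------------------------------------------------
    def do_call():
        genome = io.read_annotation(run.outdir)
        index = bsalign.build_index(genome, cfg.simulation.read_length)
        conv = {}
        for s in samples:
            reads = list(io.read_fastq(run.path(f"reads_{s}.fastq.gz")))
            alignments, stats = bsalign.map_reads(reads, index)
            report = bsalign.call_cytosines(alignments, reads, genome)
            io.write_report(run.path(f"report_{s}.tsv.gz"), report,
                            params={"sample": s})
            conv[s] = {
                "conversion_rate": bsalign.estimate_conversion_rate(
                    report, genome.spike_in),
                **stats,
            }
            log.info("sample %s: %d/%d reads unique", s, stats["unique"], stats["total"])
        io.write_json(run.path("alignment_summary.json"), conv)

    run.stage("call", [f"report_{s}.tsv.gz" for s in samples]
              + ["alignment_summary.json"], do_call,
              {"read_length": cfg.simulation.read_length})

    # -- filter -------------------------------------------------------------
    def do_filter():
        reports = {s: io.read_report(run.path(f"report_{s}.tsv.gz")) for s in samples}
        scan = filtering.threshold_stability_scan(
            reports, cfg.scan_thresholds, cfg.sd_threshold)
        scan_df = pd.DataFrame({
            "threshold": scan.thresholds,
            "usable": [scan.usable.get(t, False) for t in scan.thresholds],
            "n_stable_sites": [scan.n_sites.get(t, 0) for t in scan.thresholds],
            "stability_vs_prev": [scan.stability.get(t, np.nan) for t in scan.thresholds],
        })
        io.write_tsv(run.path("threshold_scan.tsv"), scan_df,
                     params={"recommended": scan.recommended})
        if scan.recommended is not None:
            io.write_newick(run.path("threshold_scan_tree.nwk"),
                            scan.newick(scan.recommended))
        else:
            io.write_newick(run.path("threshold_scan_tree.nwk"), ";")
        for s in samples:
            io.write_report(run.path(f"filtered_{s}.tsv.gz"),
                            filtering.filter_coverage(reports[s], cfg.min_cov),
                            params={"min_cov": cfg.min_cov})

    run.stage("filter", [f"filtered_{s}.tsv.gz" for s in samples]
              + ["threshold_scan.tsv", "threshold_scan_tree.nwk"], do_filter,
              {"min_cov": cfg.min_cov, "sd_threshold": cfg.sd_threshold})

    # -- profile ------------------------------------------------------------
    def do_profile():
        genome = io.read_annotation(run.outdir)
        reports = {s: io.read_report(run.path(f"filtered_{s}.tsv.gz")) for s in samples}
        matrix = filtering.build_matrix(reports)

        glob_rows = []
        for s in samples:
            rep = reports[s]
            for ctx in ("CG", "CHG", "CHH"):
                try:
                    glob_rows.append({"sample": s, "context": ctx,
                                      "mean_level": profiles.global_level(rep, ctx)})
                except ValueError:
                    pass
        io.write_tsv(run.path("global_levels.tsv"), pd.DataFrame(glob_rows))

        # merged view: per-site mean level over samples with data
        merged = matrix.sites.copy()
        with np.errstate(invalid="ignore"):
            merged["level"] = np.nanmean(matrix.levels, axis=1)
        chrom_lengths = {c: len(seq) for c, seq in genome.chromosomes.items()}
        io.write_tsv(run.path("density_windows.tsv"),
                     profiles.density_windows(merged, 20000, chrom_lengths))
        for ctx, tag in (("CG", "cg"), ("CHH", "chh")):
            sub = merged[merged["context"] == ctx]
            prof = profiles.metagene_profile(
                sub, genome.genes, cfg.flank_bp, cfg.flank_bins, cfg.body_bins)
            io.write_tsv(run.path(f"metagene_{tag}.tsv"), pd.DataFrame({
                "bin": prof.bin_labels, "mean_level": prof.mean_level,
                "n_sites": prof.site_count}))
            prof = profiles.cgi_profile(
                sub, genome.cg_islands, cfg.flank_bp, cfg.flank_bins, cfg.body_bins)
            io.write_tsv(run.path(f"cgi_profile_{tag}.tsv"), pd.DataFrame({
                "bin": prof.bin_labels, "mean_level": prof.mean_level,
                "n_sites": prof.site_count}))
        io.write_tsv(run.path("compartment_summary.tsv"),
                     profiles.compartment_summary(merged, genome))
        curve = profiles.autocorrelation(merged[merged["context"] == "CG"],
                                         ("CG", "CG"), "same", 50)
        io.write_tsv(run.path("autocorrelation_cg.tsv"), pd.DataFrame({
            "distance": curve.distances, "r": curve.r, "n_pairs": curve.n_pairs}))
        corr, _linkage, newick = profiles.sample_similarity(matrix)
        io.write_tsv(run.path("sample_correlation.tsv"), corr.reset_index(names="sample"))
        io.write_newick(run.path("sample_tree.nwk"), newick)

    run.stage("profile",
              ["global_levels.tsv", "density_windows.tsv", "metagene_cg.tsv",
               "metagene_chh.tsv", "cgi_profile_cg.tsv", "cgi_profile_chh.tsv",
               "compartment_summary.tsv", "autocorrelation_cg.tsv",
               "sample_correlation.tsv", "sample_tree.nwk"],
              do_profile, {"flank_bp": cfg.flank_bp})

    # -- differential -------------------------------------------------------
    def do_differential():
        genome = io.read_annotation(run.outdir)
        reports = {s: io.read_report(run.path(f"filtered_{s}.tsv.gz")) for s in samples}
        dmc_records = diffmeth.call_dmcs(
            reports, cfg.diff_cutoff, cfg.q_cutoff, cfg.min_cov)
        io.write_tsv(run.path("dmc_records.tsv"),
                     diffmeth.records_to_frame(dmc_records))
        summaries = {s: diffmeth.summarize_islands(reports[s], genome.cg_islands,
                                                   s, cfg.min_cg)
                     for s in samples}
        isl_rows = [{
            "sample": s, "chrom": im.region.chrom, "start": im.region.start,
            "end": im.region.end, "n_detected_cg": im.n_detected_cg,
            "mean_level": im.mean_level, "count_meth": im.count_meth,
            "count_unmeth": im.count_unmeth,
        } for s in samples for im in summaries[s]]
        io.write_tsv(run.path("island_levels.tsv"),
                     pd.DataFrame(isl_rows, columns=[
                         "sample", "chrom", "start", "end", "n_detected_cg",
                         "mean_level", "count_meth", "count_unmeth"]))
        dmi_records = diffmeth.call_dmis(summaries, cfg.diff_cutoff, cfg.q_cutoff)
        io.write_tsv(run.path("dmi_records.tsv"),
                     diffmeth.records_to_frame(dmi_records))
        tdmc = diffmeth.tissue_specific(dmc_records, samples)
        tdmi = diffmeth.tissue_specific(dmi_records, samples)
        rows = [{"kind": k[0], "chrom": k[1], "start": k[2], "end": k[3],
                 "strand": k[4], "context": k[5], "sample": s}
                for k, s in sorted({**tdmc, **tdmi}.items())]
        io.write_tsv(run.path("tissue_specific.tsv"),
                     pd.DataFrame(rows, columns=["kind", "chrom", "start", "end",
                                                 "strand", "context", "sample"]))
        log.info("%d DMC records, %d DMI records, %d tissue-specific features",
                 len(dmc_records), len(dmi_records), len(rows))

    run.stage("differential",
              ["dmc_records.tsv", "island_levels.tsv", "dmi_records.tsv",
               "tissue_specific.tsv"],
              do_differential,
              {"diff": cfg.diff_cutoff, "q": cfg.q_cutoff, "min_cg": cfg.min_cg})

    # -- integrate ----------------------------------------------------------
    def do_integrate():
        genome = io.read_annotation(run.outdir)
        reports = {s: io.read_report(run.path(f"filtered_{s}.tsv.gz")) for s in samples}
        matrix = filtering.build_matrix(reports)
        expression = io.read_expression(run.path("expression.tsv"))
        dmc = io.read_tsv(run.path("dmc_records.tsv"))
        dmi = io.read_tsv(run.path("dmi_records.tsv"))

        site_index = pd.MultiIndex.from_frame(
            matrix.sites[["chrom", "pos", "strand"]])
        level_df = pd.DataFrame(matrix.levels, index=site_index,
                                columns=matrix.samples)
        feat_rows, assignments = {}, []
        if len(dmc):
            for key in set(zip(dmc["chrom"], dmc["start"], dmc["strand"])):
                chrom, pos, strand = key
                fid = f"c:{chrom}:{pos}:{strand}"
                if key in level_df.index:
                    feat_rows[fid] = level_df.loc[key]
                    for gene, rc in integrate.assign_region(
                            ("cytosine", chrom, pos, pos + 1), genome.genes,
                            cfg.promoter_bp):
                        assignments.append((fid, gene, rc))
        isl = io.read_tsv(run.path("island_levels.tsv"))
        if len(dmi):
            isl_lv = isl.pivot_table(index=["chrom", "start", "end"],
                                     columns="sample", values="mean_level")
            for key in set(zip(dmi["chrom"], dmi["start"], dmi["end"])):
                fid = f"i:{key[0]}:{key[1]}-{key[2]}"
                if key in isl_lv.index:
                    feat_rows[fid] = isl_lv.loc[key].reindex(matrix.samples)
                    for gene, rc in integrate.assign_region(
                            ("island", *key), genome.genes, cfg.promoter_bp):
                        assignments.append((fid, gene, rc))
        feature_levels = pd.DataFrame(feat_rows).T
        if len(feature_levels):
            feature_levels.columns = matrix.samples
        results = integrate.correlate_expression(
            feature_levels, sorted(assignments), expression, cfg.integration_q)
        io.write_tsv(run.path("correlation_results.tsv"),
                     integrate.results_to_frame(results))
        io.write_tsv(run.path("correlation_signs.tsv"),
                     integrate.sign_by_region(results))

    run.stage("integrate", ["correlation_results.tsv", "correlation_signs.tsv"],
              do_integrate, {"q": cfg.integration_q,
                             "promoter_bp": cfg.promoter_bp})

    run._write_manifest()
    return run.outdir
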