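"""End-to-end orchestration of the analysis stages.

``run_pipeline`` executes the enabled stages in dependency order
(simulate -> dupexon / sexassign / pooldiv / segment / ancestry), writing
each stage's outputs plus the resolved configuration under
``config.out_dir`` and returning a :class:`RunReport` whose per-stage
record counts satisfy in = out + filtered for every filtering step.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import ancestry, dupexon, io, pooldiv, sexassign, synthetic
from .config import PipelineConfig

__all__ = ["RunReport", "StageRecord", "run_pipeline"]

logger = logging.getLogger("asmqc")


@dataclass
class StageRecord:
    stage: str
    n_in: int
    n_out: int
    n_filtered: int
    runtime_s: float
    details: dict = field(default_factory=dict)

    def conserved(self) -> bool:
        return self.n_in == self.n_out + self.n_filtered


@dataclass
class RunReport:
    stages: list[StageRecord] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    def add(self, record: StageRecord) -> None:
        if not record.conserved():
            raise AssertionError(
                f"count conservation violated in stage {record.stage}: "
                f"{record.n_in} != {record.n_out} + {record.n_filtered}"
            )
        self.stages.append(record)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(s.stage, s.n_in, s.n_out, s.n_filtered, s.runtime_s) for s in self.stages],
            columns=["stage", "n_in", "n_out", "n_filtered", "runtime_s"],
        )


def _require(path: str | None, stage: str, what: str) -> str:
    if path is None:
        raise FileNotFoundError(f"stage {stage!r} enabled but no {what} input configured")
    if not Path(path).exists():
        raise FileNotFoundError(f"stage {stage!r}: missing {what} input {path}")
    return path


def run_pipeline(config: PipelineConfig) -> RunReport:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "resolved_config.yaml")
    logger.info("resolved configuration (every applied threshold) written to %s",
                out / "resolved_config.yaml")
    report = RunReport()

    # fail before any stage runs if a required input is missing
    if not config.run_simulate:
        if config.run_dupexon:
            _require(config.fasta, "dupexon", "FASTA")
            _require(config.gff3, "dupexon", "GFF3")
        if config.run_sexassign:
            _require(config.female_depth, "sexassign", "female depth TSV")
            _require(config.male_depth, "sexassign", "male depth TSV")
        if config.run_pooldiv:
            _require(config.pool_counts, "pooldiv", "pool count TSV")
        if config.run_ancestry:
            _require(config.aims, "ancestry", "two-pool count TSV")
        if config.run_segment and config.rate_track is None and not config.run_pooldiv:
            raise FileNotFoundError(
                "stage 'segment' enabled but no rate track configured and pooldiv disabled"
            )

    paths = {
        "fasta": config.fasta,
        "gff3": config.gff3,
        "female_depth": config.female_depth,
        "male_depth": config.male_depth,
        "pool_counts": config.pool_counts,
        "aims": config.aims,
        "contig_classes": config.contig_classes,
    }

    if config.run_simulate:
        t0 = time.perf_counter()
        contigs, exons, truth_genome = synthetic.gen_genome_with_duplications(
            n_contigs=config.n_contigs,
            contig_length=config.contig_length,
            n_exons=config.n_exons,
            n_planted=config.n_planted,
            dup_length=config.dup_length,
            seed=config.seed,
        )
        io.write_fasta(contigs, out / "genome.fasta")
        io.write_exons_gff3(exons, out / "exons.gff3")
        truth_genome.to_json(out / "truth_genome.json")

        classes = {
            f"cov_{i+1}": ("X" if i < config.n_cov_x else "autosome")
            for i in range(config.n_cov_contigs)
        }
        tracks_f, tracks_m, truth_cov = synthetic.gen_sex_coverage(
            classes,
            config.cov_contig_length,
            mean_depth_f=config.mean_depth_f,
            mean_depth_m=config.mean_depth_m,
            dispersion=config.dispersion,
            seed=config.seed + 1,
        )
        io.write_depth_tsv(tracks_f.values(), out / "depth_female.tsv")
        io.write_depth_tsv(tracks_m.values(), out / "depth_male.tsv")
        io.write_contig_classes_tsv(classes, out / "contig_classes.tsv")
        truth_cov.to_json(out / "truth_coverage.json")

        pool_df, truth_pool = synthetic.gen_pool_counts(
            theta_true=config.theta_true,
            n_pool=config.pool_size,
            mean_depth=config.pool_mean_depth,
            n_sites=config.n_sites,
            seed=config.seed + 2,
        )
        io.write_pool_counts_tsv(pool_df, out / "pool_counts.tsv")
        truth_pool.to_json(out / "truth_pool.json")

        aims_df, truth_mosaic = synthetic.gen_ancestry_mosaic(
            n_aims=config.n_aims,
            switch_prob=config.switch_prob,
            alpha_target=config.alpha_target,
            freq_divergence=config.freq_divergence,
            depth=config.aim_depth,
            seed=config.seed + 3,
        )
        io.write_aims_tsv(aims_df, out / "aim_counts.tsv")
        truth_mosaic.to_json(out / "truth_mosaic.json")

        paths = {
            "fasta": str(out / "genome.fasta"),
            "gff3": str(out / "exons.gff3"),
            "female_depth": str(out / "depth_female.tsv"),
            "male_depth": str(out / "depth_male.tsv"),
            "pool_counts": str(out / "pool_counts.tsv"),
            "aims": str(out / "aim_counts.tsv"),
            "contig_classes": str(out / "contig_classes.tsv"),
        }
        report.add(
            StageRecord("simulate", 0, 0, 0, time.perf_counter() - t0,
                        details={"n_exons": len(exons)})
        )

    classes = (
        io.read_contig_classes_tsv(paths["contig_classes"])
        if paths.get("contig_classes")
        else {}
    )

    if config.run_dupexon:
        t0 = time.perf_counter()
        exons = io.load_exons(paths["fasta"], paths["gff3"])
        pairs = dupexon.neighboring_pairs(exons, max_gap=config.max_gap)
        scored, tr_counts, gene_counts = dupexon.scan_assembly(
            exons,
            max_gap=config.max_gap,
            score_threshold=config.score_threshold,
            min_coverage=config.min_coverage,
            max_evalue=config.max_evalue,
        )
        flagged = [s for s in scored if s.flagged]
        pd.DataFrame(
            [(s.exon_a, s.exon_b, s.gap, s.coverage_frac, s.local_significance,
              s.norm_score, s.flagged) for s in scored],
            columns=["exon_a", "exon_b", "gap", "coverage_frac", "evalue",
                     "norm_score", "flagged"],
        ).to_csv(out / "dupexon_pairs.tsv", sep="\t", index=False)
        pd.DataFrame(
            sorted(gene_counts.items()), columns=["gene_id", "n_flagged_exons"]
        ).to_csv(out / "dupexon_gene_counts.tsv", sep="\t", index=False)
        report.add(
            StageRecord("dupexon", len(pairs), len(scored), len(pairs) - len(scored),
                        time.perf_counter() - t0, details={"n_flagged": len(flagged)})
        )

    if config.run_sexassign:
        t0 = time.perf_counter()
        tracks_f = io.read_depth_tsv(paths["female_depth"])
        tracks_m = io.read_depth_tsv(paths["male_depth"])
        table, fit = sexassign.assign_contigs(
            tracks_f, tracks_m,
            step=config.subsample_step,
            percentile_cut=config.percentile_cut,
            min_m=config.min_male_depth,
            min_f=config.min_female_depth,
            min_positions=config.min_positions,
            alpha_level=config.alpha_level,
        )
        table.to_csv(out / "sex_assignment.tsv", sep="\t", index=False)
        import json

        with open(out / "sex_gmm_fit.json", "w") as fh:
            json.dump(
                {"mu1": fit.mu1, "mu2": fit.mu2, "sigma": fit.sigma,
                 "weights": list(fit.weights), "n_iter": fit.n_iter},
                fh, indent=1,
            )
        n_filtered = int((table["class"] == "filtered").sum())
        report.add(
            StageRecord("sexassign", len(table), len(table) - n_filtered, n_filtered,
                        time.perf_counter() - t0,
                        details={"mu1": fit.mu1, "mu2": fit.mu2})
        )

    windows = None
    if config.run_pooldiv:
        t0 = time.perf_counter()
        pool_df = io.read_pool_counts_tsv(paths["pool_counts"])
        windows = pooldiv.theta_windows(
            pool_df,
            pool_size=config.pool_size,
            window=config.window,
            min_analyzed=config.min_analyzed,
            min_cov=config.min_cov,
            max_cov=config.max_cov,
            min_minor=config.min_minor,
        )
        windows.to_csv(out / "theta_windows.tsv", sep="\t", index=False)
        summary = pooldiv.summarize_by_class(windows, classes)
        summary.to_csv(out / "theta_by_class.tsv", sep="\t", index=False)
        n_dropped = int(windows["dropped"].sum())
        report.add(
            StageRecord("pooldiv", len(windows), len(windows) - n_dropped, n_dropped,
                        time.perf_counter() - t0)
        )

    if config.run_segment:
        t0 = time.perf_counter()
        if config.rate_track is not None:
            track_df = pd.read_csv(config.rate_track, sep="\t")
        elif windows is not None:
            track_df = windows.rename(columns={"theta_hat": "rate"})[
                ["contig", "start", "rate"]
            ]
        else:
            raise FileNotFoundError("segment stage needs a rate track or the pooldiv stage")
        regions: list[pooldiv.RateRegion] = []
        n_windows_in = 0
        for contig, grp in track_df.groupby("contig", sort=True):
            rates = grp.sort_values("start")["rate"].to_numpy()
            n_windows_in += len(rates)
            regions.extend(
                pooldiv.hysteresis_segment(
                    rates,
                    contig=str(contig),
                    open_thresh=config.open_thresh,
                    close_thresh=config.close_thresh,
                    run=config.run_length,
                    window=config.window,
                )
            )
        io.write_regions_bed(regions, out / "rate_regions.bed")
        report.add(
            StageRecord("segment", n_windows_in, n_windows_in, 0,
                        time.perf_counter() - t0, details={"n_regions": len(regions)})
        )

    if config.run_ancestry:
        t0 = time.perf_counter()
        aims_raw = io.read_aims_tsv(paths["aims"])
        keep = ancestry.biallelic_filter(
            aims_raw, min_depth=config.min_depth, max_depth=config.max_depth
        )
        aims = ancestry.aim_select(aims_raw.loc[keep], min_diff=config.min_diff)
        params, trace = ancestry.baum_welch(aims)
        result = ancestry.paint_and_summarize(aims, params, classes)
        io.write_segments_bed(result, out / "ancestry_segments.bed")
        posterior_rows = []
        for contig, gC in result.posteriors.items():
            pos = aims.loc[aims["contig"] == contig, "pos"].to_numpy()
            posterior_rows.append(
                pd.DataFrame({"contig": contig, "pos": pos, "posterior_C": gC})
            )
        pd.concat(posterior_rows).to_csv(out / "ancestry_posteriors.tsv", sep="\t", index=False)
        import json

        with open(out / "ancestry_alpha.json", "w") as fh:
            json.dump(
                {"alpha_per_class": result.alpha_per_class,
                 "alpha_sd_per_class": result.alpha_sd_per_class,
                 "tau": params.tau, "pi_C": params.pi_C},
                fh, indent=1,
            )
        report.add(
            StageRecord("ancestry", len(aims_raw), len(aims), int(len(aims_raw) - len(aims)),
                        time.perf_counter() - t0,
                        details={"tau": params.tau,
                                 "alpha": result.alpha_per_class})
        )

    for s in report.stages:
        logger.info("stage %s: in=%d out=%d filtered=%d (%.2fs)",
                    s.stage, s.n_in, s.n_out, s.n_filtered, s.runtime_s)
    report.to_frame().to_csv(out / "run_report.tsv", sep="\t", index=False)
    return report
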