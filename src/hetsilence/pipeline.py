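"""End-to-end orchestration of the synthetic-study reproduction.

Runs generate -> occupancy -> peaks/enrichment -> survival -> expression
-> imaging and writes the per-stage tables plus a run manifest.  The
whole run is deterministic under a fixed configuration (all stage seeds
live in the config and the config hash is recorded in the manifest).
"""
from __future__ import annotations

import dataclasses
import datetime
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, expression, imaging, io, occupancy, peaks, survival, synthetic
from .config import PipelineConfig
from .tracks import RegionSet, SignalTrack

log = logging.getLogger("hetsilence")

__all__ = ["RunManifest", "run_synthetic_study", "occupancy_stage", "peak_stage"]


@dataclass
class RunManifest:
    config_hash: str
    version: str
    started: str
    finished: str = ""
    outputs: dict = field(default_factory=dict)  # stage -> list of files

    def record(self, stage: str, *paths) -> None:
        self.outputs.setdefault(stage, []).extend(str(p) for p in paths)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def occupancy_stage(genome, cfg: PipelineConfig):
    """Noise -> robust z -> control subtraction for both conditions."""
    occ = {}
    for i, condition in enumerate(synthetic.CONDITIONS):
        tagged, untagged = synthetic.generate_occupancy_tracks(
            genome,
            condition,
            noise_sd=cfg.occupancy.noise_sd,
            seed=cfg.seeds["occupancy"] + i,
        )
        occ[condition] = occupancy.control_subtract(
            occupancy.robust_z(tagged), occupancy.robust_z(untagged)
        )
    return occ


def peak_stage(genome, occ: dict, cfg: PipelineConfig):
    """Call and classify peaks, then compute class-level enrichment."""
    called = {
        cond: peaks.call_peaks(
            peaks.rolling_mean(occ[cond], cfg.peaks.smooth_window),
            z_threshold=cfg.peaks.z_threshold,
            min_width=cfg.peaks.min_width,
            merge_gap=cfg.peaks.merge_gap,
        )
        for cond in synthetic.CONDITIONS
    }
    classified = peaks.classify_peaks(
        called["wt"], called["dppk"], min_overlap_frac=cfg.peaks.min_overlap_frac
    )
    by_class = {
        cls: [p for p in classified if p.peak_class == cls]
        for cls in peaks.PEAK_CLASSES
    }
    window = cfg.enrichment.window
    metric_tracks = {
        "AT": peaks.at_content_track(genome.sequence, window),
        "HNS": peaks.rolling_mean(genome.hns_track, window),
    }
    results = []
    for mi, (metric, track) in enumerate(metric_tracks.items()):
        for ci, cls in enumerate(peaks.PEAK_CLASSES):
            members = by_class[cls]
            fc = peaks.class_log2fc(track, members)
            if members:
                p = peaks.permutation_test(
                    members,
                    track,
                    n_perm=cfg.enrichment.n_perm,
                    seed=cfg.seeds["permutation"] + 10 * mi + ci,
                )
            else:
                p = None
            results.append(
                peaks.EnrichmentResult(cls, metric, fc, p, cfg.enrichment.n_perm)
            )
    motif_hits = peaks.scan_motif(genome.sequence, cfg.enrichment.motif_consensus)
    results.extend(peaks.motif_log2_enrichment(by_class, motif_hits))
    return called, classified, by_class, results


def _enrichment_frame(results) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "class": r.class_label,
                "metric": r.metric,
                "log2fc": r.log2fc,
                "p_perm": r.p_perm,
                "n_perm": r.n_perm,
            }
            for r in results
        ]
    )


def run_synthetic_study(config: PipelineConfig, output_dir=None) -> RunManifest:
    """Execute the full synthetic study; returns the run manifest."""
    cfg = config.validate()
    outdir = Path(output_dir if output_dir is not None else cfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        config_hash=cfg.config_hash(),
        version=__version__,
        started=datetime.datetime.now().isoformat(timespec="seconds"),
    )

    # --- stage: generate ---------------------------------------------------
    log.info("stage generate: genome of %d bp", cfg.genome.genome_length)
    genome = synthetic.generate_genome(
        dataclasses.replace(cfg.genome, seed=cfg.seeds["genome"])
    )
    fasta = outdir / "genome.fa"
    bed = outdir / "epods.bed"
    io.write_fasta(fasta, "synthetic_chr", genome.sequence)
    io.write_bed(bed, genome.epods)
    manifest.record("generate", fasta, bed)

    # --- stage: occupancy --------------------------------------------------
    log.info("stage occupancy: robust z + control subtraction")
    occ = occupancy_stage(genome, cfg)
    for cond, track in occ.items():
        path = outdir / f"occupancy_{cond}.bedgraph"
        io.write_bedgraph(path, track)
        manifest.record("occupancy", path)
    classes = occupancy.classify_bins(
        genome.epods, cfg.genome.genome_length, cfg.occupancy.bin_size
    )
    summaries = occupancy.compare_class_occupancy(occ["wt"], occ["dppk"], classes)
    occ_table = pd.DataFrame(
        [
            {
                "class": s.class_label,
                "mean_wt": s.mean_occupancy["wt"],
                "mean_dppk": s.mean_occupancy["dppk"],
                "n_bins": s.n_bins,
                "p_wilcoxon": s.p_wilcoxon,
                "q_bh": s.q_bh,
            }
            for s in summaries
        ]
    )
    occ_path = outdir / "occupancy_classes.tsv"
    occ_table.to_csv(occ_path, sep="\t", index=False)
    manifest.record("occupancy", occ_path)

    # --- stage: peaks / enrichment -----------------------------------------
    log.info("stage peaks: calling, classification and enrichment")
    called, classified, by_class, enrich = peak_stage(genome, occ, cfg)
    peaks_path = outdir / "peaks.bed"
    with open(peaks_path, "w") as fh:
        for p in classified:
            fh.write(f"chr\t{p.start}\t{p.end}\t{p.peak_class}\t0\t.\n")
    enrich_path = outdir / "enrichment.tsv"
    _enrichment_frame(enrich).to_csv(enrich_path, sep="\t", index=False)
    manifest.record("peaks", peaks_path, enrich_path)

    # --- stage: survival ----------------------------------------------------
    log.info("stage survival: Bayesian Poisson fits per genotype")
    rows = []
    all_obs = []
    for gi, (genotype, delta) in enumerate(sorted(cfg.survival.delta_by_genotype.items())):
        obs = synthetic.generate_plating_counts(
            [cfg.survival.upsilon] * cfg.survival.n_replicates,
            delta,
            [cfg.survival.phi_untreated],
            seed=cfg.seeds["survival"] + gi,
            genotype=genotype,
            stress=cfg.survival.stress,
        )
        # treated arm needs a shallower dilution to keep counts countable
        obs = [o for o in obs if o.arm == "untreated"] + [
            dataclasses.replace(
                o, phi=cfg.survival.phi_treated
            )
            for o in synthetic.generate_plating_counts(
                [cfg.survival.upsilon] * cfg.survival.n_replicates,
                delta,
                [cfg.survival.phi_treated],
                seed=cfg.seeds["survival"] + 100 + gi,
                genotype=genotype,
                stress=cfg.survival.stress,
            )
            if o.arm == "treated"
        ]
        all_obs.extend(obs)
        post = survival.fit_survival_model(
            obs, dataclasses.replace(cfg.sampler, seed=cfg.sampler.seed + gi)
        )
        row = post.summary()
        row["delta_true"] = delta
        rows.append(row)
    counts_path = outdir / "plating_counts.tsv"
    io.write_plating_tsv(counts_path, all_obs)
    surv_table = pd.DataFrame(rows)
    surv_path = outdir / "survival_summary.tsv"
    surv_table.drop(columns=["upsilon_mean"]).to_csv(surv_path, sep="\t", index=False)
    manifest.record("survival", counts_path, surv_path)

    # --- stage: expression ---------------------------------------------------
    log.info("stage expression: shift tests and genotype correlations")
    table = synthetic.generate_expression_table(
        cfg.expression.n_genes,
        cfg.expression.mge_fraction,
        cfg.expression.shift_mge,
        cfg.expression.noise_sd,
        seed=cfg.seeds["expression"],
    )
    expr_rows = []
    for contrast in cfg.expression.shift_mge:
        u, p = expression.mge_shift_test(table, contrast)
        expr_rows.append({"contrast": contrast, "U": u, "p_mannwhitney": p})
    expr_path = outdir / "expression_shift.tsv"
    pd.DataFrame(expr_rows).to_csv(expr_path, sep="\t", index=False)
    contrasts = list(cfg.expression.shift_mge)
    corr_paths = []
    if len(contrasts) >= 2:
        for cat in expression.GENE_CATEGORIES:
            rho, _ = expression.genotype_spearman(table, cat, contrasts)
            path = outdir / f"spearman_{cat}.tsv"
            rho.to_csv(path, sep="\t")
            corr_paths.append(path)
    gene_path = outdir / "gene_table.tsv"
    table.to_csv(gene_path, sep="\t", index=False)
    manifest.record("expression", gene_path, expr_path, *corr_paths)

    # --- stage: imaging -------------------------------------------------------
    log.info("stage imaging: nucleoid occupancy and FRAP fits")
    cells = []
    for gi, (genotype, mean) in enumerate(
        sorted(cfg.imaging.occupancy_by_genotype.items())
    ):
        cells.extend(
            synthetic.generate_cell_measurements(
                cfg.imaging.n_cells,
                mean,
                cfg.imaging.occupancy_sd,
                seed=cfg.seeds["imaging"] + gi,
                genotype=genotype,
            )
        )
    ratios, means = imaging.chromosome_occupancy(cells)
    wt_vals = ratios.loc[ratios.genotype == "wt", "occupancy"].to_numpy()
    img_rows = []
    for gi, genotype in enumerate(sorted(cfg.imaging.occupancy_by_genotype)):
        vals = ratios.loc[ratios.genotype == genotype, "occupancy"].to_numpy()
        lo, hi = imaging.bootstrap_ci(
            vals, n_boot=2000, seed=cfg.seeds["imaging"] + 1000 + gi
        )
        p = (
            float("nan")
            if genotype == "wt"
            else imaging.wilcoxon_vs_wt(vals, wt_vals)
        )
        img_rows.append(
            {
                "genotype": genotype,
                "mean_occupancy": float(vals.mean()),
                "ci_lo": lo,
                "ci_hi": hi,
                "p_vs_wt": p,
            }
        )
    cells_path = outdir / "cell_measurements.tsv"
    io.write_cells_tsv(cells_path, cells)
    img_path = outdir / "nucleoid_occupancy.tsv"
    pd.DataFrame(img_rows).to_csv(img_path, sep="\t", index=False)

    frap_rows = []
    for i in range(cfg.imaging.frap_n_traces):
        trace = synthetic.generate_frap_trace(
            cfg.imaging.frap_y0,
            cfg.imaging.frap_plateau,
            cfg.imaging.frap_t_half,
            cfg.imaging.frap_dt,
            cfg.imaging.frap_duration,
            cfg.imaging.frap_noise_cv,
            seed=cfg.seeds["imaging"] + 2000 + i,
        )
        fit = imaging.fit_frap_trace(trace)
        frap_rows.append(
            {"trace": i, "t_half": fit.t_half, "k": fit.k, "plateau": fit.plateau,
             "y0": fit.y0, "r2": fit.r2}
        )
    frap_path = outdir / "frap_fits.tsv"
    pd.DataFrame(frap_rows).to_csv(frap_path, sep="\t", index=False)
    manifest.record("imaging", cells_path, img_path, frap_path)

    manifest.finished = datetime.datetime.now().isoformat(timespec="seconds")
    io.write_json(outdir / "manifest.json", manifest.to_dict())
    manifest.record("manifest", outdir / "manifest.json")
    missing = [
        f for files in manifest.outputs.values() for f in files if not Path(f).exists()
    ]
    if missing:  # pragma: no cover - defensive
        raise RuntimeError(f"manifest lists missing outputs: {missing}")
    return manifest
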