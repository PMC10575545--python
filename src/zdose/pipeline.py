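"""End-to-end orchestration: simulate or load a study, run every enabled
analysis stage in dependency order, and write a reproducible report.

All stage thresholds default to the study values and are echoed into the
report manifest for provenance; the master seed is fanned out into named
substreams per stage, so reruns with identical config and seed give
byte-identical outputs.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from zdose import atac, expression, io, methylation, par, scan
from zdose.datamodel import GenomeLayout, ValidationError
from zdose.simulate import SimulationConfig, substream
from zdose import simulate as sim

logger = logging.getLogger(__name__)

DEFAULT_THRESHOLDS = {
    "zfpkm_threshold": -3.0,
    "mean_fpkm_min": 1.0,
    "balance_scheme": "four",
    "ortho_min_overlap": 0.5,
    "ortho_min_samples": 2,
    "consensus_share": 0.8,
    "consensus_merge_overlap": 0.5,
    "cpm_min": 1.0,
    "cpm_min_samples": 7,
    "meth_min_cov": 10,
    "island_min_len": 250,
    "island_gc_min": 0.60,
    "island_oe_min": 0.75,
    "window_size": 688_000,
    "window_step": 344_000,
    "gene_window_k": 15,
    "n_boot": 10_000,
    "par_min_separation": 0.5,
}


def run_pipeline(config: dict, seed: int = 0, out_dir: str = "results/pipeline"
                 ) -> dict:
    """Run the enabled stages over a simulated (or loaded) study.

    ``config`` keys: ``simulate`` (SimulationConfig kwargs; required unless
    ``paths`` provides input files), ``stages`` (list among
    expression/atac/methylation/scan/par; default all), ``thresholds``
    (overrides of :data:`DEFAULT_THRESHOLDS`). Returns the report manifest.
    """
    thresholds = dict(DEFAULT_THRESHOLDS)
    thresholds.update(config.get("thresholds", {}))
    stages = config.get("stages",
                        ["expression", "atac", "methylation", "scan", "par"])
    results: dict = {}

    if "paths" in config:
        layout = io.read_layout(config["paths"]["layout"])
        data = io.load_dataset(
            {k: v for k, v in config["paths"].items() if k != "layout"}, layout,
            expression_unit=config.get("expression_unit", "counts"),
        )
        for stage in stages:
            _check_stage_inputs(stage, data)
        study = dict(data)
        study.setdefault("islands", pd.DataFrame(columns=["chrom", "start", "end"]))
    else:
        sim_kwargs = config.get("simulate")
        if sim_kwargs is None:
            study = sim.small_study(seed=seed)
        else:
            study = _full_sim(SimulationConfig(**{**sim_kwargs, "seed": seed}))
    layout: GenomeLayout = study["layout"]
    genes = study["genes"]
    samples = study["samples"]

    log2fm = None
    if "expression" in stages and "expression" in study:
        counts = study["expression"]
        fpkm = expression.compute_fpkm(counts) if counts.unit == "counts" else counts
        expressed = expression.mean_fpkm_filter(
            fpkm, samples, min_mean=thresholds["mean_fpkm_min"]
        )
        fm, n_excluded = expression.gene_fm_ratio(
            fpkm.values.loc[expressed], samples
        )
        logger.info("expression: %d genes pass mean-FPKM filter, %d unevaluable",
                    len(expressed), n_excluded)
        balance = expression.classify_balance_table(
            fm, scheme=thresholds["balance_scheme"]
        )
        results["balance_classification"] = balance
        log2fm = fm
        chrom_map = genes.set_index("gene_id")["chrom"]
        med_f = fpkm.values.loc[
            expressed, samples.loc[samples["sex"] == "F", "sample_id"]
        ].median(axis=1)
        med_m = fpkm.values.loc[
            expressed, samples.loc[samples["sex"] == "M", "sample_id"]
        ].median(axis=1)
        za = {
            "Zf_AAf": expression.za_ratio(
                med_f, chrom_map, layout.sex_chromosome, mode="linear")["pooled"],
            "ZZm_AAm": expression.za_ratio(
                med_m, chrom_map, layout.sex_chromosome, mode="linear")["pooled"],
        }
        nonpar = layout.is_nonpar_z(
            chrom_map.reindex(fm.index),
            genes.set_index("gene_id")["start"].reindex(fm.index))
        z_fm = fm[np.asarray(nonpar)].dropna()
        est = expression.bootstrap_ratio_ci(
            z_fm.to_numpy(), n_boot=thresholds["n_boot"],
            seed=int(substream(seed, "expr_boot").integers(2 ** 31)),
            label="Zf:ZZm_log2", scale="log2",
        )
        results["ratio_estimates"] = [est]
        results["za_ratios"] = za

    ortho = None
    if "atac" in stages and "peaks" in study:
        ortho = atac.build_orthologous_peaks(
            study["peaks"],
            min_overlap_frac=thresholds["ortho_min_overlap"],
            min_samples=thresholds["ortho_min_samples"],
        )
        links = atac.link_clusters_to_genes(ortho, genes, scope="gene_centred")
        per_gene, summary = atac.peak_height_fm_ratio(
            ortho, samples, links=links, by="gene",
            n_boot=thresholds["n_boot"],
            seed=int(substream(seed, "atac_boot").integers(2 ** 31)),
        )
        results["peak_fm_ratios"] = per_gene.rename_axis("gene_id").reset_index()
        if summary is not None:
            results.setdefault("ratio_estimates", []).append(summary)
        logger.info("atac: %d orthologous clusters, %d gene links",
                    len(ortho.clusters), len(links))

    if "methylation" in stages and "methylation" in study:
        feats = genes.rename(columns={"gene_id": "feature_id"})[
            ["feature_id", "chrom", "start", "end"]
        ]
        mats = methylation.feature_methylation_matrix(
            study["methylation"], feats, min_cov=thresholds["meth_min_cov"]
        )
        meth_samples = samples[
            samples["sample_id"].isin(mats["proportion"].columns)
        ]
        dml = methylation.beta_binomial_dml(
            mats["n_meth"], mats["n_total"], meth_samples
        )
        results["dml_table"] = dml
        logger.info("methylation: %d features tested", int(dml["p"].notna().sum()))

    if "scan" in stages and log2fm is not None:
        z_genes = genes[genes["chrom"] == layout.sex_chromosome].copy()
        z_fm = log2fm.reindex(z_genes["gene_id"]).to_numpy()
        z_genes["balanced"] = np.abs(z_fm) <= 0.25
        z_genes = z_genes[np.isfinite(z_fm)]
        windows = scan.make_windows(
            layout.length(layout.sex_chromosome),
            thresholds["window_size"], thresholds["window_step"],
        )
        results["fisher_scan"] = scan.fisher_window_scan(z_genes, windows)

    if "par" in stages and "coverage" in study:
        fm_track = par.normalized_fm_coverage(
            study["coverage"], layout.autosomes, layout.sex_chromosome
        )
        call = par.detect_par_boundary(
            fm_track, study.get("het_sites"),
            min_separation=thresholds["par_min_separation"],
        )
        results["par_call"] = {
            "detected": call.detected, "boundary": call.boundary,
            "coverage_boundary": call.coverage_boundary,
            "het_boundary": call.het_boundary,
            "discrepancy": call.discrepancy, "evidence": call.evidence,
        }

    return io.write_report(results, out_dir, seed=seed, thresholds=thresholds)


def _full_sim(cfg: SimulationConfig) -> dict:
    genome = sim.simulate_genome(cfg)
    layout, genes = genome["layout"], genome["genes"]
    expr, samples, truth = sim.simulate_expression(layout, genes, cfg,
                                                   tissue="liver")
    peaksets, _ = sim.simulate_atac(layout, genes, cfg, tissue="liver")
    meth, _ = sim.simulate_methylation(
        layout, genes, genome["islands"], next(iter(peaksets.values())),
        cfg, tissue="liver",
    )
    coverage = sim.simulate_coverage(layout, cfg)
    het = sim.simulate_het_sites(layout, cfg)
    return {
        **genome, "expression": expr, "samples": samples, "truth": truth,
        "peaks": peaksets, "methylation": meth, "coverage": coverage,
        "het_sites": het,
    }


_STAGE_NEEDS = {
    "expression": ["expression", "samples", "genes"],
    "atac": ["peaks", "samples", "genes"],
    "methylation": ["methylation", "samples", "genes"],
    "scan": ["expression", "genes"],
    "par": ["coverage"],
}


def _check_stage_inputs(stage: str, data: dict) -> None:
    for role in _STAGE_NEEDS.get(stage, []):
        if role not in data:
            raise ValidationError(
                f"stage {stage!r} enabled but required input role {role!r} missing"
            )
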