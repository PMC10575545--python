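"""Generative-recovery and determinism properties of the study simulator."""

import numpy as np
import pandas as pd
import pytest

from zdose import expression as ex
from zdose.datamodel import ValidationError, crow_like_layout
from zdose.simulate import (
    SimulationConfig,
    assign_compensation,
    make_samples,
    simulate_atac,
    simulate_coverage,
    simulate_expression,
    simulate_genome,
    simulate_het_sites,
    simulate_methylation,
    substream,
)


def _nonpar_ids(genome):
    g = genome["genes"]
    mask = np.asarray(genome["layout"].is_nonpar_z(g["chrom"], g["start"]))
    return g.loc[mask, "gene_id"]


class TestGenome:
    def test_layout_and_gene_counts(self):
        cfg = SimulationConfig(par_end=150_000, make_sequences=False, seed=1)
        genome = simulate_genome(cfg)
        assert genome["layout"].par == (0, 150_000)
        counts = genome["genes"].groupby("chrom").size()
        assert (counts == cfg.genes_per_chromosome).all()

    def test_determinism_and_substreams(self):
        cfg = SimulationConfig(make_sequences=False, seed=5)
        a = simulate_genome(cfg)["genes"]
        b = simulate_genome(cfg)["genes"]
        pd.testing.assert_frame_equal(a, b)
        # independent substreams: expression unchanged whether or not the
        # ATAC layer is generated in between
        genome = simulate_genome(cfg)
        e1, _, _ = simulate_expression(genome["layout"], genome["genes"], cfg)
        simulate_atac(genome["layout"], genome["genes"], cfg)
        e2, _, _ = simulate_expression(genome["layout"], genome["genes"], cfg)
        pd.testing.assert_frame_equal(e1.values, e2.values)

    def test_genes_non_overlapping(self):
        genome = simulate_genome(SimulationConfig(make_sequences=False, seed=3))
        for _, grp in genome["genes"].groupby("chrom"):
            grp = grp.sort_values("start")
            assert (grp["start"].to_numpy()[1:] >= grp["end"].to_numpy()[:-1]).all()

    def test_genes_must_fit(self):
        cfg = SimulationConfig(
            autosome_lengths=(20_000, 20_000), z_length=20_000, par_end=5_000,
            make_sequences=False,
        )
        with pytest.raises(ValidationError):
            simulate_genome(cfg)

    def test_sequences_carry_islands(self):
        genome = simulate_genome(SimulationConfig(seed=2))
        isl = genome["islands"].iloc[0]
        seq = genome["sequences"][isl["chrom"]]
        segment = seq[isl["start"]:isl["end"]]
        gc = (segment.count("G") + segment.count("C")) / len(segment)
        assert gc > 0.6
        flank = seq[isl["end"] + 50:isl["end"] + 250]
        gc_bg = (flank.count("G") + flank.count("C")) / len(flank)
        assert gc_bg < 0.4


class TestExpression:
    @pytest.mark.parametrize("c_fix, expected", [(0.5, 0.5), (1.0, 1.0)])
    def test_fm_ratio_recovers_compensation(self, c_fix, expected):
        """Median linear f:m over non-PAR Z genes converges to c_g."""
        cfg = SimulationConfig(
            n_autosomes=1, autosome_lengths=(20_000_000,), z_length=20_000_000,
            par_end=687_785, genes_per_chromosome=400, make_sequences=False,
            compensation_fixed=c_fix, seed=11,
        )
        genome = simulate_genome(cfg)
        expr, samples, _ = simulate_expression(
            genome["layout"], genome["genes"], cfg, tissue="liver"
        )
        fpkm = ex.compute_fpkm(
            expr, library_sizes=samples.set_index("sample_id")["library_size"]
        )
        fm, _ = ex.gene_fm_ratio(fpkm.values, samples)
        z = fm[_nonpar_ids(genome)].dropna()
        assert ex.median_linear_fm(z) == pytest.approx(expected, abs=0.05)

    def test_autosomal_fm_ratio_is_one(self):
        cfg = SimulationConfig(genes_per_chromosome=150,
                               autosome_lengths=(5_000_000, 5_000_000),
                               z_length=5_000_000, par_end=500_000,
                               make_sequences=False, seed=4)
        genome = simulate_genome(cfg)
        expr, samples, _ = simulate_expression(
            genome["layout"], genome["genes"], cfg, tissue="liver"
        )
        fpkm = ex.compute_fpkm(
            expr, library_sizes=samples.set_index("sample_id")["library_size"]
        )
        fm, _ = ex.gene_fm_ratio(fpkm.values, samples)
        auto = genome["genes"].loc[
            genome["genes"]["chrom"] != "chrZ", "gene_id"
        ]
        assert ex.median_linear_fm(fm[auto].dropna()) == pytest.approx(1.0, abs=0.05)

    def test_compensation_truth_bounds(self):
        cfg = SimulationConfig(make_sequences=False, seed=0)
        genome = simulate_genome(cfg)
        c = assign_compensation(genome["genes"], genome["layout"], cfg)
        nonpar = _nonpar_ids(genome)
        assert ((c[nonpar] >= 0.5) & (c[nonpar] <= 1.0)).all()
        others = c.index.difference(nonpar)
        assert (c[others] == 1.0).all()

    def test_sample_sheet_structure(self):
        cfg = SimulationConfig()
        s = make_samples(cfg)
        assert (s["sex"] == "F").sum() == 2 * cfg.n_females  # two tissues
        assert s["sample_id"].is_unique


class TestAtac:
    def test_peaks_within_bounds_and_deterministic(self, study):
        layout = study["layout"]
        for sample, peaks in study["peaks"].items():
            lengths = peaks["chrom"].map(layout.lengths)
            assert ((peaks["start"] >= 0) & (peaks["end"] > peaks["start"])
                    & (peaks["end"] <= lengths)).all()
            assert (peaks["height"] > 0).all()
        cfg = study["config"]
        again, _ = simulate_atac(layout, study["genes"], cfg, tissue="liver")
        pd.testing.assert_frame_equal(
            again[next(iter(again))], study["peaks"][next(iter(study["peaks"]))]
        )

    def test_zero_height_variance_gives_equal_heights(self):
        cfg = SimulationConfig(
            peak_height_log_sd=0.0, peak_height_sample_sd=0.0,
            female_z_height_mult=1.0, peak_presence_prob=1.0, peak_jitter=0,
            make_sequences=False, seed=6,
        )
        genome = simulate_genome(cfg)
        peaks, _ = simulate_atac(genome["layout"], genome["genes"], cfg,
                                 tissue="liver")
        heights = np.concatenate([p["height"].to_numpy() for p in peaks.values()])
        assert np.allclose(heights, heights[0])

    def test_female_z_height_multiplier_recovered(self):
        from zdose import atac as at
        cfg = SimulationConfig(
            n_autosomes=1, autosome_lengths=(5_000_000,), z_length=5_000_000,
            par_end=500_000, genes_per_chromosome=120, make_sequences=False,
            seed=8,
        )
        genome = simulate_genome(cfg)
        peaks, samples = simulate_atac(genome["layout"], genome["genes"], cfg,
                                       tissue="liver")
        table = at.build_orthologous_peaks(peaks)
        links = at.link_clusters_to_genes(table, genome["genes"])
        per_gene, _ = at.peak_height_fm_ratio(
            table, samples, links=links, by="gene", n_boot=100, seed=0
        )
        z = per_gene[per_gene.index.isin(set(_nonpar_ids(genome)))].dropna()
        assert 2.0 ** np.median(z) == pytest.approx(1.12, abs=0.05)


class TestMethylation:
    def test_counts_valid_and_region_means(self, study):
        cfg = study["config"]
        pooled_m = pooled_t = 0.0
        for calls in study["methylation"].values():
            assert (calls["n_meth"] <= calls["n_total"]).all()
            assert (calls["n_meth"] >= 0).all()
        # gene-body regional mean near the configured 0.66 (sites inside
        # accessibility peaks or CpG islands belong to those regions and
        # carry their own, lower means)
        genes = study["genes"]
        sample = next(iter(study["methylation"]))
        calls = study["methylation"][sample]

        def _inside(intervals):
            hit = np.zeros(len(calls), dtype=bool)
            for r in intervals.itertuples(index=False):
                hit |= ((calls["chrom"] == r.chrom) & (calls["pos"] >= r.start)
                        & (calls["pos"] < r.end)).to_numpy()
            return hit

        in_body = _inside(genes.rename(columns={"gene_id": "name"}))
        in_peak = _inside(study["peaks"][sample])
        in_island = _inside(study["islands"])
        body = calls[in_body & ~in_peak & ~in_island]
        prop = body["n_meth"].sum() / body["n_total"].sum()
        assert prop == pytest.approx(cfg.meth_gene_body, abs=0.05)

    def test_null_sex_effect_centred(self, study):
        """With no generative sex effect, per-feature f - m differences
        centre on zero."""
        from zdose import methylation as me
        feats = study["genes"].rename(columns={"gene_id": "feature_id"})[
            ["feature_id", "chrom", "start", "end"]
        ]
        mats = me.feature_methylation_matrix(study["methylation"], feats)
        samples = study["samples"]
        f = mats["proportion"][samples.loc[samples["sex"] == "F", "sample_id"]]
        m = mats["proportion"][samples.loc[samples["sex"] == "M", "sample_id"]]
        diff = (f.mean(axis=1) - m.mean(axis=1)).dropna()
        assert abs(diff.mean()) < 0.01


class TestCoverageAndHet:
    def test_noise_free_ploidy_ratios(self):
        layout = crow_like_layout(
            autosome_lengths=(1_000_000,), z_length=1_000_000, par_end=400_000
        )
        cfg = SimulationConfig(seed=0)
        tracks = simulate_coverage(layout, cfg, window=50_000, noise=False)
        f = tracks["F"]; m = tracks["M"]
        z_f = f[f["chrom"] == "chrZ"].reset_index(drop=True)
        z_m = m[m["chrom"] == "chrZ"].reset_index(drop=True)
        ratio = z_f["depth"] / z_m["depth"]
        mids = (z_f["start"] + z_f["end"]) // 2
        assert (ratio[mids < 400_000] == 1.0).all()
        assert (ratio[mids >= 400_000] == 0.5).all()
        # autosomal depth equal between the sexes
        a_f = f[f["chrom"] != "chrZ"]["depth"]
        a_m = m[m["chrom"] != "chrZ"]["depth"]
        assert (a_f.to_numpy() == a_m.to_numpy()).all()

    def test_het_sites_span_par(self):
        layout = crow_like_layout()
        cfg = SimulationConfig(seed=1)
        het = simulate_het_sites(layout, cfg)
        assert len(het) == cfg.n_het_snps
        assert het[-1] == layout.par[1]
        assert het[0] >= layout.par[0]
        assert (np.diff(het) > 0).all()


def test_substreams_are_independent_and_stable():
    a = substream(3, "layer", "s1").integers(0, 1000, 5)
    b = substream(3, "layer", "s1").integers(0, 1000, 5)
    c = substream(3, "layer", "s2").integers(0, 1000, 5)
    assert (a == b).all()
    assert not (a == c).all()
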