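"""CpG islands, feature methylation, beta-binomial DML and flank profiles."""

import numpy as np
import pandas as pd
import pytest
from scipy import special, stats

from zdose import methylation as me
from zdose.datamodel import ValidationError


def _make_seq(rng, length, p_gc):
    p = p_gc / 2
    return "".join(rng.choice(list("ACGT"), p=[(1 - p_gc) / 2, p, p,
                                               (1 - p_gc) / 2], size=length))


def brute_force_islands_exist(seq, min_len=250, gc_min=0.6, oe_min=0.75):
    """Oracle: does any substring satisfy all three island thresholds?
    (checks a coarse grid of substrings; used on short sequences only)"""
    n = len(seq)
    for s in range(0, n - min_len, 10):
        for e in range(s + min_len + 1, min(n, s + 1200) + 1, 10):
            sub = seq[s:e]
            L = e - s
            c, g = sub.count("C"), sub.count("G")
            if c == 0 or g == 0:
                continue
            gc = (c + g) / L
            oe = sub.count("CG") * L / (c * g)
            if gc > gc_min and oe > oe_min:
                return True
    return False


class TestCpgIslands:
    def test_embedded_island_found_and_verified(self):
        rng = np.random.default_rng(3)
        seq = (_make_seq(rng, 2000, 0.1) + _make_seq(rng, 300, 0.7)
               + _make_seq(rng, 2000, 0.1))
        out = me.call_cpg_islands(seq)
        assert len(out) == 1
        isl = out.iloc[0]
        # the called island covers the CG-rich segment
        assert isl["start"] <= 2010 and isl["end"] >= 2290
        # self-verification: recompute stats directly from sequence
        sub = seq[int(isl["start"]):int(isl["end"])]
        c, g = sub.count("C"), sub.count("G")
        gc = (c + g) / len(sub)
        oe = sub.count("CG") * len(sub) / (c * g)
        assert gc > 0.60 and oe > 0.75 and len(sub) > 250
        assert gc == pytest.approx(isl["gc_frac"])
        assert brute_force_islands_exist(seq)

    def test_short_segment_rejected(self):
        """A 200-bp CG-rich segment cannot reach the 250-bp threshold."""
        rng = np.random.default_rng(5)
        seq = (_make_seq(rng, 1500, 0.08) + _make_seq(rng, 200, 0.66)
               + _make_seq(rng, 1500, 0.08))
        out = me.call_cpg_islands(seq)
        assert len(out) == 0
        assert not brute_force_islands_exist(seq)

    def test_low_gc_segment_rejected(self):
        rng = np.random.default_rng(6)
        seq = (_make_seq(rng, 1000, 0.1) + _make_seq(rng, 400, 0.55)
               + _make_seq(rng, 1000, 0.1))
        out = me.call_cpg_islands(seq)
        assert len(out) == 0

    def test_padding_with_n_shifts_coordinates_only(self):
        rng = np.random.default_rng(3)
        seq = (_make_seq(rng, 1000, 0.1) + _make_seq(rng, 400, 0.7)
               + _make_seq(rng, 1000, 0.1))
        a = me.call_cpg_islands(seq)
        b = me.call_cpg_islands("N" * 300 + seq + "N" * 300)
        assert len(a) == len(b) == 1
        assert b.iloc[0]["start"] - 300 == a.iloc[0]["start"]
        assert b.iloc[0]["end"] - 300 == a.iloc[0]["end"]

    def test_sequence_shorter_than_window(self):
        assert me.call_cpg_islands("ACGT" * 10).empty

    def test_every_reported_island_passes_thresholds(self, study):
        seq = study["sequences"]["chrZ"]
        out = me.call_cpg_islands(seq)
        assert len(out) > 0
        for isl in out.itertuples(index=False):
            sub = seq[isl.start:isl.end]
            c, g = sub.count("C"), sub.count("G")
            gc = (c + g) / len(sub)
            oe = sub.count("CG") * len(sub) / (c * g)
            assert len(sub) > 250 and gc > 0.60 and oe > 0.75


class TestFeatureMethylation:
    features = pd.DataFrame({
        "feature_id": ["f1"], "chrom": ["chr1"], "start": [0], "end": [1000],
    })

    def test_cumulative_count_definition(self):
        calls = pd.DataFrame({
            "chrom": ["chr1", "chr1"], "pos": [10, 20],
            "n_meth": [3, 7], "n_total": [10, 10],
        })
        out = me.feature_methylation(calls, self.features, min_cov=10)
        assert out.iloc[0]["proportion"] == pytest.approx(0.5)
        assert out.iloc[0]["n_cpgs"] == 2

    def test_low_coverage_excluded(self):
        calls = pd.DataFrame({
            "chrom": ["chr1", "chr1"], "pos": [10, 20],
            "n_meth": [9, 5], "n_total": [9, 10],
        })
        out = me.feature_methylation(calls, self.features, min_cov=10)
        assert out.iloc[0]["n_cpgs"] == 1
        assert out.iloc[0]["proportion"] == pytest.approx(0.5)

    def test_all_masked_is_missing_not_zero(self):
        calls = pd.DataFrame({
            "chrom": ["chr1"], "pos": [10], "n_meth": [5], "n_total": [10],
        })
        masks = pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [100]})
        out = me.feature_methylation(calls, self.features, masks=masks)
        assert np.isnan(out.iloc[0]["proportion"])
        assert out.iloc[0]["n_cpgs"] == 0

    def test_split_records_invariant(self):
        whole = pd.DataFrame({
            "chrom": ["chr1"], "pos": [10], "n_meth": [6], "n_total": [20],
        })
        split = pd.DataFrame({
            "chrom": ["chr1", "chr1"], "pos": [10, 10],
            "n_meth": [3, 3], "n_total": [10, 10],
        })
        a = me.feature_methylation(whole, self.features)
        b = me.feature_methylation(split, self.features)
        assert a.iloc[0]["proportion"] == b.iloc[0]["proportion"]

    def test_relaxed_z_threshold(self):
        from zdose.datamodel import GenomeLayout
        layout = GenomeLayout((("chr1", 10_000), ("chrZ", 10_000)), "chrZ",
                              (0, 1_000))
        feats = pd.DataFrame({
            "feature_id": ["fz"], "chrom": ["chrZ"], "start": [0], "end": [9000],
        })
        calls = pd.DataFrame({
            "chrom": ["chrZ"], "pos": [5000], "n_meth": [3], "n_total": [6],
        })
        strict = me.feature_methylation(calls, feats, min_cov=10)
        relaxed = me.feature_methylation(calls, feats, min_cov=10,
                                         layout=layout, relaxed_z_min_cov=5)
        assert strict.iloc[0]["n_cpgs"] == 0
        assert relaxed.iloc[0]["n_cpgs"] == 1

    def test_min_cov_validated(self):
        with pytest.raises(ValidationError):
            me.feature_methylation(pd.DataFrame(columns=["chrom", "pos",
                                                         "n_meth", "n_total"]),
                                   self.features, min_cov=0)


class TestBetaBinomial:
    def test_zero_dispersion_limit_equals_binomial(self):
        """In the rho -> 0 limit the beta-binomial log-likelihood matches the
        binomial one (up to the shared combinatorial constant)."""
        y = np.array([3.0, 7.0, 5.0])
        n = np.array([10.0, 10.0, 10.0])
        mu = 0.45
        ll_bb = me.betabinom_loglik(y, n, mu, 1e-9)
        ll_bin = float(np.sum(y * np.log(mu) + (n - y) * np.log(1 - mu)))
        assert ll_bb == pytest.approx(ll_bin, abs=1e-6)

    def test_effect_recovery_high_depth(self, samples_4v4):
        """Sex log-odds recovered within ~10% at high depth."""
        rng = np.random.default_rng(7)
        rho = 0.02
        mu_f, mu_m = 0.6, 0.4
        truth = special.logit(mu_f) - special.logit(mu_m)
        nfeat = 60
        nt = rng.poisson(2000, size=(nfeat, 8)).astype(float)
        mus = np.array([mu_f] * 4 + [mu_m] * 4)
        a, b = mus * (1 - rho) / rho, (1 - mus) * (1 - rho) / rho
        p = rng.beta(a, b, size=(nfeat, 8))
        nm = rng.binomial(nt.astype(int), p).astype(float)
        dml = me.beta_binomial_dml(
            pd.DataFrame(nm, columns=samples_4v4["sample_id"]),
            pd.DataFrame(nt, columns=samples_4v4["sample_id"]), samples_4v4,
        )
        assert dml["sex_effect"].mean() == pytest.approx(truth, rel=0.10)

    def test_power_on_strong_effect(self, samples_4v4):
        """0.2 vs 0.8 at depth 30 with 4+4 samples: q < 0.05 for > 90%."""
        rng = np.random.default_rng(1)
        rho = 0.05
        nfeat = 120
        nt = rng.poisson(30, size=(nfeat, 8)).astype(float)
        mus = np.array([0.8] * 4 + [0.2] * 4)
        a, b = mus * (1 - rho) / rho, (1 - mus) * (1 - rho) / rho
        p = rng.beta(a, b, size=(nfeat, 8))
        nm = rng.binomial(nt.astype(int), p).astype(float)
        dml = me.beta_binomial_dml(
            pd.DataFrame(nm, columns=samples_4v4["sample_id"]),
            pd.DataFrame(nt, columns=samples_4v4["sample_id"]), samples_4v4,
        )
        assert (dml["q"] < 0.05).mean() > 0.9

    def test_null_pvalues_approximately_uniform_large_n(self):
        """Wald p-values approach uniformity as samples grow."""
        n_per = 20
        samples = pd.DataFrame({
            "sample_id": [f"s{i}" for i in range(2 * n_per)],
            "sex": ["F"] * n_per + ["M"] * n_per, "tissue": "t",
        })
        rng = np.random.default_rng(2)
        rho, mu = 0.05, 0.4
        a, b = mu * (1 - rho) / rho, (1 - mu) * (1 - rho) / rho
        nfeat = 200
        nt = rng.poisson(60, size=(nfeat, 2 * n_per)).astype(float)
        p = rng.beta(a, b, size=(nfeat, 2 * n_per))
        nm = rng.binomial(nt.astype(int), p).astype(float)
        dml = me.beta_binomial_dml(
            pd.DataFrame(nm, columns=samples["sample_id"]),
            pd.DataFrame(nt, columns=samples["sample_id"]), samples,
        )
        assert (dml["p"] < 0.05).mean() < 0.12
        assert dml["p"].mean() == pytest.approx(0.5, abs=0.1)

    def test_zero_coverage_feature_flagged(self, samples_4v4):
        nm = pd.DataFrame([[0.0] * 8], columns=samples_4v4["sample_id"],
                          index=["dead"])
        nt = pd.DataFrame([[0.0] * 8], columns=samples_4v4["sample_id"],
                          index=["dead"])
        dml = me.beta_binomial_dml(nm, nt, samples_4v4)
        assert not dml.iloc[0]["converged"]
        assert np.isnan(dml.iloc[0]["p"])


class TestBootstrapDivergence:
    def test_constant_proportions(self, samples_4v4):
        prop = pd.DataFrame([[0.4] * 4 + [0.2] * 4],
                            columns=samples_4v4["sample_id"], index=["f1"])
        out = me.bootstrap_meth_divergence(prop, samples_4v4, n_boot=200, seed=0)
        assert out.loc["f1", "log2_fm"] == pytest.approx(1.0)
        assert out.loc["f1", "diff_fm"] == pytest.approx(0.2)
        assert out.loc["f1", "log2_fm_lo"] == out.loc["f1", "log2_fm_hi"]

    def test_identical_sexes_zero(self, samples_4v4):
        prop = pd.DataFrame([[0.3] * 8], columns=samples_4v4["sample_id"],
                            index=["f1"])
        out = me.bootstrap_meth_divergence(prop, samples_4v4, n_boot=100, seed=0)
        assert out.loc["f1", "log2_fm"] == 0.0
        assert out.loc["f1", "diff_fm"] == 0.0

    def test_zero_male_flags_log_scale_only(self, samples_4v4):
        prop = pd.DataFrame([[0.4] * 4 + [0.0] * 4],
                            columns=samples_4v4["sample_id"], index=["f1"])
        out = me.bootstrap_meth_divergence(prop, samples_4v4, n_boot=100, seed=0)
        assert bool(out.loc["f1", "log2_flagged"])
        assert out.loc["f1", "diff_fm"] == pytest.approx(0.4)

    def test_seed_reproducibility(self, samples_4v4):
        rng = np.random.default_rng(0)
        prop = pd.DataFrame(rng.uniform(0, 1, size=(5, 8)),
                            columns=samples_4v4["sample_id"])
        a = me.bootstrap_meth_divergence(prop, samples_4v4, n_boot=300, seed=5)
        b = me.bootstrap_meth_divergence(prop, samples_4v4, n_boot=300, seed=5)
        pd.testing.assert_frame_equal(a, b)


class TestFlankProfile:
    def test_uniform_methylation_flat_profile(self):
        rng = np.random.default_rng(0)
        pos = np.arange(0, 40_000, 50)
        calls = pd.DataFrame({
            "chrom": "chr1", "pos": pos,
            "n_meth": 5, "n_total": 10,
        })
        peaks = pd.DataFrame({"chrom": ["chr1"], "start": [19_000],
                              "end": [21_000]})
        prof = me.flank_methylation_profile(calls, peaks)
        assert len(prof) == 100
        assert np.allclose(prof[~np.isnan(prof)], 0.5)

    def test_inconsistent_geometry_errors(self):
        with pytest.raises(ValidationError):
            me.flank_methylation_profile(
                pd.DataFrame(columns=["chrom", "pos", "n_meth", "n_total"]),
                pd.DataFrame(columns=["chrom", "start", "end"]),
                flank=5_000, n_windows=100,
            )

    def test_demethylated_peaks_show_central_dip(self, study):
        """Generative check: peaks are near-unmethylated, so the profile dips
        at the centre relative to the flanks."""
        sample = next(iter(study["methylation"]))
        calls = study["methylation"][sample]
        peaks = study["peaks"][sample]
        wide = peaks[(peaks["end"] - peaks["start"]) >= 300].head(40)
        prof = me.flank_methylation_profile(calls, wide)
        centre = np.nanmean(prof[48:52])
        edges = np.nanmean(np.concatenate([prof[:10], prof[-10:]]))
        assert centre < edges - 0.2
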