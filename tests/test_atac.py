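"""Peak thinning, clustering, consensus, annotation and differential tests."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from zdose import atac as at
from zdose.datamodel import ValidationError


def _peakset(*intervals, chrom="chr1", height=2.0):
    return pd.DataFrame({
        "chrom": chrom,
        "start": [i[0] for i in intervals],
        "end": [i[1] for i in intervals],
        "height": [i[2] if len(i) > 2 else height for i in intervals],
        "q": 0.01,
    })


class TestThinLibraries:
    def test_expected_totals(self):
        counts = pd.DataFrame({"a": [500, 500], "b": [1000, 1000]})
        th = at.thin_libraries(counts, seed=0)
        assert th["a"].sum() == 1000            # smallest library untouched
        assert th["b"].sum() == pytest.approx(1000, rel=0.15)

    def test_p_equal_one_identity(self):
        counts = pd.DataFrame({"a": [5, 7], "b": [5, 7]})
        th = at.thin_libraries(counts, seed=1)
        pd.testing.assert_frame_equal(th, counts)

    def test_seed_reproducibility(self):
        counts = pd.DataFrame({"a": [50, 50], "b": [500, 500]})
        pd.testing.assert_frame_equal(
            at.thin_libraries(counts, seed=3), at.thin_libraries(counts, seed=3)
        )

    def test_zero_total_errors(self):
        with pytest.raises(ValidationError):
            at.thin_libraries(pd.DataFrame({"a": [0], "b": [5]}))


class TestOrthologousPeaks:
    def test_exact_half_overlap_joins(self):
        ps = {"s1": _peakset((100, 200)), "s2": _peakset((150, 250))}
        table = at.build_orthologous_peaks(ps)
        assert len(table.clusters) == 1
        row = table.clusters.iloc[0]
        assert (row["start"], row["end"], row["n_samples"]) == (100, 250, 2)

    def test_below_half_overlap_does_not_join(self):
        ps = {"s1": _peakset((100, 200)), "s2": _peakset((151, 251))}
        table = at.build_orthologous_peaks(ps, min_samples=1)
        assert len(table.clusters) == 2

    def test_singleton_clusters_dropped(self):
        ps = {"s1": _peakset((100, 200), (1000, 1100)),
              "s2": _peakset((100, 200))}
        table = at.build_orthologous_peaks(ps)
        assert len(table.clusters) == 1

    def test_disjoint_peaks_stay_separate(self):
        ps = {"s1": _peakset((100, 200), (500, 600)),
              "s2": _peakset((100, 200), (500, 600))}
        table = at.build_orthologous_peaks(ps)
        assert len(table.clusters) == 2

    def test_order_independence(self, study):
        peaks = study["peaks"]
        fwd = at.build_orthologous_peaks(peaks)
        rev = at.build_orthologous_peaks(dict(reversed(list(peaks.items()))))
        pd.testing.assert_frame_equal(fwd.clusters, rev.clusters)
        pd.testing.assert_frame_equal(fwd.heights, rev.heights)

    def test_within_sample_duplicate_keeps_highest(self):
        ps = {"s1": _peakset((100, 200, 2.0), (110, 210, 9.0)),
              "s2": _peakset((100, 200, 3.0))}
        table = at.build_orthologous_peaks(ps)
        assert len(table.clusters) == 1
        assert table.heights.iloc[0]["s1"] == 9.0


class TestConsensusPeaks:
    def _sets(self, n_with, n_total):
        ps = {}
        for i in range(n_total):
            iv = [(100, 200)] if i < n_with else [(5000, 5100)]
            ps[f"s{i}"] = _peakset(*iv)
        return ps

    def test_eighty_percent_share_kept(self):
        cons = at.build_consensus_peaks(self._sets(8, 10))
        assert ((cons["start"] == 100) & (cons["end"] == 200)).any()

    def test_seventy_percent_share_dropped(self):
        cons = at.build_consensus_peaks(self._sets(7, 10))
        assert not ((cons["start"] == 100)).any()

    def test_retained_clusters_merge_at_sixty_percent_overlap(self):
        # two cluster positions overlapping 60% reciprocally
        ps = {
            "s1": _peakset((100, 200)), "s2": _peakset((100, 200)),
            "s3": _peakset((140, 240)), "s4": _peakset((140, 240)),
        }
        cons = at.build_consensus_peaks(ps, share_frac=0.5)
        assert len(cons) == 1
        assert (cons.iloc[0]["start"], cons.iloc[0]["end"]) == (100, 240)

    def test_consensus_pairwise_non_overlapping(self, study):
        cons = at.build_consensus_peaks(study["peaks"])
        for _, grp in cons.groupby("chrom"):
            grp = grp.sort_values("start")
            assert (grp["start"].to_numpy()[1:] >= grp["end"].to_numpy()[:-1]).all()

    def test_needs_two_samples(self):
        with pytest.raises(ValidationError):
            at.build_consensus_peaks({"s1": _peakset((0, 10))})


class TestAssignment:
    @pytest.fixture()
    def gene(self):
        return pd.DataFrame({
            "gene_id": ["g1"], "chrom": ["chr1"],
            "start": [10_000], "end": [20_000], "strand": ["+"],
        })

    def test_gene_centred_within_20kb(self, gene):
        peaks = _peakset((5_000, 5_500))
        links = at.assign_peaks_to_genes(peaks, gene, "gene_centred")
        assert links["gene_id"].tolist() == ["g1"]

    def test_regulatory_tss_window(self, gene):
        peaks = _peakset((9_200, 9_800))
        links = at.assign_peaks_to_genes(peaks, gene, "regulatory")
        assert links["gene_id"].tolist() == ["g1"]

    def test_gene_body_excluded_from_regulatory(self, gene):
        peaks = _peakset((12_000, 12_500))
        links = at.assign_peaks_to_genes(peaks, gene, "regulatory")
        assert links.empty

    def test_too_far_no_link(self, gene):
        peaks = _peakset((41_000, 41_500))
        links = at.assign_peaks_to_genes(peaks, gene, "gene_centred")
        assert links.empty

    def test_minus_strand_regulatory(self):
        gene = pd.DataFrame({
            "gene_id": ["g1"], "chrom": ["chr1"],
            "start": [10_000], "end": [20_000], "strand": ["-"],
        })
        # TSS at 19,999: upstream window is (19999, 20999]
        links = at.assign_peaks_to_genes(_peakset((20_100, 20_400)), gene,
                                         "regulatory")
        assert links["gene_id"].tolist() == ["g1"]


class TestHighestPeakCategory:
    gene = pd.Series({
        "gene_id": "g1", "chrom": "chr1", "start": 10_000, "end": 20_000,
        "strand": "+",
    })

    def test_summit_near_tss(self):
        peaks = _peakset((9_500, 9_900, 5.0))
        assert at.highest_peak_category(self.gene, peaks) == "TSS"

    def test_tie_breaks_to_tss(self):
        peaks = _peakset((9_500, 9_900, 5.0), (40_000, 40_400, 5.0))
        assert at.highest_peak_category(self.gene, peaks) == "TSS"

    def test_intron_with_exon_table(self):
        exons = pd.DataFrame({
            "gene_id": ["g1"], "chrom": ["chr1"],
            "start": [10_000], "end": [12_000],
        })
        peaks = _peakset((14_500, 15_500, 5.0))
        assert at.highest_peak_category(self.gene, peaks, exons=exons) == "intron"

    def test_intergenic(self):
        peaks = _peakset((45_000, 45_400, 2.0))
        assert at.highest_peak_category(self.gene, peaks) == "intergenic"

    def test_no_peaks_returns_none(self):
        assert at.highest_peak_category(self.gene, _peakset().iloc[0:0]) is None


class TestHeightRatios:
    def test_equal_heights_give_zero(self, samples_4v4):
        heights = pd.DataFrame(
            [[2.0] * 8, [5.0] * 8],
            columns=samples_4v4["sample_id"], index=["c0", "c1"],
        )
        clusters = pd.DataFrame({
            "cluster_id": ["c0", "c1"], "chrom": "chr1",
            "start": [0, 100], "end": [50, 150], "n_samples": 8,
        })
        table = at.OrthologousPeakTable(clusters=clusters, heights=heights)
        per_unit, _ = at.peak_height_fm_ratio(table, samples_4v4,
                                              by="chromosome", n_boot=50)
        assert per_unit["chr1"] == pytest.approx(0.0)

    def test_strict_mode_drops_incomplete_clusters(self, samples_4v4):
        h = pd.DataFrame(
            [[2.0] * 8, [5.0] * 7 + [np.nan]],
            columns=samples_4v4["sample_id"], index=["c0", "c1"],
        )
        clusters = pd.DataFrame({
            "cluster_id": ["c0", "c1"], "chrom": "chr1",
            "start": [0, 100], "end": [50, 150], "n_samples": [8, 7],
        })
        table = at.OrthologousPeakTable(clusters=clusters, heights=h)
        links = pd.DataFrame({"cluster_id": ["c0", "c1"],
                              "gene_id": ["g1", "g2"], "scope": "gene_centred"})
        per_unit, _ = at.peak_height_fm_ratio(
            table, samples_4v4, links=links, by="gene", strict=True, n_boot=50
        )
        assert "g2" not in per_unit.index


class TestPeakDifferential:
    def test_equal_counts_null(self, samples_4v4):
        counts = pd.DataFrame(
            [[100] * 8, [200] * 8],
            columns=samples_4v4["sample_id"], index=["p1", "p2"],
        )
        res = at.peak_differential(counts, samples_4v4, min_samples=7,
                                   n_perm=200, seed=0)
        assert (res["log2_fc"].abs() < 1e-9).all()
        assert res["p"].to_numpy() == pytest.approx(1.0)

    def test_cpm_filter_requires_seven_samples(self, samples_4v4):
        # p1 passes cpm > 1 in all 8; p2 only in 6 samples
        base = np.full(8, 50_000)
        low = np.array([50_000] * 6 + [0, 0])
        filler = np.full(8, 10_000_000)
        counts = pd.DataFrame(
            [base, low, filler],
            columns=samples_4v4["sample_id"], index=["p1", "p2", "bg"],
        )
        res = at.peak_differential(counts, samples_4v4, min_samples=7,
                                   n_perm=200, seed=0)
        assert "p1" in set(res["peak"]) and "p2" not in set(res["peak"])

    def test_twofold_effect_detected_by_exact_enumeration(self):
        samples = pd.DataFrame({
            "sample_id": [f"x{i}" for i in range(12)],
            "sex": ["F"] * 6 + ["M"] * 6, "tissue": "t",
        })
        rng = np.random.default_rng(0)
        f = rng.poisson(20_000, 6)
        m = rng.poisson(10_000, 6)
        counts = pd.DataFrame([np.concatenate([f, m]),
                               np.full(12, 1_000_000)],
                              columns=samples["sample_id"], index=["p", "bg"])
        res = at.peak_differential(counts, samples, min_samples=7,
                                   n_perm=1000, seed=0)
        row = res[res["peak"] == "p"].iloc[0]
        assert row["log2_fc"] == pytest.approx(1.0, abs=0.1)
        # exact enumeration: C(12,6) = 924 label assignments
        assert row["p"] <= 4 / math.comb(12, 6)

    def test_null_pvalues_uniform(self):
        """Permutation p-values on a null simulation are uniform (KS)."""
        samples = pd.DataFrame({
            "sample_id": [f"x{i}" for i in range(10)],
            "sex": ["F"] * 5 + ["M"] * 5, "tissue": "t",
        })
        rng = np.random.default_rng(4)
        counts = pd.DataFrame(
            rng.poisson(5_000, size=(200, 10)),
            columns=samples["sample_id"],
            index=[f"p{i}" for i in range(200)],
        )
        res = at.peak_differential(counts, samples, min_samples=7,
                                   n_perm=252, seed=1)
        # discrete p-values: compare against the uniform via mean/quantiles
        assert res["p"].mean() == pytest.approx(0.5, abs=0.07)
        assert (res["p"] < 0.05).mean() < 0.12

    def test_min_permutations_enforced(self, samples_4v4):
        counts = pd.DataFrame([[10] * 8], columns=samples_4v4["sample_id"])
        with pytest.raises(ValidationError):
            at.peak_differential(counts, samples_4v4, n_perm=10)
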