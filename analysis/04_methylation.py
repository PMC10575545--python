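#!/usr/bin/env python
"""5mC methylation analysis.

Calls CpG islands from the simulated sequence, computes coverage-filtered
feature methylation for genes and islands, bootstraps f:m divergence, runs
the beta-binomial sex-effect regression, and profiles methylation across
ATAC peak flanks (the demethylated-peak signature).
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from zdose import io, methylation as me
from zdose.simulate import SimulationConfig, simulate_genome

ap = argparse.ArgumentParser()
ap.add_argument("--study", type=Path, default=Path("results/study"))
ap.add_argument("--out", type=Path, default=Path("results/methylation"))
ap.add_argument("--seed", type=int, default=1)
args = ap.parse_args()

layout = io.read_layout(args.study / "layout.yaml")
samples = io.read_samples_tsv(args.study / "samples.tsv")
genes = io.read_genes_bed(args.study / "genes.bed", layout)
calls = {
    s: io.read_bismark_cov(args.study / f"meth_{s}.cov", layout)
    for s in samples["sample_id"]
}

# islands from the same simulated genome (sequence is regenerated from the
# study seed rather than shipped as FASTA)
genome = simulate_genome(SimulationConfig(seed=args.seed))
islands = []
for chrom, seq in genome["sequences"].items():
    isl = me.call_cpg_islands(seq)
    isl.insert(0, "chrom", chrom)
    islands.append(isl)
islands = pd.concat(islands, ignore_index=True)
print(f"called {len(islands)} CpG islands "
      f"(mean GC {islands['gc_frac'].mean():.2f}, "
      f"mean O/E {islands['oe_ratio'].mean():.2f})")

feats_genes = genes.rename(columns={"gene_id": "feature_id"})[
    ["feature_id", "chrom", "start", "end"]
]
feats_isl = islands.assign(
    feature_id=[f"cgi_{i}" for i in range(len(islands))]
)[["feature_id", "chrom", "start", "end"]]

for name, feats in (("genes", feats_genes), ("islands", feats_isl)):
    mats = me.feature_methylation_matrix(calls, feats, min_cov=10)
    mean_prop = np.nanmean(mats["proportion"].to_numpy())
    print(f"{name}: mean methylation {mean_prop:.2f} "
          f"over {len(feats)} features")
    if name == "genes":
        div = me.bootstrap_meth_divergence(mats["proportion"], samples,
                                           n_boot=2000, seed=args.seed)
        dml = me.beta_binomial_dml(mats["n_meth"], mats["n_total"], samples)
        n_sig = int((dml["q"] < 0.05).sum())
        print(f"  f:m divergence centred at {div['diff_fm'].median():+.3f}; "
              f"{n_sig} features sex-differential at q < 0.05")

sample0 = samples["sample_id"].iloc[0]
peaks = io.read_narrowpeak(args.study / f"atac_{sample0}.narrowPeak", layout)
profile = me.flank_methylation_profile(calls[sample0], peaks.head(60))
centre, edge = np.nanmean(profile[45:55]), np.nanmean(profile[:10])
print(f"peak-flank profile: centre {centre:.2f} vs edge {edge:.2f} "
      f"(demethylation dip {edge - centre:+.2f})")

io.write_report({
    "cpg_islands": islands,
    "divergence": div.reset_index(names="feature_id"),
    "dml_table": dml,
    "flank_profile": pd.DataFrame({"tile": np.arange(len(profile)),
                                   "median_methylation": profile}),
}, args.out, seed=args.seed)
print(f"wrote {args.out}")
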