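#!/usr/bin/env python
"""Scan the Z chromosome for regional clustering of dosage-balanced genes.

Runs the Fisher sliding-window enrichment scan (PAR-sized and 1-Mb
windows), the 15-gene block scheme, the Wilcoxon peak-height window scan,
and the autocorrelation analysis of per-gene log2(f:m) along the Z.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from zdose import atac, expression as ex, io, scan as sc

ap = argparse.ArgumentParser()
ap.add_argument("--study", type=Path, default=Path("results/study"))
ap.add_argument("--out", type=Path, default=Path("results/scan"))
ap.add_argument("--seed", type=int, default=1)
args = ap.parse_args()

layout = io.read_layout(args.study / "layout.yaml")
samples = io.read_samples_tsv(args.study / "samples.tsv")
genes = io.read_genes_bed(args.study / "genes.bed", layout)
counts = io.read_expression_tsv(args.study / "expression_counts.tsv",
                                unit="counts")
counts.gene_lengths = pd.Series(
    (genes["end"] - genes["start"]).to_numpy(), index=genes["gene_id"]
)
lib = samples.set_index("sample_id")["library_size"] \
    if "library_size" in samples else None
fpkm = ex.compute_fpkm(counts, library_sizes=lib)
fm, _ = ex.gene_fm_ratio(fpkm.values, samples)

z_len = layout.length(layout.sex_chromosome)
z_genes = genes[genes["chrom"] == layout.sex_chromosome].copy()
z_fm = fm.reindex(z_genes["gene_id"]).to_numpy()
ok = np.isfinite(z_fm)
z_genes, z_fm = z_genes[ok], z_fm[ok]
z_genes["balanced"] = np.abs(z_fm) <= 0.25
print(f"{len(z_genes)} evaluable Z genes, "
      f"{int(z_genes['balanced'].sum())} dosage balanced")

results = {}
par_size = layout.par[1] - layout.par[0]
schemes = {"par_sized": (par_size, max(1, par_size // 2)),
           "1mb": (1_000_000, 100_000)}
for name, (size, step) in schemes.items():
    windows = sc.make_windows(z_len, size, step)
    res = sc.fisher_window_scan(z_genes, windows)
    n_sig = int(res["significant"].sum())
    print(f"Fisher scan ({name}): {len(windows)} windows, "
          f"{n_sig} significant after Bonferroni")
    results[f"fisher_{name}"] = res

gene_windows = sc.make_gene_windows(z_genes, k=15)
print(f"15-gene scheme: {len(gene_windows)} blocks "
      f"({int(gene_windows['partial'].sum())} partial)")

# Wilcoxon scan on orthologous peak heights along the Z
peaksets = {
    s: io.read_narrowpeak(args.study / f"atac_{s}.narrowPeak", layout)
    for s in samples["sample_id"]
}
table = atac.build_orthologous_peaks(peaksets)
on_z = table.clusters["chrom"] == layout.sex_chromosome
z_clusters = table.clusters[on_z].reset_index(drop=True)
hz = table.heights.loc[z_clusters["cluster_id"]]
f_cols = [c for c in samples.loc[samples["sex"] == "F", "sample_id"]
          if c in hz.columns]
m_cols = [c for c in samples.loc[samples["sex"] == "M", "sample_id"]
          if c in hz.columns]
windows = sc.make_windows(z_len, par_size, max(1, par_size // 2))
wres = sc.wilcoxon_window_scan(
    z_clusters, hz[f_cols].reset_index(drop=True),
    hz[m_cols].reset_index(drop=True), windows,
)
tested = int(wres["p"].notna().sum())
print(f"Wilcoxon peak scan: {tested}/{len(wres)} windows tested, "
      f"{int(wres['significant'].fillna(False).sum())} significant")
results["wilcoxon_peaks"] = wres

if len(z_fm) >= 10:
    order = np.argsort(z_genes["start"].to_numpy())
    acf = sc.acf_scan(z_fm[order], max_lag=min(10, len(z_fm) - 2))
    n_sig = int(acf["significant"].sum())
    print(f"ACF: {n_sig}/{len(acf)} lags outside +-1.96/sqrt(n)")
    results["acf"] = acf

io.write_report(results, args.out, seed=args.seed)
print(f"wrote {args.out}")
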