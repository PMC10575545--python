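#!/usr/bin/env python
"""Simulate the full multi-omic study and write it out in standard formats.

Generates a crow-like genome (2 macro-autosomes + a Z with a PAR), 8 female
and 7 male individuals in one tissue, and the four observation layers:
RNA-seq counts, ATAC peak calls, per-CpG methylation, and sex-specific DNA
coverage with female-heterozygous sites. Everything downstream
(02-06) reads these files back through the package's loaders.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from zdose import io
from zdose.simulate import small_study

ap = argparse.ArgumentParser()
ap.add_argument("--seed", type=int, default=1)
ap.add_argument("--out", type=Path, default=Path("results/study"))
args = ap.parse_args()

study = small_study(seed=args.seed)
out = args.out
out.mkdir(parents=True, exist_ok=True)

io.write_layout(study["layout"], out / "layout.yaml")
io.write_genes_bed(study["genes"], out / "genes.bed")
io.write_samples_tsv(study["samples"], out / "samples.tsv")
io.write_expression_tsv(study["expression"], out / "expression_counts.tsv")
for sample, peaks in study["peaks"].items():
    io.write_narrowpeak(peaks, out / f"atac_{sample}.narrowPeak")
for sample, calls in study["methylation"].items():
    io.write_bismark_cov(calls, out / f"meth_{sample}.cov")
for sex, track in study["coverage"].items():
    io.write_bedgraph(track, out / f"coverage_{sex}.bedGraph")
pd.DataFrame({"pos": study["het_sites"]}).to_csv(
    out / "het_sites.tsv", sep="\t", index=False
)
study["truth"].to_csv(out / "truth_compensation.tsv", sep="\t", index=False)

n_z = int((study["genes"]["chrom"] == "chrZ").sum())
print(f"wrote study to {out}: {len(study['genes'])} genes ({n_z} on chrZ), "
      f"{len(study['samples'])} samples, "
      f"{len(study['peaks'])} ATAC peak sets, "
      f"{len(study['methylation'])} methylation call sets")
print(f"true mean compensation factor on non-PAR Z: "
      f"{study['truth'].loc[study['truth']['nonpar_z'], 'c_g'].mean():.3f}")
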