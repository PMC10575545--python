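#!/usr/bin/env python
"""Locate the pseudo-autosomal boundary on the Z.

Normalises female/male coverage by the autosomal medians, fits the
two-segment change-point to the log2(f:m) track, and reconciles it with
the extent of female heterozygosity.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from zdose import io, par as pdet

ap = argparse.ArgumentParser()
ap.add_argument("--study", type=Path, default=Path("results/study"))
ap.add_argument("--out", type=Path, default=Path("results/par"))
ap.add_argument("--seed", type=int, default=1)
args = ap.parse_args()

layout = io.read_layout(args.study / "layout.yaml")
tracks = {
    sex: io.read_bedgraph(args.study / f"coverage_{sex}.bedGraph", layout)
    for sex in ("F", "M")
}
het = pd.read_csv(args.study / "het_sites.tsv", sep="\t")["pos"].to_numpy()

fm = pdet.normalized_fm_coverage(tracks, layout.autosomes,
                                 layout.sex_chromosome)
call = pdet.detect_par_boundary(fm, het)
if call.detected:
    print(f"PAR boundary: {call.boundary:,} bp ({call.evidence}); "
          f"coverage change-point {call.coverage_boundary:,} bp, "
          f"last heterozygous site ends at {call.het_boundary:,} bp"
          + (" [evidence lines disagree]" if call.discrepancy else ""))
    print(f"true PAR end in the simulated layout: {layout.par[1]:,} bp")
else:
    print("no PAR detected (no qualifying coverage step)")

io.write_report({
    "fm_coverage_track": fm,
    "par_call": {
        "detected": call.detected, "boundary": call.boundary,
        "coverage_boundary": call.coverage_boundary,
        "het_boundary": call.het_boundary,
        "discrepancy": call.discrepancy, "evidence": call.evidence,
    },
}, args.out, seed=args.seed)
print(f"wrote {args.out}")
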