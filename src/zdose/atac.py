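"""ATAC-seq peak processing.

Library thinning to the smallest library, orthologous-peak clustering by
reciprocal overlap, consensus peak construction, peak-to-gene assignment at
gene-centred and regulatory scopes, functional annotation of the highest
peak per gene, f:m peak-height ratios, and a permutation-based differential
accessibility test on raw counts in peaks.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from statsmodels.stats.multitest import multipletests

from zdose.datamodel import ValidationError, tss, tts
from zdose.expression import bootstrap_ratio_ci


# ---------------------------------------------------------------------------
# library thinning
# ---------------------------------------------------------------------------

def thin_libraries(counts: pd.DataFrame, seed: int = 0) -> pd.DataFrame:
    """Binomial down-sampling of every library to the smallest total.

    Each sample's counts are thinned with p = min_total / sample_total; the
    smallest library is left untouched, mirroring read-level down-sampling.
    """
    totals = counts.sum(axis=0)
    if (totals <= 0).any():
        bad = totals.index[totals <= 0][0]
        raise ValidationError(f"library {bad} has zero total")
    min_total = totals.min()
    rng = np.random.default_rng(seed)
    out = counts.copy()
    for col in counts.columns:
        p = float(min_total / totals[col])
        if p >= 1.0:
            continue
        out[col] = rng.binomial(counts[col].to_numpy(dtype=np.int64), p)
    return out


# ---------------------------------------------------------------------------
# orthologous / consensus peaks
# ---------------------------------------------------------------------------

class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[max(ri, rj)] = min(ri, rj)


def _overlap_ok(s1, e1, s2, e2, frac: float, reciprocal: bool) -> bool:
    ov = min(e1, e2) - max(s1, s2)
    if ov <= 0:
        return False
    f1, f2 = ov / (e1 - s1), ov / (e2 - s2)
    return (f1 >= frac and f2 >= frac) if reciprocal else (f1 >= frac or f2 >= frac)


@dataclass
class OrthologousPeakTable:
    """Clusters of positionally matched peaks across samples.

    ``clusters``: cluster_id, chrom, start, end (union interval), n_samples.
    ``heights``: clusters x samples fold-enrichment, NaN where the sample
    contributed no peak.
    """

    clusters: pd.DataFrame
    heights: pd.DataFrame


def build_orthologous_peaks(peaksets: dict[str, pd.DataFrame],
                            min_overlap_frac: float = 0.5,
                            min_samples: int = 2,
                            reciprocal: bool = True) -> OrthologousPeakTable:
    """Cluster peaks across samples by positional overlap.

    Two peaks are joined iff they overlap by >= ``min_overlap_frac`` of each
    peak's length (reciprocal, the stricter reading; single-sided available);
    clusters are connected components. Within-sample duplicates keep the
    highest peak; clusters seen in fewer than ``min_samples`` distinct
    samples are dropped (singletons may be call errors). Sample input order
    does not affect the result.
    """
    rows = []
    for sample in sorted(peaksets):
        df = peaksets[sample]
        for r in df.itertuples(index=False):
            rows.append((r.chrom, int(r.start), int(r.end), float(r.height), sample))
    if not rows:
        return OrthologousPeakTable(
            clusters=pd.DataFrame(columns=["cluster_id", "chrom", "start", "end",
                                           "n_samples"]),
            heights=pd.DataFrame(columns=sorted(peaksets)),
        )
    allp = pd.DataFrame(rows, columns=["chrom", "start", "end", "height", "sample"])
    allp = allp.sort_values(["chrom", "start", "end", "sample"]).reset_index(drop=True)
    uf = _UnionFind(len(allp))
    for _, grp in allp.groupby("chrom", sort=True):
        idx = grp.index.to_numpy()
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        active: list[int] = []  # indices into grp arrays, sweep by start
        for i in range(len(idx)):
            active = [j for j in active if ends[j] > starts[i]]
            for j in active:
                if _overlap_ok(starts[i], ends[i], starts[j], ends[j],
                               min_overlap_frac, reciprocal):
                    uf.union(int(idx[i]), int(idx[j]))
            active.append(i)
    allp["cluster"] = [uf.find(i) for i in range(len(allp))]

    samples = sorted(peaksets)
    crows, hrows = [], []
    for cid, (_, grp) in enumerate(sorted(allp.groupby("cluster"),
                                          key=lambda kv: kv[0])):
        # within-sample duplicates: keep the highest peak
        best = grp.sort_values("height", ascending=False).drop_duplicates("sample")
        n_samp = best["sample"].nunique()
        if n_samp < min_samples:
            continue
        crows.append((f"c{len(crows)}", grp["chrom"].iloc[0],
                      int(grp["start"].min()), int(grp["end"].max()), n_samp))
        h = {s: np.nan for s in samples}
        h.update(dict(zip(best["sample"], best["height"])))
        hrows.append(h)
    clusters = pd.DataFrame(
        crows, columns=["cluster_id", "chrom", "start", "end", "n_samples"]
    )
    heights = pd.DataFrame(hrows, columns=samples)
    heights.index = clusters["cluster_id"].to_numpy() if len(clusters) else []
    return OrthologousPeakTable(clusters=clusters, heights=heights)


def build_consensus_peaks(peaksets: dict[str, pd.DataFrame],
                          share_frac: float = 0.8,
                          merge_overlap: float = 0.5,
                          min_overlap_frac: float = 0.5) -> pd.DataFrame:
    """Consensus intervals: clusters present in >= ceil(share_frac x n)
    samples, then overlapping retained clusters (>= merge_overlap) merged
    into single, pairwise non-overlapping intervals."""
    if len(peaksets) < 2:
        raise ValidationError("consensus peaks need >= 2 samples")
    need = math.ceil(share_frac * len(peaksets))
    table = build_orthologous_peaks(
        peaksets, min_overlap_frac=min_overlap_frac, min_samples=1
    )
    kept = table.clusters[table.clusters["n_samples"] >= need].reset_index(drop=True)
    if kept.empty:
        return pd.DataFrame(columns=["chrom", "start", "end"])
    uf = _UnionFind(len(kept))
    kept = kept.sort_values(["chrom", "start"]).reset_index(drop=True)
    for _, grp in kept.groupby("chrom"):
        idx = grp.index.to_numpy()
        starts, ends = grp["start"].to_numpy(), grp["end"].to_numpy()
        active: list[int] = []
        for i in range(len(idx)):
            active = [j for j in active if ends[j] > starts[i]]
            for j in active:
                if _overlap_ok(starts[i], ends[i], starts[j], ends[j],
                               merge_overlap, True):
                    uf.union(int(idx[i]), int(idx[j]))
            active.append(i)
    kept["comp"] = [uf.find(i) for i in range(len(kept))]
    merged = kept.groupby(["chrom", "comp"], as_index=False).agg(
        start=("start", "min"), end=("end", "max")
    )[["chrom", "start", "end"]]
    # merge any residual overlaps produced transitively
    out = []
    for chrom, grp in merged.sort_values(["chrom", "start"]).groupby("chrom"):
        cur_s = cur_e = None
        for r in grp.itertuples(index=False):
            if cur_s is None:
                cur_s, cur_e = r.start, r.end
            elif r.start < cur_e:
                cur_e = max(cur_e, r.end)
            else:
                out.append((chrom, cur_s, cur_e))
                cur_s, cur_e = r.start, r.end
        if cur_s is not None:
            out.append((chrom, cur_s, cur_e))
    return pd.DataFrame(out, columns=["chrom", "start", "end"])


# ---------------------------------------------------------------------------
# peak-to-gene assignment and annotation
# ---------------------------------------------------------------------------

def assign_peaks_to_genes(peaks: pd.DataFrame, genes: pd.DataFrame,
                          scope: str = "gene_centred",
                          gene_flank: int = 20_000,
                          regulatory_flank: int = 1_000) -> pd.DataFrame:
    """Link peaks to genes.

    gene_centred: peak intersects [start - 20 kb, end + 20 kb).
    regulatory: peak intersects the strand-aware 1-kb window upstream of the
    TSS or downstream of the TTS and does not lie within the gene body.
    Peaks may link to multiple genes. Returns ``peak_index, gene_id, scope``.
    """
    if scope not in ("gene_centred", "regulatory"):
        raise ValidationError(f"unknown scope {scope!r}")
    trees: dict[str, IntervalTree] = {}
    g_tss, g_tts = tss(genes), tts(genes)
    for i, g in genes.iterrows():
        tree = trees.setdefault(g["chrom"], IntervalTree())
        if scope == "gene_centred":
            tree.addi(max(0, g["start"] - gene_flank), g["end"] + gene_flank, i)
        else:
            if g["strand"] == "+":
                up = (max(0, g_tss[i] - regulatory_flank), g_tss[i])
                down = (g_tts[i] + 1, g_tts[i] + 1 + regulatory_flank)
            else:
                up = (g_tss[i] + 1, g_tss[i] + 1 + regulatory_flank)
                down = (max(0, g_tts[i] - regulatory_flank), g_tts[i])
            for s, e in (up, down):
                if e > s:
                    tree.addi(s, e, i)
    links = []
    for pi, p in peaks.iterrows():
        tree = trees.get(p["chrom"])
        if tree is None:
            continue
        hit_genes = {iv.data for iv in tree.overlap(p["start"], p["end"])}
        for gi in hit_genes:
            g = genes.loc[gi]
            if scope == "regulatory":
                # exclude peaks lying within the gene body
                if p["start"] >= g["start"] and p["end"] <= g["end"]:
                    continue
            links.append((pi, g["gene_id"], scope))
    return pd.DataFrame(links, columns=["peak_index", "gene_id", "scope"])


def highest_peak_category(gene: pd.Series, linked_peaks: pd.DataFrame,
                          exons: pd.DataFrame | None = None,
                          window: int = 1_000) -> str | None:
    """Functional category of a gene's highest linked peak.

    Category from the peak summit (narrowPeak summit offset when present,
    else the interval midpoint) with priority TSS(+-1 kb) > TTS(+-1 kb) >
    exon > intron > intergenic. Height ties break to the peak closest to
    the TSS. Without an exon table the whole gene body counts as exon.
    Returns None when the gene has no linked peaks.
    """
    if linked_peaks is None or len(linked_peaks) == 0:
        return None
    g_tss = gene["start"] if gene["strand"] == "+" else gene["end"] - 1
    g_tts = gene["end"] - 1 if gene["strand"] == "+" else gene["start"]

    def summit(p) -> int:
        if "summit" in p and not pd.isna(p["summit"]):
            return int(p["start"] + p["summit"])
        return int((p["start"] + p["end"]) // 2)

    best, best_key = None, None
    for _, p in linked_peaks.iterrows():
        key = (-float(p["height"]), abs(summit(p) - g_tss))
        if best_key is None or key < best_key:
            best, best_key = p, key
    s = summit(best)
    if abs(s - g_tss) <= window:
        return "TSS"
    if abs(s - g_tts) <= window:
        return "TTS"
    if gene["start"] <= s < gene["end"]:
        if exons is None:
            return "exon"
        ex = exons[exons["gene_id"] == gene["gene_id"]]
        in_exon = ((ex["start"] <= s) & (s < ex["end"])).any()
        return "exon" if in_exon else "intron"
    return "intergenic"


# ---------------------------------------------------------------------------
# f:m height ratios
# ---------------------------------------------------------------------------

def peak_height_fm_ratio(table: OrthologousPeakTable, samples: pd.DataFrame,
                         links: pd.DataFrame | None = None,
                         by: str = "gene", strict: bool = False,
                         n_boot: int = 10_000, seed: int = 0):
    """Per-unit log2(median female height / median male height).

    ``by='gene'`` pools the heights of all clusters linked to each gene
    (requires ``links`` with cluster_id/gene_id); ``by='chromosome'`` pools
    clusters per chromosome. Strict mode keeps only clusters called in
    every sample. Returns ``(per_unit_ratios, RatioEstimate over units)``.
    """
    heights = table.heights
    clusters = table.clusters.set_index("cluster_id")
    if strict:
        full = heights.notna().all(axis=1)
        heights = heights.loc[full]
        clusters = clusters.loc[heights.index]
    f_cols = samples.loc[samples["sex"] == "F", "sample_id"]
    m_cols = samples.loc[samples["sex"] == "M", "sample_id"]
    f_cols = [c for c in f_cols if c in heights.columns]
    m_cols = [c for c in m_cols if c in heights.columns]

    if by == "gene":
        if links is None:
            raise ValidationError("by='gene' requires cluster-to-gene links")
        groups = links.groupby("gene_id")["cluster_id"].apply(list)
    elif by == "chromosome":
        groups = pd.Series({c: list(g.index)
                            for c, g in clusters.groupby("chrom")})
    else:
        raise ValidationError(f"unknown grouping {by!r}")

    ratios = {}
    for unit, cids in groups.items():
        cids = [c for c in cids if c in heights.index]
        if not cids:
            continue
        fv = heights.loc[cids, f_cols].to_numpy().ravel()
        mv = heights.loc[cids, m_cols].to_numpy().ravel()
        med_f = np.nanmedian(fv) if np.isfinite(fv).any() else np.nan
        med_m = np.nanmedian(mv) if np.isfinite(mv).any() else np.nan
        if not np.isfinite(med_f) or not np.isfinite(med_m) or med_m == 0:
            ratios[unit] = np.nan
        else:
            ratios[unit] = float(np.log2(med_f / med_m))
    per_unit = pd.Series(ratios, name="log2_fm_height")
    evaluable = per_unit.dropna().to_numpy()
    summary = None
    if len(evaluable) >= 2:
        summary = bootstrap_ratio_ci(
            evaluable, n_boot=n_boot, seed=seed,
            label=f"fm_height_by_{by}", scale="log2",
        )
    return per_unit, summary


def link_clusters_to_genes(table: OrthologousPeakTable, genes: pd.DataFrame,
                           scope: str = "gene_centred", **kw) -> pd.DataFrame:
    """Assign orthologous clusters (union intervals) to genes; returns
    ``cluster_id, gene_id, scope``."""
    links = assign_peaks_to_genes(
        table.clusters.set_index("cluster_id")[["chrom", "start", "end"]],
        genes, scope=scope, **kw,
    )
    links = links.rename(columns={"peak_index": "cluster_id"})
    return links


# ---------------------------------------------------------------------------
# differential accessibility (permutation test)
# ---------------------------------------------------------------------------

def cpm(counts: pd.DataFrame, library_sizes: pd.Series | None = None) -> pd.DataFrame:
    lib = counts.sum(axis=0) if library_sizes is None else library_sizes
    return counts.div(lib, axis=1) * 1e6


def peak_differential(counts: pd.DataFrame, samples: pd.DataFrame,
                      cpm_min: float = 1.0, min_samples: int = 7,
                      n_perm: int = 10_000, seed: int = 0) -> pd.DataFrame:
    """Sex-differential accessibility by label permutation.

    Peaks are kept iff cpm > ``cpm_min`` in >= ``min_samples`` samples. The
    statistic is the difference of mean log2(cpm + 0.5) between sexes
    (female minus male); p-values come from exhaustive label permutation
    when feasible, Monte-Carlo otherwise; BH correction across peaks.
    """
    if n_perm < 100:
        raise ValidationError("n_perm must be >= 100")
    for sex in ("F", "M"):
        if (samples["sex"] == sex).sum() < 2:
            raise ValidationError(f"need >= 2 samples of sex {sex}")
    c = cpm(counts)
    keep = (c > cpm_min).sum(axis=1) >= min_samples
    c = c.loc[keep]
    if c.empty:
        return pd.DataFrame(columns=["peak", "log2_fc", "p", "q"])
    sex = samples.set_index("sample_id")["sex"].reindex(c.columns)
    is_f = (sex == "F").to_numpy()
    n_f = int(is_f.sum())
    x = np.log2(c.to_numpy(dtype=float) + 0.5)

    def stat(mask_f: np.ndarray) -> np.ndarray:
        return x[:, mask_f].mean(axis=1) - x[:, ~mask_f].mean(axis=1)

    obs = stat(is_f)
    n_total = x.shape[1]
    n_exact = math.comb(n_total, n_f)
    if n_exact <= n_perm:
        null = np.empty((n_exact, x.shape[0]))
        for k, combo in enumerate(itertools.combinations(range(n_total), n_f)):
            mask = np.zeros(n_total, dtype=bool)
            mask[list(combo)] = True
            null[k] = stat(mask)
        p = (np.abs(null) >= np.abs(obs)[None, :] - 1e-12).mean(axis=0)
    else:
        rng = np.random.default_rng(seed)
        exceed = np.zeros(x.shape[0])
        for _ in range(n_perm):
            mask = np.zeros(n_total, dtype=bool)
            mask[rng.choice(n_total, size=n_f, replace=False)] = True
            exceed += np.abs(stat(mask)) >= np.abs(obs) - 1e-12
        p = (exceed + 1.0) / (n_perm + 1.0)
    q = multipletests(p, method="fdr_bh")[1]
    return pd.DataFrame({
        "peak": c.index, "log2_fc": obs, "p": p, "q": q,
    }).reset_index(drop=True)
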