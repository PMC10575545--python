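"""Generative models for a ZW multi-omic study.

Emulates the statistical structure the downstream analysis assumes: a
genome of macro-autosomes plus a Z chromosome whose first ~688 kb form a
diploid PAR; 8 female / 7 male individuals in two tissues; partial female
upregulation of non-PAR Z genes (per-gene compensation factor c_g in
[0.5, 1], so the linear f:m expectation is exactly c_g); ATAC peak heights
elevated on the female Z; methylation high in gene bodies, reduced and
bimodal in CpG islands, near zero inside accessibility peaks; and
ploidy-structured DNA read depth.

Randomness policy: a master seed is fanned out into named substreams per
(layer, sample), so adding or re-running one layer never perturbs another.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from zdose.datamodel import (
    GenomeLayout,
    ExpressionMatrix,
    ValidationError,
)


def substream(seed: int, *keys) -> np.random.Generator:
    """Independent generator for a named layer, derived from the master seed."""
    entropy = [int(seed)] + [zlib.crc32(str(k).encode()) for k in keys]
    return np.random.default_rng(np.random.SeedSequence(entropy))


@dataclass
class SimulationConfig:
    """Study conditions for the generator.

    Defaults mirror the emulated study: 8F/7M individuals, two tissues,
    ~7 ATAC peaks per expressed gene, gene-body methylation 0.66, CpG-island
    methylation 0.20, near-zero methylation inside peaks, and a PAR ending
    at 687,785 bp on a 75-Mb Z (scaled layouts supply their own lengths).
    """

    # genome
    n_autosomes: int = 2
    autosome_lengths: tuple[int, ...] = (600_000, 600_000)
    z_length: int = 800_000
    par_end: int = 200_000
    genes_per_chromosome: int = 20
    gene_length_range: tuple[int, int] = (2_000, 8_000)
    make_sequences: bool = True
    island_length_range: tuple[int, int] = (300, 600)

    # samples
    n_females: int = 8
    n_males: int = 7
    tissues: tuple[str, ...] = ("liver", "spleen")

    # expression
    baseline_log_mean: float = np.log(30.0)
    baseline_log_sd: float = 1.0
    # common random numbers: reuse one baseline draw for every chromosome
    # (by within-chromosome gene rank), so Z and autosomes share identical
    # per-copy expression values rather than merely identical distributions
    shared_baseline_across_chroms: bool = False
    nb_dispersion: float = 0.08
    library_factor_range: tuple[float, float] = (0.7, 1.3)
    compensation_fixed: float | None = None  # overrides the mixture if set
    # mixture over non-PAR Z genes: (weight, c_low, c_high) per class,
    # weights from the observed fully/partially/un-balanced gene counts
    compensation_mixture: tuple[tuple[float, float, float], ...] = (
        (0.28, 1.00, 1.00),   # fully compensated
        (0.19, 0.63, 0.85),   # partially compensated
        (0.53, 0.50, 0.60),   # uncompensated (pure dose effect)
    )
    tissue_compensation_mult: dict = field(
        default_factory=lambda: {"liver": 1.0, "spleen": 1.0}
    )

    # ATAC
    peaks_per_gene_mean: float = 7.0
    peak_width_range: tuple[int, int] = (300, 600)
    peak_height_log_mean: float = np.log(5.0)
    peak_height_log_sd: float = 0.5
    peak_height_sample_sd: float = 0.25
    female_z_height_mult: float = 1.12
    peak_presence_prob: float = 0.95
    peak_jitter: int = 40
    intergenic_peaks_per_mb: float = 2.0

    # methylation
    meth_gene_body: float = 0.66
    meth_island: float = 0.20
    meth_peak: float = 0.02
    meth_background: float = 0.70
    meth_dispersion: float = 0.05  # beta-binomial intra-class correlation
    meth_depth: float = 30.0
    meth_sex_effect_logit: float = 0.0
    island_site_spacing: int = 10
    gene_body_site_spacing: int = 100
    background_site_spacing: int = 300

    # coverage / heterozygosity
    per_copy_depth: float = 10.0
    read_length: int = 150
    coverage_window: int = 50_000
    n_het_snps: int = 15

    seed: int = 0

    def __post_init__(self) -> None:
        if self.par_end >= self.z_length:
            raise ValidationError("par_end must be < z_length")
        if self.compensation_fixed is not None and not (
            0.5 <= self.compensation_fixed <= 1.0
        ):
            raise ValidationError("compensation factor must lie in [0.5, 1]")
        for w, lo, hi in self.compensation_mixture:
            if not (0.5 <= lo <= hi <= 1.0):
                raise ValidationError("mixture c ranges must lie in [0.5, 1]")
        for rate in (self.peaks_per_gene_mean, self.meth_depth, self.per_copy_depth):
            if rate <= 0:
                raise ValidationError("all rates must be > 0")


def make_layout(cfg: SimulationConfig) -> GenomeLayout:
    chroms = tuple(
        (f"chr{i + 1}", ln)
        for i, ln in enumerate(cfg.autosome_lengths[: cfg.n_autosomes])
    ) + (("chrZ", cfg.z_length),)
    return GenomeLayout(chromosomes=chroms, sex_chromosome="chrZ",
                        par=(0, cfg.par_end))


def make_samples(cfg: SimulationConfig, tissue: str | None = None) -> pd.DataFrame:
    """Sample sheet: one row per individual x tissue (or a single tissue)."""
    tissues = [tissue] if tissue is not None else list(cfg.tissues)
    rows = []
    for t in tissues:
        for i in range(cfg.n_females):
            rows.append((f"F{i + 1}_{t}", "F", t, f"F{i + 1}"))
        for i in range(cfg.n_males):
            rows.append((f"M{i + 1}_{t}", "M", t, f"M{i + 1}"))
    return pd.DataFrame(rows, columns=["sample_id", "sex", "tissue", "individual"])


# ---------------------------------------------------------------------------
# genome
# ---------------------------------------------------------------------------

def _random_sequence(rng, length: int, p_gc: float) -> np.ndarray:
    p = p_gc / 2.0
    return rng.choice(
        np.frombuffer(b"ACGT", dtype="S1"),
        size=length,
        p=[(1 - p_gc) / 2, p, p, (1 - p_gc) / 2],
    )


def simulate_genome(cfg: SimulationConfig) -> dict:
    """Genome layout, non-overlapping genes, exon structure, CpG-island
    sites, and (optionally) sequences with CG-rich islands on an AT-rich
    background.

    Returns a dict with keys ``layout, genes, exons, islands, sequences``.
    """
    layout = make_layout(cfg)
    rng = substream(cfg.seed, "genome")
    genes_rows, exon_rows, island_rows = [], [], []
    sequences: dict[str, str] = {}
    max_gene = cfg.gene_length_range[1]
    for chrom, length in layout.chromosomes:
        n = cfg.genes_per_chromosome
        slot = length // n
        if slot <= max_gene + 2 * cfg.island_length_range[1]:
            raise ValidationError(
                f"{n} genes of <= {max_gene} bp do not fit on {chrom} ({length} bp)"
            )
        for i in range(n):
            glen = int(rng.integers(*cfg.gene_length_range))
            lo = i * slot + cfg.island_length_range[1] + 100
            hi = (i + 1) * slot - glen - 100
            start = int(rng.integers(lo, hi))
            strand = "+" if rng.random() < 0.5 else "-"
            gid = f"{chrom}_g{i + 1}"
            genes_rows.append((gid, chrom, start, start + glen, strand))
            # 2-4 exons tiled across the gene body
            n_ex = int(rng.integers(2, 5))
            bounds = np.linspace(start, start + glen, n_ex + 1).astype(int)
            for j in range(n_ex):
                ex_s = int(bounds[j])
                ex_e = int(bounds[j] + max(50, (bounds[j + 1] - bounds[j]) // 2))
                exon_rows.append((gid, chrom, ex_s, min(ex_e, start + glen)))
            # CpG island upstream of the TSS
            ilen = int(rng.integers(*cfg.island_length_range))
            if strand == "+":
                isl_s = max(0, start - ilen - 20)
            else:
                isl_s = min(length - ilen, start + glen + 20)
            island_rows.append((chrom, isl_s, isl_s + ilen))
    genes = pd.DataFrame(
        genes_rows, columns=["gene_id", "chrom", "start", "end", "strand"]
    )
    exons = pd.DataFrame(exon_rows, columns=["gene_id", "chrom", "start", "end"])
    islands = pd.DataFrame(island_rows, columns=["chrom", "start", "end"])
    if cfg.make_sequences:
        for chrom, length in layout.chromosomes:
            seq = _random_sequence(substream(cfg.seed, "seq", chrom), length, 0.20)
            for _, isl in islands[islands["chrom"] == chrom].iterrows():
                s, e = int(isl["start"]), int(isl["end"])
                seq[s:e] = _random_sequence(
                    substream(cfg.seed, "seq_isl", chrom, s), e - s, 0.70
                )
            sequences[chrom] = seq.tobytes().decode()
    return {
        "layout": layout,
        "genes": genes,
        "exons": exons,
        "islands": islands,
        "sequences": sequences,
    }


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------

def assign_compensation(genes: pd.DataFrame, layout: GenomeLayout,
                        cfg: SimulationConfig, seed: int | None = None
                        ) -> pd.Series:
    """True per-gene compensation factor c_g (1.0 off the hemizygous Z)."""
    rng = substream(cfg.seed if seed is None else seed, "compensation")
    c = pd.Series(1.0, index=genes["gene_id"].to_numpy(), name="c_g")
    nonpar = layout.is_nonpar_z(genes["chrom"], genes["start"])
    z_ids = genes.loc[nonpar, "gene_id"].to_numpy()
    if cfg.compensation_fixed is not None:
        c[z_ids] = cfg.compensation_fixed
        return c
    weights = np.array([w for w, _, _ in cfg.compensation_mixture], dtype=float)
    weights /= weights.sum()
    cls = rng.choice(len(weights), size=len(z_ids), p=weights)
    draws = np.empty(len(z_ids))
    for k, (_, lo, hi) in enumerate(cfg.compensation_mixture):
        m = cls == k
        draws[m] = lo if lo == hi else rng.uniform(lo, hi, size=m.sum())
    c[z_ids] = draws
    return c


def simulate_expression(layout: GenomeLayout, genes: pd.DataFrame,
                        cfg: SimulationConfig, seed: int | None = None,
                        tissue: str | None = None
                        ) -> tuple[ExpressionMatrix, pd.DataFrame, pd.DataFrame]:
    """Negative-binomial RNA-seq counts under the copy-number/compensation model.

    Expected expression of gene g in sample s is
    ``baseline_g x copies(g, s) x c(g, s)`` where copies = 2 except 1 for
    the female non-PAR Z, and the single female Z copy is scaled by
    ``2 * c_g`` so the linear f:m expectation equals exactly ``c_g``.

    Returns ``(counts, samples, truth)`` where truth holds the generative
    baseline and c_g per gene.
    """
    seed = cfg.seed if seed is None else seed
    samples = make_samples(cfg, tissue=tissue)
    rng_base = substream(seed, "expr_baseline")
    if cfg.shared_baseline_across_chroms:
        per_chrom = genes.groupby("chrom").cumcount().to_numpy()
        draw = np.exp(rng_base.normal(
            cfg.baseline_log_mean, cfg.baseline_log_sd, size=per_chrom.max() + 1
        ))
        baseline = draw[per_chrom]
    else:
        baseline = np.exp(rng_base.normal(
            cfg.baseline_log_mean, cfg.baseline_log_sd, size=len(genes)
        ))
    c_g = assign_compensation(genes, layout, cfg, seed=seed).to_numpy()
    nonpar = np.asarray(layout.is_nonpar_z(genes["chrom"], genes["start"]))
    gene_len = (genes["end"] - genes["start"]).to_numpy()

    counts = np.zeros((len(genes), len(samples)), dtype=np.int64)
    lib_factors = np.empty(len(samples))
    for j, row in samples.iterrows():
        rng = substream(seed, "expr", row["sample_id"])
        lib = rng.uniform(*cfg.library_factor_range)
        lib_factors[j] = lib
        t_mult = cfg.tissue_compensation_mult.get(row["tissue"], 1.0)
        if row["sex"] == "F":
            c_eff = np.where(nonpar, np.clip(c_g * t_mult, 0.5, 1.0), 1.0)
            mean_per_copy = baseline * np.where(nonpar, 2.0 * c_eff, 1.0)
            copies = np.where(nonpar, 1.0, 2.0)
        else:
            mean_per_copy = baseline
            copies = np.full(len(genes), 2.0)
        # read counts scale with gene length; baseline is the diploid
        # FPKM-scale expression level, recovered exactly by compute_fpkm
        # with the nominal library size below
        mu = mean_per_copy * copies * (gene_len / 1000.0) * lib / 2.0
        r = 1.0 / cfg.nb_dispersion
        counts[:, j] = rng.negative_binomial(r, r / (r + mu))
    # nominal sequencing depth per library (sex-independent by design, so
    # FPKM normalisation does not absorb the Z-composition effect that a
    # desk-scale genome would exaggerate relative to a real transcriptome)
    samples = samples.assign(library_size=lib_factors * 1e6)
    values = pd.DataFrame(counts, index=genes["gene_id"].to_numpy(),
                          columns=samples["sample_id"].to_numpy())
    expr = ExpressionMatrix(
        values=values, unit="counts",
        gene_lengths=pd.Series(gene_len, index=genes["gene_id"].to_numpy()),
    )
    truth = pd.DataFrame({
        "gene_id": genes["gene_id"].to_numpy(),
        "chrom": genes["chrom"].to_numpy(),
        "baseline": baseline,
        "c_g": c_g,
        "nonpar_z": nonpar,
    })
    return expr, samples, truth


# ---------------------------------------------------------------------------
# ATAC peaks
# ---------------------------------------------------------------------------

def simulate_atac(layout: GenomeLayout, genes: pd.DataFrame,
                  cfg: SimulationConfig, seed: int | None = None,
                  tissue: str | None = None
                  ) -> tuple[dict[str, pd.DataFrame], pd.DataFrame]:
    """Per-sample ATAC peak calls with log-normal heights.

    Each gene receives a Poisson number of peak *sites* (promoter, body or
    flank slots) shared across samples; heights vary per sample and are
    multiplied by ``female_z_height_mult`` on the female non-PAR Z.
    Per-sample start/end jitter is small relative to peak width so
    orthologous peaks overlap reciprocally.
    """
    seed = cfg.seed if seed is None else seed
    samples = make_samples(cfg, tissue=tissue)
    rng_site = substream(seed, "atac_sites")
    lengths = layout.lengths
    sites = []  # (chrom, start, end, base_height, nonpar_z, gene_id)
    for _, g in genes.iterrows():
        n_pk = rng_site.poisson(cfg.peaks_per_gene_mean)
        gene_tss = g["start"] if g["strand"] == "+" else g["end"] - 1
        for _ in range(n_pk):
            width = int(rng_site.integers(*cfg.peak_width_range))
            slot = rng_site.choice(["promoter", "body", "flank"], p=[0.3, 0.4, 0.3])
            if slot == "promoter":
                center = gene_tss + int(rng_site.integers(-900, -100)) * (
                    1 if g["strand"] == "+" else -1
                )
            elif slot == "body":
                center = int(rng_site.integers(g["start"], g["end"]))
            else:
                off = int(rng_site.integers(2_000, 20_000))
                center = (g["start"] - off) if rng_site.random() < 0.5 else (
                    g["end"] + off
                )
            start = max(0, center - width // 2)
            end = min(lengths[g["chrom"]], start + width)
            if end - start < 50:
                continue
            h = float(np.exp(rng_site.normal(cfg.peak_height_log_mean,
                                             cfg.peak_height_log_sd)))
            npz = bool(layout.is_nonpar_z(np.array([g["chrom"]], dtype=object),
                                          np.array([start]))[0])
            sites.append((g["chrom"], start, end, h, npz, g["gene_id"]))
    # intergenic background peaks
    for chrom, length in layout.chromosomes:
        n_bg = rng_site.poisson(cfg.intergenic_peaks_per_mb * length / 1e6)
        for _ in range(n_bg):
            width = int(rng_site.integers(*cfg.peak_width_range))
            start = int(rng_site.integers(0, max(1, length - width)))
            h = float(np.exp(rng_site.normal(cfg.peak_height_log_mean,
                                             cfg.peak_height_log_sd)))
            npz = bool(layout.is_nonpar_z(np.array([chrom], dtype=object),
                                          np.array([start]))[0])
            sites.append((chrom, start, start + width, h, npz, ""))
    site_df = pd.DataFrame(
        sites, columns=["chrom", "start", "end", "base_height", "nonpar_z", "gene_id"]
    )
    peaksets: dict[str, pd.DataFrame] = {}
    for _, row in samples.iterrows():
        rng = substream(seed, "atac", row["sample_id"])
        present = rng.random(len(site_df)) < cfg.peak_presence_prob
        sub = site_df.loc[present].copy()
        jit_s = rng.integers(-cfg.peak_jitter, cfg.peak_jitter + 1, size=len(sub))
        jit_e = rng.integers(-cfg.peak_jitter, cfg.peak_jitter + 1, size=len(sub))
        sub["start"] = np.maximum(0, sub["start"] + jit_s)
        sub["end"] = np.maximum(sub["start"] + 50, sub["end"] + jit_e)
        max_len = sub["chrom"].map(lengths)
        sub["end"] = np.minimum(sub["end"], max_len)
        mult = np.where(
            sub["nonpar_z"] & (row["sex"] == "F"), cfg.female_z_height_mult, 1.0
        )
        noise = np.exp(rng.normal(0.0, cfg.peak_height_sample_sd, size=len(sub)))
        sub["height"] = sub["base_height"] * mult * noise
        sub["q"] = rng.uniform(0.0, 0.05, size=len(sub))
        peaksets[row["sample_id"]] = sub[
            ["chrom", "start", "end", "height", "q"]
        ].reset_index(drop=True)
    return peaksets, samples


# ---------------------------------------------------------------------------
# methylation
# ---------------------------------------------------------------------------

def _region_means(layout, genes, islands, peaks, cfg, positions_by_chrom):
    """Per-site methylation mean by region priority: peak > island > body > bg."""
    means = {}
    for chrom, pos in positions_by_chrom.items():
        m = np.full(len(pos), cfg.meth_background)
        gb = genes[genes["chrom"] == chrom]
        for _, g in gb.iterrows():
            m[(pos >= g["start"]) & (pos < g["end"])] = cfg.meth_gene_body
        for _, isl in islands[islands["chrom"] == chrom].iterrows():
            m[(pos >= isl["start"]) & (pos < isl["end"])] = cfg.meth_island
        if peaks is not None:
            pk = peaks[peaks["chrom"] == chrom]
            for _, p in pk.iterrows():
                m[(pos >= p["start"]) & (pos < p["end"])] = cfg.meth_peak
        means[chrom] = m
    return means


def simulate_methylation(layout: GenomeLayout, genes: pd.DataFrame,
                         islands: pd.DataFrame, peaks: pd.DataFrame | None,
                         cfg: SimulationConfig, seed: int | None = None,
                         tissue: str | None = None
                         ) -> tuple[dict[str, pd.DataFrame], pd.DataFrame]:
    """Per-CpG beta-binomial methylation calls per sample.

    CpG sites are placed densely inside islands, sparsely in gene bodies and
    the background; per-site depth is Poisson, the methylated count is
    beta-binomial around the region mean with a sex effect on the logit
    scale (zero by default, i.e. a null sex design).
    """
    seed = cfg.seed if seed is None else seed
    samples = make_samples(cfg, tissue=tissue)
    rng_pos = substream(seed, "meth_sites")
    positions: dict[str, np.ndarray] = {}
    for chrom, length in layout.chromosomes:
        pos = [np.arange(0, length, cfg.background_site_spacing)]
        for _, g in genes[genes["chrom"] == chrom].iterrows():
            pos.append(np.arange(g["start"], g["end"], cfg.gene_body_site_spacing))
        for _, isl in islands[islands["chrom"] == chrom].iterrows():
            pos.append(np.arange(isl["start"], isl["end"], cfg.island_site_spacing))
        allpos = np.unique(np.concatenate(pos))
        jitter = rng_pos.integers(0, 5, size=len(allpos))
        positions[chrom] = np.unique(np.minimum(allpos + jitter, length - 1))
    means = _region_means(layout, genes, islands, peaks, cfg, positions)
    rho = cfg.meth_dispersion
    callsets: dict[str, pd.DataFrame] = {}
    for _, row in samples.iterrows():
        rng = substream(seed, "meth", row["sample_id"])
        frames = []
        sex_shift = cfg.meth_sex_effect_logit if row["sex"] == "F" else 0.0
        for chrom, pos in positions.items():
            mu = np.clip(means[chrom], 1e-4, 1 - 1e-4)
            if sex_shift:
                logit = np.log(mu / (1 - mu)) + sex_shift
                mu = 1.0 / (1.0 + np.exp(-logit))
            n_total = rng.poisson(cfg.meth_depth, size=len(pos))
            a = mu * (1 - rho) / rho
            b = (1 - mu) * (1 - rho) / rho
            p = rng.beta(a, b)
            n_meth = rng.binomial(n_total, p)
            frames.append(pd.DataFrame({
                "chrom": chrom, "pos": pos, "n_meth": n_meth, "n_total": n_total,
            }))
        calls = pd.concat(frames, ignore_index=True)
        callsets[row["sample_id"]] = calls[calls["n_total"] > 0].reset_index(drop=True)
    return callsets, samples


# ---------------------------------------------------------------------------
# DNA coverage and heterozygosity
# ---------------------------------------------------------------------------

def simulate_coverage(layout: GenomeLayout, cfg: SimulationConfig,
                      seed: int | None = None, window: int | None = None,
                      noise: bool = True) -> dict[str, pd.DataFrame]:
    """Windowed read-depth tracks for one female and one male.

    Mean window depth is per-copy depth x copies; the female Z carries 2
    copies inside the PAR and 1 outside, the male Z and all autosomes 2.
    Noise enters at the read level: the number of reads falling in a window
    is Poisson(depth x window / read_length) and depth is recovered as
    reads x read_length / window. ``noise=False`` returns exact
    expectations (for worked examples).
    """
    seed = cfg.seed if seed is None else seed
    window = cfg.coverage_window if window is None else window
    tracks: dict[str, pd.DataFrame] = {}
    for sex in ("F", "M"):
        rng = substream(seed, "coverage", sex)
        frames = []
        for chrom, length in layout.chromosomes:
            starts = np.arange(0, length, window)
            ends = np.minimum(starts + window, length)
            copies = np.full(len(starts), 2.0)
            if chrom == layout.sex_chromosome and sex == "F":
                mids = (starts + ends) // 2
                copies = np.where(
                    (mids >= layout.par[0]) & (mids < layout.par[1]), 2.0, 1.0
                )
            mu = cfg.per_copy_depth * copies
            if noise:
                widths = (ends - starts).astype(float)
                lam = mu * widths / cfg.read_length
                depth = rng.poisson(lam) * cfg.read_length / widths
            else:
                depth = mu
            frames.append(pd.DataFrame({
                "chrom": chrom, "start": starts, "end": ends, "depth": depth,
            }))
        tracks[sex] = pd.concat(frames, ignore_index=True)
    return tracks


def simulate_het_sites(layout: GenomeLayout, cfg: SimulationConfig,
                       seed: int | None = None) -> np.ndarray:
    """Female-heterozygous genotyping SNPs on the Z.

    Emulates a sparse genotyping panel restricted to the recombining PAR:
    the first and last heterozygous sites delimit the observed interval
    (offset ~4% of the PAR from its start up to the PAR end), with the
    remaining sites uniform in between. Sorted bp positions.
    """
    seed = cfg.seed if seed is None else seed
    rng = substream(seed, "het")
    par_start, par_end = layout.par
    first = par_start + max(1, int(round(0.04 * (par_end - par_start))))
    last = par_end
    n_inner = max(0, cfg.n_het_snps - 2)
    inner = rng.integers(first + 1, last, size=n_inner) if n_inner else []
    return np.unique(np.concatenate([[first], np.sort(inner), [last]]).astype(int))


# ---------------------------------------------------------------------------
# bundled small study (test fixture)
# ---------------------------------------------------------------------------

def small_study(seed: int = 0, tissue: str | None = "liver") -> dict:
    """A small bundled study (2 autosomes + Z, 60 genes) generated on the
    fly: genome, expression counts, ATAC peak sets, methylation calls,
    coverage tracks and heterozygous sites, all from one master seed."""
    cfg = SimulationConfig(seed=seed)
    genome = simulate_genome(cfg)
    layout, genes = genome["layout"], genome["genes"]
    expr, samples, truth = simulate_expression(layout, genes, cfg, tissue=tissue)
    peaksets, _ = simulate_atac(layout, genes, cfg, tissue=tissue)
    meth, _ = simulate_methylation(
        layout, genes, genome["islands"],
        next(iter(peaksets.values())), cfg, tissue=tissue,
    )
    coverage = simulate_coverage(layout, cfg, window=10_000)
    het = simulate_het_sites(layout, cfg)
    return {
        "config": cfg,
        "layout": layout,
        "genes": genes,
        "exons": genome["exons"],
        "islands": genome["islands"],
        "sequences": genome["sequences"],
        "expression": expr,
        "samples": samples,
        "truth": truth,
        "peaks": peaksets,
        "methylation": meth,
        "coverage": coverage,
        "het_sites": het,
    }
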