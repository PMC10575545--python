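"""Expression normalisation, filtering, and dosage ratio/balance statistics.

The core statistics: per-gene f:m ratios ``log2(median(FPKM_F) /
median(FPKM_M))``, sex-specific Z:A ratios, a four/three-way dosage
balance classification, and feature-level percentile bootstrap CIs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from zdose.datamodel import ExpressionMatrix, RatioEstimate, ValidationError


def compute_fpkm(counts: ExpressionMatrix,
                 library_sizes: pd.Series | None = None) -> ExpressionMatrix:
    """FPKM = counts x 1e9 / (gene_length_bp x library_size).

    ``library_sizes`` defaults to the per-sample column sums of the count
    matrix (total assigned fragments).
    """
    if counts.unit != "counts":
        raise ValidationError("compute_fpkm expects a counts matrix")
    if counts.gene_lengths is None:
        raise ValidationError("gene lengths required for FPKM")
    lengths = counts.gene_lengths
    if (lengths <= 0).any():
        raise ValidationError("gene length must be > 0")
    if library_sizes is None:
        library_sizes = counts.values.sum(axis=0)
    library_sizes = library_sizes.reindex(counts.values.columns)
    if (library_sizes <= 0).any():
        raise ValidationError("library sizes must be > 0")
    fpkm = counts.values.mul(1e9).div(lengths, axis=0).div(library_sizes, axis=1)
    return ExpressionMatrix(values=fpkm, unit="FPKM", gene_lengths=lengths)


def zfpkm_scores(fpkm: ExpressionMatrix) -> pd.DataFrame:
    """Standardised log2-FPKM (zFPKM) scores per sample.

    Per sample, x = log2(FPKM) over genes with FPKM > 0; the distribution
    mode mu is located by a Gaussian kernel-density estimate and the spread
    is estimated from the right (actively transcribed) tail as a
    half-Gaussian: sigma = mean(x[x > mu] - mu) * sqrt(pi / 2). Genes with
    FPKM = 0 get -inf.
    """
    out = pd.DataFrame(
        -np.inf, index=fpkm.values.index, columns=fpkm.values.columns, dtype=float
    )
    for col in fpkm.values.columns:
        v = fpkm.values[col].to_numpy(dtype=float)
        pos = v > 0
        if pos.sum() < 2:
            raise ValidationError(f"{col}: need >= 2 genes with FPKM > 0")
        x = np.log2(v[pos])
        if np.ptp(x) == 0:
            raise ValidationError(f"{col}: degenerate FPKM distribution")
        kde = stats.gaussian_kde(x)
        grid = np.linspace(x.min(), x.max(), 512)
        mu = grid[np.argmax(kde(grid))]
        upper = x[x > mu]
        if len(upper) == 0:
            raise ValidationError(f"{col}: no mass right of the KDE mode")
        sigma = float(np.mean(upper - mu) * np.sqrt(np.pi / 2.0))
        if sigma == 0:
            raise ValidationError(f"{col}: zero right-tail spread")
        out.loc[pos, col] = (x - mu) / sigma
    return out


def zfpkm_filter(fpkm: ExpressionMatrix, threshold: float = -3.0
                 ) -> tuple[pd.DataFrame, pd.Index]:
    """Active-gene filter: expressed in a sample iff zFPKM > threshold.

    Returns ``(expressed_bool, intersection)`` where the intersection (genes
    expressed in all samples) is the gene set used for model fitting.
    """
    z = zfpkm_scores(fpkm)
    expressed = z > threshold
    intersection = expressed.index[expressed.all(axis=1)]
    return expressed, intersection


def mean_fpkm_filter(fpkm: ExpressionMatrix, samples: pd.DataFrame,
                     min_mean: float = 1.0) -> pd.Index:
    """Keep genes with mean FPKM >= min_mean in females AND in males."""
    for sex in ("F", "M"):
        if (samples["sex"] == sex).sum() == 0:
            raise ValidationError(f"no samples with sex {sex}")
    f_cols = samples.loc[samples["sex"] == "F", "sample_id"]
    m_cols = samples.loc[samples["sex"] == "M", "sample_id"]
    keep = (fpkm.values[f_cols].mean(axis=1) >= min_mean) & (
        fpkm.values[m_cols].mean(axis=1) >= min_mean
    )
    return fpkm.values.index[keep]


def gene_fm_ratio(values: pd.DataFrame, samples: pd.DataFrame
                  ) -> tuple[pd.Series, int]:
    """Per-gene log2(median female / median male) values.

    Genes whose female or male median is 0 are unevaluable: excluded (NaN)
    and counted in the returned tally.
    """
    f_cols = samples.loc[samples["sex"] == "F", "sample_id"]
    m_cols = samples.loc[samples["sex"] == "M", "sample_id"]
    if len(f_cols) == 0 or len(m_cols) == 0:
        raise ValidationError("need >= 1 sample of each sex")
    med_f = values[f_cols].median(axis=1)
    med_m = values[m_cols].median(axis=1)
    ok = (med_f > 0) & (med_m > 0)
    ratio = pd.Series(np.nan, index=values.index, name="log2_fm")
    ratio[ok] = np.log2(med_f[ok] / med_m[ok])
    return ratio, int((~ok).sum())


@dataclass(frozen=True)
class BalanceClass:
    value: str       # fully_balanced / partially_balanced / intermediate / unbalanced
    sex_bias: str    # none / female / male


def classify_balance(log2fm: float, scheme: str = "four") -> BalanceClass:
    """Dosage-balance category from a gene's log2(f:m) value.

    Four-class scheme (default): |v| <= 0.25 fully balanced; 0.25 < |v| <=
    0.5 partially balanced; 0.5 < |v| < 0.75 intermediate; |v| >= 0.75
    unbalanced. Boundaries fall to the less extreme class. The three-class
    scheme collapses intermediate+unbalanced into unbalanced at |v| >= 0.5.
    Sex bias is flagged only beyond |v| > 2.
    """
    if not np.isfinite(log2fm):
        raise ValidationError(f"non-finite log2(f:m): {log2fm}")
    a = abs(log2fm)
    if scheme == "four":
        if a <= 0.25:
            value = "fully_balanced"
        elif a <= 0.5:
            value = "partially_balanced"
        elif a < 0.75:
            value = "intermediate"
        else:
            value = "unbalanced"
    elif scheme == "three":
        if a <= 0.25:
            value = "fully_balanced"
        elif a <= 0.5:
            value = "partially_balanced"
        else:
            value = "unbalanced"
    else:
        raise ValidationError(f"unknown scheme {scheme!r}")
    if log2fm > 2:
        bias = "female"
    elif log2fm < -2:
        bias = "male"
    else:
        bias = "none"
    return BalanceClass(value=value, sex_bias=bias)


def classify_balance_table(log2fm: pd.Series, scheme: str = "four") -> pd.DataFrame:
    """Vector version; NaN inputs are carried through as unevaluable rows."""
    rows = []
    for gid, v in log2fm.items():
        if pd.isna(v):
            rows.append((gid, np.nan, "unevaluable", "none"))
        else:
            c = classify_balance(float(v), scheme=scheme)
            rows.append((gid, float(v), c.value, c.sex_bias))
    return pd.DataFrame(rows, columns=["gene_id", "log2_fm", "balance", "sex_bias"])


def za_ratio(values: pd.Series, gene_chrom: pd.Series, sex_chromosome: str,
             mode: str = "linear") -> dict:
    """Z:A ratio of one sex's per-gene expression summaries.

    mode "linear": median(values on Z) / median(values on A);
    mode "as_stated": median(log2 values on Z) / median(log2 values on A)
    (the formula as printed; retained for fidelity). Reported per autosome
    and pooled over all autosomes; zero denominators are flagged NaN.
    """
    if mode not in ("linear", "as_stated"):
        raise ValidationError(f"unknown za_ratio mode {mode!r}")
    chrom = gene_chrom.reindex(values.index)
    on_z = chrom == sex_chromosome
    if on_z.sum() == 0:
        raise ValidationError("no Z-linked genes")
    if (~on_z).sum() == 0:
        raise ValidationError("no autosomal genes")

    def summarise(v: pd.Series) -> float:
        if mode == "linear":
            return float(v.median())
        v = v[v > 0]
        return float(np.median(np.log2(v)))

    z_stat = summarise(values[on_z])
    out: dict[str, float] = {}
    for a in sorted(chrom[~on_z].dropna().unique()):
        denom = summarise(values[chrom == a])
        out[f"Z:{a}"] = z_stat / denom if denom != 0 else np.nan
    denom = summarise(values[~on_z])
    out["pooled"] = z_stat / denom if denom != 0 else np.nan
    return out


def bootstrap_ratio_ci(values: np.ndarray, statistic=None, n_boot: int = 10_000,
                       seed: int = 0, label: str = "", scale: str = "linear"
                       ) -> RatioEstimate:
    """Feature-level percentile bootstrap of a summary statistic.

    Features (rows of ``values``) are resampled with replacement; the point
    estimate is the median of the bootstrap distribution and the CI its
    2.5/97.5 percentiles. ``statistic`` must accept a 2-D array and an
    ``axis`` keyword (default: the median).
    """
    if n_boot < 1:
        raise ValidationError("n_boot must be >= 1")
    values = np.asarray(values, dtype=float)
    n = values.shape[0]
    if n < 2:
        raise ValidationError("need >= 2 features to bootstrap")
    statistic = np.median if statistic is None else statistic
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(n_boot, n))
    boot = statistic(values[idx], axis=1)
    lo, est, hi = np.percentile(boot, [2.5, 50.0, 97.5])
    return RatioEstimate(
        label=label, estimate=float(est), ci_low=float(lo), ci_high=float(hi),
        n_features=n, n_boot=n_boot, scale=scale,
    )


def median_linear_fm(log2fm: pd.Series) -> float:
    """Headline statistic: back-transformed median of per-gene log2(f:m)."""
    v = log2fm.dropna().to_numpy()
    if len(v) == 0:
        raise ValidationError("no evaluable genes")
    return float(2.0 ** np.median(v))
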