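"""Sliding-window and autocorrelation scans along the Z chromosome.

Window schemes: coordinate windows of 688 kb (the PAR size) stepped 344 kb
or 1 Mb stepped 100 kb, and disjoint blocks of 15 expressed genes
(mimicking the expressed-gene count of the PAR). Per-window tests: Fisher's
exact test for enrichment/depletion of dosage-compensated genes, Wilcoxon
tests on f vs m peak heights, with Bonferroni correction per
(chromosome, scheme) family; plus a lag autocorrelation scan.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from zdose.datamodel import ValidationError


def make_windows(chrom_length: int, size: int, step: int) -> pd.DataFrame:
    """Coordinate windows starting at 0, ``step`` apart; the last window may
    be truncated at the chromosome end; a size larger than the chromosome
    yields a single whole-chromosome window."""
    if step <= 0:
        raise ValidationError("step must be > 0")
    if size >= chrom_length:
        return pd.DataFrame({"start": [0], "end": [chrom_length]})
    starts, ends = [], []
    s = 0
    while True:
        e = min(s + size, chrom_length)
        starts.append(s)
        ends.append(e)
        if e >= chrom_length:
            break
        s += step
    return pd.DataFrame({"start": starts, "end": ends})


def make_gene_windows(genes: pd.DataFrame, k: int = 15) -> pd.DataFrame:
    """Disjoint consecutive blocks of ``k`` genes in positional order; the
    final partial block is kept and flagged."""
    if k < 1:
        raise ValidationError("k must be >= 1")
    ordered = genes.sort_values("start").reset_index(drop=True)
    rows = []
    for i in range(0, len(ordered), k):
        block = ordered.iloc[i:i + k]
        rows.append((
            int(block["start"].min()), int(block["end"].max()),
            list(block["gene_id"]), len(block) < k,
        ))
    return pd.DataFrame(rows, columns=["start", "end", "gene_ids", "partial"])


def fisher_two_sided_p(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p for the 2x2 table [[a, b], [c, d]] by summing
    hypergeometric point probabilities <= the observed one (the standard
    two-sided definition, computed directly from the hypergeometric pmf)."""
    n = a + b + c + d
    K = a + b          # row 1 total (e.g. in-window genes)
    N1 = a + c         # column 1 total (e.g. balanced genes)
    kmin = max(0, K - (n - N1))
    kmax = min(K, N1)
    support = np.arange(kmin, kmax + 1)
    pmf = stats.hypergeom.pmf(support, n, N1, K)
    p_obs = stats.hypergeom.pmf(a, n, N1, K)
    return float(min(1.0, pmf[pmf <= p_obs * (1 + 1e-7)].sum()))


def fisher_window_scan(genes: pd.DataFrame, windows: pd.DataFrame,
                       balanced_col: str = "balanced", alpha: float = 0.05,
                       alternative: str = "two-sided") -> pd.DataFrame:
    """Per-window Fisher's exact test for enrichment/depletion of balanced
    genes (2x2: balanced vs not x in-window vs out), Bonferroni-corrected
    over the windows of the scheme.

    ``genes`` needs ``start`` (position) and a boolean ``balanced`` column.
    Direction is read off the odds ratio; empty windows get p = 1 and
    direction ``none``.
    """
    n_bal = int(genes[balanced_col].sum())
    n_not = int((~genes[balanced_col]).sum())
    if n_bal == 0 or n_not == 0:
        # degenerate margin: every window is uninformative
        out = windows.copy()
        out["n_genes"] = 0
        out["n_balanced"] = 0
        out["p"] = 1.0
        out["p_adjusted"] = 1.0
        out["direction"] = "none"
        return _fill_window_counts(genes, out, balanced_col)
    pos = genes["start"].to_numpy()
    bal = genes[balanced_col].to_numpy(dtype=bool)
    rows = []
    for w in windows.itertuples(index=False):
        in_w = (pos >= w.start) & (pos < w.end)
        a = int((bal & in_w).sum())       # balanced in window
        b = int((~bal & in_w).sum())
        c = n_bal - a
        d = n_not - b
        if a + b == 0:
            rows.append((a + b, a, 1.0, "none"))
            continue
        if alternative == "two-sided":
            p = fisher_two_sided_p(a, b, c, d)
        else:
            _, p = stats.fisher_exact([[a, b], [c, d]], alternative=alternative)
        odds = (a * d) - (b * c)
        direction = "enriched" if odds > 0 else ("depleted" if odds < 0 else "none")
        rows.append((a + b, a, float(p), direction))
    out = windows.copy().reset_index(drop=True)
    res = pd.DataFrame(rows, columns=["n_genes", "n_balanced", "p", "direction"])
    out = pd.concat([out, res], axis=1)
    n_tests = len(out)
    out["p_adjusted"] = np.minimum(1.0, out["p"] * n_tests)
    out["significant"] = out["p_adjusted"] <= alpha
    return out


def _fill_window_counts(genes, out, balanced_col):
    pos = genes["start"].to_numpy()
    bal = genes[balanced_col].to_numpy(dtype=bool)
    for i, w in enumerate(out.itertuples(index=False)):
        in_w = (pos >= w.start) & (pos < w.end)
        out.loc[i, "n_genes"] = int(in_w.sum())
        out.loc[i, "n_balanced"] = int((bal & in_w).sum())
    out["significant"] = False
    return out


def wilcoxon_window_scan(peaks: pd.DataFrame, f_heights: pd.DataFrame,
                         m_heights: pd.DataFrame, windows: pd.DataFrame,
                         alternative: str = "two-sided",
                         min_nonzero: int = 3,
                         method: str = "rank_sum") -> pd.DataFrame:
    """Per-window Wilcoxon comparison of female vs male peak heights.

    ``peaks`` holds per-peak coordinates (``start``); ``f_heights`` /
    ``m_heights`` are peak x sample height matrices aligned to it. Windows
    in which fewer than ``min_nonzero`` individuals of either sex have
    non-zero values are untested (p = NaN). ``method`` selects the rank-sum
    (Mann-Whitney, pooled heights) or signed-rank (paired per-peak medians)
    flavour. Bonferroni adjustment over the tested windows.
    """
    pos = peaks["start"].to_numpy()
    rows = []
    for w in windows.itertuples(index=False):
        in_w = (pos >= w.start) & (pos < w.end)
        if not in_w.any():
            rows.append((0, np.nan, "untested"))
            continue
        F = f_heights.loc[in_w].to_numpy(dtype=float)
        M = m_heights.loc[in_w].to_numpy(dtype=float)
        nz_f = int((np.nan_to_num(F) > 0).any(axis=0).sum())
        nz_m = int((np.nan_to_num(M) > 0).any(axis=0).sum())
        if nz_f < min_nonzero or nz_m < min_nonzero:
            rows.append((int(in_w.sum()), np.nan, "untested"))
            continue
        fv = F[np.isfinite(F)]
        mv = M[np.isfinite(M)]
        if method == "rank_sum":
            _, p = stats.mannwhitneyu(fv, mv, alternative=alternative)
        elif method == "signed_rank":
            fmed = np.nanmedian(F, axis=1)
            mmed = np.nanmedian(M, axis=1)
            ok = np.isfinite(fmed) & np.isfinite(mmed)
            diffs = fmed[ok] - mmed[ok]
            if len(diffs) < 1 or np.all(diffs == 0):
                rows.append((int(in_w.sum()), 1.0, "none"))
                continue
            _, p = stats.wilcoxon(diffs, alternative=alternative)
        else:
            raise ValidationError(f"unknown method {method!r}")
        med_f, med_m = np.nanmedian(fv), np.nanmedian(mv)
        direction = "female_bias" if med_f > med_m else (
            "male_bias" if med_m > med_f else "none"
        )
        rows.append((int(in_w.sum()), float(p), direction))
    out = windows.copy().reset_index(drop=True)
    res = pd.DataFrame(rows, columns=["n_peaks", "p", "direction"])
    out = pd.concat([out, res], axis=1)
    tested = out["p"].notna()
    out["p_adjusted"] = np.nan
    out.loc[tested, "p_adjusted"] = np.minimum(
        1.0, out.loc[tested, "p"] * int(tested.sum())
    )
    out["significant"] = out["p_adjusted"] <= 0.05
    return out


def acf_scan(values: np.ndarray, max_lag: int) -> pd.DataFrame:
    """Sample autocorrelation of positionally ordered values at lags
    1..max_lag with +-1.96/sqrt(n) significance bounds; lags beyond n - 2
    are omitted. A constant series has no defined autocorrelation."""
    v = np.asarray(values, dtype=float)
    if len(v) < 10:
        raise ValidationError("need >= 10 values for the ACF scan")
    if not np.all(np.isfinite(v)):
        raise ValidationError("non-finite values in ACF input")
    if np.var(v) == 0:
        raise ValidationError("constant series: autocorrelation undefined")
    n = len(v)
    max_lag = min(max_lag, n - 2)
    x = v - v.mean()
    denom = float(np.dot(x, x))
    lags = np.arange(1, max_lag + 1)
    acf = np.array([np.dot(x[:-k], x[k:]) / denom for k in lags])
    bound = 1.96 / np.sqrt(n)
    return pd.DataFrame({
        "lag": lags, "acf": acf, "bound_low": -bound, "bound_high": bound,
        "significant": np.abs(acf) > bound,
    })
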