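"""5mC methylation analysis.

CpG-island calling by threshold scan (length > 250 bp, GC > 60%, CpG
observed/expected > 0.75), coverage-filtered feature-level methylation,
bootstrap f:m divergence, per-feature beta-binomial regression with a Wald
test on the sex effect, and methylation profiles across peak flanks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, special, stats
from statsmodels.stats.multitest import multipletests

from zdose.datamodel import GenomeLayout, ValidationError


# ---------------------------------------------------------------------------
# CpG islands
# ---------------------------------------------------------------------------

def _seq_stats(seq: np.ndarray, start: int, end: int,
               cum_c, cum_g, cum_cg) -> tuple[float, float]:
    """(gc_fraction, observed/expected CpG) of seq[start:end] via cumsums."""
    L = end - start
    c = cum_c[end] - cum_c[start]
    g = cum_g[end] - cum_g[start]
    cg = cum_cg[end - 1] - cum_cg[start] if end - 1 > start else 0
    gc = (c + g) / L
    oe = (cg * L) / (c * g) if c > 0 and g > 0 else 0.0
    return gc, oe


def call_cpg_islands(sequence: str, min_len: int = 250, gc_min: float = 0.60,
                     oe_min: float = 0.75, window: int = 200,
                     step: int = 1) -> pd.DataFrame:
    """Deterministic CpG-island caller.

    Slides a 200-bp window (step 1 bp) scoring GC fraction and CpG O/E =
    (#CG x L) / (#C x #G); qualifying windows are merged, and merged
    segments are reported only if they re-verify all three thresholds
    (length > min_len, GC > gc_min, O/E > oe_min) when recomputed over the
    whole segment. Returns ``start, end, gc_frac, oe_ratio``.
    """
    s = np.frombuffer(sequence.upper().encode(), dtype="S1")
    n = len(s)
    cols = ["start", "end", "gc_frac", "oe_ratio"]
    if n < window:
        return pd.DataFrame(columns=cols)
    is_c = (s == b"C").astype(np.int64)
    is_g = (s == b"G").astype(np.int64)
    is_cg = np.zeros(n, dtype=np.int64)
    if n > 1:
        is_cg[:-1] = (s[:-1] == b"C") & (s[1:] == b"G")
    cum_c = np.concatenate([[0], np.cumsum(is_c)])
    cum_g = np.concatenate([[0], np.cumsum(is_g)])
    cum_cg = np.concatenate([[0], np.cumsum(is_cg)])

    starts = np.arange(0, n - window + 1, step)
    c_w = cum_c[starts + window] - cum_c[starts]
    g_w = cum_g[starts + window] - cum_g[starts]
    cg_w = cum_cg[starts + window - 1] - cum_cg[starts]
    gc_w = (c_w + g_w) / window
    with np.errstate(divide="ignore", invalid="ignore"):
        oe_w = np.where(
            (c_w > 0) & (g_w > 0), cg_w * window / (c_w * g_w), 0.0
        )
    ok = (gc_w > gc_min) & (oe_w > oe_min)
    if not ok.any():
        return pd.DataFrame(columns=cols)
    # merge overlapping/adjacent qualifying windows into segments
    rows = []
    ok_starts = starts[ok]
    seg_s, seg_e = int(ok_starts[0]), int(ok_starts[0]) + window
    for st in ok_starts[1:]:
        if st <= seg_e:
            seg_e = int(st) + window
        else:
            rows.append((seg_s, seg_e))
            seg_s, seg_e = int(st), int(st) + window
    rows.append((seg_s, seg_e))
    out = []
    for seg_s, seg_e in rows:
        # trim to the maximal qualifying extent: merged unions bleed into
        # the background, so shrink 1 bp per side until the segment itself
        # passes both composition thresholds
        while seg_e - seg_s > min_len:
            gc, oe = _seq_stats(s, seg_s, seg_e, cum_c, cum_g, cum_cg)
            if gc > gc_min and oe > oe_min:
                break
            seg_s += 1
            seg_e -= 1
        if seg_e - seg_s <= min_len:
            continue
        gc, oe = _seq_stats(s, seg_s, seg_e, cum_c, cum_g, cum_cg)
        if gc > gc_min and oe > oe_min:
            out.append((seg_s, seg_e, gc, oe))
    return pd.DataFrame(out, columns=cols)


# ---------------------------------------------------------------------------
# feature-level methylation
# ---------------------------------------------------------------------------

def _mask_positions(calls: pd.DataFrame, masks: pd.DataFrame) -> pd.DataFrame:
    """Drop CpG calls falling inside any masked interval (chrom,start,end)."""
    keep = np.ones(len(calls), dtype=bool)
    for chrom, grp in masks.groupby("chrom"):
        iv = grp.sort_values("start")[["start", "end"]].to_numpy()
        # merge to non-overlapping intervals for searchsorted lookup
        merged = []
        for st, en in iv:
            if merged and st <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], en)
            else:
                merged.append([st, en])
        merged = np.asarray(merged)
        sel = calls["chrom"] == chrom
        pos = calls.loc[sel, "pos"].to_numpy()
        j = np.searchsorted(merged[:, 0], pos, side="right") - 1
        inside = (j >= 0) & (pos < merged[np.clip(j, 0, None), 1])
        keep[np.where(sel)[0][inside]] = False
    return calls.loc[keep]


def feature_methylation(calls: pd.DataFrame, features: pd.DataFrame,
                        min_cov: int = 10, masks: pd.DataFrame | None = None,
                        layout: GenomeLayout | None = None,
                        relaxed_z_min_cov: int | None = None) -> pd.DataFrame:
    """Cumulative-count methylation per feature for one sample.

    CpGs inside exclusion masks are removed; CpGs with coverage below
    ``min_cov`` reads are removed (optionally relaxed to
    ``relaxed_z_min_cov`` on the Z chromosome, for the single-copy female
    Z). The proportion is cumulative methylated / cumulative total over the
    retained CpGs; features with no retained CpG are missing (NaN), not 0.

    ``features`` needs ``feature_id, chrom, start, end``.
    """
    if min_cov < 1:
        raise ValidationError("min_cov must be >= 1")
    if masks is not None and len(masks):
        calls = _mask_positions(calls, masks)
    cov_ok = calls["n_total"] >= min_cov
    if relaxed_z_min_cov is not None:
        if layout is None:
            raise ValidationError("relaxed Z threshold requires a layout")
        on_z = calls["chrom"] == layout.sex_chromosome
        cov_ok = cov_ok | (on_z & (calls["n_total"] >= relaxed_z_min_cov))
    calls = calls.loc[cov_ok]
    # sorted positions + cumulative counts per chromosome for O(log n) lookups
    by_chrom = {}
    for chrom, grp in calls.groupby("chrom"):
        grp = grp.sort_values("pos")
        by_chrom[chrom] = (
            grp["pos"].to_numpy(),
            np.concatenate([[0], np.cumsum(grp["n_meth"].to_numpy())]),
            np.concatenate([[0], np.cumsum(grp["n_total"].to_numpy())]),
        )
    rows = []
    for f in features.itertuples(index=False):
        entry = by_chrom.get(f.chrom)
        if entry is None:
            rows.append((f.feature_id, np.nan, 0, 0, 0))
            continue
        pos, cum_m, cum_t = entry
        i = int(np.searchsorted(pos, f.start, side="left"))
        j = int(np.searchsorted(pos, f.end, side="left"))
        n_meth = int(cum_m[j] - cum_m[i])
        n_total = int(cum_t[j] - cum_t[i])
        prop = n_meth / n_total if n_total > 0 else np.nan
        rows.append((f.feature_id, prop, n_meth, n_total, j - i))
    return pd.DataFrame(
        rows, columns=["feature_id", "proportion", "n_meth", "n_total", "n_cpgs"]
    )


def feature_methylation_matrix(callsets: dict[str, pd.DataFrame],
                               features: pd.DataFrame, **kw) -> dict:
    """Per-sample feature methylation; returns dict with ``proportion``,
    ``n_meth`` and ``n_total`` feature x sample DataFrames."""
    per_sample = {
        s: feature_methylation(c, features, **kw).set_index("feature_id")
        for s, c in callsets.items()
    }
    out = {}
    for col in ("proportion", "n_meth", "n_total"):
        out[col] = pd.DataFrame({s: d[col] for s, d in per_sample.items()})
    return out


# ---------------------------------------------------------------------------
# beta-binomial differential methylation
# ---------------------------------------------------------------------------

_RHO_MIN = 1e-6  # dispersion lower bound avoids the binomial boundary


def betabinom_loglik(y, n, mu, rho) -> float:
    """Beta-binomial log-likelihood (up to the binomial coefficient) with
    mean mu and intra-class correlation rho; the rho -> 0 limit is the
    binomial likelihood."""
    a = mu * (1 - rho) / rho
    b = (1 - mu) * (1 - rho) / rho
    return float(np.sum(
        special.betaln(y + a, n - y + b) - special.betaln(a, b)
    ))


def _negll(params, y, n, X):
    k = X.shape[1]
    eta = X @ params[:k]
    mu = special.expit(np.clip(eta, -30, 30))
    mu = np.clip(mu, 1e-8, 1 - 1e-8)
    rho = special.expit(params[k])
    rho = np.clip(rho, _RHO_MIN, 1 - 1e-6)
    a = mu * (1 - rho) / rho
    b = (1 - mu) * (1 - rho) / rho
    ll = np.sum(special.betaln(y + a, n - y + b) - special.betaln(a, b))
    return -ll


def _numeric_hessian(f, x, eps=1e-4):
    k = len(x)
    H = np.zeros((k, k))
    for i in range(k):
        for j in range(i, k):
            ei = np.zeros(k); ei[i] = eps
            ej = np.zeros(k); ej[j] = eps
            H[i, j] = H[j, i] = (
                f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
            ) / (4 * eps * eps)
    return H


@dataclass
class DMLResult:
    feature_id: str
    sex_effect: float      # logit-scale female-vs-male coefficient
    dispersion: float
    wald: float
    p: float
    converged: bool


def beta_binomial_dml(n_meth: pd.DataFrame, n_total: pd.DataFrame,
                      samples: pd.DataFrame, include_tissue: bool = False
                      ) -> pd.DataFrame:
    """Per-feature beta-binomial regression with a Wald test on sex.

    The mean is logit-linear (intercept + sex, optionally + tissue); one
    dispersion per feature, ML-estimated with a small lower bound to avoid
    boundary failures. Features failing convergence are flagged, not
    dropped; all-zero-coverage features are skipped with a flag. BH
    correction across tested features.
    """
    for sex in ("F", "M"):
        if (samples["sex"] == sex).sum() < 2:
            raise ValidationError(f"need >= 2 samples of sex {sex}")
    sample_ids = list(n_meth.columns)
    meta = samples.set_index("sample_id").loc[sample_ids]
    cols = [np.ones(len(sample_ids)), (meta["sex"] == "F").to_numpy(float)]
    if include_tissue:
        tiss = pd.get_dummies(meta["tissue"], drop_first=True)
        for c in tiss.columns:
            cols.append(tiss[c].to_numpy(float))
    X_full = np.column_stack(cols)
    results = []
    for fid in n_meth.index:
        y = n_meth.loc[fid].to_numpy(dtype=float)
        n = n_total.loc[fid].to_numpy(dtype=float)
        ok = np.isfinite(y) & np.isfinite(n) & (n > 0)
        if ok.sum() == 0:
            results.append(DMLResult(fid, np.nan, np.nan, np.nan, np.nan, False))
            continue
        yv, nv, X = y[ok], n[ok], X_full[ok]
        p0 = np.clip(yv.sum() / nv.sum(), 1e-4, 1 - 1e-4)
        x0 = np.zeros(X.shape[1] + 1)
        x0[0] = np.log(p0 / (1 - p0))
        x0[-1] = special.logit(0.05)
        opt = optimize.minimize(
            _negll, x0, args=(yv, nv, X), method="Nelder-Mead",
            options={"maxiter": 2000, "xatol": 1e-6, "fatol": 1e-8},
        )
        opt = optimize.minimize(
            _negll, opt.x, args=(yv, nv, X), method="BFGS",
            options={"maxiter": 500},
        )
        est = opt.x
        sex_idx = 1
        # observed information over the mean coefficients with the
        # dispersion held at its ML estimate; the full Hessian is singular
        # whenever the dispersion sits on its lower bound
        k = X.shape[1]
        rho_hat = float(special.expit(est[-1]))

        def negll_beta(beta):
            return _negll(np.concatenate([beta, [est[-1]]]), yv, nv, X)

        H = _numeric_hessian(negll_beta, est[:k])
        try:
            cov = np.linalg.pinv(H)
            se = np.sqrt(cov[sex_idx, sex_idx]) if cov[sex_idx, sex_idx] > 0 else np.nan
        except np.linalg.LinAlgError:
            se = np.nan
        beta_sex = est[sex_idx]
        converged = bool(np.isfinite(se) and se > 0)
        wald = beta_sex / se if converged else np.nan
        p = 2 * stats.norm.sf(abs(wald)) if converged else np.nan
        results.append(DMLResult(
            fid, float(beta_sex), rho_hat,
            float(wald) if converged else np.nan,
            float(p) if converged else np.nan, converged,
        ))
    df = pd.DataFrame([r.__dict__ for r in results])
    df["q"] = np.nan
    tested = df["p"].notna()
    if tested.any():
        df.loc[tested, "q"] = multipletests(df.loc[tested, "p"], method="fdr_bh")[1]
    return df


# ---------------------------------------------------------------------------
# bootstrap divergence and flank profiles
# ---------------------------------------------------------------------------

def bootstrap_meth_divergence(proportions: pd.DataFrame, samples: pd.DataFrame,
                              n_boot: int = 10_000, seed: int = 0) -> pd.DataFrame:
    """Per-feature median and 95% CI of log2(f:m) and (f - m) divergence.

    Samples are resampled with replacement within sex; per replicate the
    divergences compare the mean female and male proportions. Features
    whose male proportion hits 0 in a replicate get a flagged log2 value
    (NaN) while (f - m) is always reported.
    """
    f_ids = samples.loc[samples["sex"] == "F", "sample_id"]
    m_ids = samples.loc[samples["sex"] == "M", "sample_id"]
    f_ids = [c for c in f_ids if c in proportions.columns]
    m_ids = [c for c in m_ids if c in proportions.columns]
    if not f_ids or not m_ids:
        raise ValidationError("need >= 1 sample with data per sex")
    F = proportions[f_ids].to_numpy(dtype=float)
    M = proportions[m_ids].to_numpy(dtype=float)
    rng = np.random.default_rng(seed)
    fi = rng.integers(0, F.shape[1], size=(n_boot, F.shape[1]))
    mi = rng.integers(0, M.shape[1], size=(n_boot, M.shape[1]))
    # replicate x feature mean proportions
    f_mean = np.nanmean(F[:, fi], axis=2).T  # (n_boot, features)
    m_mean = np.nanmean(M[:, mi], axis=2).T
    diff = f_mean - m_mean
    with np.errstate(divide="ignore", invalid="ignore"):
        log2fm = np.where(m_mean > 0, np.log2(f_mean / m_mean), np.nan)
    out = pd.DataFrame(index=proportions.index)
    import warnings as _warnings
    with _warnings.catch_warnings():
        # features whose male proportion is always 0 have no log2 scale at
        # all; they surface as NaN + the flag, not as a warning
        _warnings.filterwarnings("ignore", "All-NaN slice")
        out["log2_fm"] = np.nanmedian(log2fm, axis=0)
        out["log2_fm_lo"] = np.nanpercentile(log2fm, 2.5, axis=0)
        out["log2_fm_hi"] = np.nanpercentile(log2fm, 97.5, axis=0)
    out["diff_fm"] = np.median(diff, axis=0)
    out["diff_fm_lo"] = np.percentile(diff, 2.5, axis=0)
    out["diff_fm_hi"] = np.percentile(diff, 97.5, axis=0)
    out["log2_flagged"] = np.isnan(log2fm).any(axis=0)
    return out


def flank_methylation_profile(calls: pd.DataFrame, peaks: pd.DataFrame,
                              flank: int = 10_000, n_windows: int = 100,
                              tile: int = 200) -> np.ndarray:
    """Median methylation in tiles across peak-centred flanks.

    The +-``flank`` region around each peak midpoint is divided into
    ``n_windows`` tiles of ``tile`` bp; per tile the median per-CpG
    proportion is taken, and profiles are averaged across peaks (NaN
    tiles ignored).
    """
    if 2 * flank != n_windows * tile:
        raise ValidationError(
            f"flank {flank} inconsistent with {n_windows} x {tile}-bp tiles"
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        prop = calls["n_meth"].to_numpy(float) / calls["n_total"].to_numpy(float)
    profiles = []
    for p in peaks.itertuples(index=False):
        center = (int(p.start) + int(p.end)) // 2
        lo = center - flank
        sel = (calls["chrom"] == p.chrom).to_numpy()
        pos = calls["pos"].to_numpy()
        in_win = sel & (pos >= lo) & (pos < center + flank)
        if not in_win.any():
            continue
        tiles = ((pos[in_win] - lo) // tile).astype(int)
        vals = prop[in_win]
        row = np.full(n_windows, np.nan)
        for t in np.unique(tiles):
            row[t] = np.nanmedian(vals[tiles == t])
        profiles.append(row)
    if not profiles:
        return np.full(n_windows, np.nan)
    with np.errstate(invalid="ignore"):
        return np.nanmean(np.vstack(profiles), axis=0)
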